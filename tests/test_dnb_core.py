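import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnbkit.dnb_core import (
    CriticalityProfile,
    SearchParams,
    criticality_index,
    detect_transition,
    find_dominant_group,
    group_stats,
    jaccard,
    profile_group,
    search_ci_profile,
    timepoint_correlation,
)
from dnbkit.synthetic_data import SimulationConfig, expected_ci, simulate_series

from conftest import brute_pearson, make_series


def random_series(n_genes, n_timepoints, n_replicates, seed):
    rng = np.random.default_rng(seed)
    return make_series(
        rng.normal(size=(n_genes, n_timepoints * n_replicates)), n_timepoints, n_replicates
    )


class TestTimepointCorrelation:
    def test_perfect_linearity(self):
        vals = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        series = make_series(vals, 1, 3)
        tc = timepoint_correlation(series, "T1", ["g001", "g002"])
        assert tc.matrix[0, 1] == pytest.approx(1.0)

    def test_perfect_anti_linearity(self):
        vals = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        series = make_series(vals, 1, 3)
        tc = timepoint_correlation(series, "T1", ["g001", "g002"])
        assert tc.matrix[0, 1] == pytest.approx(-1.0)
        assert abs(tc.matrix[0, 1]) == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        series = random_series(6, 1, 5, seed=12)
        genes = list(series.genes)
        tc = timepoint_correlation(series, "T1", genes)
        x = series.replicate_matrix("T1", genes)
        for i in range(6):
            for j in range(6):
                expected = 1.0 if i == j else brute_pearson(list(x[i]), list(x[j]))
                assert tc.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_unit_diagonal(self):
        series = random_series(8, 1, 6, seed=1)
        tc = timepoint_correlation(series, "T1", list(series.genes))
        np.testing.assert_allclose(tc.matrix, tc.matrix.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(tc.matrix), 1.0)

    def test_two_replicates_error(self):
        series = random_series(3, 1, 2, seed=0)
        with pytest.raises(ValueError, match="3 required"):
            timepoint_correlation(series, "T1", list(series.genes))

    def test_zero_variance_gene_flagged_zero(self):
        vals = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 4.0], [2.0, 1.0, 0.0]])
        series = make_series(vals, 1, 3)
        tc = timepoint_correlation(series, "T1", list(series.genes))
        assert tc.zero_variance.tolist() == [True, False, False]
        assert tc.matrix[0, 1] == 0.0
        assert tc.matrix[2, 0] == 0.0
        assert tc.matrix[0, 0] == 1.0


class TestGroupStats:
    def test_duplicated_rows_pcc_in_one(self):
        rng = np.random.default_rng(5)
        row = rng.normal(size=4)
        vals = np.vstack([row, row, rng.normal(size=4)])
        series = make_series(vals, 1, 4)
        st = group_stats(series, ["g001", "g002"], ["g003"], "T1")
        assert st.pcc_in == pytest.approx(1.0)

    def test_constant_genes_zero_sd_zero_ci(self):
        vals = np.ones((3, 3))
        series = make_series(vals, 1, 3)
        st = group_stats(series, ["g001", "g002"], ["g003"], "T1")
        assert st.sd_in == 0.0
        assert criticality_index(st.sd_in, st.pcc_in, st.pcc_out, 2) == 0.0

    def test_brute_force_oracle(self):
        series = random_series(25, 1, 6, seed=33)
        group = list(series.genes[:5])
        background = list(series.genes[5:])
        st = group_stats(series, group, background, "T1")

        x = series.replicate_matrix("T1", group)
        sds = []
        for row in x:
            m = sum(row) / len(row)
            sds.append((sum((v - m) ** 2 for v in row) / (len(row) - 1)) ** 0.5)
        assert st.sd_in == pytest.approx(sum(sds) / len(sds), abs=1e-12)

        xb = series.replicate_matrix("T1", background)
        pin = [
            abs(brute_pearson(list(x[i]), list(x[j])))
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        pout = [
            abs(brute_pearson(list(x[i]), list(xb[j])))
            for i in range(5)
            for j in range(20)
        ]
        assert st.pcc_in == pytest.approx(sum(pin) / len(pin), abs=1e-12)
        assert st.pcc_out == pytest.approx(sum(pout) / len(pout), abs=1e-12)

    def test_overlap_errors(self):
        series = random_series(4, 1, 3, seed=0)
        with pytest.raises(ValueError, match="overlap"):
            group_stats(series, ["g001", "g002"], ["g002", "g003"], "T1")


class TestCriticalityIndex:
    def test_direct_formula(self):
        assert criticality_index(2.0, 0.8, 0.1, 16) == pytest.approx(64.0)

    def test_zero_sd_annihilates(self):
        assert criticality_index(0.0, 0.9, 0.01, 100) == 0.0

    def test_floor_contract(self):
        value = criticality_index(1.5, 0.6, 0.0, 9, pcc_out_floor=1e-6)
        assert value == pytest.approx(1e6 * 3 * 0.6 * 1.5)

    def test_size_below_two_errors(self):
        with pytest.raises(ValueError):
            criticality_index(1.0, 0.5, 0.5, 1)

    @pytest.mark.parametrize(
        "kwargs", [dict(sd_in=-1.0), dict(pcc_in=1.5), dict(pcc_out=-0.1)]
    )
    def test_domain_errors(self, kwargs):
        args = dict(sd_in=1.0, pcc_in=0.5, pcc_out=0.5, size=4)
        args.update(kwargs)
        with pytest.raises(ValueError):
            criticality_index(**args)

    def test_monotonicity(self):
        base = criticality_index(1.0, 0.5, 0.4, 10)
        assert criticality_index(1.2, 0.5, 0.4, 10) > base
        assert criticality_index(1.0, 0.6, 0.4, 10) > base
        assert criticality_index(1.0, 0.5, 0.5, 10) < base

    @given(
        sd=st.floats(0.0, 100.0),
        pin=st.floats(0.0, 1.0),
        pout=st.floats(0.0, 1.0),
        size=st.integers(2, 10_000),
        c=st.floats(0.001, 1000.0),
    )
    def test_property_nonnegative_and_scale_linear(self, sd, pin, pout, size, c):
        value = criticality_index(sd, pin, pout, size)
        assert value >= 0.0
        scaled = criticality_index(c * sd, pin, pout, size)
        assert scaled == pytest.approx(c * value, rel=1e-9)

    @given(
        sd=st.floats(0.01, 100.0),
        pin=st.floats(0.01, 1.0),
        floor=st.floats(1e-9, 1e-3),
        size=st.integers(2, 10_000),
    )
    def test_property_floor_caps_blowup(self, sd, pin, floor, size):
        # CI at pcc_out = 0 equals CI at pcc_out = floor: the floor is a cap
        at_zero = criticality_index(sd, pin, 0.0, size, pcc_out_floor=floor)
        at_floor = criticality_index(sd, pin, floor, size, pcc_out_floor=floor)
        assert at_zero == pytest.approx(at_floor, rel=1e-12)


class TestInvariants:
    def test_scale_equivariance(self):
        series = random_series(15, 2, 5, seed=21)
        scaled = make_series(series.values * 3.7, 2, 5, genes=list(series.genes))
        group, bg = list(series.genes[:4]), list(series.genes[4:])
        s1 = group_stats(series, group, bg, "T2")
        s2 = group_stats(scaled, group, bg, "T2")
        assert s2.pcc_in == pytest.approx(s1.pcc_in, rel=1e-12)
        assert s2.pcc_out == pytest.approx(s1.pcc_out, rel=1e-12)
        assert s2.sd_in == pytest.approx(3.7 * s1.sd_in, rel=1e-12)
        c1 = criticality_index(s1.sd_in, s1.pcc_in, s1.pcc_out, 4)
        c2 = criticality_index(s2.sd_in, s2.pcc_in, s2.pcc_out, 4)
        assert c2 == pytest.approx(3.7 * c1, rel=1e-12)

    def test_permutation_invariance(self):
        series = random_series(12, 2, 5, seed=2)
        rng = np.random.default_rng(9)
        gperm = rng.permutation(12)
        sperm = rng.permutation(10)
        shuffled = make_series(np.zeros((12, 10)), 2, 5)
        shuffled.genes = [series.genes[i] for i in gperm]
        shuffled.samples = [series.samples[j] for j in sperm]
        shuffled.values = series.values[np.ix_(gperm, sperm)]
        shuffled.timepoint_of = series.timepoint_of
        shuffled.replicate_of = series.replicate_of
        shuffled.timepoint_order = series.timepoint_order
        shuffled._gene_index = {g: i for i, g in enumerate(shuffled.genes)}
        group, bg = list(series.genes[:5]), list(series.genes[5:])
        s1 = group_stats(series, group, bg, "T1")
        s2 = group_stats(shuffled, group, bg, "T1")
        assert s1.sd_in == pytest.approx(s2.sd_in, rel=1e-12)
        assert s1.pcc_in == pytest.approx(s2.pcc_in, rel=1e-12)
        assert s1.pcc_out == pytest.approx(s2.pcc_out, rel=1e-12)


class TestFindDominantGroup:
    def test_recovers_planted_transition(self):
        for seed in (0, 1, 2):
            cfg = SimulationConfig.strong_effect(seed=seed)
            series, truth = simulate_series(cfg)
            res = find_dominant_group(series, series.genes, SearchParams())
            assert res.found
            assert res.critical_timepoint == truth.t_star
            assert jaccard(res.group, truth.dnb_genes) >= 0.6
            assert res.profile is not None
            assert len(res.diagnostics) > 0

    def test_no_cluster_returns_structured_result(self):
        # independent genes with a tiny cut height: nothing ever clusters
        cfg = SimulationConfig.null_effect(seed=0)
        series, _ = simulate_series(cfg)
        res = find_dominant_group(
            series, series.genes, SearchParams(cut_height=0.01, min_group_size=5)
        )
        assert not res.found
        assert res.group == ()
        assert res.profile is None
        assert res.critical_timepoint is None

    def test_too_few_candidates_errors(self):
        cfg = SimulationConfig.null_effect(seed=0)
        series, _ = simulate_series(cfg)
        with pytest.raises(ValueError, match="min_group_size"):
            find_dominant_group(series, series.genes[:3], SearchParams(min_group_size=5))

    def test_background_candidates_mode(self):
        cfg = SimulationConfig.strong_effect(seed=0)
        series, truth = simulate_series(cfg)
        res = find_dominant_group(
            series, series.genes[:40], SearchParams(background="candidates")
        )
        assert res.found
        assert set(res.group) <= set(series.genes[:40])

    def test_search_ci_profile_covers_timepoints(self):
        cfg = SimulationConfig.strong_effect(seed=0)
        series, truth = simulate_series(cfg)
        res = find_dominant_group(series, series.genes, SearchParams())
        prof = search_ci_profile(res)
        assert set(prof) <= set(series.timepoints)
        best_tp = max(prof, key=lambda t: prof[t])
        assert best_tp == res.critical_timepoint


def make_profile(ci, timepoints=None):
    ci = np.asarray(ci, dtype=float)
    n = len(ci)
    timepoints = timepoints or [f"T{i + 1}" for i in range(n)]
    return CriticalityProfile(
        group=("a", "b"),
        timepoints=timepoints,
        sd_in=np.ones(n),
        pcc_in=np.full(n, 0.5),
        pcc_out=np.full(n, 0.5),
        ci=ci,
        floor_engaged=np.zeros(n, dtype=bool),
    )


class TestDetectTransition:
    def test_argmax(self):
        call = detect_transition(make_profile([1, 2, 9, 3, 2]))
        assert call.found and call.timepoint == "T3" and not call.tied

    def test_tie_earliest_flagged(self):
        call = detect_transition(make_profile([4, 4, 4]))
        assert call.found and call.timepoint == "T1" and call.tied

    def test_all_zero_is_no_transition(self):
        call = detect_transition(make_profile([0, 0, 0]))
        assert not call.found and call.timepoint is None

    def test_single_timepoint_errors(self):
        with pytest.raises(ValueError):
            detect_transition(make_profile([1.0]))

    def test_closed_form_profile_peaks_at_t_star(self):
        cfg = SimulationConfig.strong_effect()
        ci = [expected_ci(cfg, t) for t in range(1, cfg.n_timepoints + 1)]
        call = detect_transition(make_profile(ci))
        assert call.found
        assert call.index == cfg.t_star - 1


class TestJaccard:
    def test_values(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert jaccard(set(), set()) == 1.0
        assert jaccard({"a"}, set()) == 0.0
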