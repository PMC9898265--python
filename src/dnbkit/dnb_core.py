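"""Per-timepoint group statistics, the criticality index, and dominant-group search.

For a gene group G at one timepoint (statistics taken across that
timepoint's replicates):

* ``SD_in``  -- mean per-gene sample standard deviation (n-1 denominator);
* ``PCC_in`` -- mean absolute Pearson correlation over within-group pairs;
* ``PCC_out`` -- mean absolute Pearson correlation over group x background
  pairs;
* ``CI = sqrt(|G|) * (PCC_in / PCC_out) * SD_in``.

A rising CI marks a group whose members fluctuate strongly and coherently
while decoupling from the rest of the system -- the operational signature
of an approaching state transition. The dominant group is found per
timepoint by average-linkage hierarchical clustering of candidates on the
distance ``1 - |PCC|``, scoring every cluster above a minimum size and
taking the (cluster, timepoint) pair with the globally maximal CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from dnbkit.io_expr import ExpressionSeries

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class TimepointCorrelation:
    """Correlation of a gene set across one timepoint's replicates."""

    genes: list[str]
    matrix: np.ndarray
    zero_variance: np.ndarray  # bool mask per gene


@dataclass(frozen=True)
class GroupStats:
    sd_in: float
    pcc_in: float
    pcc_out: float


@dataclass
class CriticalityProfile:
    """Per-timepoint (SD_in, PCC_in, PCC_out, CI) for one gene group."""

    group: tuple[str, ...]
    timepoints: list[str]
    sd_in: np.ndarray
    pcc_in: np.ndarray
    pcc_out: np.ndarray
    ci: np.ndarray
    floor_engaged: np.ndarray  # bool per timepoint

    @property
    def size(self) -> int:
        return len(self.group)


@dataclass(frozen=True)
class ClusterScore:
    """Diagnostics for one evaluated (cluster, timepoint) pair."""

    timepoint: str
    genes: tuple[str, ...]
    stats: GroupStats
    ci: float


@dataclass
class DNBResult:
    """Outcome of the dominant-group search."""

    found: bool
    group: tuple[str, ...]
    profile: CriticalityProfile | None
    critical_timepoint: str | None
    diagnostics: list[ClusterScore] = field(default_factory=list)
    members: list | None = None  # list[RankedGene] once ranking has run


@dataclass(frozen=True)
class TransitionCall:
    found: bool
    timepoint: str | None
    index: int | None  # position within the profile's timepoints
    tied: bool


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the dominant-group search; all exposed on the CLI."""

    min_group_size: int = 5
    cut_height: float = 0.5
    pcc_out_floor: float = 1e-6
    background: str = "all"  # or "candidates"

    def __post_init__(self) -> None:
        if self.min_group_size < 2:
            raise ValueError("min_group_size must be >= 2")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")
        if self.pcc_out_floor <= 0:
            raise ValueError("pcc_out_floor must be positive")
        if self.background not in ("all", "candidates"):
            raise ValueError("background must be 'all' or 'candidates'")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def timepoint_correlation(
    series: ExpressionSeries, timepoint: str, genes: Sequence[str]
) -> TimepointCorrelation:
    """Pearson correlation of every gene pair across one timepoint's replicates.

    Requires >= 3 replicates (with 2, every correlation is +-1). Genes with
    zero variance at the timepoint get correlation 0 against everything
    (unit diagonal retained) and are flagged, not dropped.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a correlation matrix")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in correlation request")
    x = series.replicate_matrix(timepoint, genes)
    if x.shape[1] < 3:
        raise ValueError(
            f"timepoint {timepoint!r} has {x.shape[1]} replicates; >= 3 required"
        )
    zero_var = x.std(axis=1, ddof=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(x)
    corr = np.clip(corr, -1.0, 1.0)
    if zero_var.any():
        log.warning(
            "%d zero-variance gene(s) at timepoint %s; their correlations set to 0",
            int(zero_var.sum()),
            timepoint,
        )
        corr[zero_var, :] = 0.0
        corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, 1.0)
    return TimepointCorrelation(genes=genes, matrix=corr, zero_variance=zero_var)


def group_stats(
    series: ExpressionSeries,
    group: Sequence[str],
    background: Sequence[str],
    timepoint: str,
) -> GroupStats:
    """(SD_in, PCC_in, PCC_out) of ``group`` vs ``background`` at one timepoint."""
    group = series.order_genes(group)
    background = series.order_genes(background)
    overlap = set(group) & set(background)
    if overlap:
        raise ValueError(f"group and background overlap: {sorted(overlap)[:5]}")
    if len(group) < 2:
        raise ValueError("group must have >= 2 genes")
    if len(background) < 1:
        raise ValueError("background must have >= 1 gene")

    g = len(group)
    tc = timepoint_correlation(series, timepoint, list(group) + list(background))
    absc = np.abs(tc.matrix)

    x = series.replicate_matrix(timepoint, group)
    sd_in = float(x.std(axis=1, ddof=1).mean())

    iu = np.triu_indices(g, k=1)
    pcc_in = float(absc[:g, :g][iu].mean())
    pcc_out = float(absc[:g, g:].mean())
    return GroupStats(sd_in=sd_in, pcc_in=pcc_in, pcc_out=pcc_out)


def criticality_index(
    sd_in: float,
    pcc_in: float,
    pcc_out: float,
    size: int,
    pcc_out_floor: float = 1e-6,
) -> float:
    """``sqrt(size) * (pcc_in / max(pcc_out, floor)) * sd_in``.

    The floor guards against division blow-up when the group is essentially
    uncorrelated with the background; engagement is logged.
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    if sd_in < 0:
        raise ValueError("sd_in must be >= 0")
    if not (0 <= pcc_in <= 1 and 0 <= pcc_out <= 1):
        raise ValueError("pcc_in and pcc_out must lie in [0, 1]")
    if pcc_out < pcc_out_floor:
        log.warning(
            "PCC_out %.3g below floor %.3g; floor engaged", pcc_out, pcc_out_floor
        )
    return float(np.sqrt(size) * (pcc_in / max(pcc_out, pcc_out_floor)) * sd_in)


def profile_group(
    series: ExpressionSeries,
    group: Sequence[str],
    background: Sequence[str] | None = None,
    pcc_out_floor: float = 1e-6,
) -> CriticalityProfile:
    """Criticality profile of one group over every timepoint of the series.

    ``background`` defaults to all genes outside the group.
    """
    group = tuple(series.order_genes(group))
    if background is None:
        background = [g for g in series.genes if g not in set(group)]
    tps = series.timepoints
    sd_in = np.empty(len(tps))
    pcc_in = np.empty(len(tps))
    pcc_out = np.empty(len(tps))
    ci = np.empty(len(tps))
    floored = np.zeros(len(tps), dtype=bool)
    for i, tp in enumerate(tps):
        st = group_stats(series, group, background, tp)
        sd_in[i], pcc_in[i], pcc_out[i] = st.sd_in, st.pcc_in, st.pcc_out
        floored[i] = st.pcc_out < pcc_out_floor
        ci[i] = criticality_index(st.sd_in, st.pcc_in, st.pcc_out, len(group), pcc_out_floor)
    return CriticalityProfile(
        group=group,
        timepoints=list(tps),
        sd_in=sd_in,
        pcc_in=pcc_in,
        pcc_out=pcc_out,
        ci=ci,
        floor_engaged=floored,
    )


# ---------------------------------------------------------------------------
# dominant-group search
# ---------------------------------------------------------------------------


def _clusters_at(
    corr: np.ndarray, genes: list[str], cut_height: float, min_size: int
) -> list[tuple[str, ...]]:
    """Average-linkage clusters of genes on distance 1 - |PCC|, cut at height."""
    d = 1.0 - np.abs(corr)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=cut_height, criterion="distance")
    by_label: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        by_label.setdefault(int(lab), []).append(g)
    clusters = [tuple(members) for members in by_label.values() if len(members) >= min_size]
    clusters.sort(key=lambda c: c[0])  # deterministic evaluation order
    return clusters


def find_dominant_group(
    series: ExpressionSeries,
    candidates: Sequence[str],
    params: SearchParams = SearchParams(),
) -> DNBResult:
    """Search every timepoint for the gene cluster with the maximal CI.

    Per timepoint: cluster the candidates on 1 - |PCC| (average linkage,
    cut at ``params.cut_height``), score every cluster of at least
    ``params.min_group_size`` genes against the background (all non-cluster
    genes by default, or non-cluster candidates), and keep full diagnostics.
    The dominant group is the globally best (cluster, timepoint) pair; its
    timepoint is the critical timepoint. Returns a structured "not found"
    result when no cluster meets the size threshold anywhere.
    """
    candidates = series.order_genes(set(candidates))
    if len(candidates) < params.min_group_size:
        raise ValueError(
            f"{len(candidates)} candidate(s) but min_group_size={params.min_group_size}"
        )
    min_rep = min(series.n_replicates(t) for t in series.timepoints)
    if min_rep < 5:
        log.warning(
            "only %d replicates at some timepoints; correlation estimates will be noisy",
            min_rep,
        )

    diagnostics: list[ClusterScore] = []
    best: ClusterScore | None = None
    for tp in series.timepoints:
        tc = timepoint_correlation(series, tp, candidates)
        for cluster in _clusters_at(tc.matrix, candidates, params.cut_height, params.min_group_size):
            in_cluster = set(cluster)
            if params.background == "all":
                bg = [g for g in series.genes if g not in in_cluster]
            else:
                bg = [g for g in candidates if g not in in_cluster]
            if not bg:
                continue
            st = group_stats(series, cluster, bg, tp)
            ci = criticality_index(
                st.sd_in, st.pcc_in, st.pcc_out, len(cluster), params.pcc_out_floor
            )
            score = ClusterScore(timepoint=tp, genes=cluster, stats=st, ci=ci)
            diagnostics.append(score)
            if best is None or ci > best.ci:  # strict >: ties keep the earliest
                best = score

    if best is None:
        log.info("no cluster met min_group_size=%d at any timepoint", params.min_group_size)
        return DNBResult(found=False, group=(), profile=None, critical_timepoint=None,
                         diagnostics=diagnostics)

    if params.background == "all":
        bg = [g for g in series.genes if g not in set(best.genes)]
    else:
        bg = [g for g in candidates if g not in set(best.genes)]
    profile = profile_group(series, best.genes, bg, params.pcc_out_floor)
    return DNBResult(
        found=True,
        group=tuple(series.order_genes(best.genes)),
        profile=profile,
        critical_timepoint=best.timepoint,
        diagnostics=diagnostics,
    )


def detect_transition(profile: CriticalityProfile) -> TransitionCall:
    """Locate the CI peak of a profile: argmax, ties broken earliest (flagged)."""
    ci = np.asarray(profile.ci, dtype=float)
    if ci.size < 2:
        raise ValueError("CI must be defined for at least 2 timepoints")
    if np.all(ci == 0):
        return TransitionCall(found=False, timepoint=None, index=None, tied=False)
    idx = int(np.argmax(ci))  # argmax returns the first maximum
    tied = int((ci == ci[idx]).sum()) > 1
    if tied:
        log.info("CI maximum tied across timepoints; earliest (%s) reported",
                 profile.timepoints[idx])
    return TransitionCall(found=True, timepoint=profile.timepoints[idx], index=idx, tied=tied)


def search_ci_profile(result: DNBResult) -> dict[str, float | None]:
    """Best cluster CI per timepoint, from the search diagnostics.

    Every timepoint is subjected to the same clustering-and-maximization
    pressure, so under a null (no planted structure) this profile is flat;
    a genuine transition shows up as a sharp peak. Timepoints where no
    cluster met the size threshold map to ``None``.
    """
    out: dict[str, float | None] = {}
    for score in result.diagnostics:
        cur = out.get(score.timepoint)
        if cur is None or score.ci > cur:
            out[score.timepoint] = score.ci
    return out


def jaccard(a: set[str] | Sequence[str], b: set[str] | Sequence[str]) -> float:
    """Jaccard similarity of two gene sets (1.0 for two empty sets)."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
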