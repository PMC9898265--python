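import numpy as np
import pytest

from dnbkit.io_expr import ExpressionSeries


def make_series(values, n_timepoints, n_replicates, genes=None, scale="raw"):
    """Build an ExpressionSeries from a dense matrix laid out timepoint-major."""
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    assert values.shape[1] == n_timepoints * n_replicates
    genes = genes or [f"g{i + 1:03d}" for i in range(n_genes)]
    labels = [f"T{t}" for t in range(1, n_timepoints + 1)]
    samples, timepoint_of, replicate_of = [], {}, {}
    for tp in labels:
        for r in range(1, n_replicates + 1):
            s = f"{tp}_r{r}"
            samples.append(s)
            timepoint_of[s] = tp
            replicate_of[s] = r
    return ExpressionSeries(
        genes=genes,
        samples=samples,
        values=values,
        timepoint_of=timepoint_of,
        replicate_of=replicate_of,
        timepoint_order=labels,
        scale=scale,
    )


@pytest.fixture
def toy_series():
    """4 genes x 6 samples: 2 timepoints x 3 replicates."""
    rng = np.random.default_rng(42)
    return make_series(rng.normal(size=(4, 6)), n_timepoints=2, n_replicates=3)


@pytest.fixture
def toy_matrix_files(tmp_path):
    """Matching matrix/metadata TSVs for the 4x6 toy design."""
    matrix = tmp_path / "expr.tsv"
    meta = tmp_path / "meta.tsv"
    rng = np.random.default_rng(7)
    vals = rng.normal(size=(4, 6))
    samples = [f"T{t}_r{r}" for t in (1, 2) for r in (1, 2, 3)]
    with open(matrix, "w") as fh:
        fh.write("gene\t" + "\t".join(samples) + "\n")
        for i in range(4):
            fh.write(f"g{i + 1:03d}\t" + "\t".join(repr(float(v)) for v in vals[i]) + "\n")
    with open(meta, "w") as fh:
        fh.write("sample\ttimepoint\treplicate\n")
        for t in (1, 2):
            for r in (1, 2, 3):
                fh.write(f"T{t}_r{r}\tT{t}\t{r}\n")
    return matrix, meta


def brute_pearson(x, y):
    """Textbook Pearson correlation, independent of numpy.corrcoef."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = (sum((a - mx) ** 2 for a in x) / (n - 1)) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / (n - 1)) ** 0.5
    if sx == 0 or sy == 0:
        return 0.0
    return cov / (sx * sy)


def brute_bh(pvalues):
    """Step-up Benjamini-Hochberg adjustment, written from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, pvalues[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted
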