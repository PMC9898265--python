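"""Candidate-gene screening across timepoints, plus the qPCR fold-change utility.

The screen runs one Welch two-sample t-test per gene for each one-vs-rest
timepoint comparison and applies Benjamini-Hochberg adjustment. It is a
deliberately simple, self-contained stand-in for a count-model differential
pipeline: it operates on (log-scale) continuous values and performs no
normalization, dispersion estimation or shrinkage. Its only job here is to
produce a candidate list upstream of the criticality-index stage, and that
stage also accepts an explicit candidate list to bypass the screen
entirely.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dnbkit.io_expr import ExpressionSeries


@dataclass
class DEResult:
    """Per-gene, per-comparison Welch statistics and the candidate union.

    ``table`` columns: gene, comparison, diff, t, p, q. ``candidates`` is
    the union over comparisons of genes with q < ``q_threshold``.
    """

    table: pd.DataFrame
    candidates: set[str]
    q_threshold: float
    scope: str


def one_vs_rest_screen(
    series: ExpressionSeries,
    q_threshold: float = 0.05,
    scope: str = "per_comparison",
) -> DEResult:
    """Screen genes with one-vs-rest Welch tests across all timepoints.

    For each timepoint, every gene is tested (two-sided, unequal variances)
    for that timepoint's samples against all other samples. With
    ``scope="per_comparison"`` (default) BH adjustment is applied within
    each comparison; ``scope="global"`` adjusts across all comparisons at
    once. A gene with zero variance and equal means in both classes gets
    t = 0, p = 1.
    """
    if scope not in ("per_comparison", "global"):
        raise ValueError("scope must be 'per_comparison' or 'global'")
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must be in (0, 1)")

    frames = []
    for tp in series.timepoints:
        in_cols = [series.samples.index(s) for s in series.samples_at(tp)]
        out_cols = [i for i in range(len(series.samples)) if i not in in_cols]
        if len(in_cols) < 2:
            raise ValueError(f"timepoint {tp!r} has fewer than 2 samples")
        if len(out_cols) < 2:
            raise ValueError(f"rest class for timepoint {tp!r} has fewer than 2 samples")
        a = series.values[:, in_cols]
        b = series.values[:, out_cols]
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant genes
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        tstat = np.asarray(res.statistic, dtype=float)
        pval = np.asarray(res.pvalue, dtype=float)
        diff = a.mean(axis=1) - b.mean(axis=1)
        # both classes constant: scipy yields nan; define the degenerate cases
        degenerate = (a.std(axis=1, ddof=1) == 0) & (b.std(axis=1, ddof=1) == 0)
        same = degenerate & (diff == 0)
        tstat[same], pval[same] = 0.0, 1.0
        shifted = degenerate & (diff != 0)
        tstat[shifted] = np.sign(diff[shifted]) * np.inf
        pval[shifted] = 0.0
        frames.append(
            pd.DataFrame(
                {
                    "gene": series.genes,
                    "comparison": f"{tp}_vs_rest",
                    "diff": diff,
                    "t": tstat,
                    "p": pval,
                }
            )
        )

    table = pd.concat(frames, ignore_index=True)
    if scope == "per_comparison":
        table["q"] = table.groupby("comparison", sort=False)["p"].transform(
            lambda p: multipletests(p, method="fdr_bh")[1]
        )
    else:
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]

    candidates = set(table.loc[table["q"] < q_threshold, "gene"])
    return DEResult(table=table, candidates=candidates, q_threshold=q_threshold, scope=scope)


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl);
    returns 2^-ddCt.
    """
    cts = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError(f"Ct values must be finite, got {cts}")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
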