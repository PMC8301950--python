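"""Differential miRNA expression: CPM normalisation, fold-change/t-test
gating, and the treatment-specific / co-regulated partition.

A miRNA is differentially expressed (DEM) between a treatment and control
when |log2 fold change| > 1 and the two-sample Student t-test on
normalised replicate values gives p < 0.05 — fold-change thresholding on
raw p-values, as is conventional for 3v3 small-RNA designs; BH-adjusted
q-values are reported alongside for users who want them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT_CPM = 0.01


@dataclass
class ExpressionMatrix:
    """Raw counts and CPM of validated/accepted miRNAs (rows) per library
    (columns).  CPM columns sum to 1e6 whenever the library has counts."""

    raw: pd.DataFrame
    cpm: pd.DataFrame

    def condition_columns(self, condition: str) -> list[str]:
        return [c for c in self.cpm.columns if c.split("-")[0] == condition]


def normalize(counts: pd.DataFrame) -> ExpressionMatrix:
    """Counts-per-million over the miRNA-assigned total of each library."""
    if len(counts) == 0 or not counts.values.any():
        raise ValueError("no miRNA with nonzero counts to normalise")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"library without miRNA-assigned reads: "
                         f"{', '.join(zero.index)}")
    cpm = counts.astype(float) / totals.values * 1e6
    return ExpressionMatrix(counts.copy(), cpm)


def _ttest_row(a: np.ndarray, b: np.ndarray) -> float:
    """Equal-variance two-sided t-test with deterministic degenerate cases:
    all values identical -> p=1; zero within-group variance but different
    means -> p=0."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(p)


def call_dems(matrix: ExpressionMatrix, cond_a: str, cond_b: str,
              lfc_threshold: float = 1.0, alpha: float = 0.05,
              pseudocount: float = PSEUDOCOUNT_CPM) -> pd.DataFrame:
    """Differential calls for ``cond_a`` vs ``cond_b`` (b = baseline).

    log2FC = log2((mean_a + eps) / (mean_b + eps)) on CPM; miRNAs expressed
    in neither condition are excluded; records sorted by |log2FC| desc.
    """
    cols_a = matrix.condition_columns(cond_a)
    cols_b = matrix.condition_columns(cond_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 replicates per condition")
    A = matrix.cpm[cols_a]
    B = matrix.cpm[cols_b]
    expressed = (A.sum(axis=1) > 0) | (B.sum(axis=1) > 0)
    A, B = A[expressed], B[expressed]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    pvals = np.array([_ttest_row(A.loc[i].values, B.loc[i].values)
                      for i in A.index])
    qvals = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    out = pd.DataFrame({
        "mirna_id": A.index,
        "comparison": f"{cond_a}/{cond_b}",
        "mean_a": mean_a.values, "mean_b": mean_b.values,
        "log2fc": lfc.values, "p_value": pvals, "q_value": qvals,
    })
    out["direction"] = np.where(out.log2fc > 0, "up", "down")
    out["is_dem"] = (out.log2fc.abs() > lfc_threshold) & (out.p_value < alpha)
    return (out.reindex(out.log2fc.abs().sort_values(ascending=False).index)
            .reset_index(drop=True))


def venn_partition(dems_a: pd.DataFrame, dems_b: pd.DataFrame) -> dict:
    """Partition DEMs of two comparisons into A-only / B-only /
    co-regulated sets (with per-comparison directions and concordance)."""
    a = dems_a[dems_a.is_dem].set_index("mirna_id")
    b = dems_b[dems_b.is_dem].set_index("mirna_id")
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    co = sorted(set(a.index) & set(b.index))
    part = {
        "a_only_up": [m for m in only_a if a.loc[m, "direction"] == "up"],
        "a_only_down": [m for m in only_a if a.loc[m, "direction"] == "down"],
        "b_only_up": [m for m in only_b if b.loc[m, "direction"] == "up"],
        "b_only_down": [m for m in only_b if b.loc[m, "direction"] == "down"],
        "co_regulated": {
            m: {"direction_a": a.loc[m, "direction"],
                "direction_b": b.loc[m, "direction"],
                "concordant": bool(a.loc[m, "direction"]
                                   == b.loc[m, "direction"])}
            for m in co},
    }
    part["counts"] = {
        "a_only": len(only_a), "b_only": len(only_b), "co": len(co),
        "union": len(set(a.index) | set(b.index)),
        "co_concordant": sum(v["concordant"]
                             for v in part["co_regulated"].values()),
    }
    return part


def heatmap_matrix(matrix: ExpressionMatrix, dem_ids: list[str]
                   ) -> pd.DataFrame:
    """Deterministic log-scale expression matrix of the DEM set, rows
    ordered by hierarchical-clustering-free mean expression then id —
    the exportable analogue of an expression heat map."""
    sub = matrix.cpm.loc[[m for m in dem_ids if m in matrix.cpm.index]]
    logged = np.log2(sub + 1.0)
    order = logged.mean(axis=1).sort_values(ascending=False).index
    return logged.loc[order]
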