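"""2^-ddCt relative quantification and miRNA-target correlation.

Technical replicates are averaged on the Ct scale per biological
replicate; dCt = Ct_assay - Ct_reference within each sample; ddCt
subtracts the mean calibrator-condition dCt; relative expression is
2^-ddCt per biological replicate, summarised as mean +/- sd.  The mean
relative expression of the calibrator condition is 1 by construction.
Pearson correlation between a miRNA and its target is computed over
paired condition means, with the sign distinguishing inverse from
positive miRNA-target modules.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["assay", "condition", "bio_rep", "tech_rep", "ct"]


def load_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if not df.ct.between(0, 45, inclusive="neither").all():
        raise ValueError("Ct values must lie in (0, 45)")
    return df


def ddct(table: pd.DataFrame, reference_assay: str,
         calibrator: str = "CK") -> pd.DataFrame:
    """Per-assay relative expression by the 2^-ddCt method.

    Returns one row per (assay, condition, bio_rep) with ``rel_expr`` plus
    condition-level mean and sd.  Raises when the reference assay is
    missing from any sample that carries a target assay.
    """
    if reference_assay not in set(table.assay):
        raise ValueError(f"reference assay {reference_assay!r} not measured")
    # average technical replicates on the Ct scale
    ct = (table.groupby(["assay", "condition", "bio_rep"], sort=False)["ct"]
          .mean().reset_index())
    ref = ct[ct.assay == reference_assay] \
        .set_index(["condition", "bio_rep"])["ct"]
    rows = []
    for assay, grp in ct[ct.assay != reference_assay].groupby("assay",
                                                              sort=False):
        grp = grp.copy()
        keys = list(zip(grp.condition, grp.bio_rep))
        missing = [k for k in keys if k not in ref.index]
        if missing:
            raise ValueError(
                f"reference {reference_assay!r} missing in sample(s): "
                + ", ".join(f"{c}/rep{b}" for c, b in missing))
        grp["dct"] = grp.ct.values - ref.loc[keys].values
        cal = grp[grp.condition == calibrator]
        if cal.empty:
            raise ValueError(f"calibrator condition {calibrator!r} missing "
                             f"for assay {assay!r}")
        ddct_vals = grp.dct - cal.dct.mean()
        grp["rel_expr"] = 2.0 ** (-ddct_vals)
        rows.append(grp)
    out = pd.concat(rows, ignore_index=True)
    summary = (out.groupby(["assay", "condition"], sort=False)["rel_expr"]
               .agg(["mean", "std"]).rename(
                   columns={"mean": "rel_mean", "std": "rel_sd"}))
    return out.join(summary, on=["assay", "condition"])


def condition_means(rel: pd.DataFrame, assay: str) -> pd.Series:
    sub = rel[rel.assay == assay]
    return sub.groupby("condition", sort=False)["rel_expr"].mean()


def correlate(rel_mirna: pd.DataFrame, rel_target: pd.DataFrame,
              mirna_assay: str, target_assay: str
              ) -> dict:
    """Pearson correlation of miRNA vs target relative expression over
    paired condition means.

    Returns r, r^2 and the relationship sign; flags the degenerate
    zero-variance case instead of reporting a number.
    """
    a = condition_means(rel_mirna, mirna_assay)
    b = condition_means(rel_target, target_assay)
    common = [c for c in a.index if c in b.index]
    if len(common) < 3:
        raise ValueError("need at least 3 paired conditions to correlate")
    x, y = a.loc[common].values, b.loc[common].values
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"mirna": mirna_assay, "target": target_assay, "n": len(common),
                "r": math.nan, "r2": math.nan, "relationship": "undefined",
                "degenerate": True}
    r = float(stats.pearsonr(x, y).statistic)
    return {"mirna": mirna_assay, "target": target_assay, "n": len(common),
            "r": round(r, 6), "r2": round(r * r, 6),
            "relationship": "inverse" if r < 0 else "positive",
            "degenerate": False}
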