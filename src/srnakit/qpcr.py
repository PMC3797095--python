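"""Relative qPCR quantification by the 2^-ddCt method.

Technical replicates are averaged on the Ct scale, dCt = Ct_target -
Ct_reference per sample, ddCt is taken against the calibrator group's
mean dCt, and relative expression is 2^-ddCt (amplification efficiency
fixed at exact doubling). Group differences use one-way ANOVA.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import f_oneway


def delta_delta_ct(records: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-sample relative expression 2^-ddCt.

    ``records`` columns: sample, group, target_ct, ref_ct (and optionally
    rep for technical replicates, averaged first). The calibrator group's
    geometric-mean expression is 1 by construction.
    """
    required = {"sample", "group", "target_ct", "ref_ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if records[["target_ct", "ref_ct"]].isna().any().any():
        bad = records[records[["target_ct", "ref_ct"]].isna().any(axis=1)]["sample"]
        raise ValueError(f"missing Ct for sample(s): {sorted(set(bad))}")
    per_sample = (records.groupby(["sample", "group"], as_index=False)
                  [["target_ct", "ref_ct"]].mean())
    per_sample["dct"] = per_sample["target_ct"] - per_sample["ref_ct"]
    cal = per_sample[per_sample["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    cal_mean = cal["dct"].mean()
    per_sample["ddct"] = per_sample["dct"] - cal_mean
    per_sample["rel_expr"] = 2.0 ** (-per_sample["ddct"])
    return per_sample[["sample", "group", "dct", "ddct", "rel_expr"]]


def group_test(values_by_group: dict[str, list[float]]) -> tuple[float, float]:
    """One-way ANOVA over >= 2 groups. Returns (F, p).

    With zero between-group variance returns (0, 1); with zero variance
    everywhere but distinct means, p is reported as 0 with a warning.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    means = [g.mean() for g in groups]
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if np.allclose(means, means[0]):
        return 0.0, 1.0
    if ssw == 0:
        warnings.warn("zero within-group variance in all groups; p reported as 0")
        return float("inf"), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = f_oneway(*groups)
    return float(f_stat), float(p)


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_summary(rel: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of relative expression per group, with ANOVA p and stars."""
    by_group = {g: df["rel_expr"].tolist() for g, df in rel.groupby("group")}
    f_stat, p = group_test(by_group)
    rows = [{"group": g, "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
             "n": len(v), "F": f_stat, "p": p, "stars": significance_stars(p)}
            for g, v in sorted(by_group.items())]
    return pd.DataFrame(rows)
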