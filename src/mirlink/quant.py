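"""qRT-PCR relative quantification and dual-luciferase analysis.

Relative expression uses the 2^-ddCt method with multi-reference
normalization: each sample's target Ct is normalized to the arithmetic
mean of its reference-assay Ts (equivalent to geometric-mean
normalization of expression in linear space), then to the mean dCt of a
calibrator group. No amplification-efficiency correction is applied.

Luciferase activity is the per-well experimental/control luminescence
ratio, rescaled so the baseline condition has mean 1, with a two-sided
Student t against the baseline per condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import StatTestResult, compare_continuous

__all__ = ["ddct", "luciferase_activity"]


def ddct(
    ct: pd.DataFrame,
    target: str,
    references: list[str],
    calibrator_group: str,
) -> tuple[pd.DataFrame, StatTestResult]:
    """Per-sample 2^-ddCt fold changes and a group comparison on dCt.

    ``ct`` needs columns sample_id, group, assay_id, ct, with the target
    and every reference assay measured once in each sample. Returns the
    per-sample table (dct, ddct, fold) and the two-group test on dCt
    values (normality-gated t / Mann-Whitney via ``compare_continuous``).
    """
    if not references:
        raise ValueError("at least one reference assay is required")
    wide = ct.pivot_table(index="sample_id", columns="assay_id", values="ct")
    for assay in [target, *references]:
        if assay not in wide.columns or wide[assay].isna().any():
            missing = (
                list(wide.index[wide[assay].isna()]) if assay in wide.columns else "all"
            )
            raise ValueError(f"assay {assay!r} missing for sample(s): {missing}")
    groups = ct.drop_duplicates("sample_id").set_index("sample_id")["group"]
    if calibrator_group not in set(groups):
        raise ValueError(f"calibrator group {calibrator_group!r} not present")

    dct = wide[target] - wide[list(references)].mean(axis=1)
    calibrator_mean = dct[groups.loc[dct.index] == calibrator_group].mean()
    ddct_values = dct - calibrator_mean
    per_sample = pd.DataFrame(
        {
            "group": groups.loc[dct.index],
            "dct": dct,
            "ddct": ddct_values,
            "fold": 2.0 ** (-ddct_values),
        }
    )
    labels = [g for g in dict.fromkeys(groups) ]
    other = [g for g in labels if g != calibrator_group]
    if len(other) != 1:
        raise ValueError(f"expected exactly two groups, found {labels}")
    test = compare_continuous(
        per_sample.loc[per_sample["group"] == other[0], "dct"].to_numpy(),
        per_sample.loc[per_sample["group"] == calibrator_group, "dct"].to_numpy(),
    )
    return per_sample, test


def luciferase_activity(
    readings: pd.DataFrame, baseline_condition: str
) -> pd.DataFrame:
    """Normalized luciferase activities with per-condition tests vs baseline.

    ``readings`` needs columns condition, signal, control (> 0), with >= 3
    replicates per condition. Activity = signal / control per well,
    rescaled so the baseline condition's mean is 1. Each non-baseline
    condition is compared to the baseline with a two-sided Student t.
    """
    if (readings["control"] <= 0).any():
        bad = readings.loc[readings["control"] <= 0, "condition"].iloc[0]
        raise ValueError(f"non-positive control reading in condition {bad!r}")
    if baseline_condition not in set(readings["condition"]):
        raise ValueError(f"baseline condition {baseline_condition!r} not present")
    counts = readings.groupby("condition").size()
    if (counts < 3).any():
        bad = counts.index[counts < 3][0]
        raise ValueError(f"condition {bad!r} has fewer than 3 replicates")

    activity = readings["signal"] / readings["control"]
    baseline_mask = readings["condition"] == baseline_condition
    scaled = activity / activity[baseline_mask].mean()
    base = scaled[baseline_mask].to_numpy()

    rows = []
    for condition, values in scaled.groupby(readings["condition"]):
        v = values.to_numpy()
        if condition == baseline_condition:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(v, base, equal_var=True)
        rows.append(
            {
                "condition": condition,
                "n": v.size,
                "mean_activity": float(v.mean()),
                "sd": float(v.std(ddof=1)),
                "t": float(t_stat),
                "pvalue": float(p),
            }
        )
    out = pd.DataFrame(rows).set_index("condition")
    return out.loc[[baseline_condition] + sorted(set(out.index) - {baseline_condition})]
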