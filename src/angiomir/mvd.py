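"""Microvessel-density discovery filter.

Tumours are grouped by microvessel density (vessels per high-power field)
extremes — strictly above a high threshold, strictly below a low threshold,
everything else excluded — and miRNAs are retained when their median
expression in the highly angiogenic group is decreased by more than a stated
fraction relative to the poorly angiogenic group (default: >80%, i.e. a
median ratio strictly below 0.2). The rule operates on group medians of
already-normalized non-negative counts and is scale invariant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._util import ValidationError

log = logging.getLogger(__name__)

HIGH_MVD_THRESHOLD = 36.0
LOW_MVD_THRESHOLD = 16.0


def assign_mvd_groups(
    mvd: pd.DataFrame,
    high_threshold: float = HIGH_MVD_THRESHOLD,
    low_threshold: float = LOW_MVD_THRESHOLD,
) -> pd.DataFrame:
    """Assign samples to MVD groups: high (> high_threshold), low (< low_threshold).

    Samples at or between the thresholds are excluded (strict inequalities).
    Input: DataFrame with columns ``sample`` and ``vessels_per_hpf``.
    """
    if low_threshold > high_threshold:
        raise ValidationError("low_threshold must be <= high_threshold")
    df = mvd.copy()
    v = df["vessels_per_hpf"].to_numpy(dtype=float)
    if (v < 0).any():
        bad = df.loc[v < 0, "sample"].iloc[0]
        raise ValidationError(f"negative microvessel density for sample {bad!r}")
    group = np.where(v > high_threshold, "high", np.where(v < low_threshold, "low", "excluded"))
    df["group"] = group
    counts = df["group"].value_counts()
    log.info(
        "MVD groups: high=%d low=%d excluded=%d",
        counts.get("high", 0), counts.get("low", 0), counts.get("excluded", 0),
    )
    return df


def median_decrease_screen(
    expr: pd.DataFrame,
    groups: pd.DataFrame,
    decrease_threshold: float = 0.8,
) -> pd.DataFrame:
    """Median-decrease differential filter between MVD extremes.

    For each miRNA (row of ``expr``) the medians over the high- and low-MVD
    sample groups are compared; the miRNA passes when
    ``median_high < (1 - decrease_threshold) * median_low`` (strict), i.e. a
    decrease of more than the threshold fraction. The decrease fraction
    ``1 - median_high/median_low`` is NaN when the low-group median is zero,
    and such miRNAs never pass.

    Returns one row per miRNA with columns mirna, median_high, median_low,
    decrease, passes — sorted by decrease descending (undefined last).
    """
    if not 0 < decrease_threshold < 1:
        raise ValidationError("decrease_threshold must lie in (0, 1)")
    high = groups.loc[groups["group"] == "high", "sample"].tolist()
    low = groups.loc[groups["group"] == "low", "sample"].tolist()
    if not high or not low:
        raise ValidationError("both MVD groups must be non-empty")
    missing = [s for s in high + low if s not in expr.columns]
    if missing:
        raise ValidationError(f"grouped sample(s) missing from expression matrix: {missing}")
    sub = expr[high + low]
    if (sub.to_numpy() < 0).any():
        raise ValidationError("expression must be non-negative counts")
    med_high = expr[high].median(axis=1)
    med_low = expr[low].median(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        decrease = 1.0 - med_high / med_low
    decrease = decrease.where(med_low > 0, np.nan)
    passes = (med_low > 0) & (med_high < (1.0 - decrease_threshold) * med_low)
    undefined = med_low == 0
    if undefined.any():
        log.info("miRNA(s) with zero low-group median (decrease undefined): %s",
                 list(expr.index[undefined]))
    out = pd.DataFrame(
        {
            "mirna": expr.index,
            "median_high": med_high.to_numpy(),
            "median_low": med_low.to_numpy(),
            "decrease": decrease.to_numpy(),
            "passes": passes.to_numpy(),
        }
    )
    out = out.sort_values(
        ["decrease", "mirna"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return out
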