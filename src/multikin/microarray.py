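"""Peptide-microarray competition quantification.

Spots are printed as internal left/right duplicates; for each condition the
background-subtracted intensities of all spots of interest are summed and
normalized to the summed intensity of the no-competitor condition, giving a
relative target-binding value per competitor concentration.  The
duplicate-spot deviation is the population standard deviation of the pooled
left/right values, sqrt(sum((x - mean)^2) / n).  Neutralization potency is
quantified as the IC50 of a logistic fit of relative binding versus
competitor concentration, reusing the Hill machinery of
:mod:`multikin.competition`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .competition import fit_hill
from .types import HillFit

__all__ = [
    "validate_spot_table",
    "subtract_background",
    "duplicate_stdev",
    "normalize_competition",
    "neutralization_ic50",
]

logger = logging.getLogger("multikin")

SIDES = ("left", "right")


def validate_spot_table(table: pd.DataFrame) -> None:
    """Check the duplicate structure: every (spot, condition) on both sides."""
    required = {"spot_id", "side", "condition_id", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"spot table missing columns {sorted(missing)}")
    if (table["intensity"] < 0).any():
        raise ValueError("intensities must be non-negative")
    sides = table.groupby(["spot_id", "condition_id"])["side"].agg(
        lambda s: tuple(sorted(set(s)))
    )
    bad = sides[sides != ("left", "right")]
    if len(bad):
        key = bad.index[0]
        raise ValueError(
            f"spot {key[0]!r} condition {key[1]!r} is missing a duplicate side"
        )


def subtract_background(table: pd.DataFrame) -> pd.DataFrame:
    """Per-spot local background subtraction, floored at zero.

    intensity' = max(0, intensity - background); the number of clipped
    (negative) values is logged.
    """
    out = table.copy()
    corrected = out["intensity"] - out["background"]
    n_clip = int((corrected < 0).sum())
    if n_clip:
        logger.info("background subtraction clipped %d negative intensities", n_clip)
    out["intensity"] = corrected.clip(lower=0.0)
    return out


def duplicate_stdev(left, right) -> float:
    """Deviation between duplicate sides: pooled within-pair population SD.

    Each (left_i, right_i) pair deviates from its own pair mean;
    sqrt(sum over all points of (x - pair mean)^2 / n) with n the total
    number of data points.  Identical sides give 0 regardless of spot-to-spot
    variation; a single pair {4, 8} gives 2.  (The usual printed
    duplicate-deviation formula drops the square on the deviations, which is
    dimensionally inconsistent; the standard population SD is computed
    instead.)
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right duplicate vectors must have equal length")
    if left.size == 0:
        raise ValueError("no data points")
    # per-pair mean m_i: each side deviates by (left_i - right_i)/2
    return float(np.sqrt(np.mean(((left - right) / 2.0) ** 2)))


def normalize_competition(
    table: pd.DataFrame, subtract_bg: bool = True
) -> pd.DataFrame:
    """Summed-intensity normalization against the no-competitor condition.

    Sums (background-subtracted) intensities of all spots per condition and
    divides by the no-competitor (conc 0) sum.  Returns one row per
    condition: condition_id, conc_M, rel_binding, duplicate_sd (Eq.-style
    pooled SD of per-side sums expressed on the normalized scale).
    """
    validate_spot_table(table)
    work = subtract_background(table) if subtract_bg and "background" in table else table
    if "conc_M" not in work.columns:
        raise ValueError("spot table needs a conc_M column")
    sums = work.groupby(["condition_id", "conc_M"])["intensity"].sum()
    zero = sums[sums.index.get_level_values("conc_M") == 0.0]
    if zero.empty:
        raise ValueError("no-competitor (conc 0) condition is required")
    ref = float(zero.iloc[0])
    if ref <= 0:
        raise ValueError("no-competitor condition has zero summed intensity")
    side_sums = work.groupby(["condition_id", "conc_M", "side"])["intensity"].sum()
    rows = []
    for (cond, conc), total in sums.items():
        per_side = side_sums.loc[cond, conc]
        sd = duplicate_stdev(
            [per_side.get("left", np.nan)], [per_side.get("right", np.nan)]
        )
        rows.append(
            {
                "condition_id": cond,
                "conc_M": conc,
                "rel_binding": total / ref,
                "duplicate_sd": sd / ref,
            }
        )
    return pd.DataFrame(rows).sort_values("conc_M", ignore_index=True)


def neutralization_ic50(normalized: pd.DataFrame) -> HillFit:
    """Logistic IC50 of relative binding vs competitor concentration.

    Takes the output of :func:`normalize_competition`; the no-competitor
    point anchors the top plateau but is excluded from the log-concentration
    fit.  A fit without a resolvable transition carries a flag and the IC50
    is only a bound relative to the concentration grid.
    """
    pos = normalized[normalized["conc_M"] > 0]
    if len(pos) < 5:
        raise ValueError("need >= 5 positive competitor concentrations")
    return fit_hill(pos["conc_M"].to_numpy(), pos["rel_binding"].to_numpy())
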