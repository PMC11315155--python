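"""Relative odor activity values and key-odorant selection.

A compound's contribution to the overall aroma is judged by the ratio of
its concentration to its odor threshold in the matching medium:

    ROAV = C [ug/L] / T [ug/L]

Compounds with ROAV strictly greater than 1 are key contributors to the
aroma profile. Compounds whose threshold is unknown ("n. f" in reference
tables) cannot be evaluated and are reported separately rather than
silently dropped or treated as zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .core import ConcentrationMatrix
from .errors import ValidationError


@dataclass
class RoavResult:
    """Long-format ROAV records plus the compounds that could not be scored.

    ``records`` columns: wine_label, compound_id, concentration, threshold,
    roav, is_key. ``unevaluable`` lists detected compounds with no known
    threshold.
    """
    records: pd.DataFrame
    unevaluable: list[str] = field(default_factory=list)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used in printed ROAV tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def compute_roav(matrix: ConcentrationMatrix, thresholds: pd.DataFrame,
                 cutoff: float = 1.0) -> RoavResult:
    """ROAV for every (wine, compound) with a concentration and a threshold.

    ``thresholds`` needs columns compound_id and threshold_ug_per_L.
    ``is_key`` applies the strict ``roav > cutoff`` rule to the unrounded
    value; C == T is therefore not a key odorant.
    """
    thr = thresholds.dropna(subset=["threshold_ug_per_L"])
    if (thr["threshold_ug_per_L"] <= 0).any():
        bad = thr.loc[thr["threshold_ug_per_L"] <= 0, "compound_id"].tolist()
        raise ValidationError(f"non-positive odor thresholds for {bad}")
    tmap = thr.set_index("compound_id")["threshold_ug_per_L"]

    rows = []
    unevaluable = set()
    for wine in matrix.wines:
        conc = matrix.mean.loc[wine].dropna()
        for compound, c in conc.items():
            t = tmap.get(compound)
            if t is None or pd.isna(t):
                unevaluable.add(compound)
                continue
            roav = c / t
            rows.append((wine, compound, c, float(t), roav, roav > cutoff))
    records = pd.DataFrame(
        rows, columns=["wine_label", "compound_id", "concentration",
                       "threshold", "roav", "is_key"])
    return RoavResult(records=records, unevaluable=sorted(unevaluable))


def select_key_odorants(result: RoavResult, cutoff: float = 1.0) -> dict[str, pd.DataFrame]:
    """Per-wine key odorants (ROAV > cutoff), sorted by descending ROAV."""
    if cutoff <= 0:
        raise ValidationError("ROAV cutoff must be positive")
    records = result.records
    out: dict[str, pd.DataFrame] = {}
    for wine, sub in records.groupby("wine_label", sort=False):
        keys = sub[sub["roav"] > cutoff].sort_values(
            "roav", ascending=False, kind="mergesort")
        out[wine] = keys.reset_index(drop=True)
    return out
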