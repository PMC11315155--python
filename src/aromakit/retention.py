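"""Temperature-programmed retention indices on the n-alkane scale.

Under a linear oven ramp the retention index of an analyte eluting at
``RT_x`` between the alkanes with carbon numbers ``Z`` and ``Z+1`` is

    RI_x = 100 * ( Z + (RT_x - RT_z) / (RT_{z+1} - RT_z) )

(the van den Dool & Kratz form; the isothermal logarithmic Kovats variant
is deliberately not provided). Peaks are annotated by nearest reference RI
within a tolerance, with best-match-wins tie handling per replicate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import PeakTable
from .errors import AnnotationError, CalibrationError

DEFAULT_RI_TOLERANCE = 10.0


class RIValue(NamedTuple):
    """A computed retention index and how it was obtained."""
    value: float
    bracketing_z: int
    extrapolated: bool


@dataclass(frozen=True)
class AlkaneLadder:
    """Monotone carbon-number -> retention-time calibration.

    ``carbon`` is strictly increasing (typically C7..C30) and so is ``rt``;
    both are stored sorted by carbon number.
    """
    carbon: np.ndarray
    rt: np.ndarray

    def span(self) -> tuple[float, float]:
        return float(self.rt[0]), float(self.rt[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"carbon_number": self.carbon,
                             "retention_time_min": self.rt})


def fit_ladder(rungs) -> AlkaneLadder:
    """Build a validated ladder from (carbon_number, retention_time) pairs."""
    arr = sorted((int(z), float(rt)) for z, rt in rungs)
    if len(arr) < 2:
        raise CalibrationError("alkane ladder needs at least two rungs")
    carbon = np.array([z for z, _ in arr])
    rt = np.array([t for _, t in arr])
    if (np.diff(carbon) <= 0).any():
        raise CalibrationError("duplicate carbon numbers in alkane ladder")
    if (np.diff(rt) <= 0).any():
        raise CalibrationError(
            "retention times not strictly increasing with carbon number")
    return AlkaneLadder(carbon=carbon, rt=rt)


def read_ladder(path) -> AlkaneLadder:
    frame = pd.read_csv(path)
    cols = list(frame.columns[:2])
    return fit_ladder(frame[cols].itertuples(index=False))


def compute_ri(rt: float, ladder: AlkaneLadder) -> RIValue:
    """Retention index of a peak at ``rt`` minutes.

    Outside the ladder span the first/last rung pair is extended linearly
    and the result is flagged ``extrapolated``.
    """
    if rt <= 0:
        raise CalibrationError(f"retention time must be positive, got {rt}")
    lo, hi = ladder.span()
    extrapolated = rt < lo or rt > hi
    # bracketing lower rung; clip so edge pairs serve for extrapolation
    idx = int(np.searchsorted(ladder.rt, rt, side="right") - 1)
    idx = min(max(idx, 0), len(ladder.rt) - 2)
    z = ladder.carbon[idx]
    rt_z, rt_z1 = ladder.rt[idx], ladder.rt[idx + 1]
    value = 100.0 * (z + (rt - rt_z) / (rt_z1 - rt_z))
    return RIValue(value=float(value), bracketing_z=int(z), extrapolated=extrapolated)


def compute_ri_array(rts: np.ndarray, ladder: AlkaneLadder) -> np.ndarray:
    return np.array([compute_ri(rt, ladder).value for rt in np.asarray(rts, float)])


def annotate_peaks(table: PeakTable, library: pd.DataFrame,
                   ladder: AlkaneLadder,
                   tolerance: float = DEFAULT_RI_TOLERANCE) -> PeakTable:
    """Assign library compounds to unannotated peaks by RI proximity.

    Within each replicate, assignments are injective: every library entry
    goes to its closest peak (ties at exactly equal RI distance leave the
    peak unannotated, since no spectral evidence is available to break
    them). Already-annotated peaks are left untouched, which makes the
    operation idempotent.
    """
    if tolerance <= 0:
        raise AnnotationError("RI tolerance must be positive")
    ref = library.dropna(subset=["reference_ri"])
    if ref.empty:
        raise AnnotationError("compound library carries no reference RI values")
    ref_ids = ref["compound_id"].to_numpy()
    ref_ri = ref["reference_ri"].to_numpy(float)

    peaks = table.peaks.copy()
    peaks["compound_id"] = peaks["compound_id"].astype(object)
    peaks["ri"] = compute_ri_array(peaks["retention_time"].to_numpy(), ladder)

    for _rid, idx in peaks.groupby("sample_id").groups.items():
        idx = [i for i in idx
               if not peaks.at[i, "is_internal_standard"]
               and pd.isna(peaks.at[i, "compound_id"])]
        if not idx:
            continue
        peak_ri = peaks.loc[idx, "ri"].to_numpy()
        # candidate (distance, peak, library entry) triples within tolerance
        dist = np.abs(peak_ri[:, None] - ref_ri[None, :])
        cand = np.argwhere(dist <= tolerance)
        order = np.argsort(dist[cand[:, 0], cand[:, 1]], kind="stable")
        used_peaks: set[int] = set()
        used_refs: set[int] = set()
        k = 0
        while k < len(order):
            i, j = cand[order[k]]
            d = dist[i, j]
            if i in used_peaks or j in used_refs:
                k += 1
                continue
            # tie at identical distance for the same peak or the same
            # library entry: ambiguous, leave unannotated
            tied = [(a, b) for a, b in cand[order[k:]]
                    if dist[a, b] == d and (a == i or b == j)
                    and (a, b) != (i, j)
                    and a not in used_peaks and b not in used_refs]
            if tied:
                used_peaks.add(i)
                for a, b in tied:
                    used_peaks.add(a)
                k += 1
                continue
            peaks.at[idx[i], "compound_id"] = ref_ids[j]
            used_peaks.add(i)
            used_refs.add(j)
            k += 1
    return PeakTable(peaks, table.meta)
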