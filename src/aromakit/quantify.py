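"""Internal-standard semi-quantification and class summaries.

Each sample receives a fixed spike of internal standard (2-octanol at a
final concentration of 328.8 ug/L in the reference protocol). An analyte's
concentration in a replicate is the area ratio against that replicate's IS
peak:

    C = (A_analyte / A_IS) * C_IS            [ug/L]

Replicates are then aggregated per (wine, compound) into mean and sample
SD over the replicates in which the compound was detected; zero detections
leave the cell missing. Class totals and per-group presence/absence sets
summarize the panel composition.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CHEM_CLASSES, ConcentrationMatrix, PeakTable
from .errors import QuantificationError, ValidationError


@dataclass(frozen=True)
class ISConfig:
    """Internal-standard spike: compound name and final concentration (ug/L)."""
    name: str = "2-octanol"
    final_concentration: float = 328.8

    def __post_init__(self) -> None:
        if self.final_concentration <= 0:
            raise ValidationError("IS final concentration must be > 0")


def semi_quantify(table: PeakTable, is_config: ISConfig = ISConfig()) -> pd.DataFrame:
    """Concentration records (sample_id, compound_id, concentration) per replicate.

    Every annotated, non-IS peak is ratioed against its own replicate's
    internal-standard area. A replicate without an IS peak is an error.
    """
    is_peaks = table.internal_standards()
    is_area = is_peaks.set_index("sample_id")["peak_area"]
    missing = [r for r in table.replicate_ids() if r not in is_area.index]
    if missing:
        raise QuantificationError(
            f"replicate(s) lack an internal-standard peak: {missing}")

    analytes = table.peaks[
        ~table.peaks["is_internal_standard"]
        & table.peaks["compound_id"].notna()
    ]
    conc = (analytes["peak_area"].to_numpy()
            / is_area.loc[analytes["sample_id"]].to_numpy()
            * is_config.final_concentration)
    return pd.DataFrame({
        "sample_id": analytes["sample_id"].to_numpy(),
        "compound_id": analytes["compound_id"].to_numpy(),
        "concentration": conc,
    })


def aggregate_replicates(records: pd.DataFrame, meta: pd.DataFrame) -> ConcentrationMatrix:
    """Collapse replicate records to a wines x compounds matrix.

    mean/SD run over the replicates in which the compound was detected
    (sample SD, ddof=1; a single detected replicate gets SD 0 and is
    flagged low-support). A compound never detected in a wine stays
    missing for that wine.
    """
    merged = records.merge(meta[["sample_id", "wine_label"]], on="sample_id")
    grouped = merged.groupby(["wine_label", "compound_id"])["concentration"]
    mean = grouped.mean().unstack()
    n = grouped.size().unstack().fillna(0).astype(int)
    sd = grouped.std(ddof=1).unstack()
    sd = sd.where(n != 1, 0.0).where(mean.notna(), np.nan)

    wines = list(meta["wine_label"].unique())
    mean = mean.reindex(wines)
    sd = sd.reindex(wines)
    n = n.reindex(wines).fillna(0).astype(int)
    low = (n == 1) & mean.notna()
    return ConcentrationMatrix(mean=mean, sd=sd, n=n, low_support=low)


def class_totals(matrix: ConcentrationMatrix, library: pd.DataFrame) -> pd.DataFrame:
    """Per-wine, per-class concentration totals (ug/L); missing counts as 0.

    Mirrors the "Total" rows of a semi-quantitative compound table, which
    sum only the detected compounds of each chemical class.
    """
    classes = library.set_index("compound_id")["chem_class"]
    unknown = [c for c in matrix.compounds if c not in classes.index
               or pd.isna(classes.get(c))]
    if unknown:
        raise ValidationError(f"compounds without a chemical class: {unknown}")
    totals = pd.DataFrame(0.0, index=matrix.wines, columns=list(CHEM_CLASSES))
    filled = matrix.mean.fillna(0.0)
    for compound in matrix.compounds:
        totals[classes[compound]] += filled[compound]
    return totals


def presence_sets(matrix: ConcentrationMatrix,
                  grouping: dict[str, str]) -> dict:
    """Per-group detected-compound sets and all intersection cardinalities.

    A compound is present in a group iff it is detected in at least one
    wine of that group. Returns ``{"sets": {group: set}, "regions":
    {frozenset-of-groups: count}, "unique": {group: set}}`` -- the data
    behind a Venn diagram, without the drawing.
    """
    detected = matrix.detected()
    groups = sorted(set(grouping.values()))
    sets: dict[str, set] = {g: set() for g in groups}
    for wine in matrix.wines:
        g = grouping.get(wine)
        if g is None:
            continue
        sets[g].update(detected.columns[detected.loc[wine]])

    regions: dict[frozenset, int] = {}
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            inside = set.intersection(*(sets[g] for g in combo))
            outside = set.union(set(), *(sets[g] for g in groups if g not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    unique = {g: sets[g] - set.union(set(), *(sets[h] for h in groups if h != g))
              for g in groups}
    return {"sets": sets, "regions": regions, "unique": unique}
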