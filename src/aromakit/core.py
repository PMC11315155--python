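"""Core in-memory containers shared across the pipeline.

The package works on three tabular objects:

``PeakTable``
    replicate-level integrated GC-MS peaks (retention time in minutes,
    detector peak area) joined to sample metadata;
``ConcentrationMatrix``
    wines x compounds semi-quantified concentrations in ug/L, stored as
    separate mean / sd / replicate-count frames with NaN marking cells in
    which a compound was never detected;
``CompoundLibrary`` (a plain DataFrame)
    one row per library compound: id, CAS, chemical class, optional
    reference retention index, identification evidence and odor description.

Sample metadata lives in a DataFrame with columns ``sample_id``,
``wine_label``, ``group_label`` and ``replicate_index``; (wine, replicate)
pairs are unique and each sample belongs to exactly one group.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

META_COLUMNS = ["sample_id", "wine_label", "group_label", "replicate_index"]
PEAK_COLUMNS = ["sample_id", "retention_time", "peak_area", "compound_id",
                "is_internal_standard"]
CHEM_CLASSES = ("acid", "alcohol", "aldehyde", "ester", "other")


def make_sample_meta(rows: list[tuple[str, str, str, int]]) -> pd.DataFrame:
    """Build a sample-metadata frame from (sample_id, wine, group, replicate)."""
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return validate_sample_meta(meta)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"sample metadata lacks columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dupes}")
    pair = meta[["wine_label", "replicate_index"]].apply(tuple, axis=1)
    if pair.duplicated().any():
        raise ValidationError("duplicate (wine_label, replicate_index) pairs")
    if (meta["replicate_index"] < 1).any():
        raise ValidationError("replicate_index must be a positive integer")
    return meta.reset_index(drop=True)


@dataclass
class LoadReport:
    """What happened while loading a peak table."""
    n_rows: int = 0
    n_dropped_nonpositive: int = 0


@dataclass
class PeakTable:
    """Replicate-level integrated peaks plus sample metadata.

    ``peaks`` columns: sample_id, retention_time (min), peak_area,
    compound_id (NaN while unannotated), is_internal_standard (bool) and,
    after RI annotation, ``ri``.
    """
    peaks: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.peaks.columns]
        if missing:
            raise ValidationError(f"peak table lacks columns: {missing}")
        self.meta = validate_sample_meta(self.meta)
        unknown = set(self.peaks["sample_id"]) - set(self.meta["sample_id"])
        if unknown:
            raise ValidationError(f"peaks reference unknown samples: {sorted(unknown)}")

    def canonicalized(self) -> "PeakTable":
        """Stable ordering (sample then retention time) for byte-stable I/O."""
        peaks = self.peaks.sort_values(
            ["sample_id", "retention_time", "peak_area"], kind="mergesort"
        ).reset_index(drop=True)
        meta = self.meta.sort_values("sample_id", kind="mergesort").reset_index(drop=True)
        return PeakTable(peaks, meta)

    def internal_standards(self) -> pd.DataFrame:
        return self.peaks[self.peaks["is_internal_standard"]]

    def replicate_ids(self) -> list[str]:
        return list(self.meta["sample_id"])


@dataclass
class ConcentrationMatrix:
    """wines x compounds semi-quantified concentrations (ug/L).

    All three frames share index (wine labels) and columns (compound ids).
    ``mean``/``sd`` carry NaN where the compound was detected in zero
    replicates of a wine -- missingness is explicit, never encoded as 0.
    """
    mean: pd.DataFrame
    sd: pd.DataFrame
    n: pd.DataFrame
    low_support: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        for name, frame in [("sd", self.sd), ("n", self.n)]:
            if not frame.index.equals(self.mean.index) or not frame.columns.equals(self.mean.columns):
                raise ValidationError(f"ConcentrationMatrix.{name} is misaligned with mean")
        if (self.sd.to_numpy() < 0).any():
            raise ValidationError("negative sd in concentration matrix")
        present = ~np.isnan(self.mean.to_numpy())
        if (self.n.to_numpy()[present] < 1).any():
            raise ValidationError("present mean with replicate count < 1")

    @property
    def wines(self) -> list[str]:
        return list(self.mean.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.mean.columns)

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (non-missing) cells."""
        return self.mean.notna()


@dataclass
class ValidationReport:
    """Report-only panel check; the panel passes iff all lists are empty."""
    unresolved_compounds: list[str] = field(default_factory=list)
    replicates_missing_is: list[str] = field(default_factory=list)
    replicates_duplicate_is: list[str] = field(default_factory=list)
    rt_anomalies: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not (self.unresolved_compounds or self.replicates_missing_is
                    or self.replicates_duplicate_is or self.rt_anomalies)
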