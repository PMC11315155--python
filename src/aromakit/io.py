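"""Reading and writing the pipeline's tabular artifacts.

All files are comma-separated UTF-8 with a header row; missing values are
empty cells or the literal ``NA``. Peak tables need at least
``retention_time`` and ``peak_area`` columns plus a resolvable
``sample_id``. The packaged reference panel (128 volatile compounds
semi-quantified across 9 Chinese rice and grape wines, with odor
thresholds) is exposed through :func:`load_paper_fixture`.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (CHEM_CLASSES, ConcentrationMatrix, LoadReport, PeakTable,
                   ValidationReport, validate_sample_meta)
from .errors import FixtureIntegrityError, FormatError, ValidationError

_NA_VALUES = ["", "NA"]

WINE_LABELS = ["YJ", "JJ", "NEH", "GLS", "SKM", "KJS", "XH", "CC", "ZY"]

#: wine -> study group used throughout the multivariate analyses
DEFAULT_GROUPS = {
    "YJ": "Xijiao_SCT", "JJ": "Xijiao_SCT",
    "NEH": "Xijiao_LCT",
    "GLS": "MCRW", "SKM": "MCRW", "KJS": "MCRW", "XH": "MCRW",
    "CC": "GW", "ZY": "GW",
}


def read_peak_table(path: str | Path, meta: pd.DataFrame) -> tuple[PeakTable, LoadReport]:
    """Read a replicate-level peak CSV and validate it against ``meta``.

    Rows with non-positive peak area are dropped and counted in the load
    report. A replicate holding more than one internal-standard peak is a
    validation error.
    """
    frame = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False,
                        float_precision="round_trip")
    required = {"sample_id", "retention_time", "peak_area"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if "compound_id" not in frame.columns:
        frame["compound_id"] = np.nan
    if "is_internal_standard" in frame.columns:
        frame["is_internal_standard"] = frame["is_internal_standard"].astype(bool)
    else:
        frame["is_internal_standard"] = False
    keep = frame["peak_area"] > 0
    report = LoadReport(n_rows=int(keep.sum()),
                        n_dropped_nonpositive=int((~keep).sum()))
    frame = frame[keep].reset_index(drop=True)
    is_counts = frame[frame["is_internal_standard"]].groupby("sample_id").size()
    dup = is_counts[is_counts > 1]
    if len(dup):
        raise ValidationError(
            f"duplicate internal-standard peak in replicate(s): {list(dup.index)}")
    table = PeakTable(frame, validate_sample_meta(meta))
    return table, report


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write a canonicalized (sample then RT ordered) peak CSV."""
    canon = table.canonicalized()
    canon.peaks.to_csv(path, index=False, na_rep="NA")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    return validate_sample_meta(meta)


def read_compound_library(path: str | Path) -> pd.DataFrame:
    """Read a compound library CSV (compound_id, chem_class, reference_ri, ...)."""
    lib = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    if "compound_id" not in lib.columns:
        raise FormatError(f"{path}: compound library needs a compound_id column")
    if lib["compound_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate compound_id entries")
    if "chem_class" in lib.columns:
        bad = set(lib["chem_class"].dropna()) - set(CHEM_CLASSES)
        if bad:
            raise ValidationError(f"{path}: unknown chem_class values {sorted(bad)}")
    if "reference_ri" not in lib.columns:
        lib["reference_ri"] = np.nan
    return lib


def read_msp_names(path: str | Path) -> pd.DataFrame:
    """Extract compound names/CAS from a NIST MSP text library (spectra ignored)."""
    names, cas = [], []
    for line in Path(path).read_text().splitlines():
        key, _, value = line.partition(":")
        key = key.strip().lower()
        if key == "name":
            names.append(value.strip())
            cas.append("")
        elif key in ("cas#", "casno", "cas") and names:
            cas[-1] = value.strip()
    return pd.DataFrame({"compound_id": names, "cas": cas})


def read_threshold_table(path: str | Path) -> pd.DataFrame:
    """Read an odor-threshold CSV (compound, threshold_ug_per_L[, medium])."""
    thr = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    if "compound" in thr.columns and "compound_id" not in thr.columns:
        thr = thr.rename(columns={"compound": "compound_id"})
    required = {"compound_id", "threshold_ug_per_L"}
    missing = required - set(thr.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "medium" not in thr.columns:
        thr["medium"] = "unspecified"
    if (thr["threshold_ug_per_L"].dropna() <= 0).any():
        raise ValidationError(f"{path}: thresholds must be > 0 when present")
    return thr


def write_concentration_matrix(matrix: ConcentrationMatrix, path: str | Path) -> None:
    """Wide CSV with interleaved <wine>_mean / <wine>_sd column pairs."""
    out = {}
    for wine in matrix.wines:
        out[f"{wine}_mean"] = matrix.mean.loc[wine]
        out[f"{wine}_sd"] = matrix.sd.loc[wine]
    pd.DataFrame(out).rename_axis("compound").to_csv(path, na_rep="NA")


def read_concentration_matrix(path: str | Path) -> ConcentrationMatrix:
    frame = pd.read_csv(path, index_col=0, na_values=_NA_VALUES,
                        keep_default_na=False, float_precision="round_trip")
    wines = [c[:-5] for c in frame.columns if c.endswith("_mean")]
    mean = pd.DataFrame({w: frame[f"{w}_mean"] for w in wines}).T
    sd = pd.DataFrame({w: frame[f"{w}_sd"] for w in wines}).T
    sd = sd.where(mean.notna(), np.nan)
    n = mean.notna().astype(int)
    return ConcentrationMatrix(mean=mean, sd=sd, n=n)


def validate_panel(table: PeakTable, library: pd.DataFrame | None = None) -> ValidationReport:
    """Report-only structural check of a peak panel.

    Lists compound ids missing from the library, replicates without (or
    with duplicated) internal-standard peaks, and retention times that are
    non-positive.
    """
    report = ValidationReport()
    if library is not None:
        known = set(library["compound_id"])
        analytes = table.peaks[~table.peaks["is_internal_standard"]]
        seen = set(analytes["compound_id"].dropna())
        report.unresolved_compounds = sorted(seen - known)
    is_counts = table.internal_standards().groupby("sample_id").size()
    for rid in table.replicate_ids():
        count = int(is_counts.get(rid, 0))
        if count == 0:
            report.replicates_missing_is.append(rid)
        elif count > 1:
            report.replicates_duplicate_is.append(rid)
    bad_rt = table.peaks["retention_time"] <= 0
    if bad_rt.any():
        rows = table.peaks.loc[bad_rt, "sample_id"].tolist()
        report.rt_anomalies = [f"non-positive retention time in {r}" for r in rows]
    return report


# ---------------------------------------------------------------------------
# packaged reference panel
# ---------------------------------------------------------------------------

@dataclass
class PanelFixture:
    """The packaged 9-wine reference panel.

    ``concentrations``: 9 wines x 128 compounds (printed means/SDs, n=3);
    ``thresholds``: odor thresholds in ug/L; ``library``: compound metadata;
    ``printed_roav``: the OAV table as printed (numbers and ``<1`` flags);
    ``printed_class_totals``: the per-class total rows as printed.
    """
    concentrations: ConcentrationMatrix
    thresholds: pd.DataFrame
    library: pd.DataFrame
    printed_roav: pd.DataFrame
    printed_class_totals: pd.DataFrame

    #: printed per-class totals that do not equal the sum of their own
    #: printed cells (source-table inconsistencies, kept as printed)
    KNOWN_TOTAL_DISCREPANCIES = (("aldehyde", "NEH"), ("aldehyde", "KJS"))


def _fixture_bytes(name: str) -> bytes:
    return resources.files("aromakit.data").joinpath(name).read_bytes()


def load_paper_fixture() -> PanelFixture:
    """Load and checksum-verify the packaged reference panel."""
    digests = json.loads(_fixture_bytes("checksums.json"))
    for name, expected in digests.items():
        actual = hashlib.sha256(_fixture_bytes(name)).hexdigest()
        if actual != expected:
            raise FixtureIntegrityError(f"packaged fixture {name} is corrupted")

    def _read(name: str, **kwargs) -> pd.DataFrame:
        with resources.files("aromakit.data").joinpath(name).open("rb") as fh:
            return pd.read_csv(fh, **kwargs)

    table1 = _read("wine_panel_concentrations.csv",
                   na_values=_NA_VALUES, keep_default_na=False)
    thresholds = _read("odor_thresholds.csv")
    printed_roav = _read("printed_roav.csv")
    totals = _read("printed_class_totals.csv", index_col=0)

    library = table1[["compound", "cas", "chem_class", "evidence",
                      "odor_description"]].rename(columns={"compound": "compound_id"})
    library["reference_ri"] = np.nan
    mean = pd.DataFrame(
        {w: table1[f"{w}_mean"].to_numpy() for w in WINE_LABELS},
        index=table1["compound"]).T
    sd = pd.DataFrame(
        {w: table1[f"{w}_sd"].to_numpy() for w in WINE_LABELS},
        index=table1["compound"]).T
    n = mean.notna().astype(int) * 3  # three parallel measurements per cell
    n = n.where(mean.notna(), 0)
    conc = ConcentrationMatrix(mean=mean, sd=sd, n=n)
    thresholds = thresholds.rename(columns={"compound": "compound_id"})
    thresholds["medium"] = "unspecified"
    return PanelFixture(concentrations=conc, thresholds=thresholds,
                        library=library, printed_roav=printed_roav,
                        printed_class_totals=totals)
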