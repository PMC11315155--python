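"""Synthetic SPME-GC-MS wine panels with known ground truth.

The generator emulates the study design the package targets: a panel of
wines in a few groups, three replicate injections per wine, an internal
standard spiked to a fixed final concentration (328.8 ug/L of 2-octanol by
default), multiplicative log-normal concentration noise parameterized by a
coefficient of variation, a detection floor below which a compound is
simply absent from the peak list, and retention times that are affine in
the compound's reference retention index plus Gaussian jitter.

It does not simulate chromatogram shape: no peak widths, co-elution or
spectra -- a peak is a (retention time, area) pair.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import PeakTable, make_sample_meta
from .errors import ConfigurationError
from .quantify import ISConfig
from .retention import AlkaneLadder, fit_ladder


def default_ladder() -> AlkaneLadder:
    """C7..C30 ladder consistent with the default affine RT model."""
    carbons = np.arange(7, 31)
    return fit_ladder(zip(carbons, carbons * 100 * 0.02 - 10.0))


@dataclass(frozen=True)
class RtModel:
    """Affine map from retention index to minutes, with jitter.

    Defaults place RI 700..2400 between 4 and 38 minutes, matching a
    48-minute temperature-programmed run; the 0.02 min jitter SD keeps
    RI annotation solvable at the default 10-unit tolerance while staying
    nonzero.
    """
    slope_min_per_ri: float = 0.02
    intercept_min: float = -10.0
    jitter_sd_min: float = 0.02

    def rt_of(self, ri: float) -> float:
        return self.slope_min_per_ri * ri + self.intercept_min


@dataclass
class CompoundSpec:
    """One panel compound: per-wine true means (ug/L) and noise CV."""
    compound_id: str
    chem_class: str
    reference_ri: float
    means: dict[str, float]
    cvs: dict[str, float] = field(default_factory=dict)
    default_cv: float = 0.1

    def cv_for(self, wine: str) -> float:
        return self.cvs.get(wine, self.default_cv)


@dataclass
class GroupSpec:
    label: str
    wines: list[str]
    n_replicates: int = 3


@dataclass
class PanelSpec:
    """Complete recipe for a synthetic panel; a seed makes it deterministic."""
    groups: list[GroupSpec]
    compounds: list[CompoundSpec]
    lod: float = 0.5
    rt_model: RtModel = field(default_factory=RtModel)
    is_config: ISConfig = field(default_factory=ISConfig)
    is_reference_ri: float = 996.0      # 2-octanol on a 5%-phenyl column
    is_area_nominal: float = 1.0e6
    is_area_cv: float = 0.05
    alkane_ladder: AlkaneLadder = field(default_factory=default_ladder)
    label_peaks: bool = True
    markers: dict[str, tuple[str, float]] = field(default_factory=dict)
    seed: int = 0

    def sample_meta(self) -> pd.DataFrame:
        rows = []
        for group in self.groups:
            for wine in group.wines:
                for rep in range(1, group.n_replicates + 1):
                    rows.append((f"{wine}{rep}", wine, group.label, rep))
        return make_sample_meta(rows)

    def wine_groups(self) -> dict[str, str]:
        return {w: g.label for g in self.groups for w in g.wines}

    def library(self) -> pd.DataFrame:
        return pd.DataFrame({
            "compound_id": [c.compound_id for c in self.compounds],
            "chem_class": [c.chem_class for c in self.compounds],
            "reference_ri": [c.reference_ri for c in self.compounds],
        })


@dataclass
class GroundTruth:
    """What the generator actually drew, peak by peak."""
    records: pd.DataFrame   # sample_id, compound_id, true_concentration, detected, true_rt
    is_areas: pd.Series     # per replicate
    markers: dict[str, tuple[str, float]]

    def true_concentration(self, sample_id: str, compound_id: str) -> float:
        rec = self.records
        row = rec[(rec["sample_id"] == sample_id)
                  & (rec["compound_id"] == compound_id)]
        return float(row["true_concentration"].iloc[0])


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def generate_panel(spec: PanelSpec) -> tuple[PeakTable, GroundTruth]:
    """Draw one panel. Identical specs (and seeds) give identical output."""
    rng = np.random.default_rng(spec.seed)
    meta = spec.sample_meta()
    peak_rows = []
    truth_rows = []
    is_areas = {}
    for group in spec.groups:
        for wine in group.wines:
            for rep in range(1, group.n_replicates + 1):
                sid = f"{wine}{rep}"
                a_is = _lognormal(rng, spec.is_area_nominal, spec.is_area_cv)
                is_areas[sid] = a_is
                rt_is = spec.rt_model.rt_of(spec.is_reference_ri) \
                    + rng.normal(0, spec.rt_model.jitter_sd_min)
                peak_rows.append((sid, rt_is, a_is, spec.is_config.name, True))
                for comp in spec.compounds:
                    mean = comp.means.get(wine)
                    if mean is None or mean <= 0:
                        continue
                    c_true = _lognormal(rng, mean, comp.cv_for(wine))
                    rt_true = spec.rt_model.rt_of(comp.reference_ri) \
                        + rng.normal(0, spec.rt_model.jitter_sd_min)
                    detected = c_true >= spec.lod
                    truth_rows.append((sid, comp.compound_id, c_true,
                                       detected, rt_true))
                    if not detected:
                        continue
                    area = c_true / spec.is_config.final_concentration * a_is
                    label = comp.compound_id if spec.label_peaks else np.nan
                    peak_rows.append((sid, rt_true, area, label, False))
    peaks = pd.DataFrame(
        peak_rows, columns=["sample_id", "retention_time", "peak_area",
                            "compound_id", "is_internal_standard"])
    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "compound_id", "true_concentration",
                             "detected", "true_rt"])
    ground = GroundTruth(records=truth, is_areas=pd.Series(is_areas),
                         markers=dict(spec.markers))
    return PeakTable(peaks, meta), ground


def plant_markers(spec: PanelSpec, compound_ids, fold_change: float,
                  target_group: str) -> PanelSpec:
    """Multiply the target group's means for the named compounds.

    Returns a new spec; marker identities are recorded so downstream
    recovery experiments know the ground truth.
    """
    if fold_change <= 0:
        raise ConfigurationError("fold_change must be positive")
    groups = {g.label: g for g in spec.groups}
    if target_group not in groups:
        raise ConfigurationError(f"unknown group {target_group!r}")
    known = {c.compound_id for c in spec.compounds}
    unknown = set(compound_ids) - known
    if unknown:
        raise ConfigurationError(f"unknown compound ids: {sorted(unknown)}")
    wines = set(groups[target_group].wines)
    new_compounds = []
    for comp in spec.compounds:
        if comp.compound_id in set(compound_ids):
            means = {w: (m * fold_change if w in wines else m)
                     for w, m in comp.means.items()}
            comp = replace(comp, means=means)
        new_compounds.append(comp)
    markers = dict(spec.markers)
    markers.update({c: (target_group, fold_change) for c in compound_ids})
    return replace(spec, compounds=new_compounds, markers=markers)


def two_group_spec(n_markers: int = 13, n_nulls: int = 60,
                   fold_change: float = 4.0, cv: float = 0.25,
                   n_replicates: int = 3, n_control_wines: int = 2,
                   n_treated_wines: int = 1, seed: int = 0) -> PanelSpec:
    """Marker-recovery study design: two groups with planted markers.

    The default shape mirrors the cellar-time contrast of the reference
    study -- two wines in the control-like group against one in the
    treated group, three replicate injections each (nine samples).
    Baseline means are log-uniform over 10..1000 ug/L (drawn from the same
    seed), identical between groups except for the planted fold change.
    """
    rng = np.random.default_rng(seed)
    n = n_markers + n_nulls
    base = np.exp(rng.uniform(np.log(10.0), np.log(1000.0), size=n))
    ctl = [f"C{k + 1}" for k in range(n_control_wines)]
    trt = [f"T{k + 1}" for k in range(n_treated_wines)]
    compounds = [
        CompoundSpec(
            compound_id=f"{'marker' if i < n_markers else 'null'}_{i:03d}",
            chem_class="ester",
            reference_ri=760.0 + 12.0 * i,
            means={w: float(base[i]) for w in ctl + trt},
            default_cv=cv,
        )
        for i in range(n)
    ]
    spec = PanelSpec(
        groups=[GroupSpec("control", ctl, n_replicates),
                GroupSpec("treated", trt, n_replicates)],
        compounds=compounds,
        seed=seed,
    )
    marker_ids = [c.compound_id for c in compounds[:n_markers]]
    return plant_markers(spec, marker_ids, fold_change, "treated")


def marker_recovery(spec: PanelSpec, n_orthogonal: int = 1,
                    log_transform: bool = True) -> dict:
    """Run the full generate -> quantify -> OPLS-DA -> VIP>1 experiment.

    Concentrations are imputed, quotient-normalized against the first
    replicate, log-transformed (they are log-normal by construction, so
    the log makes replicate noise homoscedastic) and Pareto-scaled before
    the model fit. Returns recovery (fraction of planted markers with
    VIP > 1) and the false share among selections.
    """
    from . import chemometrics as chem
    from .quantify import semi_quantify

    table, truth = generate_panel(spec)
    records = semi_quantify(table, spec.is_config)
    wide = chem.replicate_matrix(records, table.meta)
    imputed, _ = chem.impute_missing(wide)
    normalized = chem.normalize_to_reference(imputed, imputed.index[0])
    if log_transform:
        normalized = np.log(normalized)
    scaled = chem.pareto_scale(normalized)
    y = table.meta.set_index("sample_id")["group_label"] \
        .loc[scaled.index].to_numpy()
    model = chem.fit_oplsda(scaled, y, n_orthogonal=n_orthogonal)
    vip = chem.compute_vip(model)
    selected = chem.select_discriminants(vip)
    markers = set(truth.markers)
    hits = [c for c in selected.index if c in markers]
    return {
        "vip": vip,
        "selected": list(selected.index),
        "markers": sorted(markers),
        "recovery": len(hits) / max(len(markers), 1),
        "false_share": (len(selected) - len(hits)) / max(len(selected), 1),
        "model": model,
        "scaled": scaled,
        "labels": y,
    }


def fixture_spec(default_cv: float = 0.1) -> PanelSpec:
    """PanelSpec mirroring the packaged 9-wine reference panel.

    Per-wine means equal the packaged concentration table; CVs are sd/mean
    per cell (``default_cv`` where the printed SD is missing). Reference
    retention indices are synthetic -- the source table prints none -- and
    are spaced 12 index units apart so that RI annotation is solvable.
    """
    from .io import DEFAULT_GROUPS, load_paper_fixture

    fixture = load_paper_fixture()
    conc = fixture.concentrations
    classes = fixture.library.set_index("compound_id")["chem_class"]
    compounds = []
    for i, compound in enumerate(conc.compounds):
        means, cvs = {}, {}
        for wine in conc.wines:
            m = conc.mean.at[wine, compound]
            if pd.isna(m):
                continue
            means[wine] = float(m)
            s = conc.sd.at[wine, compound]
            if pd.notna(s) and m > 0:
                cvs[wine] = float(s / m)
        compounds.append(CompoundSpec(
            compound_id=compound, chem_class=classes[compound],
            reference_ri=750.0 + 12.0 * i, means=means, cvs=cvs,
            default_cv=default_cv))
    groups: dict[str, list[str]] = {}
    for wine, group in DEFAULT_GROUPS.items():
        groups.setdefault(group, []).append(wine)
    return PanelSpec(
        groups=[GroupSpec(label, wines, 3) for label, wines in groups.items()],
        compounds=compounds,
    )
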