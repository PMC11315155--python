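"""End-to-end orchestration: validate -> annotate -> quantify -> ROAV ->
chemometrics -> report bundle.

Every run writes a manifest carrying the configuration hash, the seed and
one log line per stage, so any numeric output is traceable to the exact
configuration that produced it. A stage failure aborts the run, removes
the partial outputs and re-raises with the stage name attached.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import chemometrics as chem
from .errors import AromakitError, ConfigurationError
from .io import (load_paper_fixture, read_compound_library, read_peak_table,
                 read_sample_meta, read_threshold_table, validate_panel,
                 write_concentration_matrix)
from .quantify import ISConfig, aggregate_replicates, class_totals, semi_quantify
from .retention import DEFAULT_RI_TOLERANCE, annotate_peaks, read_ladder
from .roav import compute_roav, select_key_odorants


@dataclass
class ChemometricsOptions:
    enabled: bool = True
    metric: str = "braycurtis"
    folds: int = 5
    permutations: int = 100
    max_components: int = 5
    reference_sample: str | None = None
    seed: int = 17


@dataclass
class PipelineConfig:
    """Input paths and stage options for one pipeline run."""
    peaks: str
    meta: str
    library: str
    thresholds: str
    out_dir: str
    ladder: str | None = None
    is_name: str = "2-octanol"
    is_concentration: float = 328.8
    ri_tolerance: float = DEFAULT_RI_TOLERANCE
    roav_cutoff: float = 1.0
    chemometrics: ChemometricsOptions = field(default_factory=ChemometricsOptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        chem_opts = ChemometricsOptions(**raw.pop("chemometrics", {}))
        return cls(chemometrics=chem_opts, **raw)

    def digest(self) -> str:
        """Hash of every analytic field (where outputs go does not change
        what they contain, so ``out_dir`` is excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")
        blob = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class ReportBundle:
    """Paths of everything a run wrote, keyed by artifact name."""
    out_dir: Path
    artifacts: dict[str, Path]
    manifest: dict


class StageFailure(AromakitError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: list[dict] = []
    stage = "load"

    def done(name: str, **counts) -> None:
        log.append({"stage": name, **counts})

    try:
        for path_attr in ("peaks", "meta", "library", "thresholds"):
            if not Path(getattr(config, path_attr)).exists():
                raise ConfigurationError(
                    f"input file for {path_attr!r} not found: "
                    f"{getattr(config, path_attr)}")
        meta = read_sample_meta(config.meta)
        library = read_compound_library(config.library)
        table, load_report = read_peak_table(config.peaks, meta)
        done("load", rows=load_report.n_rows,
             dropped=load_report.n_dropped_nonpositive)

        stage = "validate"
        unannotated = table.peaks["compound_id"].isna() \
            & ~table.peaks["is_internal_standard"]
        report = validate_panel(
            table, library if not unannotated.any() else None)
        if not report.passed:
            raise AromakitError(f"panel validation failed: {report}")
        done("validate", replicates=len(table.meta))

        if config.ladder is not None:
            stage = "annotate"
            ladder = read_ladder(config.ladder)
            table = annotate_peaks(table, library, ladder,
                                   tolerance=config.ri_tolerance)
            done("annotate",
                 annotated=int(table.peaks["compound_id"].notna().sum()))

        stage = "quantify"
        is_config = ISConfig(config.is_name, config.is_concentration)
        records = semi_quantify(table, is_config)
        matrix = aggregate_replicates(records, meta)
        path = out / "concentration_matrix.csv"
        write_concentration_matrix(matrix, path)
        artifacts["concentration_matrix"] = path
        if library["chem_class"].notna().all():
            totals = class_totals(matrix, library)
            path = out / "class_totals.csv"
            totals.rename_axis("wine").to_csv(path)
            artifacts["class_totals"] = path
        done("quantify", records=len(records))

        stage = "roav"
        thresholds = read_threshold_table(config.thresholds)
        roav_result = compute_roav(matrix, thresholds, cutoff=config.roav_cutoff)
        path = out / "roav.csv"
        roav_result.records.to_csv(path, index=False)
        artifacts["roav"] = path
        key = select_key_odorants(roav_result, cutoff=config.roav_cutoff)
        key_json = {
            "cutoff": config.roav_cutoff,
            "key_odorants": {w: frame["compound_id"].tolist()
                             for w, frame in key.items()},
            "unevaluable": roav_result.unevaluable,
        }
        path = out / "key_odorants.json"
        path.write_text(json.dumps(key_json, indent=1) + "\n")
        artifacts["key_odorants"] = path
        done("roav", records=len(roav_result.records),
             unevaluable=len(roav_result.unevaluable))

        opts = config.chemometrics
        groups = meta.set_index("sample_id")["group_label"]
        if opts.enabled and groups.nunique() >= 2:
            stage = "chemometrics"
            wide = chem.replicate_matrix(records, meta)
            imputed, dropped = chem.impute_missing(wide)
            reference = opts.reference_sample or imputed.index[0]
            normalized = chem.normalize_to_reference(imputed, reference)
            scaled = chem.pareto_scale(normalized)
            y = groups.loc[scaled.index].to_numpy()

            ordination = chem.pcoa(imputed, metric=opts.metric)
            path = out / "pcoa_coordinates.csv"
            ordination.coordinates.rename_axis("sample_id").to_csv(path)
            artifacts["pcoa_coordinates"] = path
            path = out / "spearman.csv"
            chem.spearman_matrix(imputed).rename_axis("sample_id").to_csv(path)
            artifacts["spearman"] = path

            n_comp = chem.choose_n_components(
                scaled, y, max_components=opts.max_components,
                folds=opts.folds, seed=opts.seed)
            spec = chem.ModelSpec("plsda", n_components=n_comp)
            model = spec.fit(scaled, y)
            vip = chem.compute_vip(model)
            validation = chem.permutation_test(
                scaled, y, spec, n_permutations=opts.permutations,
                folds=opts.folds, seed=opts.seed)
            path = out / "plsda_scores.csv"
            model.scores_frame(index=scaled.index).rename_axis("sample_id").to_csv(path)
            artifacts["plsda_scores"] = path
            path = out / "vip.csv"
            pd.DataFrame({"vip": vip}).rename_axis("compound").to_csv(path)
            artifacts["vip"] = path
            validation_json = {
                "model": "plsda", "n_components": n_comp,
                "r2": validation.r2, "q2": validation.q2,
                "folds": validation.folds,
                "permutation_p": validation.permutation_p,
                "n_permutations": validation.n_permutations,
                "dropped_columns": dropped,
                "provenance": scaled.attrs.get("provenance", []),
            }
            if groups.nunique() == 2:
                ospec = chem.ModelSpec("oplsda", n_orthogonal=1)
                omodel = ospec.fit(scaled, y)
                ovip = chem.compute_vip(omodel)
                path = out / "oplsda_vip.csv"
                pd.DataFrame({"vip": ovip}).rename_axis("compound").to_csv(path)
                artifacts["oplsda_vip"] = path
                oval = chem.permutation_test(
                    scaled, y, ospec, n_permutations=opts.permutations,
                    folds=opts.folds, seed=opts.seed)
                validation_json["oplsda"] = {
                    "r2": oval.r2, "q2": oval.q2,
                    "permutation_p": oval.permutation_p,
                }
            path = out / "validation.json"
            path.write_text(json.dumps(validation_json, indent=1) + "\n")
            artifacts["validation"] = path
            done("chemometrics", samples=len(scaled), compounds=scaled.shape[1])

        stage = "manifest"
        manifest = {
            "aromakit_version": __version__,
            "config_sha256": config.digest(),
            "seed": config.chemometrics.seed,
            "stages": log,
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=1) + "\n")
        artifacts["manifest"] = path
    except Exception as exc:
        # no partial bundles: drop whatever this run managed to write
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for p in artifacts.values():
                p.unlink(missing_ok=True)
        raise StageFailure(stage, exc) from exc
    return ReportBundle(out_dir=out, artifacts=artifacts, manifest=manifest)


def fixture_report(out_dir: str | Path, cutoff: float = 1.0) -> ReportBundle:
    """Recompute ROAVs, key odorants and class totals from the packaged panel."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture = load_paper_fixture()
    result = compute_roav(fixture.concentrations, fixture.thresholds, cutoff=cutoff)
    key = select_key_odorants(result, cutoff=cutoff)
    totals = class_totals(fixture.concentrations, fixture.library)
    artifacts = {}
    path = out / "roav.csv"
    result.records.to_csv(path, index=False)
    artifacts["roav"] = path
    path = out / "key_odorants.json"
    path.write_text(json.dumps(
        {"cutoff": cutoff,
         "counts": {w: len(f) for w, f in key.items()},
         "key_odorants": {w: f["compound_id"].tolist() for w, f in key.items()},
         "unevaluable": result.unevaluable}, indent=1) + "\n")
    artifacts["key_odorants"] = path
    path = out / "class_totals.csv"
    totals.rename_axis("wine").to_csv(path)
    artifacts["class_totals"] = path
    manifest = {"aromakit_version": __version__, "mode": "fixture",
                "cutoff": cutoff}
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1) + "\n")
    artifacts["manifest"] = path
    return ReportBundle(out_dir=out, artifacts=artifacts, manifest=manifest)
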