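"""End-to-end orchestration of the two-pass ensemble procedure.

One run: ingest and deduplicate records; clip the stack to the study area;
delimit the occupied envelope with the one-class profile and draw
density-weighted pseudo-absences from outside it; screen correlated
variables (PCA-guided greedy scan on presences + pseudo-absences); build
the balanced 80/20 design; fit the seven families; merge by AUC-weighted
consensus.  The whole sequence executes twice — once with all records and
once with breeding-evidence records only (its own profile, pseudo-absences
and design, same retained variables) — then the reproductive consensus is
Gaussian-blurred at the home-range scale, combined with the all-records
consensus, and binarized at the equal-sensitivity/specificity threshold
evaluated on the all-records held-out partition.

Every intermediate artifact is written; the run manifest records the
config, per-family AUCs, and SHA-256 hashes of each output so reruns can
be compared byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import background, classify_report, ensemble_merge, environment, occurrences, sdm_models
from .environment import EnvStack, RasterGrid
from .sdm_models import MODEL_FAMILIES, ModelSpec, SuitabilityMap
from .synthetic_data import METERS_PER_DEGREE

logger = logging.getLogger("harpyrange")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    occurrences_csv: str
    stack_manifest: str
    popdensity: str
    outdir: str
    seed: int = 0
    r_threshold: float = 0.7
    inclusion_target: float = 0.90
    test_fraction: float = 0.20
    families: tuple[str, ...] = MODEL_FAMILIES
    blur_mode: str = "literal"
    combine_rule: str = "product"
    max_lat: float = 40.0
    reference_area_km2: Optional[float] = None
    bias_permutations: int = 199

    def __post_init__(self):
        for name, v in (("r_threshold", self.r_threshold),
                        ("inclusion_target", self.inclusion_target),
                        ("test_fraction", self.test_fraction)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        unknown = set(self.families) - set(MODEL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families {sorted(unknown)}")
        if len(self.families) < 2:
            raise ValueError("at least two model families required")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    aucs: dict = field(default_factory=dict)  # run label -> family -> auc
    artifacts: dict = field(default_factory=dict)  # name -> {path, sha256}
    counts: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cell_area_km2(grid: RasterGrid) -> float:
    cs = grid.geotransform[2]
    if grid.crs.upper() in {"EPSG:4326", "WGS84", "CRS:84"}:
        cs = cs * METERS_PER_DEGREE
    return (cs / 1000.0) ** 2


def _stage(manifest: RunManifest, name: str):
    manifest.timestamps[name] = time.strftime("%Y-%m-%dT%H:%M:%S")
    logger.info("%s | start", name)


class _Artifacts:
    def __init__(self, manifest: RunManifest, outdir: Path):
        self.manifest = manifest
        self.outdir = outdir

    def save_map(self, name: str, smap: SuitabilityMap | RasterGrid) -> Path:
        grid = smap.grid if hasattr(smap, "grid") else smap
        path = self.outdir / f"{name}.asc"
        environment.write_raster(grid, path)
        self.manifest.artifacts[name] = {"path": str(path), "sha256": _sha256(path)}
        return path

    def save_text(self, name: str, path: Path) -> None:
        self.manifest.artifacts[name] = {"path": str(path), "sha256": _sha256(path)}


def _single_pass(
    label: str,
    presence_cells: pd.DataFrame,
    stack: EnvStack,
    popdensity: RasterGrid,
    retained: Sequence[str] | None,
    config: PipelineConfig,
    seed_base: int,
    art: _Artifacts,
):
    """Profile -> pseudo-absences -> (screen) -> design -> 7 fits -> consensus.

    ``presence_cells`` is the extracted feature table (all layers plus
    row/col).  Returns (consensus, models, design, selection, absences).
    """
    layer_names = stack.names
    pres_X_full = presence_cells[layer_names]

    profile = background.fit_environmental_profile(
        pres_X_full, inclusion_target=config.inclusion_target
    )
    suitable = background.classify_cells(profile, stack)
    unsuitable = suitable.copy_with(
        np.where(suitable.valid_mask(), 1.0 - suitable.values, suitable.nodata)
    )
    art.save_map(f"{label}_unsuitable_region", unsuitable)

    pres_keys = set(zip(presence_cells["row"].astype(int), presence_cells["col"].astype(int)))
    absences = background.sample_pseudo_absences(
        unsuitable, popdensity, n=len(presence_cells),
        seed=(seed_base + 11) % 2**31, exclude_cells=pres_keys,
    )
    abs_X_full, _ = environment.extract_values(stack, absences)

    if retained is None:
        screen = pd.concat(
            [pres_X_full, abs_X_full[layer_names]], ignore_index=True
        )
        selection = environment.select_variables_pca(screen, config.r_threshold)
        retained = selection.retained
    else:
        selection = None

    design = background.build_design(
        pres_X_full[list(retained)],
        abs_X_full[list(retained)],
        test_fraction=config.test_fraction,
        seed=(seed_base + 23) % 2**31,
    )

    models, maps, aucs = {}, {}, {}
    for fam in config.families:
        spec = ModelSpec(family=fam, seed=(seed_base + 31) % 2**31)
        m = sdm_models.fit_model(spec, design)
        models[fam] = m
        maps[fam] = sdm_models.predict_map(m, stack)
        aucs[fam] = m.test_auc
        art.save_map(f"{label}_{fam}", maps[fam])
        logger.info("%s | fit %s | test AUC %.4f", label, fam, m.test_auc)

    consensus = ensemble_merge.consensus_weighted(maps, aucs)
    art.save_map(f"consensus_{label}", consensus.grid)
    return consensus, models, design, selection, absences, profile


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full two-pass procedure and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config))
    art = _Artifacts(manifest, outdir)
    stage = "ingest"
    try:
        _stage(manifest, stage)
        occ = occurrences.read_occurrences_csv(config.occurrences_csv)
        occ = occurrences.filter_study_area(occ, config.max_lat)
        stack = EnvStack.read(config.stack_manifest)
        popdensity = environment.read_raster(config.popdensity)
        popdensity.crs = stack.ref.crs
        if not popdensity.same_grid(stack.ref):
            raise PipelineError("population-density grid is not co-registered with the stack")

        stage = "clip"
        _stage(manifest, stage)
        stack = environment.clip_study_area(stack, config.max_lat)
        occ = occurrences.dedup_pseudoreplicates(occ, stack.ref)
        breeding, _nonbreeding = occurrences.classify_breeding(occ)
        manifest.counts = {
            "n_records": len(occ),
            "n_breeding": len(breeding),
            "n_nonbreeding": len(_nonbreeding),
        }
        assert len(breeding) <= len(occ)

        stage = "extract"
        _stage(manifest, stage)
        X_all, log_all = environment.extract_values(stack, occ)
        manifest.counts["extraction"] = log_all
        breeding_ids = {r.id for r in breeding}
        all_ids = [r.id for r in occ]
        breed_pos = {i for i, rid in enumerate(all_ids) if rid in breeding_ids}
        X_breed = X_all.loc[[i for i in X_all.index if i in breed_pos]]

        stage = "all_records_pass"
        _stage(manifest, stage)
        cons_all, models_all, design_all, selection, abs_all, prof_all = _single_pass(
            "all", X_all, stack, popdensity, None, config, config.seed * 1000 + 1, art
        )
        retained = selection.retained
        sel_path = outdir / "variable_selection.json"
        selection.to_json(sel_path)
        art.save_text("variable_selection", sel_path)
        manifest.counts["retained_variables"] = retained
        manifest.counts["profile_inclusion_all"] = prof_all.achieved_inclusion

        stage = "breeding_pass"
        _stage(manifest, stage)
        cons_rep, models_rep, design_rep, _, abs_rep, prof_rep = _single_pass(
            "repro", X_breed, stack, popdensity, retained, config,
            config.seed * 1000 + 2, art,
        )
        manifest.counts["profile_inclusion_repro"] = prof_rep.achieved_inclusion
        manifest.aucs = {
            "all": {f: m.test_auc for f, m in models_all.items()},
            "reproductive": {f: m.test_auc for f, m in models_rep.items()},
        }
        auc_csv = outdir / "auc_table.csv"
        pd.concat([
            sdm_models.auc_table(models_all, "All"),
            sdm_models.auc_table(models_rep, "Reproductive"),
        ]).to_csv(auc_csv, index=False)
        art.save_text("auc_table", auc_csv)

        stage = "merge"
        _stage(manifest, stage)
        blur = ensemble_merge.derive_blur_sd(mode=config.blur_mode)
        repro_blurred = ensemble_merge.gaussian_blur_map(cons_rep.grid, blur)
        art.save_map("repro_blurred", repro_blurred)
        final = ensemble_merge.combine_final(cons_all, repro_blurred, config.combine_rule)
        art.save_map("final_continuous", final)

        stage = "threshold"
        _stage(manifest, stage)
        test_rows = design_all.is_test
        labels = design_all.labels[test_rows]
        cells = np.concatenate([
            X_all[["row", "col"]].to_numpy(int),
            abs_all[["row", "col"]].to_numpy(int),
        ])[test_rows]
        consensus_scores = cons_all.grid.grid.values[cells[:, 0], cells[:, 1]]
        consensus_test_auc = sdm_models.compute_auc(labels, consensus_scores)
        scores = final.grid.values[cells[:, 0], cells[:, 1]]
        final_test_auc = sdm_models.compute_auc(labels, scores)
        t, sens, spec = classify_report.threshold_equal_ss(
            scores[labels == 1], scores[labels == 0]
        )
        bmap = classify_report.binarize(final, t)
        bmap.sensitivity_at_t, bmap.specificity_at_t = sens, spec
        art.save_map("final_binary", bmap.grid)

        stage = "report"
        _stage(manifest, stage)
        report = classify_report.range_area(
            bmap, _cell_area_km2(stack.ref), config.reference_area_km2
        )
        diag = classify_report.bias_diagnostic(
            final, popdensity,
            presence_cells=X_all[["row", "col"]].to_numpy(int),
            absence_cells=abs_all[["row", "col"]].to_numpy(int),
            n_permutations=config.bias_permutations,
            seed=(config.seed * 1000 + 7) % 2**31,
        )
        manifest.report = {
            "threshold": t,
            "sensitivity": sens,
            "specificity": spec,
            "consensus_test_auc": consensus_test_auc,
            "final_test_auc": final_test_auc,
            "blur_sd_m": blur.sd_map_units,
            "blur_mode": config.blur_mode,
            "combine_rule": config.combine_rule,
            "area_km2": report.area_km2,
            "n_presence_cells": report.n_presence_cells,
            "percent_reduction": report.percent_reduction,
            "bias_diagnostic": diag,
        }
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(manifest.report, indent=1))
        art.save_text("report", report_path)
        pd.DataFrame([{k: v for k, v in manifest.report.items() if not isinstance(v, dict)}]).to_csv(
            outdir / "report.csv", index=False
        )

        manifest.write(outdir / "manifest.json")
        return manifest
    except PipelineError:
        manifest.write(outdir / "manifest.json")
        raise
    except Exception as exc:
        manifest.write(outdir / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def run_synthetic(
    synth_config,
    outdir: str | Path,
    **overrides,
):
    """Generate a seeded synthetic dataset, run the pipeline on it, and
    return (manifest, dataset).

    Convenience wrapper used by validation studies: the virtual species'
    true suitability in ``dataset.species`` allows pattern-recovery checks
    against the pipeline's final map.
    """
    from . import synthetic_data

    outdir = Path(outdir)
    ds = synthetic_data.make_dataset(synth_config)
    paths = synthetic_data.write_dataset(ds, outdir / "fixture")
    cfg = PipelineConfig(
        occurrences_csv=str(paths["occurrences"]),
        stack_manifest=str(paths["stack_manifest"]),
        popdensity=str(paths["popdensity"]),
        outdir=str(outdir / "run"),
        seed=synth_config.seed,
        **overrides,
    )
    manifest = run_all(cfg)
    return manifest, ds
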