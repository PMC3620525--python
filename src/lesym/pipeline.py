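"""End-to-end pipeline: lesions -> scores -> VLSM -> tract ROIs -> ladder.

Stage order follows the two-stage analysis design: first assumption-free
voxel-based lesion-symptom mapping per lesion class, then the tract-ROI
regional analysis on the tracts selected from the VLSM map, and finally the
hierarchical regression ladder quantifying strategic-location effects over
total lesion burden.

A lesion class whose eligibility mask is empty (no voxel lesioned in at
least ``min_patients`` patients — typical for sparse lacunes) is skipped
with an explicit notice; ROI volumetry and the ladder still run.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cognition import composite_scores, residualize
from .cohort import LesionCohort, read_cohort
from .io import save_volume, write_atlas, write_cohort, write_table
from .ladder import LadderResult, RegressionLadder
from .simulate import SimulationConfig, default_config, ground_truth, simulate_cohort
from .tracts import TractAtlas, binarize_atlas, regional_volumes, tract_summary
from .vlsm import InsufficientCoverageError, LesionSymptomMapper

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of a full run.

    In ``synthetic`` mode a cohort is generated from ``sim`` (defaults to
    :func:`lesym.simulate.default_config` with the run seed); in ``files``
    mode ``manifest``, ``atlas_paths``, ``subtests_path`` and
    ``covariates_path`` must point at existing inputs.
    """

    mode: str = "synthetic"  # "synthetic" | "files"
    sim: SimulationConfig | None = None
    manifest: str | None = None
    atlas_paths: dict[str, str] | None = None
    subtests_path: str | None = None
    covariates_path: str | None = None

    domain: str = "executive"
    lesion_classes: tuple[str, ...] = ("wml", "ll")
    selection_class: str = "wml"  # class whose VLSM map drives tract selection
    min_patients: int = 5
    q: float = 0.05
    alternative: str = "greater"
    atlas_threshold: float = 0.1
    min_total_voxels: int = 50
    min_cluster_voxels: int = 5
    connectivity: int = 26
    ladder_tracts: tuple[str, str] | None = None  # default: top-2 by overlap
    seed: int = 0
    out_dir: str | None = None
    write_volumes: bool = True


@dataclass
class PipelineReport:
    """In-memory results of one pipeline run."""

    config: PipelineConfig
    cohort: LesionCohort
    atlas: TractAtlas
    scores: pd.DataFrame
    residuals: pd.DataFrame
    vlsm: dict[str, LesionSymptomMapper]
    skipped: dict[str, str]
    summary: "pd.DataFrame"
    selected_tracts: tuple[str, ...]
    ladder_tracts: tuple[str, str]
    regional: pd.DataFrame
    ladder: LadderResult
    counts: dict[str, object]


def _load_inputs(config: PipelineConfig):
    if config.mode == "synthetic":
        sim = config.sim or default_config(seed=config.seed)
        atlas, cohort, covariates, subtests, _ = simulate_cohort(sim)
        return atlas, cohort, covariates, subtests, sim.subtest_scheme()
    if config.mode != "files":
        raise ValueError("mode must be 'synthetic' or 'files'")
    for name in ("manifest", "atlas_paths", "subtests_path", "covariates_path"):
        if getattr(config, name) in (None, {}):
            raise ValueError(f"files mode requires {name}")
    cohort = read_cohort(config.manifest)
    atlas = TractAtlas.from_niftis(config.atlas_paths)
    subtests = pd.read_csv(config.subtests_path, sep="\t").set_index("patient_id")
    covariates = pd.read_csv(config.covariates_path, sep="\t").set_index("patient_id")
    return atlas, cohort, covariates, subtests, None


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage and (optionally) write the report bundle."""
    atlas, cohort, covariates, subtests, scheme = _load_inputs(config)
    cohort.grid.require_match(atlas.grid, "cohort vs atlas")

    scores = composite_scores(subtests, scheme=scheme)
    residuals = residualize(scores, covariates)
    totals = cohort.total_volumes()

    vlsm_fits: dict[str, LesionSymptomMapper] = {}
    skipped: dict[str, str] = {}
    for cls in config.lesion_classes:
        mapper = LesionSymptomMapper(
            lesion_class=cls,
            min_patients=config.min_patients,
            q=config.q,
            alternative=config.alternative,
            connectivity=config.connectivity,
        )
        try:
            mapper.fit(cohort, residuals[config.domain])
            vlsm_fits[cls] = mapper
            log.info("VLSM %s: %d eligible voxels, %d significant", cls,
                     mapper.mask_.n_voxels, mapper.fdr_.n_significant)
        except InsufficientCoverageError as exc:
            skipped[cls] = str(exc)
            log.warning("VLSM skipped for %s: %s", cls, exc)

    masks = binarize_atlas(atlas, config.atlas_threshold)
    if config.selection_class in vlsm_fits:
        sel = vlsm_fits[config.selection_class]
        summary = tract_summary(
            sel.fdr_.sig_mask,
            sel.clusters_.labels,
            masks,
            min_total=config.min_total_voxels,
            min_cluster=config.min_cluster_voxels,
            connectivity=config.connectivity,
        )
    else:
        empty = np.zeros(cohort.grid.shape, dtype=bool)
        summary = tract_summary(empty, empty.astype(int), masks,
                                min_total=config.min_total_voxels,
                                min_cluster=config.min_cluster_voxels)
    selected = summary.selected

    if config.ladder_tracts is not None:
        pair = tuple(config.ladder_tracts)
    else:
        ranked = summary.table.sort_values(
            ["selected", "n_significant"], ascending=False
        ).index.tolist()
        if len(ranked) < 2:
            raise ValueError("ladder needs at least two tracts in the atlas")
        pair = (ranked[0], ranked[1])

    regional = regional_volumes(cohort, masks)
    ladder_est = RegressionLadder(tracts=pair, domain=config.domain)
    ladder_est.fit(scores, covariates, totals, regional)
    ladder = ladder_est.result_

    counts = {
        "n_patients": cohort.n_patients,
        "n_ladder": ladder_est.n_used_,
        "eligible_voxels": {c: int(m.mask_.n_voxels) for c, m in vlsm_fits.items()},
        "significant_voxels": {c: int(m.fdr_.n_significant) for c, m in vlsm_fits.items()},
        "t_cutoff": {c: m.fdr_.t_cutoff for c, m in vlsm_fits.items()},
        "skipped": skipped,
        "tracts_selected": list(selected),
        "ladder_tracts": list(pair),
    }

    report = PipelineReport(
        config=config, cohort=cohort, atlas=atlas, scores=scores,
        residuals=residuals, vlsm=vlsm_fits, skipped=skipped, summary=summary.table,
        selected_tracts=selected, ladder_tracts=pair, regional=regional,
        ladder=ladder, counts=counts,
    )
    if config.out_dir is not None:
        _write_bundle(report, Path(config.out_dir))
    return report


def _write_bundle(report: PipelineReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    if cfg.write_volumes:
        if cfg.mode == "synthetic":
            write_cohort(report.cohort, out / "cohort")
            write_atlas(report.atlas, out / "atlas")
            sim = cfg.sim or default_config(seed=cfg.seed)
            ground_truth(sim).to_json(out / "ground_truth.json")
        for cls, mapper in report.vlsm.items():
            save_volume(mapper.prevalence_.counts, report.cohort.grid,
                        out / f"prevalence_{cls}.nii.gz", dtype=np.int16)
            save_volume(mapper.mask_.mask, report.cohort.grid, out / f"mask_{cls}.nii.gz")
            save_volume(np.nan_to_num(mapper.tmap_.t), report.cohort.grid,
                        out / f"tmap_{cls}.nii.gz", dtype=np.float32)
            save_volume(np.nan_to_num(mapper.tmap_.p, nan=1.0), report.cohort.grid,
                        out / f"pmap_{cls}.nii.gz", dtype=np.float32)
            save_volume(mapper.fdr_.sig_mask, report.cohort.grid, out / f"sig_{cls}.nii.gz")
            save_volume(mapper.clusters_.labels, report.cohort.grid,
                        out / f"clusters_{cls}.nii.gz", dtype=np.int32)

    write_table(report.scores, out / "domain_scores.tsv")
    write_table(report.residuals, out / "residual_scores.tsv")
    write_table(report.summary, out / "tract_summary.tsv")
    write_table(report.regional, out / "regional_volumes.tsv")
    write_table(report.ladder.to_frame(), out / "ladder_report.tsv")

    ladder_json = {
        label: {
            "predictors": list(fit.predictors),
            "r2": fit.r2,
            "n": fit.n,
            "coef": {k: float(v) for k, v in fit.coef.items()},
            "ci": {k: [float(fit.conf_int.loc[k, "low"]), float(fit.conf_int.loc[k, "high"])]
                   for k in fit.conf_int.index},
        }
        for label, fit in report.ladder.fits.items()
    }
    steps_json = {
        label: {"base": s.base, "delta_r2": s.delta_r2, "f": s.f, "p": s.p, "k": s.k}
        for label, s in report.ladder.steps.items()
    }
    manifest = {
        "lesym_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "domain": cfg.domain,
            "lesion_classes": list(cfg.lesion_classes),
            "min_patients": cfg.min_patients,
            "q": cfg.q,
            "alternative": cfg.alternative,
            "atlas_threshold": cfg.atlas_threshold,
            "min_total_voxels": cfg.min_total_voxels,
            "min_cluster_voxels": cfg.min_cluster_voxels,
            "connectivity": cfg.connectivity,
        },
        "counts": report.counts,
        "ladder": {"fits": ladder_json, "steps": steps_json},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
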