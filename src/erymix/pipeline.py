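"""End-to-end orchestration of the analysis stages.

Sequence: simulate (or load) -> completeness filter + imputation ->
multi-stage ANOVA + clustering -> marker panels -> mixture deconvolution
benchmark -> proteomic ruler.  Every output is written to the run
directory together with a machine-readable manifest; re-running with the
same config reproduces all outputs bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .deconvolution import generate_ratios
from .evaluation import EvaluationReport, evaluate_panels
from .markers import MarkerPanel, assemble_panels, write_panels
from .matrix import ProteomeMatrix
from .profiles import (
    StageStats,
    anova_stage_test,
    cluster_profiles,
    filter_completeness,
    impute_missing,
)
from .ruler import RulerResult, estimate_copy_numbers, summarize_copies
from .simulate import GroundTruth, generate_proteome, read_curated_list

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    matrix: ProteomeMatrix
    truth: GroundTruth | None
    stats: StageStats
    panels: list[MarkerPanel]
    report: EvaluationReport
    ruler: RulerResult | None
    summary: pd.DataFrame = field(default=None)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run every stage; optionally persist all artifacts under ``outdir``."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # -- input ---------------------------------------------------------------
    truth: GroundTruth | None = None
    if config.matrix_path is not None:
        log.info("[input] loading matrix from %s", config.matrix_path)
        matrix = ProteomeMatrix.from_tsv(config.matrix_path, stages=config.stages)
        histone_ids = (
            read_curated_list(config.histone_list) if config.histone_list else []
        )
        curated = {
            name: read_curated_list(path)
            for name, path in config.curated_lists.items()
        }
    else:
        synth = config.synth
        synth = type(synth)(**{**synth.__dict__, "seed": config.seed_for("simulate")})
        log.info("[simulate] %d proteins, %d stages, seed %d",
                 synth.n_proteins, len(synth.stages), synth.seed)
        matrix, truth = generate_proteome(synth)
        histone_ids = truth.histone_ids
        curated = {k: list(v) for k, v in truth.marker_panels.items()}
        if out is not None:
            matrix.to_tsv(out / "matrix.tsv")
            truth.to_tsv(out / "ground_truth.tsv")

    # -- preprocess ----------------------------------------------------------
    log.info("[preprocess] completeness filter and imputation")
    filtered = filter_completeness(
        matrix, config.min_fraction_per_stage, config.n_stages_required
    )
    log2 = filtered.log2()
    imputed = impute_missing(
        log2, config.impute_width, config.impute_downshift,
        seed=config.seed_for("impute"),
    )

    log.info("[anova] %d permutations, s0=%.2g", config.n_permutations, config.s0)
    stats = anova_stage_test(
        imputed, filtered.design(),
        n_permutations=config.n_permutations, s0=config.s0,
        seed=config.seed_for("anova"),
    )
    stats = cluster_profiles(stats, q_threshold=config.q_threshold, k=config.n_clusters)
    if out is not None:
        stats.to_tsv(out / "stage_stats.tsv")

    # -- panels --------------------------------------------------------------
    log.info("[markers] assembling panels (q < %g)", config.q_threshold)
    panels = assemble_panels(
        stats,
        curated=curated,
        universe=filtered.protein_ids,
        q_threshold=config.q_threshold,
        per_cluster=config.per_cluster,
        any20_size=config.any20_size,
        seed=config.seed_for("any20"),
    )
    if out is not None:
        write_panels(panels, out / "panels.tsv")

    # -- deconvolution benchmark --------------------------------------------
    log.info("[deconvolve] %d mixtures x %d panels", config.n_mixtures, len(panels))
    ratios = generate_ratios(
        config.n_mixtures, len(matrix.stages), seed=config.seed_for("ratios")
    )
    report = evaluate_panels(
        matrix,
        panels,
        ratios,
        signature_replicates=config.signature_replicates,
        mixture_replicates=config.mixture_replicates,
        retain_fraction=config.retain_fraction,
        control_seed=config.seed_for("controls"),
    )
    summary = report.summary()
    if out is not None:
        report.to_tsv(out / "deconvolution_errors.tsv")
        summary.rename_axis("panel").to_csv(out / "deconvolution_summary.tsv", sep="\t")

    # -- ruler ---------------------------------------------------------------
    ruler_result = None
    if histone_ids:
        log.info("[ruler] histone ruler over %d histones", len(histone_ids))
        ruler_input = filter_completeness(matrix, 1.0, 1)
        present = [h for h in histone_ids if h in ruler_input.protein_ids]
        if present:
            ruler_result = estimate_copy_numbers(ruler_input, present, config.ruler)
            if out is not None:
                ruler_result.copies.rename_axis("protein_id").to_csv(
                    out / "copy_numbers.tsv", sep="\t"
                )
                sets = {"all": list(ruler_input.protein_ids), "histones": present}
                summarize_copies(ruler_result, sets).to_csv(
                    out / "copy_number_summary.tsv", sep="\t", index=False
                )
        else:
            log.warning("[ruler] no histones survive the completeness filter; skipped")

    if out is not None:
        _write_manifest(out, config, matrix, panels, report)
    return PipelineResult(
        matrix=matrix, truth=truth, stats=stats, panels=panels,
        report=report, ruler=ruler_result, summary=summary,
    )


def _write_manifest(
    out: Path,
    config: PipelineConfig,
    matrix: ProteomeMatrix,
    panels: list[MarkerPanel],
    report: EvaluationReport,
) -> None:
    from .config import STAGE_SEED_KEYS

    manifest = {
        "erymix_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "master_seed": config.seed,
        "stage_seeds": {s: config.seed_for(s) for s in STAGE_SEED_KEYS},
        "config": _jsonable(config.to_dict()),
        "n_proteins": matrix.n_proteins,
        "stages": list(matrix.stages),
        "panel_sizes": {p.name: len(p) for p in panels},
        "skipped_panels": list(report.skipped_panels),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
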