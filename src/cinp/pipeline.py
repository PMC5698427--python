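"""Stage orchestration: deterministic end-to-end runs with a manifest.

A run configuration (YAML or a plain dict) selects stages and parameters;
``run`` generates (or loads) inputs, executes the requested stages in
dependency order and writes versioned result tables plus ``manifest.json``
recording parameter values, seeds and sha256 hashes of every input and
output.  Identical configuration and seeds reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import motility, expression, survival, poreimage, synthgen

__all__ = ["RunConfig", "StageError", "run", "load_config"]

log = logging.getLogger("cinp")

STAGES = ("simulate", "motility", "expression", "survival", "pores")


class StageError(RuntimeError):
    """A stage failed; names the stage and the offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class RunConfig:
    """Configuration for an end-to-end run.

    With no explicit input paths each stage consumes the synthetic fixtures
    generated by the ``simulate`` stage under the output directory.
    """

    stages: tuple[str, ...] = STAGES
    out_dir: str = "cinp_run"
    seed: int = 0
    # motility
    n_tracks: int = 40
    prw_low: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.3, "P": 5.0, "sigma": 0.5}
    )
    prw_high: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.5, "P": 30.0, "sigma": 0.5}
    )
    track_duration_min: float = 720.0
    max_lag_fraction: float = 1.0 / 3.0
    trajectories_csv: str | None = None
    # expression
    fc_threshold: float = 1.5
    detection_tpm: float = 5.0
    pseudocount: float = 1.0
    cancer_lines: tuple[str, ...] = synthgen.CANCER_LINES
    normal_lines: tuple[str, ...] = synthgen.NORMAL_LINES
    tpm_tsv: str | None = None
    meta_tsv: str | None = None
    gmt_file: str | None = None
    alpha: float = 0.05
    # survival
    cohort_tsv: str | None = None
    module_file: str | None = None
    quantile: float = 0.30
    covariates: tuple[str, ...] = ("age", "score")
    truncate_months: float | None = None
    cohort_beta: float = 0.7
    cohort_n: int = 400
    # pores
    image_file: str | None = None
    pixel_size: float | None = None
    pore_diameters_px: tuple[float, ...] = (8, 10, 12, 14, 16, 20, 24)
    background_scale: float = 64.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 1 < self.fc_threshold:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.quantile <= 0.5:
            raise ValueError("quantile must be in (0, 0.5]")
        for path_attr in ("trajectories_csv", "tpm_tsv", "meta_tsv", "gmt_file",
                          "cohort_tsv", "module_file", "image_file"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"configured input does not exist: {path_attr}={p}")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("stages", "cancer_lines", "normal_lines", "covariates", "pore_diameters_px"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    report: dict[str, Any] = {}
    rng_seed = config.seed

    def record(name: str, path: Path) -> None:
        artifacts[name] = path

    if "simulate" in config.stages:
        try:
            _stage_simulate(config, out, record)
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc
    if "motility" in config.stages:
        try:
            report["motility"] = _stage_motility(config, out, record)
        except Exception as exc:
            raise StageError("motility", str(exc)) from exc
    if "expression" in config.stages:
        try:
            report["expression"] = _stage_expression(config, out, record)
        except Exception as exc:
            raise StageError("expression", str(exc)) from exc
    if "survival" in config.stages:
        try:
            report["survival"] = _stage_survival(config, out, record)
        except Exception as exc:
            raise StageError("survival", str(exc)) from exc
    if "pores" in config.stages:
        try:
            report["pores"] = _stage_pores(config, out, record)
        except Exception as exc:
            raise StageError("pores", str(exc)) from exc

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
                   for k, v in asdict(config).items()},
        "seed": rng_seed,
        "artifacts": {name: {"path": str(p), "sha256": _sha256(p)}
                      for name, p in sorted(artifacts.items())},
        "report": report,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, record) -> None:
    log.info("simulate: generating synthetic fixtures")
    truth: dict[str, Any] = {}
    # trajectories for the two collagen conditions
    tracks = []
    for label, prw in (("low", config.prw_low), ("high", config.prw_high)):
        params = synthgen.PRWParams(duration=config.track_duration_min, **prw)
        sub = synthgen.simulate_prw_ensemble(
            params, config.n_tracks, seed=config.seed + (0 if label == "low" else 1)
        )
        tracks.extend(
            motility.Trajectory(f"{label}_{t.cell_id}", t.times, t.x, t.y) for t in sub
        )
        truth[f"prw_{label}"] = dict(prw)
    traj_path = out / "trajectories.csv"
    cio.write_trajectories(tracks, traj_path)
    record("trajectories", traj_path)

    ds, expr_truth = synthgen.generate_expression_dataset(
        synthgen.default_design(), seed=config.seed + 2
    )
    cio.write_expression(ds, out / "tpm.tsv", out / "samples.tsv")
    record("tpm", out / "tpm.tsv")
    record("samples", out / "samples.tsv")
    truth["planted_modules"] = {k: sorted(v) for k, v in expr_truth.planted_modules.items()}
    # annotation fixture: one term per planted module plus random terms
    rng = np.random.default_rng(config.seed + 3)
    genes = list(ds.tpm.index)
    terms = {
        f"planted:{name}": frozenset(members)
        for name, members in expr_truth.planted_modules.items()
    }
    for i in range(10):
        terms[f"random:{i:02d}"] = frozenset(rng.choice(genes, size=50, replace=False))
    ann = expression.AnnotationMap(terms=terms, universe=frozenset(genes))
    cio.write_gmt(ann, out / "annotation.gmt")
    record("annotation", out / "annotation.gmt")

    cohort, cohort_truth = synthgen.generate_survival_cohort(
        synthgen.SyntheticCohortSpec(
            n_patients=config.cohort_n, beta=config.cohort_beta, seed=config.seed + 4
        )
    )
    cio.write_cohort(cohort, out / "cohort.tsv")
    record("cohort", out / "cohort.tsv")
    cio.write_gene_list(cohort.module_genes, out / "module_genes.txt")
    record("module_genes", out / "module_genes.txt")
    truth["cohort_beta"] = cohort_truth.beta

    img, pore_truth = synthgen.generate_pore_image(
        config.pore_diameters_px, gradient=True, noise_sd=0.01, seed=config.seed + 5
    )
    cio.write_image(img, out / "matrix.png")
    record("matrix_image", out / "matrix.png")
    truth["pore_diameters_px"] = pore_truth.pore_diameters_px

    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    record("truth", out / "truth.json")


def _stage_motility(config: RunConfig, out: Path, record) -> dict[str, Any]:
    path = Path(config.trajectories_csv or out / "trajectories.csv")
    log.info("motility: fitting PRW model to %s", path)
    tracks = cio.read_trajectories(path)
    rows = []
    for traj in tracks:
        msd = motility.compute_msd(traj, config.max_lag_fraction)
        fit = motility.fit_prw(msd)
        speeds = motility.instantaneous_speeds(traj)
        rows.append({
            "cell_id": traj.cell_id,
            "S": fit.S, "P": fit.P, "sigma": fit.sigma,
            "sse": fit.residual_sse, "converged": fit.converged,
            "mean_speed": float(np.mean(speeds)),
            "net_invasion_um": motility.net_invasion_distance(traj),
        })
    table = pd.DataFrame(rows)
    _write_table(table, out / "motility_fits.tsv")
    record("motility_fits", out / "motility_fits.tsv")
    groups = {
        "low": table.loc[table["cell_id"].str.startswith("low"), "P"].tolist(),
        "high": table.loc[table["cell_id"].str.startswith("high"), "P"].tolist(),
    }
    summary: dict[str, Any] = {"n_cells": len(table)}
    if all(len(v) >= 3 for v in groups.values()):
        comp = motility.summarize_groups(groups)
        _write_table(comp.reset_index(), out / "motility_groups.tsv")
        record("motility_groups", out / "motility_groups.tsv")
        summary["median_P"] = {k: float(np.median(v)) for k, v in groups.items()}
        summary["mannwhitney_p"] = float(comp["p_value"].iloc[0])
    return summary


def _stage_expression(config: RunConfig, out: Path, record) -> dict[str, Any]:
    tpm = Path(config.tpm_tsv or out / "tpm.tsv")
    meta = Path(config.meta_tsv or out / "samples.tsv")
    log.info("expression: modules from %s", tpm)
    ds = cio.read_expression(tpm, meta)
    sets = expression.degsets_for_all_lines(ds, config.fc_threshold, config.pseudocount)
    part = expression.venn_modules(sets, config.cancer_lines, config.normal_lines)
    cio.write_gene_list(part.common_to_cancer, out / "module_common_to_cancer.txt")
    cio.write_gene_list(part.common_to_all, out / "module_common_to_all.txt")
    record("module_common_to_cancer", out / "module_common_to_cancer.txt")
    record("module_common_to_all", out / "module_common_to_all.txt")
    sens = expression.threshold_sensitivity(
        ds, config.cancer_lines, config.normal_lines,
        reference_threshold=config.fc_threshold, pseudocount=config.pseudocount,
    )
    _write_table(sens, out / "threshold_sensitivity.tsv")
    record("threshold_sensitivity", out / "threshold_sensitivity.tsv")
    summary = {
        "n_common_to_cancer": len(part.common_to_cancer),
        "n_common_to_all": len(part.common_to_all),
    }
    gmt = config.gmt_file or (out / "annotation.gmt")
    if Path(gmt).exists():
        ann = cio.read_gmt(gmt)
        detected = expression.detect_genes(ds)
        table = expression.enrich(
            part.common_to_cancer & detected, ann, alpha=config.alpha,
            background=detected & ann.universe,
        )
        _write_table(table, out / "enrichment_common_to_cancer.tsv")
        record("enrichment", out / "enrichment_common_to_cancer.tsv")
        summary["n_enriched_terms"] = int(table["significant"].sum())
    return summary


def _stage_survival(config: RunConfig, out: Path, record) -> dict[str, Any]:
    path = Path(config.cohort_tsv or out / "cohort.tsv")
    log.info("survival: metagene pipeline on %s", path)
    cohort = cio.read_cohort(path)
    genes = cio.read_gene_list(config.module_file) if config.module_file else None
    rep = survival.survival_pipeline(
        cohort, genes, covariates=config.covariates,
        quantile=config.quantile, truncation_months=config.truncate_months,
    )
    _write_table(rep.km_high.step_coordinates(), out / "km_high.csv")
    _write_table(rep.km_low.step_coordinates(), out / "km_low.csv")
    _write_table(rep.cox.summary.reset_index(names="covariate"), out / "cox.tsv")
    (out / "survival_report.json").write_text(
        json.dumps(rep.to_dict(), indent=2, sort_keys=True, default=float) + "\n"
    )
    for name in ("km_high.csv", "km_low.csv", "cox.tsv", "survival_report.json"):
        record(name.split(".")[0] if name != "cox.tsv" else "cox", out / name)
    return {
        "logrank_p": rep.logrank_p,
        "hr_score": rep.cox.hr("score") if "score" in rep.cox.summary.index else None,
    }


def _stage_pores(config: RunConfig, out: Path, record) -> dict[str, Any]:
    path = Path(config.image_file or out / "matrix.png")
    log.info("pores: quantifying %s", path)
    img = cio.read_image(path, pixel_size=config.pixel_size)
    stats = poreimage.analyze_pores(img, background_scale=config.background_scale)
    table = pd.DataFrame({"diameter_px": stats.diameters_px})
    if stats.diameters_um is not None:
        table["diameter_um"] = stats.diameters_um
    _write_table(table, out / "pores.csv")
    record("pores", out / "pores.csv")
    return {
        "pore_count": stats.pore_count,
        "median_diameter_px": float(np.median(stats.diameters_px)) if stats.pore_count else None,
        "coverage": stats.coverage,
    }
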