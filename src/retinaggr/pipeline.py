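"""Configuration-driven orchestration and table export.

A :class:`PipelineConfig` (YAML-loadable, pydantic-validated) selects
stages, a seed and an output directory; :func:`run` executes the selected
stages in a fixed order on synthetic inputs generated from the config seed
and collects one table per stage into a :class:`ReportBundle`.
:func:`export_tables` writes each table as CSV and JSON with a stable
column order.  Re-running an identical config byte-reproduces the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__
from . import coloc, erg, expression, fields, fret, onl, synth

logger = logging.getLogger("retinaggr")

STAGES = ("synth", "fret", "coloc", "kinetics", "erg", "count", "expr")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_RUNTIME = 3


class ConfigError(Exception):
    """Invalid pipeline configuration; message lists all violations."""


class StageError(Exception):
    """A stage failed at run time."""


class FretStageParams(BaseModel):
    noise_sigma: float = Field(0.01, ge=0)
    e_max_nonspecific: dict[str, float] = {"dm_sensitive": 0.05, "dm_insensitive": 0.05}
    alpha: float = Field(0.05, gt=0, lt=1)


class KineticsStageParams(BaseModel):
    k_per_series: dict[str, float] = {
        "P23H_het": 0.24, "G188R_het": 0.49, "P23H_homo": 1.84, "G188R_homo": 3.29,
    }
    y0: float = Field(21.0, gt=0)
    plateau: float = 1.0
    noise_sigma: float = Field(1.0, ge=0)


class ColocStageParams(BaseModel):
    rho: float = Field(0.7, ge=-1, le=1)
    n_images: int = Field(6, ge=1)
    size: int = Field(128, ge=8)


class ErgStageParams(BaseModel):
    r_max: float = Field(400.0, ge=0)
    log_ka: float = -1.0
    noise_sigma: float = Field(10.0, ge=0)
    alpha: float = Field(0.05, gt=0, lt=1)


class CountStageParams(BaseModel):
    n_particles: int = Field(15, ge=0)
    n_fields: int = Field(4, ge=1)
    min_area: float = Field(fields.DEFAULT_MIN_AREA_UM2, gt=0)
    threshold: float | str = "auto"


class ExprStageParams(BaseModel):
    true_folds: dict[str, float] = {"het": 1.0, "homo": 0.3}
    ct_noise_sigma: float = Field(0.15, ge=0)
    replicates: int = Field(3, ge=1)


class PipelineConfig(BaseModel):
    """Validated run configuration (YAML file or keyword construction)."""

    stages: list[str] = list(STAGES)
    seed: int = 0
    outdir: Path = Path("retinaggr-out")
    fret_params: FretStageParams = FretStageParams()
    kinetics: KineticsStageParams = KineticsStageParams()
    coloc_params: ColocStageParams = ColocStageParams()
    erg_params: ErgStageParams = ErgStageParams()
    count: CountStageParams = CountStageParams()
    expr: ExprStageParams = ExprStageParams()

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: list[str]) -> list[str]:
        unknown = [s for s in v if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage name(s): {unknown}; valid: {list(STAGES)}")
        if not v:
            raise ValueError("at least one stage must be selected")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; raises ConfigError listing violations."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except OSError as exc:
        raise ConfigError(f"cannot read config file: {exc}") from exc
    return validate_config(raw)


def validate_config(raw: dict) -> PipelineConfig:
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        lines = [f"{'.'.join(map(str, e['loc']))}: {e['msg']}" for e in exc.errors()]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from exc


@dataclass
class ReportBundle:
    """Per-stage result tables plus provenance of the run."""

    tables: dict[str, pd.DataFrame] = dataclass_field(default_factory=dict)
    provenance: dict = dataclass_field(default_factory=dict)
    log_records: list[str] = dataclass_field(default_factory=list)

    def note(self, msg: str) -> None:
        logger.info(msg)
        self.log_records.append(msg)


def _stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage substream seed below 2**31."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# --- stage implementations -------------------------------------------------


def _run_synth(cfg: PipelineConfig, bundle: ReportBundle) -> pd.DataFrame:
    rows = []
    seed = _stage_seed(cfg.seed, "synth")
    series, manifest = synth.make_fret_dataset(noise_sigma=cfg.fret_params.noise_sigma, seed=seed)
    rows.append(("fret", manifest.generator, manifest.seed, len(series)))
    _, m2 = synth.make_onl_series(cfg.kinetics.k_per_series, seed=seed,
                                  noise_sigma=cfg.kinetics.noise_sigma)
    rows.append(("kinetics", m2.generator, m2.seed, len(cfg.kinetics.k_per_series)))
    _, _, m3 = synth.make_coloc_pair(cfg.coloc_params.rho, seed=seed,
                                     size=(cfg.coloc_params.size,) * 2)
    rows.append(("coloc", m3.generator, m3.seed, 2))
    _, m4 = synth.make_erg_sweep(
        {"model": "standard", "r_max": cfg.erg_params.r_max, "log_ka": cfg.erg_params.log_ka},
        noise_sigma=cfg.erg_params.noise_sigma, seed=seed)
    rows.append(("erg", m4.generator, m4.seed, len(synth.DEFAULT_ERG_GRID)))
    _, m5 = synth.make_field_image(cfg.count.n_particles, seed=seed)
    rows.append(("count", m5.generator, m5.seed, cfg.count.n_particles))
    _, _, m6 = synth.make_qpcr_table(cfg.expr.true_folds, seed=seed,
                                     ct_noise_sigma=cfg.expr.ct_noise_sigma,
                                     replicates=cfg.expr.replicates)
    rows.append(("expr", m6.generator, m6.seed, len(cfg.expr.true_folds)))
    return pd.DataFrame(rows, columns=["stage", "generator", "seed", "n_items"])


def _run_fret(cfg: PipelineConfig, bundle: ReportBundle) -> pd.DataFrame:
    p = cfg.fret_params
    seed = _stage_seed(cfg.seed, "fret")
    series, _ = synth.make_fret_dataset(noise_sigma=p.noise_sigma, seed=seed)
    table = fret.efficiencies_table(series)
    rows = []
    for component, col in (("dm_sensitive", 2), ("dm_insensitive", 3)):
        pts = list(zip(table[:, 0], table[:, col]))
        ceiling = p.e_max_nonspecific[component]
        spec = fret.test_specificity(pts, ceiling, alpha=p.alpha)
        fit = spec.fit
        rows.append((component, fit.e_max, fit.se_e_max, fit.ec50, fit.se_ec50,
                     fit.n_points, spec.f_statistic, spec.p_value, spec.is_specific))
    return pd.DataFrame(rows, columns=[
        "component", "e_max", "se_e_max", "ec50", "se_ec50", "n", "F", "p", "is_specific",
    ])


def _run_coloc(cfg: PipelineConfig, bundle: ReportBundle) -> pd.DataFrame:
    p = cfg.coloc_params
    results = []
    for i in range(p.n_images):
        seed = _stage_seed(cfg.seed, f"coloc-{i}")
        a, b, _ = synth.make_coloc_pair(p.rho, size=(p.size, p.size), seed=seed)
        results.append(coloc.pearson_r(a, b, image_id=f"img-{i}"))
    summary = coloc.summarize_replicates(results)
    rows = [(r.pair[0], r.pair[1], r.r, r.n_pixels, r.image_id) for r in results]
    df = pd.DataFrame(rows, columns=["channel_a", "channel_b", "r", "n_pixels", "image_id"])
    bundle.note(f"coloc: mean r = {summary.mean_r:.3f} +/- {summary.sd_r:.3f} (n={summary.n})")
    df.attrs["summary"] = {"mean_r": summary.mean_r, "sd_r": summary.sd_r, "n": summary.n}
    return df


def _run_kinetics(cfg: PipelineConfig, bundle: ReportBundle) -> pd.DataFrame:
    p = cfg.kinetics
    rows = []
    for region in ("superior", "inferior"):
        seed = _stage_seed(cfg.seed, f"kinetics-{region}")
        data, _ = synth.make_onl_series(
            p.k_per_series, y0=p.y0, plateau=p.plateau,
            noise_sigma=p.noise_sigma, seed=seed, region=region)
        series = {lab: d["mean_points"] for lab, d in data.items()}
        joint = onl.fit_one_phase_decay(series, plateau=p.plateau)
        for lab, sf in joint.per_series.items():
            rows.append((region, lab, sf.k, sf.se_k))
    return pd.DataFrame(rows, columns=["region", "genotype", "k", "se_k"])


def _run_erg(cfg: PipelineConfig, bundle: ReportBundle) -> pd.DataFrame:
    p = cfg.erg_params
    seed = _stage_seed(cfg.seed, "erg")
    sweep, _ = synth.make_erg_sweep(
        {"model": "standard", "r_max": p.r_max, "log_ka": p.log_ka},
        noise_sigma=p.noise_sigma, seed=seed)
    sel = erg.select_model(sweep, alpha=p.alpha)
    fit = sel.preferred
    return pd.DataFrame(
        [(sweep.wave, fit.model, fit.r_max, fit.se_r_max, fit.log_ka, fit.se_log_ka,
          sel.f_statistic, sel.p_value)],
        columns=["wave", "model", "r_max", "se_r_max", "log_ka", "se_log_ka", "F", "p"],
    )


def _run_count(cfg: PipelineConfig, bundle: ReportBundle) -> pd.DataFrame:
    p = cfg.count
    rows = []
    for i in range(p.n_fields):
        seed = _stage_seed(cfg.seed, f"count-{i}")
        image, manifest = synth.make_field_image(p.n_particles, seed=seed)
        result = fields.count_field(image, threshold=p.threshold, min_area=p.min_area)
        rows.append((f"field-{i}", image.stain, image.region, result.count,
                     manifest.parameters["n_particles"], result.threshold_used,
                     result.min_area_used))
    return pd.DataFrame(rows, columns=[
        "field_id", "stain", "region", "count", "true_count", "threshold", "min_area_um2",
    ])


def _run_expr(cfg: PipelineConfig, bundle: ReportBundle) -> pd.DataFrame:
    p = cfg.expr
    seed = _stage_seed(cfg.seed, "expr")
    samples, control, _ = synth.make_qpcr_table(
        p.true_folds, ct_noise_sigma=p.ct_noise_sigma, replicates=p.replicates, seed=seed)
    rows = []
    for lab, sample in samples.items():
        rq = expression.ddct_fold(sample, control, "18s_rrna")
        rows.append((lab, "ddct", rq.value, rq.delta_delta_ct))
    return pd.DataFrame(rows, columns=["sample", "basis", "fold", "ddct"])


_STAGE_RUNNERS: dict[str, Callable[[PipelineConfig, ReportBundle], pd.DataFrame]] = {
    "synth": _run_synth,
    "fret": _run_fret,
    "coloc": _run_coloc,
    "kinetics": _run_kinetics,
    "erg": _run_erg,
    "count": _run_count,
    "expr": _run_expr,
}


def run(config: PipelineConfig) -> ReportBundle:
    """Execute the selected stages in dependency order.

    A stage failure is recorded and does not corrupt other stages' outputs;
    the failure is re-raised as :class:`StageError` after all stages ran
    (so the CLI exits non-zero).
    """
    bundle = ReportBundle(
        provenance={
            "package_version": __version__,
            "seed": config.seed,
            "stages": list(config.stages),
            "config_hash": hashlib.sha256(
                config.model_dump_json().encode()
            ).hexdigest()[:16],
        }
    )
    failures: list[tuple[str, Exception]] = []
    for stage in STAGES:  # fixed order regardless of selection order
        if stage not in config.stages:
            continue
        bundle.note(f"running stage {stage!r} (seed {_stage_seed(config.seed, stage)})")
        try:
            bundle.tables[stage] = _STAGE_RUNNERS[stage](config, bundle)
        except Exception as exc:  # noqa: BLE001 - isolate stage failures
            logger.exception("stage %r failed", stage)
            failures.append((stage, exc))
    if failures:
        names = ", ".join(s for s, _ in failures)
        raise StageError(f"stage(s) failed: {names}") from failures[0][1]
    return bundle


def export_tables(bundle: ReportBundle, outdir: str | Path, formats=("csv", "json")) -> list[Path]:
    """Write each stage table as CSV/JSON with stable column order."""
    if not bundle.tables:
        raise StageError("empty bundle: nothing to export")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for stage, df in bundle.tables.items():
        if df.empty:
            bundle.note(f"stage {stage!r} produced an empty table; omitted")
            continue
        if "csv" in formats:
            path = outdir / f"{stage}.csv"
            df.to_csv(path, index=False)
            written.append(path)
        if "json" in formats:
            path = outdir / f"{stage}.json"
            path.write_text(df.to_json(orient="records", indent=2))
            written.append(path)
    prov = outdir / "provenance.json"
    prov.write_text(json.dumps(
        {**bundle.provenance, "log": bundle.log_records}, indent=2, sort_keys=True))
    written.append(prov)
    return written
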