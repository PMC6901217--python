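"""End-to-end pipeline: simulate → calibrate → variance → assign →
validate → compare, configured, logged and seed-reproducible.

A single config seed is fanned out deterministically to stage-specific
child seeds (``numpy.random.SeedSequence(seed, spawn_key=(stage,))``),
so any stage can be rerun in isolation and two runs with the same
config produce byte-identical record CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .assignment import DEFAULT_ODDS_THRESHOLD, assignment_region, posterior_surface
from .calibration import fit_mlr_stepwise, fit_simple_calibration, predict_surface
from .exceptions import ConfigError
from .grids import SampleSet, read_raster, write_raster
from .metrics import compare_models, comparison_table
from .synthetic_data import COVARIATE_NAMES, SyntheticConfig, simulate_study
from .validation import (
    make_fold_partitions,
    records_table,
    repeated_kfold_assign,
    summarize_cv,
)
from .variance import total_variance_surface

logger = logging.getLogger("isoassign")

# seed fan-out stages (offsets into the pipeline's SeedSequence spawn key)
_SEED_SIMULATE = 0
_SEED_FOLDS = 1
_SEED_DIAGNOSTICS = 2


def _child_seed(seed: int, stage: int) -> int:
    """Deterministic 31-bit child seed for one pipeline stage."""
    return int(
        np.random.SeedSequence(seed, spawn_key=(stage,)).generate_state(1)[0] % (2**31)
    )


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.  Defaults follow the study
    conventions: 5-km buffer, 0.667 odds threshold, 10×10-fold CV."""

    out_dir: str = "isoassign_run"
    seed: int = 0
    # inputs; when raster paths are absent the simulate stage runs
    base_raster: str | None = None
    base_variance_raster: str | None = None
    samples_csv: str | None = None
    raster_dialect: str = "esri_ascii"
    # models to fit/compare: subset of {"simple", "mlr"}
    models: tuple[str, ...] = ("simple", "mlr")
    candidate_covariates: tuple[str, ...] = COVARIATE_NAMES
    # validation / assignment parameters
    k: int = 10
    repeats: int = 10
    threshold: float = DEFAULT_ODDS_THRESHOLD
    buffer_radius_km: float = 5.0
    # behaviour flags (all logged)
    use_covariance_term: bool = False
    similarity_denominator: str = "union"
    rescale_mode: str = "max"
    scale_base_by_slope: bool = True
    # synthetic generation overrides (applied onto SyntheticConfig defaults)
    synthetic: dict[str, Any] = field(default_factory=dict)

    _KNOWN = None  # populated below

    def __post_init__(self) -> None:
        if not self.models or set(self.models) - {"simple", "mlr"}:
            raise ConfigError(f"models must be a non-empty subset of simple/mlr: {self.models}")
        if self.k < 2:
            raise ConfigError("k must be at least 2")
        if not 0 <= self.threshold < 1:
            raise ConfigError(f"threshold must be in [0, 1), got {self.threshold}")
        if self.buffer_radius_km <= 0:
            raise ConfigError("buffer_radius_km must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        for key in ("models", "candidate_covariates"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every configured stage; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d out=%s", config.seed, out)
    for flag in (
        "use_covariance_term",
        "similarity_denominator",
        "rescale_mode",
        "scale_base_by_slope",
        "threshold",
        "buffer_radius_km",
    ):
        logger.info("flag %s = %r", flag, getattr(config, flag))

    artifacts: list[str] = []

    def save(name: str) -> Path:
        artifacts.append(name)
        return out / name

    # ---- stage: inputs (load or simulate) --------------------------
    covariate_grids = None
    if config.base_raster is not None:
        base = read_raster(config.base_raster, config.raster_dialect, role="isoscape")
        base_var = (
            read_raster(config.base_variance_raster, config.raster_dialect, role="variance")
            if config.base_variance_raster
            else None
        )
        if config.samples_csv is None:
            raise ConfigError("samples_csv is required when rasters are supplied")
        samples = SampleSet.read_csv(config.samples_csv)
    else:
        syn = SyntheticConfig(
            seed=_child_seed(config.seed, _SEED_SIMULATE), **config.synthetic
        )
        study = simulate_study(syn)
        base, base_var = study.isoscape, study.base_variance
        covariate_grids = study.covariate_grids
        samples = study.samples
        write_raster(base, save("base_isoscape.asc"))
        write_raster(base_var, save("base_variance.asc"))
        samples.to_csv(save("samples.csv"))
        logger.info("simulated study: %d sites on %s grid", len(samples), base.shape)

    train = samples.split("train") if "split" in samples.frame.columns else samples
    try:
        test = samples.split("test")
    except Exception:
        test = None
    n = len(train)
    if config.k > n:
        raise ConfigError(f"k={config.k} exceeds the {n} training samples")

    # ---- stage: calibrate + variance per model ---------------------
    fitted: dict[str, Any] = {}
    for kind in config.models:
        if kind == "simple":
            model = fit_simple_calibration(train, base, config.buffer_radius_km)
            predicted = predict_surface(model, base=base)
            comps = total_variance_surface(
                model,
                base=base,
                base_pred_var=base_var,
                covariance=None if not config.use_covariance_term else base_var.with_values(
                    np.zeros(base.shape)
                ),
                scale_base_by_slope=config.scale_base_by_slope,
            )
        else:
            if covariate_grids is None:
                raise ConfigError("mlr model needs covariate grids (simulate stage)")
            model = fit_mlr_stepwise(train, list(config.candidate_covariates))
            predicted = predict_surface(model, covariate_grids=covariate_grids)
            comps = total_variance_surface(model, covariate_grids=covariate_grids)
        model.to_json(save(f"model_{kind}.json"))
        write_raster(predicted, save(f"predicted_{kind}.asc"))
        write_raster(comps.total, save(f"total_variance_{kind}.asc"))
        fitted[kind] = (model, predicted, comps)
        logger.info(
            "fitted %s: rse=%.3f r2=%.3f coefficients=%s", kind, model.rse, model.r2,
            model.coefficients,
        )

    # ---- stage: validate (identical folds for every model) ---------
    folds = make_fold_partitions(n, config.k, config.repeats, _child_seed(config.seed, _SEED_FOLDS))
    cv_records: dict[str, list] = {}
    summaries: dict[str, Any] = {}
    for kind in config.models:
        records = repeated_kfold_assign(
            train,
            base=base,
            base_pred_var=base_var if kind == "simple" else None,
            covariate_grids=covariate_grids,
            model_kind=kind,
            candidate_covariates=list(config.candidate_covariates),
            threshold=config.threshold,
            radius_km=config.buffer_radius_km,
            folds=folds,
        )
        cv_records[kind] = records
        summary = summarize_cv(records)
        summaries[kind] = dataclasses.asdict(summary)
        records_table(records).to_csv(save(f"cv_records_{kind}.csv"), index=False)
        logger.info(
            "CV %s: %d tests, coverage %.1f%%, mean precision %.0f km²",
            kind, summary.n_tests, summary.coverage_pct, summary.mean_precision_km2,
        )
    json.dump(summaries, open(save("cv_summary.json"), "w"), indent=2)

    # ---- stage: assign the external test set -----------------------
    test_surfaces: dict[str, list] = {}
    if test is not None and len(test) > 0:
        rows = []
        for kind in config.models:
            model, predicted, comps = fitted[kind]
            surfaces = []
            for i, site in enumerate(test.sites()):
                post = posterior_surface(
                    test.d2H[i], predicted, comps.total,
                    sample_id=site.id, rescale_mode=config.rescale_mode,
                )
                region = assignment_region(post, config.threshold, true_site=site)
                surfaces.append(post)
                rows.append(
                    {
                        "model": kind,
                        "sample_id": site.id,
                        "prob_at_true_origin": region.prob_at_true_origin,
                        "area_km2": region.area_km2,
                        "contains_true_origin": region.contains_true_origin,
                    }
                )
            test_surfaces[kind] = surfaces
        import pandas as pd

        pd.DataFrame(rows).to_csv(save("test_assignments.csv"), index=False)

    # ---- stage: compare model pairs --------------------------------
    if len(config.models) >= 2 and test_surfaces:
        kinds = list(config.models)
        sites = list(test.sites())
        for a_idx in range(len(kinds)):
            for b_idx in range(a_idx + 1, len(kinds)):
                a, b = kinds[a_idx], kinds[b_idx]
                records, summary = compare_models(
                    test_surfaces[a], test_surfaces[b], sites,
                    denominator=config.similarity_denominator,
                )
                comparison_table(records).to_csv(
                    save(f"comparison_{a}_vs_{b}.csv"), index=False
                )
                json.dump(
                    dataclasses.asdict(summary),
                    open(save(f"comparison_{a}_vs_{b}.json"), "w"),
                    indent=2,
                )
                logger.info(
                    "compare %s vs %s: mean acc diff %.3f, mean precision diff %.1f"
                    " ×10³ km², mean similarity %.2f",
                    a, b, summary.mean_accuracy_diff,
                    summary.mean_precision_diff_thousand_km2, summary.mean_similarity,
                )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "artifacts": artifacts + ["manifest.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline done: %d artifacts in %s", len(manifest["artifacts"]), out)
    return manifest
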