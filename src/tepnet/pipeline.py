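"""Config-driven orchestration of the full analysis.

Stages: simulate -> preprocess -> features -> stats -> classify -> regress.
One global seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence``; identical config + seed gives a
byte-identical report bundle.  Intermediate artifacts are plain files so
every stage can also be run (and unit-tested) independently through the
CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .classify import run_cv_svm
from .features import (MEASURES, build_feature_vector, build_template,
                       compute_feature_table)
from .preprocess import (DEFAULT_HOTSPOTS, DEFAULT_P2P_LIMIT_UV,
                         PROXIMAL_HOTSPOTS, preprocess_epochs)
from .regress import run_cv_regression
from .simulate import SimulationConfig, simulate_cohort
from .stats import compare_groups

__all__ = ["RunConfig", "run_pipeline", "select_reference_subjects"]

log = logging.getLogger("tepnet")

STAGES = ("simulate", "preprocess", "features", "stats", "classify", "regress")


@dataclass
class RunConfig:
    """Whole-run configuration; round-trips losslessly through YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    peak_to_peak_limit: float = DEFAULT_P2P_LIMIT_UV
    bandpass: tuple[float, float] = (0.5, 45.0)
    baseline_window: tuple[float, float] = (-100.0, -10.0)
    wfa_metric: str = "pearson"
    n_reference: int = 8
    feature_hotspots: tuple[str, ...] = PROXIMAL_HOTSPOTS
    n_perm: int = 50
    k_folds: int = 5
    svm_c: float = 1.0
    class_weight: str = "balanced"
    stats_family: str = "per_measure"
    alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "peak_to_peak_limit": self.peak_to_peak_limit,
            "bandpass": list(self.bandpass),
            "baseline_window": list(self.baseline_window),
            "wfa_metric": self.wfa_metric,
            "n_reference": self.n_reference,
            "feature_hotspots": list(self.feature_hotspots),
            "n_perm": self.n_perm,
            "k_folds": self.k_folds,
            "svm_c": self.svm_c,
            "class_weight": self.class_weight,
            "stats_family": self.stats_family,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        cfg = cls(simulation=SimulationConfig.from_dict(sim))
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key in ("bandpass", "baseline_window", "feature_hotspots"):
                val = tuple(val)
            setattr(cfg, key, val)
        return cfg

    def to_yaml(self, path) -> None:
        # sort_keys=False keeps ROI/hotspot dict ordering stable round-trip
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(STAGES))
        return {stage: int(c.generate_state(1)[0] % (2**31))
                for stage, c in zip(STAGES, children)}


def select_reference_subjects(labels: pd.Series, n_reference: int) -> list[str]:
    """First ``n_reference`` healthy subjects (sorted) form the template set."""
    healthy = sorted(labels.index[labels == "healthy"])
    if len(healthy) <= n_reference:
        raise ValueError(
            f"need more than n_reference={n_reference} healthy subjects "
            f"to keep an evaluation set, got {len(healthy)}")
    return healthy[:n_reference]


def run_pipeline(config: RunConfig, outdir, write_epochs: bool = False) -> dict:
    """Execute every stage, writing the report bundle into ``outdir``.

    Returns the run manifest.  Stages that are impossible for the given
    cohort (single-class classification, too few subjects for regression)
    are skipped with the reason recorded in the manifest; hard errors in a
    stage abort the run with the stage name in the exception message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "stages": {},
        "skipped": {},
    }
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()

    def _stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts}
            log.info("stage %s done in %.2fs %s", name,
                     time.perf_counter() - t0, counts)
        return done

    # --- simulate ----------------------------------------------------
    done = _stage("simulate")
    sim_cfg = SimulationConfig.from_dict(
        config.simulation.to_dict() | {"seed": seeds["simulate"]})
    try:
        epochs, fa_table, labels = simulate_cohort(sim_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    io.write_labels(outdir / "labels.tsv", labels)
    io.write_table(outdir / "fa.tsv", fa_table, index=True)
    if write_epochs:
        io.write_epochs_h5(outdir / "epochs.h5", epochs)
    done(n_subjects=len(epochs.subjects), n_epochs=epochs.n_epochs)

    # --- preprocess --------------------------------------------------
    done = _stage("preprocess")
    try:
        teps, rej_log = preprocess_epochs(
            epochs, config.peak_to_peak_limit, *config.bandpass,
            baseline_window=config.baseline_window)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc
    io.write_table(outdir / "rejections.tsv", rej_log)
    io.write_table(outdir / "teps.tsv", teps.to_frame())
    done(n_rejected=len(rej_log), n_hotspots=len(teps.hotspots))

    # --- features ----------------------------------------------------
    done = _stage("features")
    try:
        reference = select_reference_subjects(labels, config.n_reference)
        eval_subjects = [s for s in teps.subjects if s not in set(reference)]
        template = build_template(teps, reference,
                                  evaluation_ids=eval_subjects)
        feats = compute_feature_table(teps, template,
                                      subjects=eval_subjects,
                                      wfa_metric=config.wfa_metric)
        X, fv_log = build_feature_vector(feats, config.feature_hotspots)
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc
    io.write_table(outdir / "features.tsv", feats)
    io.write_table(outdir / "feature_matrix.tsv", X, index=True)
    done(n_eval=len(eval_subjects), n_reference=len(reference),
         n_imputed=len(fv_log.imputed), n_dropped=len(fv_log.dropped))

    eval_labels = labels.loc[X.index]

    # --- stats -------------------------------------------------------
    done = _stage("stats")
    try:
        comparison = compare_groups(feats, labels, MEASURES, config.alpha,
                                    config.stats_family)
        io.write_table(outdir / "comparison.tsv", comparison)
        done(n_cells=len(comparison))
    except ValueError as exc:
        manifest["skipped"]["stats"] = str(exc)
        log.warning("stats skipped: %s", exc)

    # --- classify ----------------------------------------------------
    done = _stage("classify")
    try:
        report = run_cv_svm(X.to_numpy(), eval_labels.to_numpy(),
                            n_perm=config.n_perm, k=config.k_folds,
                            seed=seeds["classify"], C=config.svm_c,
                            class_weight=config.class_weight)
        io.write_json(outdir / "cv_report.json", report.to_dict())
        io.write_table(outdir / "roc.tsv", pd.DataFrame(
            {"fpr": report.fpr_grid, "mean_tpr": report.mean_tpr}))
        done(**{key: report.summary[key] for key in
                ("balanced_accuracy_mean", "auc_mean")})
    except ValueError as exc:
        manifest["skipped"]["classify"] = str(exc)
        log.warning("classification skipped: %s", exc)

    # --- regress -----------------------------------------------------
    done = _stage("regress")
    try:
        reg = run_cv_regression(X, fa_table, n_perm=config.n_perm,
                                k=config.k_folds, seed=seeds["regress"])
        io.write_table(outdir / "regression.tsv", reg.table)
        io.write_table(outdir / "regression_scatter.tsv", reg.scatter)
        done(n_rois=len(reg.table), ridge_folds=reg.ridge_folds)
    except ValueError as exc:
        manifest["skipped"]["regress"] = str(exc)
        log.warning("regression skipped: %s", exc)

    io.write_json(outdir / "manifest.json",
                  {k: v for k, v in manifest.items() if k != "stages"}
                  | {"stages": {s: {kk: vv for kk, vv in d.items()
                                    if kk != "seconds"}
                                for s, d in manifest["stages"].items()}})
    return manifest
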