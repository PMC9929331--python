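"""End-to-end pipeline driver: simulate → preprocess → power → train → interpret.

``run_pipeline`` executes the whole analysis from a :class:`PipelineConfig`
and writes every intermediate table to ``out_dir`` as CSV/JSON.  All
randomness flows from the named seeds in the config; re-running with the
same config reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io, power
from .interpret import (garson_importance, impact_matrix,
                        permutation_importance, plot_surface, sliced_surfaces)
from .mlp import TrainConfig, ensemble_to_dict, evaluate, train_ensemble
from .preprocess import preprocess_cohort, tercile_thresholds
from .psych import MODEL_PREDICTORS, build_model_inputs, normalize_profiles
from .simulate import EffectSpec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from YAML."""

    out_dir: str = "sclimagery_out"
    n_participants: int = 30
    cohort_seed: int = 11
    train_seed: int = 17
    permutation_seed: int = 23
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    models: tuple[int, ...] = (1, 2, 3)
    alpha: float = 0.05
    sides: int = 2
    grid_resolution: int = 25
    impact_resolution: int = 7
    midpoint_convention: str = "median"
    quantile_method: str = "linear"
    variance_ddof: int = 0
    importance_reps: int = 20
    use_observed_range: bool = False
    make_plots: bool = False
    # optional real-data inputs; when unset, a synthetic cohort is generated
    recordings_csv: str | None = None
    markers_csv: str | None = None
    questionnaire_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "effect_spec" in payload:
            payload["effect_spec"] = _effect_spec_from_dict(payload["effect_spec"])
        if "train" in payload:
            payload["train"] = TrainConfig(**payload["train"])
        if "models" in payload:
            payload["models"] = tuple(payload["models"])
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["effect_spec"]["interactions"] = {
            "|".join(k): v for k, v in payload["effect_spec"]["interactions"].items()}
        payload["models"] = list(self.models)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _effect_spec_from_dict(payload: dict) -> EffectSpec:
    payload = dict(payload)
    if "interactions" in payload:
        payload["interactions"] = {tuple(k.split("|")): v
                                   for k, v in payload["interactions"].items()}
    return EffectSpec(**payload)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report bundle (also written to disk)."""
    out = io.ensure_dir(config.out_dir)
    bundle: dict = {}

    # --- inputs: simulate or load --------------------------------------
    if config.recordings_csv is None:
        logger.info("simulating cohort of %d participants (seed %d)",
                    config.n_participants, config.cohort_seed)
        profiles, recordings, truth = generate_cohort(
            config.n_participants, config.effect_spec, seed=config.cohort_seed)
        io.write_recordings(recordings, out / "recordings.csv", out / "markers.csv")
        io.write_ground_truth(truth, out / "truth_scripts.csv",
                              out / "truth_participants.csv")
    else:
        recordings = io.read_recordings(config.recordings_csv, config.markers_csv)
        profiles = normalize_profiles(io.read_profiles(config.questionnaire_csv),
                                      use_observed_range=config.use_observed_range)
    io.write_profiles(profiles, out / "profiles.csv")

    # --- preprocessing ---------------------------------------------------
    summaries, outcomes = preprocess_cohort(
        recordings, ddof=config.variance_ddof, method=config.quantile_method)
    summaries.to_csv(out / "script_summaries.csv", index=False)
    outcomes.to_csv(out / "participant_outcomes.csv", index=False)
    n_excluded = int((~summaries["retained"]).sum())
    logger.info("preprocessing: %d participants, %d scripts excluded by IQR rule",
                outcomes.shape[0], n_excluded)
    bundle["outcomes"] = outcomes
    bundle["n_scripts_excluded"] = n_excluded

    lo, hi = tercile_thresholds(outcomes["mscl"].to_numpy(),
                                method=config.quantile_method)
    bundle["mscl_tercile_thresholds"] = (lo, hi)

    # --- power from the test-scene contrast ------------------------------
    mean_diff, sd, n_power = power.test_scene_contrast(summaries)
    report = power.power_report(mean_diff, sd, n_power, config.alpha, config.sides)
    (out / "power_report.json").write_text(report.to_json(indent=2))
    logger.info("power: %s", report)
    bundle["power"] = report

    # --- per-model training and interpretation ---------------------------
    bundle["models"] = {}
    for model in config.models:
        predictors = MODEL_PREDICTORS[model]
        rows = build_model_inputs(profiles, outcomes, model)
        X = rows[list(predictors)].to_numpy()
        y = rows["mscl"].to_numpy()
        k = min(config.train.k, len(rows))
        train_cfg = dataclasses.replace(config.train, k=k,
                                        seed=config.train_seed + model)
        logger.info("model %d: %d rows, k=%d folds (%d train / %d validation)",
                    model, len(rows), k, len(rows) - len(rows) // k,
                    len(rows) // k)
        ensemble = train_ensemble(X, y, train_cfg)
        (out / f"model{model}.json").write_text(
            json.dumps(ensemble_to_dict(ensemble)))

        metrics = evaluate(ensemble, X, y)
        imp_perm = permutation_importance(ensemble, rows[list(predictors)], y,
                                          reps=config.importance_reps,
                                          seed=config.permutation_seed + model)
        imp_garson = garson_importance(ensemble, predictor_names=predictors)
        imp = pd.concat([imp_perm, imp_garson], ignore_index=True)
        imp.insert(0, "model", model)
        imp.to_csv(out / f"model{model}_importance.csv", index=False)

        matrix = impact_matrix(ensemble, rows, predictors, thresholds=(lo, hi),
                               resolution=config.impact_resolution)
        matrix.to_csv(out / f"model{model}_impact_matrix.csv", index=False)

        surfaces = sliced_surfaces(ensemble, predictors, rows,
                                   resolution=config.grid_resolution,
                                   convention=config.midpoint_convention)
        surf_frames = [s.to_dataframe() for s in surfaces]
        pd.concat(surf_frames, ignore_index=True).to_csv(
            out / f"model{model}_surfaces.csv", index=False)
        if config.make_plots:
            for idx, s in enumerate(surfaces):
                plot_surface(s, out / f"model{model}_surface_{idx:02d}.png",
                             thresholds=(lo, hi))

        bundle["models"][model] = {
            "ensemble": ensemble, "metrics": metrics, "importance": imp,
            "impact_matrix": matrix,
        }

    summary = {
        "n_participants": int(outcomes.shape[0]),
        "n_scripts_excluded": n_excluded,
        "mscl_tercile_thresholds": [lo, hi],
        "power": json.loads(report.to_json()),
        "models": {m: {"rmse": bundle["models"][m]["metrics"].rmse,
                       "r2": bundle["models"][m]["metrics"].r2}
                   for m in bundle["models"]},
    }
    (out / "report.json").write_text(json.dumps(summary, indent=2))
    bundle["summary"] = summary
    return bundle
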