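"""Synthetic guided-imagery cohorts with known ground truth.

Each simulated participant carries five trait scores (drawn uniformly over
the instrument ranges) and seven scripted scenes: one "squats" test scene and
six imagery scenes.  A configurable ground-truth surface maps the normalized
traits to a per-participant mean percent SCL change; each scene realizes that
value plus script-level jitter.  A recording per scene is synthesized at
40 Hz as

    pause (5 s, tonic baseline)  →  listening (30 s)  →  imagery (60 s)

where the imagery window's mean conductance equals
``baseline × (1 + planted_percent / 100)`` before measurement noise and
linear drift are added.  The tonic baseline is log-normal (median 5 μS) so
conductance stays positive.  With zero noise, jitter and drift, the
preprocessing pipeline recovers the planted values exactly, which is what
makes every downstream stage testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_FS, SCLRecording
from .psych import INSTRUMENT_RANGES, TRAITS, normalize_profiles

#: scene labels: the squats test scene plus the six imagery scenes
TEST_SCRIPT = "squats"
SCENE_SCRIPTS = (
    "fitness_activity",
    "successful_competition",
    "home_venue",
    "training_session",
    "slow_start",
    "championship_start",
)
ALL_SCRIPTS = (TEST_SCRIPT,) + SCENE_SCRIPTS


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth data-generating configuration.

    ``coefficients`` act on the [−1, 1] normalized trait scale and are in
    percent-SCL-change units; ``interactions`` maps trait pairs to pairwise
    product coefficients.  The default surface is additive in all five traits
    with one neuroticism × somatic-anxiety interaction, signs matching the
    qualitative finding that arousal rises with neuroticism, somatic anxiety
    and general imagery use.
    """

    intercept: float = -1.5
    coefficients: dict = field(default_factory=lambda: {
        "general_imagery": 1.5,
        "neuroticism": 3.0,
        "somatic_anxiety": 2.0,
        "worry": 1.0,
        "concentration_disruption": 1.0,
    })
    interactions: dict = field(default_factory=lambda: {
        ("neuroticism", "somatic_anxiety"): 1.0,
    })
    script_jitter_sd: float = 1.0      # percent, scene-to-scene
    noise_sd: float = 0.05             # μS, per sample
    drift_slope_sd: float = 0.001      # μS/s, per script
    baseline_median: float = 5.0       # μS, log-normal median
    baseline_log_sd: float = 0.4       # log-scale SD of the tonic level
    test_scene_delta: float = 2.0      # percent change planted in the squats scene
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 15.0    # percent-change units
    pause_seconds: float = 5.0
    listening_seconds: float = 30.0
    imagery_seconds: float = 60.0
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if self.script_jitter_sd < 0 or self.noise_sd < 0 or self.drift_slope_sd < 0:
            raise ValueError("noise, jitter and drift SDs must be >= 0")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier fraction must be in [0, 1)")
        if self.baseline_median <= 0:
            raise ValueError("baseline tonic level must be strictly positive")
        if self.pause_seconds < 5.0:
            raise ValueError("pause must cover at least the 5 s baseline span")


def noise_free(spec: EffectSpec | None = None) -> EffectSpec:
    """A copy of ``spec`` with all stochastic trace components switched off."""
    spec = spec if spec is not None else EffectSpec()
    return replace(spec, script_jitter_sd=0.0, noise_sd=0.0, drift_slope_sd=0.0)


@dataclass
class GroundTruth:
    """What the generator planted, kept apart from the pipeline inputs.

    ``scripts`` has one row per participant × script (planted percent change,
    outlier flag); ``participants`` holds the true mean percent change
    ``mscl_true`` = mean of planted values over non-outlier, non-test scripts.
    """

    scripts: pd.DataFrame
    participants: pd.DataFrame


def true_surface(profile, spec: EffectSpec) -> float:
    """Evaluate the ground-truth percent-change surface at a normalized profile.

    ``profile`` maps trait names to values in [−1, 1] (a mapping or a pandas
    row with ``<trait>_norm`` or plain trait keys).
    """
    def get(trait: str) -> float:
        for key in (f"{trait}_norm", trait):
            if key in profile:
                return float(profile[key])
        raise KeyError(f"profile has no value for trait {trait!r}")

    vals = {}
    for trait in TRAITS:
        v = get(trait)
        if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
            raise ValueError(
                f"trait {trait!r} = {v} is not normalized to [-1, 1]")
        vals[trait] = v
    y = spec.intercept
    for trait, c in spec.coefficients.items():
        y += c * vals[trait]
    for (a, b), c in spec.interactions.items():
        y += c * vals[a] * vals[b]
    return float(y)


def _synthesize_recording(pid: str, script: str, is_test: bool, baseline: float,
                          planted_pct: float, spec: EffectSpec,
                          rng: np.random.Generator) -> SCLRecording:
    fs = spec.fs
    n_pause = int(round(spec.pause_seconds * fs))
    n_listen = int(round(spec.listening_seconds * fs))
    n_imagery = int(round(spec.imagery_seconds * fs))
    n = n_pause + n_listen + n_imagery

    trace = np.full(n, baseline)
    trace[n_pause + n_listen:] = baseline * (1.0 + planted_pct / 100.0)
    if spec.drift_slope_sd > 0:
        slope = rng.normal(0.0, spec.drift_slope_sd)
        trace = trace + slope * np.arange(n) / fs
    if spec.noise_sd > 0:
        trace = trace + rng.normal(0.0, spec.noise_sd, size=n)
    # clip away (vanishingly rare) non-physical values so recordings validate
    np.clip(trace, 1e-3, None, out=trace)
    return SCLRecording(pid, script, is_test, fs, trace,
                        pause_start=0, imagery_start=n_pause + n_listen,
                        imagery_end=n)


def generate_cohort(n: int, spec: EffectSpec | None = None, seed: int = 0,
                    ) -> tuple[pd.DataFrame, list[SCLRecording], GroundTruth]:
    """Simulate ``n`` participants × 7 scripts with known ground truth.

    Returns ``(profiles, recordings, truth)``: a trait frame with raw and
    normalized columns, one recording per participant × script, and the
    planted per-script/per-participant values.  Identical ``(n, spec, seed)``
    triples produce identical cohorts.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    spec = spec if spec is not None else EffectSpec()
    rng_traits, rng_traces, rng_outliers = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3))

    pids = [f"P{i + 1:03d}" for i in range(n)]
    raw = {"participant_id": pids}
    for trait in TRAITS:
        lo, hi = INSTRUMENT_RANGES[trait]
        raw[trait] = rng_traits.uniform(lo, hi, size=n)
    profiles = normalize_profiles(pd.DataFrame(raw))

    script_rows = []
    recordings: list[SCLRecording] = []
    for i, pid in enumerate(pids):
        surface = true_surface(profiles.iloc[i], spec)
        baseline = spec.baseline_median * np.exp(
            rng_traces.normal(0.0, spec.baseline_log_sd))
        for script in ALL_SCRIPTS:
            is_test = script == TEST_SCRIPT
            planted = spec.test_scene_delta if is_test else surface
            if spec.script_jitter_sd > 0:
                planted += rng_traces.normal(0.0, spec.script_jitter_sd)
            recordings.append(_synthesize_recording(
                pid, script, is_test, baseline, planted, spec, rng_traces))
            script_rows.append({"participant_id": pid, "script_id": script,
                                "is_test_scene": is_test,
                                "planted_pct": planted, "is_outlier": False})
    scripts = pd.DataFrame(script_rows)

    if spec.outlier_fraction > 0:
        recordings, scripts = plant_outliers(
            recordings, scripts, spec.outlier_fraction, spec.outlier_magnitude,
            rng=rng_outliers)

    participants = (
        scripts[~scripts["is_test_scene"] & ~scripts["is_outlier"]]
        .groupby("participant_id", sort=False)["planted_pct"].mean()
        .rename("mscl_true").reset_index())
    return profiles, recordings, GroundTruth(scripts, participants)


def plant_outliers(recordings: list[SCLRecording], scripts: pd.DataFrame,
                   fraction: float, magnitude: float, seed: int | None = None,
                   *, kind: str = "mean",
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[SCLRecording], pd.DataFrame]:
    """Shift the imagery window of a deterministic share of scripts.

    Per participant, ``round(fraction × n_scripts)`` non-test scripts are
    chosen (seeded) and their imagery window is made aberrant: ``kind="mean"``
    shifts the window mean by ``magnitude`` percent of baseline;
    ``kind="variance"`` superimposes a zero-mean square wave of amplitude
    ``magnitude`` percent, raising the variance while leaving the mean
    unchanged.  Flags are recorded in the returned scripts frame.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    if kind not in ("mean", "variance"):
        raise ValueError(f"kind must be 'mean' or 'variance', got {kind!r}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    scripts = scripts.copy()
    index = {(r.participant_id, r.script_id): k for k, r in enumerate(recordings)}
    out = list(recordings)
    for pid, grp in scripts.groupby("participant_id", sort=False):
        candidates = grp.index[~grp["is_test_scene"]].to_numpy()
        n_flag = int(round(fraction * len(grp)))
        if n_flag == 0:
            continue
        chosen = rng.choice(candidates, size=min(n_flag, candidates.size),
                            replace=False)
        for idx in chosen:
            scripts.loc[idx, "is_outlier"] = True
            sid = scripts.loc[idx, "script_id"]
            rec = out[index[(pid, sid)]]
            samples = rec.samples.copy()
            window = slice(rec.imagery_start, rec.imagery_end)
            base = float(np.mean(samples[rec.pause_start:rec.imagery_start]))
            if kind == "mean":
                samples[window] += base * magnitude / 100.0
            else:
                wobble = np.where(np.arange(rec.imagery_end - rec.imagery_start) % 2 == 0,
                                  1.0, -1.0) * base * magnitude / 100.0
                samples[window] += wobble
            np.clip(samples, 1e-3, None, out=samples)
            out[index[(pid, sid)]] = SCLRecording(
                rec.participant_id, rec.script_id, rec.is_test_scene, rec.fs,
                samples, rec.pause_start, rec.imagery_start, rec.imagery_end)
    return out, scripts
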