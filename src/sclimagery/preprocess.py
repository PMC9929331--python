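"""Raw skin-conductance-level (SCL) trace preprocessing.

The tonic electrodermal signal recorded during a guided-imagery session is
turned into the per-participant dependent variable *mSCL* in four steps:

1. ``baseline_pscl`` — average conductance over the final 5 s of the
   pre-script pause (pSCL, in μS).
2. ``normalize_trace`` — percent change from that baseline,
   ``nSCL = 100 * (SCL - pSCL) / pSCL``.
3. ``script_summary`` / ``clean_scripts`` — per-script imagery-window mean
   and variance, with within-participant 1.5·IQR exclusion of scripts whose
   mean or variance is outlying.
4. ``participant_mscl`` — unweighted mean of the retained non-test script
   means; the squats test scene never contributes to mSCL.

All quantile computations default to linear interpolation; the convention is
configurable because with only seven scripts per participant the IQR fences
are sensitive to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: expected sampling rate of the acquisition device (Hz)
DEFAULT_FS = 40.0

#: seconds of pre-script pause used for the baseline
PAUSE_BASELINE_SECONDS = 5.0


@dataclass
class SCLRecording:
    """One participant × script conductance trace with segment markers.

    ``samples`` holds the raw conductance in μS.  Marker indices delimit the
    pre-script pause and the imagery window; the listening span between them
    is never summarized.  Markers are part of the input, not inferred from
    the signal.
    """

    participant_id: str
    script_id: str
    is_test_scene: bool
    fs: float
    samples: np.ndarray
    pause_start: int
    imagery_start: int
    imagery_end: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not (0 <= self.pause_start < self.imagery_start <= self.imagery_end
                <= self.samples.size):
            raise ValueError(
                f"markers out of order for {self.participant_id}/{self.script_id}: "
                f"pause_start={self.pause_start}, imagery_start={self.imagery_start}, "
                f"imagery_end={self.imagery_end}, n={self.samples.size}")
        if self.imagery_end == self.imagery_start:
            raise ValueError(
                f"empty imagery window for {self.participant_id}/{self.script_id}")
        if np.any(self.samples <= 0):
            bad = int(np.argmax(self.samples <= 0))
            raise ValueError(
                f"non-positive conductance at sample {bad} of "
                f"{self.participant_id}/{self.script_id}")

    @property
    def pause(self) -> np.ndarray:
        return self.samples[self.pause_start:self.imagery_start]

    @property
    def imagery(self) -> np.ndarray:
        return self.samples[self.imagery_start:self.imagery_end]


@dataclass
class NormalizedTrace:
    """Percent-change (nSCL) trace with its baseline pSCL."""

    participant_id: str
    script_id: str
    is_test_scene: bool
    nscl: np.ndarray
    pscl: float
    imagery_start: int
    imagery_end: int

    @property
    def imagery(self) -> np.ndarray:
        return self.nscl[self.imagery_start:self.imagery_end]


def baseline_pscl(rec: SCLRecording, *, seconds: float = PAUSE_BASELINE_SECONDS) -> float:
    """Mean conductance over the final ``seconds`` of the pre-script pause.

    Raises ``ValueError`` when the pause is shorter than the requested span
    (200 samples at 40 Hz for the default 5 s).
    """
    needed = int(round(seconds * rec.fs))
    pause = rec.pause
    if pause.size < needed:
        raise ValueError(
            f"pause of {rec.participant_id}/{rec.script_id} has {pause.size} samples "
            f"({pause.size / rec.fs:.2f} s); {needed} samples ({seconds:g} s) required")
    return float(np.mean(pause[-needed:]))


def normalize_trace(rec: SCLRecording, *, baseline_seconds: float = PAUSE_BASELINE_SECONDS,
                    ) -> NormalizedTrace:
    """Express a recording as percent change from its pre-script baseline."""
    pscl = baseline_pscl(rec, seconds=baseline_seconds)
    if pscl <= 0:
        raise ValueError(
            f"non-physiological baseline pSCL={pscl} μS for "
            f"{rec.participant_id}/{rec.script_id}")
    nscl = 100.0 * (rec.samples - pscl) / pscl
    return NormalizedTrace(rec.participant_id, rec.script_id, rec.is_test_scene,
                           nscl, pscl, rec.imagery_start, rec.imagery_end)


def script_summary(tr: NormalizedTrace, *, ddof: int = 0) -> dict:
    """Imagery-window mean and variance of the normalized trace.

    Population variance (``ddof=0``) is the default convention for window
    summaries; pass ``ddof=1`` for the sample variance.
    """
    window = tr.imagery
    if window.size == 0:
        raise ValueError(
            f"empty imagery window for {tr.participant_id}/{tr.script_id}")
    return {
        "participant_id": tr.participant_id,
        "script_id": tr.script_id,
        "is_test_scene": tr.is_test_scene,
        "mean_nscl": float(np.mean(window)),
        "var_nscl": float(np.var(window, ddof=ddof)) if window.size > ddof else 0.0,
        "retained": True,
    }


def iqr_clean(values, *, factor: float = 1.5, method: str = "linear") -> np.ndarray:
    """Tukey fence mask: True where a value lies inside [Q1 − f·IQR, Q3 + f·IQR].

    Quartiles use ``numpy.percentile`` with the given interpolation method
    (linear by default).  Fewer than four values give no meaningful fence:
    everything is retained and a warning is logged.  Empty input is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("iqr_clean requires at least one value")
    if x.size < 4:
        logger.warning("iqr_clean: only %d values, fences unreliable; retaining all", x.size)
        return np.ones(x.size, dtype=bool)
    q1, q3 = np.percentile(x, [25.0, 75.0], method=method)
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    return (x >= lo) & (x <= hi)


def clean_scripts(summaries: pd.DataFrame, *, factor: float = 1.5,
                  method: str = "linear") -> pd.DataFrame:
    """Flag scripts whose mean or variance is outlying within a participant.

    A script is excluded when *either* its imagery-window mean *or* its
    variance falls outside that participant's 1.5·IQR fences ("and/or" read
    as OR).  The test scene participates in the diagnostics like any other
    script.  Participants left with zero retained scripts are dropped with a
    logged warning.
    """
    out = summaries.copy()
    out["retained"] = True
    for pid, grp in out.groupby("participant_id", sort=False):
        ok_mean = iqr_clean(grp["mean_nscl"].to_numpy(), factor=factor, method=method)
        ok_var = iqr_clean(grp["var_nscl"].to_numpy(), factor=factor, method=method)
        keep = ok_mean & ok_var
        out.loc[grp.index, "retained"] = keep
        for sid, km, kv in zip(grp["script_id"], ok_mean, ok_var):
            if not (km and kv):
                reason = []
                if not km:
                    reason.append("mean")
                if not kv:
                    reason.append("variance")
                logger.info("excluding %s/%s: outlying %s", pid, sid, "+".join(reason))
        if not keep.any():
            logger.warning("participant %s has no retained scripts; dropped", pid)
    return out


def participant_mscl(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mSCL: mean of retained, non-test script means.

    Participants without at least one retained non-test script are omitted.
    Returns a frame with columns ``participant_id, mscl, n_retained``.
    """
    rows = []
    for pid, grp in summaries.groupby("participant_id", sort=False):
        use = grp[grp["retained"] & ~grp["is_test_scene"]]
        if use.empty:
            logger.warning("participant %s: no retained non-test scripts; omitted", pid)
            continue
        rows.append({"participant_id": pid,
                     "mscl": float(use["mean_nscl"].mean()),
                     "n_retained": int(len(use))})
    return pd.DataFrame(rows, columns=["participant_id", "mscl", "n_retained"])


def tercile_thresholds(values, *, method: str = "linear") -> tuple[float, float]:
    """33.3rd and 66.7th percentiles splitting values into three equal bands.

    Classification convention: low < lower, moderate in [lower, upper],
    high > upper.  Requires at least three values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"tercile thresholds need >= 3 values, got {x.size}")
    lower, upper = np.percentile(x, [100.0 / 3.0, 200.0 / 3.0], method=method)
    return float(lower), float(upper)


def preprocess_cohort(recordings, *, ddof: int = 0, factor: float = 1.5,
                      method: str = "linear") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full trace → mSCL pipeline over an iterable of recordings.

    Returns ``(script_summaries, participant_outcomes)``.
    """
    summaries = pd.DataFrame(
        [script_summary(normalize_trace(rec), ddof=ddof) for rec in recordings])
    summaries = clean_scripts(summaries, factor=factor, method=method)
    outcomes = participant_mscl(summaries)
    return summaries, outcomes
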