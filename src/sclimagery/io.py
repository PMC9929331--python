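"""CSV formats for recordings, markers, questionnaires and ground truth.

Signals travel as long-format CSV (one row per sample) with a marker sidecar
(one row per participant × script carrying the segment indices and sampling
rate); the long format is robust to ragged script lengths and keeps the
sample table narrow.  Ground truth is serialized to separate files so tests
never leak it into the pipeline path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_FS, SCLRecording
from .psych import TRAITS
from .simulate import GroundTruth

RECORDING_COLUMNS = ["participant_id", "script_id", "is_test_scene",
                     "sample_index", "scl_uS"]
MARKER_COLUMNS = ["participant_id", "script_id", "fs_hz", "pause_start",
                  "imagery_start", "imagery_end"]


class ValidationError(ValueError):
    """A named violation of an input-file contract."""


def write_recordings(recordings, samples_path, markers_path) -> None:
    """Write recordings as a long-format sample CSV plus a marker sidecar."""
    sample_frames = []
    marker_rows = []
    for rec in recordings:
        sample_frames.append(pd.DataFrame({
            "participant_id": rec.participant_id,
            "script_id": rec.script_id,
            "is_test_scene": rec.is_test_scene,
            "sample_index": np.arange(rec.samples.size),
            "scl_uS": rec.samples,
        }))
        marker_rows.append({
            "participant_id": rec.participant_id, "script_id": rec.script_id,
            "fs_hz": rec.fs, "pause_start": rec.pause_start,
            "imagery_start": rec.imagery_start, "imagery_end": rec.imagery_end,
        })
    pd.concat(sample_frames, ignore_index=True).to_csv(samples_path, index=False)
    pd.DataFrame(marker_rows).to_csv(markers_path, index=False)


def read_recordings(samples_path, markers_path,
                    expected_fs: float | None = DEFAULT_FS) -> list[SCLRecording]:
    """Read and validate recordings from the two-file CSV layout.

    Raises :class:`ValidationError` naming the offending column, row or
    marker when the contract is violated; when ``expected_fs`` is given the
    sidecar's sampling rate must match it.
    """
    samples = pd.read_csv(samples_path)
    markers = pd.read_csv(markers_path)
    for cols, frame, path in ((RECORDING_COLUMNS, samples, samples_path),
                              (MARKER_COLUMNS, markers, markers_path)):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
    bad = samples.index[samples["scl_uS"] <= 0]
    if len(bad):
        raise ValidationError(
            f"{samples_path}: non-positive conductance at row {bad[0]}")
    marker_map = {(r.participant_id, r.script_id): r
                  for r in markers.itertuples(index=False)}
    recordings = []
    for (pid, sid), grp in samples.groupby(["participant_id", "script_id"],
                                           sort=False):
        key = (pid, sid)
        if key not in marker_map:
            raise ValidationError(f"{markers_path}: no markers for {pid}/{sid}")
        mk = marker_map[key]
        if expected_fs is not None and not np.isclose(mk.fs_hz, expected_fs):
            raise ValidationError(
                f"{markers_path}: {pid}/{sid} sampled at {mk.fs_hz} Hz, "
                f"expected {expected_fs}")
        if not mk.pause_start < mk.imagery_start <= mk.imagery_end:
            raise ValidationError(
                f"{markers_path}: markers out of order for {pid}/{sid}")
        trace = grp.sort_values("sample_index")["scl_uS"].to_numpy()
        try:
            recordings.append(SCLRecording(
                str(pid), str(sid), bool(grp["is_test_scene"].iloc[0]),
                float(mk.fs_hz), trace, int(mk.pause_start),
                int(mk.imagery_start), int(mk.imagery_end)))
        except ValueError as exc:
            raise ValidationError(str(exc)) from exc
    return recordings


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [t for t in TRAITS if t not in frame.columns]
    if "participant_id" not in frame.columns:
        raise ValidationError(f"{path}: missing column participant_id")
    if missing:
        raise ValidationError(f"{path}: missing trait columns {missing}")
    return frame


def write_ground_truth(truth: GroundTruth, scripts_path, participants_path) -> None:
    truth.scripts.to_csv(scripts_path, index=False)
    truth.participants.to_csv(participants_path, index=False)


def read_ground_truth(scripts_path, participants_path) -> GroundTruth:
    return GroundTruth(pd.read_csv(scripts_path), pd.read_csv(participants_path))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
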