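"""On-disk formats for recordings, sessions, and questionnaires.

One directory per participant holding one wide CSV per stream
(``timestamp, valid, <channel columns>``), a JSON manifest per session
naming the files and metadata, and a flat CSV for questionnaire records.
Values use '.' decimals and UTF-8; NaN coordinates serialize as empty cells
and read back as invalid frames.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Condition,
    DataError,
    DyadSession,
    ParticipantRecording,
    QuestionnaireRecord,
    SchemaError,
    TimestampedStream,
)
from .naming import (
    BLENDSHAPE_NAMES,
    GAZE_CHANNELS,
    HEAD_POSE_CHANNELS,
    SKELETON_CHANNELS,
)

log = logging.getLogger(__name__)

STREAM_SCHEMAS: dict[str, tuple[str, ...]] = {
    "skeleton": SKELETON_CHANNELS,
    "blendshapes": BLENDSHAPE_NAMES,
    "head_pose": HEAD_POSE_CHANNELS,
    "gaze": GAZE_CHANNELS,
}

#: Physical bounds used to flag (not drop) implausible frames.
MAX_JOINT_COORD_M = 10.0


def _bound_violations(kind: str, values: np.ndarray) -> np.ndarray:
    """Per-frame flag of frames containing out-of-bound samples."""
    with np.errstate(invalid="ignore"):
        if kind == "skeleton":
            bad = np.abs(values) >= MAX_JOINT_COORD_M
        elif kind == "blendshapes":
            bad = (values < 0.0) | (values > 1.0)
        else:
            bad = np.zeros_like(values, dtype=bool)
    return bad.any(axis=1)


def read_recording(path: str | Path, kind: str) -> TimestampedStream:
    """Read one stream CSV, validating the documented schema.

    Frames violating physical bounds (blendshapes outside [0, 1], joint
    coordinates beyond 10 m) or holding NaN are flagged invalid rather than
    dropped, so the per-window validity rule downstream sees them.
    """
    if kind not in STREAM_SCHEMAS:
        raise SchemaError(f"unknown stream kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    expected = ["timestamp", "valid", *STREAM_SCHEMAS[kind]]
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path.name}: schema mismatch for {kind!r} "
            f"(missing columns: {missing or 'none'}, extra: {extra or 'none'})"
        )
    df = df[expected]
    ts = df["timestamp"].to_numpy(dtype=float)
    if len(ts) > 1 and np.any(np.diff(ts) <= 0):
        row = int(np.argmax(np.diff(ts) <= 0)) + 1
        raise DataError(f"{path.name}: non-monotone timestamp at row {row}")
    values = df[list(STREAM_SCHEMAS[kind])].to_numpy(dtype=float)
    valid = df["valid"].to_numpy(dtype=bool)
    nan_frames = np.isnan(values).any(axis=1)
    oob = _bound_violations(kind, values)
    n_flagged = int(np.sum((nan_frames | oob) & valid))
    if n_flagged:
        log.warning(
            "%s: flagged %d frame(s) invalid (NaN or out-of-bound values)",
            path.name, n_flagged,
        )
    valid = valid & ~nan_frames & ~oob
    return TimestampedStream(ts, values, STREAM_SCHEMAS[kind], valid)


def write_stream(stream: TimestampedStream, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(stream.values, columns=list(stream.channels))
    df.insert(0, "valid", stream.valid.astype(int))
    df.insert(0, "timestamp", stream.timestamps)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def write_recording(rec: ParticipantRecording, directory: str | Path) -> Path:
    """Write all four stream CSVs for one participant; returns the directory."""
    directory = Path(directory)
    for name, stream in rec.streams().items():
        write_stream(stream, directory / f"{name}.csv")
    return directory


def read_participant(directory: str | Path, participant_id: str) -> ParticipantRecording:
    directory = Path(directory)
    streams = {
        kind: read_recording(directory / f"{kind}.csv", kind)
        for kind in STREAM_SCHEMAS
    }
    return ParticipantRecording(participant_id=participant_id, **streams)


def write_session(session: DyadSession, directory: str | Path) -> Path:
    """Write both participants plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "dyad_id": session.dyad_id,
        "condition": {
            "body_visible": session.condition.body_visible,
            "face_visible": session.condition.face_visible,
        },
        "gender": session.gender,
        "task_order": session.task_order,
        "participants": [],
    }
    for rec in session.participants:
        subdir = directory / rec.participant_id
        write_recording(rec, subdir)
        manifest["participants"].append(
            {"participant_id": rec.participant_id, "directory": rec.participant_id}
        )
    manifest_path = directory / "session.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_session(manifest_path: str | Path) -> DyadSession:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    recs = tuple(
        read_participant(base / p["directory"], p["participant_id"])
        for p in manifest["participants"]
    )
    if len(recs) != 2:
        raise DataError(f"{manifest_path}: a session must name exactly two participants")
    cond = manifest["condition"]
    return DyadSession(
        dyad_id=manifest["dyad_id"],
        participants=recs,
        condition=Condition(bool(cond["body_visible"]), bool(cond["face_visible"])),
        gender=manifest.get("gender", "F"),
        task_order=manifest.get("task_order", "AB"),
    )


_Q_COLUMNS = (
    ["participant_id"]
    + [f"attr_{i}" for i in range(1, 9)]
    + [f"bfi_self_{i}" for i in range(1, 16)]
    + [f"bfi_obs_{i}" for i in range(1, 16)]
    + ["pos_pct", "neg_pct", "gender"]
)


def write_questionnaires(records: list[QuestionnaireRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        rows.append(
            [r.participant_id, *r.attraction_items.astype(int),
             *r.bfi_self.astype(int), *r.bfi_observer,
             r.pos_pct, r.neg_pct, r.gender]
        )
    pd.DataFrame(rows, columns=_Q_COLUMNS).to_csv(path, index=False)
    return path


def read_questionnaires(path: str | Path) -> list[QuestionnaireRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _Q_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"questionnaire file missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            QuestionnaireRecord(
                participant_id=str(row["participant_id"]),
                attraction_items=row[[f"attr_{i}" for i in range(1, 9)]].to_numpy(float),
                bfi_self=row[[f"bfi_self_{i}" for i in range(1, 16)]].to_numpy(float),
                bfi_observer=row[[f"bfi_obs_{i}" for i in range(1, 16)]].to_numpy(float),
                pos_pct=float(row["pos_pct"]),
                neg_pct=float(row["neg_pct"]),
                gender=str(row["gender"]),
            )
        )
    return records
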