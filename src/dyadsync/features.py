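"""Per-participant candidate feature construction.

The candidate layer mirrors the study's input blocks: windowed
cross-correlation synchrony summaries (five variants) for the composite
body extent, each of the 17 joints, the 10 joint angles, the composite
facial movement and each of the 52 blendshape channels; six descriptive
statistics per joint coordinate; per-joint 0.1-s Euclidean displacement
mean/SD; joint-angle statistics; head-rotation and gaze statistics;
mean/SD per merged facial item; per-stream validity; and gender. The
enumeration is deterministic and exposed as :data:`FEATURE_NAMES` /
:data:`N_CANDIDATE_FEATURES`.

Synchrony features are dyad-level: both members of a dyad carry identical
values in that block. Missing features stay NaN until the table-level
median imputation, which logs every imputed column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import DataError, DyadSession, UniformSeries
from .kinematics import frame_displacement
from .naming import (
    ANGLE_NAMES,
    BLENDSHAPE_NAMES,
    GAZE_CHANNELS,
    HEAD_POSE_CHANNELS,
    JOINT_NAMES,
    MERGED_BLENDSHAPE_NAMES,
    STREAM_NAMES,
)
from .synchrony import (
    PreparedDyad,
    SynchronySummary,
    WindowedCrossCorrelation,
    crosscorr_matrix,
    lag_grid,
    summarize_synchrony,
    _lag_samples,
)

log = logging.getLogger(__name__)

SYNC_VARIANTS = ("mean", "abs_mean", "nonneg_mean", "max", "abs_max")
STAT_NAMES = ("mean", "sd", "grad_mean", "grad_sd", "grad_max", "grad2_max")
ANGLE_STAT_NAMES = ("mean", "sd", "absgrad_mean", "absgrad_sd")


def _enumerate_names() -> tuple[str, ...]:
    names: list[str] = []
    for ch in ("composite", *JOINT_NAMES, *ANGLE_NAMES):
        names += [f"sync_body_{ch}__{v}" for v in SYNC_VARIANTS]
    for ch in ("composite", *BLENDSHAPE_NAMES):
        names += [f"sync_face_{ch}__{v}" for v in SYNC_VARIANTS]
    for j in JOINT_NAMES:
        for axis in "xyz":
            names += [f"joint_{j}_{axis}__{s}" for s in STAT_NAMES]
    for j in JOINT_NAMES:
        names += [f"disp10_{j}__mean", f"disp10_{j}__sd"]
    for a in ANGLE_NAMES:
        names += [f"angle_{a}__{s}" for s in ANGLE_STAT_NAMES]
    for ch in HEAD_POSE_CHANNELS:
        names += [f"head_{ch}__mean", f"head_{ch}__sd",
                  f"head_{ch}_grad__mean", f"head_{ch}_grad__sd"]
    for ch in MERGED_BLENDSHAPE_NAMES:
        names += [f"face_{ch}__mean", f"face_{ch}__sd"]
    for ch in GAZE_CHANNELS:
        names += [f"gaze_{ch}__mean", f"gaze_{ch}__sd"]
    for stream in STREAM_NAMES:
        names += [f"valid_{stream}__pct", f"valid_{stream}__max_missing_run"]
    names.append("gender")
    return tuple(names)


FEATURE_NAMES: tuple[str, ...] = _enumerate_names()
N_CANDIDATE_FEATURES: int = len(FEATURE_NAMES)


def stat_block(values: np.ndarray, valid: np.ndarray, rate_hz: float) -> dict[str, float]:
    """Six descriptive statistics of a scalar uniform series.

    Gradients are first differences scaled to per-second units; a gradient
    sample is defined only where both endpoint frames are valid. All six
    statistics are missing (NaN) with fewer than 3 valid frames; maxima are
    of the signed values.
    """
    v = np.asarray(values, dtype=float)
    m = np.asarray(valid, dtype=bool)
    if m.sum() < 3:
        return dict.fromkeys(STAT_NAMES, np.nan)
    grad = np.diff(v) * rate_hz
    grad_valid = m[1:] & m[:-1]
    grad2 = np.diff(grad) * rate_hz
    grad2_valid = grad_valid[1:] & grad_valid[:-1]
    out = {
        "mean": float(v[m].mean()),
        "sd": float(v[m].std()),
        "grad_mean": float(grad[grad_valid].mean()) if grad_valid.any() else np.nan,
        "grad_sd": float(grad[grad_valid].std()) if grad_valid.any() else np.nan,
        "grad_max": float(grad[grad_valid].max()) if grad_valid.any() else np.nan,
        "grad2_max": float(grad2[grad2_valid].max()) if grad2_valid.any() else np.nan,
    }
    return out


def _angle_stat_block(values, valid, rate_hz) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    m = np.asarray(valid, dtype=bool)
    if m.sum() < 3:
        return dict.fromkeys(ANGLE_STAT_NAMES, np.nan)
    grad = np.abs(np.diff(v) * rate_hz)
    gm = m[1:] & m[:-1]
    return {
        "mean": float(v[m].mean()),
        "sd": float(v[m].std()),
        "absgrad_mean": float(grad[gm].mean()) if gm.any() else np.nan,
        "absgrad_sd": float(grad[gm].std()) if gm.any() else np.nan,
    }


def _summaries_multi(
    x: UniformSeries, y: UniformSeries, plan, max_lag_s: float, cfg: PipelineConfig
) -> list[SynchronySummary]:
    """Per-channel synchrony summaries for aligned multichannel series."""
    lags = lag_grid(max_lag_s, cfg.lag_step_s)
    kept = plan.kept_indices
    n_ch = x.values.shape[1]
    if len(kept) == 0:
        return [SynchronySummary.missing() for _ in range(n_ch)]
    n = min(x.n_frames, y.n_frames)
    r, n_ov = crosscorr_matrix(
        x.values[:n], y.values[:n], x.valid[:n], y.valid[:n],
        plan.bounds, kept, _lag_samples(lags, x.rate_hz),
        cfg.min_overlap_samples,
    )
    return [
        summarize_synchrony(WindowedCrossCorrelation(lags, r[:, :, c], n_ov, kept))
        for c in range(n_ch)
    ]


def _validity_stats(series: UniformSeries) -> tuple[float, int]:
    mask = series.valid
    pct = 100.0 * mask.mean() if len(mask) else np.nan
    runs = 0
    longest = 0
    for v in mask:
        runs = 0 if v else runs + 1
        longest = max(longest, runs)
    return float(pct), int(longest)


def dyad_features(
    session: DyadSession,
    cfg: PipelineConfig | None = None,
    prepared: PreparedDyad | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Candidate feature vectors for both members of one dyad."""
    cfg = cfg or PipelineConfig()
    prep = prepared or PreparedDyad(session, cfg)
    a, b = prep.participants

    shared: dict[str, float] = {}

    # --- dyad-level synchrony blocks (identical for both members) ---
    body_channels = ("composite", *JOINT_NAMES)
    body_order = [a.extent10.channels.index(c) for c in ("composite", *JOINT_NAMES)]
    ext_a = UniformSeries(a.extent10.rate_hz, a.extent10.start,
                          body_channels, a.extent10.values[:, body_order],
                          a.extent10.valid)
    ext_b = UniformSeries(b.extent10.rate_hz, b.extent10.start,
                          body_channels, b.extent10.values[:, body_order],
                          b.extent10.valid)
    for ch, summ in zip(
        body_channels,
        _summaries_multi(ext_a, ext_b, prep.body_plan, cfg.body_max_lag_s, cfg),
    ):
        for variant, value in summ.as_dict().items():
            shared[f"sync_body_{ch}__{variant}"] = value

    for ch, summ in zip(
        ANGLE_NAMES,
        _summaries_multi(a.angles10, b.angles10, prep.body_plan,
                         cfg.body_max_lag_s, cfg),
    ):
        for variant, value in summ.as_dict().items():
            shared[f"sync_body_{ch}__{variant}"] = value

    face_summs = _summaries_multi(
        a.face_movement10, b.face_movement10, prep.face_plan,
        cfg.face_max_lag_s, cfg,
    )
    for variant, value in face_summs[0].as_dict().items():
        shared[f"sync_face_composite__{variant}"] = value
    for ch, summ in zip(
        BLENDSHAPE_NAMES,
        _summaries_multi(a.face10, b.face10, prep.face_plan,
                         cfg.face_max_lag_s, cfg),
    ):
        for variant, value in summ.as_dict().items():
            shared[f"sync_face_{ch}__{variant}"] = value

    # --- participant-level blocks ---
    out = []
    for part in (a, b):
        feats = dict(shared)
        skel = part.skel30
        for j in JOINT_NAMES:
            for axis in "xyz":
                col = skel.channel(f"{j}_{axis}")
                for stat, value in stat_block(col, skel.valid, skel.rate_hz).items():
                    feats[f"joint_{j}_{axis}__{stat}"] = value
        skel10 = part.skel10
        disp10 = frame_displacement(skel10)
        for j in JOINT_NAMES:
            col = disp10.channel(j)
            m = disp10.valid
            if m.sum() >= 2:
                feats[f"disp10_{j}__mean"] = float(col[m].mean())
                feats[f"disp10_{j}__sd"] = float(col[m].std())
            else:
                feats[f"disp10_{j}__mean"] = np.nan
                feats[f"disp10_{j}__sd"] = np.nan
        ang = part.angles30
        for name in ANGLE_NAMES:
            col = ang.channel(name)
            for stat, value in _angle_stat_block(col, ang.valid, ang.rate_hz).items():
                feats[f"angle_{name}__{stat}"] = value
        head = part.head30
        for ch in HEAD_POSE_CHANNELS:
            sb = stat_block(head.channel(ch), head.valid, head.rate_hz)
            feats[f"head_{ch}__mean"] = sb["mean"]
            feats[f"head_{ch}__sd"] = sb["sd"]
            feats[f"head_{ch}_grad__mean"] = sb["grad_mean"]
            feats[f"head_{ch}_grad__sd"] = sb["grad_sd"]
        merged = part.face_merged30
        for ch in MERGED_BLENDSHAPE_NAMES:
            col = merged.channel(ch)
            m = merged.valid
            feats[f"face_{ch}__mean"] = float(col[m].mean()) if m.any() else np.nan
            feats[f"face_{ch}__sd"] = float(col[m].std()) if m.any() else np.nan
        gaze = part.gaze30
        for ch in GAZE_CHANNELS:
            col = gaze.channel(ch)
            m = gaze.valid
            feats[f"gaze_{ch}__mean"] = float(col[m].mean()) if m.any() else np.nan
            feats[f"gaze_{ch}__sd"] = float(col[m].std()) if m.any() else np.nan
        for stream_name, series in (
            ("skeleton", part.skel30), ("blendshapes", part.face30),
            ("head_pose", part.head30), ("gaze", part.gaze30),
        ):
            pct, run = _validity_stats(series)
            feats[f"valid_{stream_name}__pct"] = pct
            feats[f"valid_{stream_name}__max_missing_run"] = float(run)
        feats["gender"] = 1.0 if session.gender == "M" else 0.0
        out.append({name: feats[name] for name in FEATURE_NAMES})
    return out[0], out[1]


def participant_features(
    session: DyadSession, participant_index: int, cfg: PipelineConfig | None = None
) -> dict[str, float]:
    """Feature vector for one member of a dyad (0 or 1)."""
    if participant_index not in (0, 1):
        raise DataError("participant_index must be 0 or 1")
    return dyad_features(session, cfg)[participant_index]


def build_feature_table(
    sessions: list[DyadSession],
    cfg: PipelineConfig | None = None,
    outcomes: pd.DataFrame | None = None,
    prepared: dict[str, PreparedDyad] | None = None,
) -> pd.DataFrame:
    """Participants x features matrix with optional outcome alignment.

    Columns missing in more than ``cfg.max_missing_feature_fraction`` of
    rows are dropped (logged); remaining missing cells are median-imputed
    (logged). Non-missing cells are never modified.
    """
    cfg = cfg or PipelineConfig()
    rows = {}
    dyad_of = {}
    for session in sessions:
        prep = (prepared or {}).get(session.dyad_id)
        fa, fb = dyad_features(session, cfg, prep)
        for rec, feats in zip(session.participants, (fa, fb)):
            if rec.participant_id in rows:
                raise DataError(f"duplicate participant id {rec.participant_id}")
            rows[rec.participant_id] = feats
            dyad_of[rec.participant_id] = session.dyad_id
    return assemble_feature_table(rows, dyad_of, cfg, outcomes)


def assemble_feature_table(
    rows: dict[str, dict],
    dyad_of: dict[str, str],
    cfg: PipelineConfig,
    outcomes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble precomputed feature rows into the imputed, aligned table."""
    table = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]
    table.index.name = "participant_id"
    table.insert(0, "dyad_id", [dyad_of[i] for i in table.index])

    feature_cols = [c for c in table.columns if c != "dyad_id"]
    frac_missing = table[feature_cols].isna().mean()
    to_drop = frac_missing[frac_missing > cfg.max_missing_feature_fraction].index
    if len(to_drop):
        log.info("dropping %d feature column(s) with > %.0f%% missing: %s",
                 len(to_drop), 100 * cfg.max_missing_feature_fraction,
                 list(to_drop)[:10])
        table = table.drop(columns=list(to_drop))
        feature_cols = [c for c in feature_cols if c not in set(to_drop)]
    n_imputed = int(table[feature_cols].isna().sum().sum())
    if n_imputed:
        log.info("median-imputing %d missing feature cell(s)", n_imputed)
        medians = table[feature_cols].median()
        table[feature_cols] = table[feature_cols].fillna(medians)

    if outcomes is not None:
        # the numeric "gender" feature column already encodes gender
        extra = outcomes.set_index("participant_id").drop(
            columns=["gender"], errors="ignore"
        )
        table = table.join(extra, how="left")
    return table
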