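"""Synthetic dyad sessions with known ground truth.

No public corpus of paired skeleton + blendshape recordings exists for this
kind of dyadic study, so every downstream stage is exercised against a
generator whose coupling structure is analytically controlled:

* Each participant carries a nonnegative scalar *movement drive*. Partner A's
  drive is ``c + g(t) + e_A(t)``; partner B's is
  ``c + alpha * g(t - tau) + sqrt(1 - alpha^2) * e_B(t)``, where ``g`` is a
  shared smooth band-limited process and ``e_A, e_B`` are independent smooth
  noises matched in variance to ``g``. The drives' lagged correlation
  therefore peaks at ``tau`` with a strength that grows monotonically in
  ``alpha``.
* Joint displacements have magnitude exactly proportional to the drive (the
  direction follows a smooth random field), so the extent-of-movement series
  inherits the drive coupling by construction.
* Blendshape channels carry sparse attack-sustain-decay activation pulses;
  partner B mimics each of A's events with probability ``alpha`` at lag
  ``tau``. Mirrored left/right channels share a common pulse with small
  asymmetry noise.
* A latent attraction score per dyad shifts movement amplitude and facial
  event rate (``attraction_effect_size``) and drives the questionnaire
  items, giving the classifier a recoverable signal.

Timestamps are jittered and dropout runs are deleted to emulate real sensor
streams. All randomness flows through a single seed hierarchy
(cohort seed -> dyad seeds -> stream seeds), so any dyad is reproducible in
isolation and identical (config, seed) pairs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import ConfigError, SynthConfig
from .core import (
    Condition,
    DyadSession,
    ParticipantRecording,
    QuestionnaireRecord,
    TimestampedStream,
)
from .naming import (
    BLENDSHAPE_NAMES,
    GAZE_CHANNELS,
    HEAD_POSE_CHANNELS,
    JOINT_NAMES,
    SKELETON_CHANNELS,
)

#: Rest positions (meters, sensor-centered: +x right, +y up, +z toward the
#: participant) for a seated adult about 2 m from the sensor.
SKELETON_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "SpineBase": (0.0, 0.65, 2.0),
    "SpineMid": (0.0, 0.95, 2.0),
    "SpineShoulder": (0.0, 1.25, 2.0),
    "Neck": (0.0, 1.35, 2.0),
    "Head": (0.0, 1.55, 2.0),
    "ShoulderLeft": (-0.20, 1.25, 2.0),
    "ElbowLeft": (-0.30, 1.00, 2.0),
    "WristLeft": (-0.32, 0.78, 1.95),
    "HandLeft": (-0.33, 0.72, 1.93),
    "HandTipLeft": (-0.34, 0.66, 1.92),
    "ThumbLeft": (-0.30, 0.70, 1.90),
    "ShoulderRight": (0.20, 1.25, 2.0),
    "ElbowRight": (0.30, 1.00, 2.0),
    "WristRight": (0.32, 0.78, 1.95),
    "HandRight": (0.33, 0.72, 1.93),
    "HandTipRight": (0.34, 0.66, 1.92),
    "ThumbRight": (0.30, 0.70, 1.90),
}

#: Blendshape groups that carry activation events (mirrored pairs share one
#: latent pulse train).
ACTIVE_BLENDSHAPE_GROUPS: tuple[tuple[str, ...], ...] = (
    ("mouthSmileLeft", "mouthSmileRight"),
    ("mouthFrownLeft", "mouthFrownRight"),
    ("browInnerUp",),
    ("jawOpen",),
    ("eyeSquintLeft", "eyeSquintRight"),
    ("mouthPressLeft", "mouthPressRight"),
    ("browDownLeft", "browDownRight"),
    ("mouthPucker",),
)


@dataclass
class GroundTruth:
    """Generator-side truth: the recovery target of acceptance tests."""

    dyads: pd.DataFrame           # per-dyad latent coupling and attraction
    participants: pd.DataFrame    # per-participant latents


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _smooth_noise_nd(
    rng: np.random.Generator, shape: tuple, rate_hz: float, bandwidth_hz: float
) -> np.ndarray:
    """Zero-mean, unit-variance band-limited Gaussian series (columns)."""
    n = shape[0]
    white = rng.standard_normal((n + 200, *shape[1:]))
    b, a = signal.butter(2, bandwidth_hz / (rate_hz / 2.0), btype="low")
    smooth = signal.filtfilt(b, a, white, axis=0)[100:-100]
    sd = smooth.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return smooth / sd


def _smooth_noise(
    rng: np.random.Generator, n: int, rate_hz: float, bandwidth_hz: float
) -> np.ndarray:
    return _smooth_noise_nd(rng, (n,), rate_hz, bandwidth_hz)


def generate_drive_pair(
    cfg: SynthConfig, seed, amplitude_scales: tuple[float, float] = (1.0, 1.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Movement-drive pair on the nominal sampling grid.

    Both series are nonnegative; their lagged cross-correlation peaks at
    ``cfg.coupling_lag_s`` (positive lag = B trails A) with a height
    monotone in ``cfg.coupling_alpha``.
    """
    rng = _rng(seed)
    rate = cfg.nominal_rate_hz
    n = int(round(cfg.duration_s * rate))
    shift = int(round(cfg.coupling_lag_s * rate))
    if abs(cfg.coupling_lag_s) > cfg.duration_s / 2:
        raise ConfigError("coupling lag exceeds half the session duration")
    off_a, off_b = max(shift, 0), max(-shift, 0)
    g = _smooth_noise(rng, n + abs(shift), rate, cfg.drive_bandwidth_hz)
    e_a = _smooth_noise(rng, n, rate, cfg.drive_bandwidth_hz)
    e_b = _smooth_noise(rng, n, rate, cfg.drive_bandwidth_hz)
    a = cfg.coupling_alpha
    sd = cfg.drive_sd
    drive_a = cfg.drive_baseline + sd * (g[off_a:off_a + n] + e_a)
    drive_b = cfg.drive_baseline + sd * (
        a * g[off_b:off_b + n] + np.sqrt(1.0 - a * a) * e_b
    )
    drive_a = np.clip(drive_a * amplitude_scales[0], 0.0, None)
    drive_b = np.clip(drive_b * amplitude_scales[1], 0.0, None)
    return drive_a, drive_b


def _jittered_timestamps(
    rng: np.random.Generator, n: int, rate_hz: float, jitter_sd: float
) -> np.ndarray:
    dt = 1.0 / rate_hz
    jitter = np.clip(rng.normal(0.0, jitter_sd, n), -0.45 * dt, 0.45 * dt)
    return np.arange(n) * dt + jitter


def _dropout_keep_mask(
    rng: np.random.Generator, n: int, fraction: float, mean_run: float
) -> np.ndarray:
    """Two-state Markov dropout: stationary drop fraction and mean run length."""
    if fraction <= 0:
        return np.ones(n, dtype=bool)
    p_leave_drop = 1.0 / max(mean_run, 1.0)
    p_enter_drop = p_leave_drop * fraction / (1.0 - fraction)
    keep = np.ones(n, dtype=bool)
    i = 0
    dropped = rng.random() < fraction
    while i < n:
        if dropped:
            run = rng.geometric(p_leave_drop)
            keep[i:i + run] = False
        else:
            run = rng.geometric(p_enter_drop)
        i += run
        dropped = not dropped
    # never drop the stream endpoints, so the session span survives
    keep[0] = keep[-1] = True
    return keep


def _skeleton_stream(
    drive: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> TimestampedStream:
    """Skeleton positions whose per-frame joint displacement magnitude is
    exactly ``drive * displacement_scale_m`` along a smooth direction field."""
    n = len(drive)
    rate = cfg.nominal_rate_hz
    dirs = _smooth_noise_nd(
        rng, (n, len(JOINT_NAMES), 3), rate, cfg.drive_bandwidth_hz
    )
    norms = np.linalg.norm(dirs, axis=2, keepdims=True)
    norms[norms == 0] = 1.0
    dirs /= norms
    steps = drive[:, None, None] * cfg.displacement_scale_m * dirs
    steps[0] = 0.0
    template = np.array([SKELETON_TEMPLATE[j] for j in JOINT_NAMES])
    pos = template[None] + np.cumsum(steps, axis=0)
    ts = _jittered_timestamps(rng, n, rate, cfg.timestamp_jitter_sd_s)
    keep = _dropout_keep_mask(rng, n, cfg.dropout_fraction, cfg.dropout_mean_run)
    values = pos.reshape(n, -1)[keep]
    return TimestampedStream(ts[keep], values, SKELETON_CHANNELS)


def generate_skeleton_pair(
    cfg: SynthConfig, seed
) -> tuple[TimestampedStream, TimestampedStream]:
    """Partner-coupled skeleton streams (convenience wrapper)."""
    ss = np.random.SeedSequence(seed)
    s_drive, s_a, s_b = ss.spawn(3)
    drive_a, drive_b = generate_drive_pair(cfg, s_drive)
    return (
        _skeleton_stream(drive_a, cfg, _rng(s_a)),
        _skeleton_stream(drive_b, cfg, _rng(s_b)),
    )


def _pulse(duration_frames: int) -> np.ndarray:
    """Attack-sustain-decay activation pulse (raised-cosine flanks)."""
    attack = duration_frames // 3
    decay = duration_frames // 3
    sustain = duration_frames - attack - decay
    up = 0.5 * (1 - np.cos(np.linspace(0, np.pi, max(attack, 1))))
    down = 0.5 * (1 + np.cos(np.linspace(0, np.pi, max(decay, 1))))
    return np.concatenate([up, np.ones(max(sustain, 0)), down])


def _add_events(
    out: np.ndarray,
    channel_idx: list[int],
    times: np.ndarray,
    amps: np.ndarray,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> None:
    n = out.shape[0]
    dur = int(round(cfg.blendshape_event_duration_s * cfg.nominal_rate_hz))
    base = _pulse(dur)
    for t0, amp in zip(times, amps):
        i0 = int(round(t0 * cfg.nominal_rate_hz))
        if i0 >= n:
            continue
        seg = base[: n - i0]
        for ci in channel_idx:
            side = 1.0 + rng.normal(0.0, cfg.blendshape_asymmetry_sd)
            out[i0:i0 + len(seg), ci] += amp * side * seg


def _blendshape_values_pair(
    cfg: SynthConfig, rng: np.random.Generator,
    rate_scales: tuple[float, float] = (1.0, 1.0),
    mimic_alpha: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(cfg.duration_s * cfg.nominal_rate_hz))
    alpha = cfg.coupling_alpha if mimic_alpha is None else mimic_alpha
    out_a = np.zeros((n, len(BLENDSHAPE_NAMES)))
    out_b = np.zeros((n, len(BLENDSHAPE_NAMES)))
    name_idx = {name: i for i, name in enumerate(BLENDSHAPE_NAMES)}
    for group in ACTIVE_BLENDSHAPE_GROUPS:
        idx = [name_idx[g] for g in group]
        n_events_a = rng.poisson(
            cfg.blendshape_event_rate_hz * cfg.duration_s * rate_scales[0]
        )
        times_a = np.sort(rng.uniform(0, cfg.duration_s, n_events_a))
        amps_a = rng.uniform(0.35, cfg.blendshape_event_amplitude, n_events_a)
        _add_events(out_a, idx, times_a, amps_a, cfg, rng)
        # B mimics A's events with probability alpha at the coupling lag,
        # plus independent events keeping the overall rate comparable.
        mimic = rng.random(n_events_a) < alpha
        _add_events(
            out_b, idx, times_a[mimic] + cfg.coupling_lag_s, amps_a[mimic],
            cfg, rng,
        )
        n_own = rng.poisson(
            cfg.blendshape_event_rate_hz * cfg.duration_s
            * rate_scales[1] * (1.0 - alpha)
        )
        times_b = np.sort(rng.uniform(0, cfg.duration_s, n_own))
        amps_b = rng.uniform(0.35, cfg.blendshape_event_amplitude, n_own)
        _add_events(out_b, idx, times_b, amps_b, cfg, rng)
    return np.clip(out_a, 0.0, 1.0), np.clip(out_b, 0.0, 1.0)


def generate_blendshape_pair(
    cfg: SynthConfig, seed
) -> tuple[TimestampedStream, TimestampedStream]:
    """Partner-coupled facial blendshape streams; all values in [0, 1]."""
    rng = _rng(seed)
    vals_a, vals_b = _blendshape_values_pair(cfg, rng)
    streams = []
    for vals in (vals_a, vals_b):
        n = vals.shape[0]
        ts = _jittered_timestamps(rng, n, cfg.nominal_rate_hz,
                                  cfg.timestamp_jitter_sd_s)
        keep = _dropout_keep_mask(rng, n, cfg.dropout_fraction,
                                  cfg.dropout_mean_run)
        streams.append(TimestampedStream(ts[keep], vals[keep], BLENDSHAPE_NAMES))
    return streams[0], streams[1]


def _aux_streams(
    cfg: SynthConfig, rng: np.random.Generator
) -> tuple[TimestampedStream, TimestampedStream]:
    """Head-pose (degrees) and gaze (normalized screen) streams."""
    n = int(round(cfg.duration_s * cfg.nominal_rate_hz))
    rate = cfg.nominal_rate_hz
    head = cfg.head_pose_sd_deg * _smooth_noise_nd(
        rng, (n, len(HEAD_POSE_CHANNELS)), rate, cfg.drive_bandwidth_hz
    )
    gaze = np.clip(
        0.5 + cfg.gaze_sd * _smooth_noise_nd(
            rng, (n, len(GAZE_CHANNELS)), rate, cfg.drive_bandwidth_hz
        ), 0, 1,
    )
    ts_h = _jittered_timestamps(rng, n, rate, cfg.timestamp_jitter_sd_s)
    keep_h = _dropout_keep_mask(rng, n, cfg.dropout_fraction, cfg.dropout_mean_run)
    ts_g = _jittered_timestamps(rng, n, rate, cfg.timestamp_jitter_sd_s)
    keep_g = _dropout_keep_mask(rng, n, cfg.dropout_fraction, cfg.dropout_mean_run)
    return (
        TimestampedStream(ts_h[keep_h], head[keep_h], HEAD_POSE_CHANNELS),
        TimestampedStream(ts_g[keep_g], gaze[keep_g], GAZE_CHANNELS),
    )


def generate_session(
    cfg: SynthConfig,
    seed,
    dyad_id: str = "dyad_000",
    condition: Condition = Condition(True, True),
    gender: str = "F",
    task_order: str = "AB",
    latent_attraction: float = 0.0,
) -> DyadSession:
    """One full dyad session.

    Body coupling applies only when the partners could see each other's body
    (``condition.body_visible``); facial mimicry only when faces were
    visible. ``latent_attraction`` (z-scored across a cohort) scales movement
    amplitude and facial event rate via ``attraction_effect_size``.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_drive, s_sk_a, s_sk_b, s_face, s_aux_a, s_aux_b = ss.spawn(6)
    d = cfg.attraction_effect_size
    scale = float(np.clip(1.0 + 0.25 * d * latent_attraction, 0.2, None))
    scales = (scale, scale)

    body_cfg = cfg if condition.body_visible else _with_alpha(cfg, 0.0)
    drive_a, drive_b = generate_drive_pair(body_cfg, s_drive, scales)
    skel_a = _skeleton_stream(drive_a, cfg, _rng(s_sk_a))
    skel_b = _skeleton_stream(drive_b, cfg, _rng(s_sk_b))

    face_alpha = cfg.coupling_alpha if condition.face_visible else 0.0
    rng_face = _rng(s_face)
    vals_a, vals_b = _blendshape_values_pair(cfg, rng_face, scales, face_alpha)
    faces = []
    for vals in (vals_a, vals_b):
        n = vals.shape[0]
        ts = _jittered_timestamps(rng_face, n, cfg.nominal_rate_hz,
                                  cfg.timestamp_jitter_sd_s)
        keep = _dropout_keep_mask(rng_face, n, cfg.dropout_fraction,
                                  cfg.dropout_mean_run)
        faces.append(TimestampedStream(ts[keep], vals[keep], BLENDSHAPE_NAMES))

    head_a, gaze_a = _aux_streams(cfg, _rng(s_aux_a))
    head_b, gaze_b = _aux_streams(cfg, _rng(s_aux_b))

    recs = (
        ParticipantRecording(f"{dyad_id}_p1", skel_a, faces[0], head_a, gaze_a),
        ParticipantRecording(f"{dyad_id}_p2", skel_b, faces[1], head_b, gaze_b),
    )
    return DyadSession(dyad_id, recs, condition, gender, task_order)


def _with_alpha(cfg: SynthConfig, alpha: float) -> SynthConfig:
    import dataclasses
    return dataclasses.replace(cfg, coupling_alpha=alpha)


def _likert(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values), 1, 7)


def generate_questionnaires(
    truth: GroundTruth, cfg: SynthConfig, seed
) -> list[QuestionnaireRecord]:
    """Questionnaire records consistent with the cohort's latent truth.

    Attraction items discretize ``attraction_scale_mean`` plus item noise;
    observer BFI items are the self items plus observer noise (zero observer
    noise therefore yields a profile correlation of exactly 1).
    """
    rng = _rng(seed)
    records = []
    for _, row in truth.participants.iterrows():
        items = _likert(
            row["attraction_scale_mean"]
            + rng.normal(0, cfg.attraction_item_noise_sd, 8)
        )
        traits = np.asarray([row[f"trait_{i}"] for i in range(1, 16)])
        bfi_self = _likert(traits + rng.normal(0, 0.3, 15))
        bfi_obs = _likert(bfi_self + rng.normal(0, cfg.bfi_observer_noise_sd, 15))
        missing = rng.random(15) < cfg.bfi_missing_prob
        bfi_obs = np.where(missing, np.nan, bfi_obs)
        pos = float(np.clip(
            5.5 + cfg.valence_attraction_slope * row["latent_attraction"]
            + rng.normal(0, 2.0), 0, 60,
        ))
        neg = float(np.clip(rng.normal(1.9, 1.0), 0, 100 - pos))
        records.append(
            QuestionnaireRecord(
                participant_id=row["participant_id"],
                attraction_items=items,
                bfi_self=bfi_self,
                bfi_observer=bfi_obs,
                pos_pct=pos,
                neg_pct=neg,
                gender=row["gender"],
            )
        )
    return records


_CONDITIONS = (
    Condition(True, True),
    Condition(True, False),
    Condition(False, True),
    Condition(False, False),
)


def generate_cohort(
    n_dyads: int, cfg: SynthConfig, seed
) -> tuple[list[DyadSession], list[QuestionnaireRecord], GroundTruth]:
    """A balanced cohort of dyads with ground truth.

    Condition assignment cycles through the four cells of the 2x2 design;
    gender alternates within each cell (equal male/female dyads per cell
    when ``n_dyads`` divides evenly). The binary attraction class is the
    deterministic median split of the latent attraction scores.
    """
    ss = np.random.SeedSequence(seed)
    s_latent, s_quest, *dyad_seeds = ss.spawn(2 + n_dyads)
    rng = _rng(s_latent)

    latents = rng.standard_normal(n_dyads)
    median = np.median(latents)
    dyad_rows = []
    part_rows = []
    sessions = []
    cell_counts = [0, 0, 0, 0]
    for i in range(n_dyads):
        cond = _CONDITIONS[i % 4]
        gender = "F" if cell_counts[i % 4] % 2 == 0 else "M"
        cell_counts[i % 4] += 1
        dyad_id = f"dyad_{i:03d}"
        task_order = "AB" if i % 2 == 0 else "BA"
        session = generate_session(
            cfg, dyad_seeds[i], dyad_id, cond, gender, task_order,
            latent_attraction=float(latents[i]),
        )
        sessions.append(session)
        cls = "high" if latents[i] > median else "low"
        dyad_rows.append({
            "dyad_id": dyad_id,
            "coupling_alpha": cfg.coupling_alpha,
            "coupling_lag_s": cfg.coupling_lag_s,
            "latent_attraction": float(latents[i]),
            "attraction_class": cls,
            "condition": cond.name,
            "gender": gender,
        })
        for rec in session.participants:
            traits = np.clip(rng.normal(4.5, 1.0, 15), 1.5, 6.5)
            row = {
                "participant_id": rec.participant_id,
                "dyad_id": dyad_id,
                "latent_attraction": float(latents[i]),
                "attraction_class": cls,
                "attraction_scale_mean":
                    4.5 + cfg.attraction_item_slope * float(latents[i]),
                "gender": gender,
            }
            row.update({f"trait_{k + 1}": traits[k] for k in range(15)})
            part_rows.append(row)

    truth = GroundTruth(pd.DataFrame(dyad_rows), pd.DataFrame(part_rows))
    questionnaires = generate_questionnaires(truth, cfg, s_quest)
    return sessions, questionnaires, truth
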