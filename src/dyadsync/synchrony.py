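"""Windowed lagged cross-correlation of paired movement series.

Interactional synchrony is quantified by cross-correlating the two partners'
movement time series within consecutive 100-s windows, stepwise shifting one
series against the other over a symmetric lag grid (0.1-s steps, up to +-5 s
for bodily movement and +-1 s for facial movement). Each (window, lag) cell
is the Pearson correlation over the jointly valid, overlapping samples; the
shift stays inside the window, so overlap shrinks as |lag| grows, and cells
with too few overlapping samples are missing rather than noisy.

Sign convention: positive lag means the second series trails the first —
r[w, tau] correlates x(t) with y(t + tau).
"""

from __future__ import annotations

import logging

import numpy as np

from .config import PipelineConfig
from .core import (
    DataError,
    DyadSession,
    SynchronySummary,
    UniformSeries,
    WindowedCrossCorrelation,
    WindowPlan,
)
from .kinematics import frame_displacement, joint_angles, merge_mirrored_channels
from .preprocessing import (
    butterworth_zero_phase,
    combine_plans,
    downsample,
    interpolate_uniform,
    plan_windows,
)

log = logging.getLogger(__name__)


def lag_grid(max_lag_s: float, lag_step_s: float) -> np.ndarray:
    """Symmetric lag grid in seconds: -max_lag .. +max_lag in lag_step steps."""
    n = int(round(max_lag_s / lag_step_s))
    return np.arange(-n, n + 1) * lag_step_s


def _lag_samples(lags_s: np.ndarray, rate_hz: float) -> np.ndarray:
    steps = lags_s * rate_hz
    rounded = np.rint(steps).astype(int)
    if np.max(np.abs(steps - rounded)) > 1e-6:
        raise DataError(
            f"lag step must align with the sample grid at {rate_hz} Hz"
        )
    return rounded


def crosscorr_matrix(
    x: np.ndarray,
    y: np.ndarray,
    valid_x: np.ndarray,
    valid_y: np.ndarray,
    bounds: np.ndarray,
    window_ids: np.ndarray,
    lag_samples: np.ndarray,
    n_min: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Core correlation loop, vectorized over channels.

    x, y: (n, C) aligned value matrices; returns r of shape
    (windows, lags, C) with NaN for missing cells, and overlap counts.
    """
    n, n_ch = x.shape
    r = np.full((len(window_ids), len(lag_samples), n_ch), np.nan)
    n_ov = np.zeros((len(window_ids), len(lag_samples)), dtype=int)
    for wi, w in enumerate(window_ids):
        s0, s1 = int(bounds[w, 0]), int(bounds[w, 1])
        s1 = min(s1, n)
        for li, k in enumerate(lag_samples):
            t0 = max(s0, s0 - k)
            t1 = min(s1, s1 - k)
            if t1 - t0 < 2:
                continue
            m = valid_x[t0:t1] & valid_y[t0 + k:t1 + k]
            cnt = int(m.sum())
            n_ov[wi, li] = cnt
            if cnt < max(n_min, 2):
                continue
            a = x[t0:t1][m]
            b = y[t0 + k:t1 + k][m]
            a = a - a.mean(axis=0)
            b = b - b.mean(axis=0)
            denom = np.sqrt(np.einsum("ij,ij->j", a, a)
                            * np.einsum("ij,ij->j", b, b))
            with np.errstate(invalid="ignore", divide="ignore"):
                rr = np.einsum("ij,ij->j", a, b) / denom
            rr[denom == 0] = np.nan
            r[wi, li] = rr
    return r, n_ov


def windowed_crosscorr(
    x: UniformSeries,
    y: UniformSeries,
    plan: WindowPlan,
    max_lag_s: float,
    lag_step_s: float = 0.1,
    n_min: int = 50,
) -> WindowedCrossCorrelation:
    """Windows x lags correlation matrix for a pair of scalar series."""
    if abs(x.rate_hz - y.rate_hz) > 1e-9:
        raise DataError(f"rate mismatch: {x.rate_hz} vs {y.rate_hz} Hz")
    if x.values.shape[1] != 1 or y.values.shape[1] != 1:
        raise DataError("windowed_crosscorr expects scalar (1-channel) series")
    lags = lag_grid(max_lag_s, lag_step_s)
    kept = plan.kept_indices
    if len(kept) == 0:
        log.warning("no kept windows; empty cross-correlation result")
        return WindowedCrossCorrelation(
            lags, np.empty((0, len(lags))), np.empty((0, len(lags)), int), kept
        )
    n = min(x.n_frames, y.n_frames)
    r, n_ov = crosscorr_matrix(
        x.values[:n], y.values[:n], x.valid[:n], y.valid[:n],
        plan.bounds, kept, _lag_samples(lags, x.rate_hz), n_min,
    )
    return WindowedCrossCorrelation(lags, r[:, :, 0], n_ov, kept)


def summarize_synchrony(wcc: WindowedCrossCorrelation) -> SynchronySummary:
    """The five synchrony summaries over all non-missing (window, lag) cells.

    abs_max is the signed value of the cell with the largest magnitude;
    nonneg_mean averages only the cells with r >= 0 (missing if none).
    """
    r = np.asarray(wcc.r, dtype=float)
    finite = np.isfinite(r)
    if r.size == 0 or not finite.any():
        return SynchronySummary.missing()
    cells = r[finite]
    nonneg = cells[cells >= 0]
    peak = cells[np.argmax(np.abs(cells))]
    profile = np.full(r.shape[1], np.nan)
    counts = finite.sum(axis=0)
    has = counts > 0
    profile[has] = np.nansum(np.where(finite, r, 0.0), axis=0)[has] / counts[has]
    return SynchronySummary(
        mean_r=float(cells.mean()),
        abs_mean_r=float(np.abs(cells).mean()),
        nonneg_mean_r=float(nonneg.mean()) if nonneg.size else np.nan,
        max_r=float(cells.max()),
        abs_max_r=float(peak),
        lags_s=wcc.lags_s,
        profile=profile,
        n_windows=r.shape[0],
    )


def synchrony_lag_profile(wcc: WindowedCrossCorrelation) -> np.ndarray:
    """Per-lag mean correlation over windows (the lag-decay diagnostic)."""
    return summarize_synchrony(wcc).profile


# ---------------------------------------------------------------------------
# Session-level preparation shared by synchrony scoring and the feature table


class PreparedParticipant:
    """All uniform series derived from one participant's raw streams."""

    def __init__(self, rec, cfg: PipelineConfig, duration_s: float | None = None):
        self.participant_id = rec.participant_id
        rate = cfg.resample_rate_hz
        self.skel30 = interpolate_uniform(
            rec.skeleton, rate, cfg.max_gap_s, duration_s=duration_s
        )
        self.skel30 = butterworth_zero_phase(
            self.skel30, cfg.filter_cutoff_hz, cfg.filter_order
        )
        self.face30 = interpolate_uniform(
            rec.blendshapes, rate, cfg.max_gap_s, duration_s=duration_s
        )
        if cfg.filter_faces:
            self.face30 = butterworth_zero_phase(
                self.face30, cfg.filter_cutoff_hz, cfg.filter_order
            )
        self.head30 = interpolate_uniform(
            rec.head_pose, rate, cfg.max_gap_s, duration_s=duration_s
        )
        self.gaze30 = interpolate_uniform(
            rec.gaze, rate, cfg.max_gap_s, duration_s=duration_s
        )
        self.extent30 = frame_displacement(self.skel30)
        self.angles30 = joint_angles(self.skel30)
        self.skel10 = downsample(self.skel30, cfg.synchrony_rate_hz)
        self.face_merged30 = merge_mirrored_channels(self.face30)
        self.extent10 = downsample(self.extent30, cfg.synchrony_rate_hz)
        self.angles10 = downsample(self.angles30, cfg.synchrony_rate_hz)
        self.face10 = downsample(self.face30, cfg.synchrony_rate_hz)
        merged10 = merge_mirrored_channels(self.face10)
        composite = merged10.values.mean(axis=1, keepdims=True)
        self.face_movement10 = UniformSeries(
            merged10.rate_hz, merged10.start, ("face_movement",),
            composite, merged10.valid.copy(),
        )


class PreparedDyad:
    """Both partners preprocessed on aligned grids, plus dyad window plans."""

    def __init__(self, session: DyadSession, cfg: PipelineConfig):
        self.session = session
        self.cfg = cfg
        dur = min(
            min(rec.skeleton.timestamps[-1], rec.blendshapes.timestamps[-1],
                rec.head_pose.timestamps[-1], rec.gaze.timestamps[-1])
            for rec in session.participants
        )
        self.participants = tuple(
            PreparedParticipant(rec, cfg, duration_s=dur)
            for rec in session.participants
        )
        a, b = self.participants
        self.body_plan = combine_plans(
            plan_windows(a.extent10, cfg.window_s, cfg.min_window_valid_fraction),
            plan_windows(b.extent10, cfg.window_s, cfg.min_window_valid_fraction),
        )
        self.face_plan = combine_plans(
            plan_windows(a.face10, cfg.window_s, cfg.min_window_valid_fraction),
            plan_windows(b.face10, cfg.window_s, cfg.min_window_valid_fraction),
        )


def _scalar(series: UniformSeries, channel: str) -> UniformSeries:
    return UniformSeries(
        series.rate_hz, series.start, (channel,),
        series.values[:, [series.channels.index(channel)]], series.valid,
    )


def body_synchrony(
    session: DyadSession, cfg: PipelineConfig | None = None,
    prepared: PreparedDyad | None = None,
) -> SynchronySummary:
    """Synchrony of the partners' composite extent-of-bodily-movement series.

    Composite extents (filtered at 6 Hz, resampled to 10 Hz) are
    cross-correlated over 100-s windows at lags up to +-5 s (101 lags).
    """
    cfg = cfg or PipelineConfig()
    prep = prepared or PreparedDyad(session, cfg)
    a, b = prep.participants
    wcc = windowed_crosscorr(
        _scalar(a.extent10, "composite"), _scalar(b.extent10, "composite"),
        prep.body_plan, cfg.body_max_lag_s, cfg.lag_step_s,
        cfg.min_overlap_samples,
    )
    return summarize_synchrony(wcc)


def face_synchrony(
    session: DyadSession, cfg: PipelineConfig | None = None,
    prepared: PreparedDyad | None = None,
) -> SynchronySummary:
    """Synchrony of the partners' composite facial-movement series (+-1 s)."""
    cfg = cfg or PipelineConfig()
    prep = prepared or PreparedDyad(session, cfg)
    a, b = prep.participants
    wcc = windowed_crosscorr(
        a.face_movement10, b.face_movement10,
        prep.face_plan, cfg.face_max_lag_s, cfg.lag_step_s,
        cfg.min_overlap_samples,
    )
    return summarize_synchrony(wcc)
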