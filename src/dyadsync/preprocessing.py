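"""Raw-stream post-processing: interpolation to a uniform grid, zero-phase
low-pass filtering, downsampling, and window planning with the 90% validity
rule.

The sequence mirrors the measurement protocol for depth-camera body tracking:
non-uniform 30 Hz frames are linearly interpolated to an exact 30 Hz grid,
body coordinates pass through a second-order zero-phase (forward-backward)
Butterworth low-pass at 6 Hz, synchrony inputs are brought to 10 Hz, and the
session is tiled into consecutive non-overlapping 100-s windows, each kept
only if at least 90% of its frames are valid.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .core import DataError, TimestampedStream, UniformSeries, WindowPlan

log = logging.getLogger(__name__)


def interpolate_uniform(
    stream: TimestampedStream,
    rate_hz: float,
    max_gap_s: float = 0.2,
    start: float = 0.0,
    duration_s: float | None = None,
) -> UniformSeries:
    """Linearly interpolate a non-uniform stream onto a uniform grid.

    Grid frames bracketed by valid source frames more than ``max_gap_s``
    apart are marked invalid instead of bridged — interpolating across a
    long dropout would fabricate motion. Frames before the first or after
    the last valid source frame are invalid (no extrapolation).
    """
    valid_idx = np.flatnonzero(stream.valid)
    if len(valid_idx) < 2:
        raise DataError("interpolation requires at least two valid frames")
    ts = stream.timestamps[valid_idx]
    vals = stream.values[valid_idx]

    if duration_s is None:
        duration_s = float(stream.timestamps[-1]) - start
    n = int(np.floor(duration_s * rate_hz)) + 1
    grid = start + np.arange(n) / rate_hz

    out = np.empty((n, vals.shape[1]))
    for c in range(vals.shape[1]):
        out[:, c] = np.interp(grid, ts, vals[:, c])

    valid = (grid >= ts[0] - 1e-12) & (grid <= ts[-1] + 1e-12)
    # A grid frame is invalid when its bracketing valid source samples are
    # further apart than max_gap_s.
    right = np.searchsorted(ts, grid, side="left")
    inside = (right > 0) & (right < len(ts))
    gaps = np.zeros(n)
    gaps[inside] = ts[right[inside]] - ts[right[inside] - 1]
    on_sample = np.zeros(n, dtype=bool)
    exact = np.clip(right, 0, len(ts) - 1)
    on_sample = np.abs(ts[exact] - grid) < 1e-9
    valid &= on_sample | (gaps <= max_gap_s + 1e-12)
    return UniformSeries(rate_hz, start, stream.channels, out, valid)


def _startup_len(order: int) -> int:
    # filtfilt's default edge padding for a second-order section of this size
    return 3 * (2 * order + 1)


def butterworth_zero_phase(
    series: UniformSeries, cutoff_hz: float, order: int = 2
) -> UniformSeries:
    """Forward-backward Butterworth low-pass applied per contiguous valid run.

    Zero-phase by construction (the backward pass cancels the forward pass's
    phase), at the cost of squaring the magnitude response: the -3 dB cutoff
    becomes a 0.5 amplitude ratio. Invalid frames are left untouched; runs
    shorter than three filter startup lengths pass through unfiltered.
    """
    nyquist = series.rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise DataError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {nyquist} Hz"
        )
    b, a = signal.butter(order, cutoff_hz / nyquist, btype="low")
    padlen = _startup_len(order)
    out = series.values.copy()
    # contiguous runs of valid frames
    v = series.valid.astype(int)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], v, [0]))))
    for s0, s1 in edges.reshape(-1, 2):
        if s1 - s0 < 3 * padlen:
            log.warning(
                "valid run of %d frames too short to filter; passed through",
                s1 - s0,
            )
            continue
        out[s0:s1] = signal.filtfilt(b, a, series.values[s0:s1], axis=0, padlen=padlen)
    return UniformSeries(series.rate_hz, series.start, series.channels,
                         out, series.valid.copy())


def downsample(series: UniformSeries, target_rate_hz: float) -> UniformSeries:
    """Resample to a lower rate by linear interpolation on the uniform grid.

    A target frame is invalid when either bracketing source frame is invalid.
    """
    if target_rate_hz > series.rate_hz:
        raise DataError("target rate exceeds source rate")
    n_out = int(np.floor((series.n_frames - 1) * target_rate_hz / series.rate_hz)) + 1
    t_out = np.arange(n_out) / target_rate_hz
    pos = t_out * series.rate_hz
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, series.n_frames - 1)
    frac = (pos - lo)[:, None]
    values = (1 - frac) * series.values[lo] + frac * series.values[hi]
    exact = np.abs(pos - lo) < 1e-9
    valid = np.where(
        exact,
        series.valid[lo],
        series.valid[lo] & series.valid[hi],
    )
    return UniformSeries(target_rate_hz, series.start, series.channels, values, valid)


def plan_windows(
    series: UniformSeries, window_s: float, min_valid_fraction: float = 0.9
) -> WindowPlan:
    """Tile the session into consecutive non-overlapping windows from t = 0.

    The trailing partial window is dropped; a window is kept iff at least
    ``min_valid_fraction`` of its frames are valid.
    """
    per_window = int(round(window_s * series.rate_hz))
    n_windows = int(series.n_frames // per_window)
    if n_windows == 0:
        log.warning(
            "series of %.1f s shorter than one %.1f-s window; zero windows",
            series.duration_s, window_s,
        )
    bounds = np.array(
        [[w * per_window, (w + 1) * per_window] for w in range(n_windows)],
        dtype=int,
    ).reshape(n_windows, 2)
    fractions = np.array(
        [series.valid[s0:s1].mean() for s0, s1 in bounds], dtype=float
    )
    keep = fractions >= min_valid_fraction
    return WindowPlan(window_s, bounds, fractions, keep)


def combine_plans(a: WindowPlan, b: WindowPlan) -> WindowPlan:
    """Dyad-level plan: a window is kept only if kept for both partners."""
    n = min(a.n_windows, b.n_windows)
    return WindowPlan(
        a.window_s,
        a.bounds[:n],
        np.minimum(a.valid_fraction[:n], b.valid_fraction[:n]),
        a.keep[:n] & b.keep[:n],
    )
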