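"""In-memory containers shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


class SchemaError(ValueError):
    """A file or record does not match its documented schema."""


class DataError(ValueError):
    """Well-formed input whose content violates an invariant."""


@dataclass
class TimestampedStream:
    """Non-uniformly sampled multichannel stream.

    timestamps are seconds from session start, strictly increasing; ``valid``
    is a per-frame flag (out-of-bound or missing samples are flagged, not
    dropped, so downstream window validity accounting sees them).
    """

    timestamps: np.ndarray            # (n,) float
    values: np.ndarray                # (n, c) float
    channels: tuple[str, ...]
    valid: np.ndarray = None          # (n,) bool

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.shape[0]:
            self.values = self.values.T
        self.channels = tuple(self.channels)
        if self.valid is None:
            self.valid = np.ones(len(self.timestamps), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != (len(self.timestamps), len(self.channels)):
            raise SchemaError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.timestamps)} frames x {len(self.channels)} channels"
            )
        if len(self.timestamps) > 1:
            diffs = np.diff(self.timestamps)
            if np.any(diffs <= 0):
                idx = int(np.argmax(diffs <= 0))
                raise DataError(f"timestamps not strictly increasing at row {idx + 1}")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class ParticipantRecording:
    """All raw tracked streams for one participant."""

    participant_id: str
    skeleton: TimestampedStream
    blendshapes: TimestampedStream
    head_pose: TimestampedStream
    gaze: TimestampedStream

    def streams(self) -> dict[str, TimestampedStream]:
        return {
            "skeleton": self.skeleton,
            "blendshapes": self.blendshapes,
            "head_pose": self.head_pose,
            "gaze": self.gaze,
        }


@dataclass(frozen=True)
class Condition:
    """Cell of the 2x2 rendering design: which channels the avatar showed."""

    body_visible: bool
    face_visible: bool

    @property
    def name(self) -> str:
        return {
            (True, True): "face_and_body",
            (True, False): "body_only",
            (False, True): "face_only",
            (False, False): "static",
        }[(self.body_visible, self.face_visible)]


@dataclass
class DyadSession:
    dyad_id: str
    participants: tuple[ParticipantRecording, ParticipantRecording]
    condition: Condition
    gender: str = "F"
    task_order: str = "AB"

    def __post_init__(self) -> None:
        if len(self.participants) != 2:
            raise DataError("a dyad session requires exactly two participants")


@dataclass
class QuestionnaireRecord:
    participant_id: str
    attraction_items: np.ndarray      # 8 ints in 1..7
    bfi_self: np.ndarray              # 15 ints in 1..7
    bfi_observer: np.ndarray          # 15 floats in 1..7, NaN = cannot judge
    pos_pct: float
    neg_pct: float
    gender: str = "F"

    def __post_init__(self) -> None:
        self.attraction_items = np.asarray(self.attraction_items, dtype=float)
        self.bfi_self = np.asarray(self.bfi_self, dtype=float)
        self.bfi_observer = np.asarray(self.bfi_observer, dtype=float)
        if self.attraction_items.shape != (8,):
            raise SchemaError("attraction scale requires exactly 8 items")
        if self.bfi_self.shape != (15,) or self.bfi_observer.shape != (15,):
            raise SchemaError("BFI-S requires exactly 15 items per rater")
        for arr, lo, hi, what in (
            (self.attraction_items, 1, 7, "attraction item"),
            (self.bfi_self, 1, 7, "self BFI item"),
        ):
            if np.any((arr < lo) | (arr > hi)):
                raise DataError(f"{what} outside scale bounds {lo}..{hi}")
        obs = self.bfi_observer[~np.isnan(self.bfi_observer)]
        if np.any((obs < 1) | (obs > 7)):
            raise DataError("observer BFI item outside scale bounds 1..7")
        if not (0 <= self.pos_pct <= 100 and 0 <= self.neg_pct <= 100):
            raise DataError("emotion-word percentages must lie in [0, 100]")
        if self.pos_pct + self.neg_pct > 100:
            raise DataError("pos_pct + neg_pct exceeds 100")


@dataclass
class UniformSeries:
    """Regularly sampled multichannel series; frame k sits at start + k/rate."""

    rate_hz: float
    start: float
    channels: tuple[str, ...]
    values: np.ndarray                # (n, c)
    valid: np.ndarray                 # (n,) bool

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.valid = np.asarray(self.valid, dtype=bool)
        self.channels = tuple(self.channels)
        if self.values.shape[0] != len(self.valid):
            raise SchemaError("valid mask length must equal frame count")
        if self.values.shape[1] != len(self.channels):
            raise SchemaError("channel-name count must match value columns")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(self.n_frames) / self.rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]

    def copy(self) -> "UniformSeries":
        return UniformSeries(
            self.rate_hz, self.start, self.channels,
            self.values.copy(), self.valid.copy(),
        )


@dataclass
class WindowPlan:
    """Consecutive non-overlapping analysis windows with the keep rule applied."""

    window_s: float
    bounds: np.ndarray                # (w, 2) start/stop sample indices
    valid_fraction: np.ndarray        # (w,)
    keep: np.ndarray                  # (w,) bool

    @property
    def n_windows(self) -> int:
        return len(self.bounds)

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep)


@dataclass
class WindowedCrossCorrelation:
    """Correlation matrix over kept windows x lag grid for one series pair."""

    lags_s: np.ndarray                # (L,) symmetric about 0
    r: np.ndarray                     # (w, L), NaN = missing cell
    n_overlap: np.ndarray             # (w, L) int
    window_ids: np.ndarray            # (w,) indices into the WindowPlan


@dataclass
class SynchronySummary:
    """The five windowed cross-correlation summaries plus the lag profile.

    All fields are NaN when no window survived the validity rule; a missing
    summary propagates as a missing feature, never as zero.
    """

    mean_r: float
    abs_mean_r: float
    nonneg_mean_r: float
    max_r: float
    abs_max_r: float
    lags_s: np.ndarray = field(default=None, repr=False)
    profile: np.ndarray = field(default=None, repr=False)
    n_windows: int = 0

    @classmethod
    def missing(cls) -> "SynchronySummary":
        return cls(np.nan, np.nan, np.nan, np.nan, np.nan, None, None, 0)

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean_r,
            "abs_mean": self.abs_mean_r,
            "nonneg_mean": self.nonneg_mean_r,
            "max": self.max_r,
            "abs_max": self.abs_max_r,
        }


def asdict_shallow(obj) -> dict:
    """dataclasses.asdict without deep-copying large arrays."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
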