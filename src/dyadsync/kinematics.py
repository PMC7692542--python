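"""Extent-of-movement metrics and joint angles.

Bodily extent is the per-frame Euclidean displacement of each tracked joint
on the uniform 30 Hz grid (meters per 1/30-s interval), averaged across the
17 upper-body joints into a composite. Facial extent is the mean blendshape
deviation from the neutral position (0), with mirrored left/right channels
merged first and near-constant channels excluded. Both are translation- and
rotation-invariant by construction (displacements and angles, not raw
coordinates).
"""

from __future__ import annotations

import logging

import numpy as np

from .core import DataError, UniformSeries
from .naming import ANGLE_DEFS, BLENDSHAPE_MIRROR_PAIRS, JOINT_NAMES

log = logging.getLogger(__name__)


def _joint_positions(skel: UniformSeries) -> np.ndarray:
    """(frames, joints, 3) view of a skeleton series in canonical order."""
    idx = [
        [skel.channels.index(f"{j}_{c}") for c in ("x", "y", "z")]
        for j in JOINT_NAMES
    ]
    return skel.values[:, np.asarray(idx)]


def frame_displacement(skel: UniformSeries) -> UniformSeries:
    """Per-joint Euclidean displacement between consecutive frames.

    Returns a series with one channel per joint plus a ``composite`` channel
    (mean across the 17 joints). The first frame is invalid (no predecessor);
    a displacement frame is valid only when both endpoint frames are valid,
    and the composite requires all 17 joints — i.e. the whole frame — valid,
    so the composite's scale never shifts with partial joint dropouts.
    """
    pos = _joint_positions(skel)
    disp = np.zeros((skel.n_frames, len(JOINT_NAMES)))
    disp[1:] = np.linalg.norm(np.diff(pos, axis=0), axis=2)
    valid = skel.valid & np.concatenate(([False], skel.valid[:-1]))
    composite = disp.mean(axis=1, keepdims=True)
    values = np.hstack([disp, composite])
    channels = tuple(JOINT_NAMES) + ("composite",)
    return UniformSeries(skel.rate_hz, skel.start, channels, values, valid)


def body_extent(extent: UniformSeries) -> tuple[float, dict[str, float]]:
    """Composite extent of bodily movement plus per-joint means.

    Per-joint mean displacement over valid frames; the composite is the mean
    of the 17 per-joint means (equal to the frame-then-joint average because
    composite frames require all joints valid).
    """
    if not np.any(extent.valid):
        raise DataError("no valid frames for extent computation")
    vals = extent.values[extent.valid]
    per_joint = {
        j: float(vals[:, extent.channels.index(j)].mean()) for j in JOINT_NAMES
    }
    composite = float(np.mean(list(per_joint.values())))
    return composite, per_joint


def merge_mirrored_channels(face: UniformSeries) -> UniformSeries:
    """Average mirrored left/right blendshape pairs into single items."""
    paired = {left: (merged, right) for merged, left, right in BLENDSHAPE_MIRROR_PAIRS}
    rights = {right for _, _, right in BLENDSHAPE_MIRROR_PAIRS}
    channels: list[str] = []
    columns: list[np.ndarray] = []
    for name in face.channels:
        if name in rights:
            continue
        if name in paired:
            merged, right = paired[name]
            channels.append(merged)
            columns.append(
                0.5 * (face.channel(name) + face.channel(right))
            )
        else:
            channels.append(name)
            columns.append(face.channel(name))
    return UniformSeries(
        face.rate_hz, face.start, tuple(channels),
        np.column_stack(columns), face.valid.copy(),
    )


def face_extent(
    face: UniformSeries, low_variance_threshold: float = 1e-4
) -> tuple[float, dict[str, float]]:
    """Composite extent of facial movement.

    Mirrored pairs are merged first; channels whose variance over valid
    frames falls below the threshold are excluded (flat channels reflect
    untracked regions, and spurious constants would dilute the composite).
    The composite is the mean over surviving channels of their per-frame
    mean deviation from neutral (0).
    """
    if not np.any(face.valid):
        raise DataError("no valid frames for face extent")
    merged = merge_mirrored_channels(face)
    vals = merged.values[merged.valid]
    variances = vals.var(axis=0)
    surviving = variances >= low_variance_threshold
    if not np.any(surviving):
        raise DataError(
            f"all facial channels fall below variance threshold "
            f"{low_variance_threshold}"
        )
    dropped = [c for c, s in zip(merged.channels, surviving) if not s]
    if dropped:
        log.info("face extent: %d low-variance channel(s) excluded", len(dropped))
    per_channel = {
        c: float(vals[:, i].mean())
        for i, c in enumerate(merged.channels)
        if surviving[i]
    }
    composite = float(np.mean(list(per_channel.values())))
    return composite, per_channel


def joint_angles(
    skel: UniformSeries,
    angle_defs: tuple[tuple[str, tuple[str, str, str]], ...] = ANGLE_DEFS,
) -> UniformSeries:
    """Angles (degrees) at each defined joint triple, per frame.

    The angle at the middle joint is the arccos of the normalized dot product
    of the two bone vectors. Frames with a zero-length bone get NaN and rely
    on the validity mask plus downstream NaN handling.
    """
    values = np.empty((skel.n_frames, len(angle_defs)))
    for i, (_, (a, b, c)) in enumerate(angle_defs):
        pa = skel.values[:, [skel.channels.index(f"{a}_{k}") for k in "xyz"]]
        pb = skel.values[:, [skel.channels.index(f"{b}_{k}") for k in "xyz"]]
        pc = skel.values[:, [skel.channels.index(f"{c}_{k}") for k in "xyz"]]
        u = pa - pb
        v = pc - pb
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
        values[:, i] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        values[nu * nv == 0, i] = np.nan
    names = tuple(name for name, _ in angle_defs)
    valid = skel.valid & ~np.isnan(values).any(axis=1)
    return UniformSeries(skel.rate_hz, skel.start, names, values, valid)
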