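"""Canonical channel naming for dyadic motion-capture streams.

Seventeen upper-body skeletal joints (depth-camera convention, lower-body
joints excluded for tracking reliability), the 52 facial blendshape channels
of the TrueDepth/ARKit face model, the merged left/right blendshape items
used for the extent-of-facial-movement composite, and the ten joint-angle
definitions used by the kinematics layer.
"""

from __future__ import annotations

#: The 17 upper-body joints, in canonical order.
JOINT_NAMES: tuple[str, ...] = (
    "SpineBase",
    "SpineMid",
    "SpineShoulder",
    "Neck",
    "Head",
    "ShoulderLeft",
    "ElbowLeft",
    "WristLeft",
    "HandLeft",
    "HandTipLeft",
    "ThumbLeft",
    "ShoulderRight",
    "ElbowRight",
    "WristRight",
    "HandRight",
    "HandTipRight",
    "ThumbRight",
)

#: Skeleton CSV channel order: "{Joint}_{x|y|z}" per joint.
SKELETON_CHANNELS: tuple[str, ...] = tuple(
    f"{j}_{c}" for j in JOINT_NAMES for c in ("x", "y", "z")
)

#: The 52 facial blendshape channels, values in [0, 1].
BLENDSHAPE_NAMES: tuple[str, ...] = (
    "eyeBlinkLeft", "eyeLookDownLeft", "eyeLookInLeft", "eyeLookOutLeft",
    "eyeLookUpLeft", "eyeSquintLeft", "eyeWideLeft",
    "eyeBlinkRight", "eyeLookDownRight", "eyeLookInRight", "eyeLookOutRight",
    "eyeLookUpRight", "eyeSquintRight", "eyeWideRight",
    "browDownLeft", "browDownRight", "browInnerUp",
    "browOuterUpLeft", "browOuterUpRight",
    "cheekPuff", "cheekSquintLeft", "cheekSquintRight",
    "noseSneerLeft", "noseSneerRight",
    "jawForward", "jawLeft", "jawRight", "jawOpen",
    "mouthClose", "mouthFunnel", "mouthPucker", "mouthLeft", "mouthRight",
    "mouthSmileLeft", "mouthSmileRight", "mouthFrownLeft", "mouthFrownRight",
    "mouthDimpleLeft", "mouthDimpleRight", "mouthStretchLeft",
    "mouthStretchRight", "mouthRollLower", "mouthRollUpper",
    "mouthShrugLower", "mouthShrugUpper", "mouthPressLeft", "mouthPressRight",
    "mouthLowerDownLeft", "mouthLowerDownRight", "mouthUpperUpLeft",
    "mouthUpperUpRight", "tongueOut",
)

# jawLeft/jawRight and mouthLeft/mouthRight encode sideways movement
# directions, not mirrored left/right versions of one expression, so they
# are never merged.
_NON_MIRROR_STEMS = frozenset({"jaw", "mouth"})


def _mirror_pairs() -> list[tuple[str, str, str]]:
    names = set(BLENDSHAPE_NAMES)
    pairs = []
    for name in BLENDSHAPE_NAMES:
        if name.endswith("Left"):
            stem = name[: -len("Left")]
            if stem in _NON_MIRROR_STEMS:
                continue
            right = stem + "Right"
            if right in names:
                pairs.append((stem, name, right))
    return pairs


#: (merged_name, left_channel, right_channel) for mirrored expressions.
BLENDSHAPE_MIRROR_PAIRS: tuple[tuple[str, str, str], ...] = tuple(_mirror_pairs())

#: Merged facial items: mirrored pairs averaged, non-mirrored kept verbatim.
MERGED_BLENDSHAPE_NAMES: tuple[str, ...] = tuple(
    name
    for name in dict.fromkeys(
        next((p[0] for p in BLENDSHAPE_MIRROR_PAIRS if n in p[1:]), n)
        for n in BLENDSHAPE_NAMES
    )
)

#: Ten joint angles as (name, (joint_a, vertex_joint, joint_b)); the angle is
#: measured at the vertex between the two bone vectors.
ANGLE_DEFS: tuple[tuple[str, tuple[str, str, str]], ...] = (
    ("ElbowLeftAngle", ("ShoulderLeft", "ElbowLeft", "WristLeft")),
    ("ElbowRightAngle", ("ShoulderRight", "ElbowRight", "WristRight")),
    ("ShoulderLeftAngle", ("SpineShoulder", "ShoulderLeft", "ElbowLeft")),
    ("ShoulderRightAngle", ("SpineShoulder", "ShoulderRight", "ElbowRight")),
    ("WristLeftAngle", ("ElbowLeft", "WristLeft", "HandLeft")),
    ("WristRightAngle", ("ElbowRight", "WristRight", "HandRight")),
    ("HandLeftAngle", ("WristLeft", "HandLeft", "HandTipLeft")),
    ("HandRightAngle", ("WristRight", "HandRight", "HandTipRight")),
    ("NeckAngle", ("Head", "Neck", "SpineShoulder")),
    ("SpineAngle", ("Neck", "SpineShoulder", "SpineMid")),
)

ANGLE_NAMES: tuple[str, ...] = tuple(name for name, _ in ANGLE_DEFS)

HEAD_POSE_CHANNELS: tuple[str, ...] = ("pitch", "yaw", "roll")
GAZE_CHANNELS: tuple[str, ...] = ("gx", "gy")

STREAM_NAMES: tuple[str, ...] = ("skeleton", "blendshapes", "head_pose", "gaze")
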