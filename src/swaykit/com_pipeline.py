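"""The CoM-path recorder pipeline: mirror, align, estimate CoM, emit a path.

The primary estimator is the three-joint centroid (left hip, right hip, mid
spine) — a deliberately simple stand-in for the total-body centre of mass
that avoids the poorly tracked distal joints.  A segmental total-body CoM
(TBCM) built from anthropometric mass fractions is provided as a comparator.

Pipeline stages, in order:

1. ``flip_ml`` — negate the mediolateral axis (the camera films the subject
   from behind, so its ML axis is mirrored relative to the plate frame);
2. ``align_to_first`` — rigid translation putting the first frame's
   three-joint centroid at the origin, so all motion is relative to the
   starting posture;
3. per-frame CoM (three-joint or segmental);
4. drop the superior-inferior axis and convert m → mm.

Skeletons are metres throughout; the emitted path is millimetres, which is
the unit of every downstream sway statistic.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .skeleton_io import (
    AP,
    CORE_JOINT_IDX,
    ML,
    JointName,
    SkeletonFrame,
    SkeletonSequence,
    TrackingState,
    validate_recording,
)

__all__ = [
    "CoMPath",
    "Segment",
    "SegmentTable",
    "DEFAULT_SEGMENT_TABLE",
    "flip_ml",
    "align_to_first",
    "com_three_joint",
    "com_tbcm",
    "com_path",
    "interpolate_gaps",
    "read_com_path",
    "write_com_path",
]

M_TO_MM = 1000.0

METHODS = ("three_joint", "tbcm", "pendulum")


@dataclass
class CoMPath:
    """A 2D (ML, AP) centre-of-mass trajectory in millimetres."""

    t: np.ndarray  # (n,) seconds
    ml_mm: np.ndarray
    ap_mm: np.ndarray
    rate_hz: float
    method: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ml_mm = np.asarray(self.ml_mm, dtype=float)
        self.ap_mm = np.asarray(self.ap_mm, dtype=float)
        if not (self.t.shape == self.ml_mm.shape == self.ap_mm.shape):
            raise ValueError("t, ml_mm, ap_mm must have equal shape")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        for arr, name in ((self.ml_mm, "ml_mm"), (self.ap_mm, "ap_mm")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of (ML, AP) samples in mm."""
        return np.column_stack([self.ml_mm, self.ap_mm])


# ---------------------------------------------------------------------------
# Segmental (TBCM) model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One body segment: its mass fraction and the joints that bound it.

    ``com_fraction`` locates the segment CoM along the proximal→distal line.
    """

    name: str
    mass_fraction: float
    proximal: JointName
    distal: JointName
    com_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.com_fraction <= 1.0:
            raise ValueError(f"com_fraction out of [0,1] for {self.name}")
        if self.mass_fraction < 0:
            raise ValueError(f"negative mass fraction for {self.name}")


@dataclass(frozen=True)
class SegmentTable:
    """A segmental body model: mass fractions must sum to one."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"segment mass fractions sum to {total}, not 1")

    def __iter__(self):
        return iter(self.segments)

    def joints(self) -> set[JointName]:
        out: set[JointName] = set()
        for s in self.segments:
            out |= {s.proximal, s.distal}
        return out


def _seg(name, mass, prox, dist, com):
    return Segment(name, mass, JointName(prox), JointName(dist), com)


#: Classic cadaver-study anthropometry (Dempster-style mass fractions and
#: proximal CoM locations), mapped onto the 25-joint camera model.  The trunk
#: is one segment spanning pelvis to shoulder girdle; hands and feet are
#: short distal segments.  Fractions sum to 1 exactly.
DEFAULT_SEGMENT_TABLE = SegmentTable((
    _seg("head_neck", 0.081, "spine_shoulder", "head", 0.500),
    _seg("trunk", 0.497, "spine_base", "spine_shoulder", 0.500),
    _seg("upper_arm_left", 0.028, "shoulder_left", "elbow_left", 0.436),
    _seg("upper_arm_right", 0.028, "shoulder_right", "elbow_right", 0.436),
    _seg("forearm_left", 0.016, "elbow_left", "wrist_left", 0.430),
    _seg("forearm_right", 0.016, "elbow_right", "wrist_right", 0.430),
    _seg("hand_left", 0.006, "wrist_left", "hand_left", 0.506),
    _seg("hand_right", 0.006, "wrist_right", "hand_right", 0.506),
    _seg("thigh_left", 0.100, "hip_left", "knee_left", 0.433),
    _seg("thigh_right", 0.100, "hip_right", "knee_right", 0.433),
    _seg("shank_left", 0.0465, "knee_left", "ankle_left", 0.433),
    _seg("shank_right", 0.0465, "knee_right", "ankle_right", 0.433),
    _seg("foot_left", 0.0145, "ankle_left", "foot_left", 0.500),
    _seg("foot_right", 0.0145, "ankle_right", "foot_right", 0.500),
))


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def flip_ml(seq: SkeletonSequence) -> SkeletonSequence:
    """Negate the mediolateral coordinate of every joint (rear-camera mirror).

    An involution: applying it twice returns the original sequence.
    """
    pos = seq.positions.copy()
    pos[:, :, ML] = -pos[:, :, ML]
    return seq.with_positions(pos)


def _frame_centroid(positions: np.ndarray) -> np.ndarray:
    """Three-joint centroid of a (25, 3) position block."""
    return positions[CORE_JOINT_IDX].mean(axis=0)


def align_to_first(seq: SkeletonSequence) -> SkeletonSequence:
    """Rigidly translate every frame by minus the frame-0 three-joint centroid.

    Makes all movement relative to the initial posture: the first frame's
    centroid maps to the origin, and intra-frame geometry is preserved
    exactly.  Idempotent.
    """
    f0 = seq.frame(0)
    for j in ("hip_left", "hip_right", "spine_mid"):
        if not f0.is_tracked(j):
            raise ValueError(f"cannot align: {j} not tracked in the first frame")
    origin = _frame_centroid(seq.positions[0])
    return seq.with_positions(seq.positions - origin)


def com_three_joint(frame: SkeletonFrame) -> np.ndarray:
    """Per-frame CoM estimate: the mean of left hip, right hip and mid spine.

    Returns a 3-vector (ML, SI, AP) in metres.  Raises if any of the three
    joints is untracked — the caller decides whether to interpolate.
    """
    for j in ("hip_left", "hip_right", "spine_mid"):
        if not frame.is_tracked(j):
            raise ValueError(f"{j} not tracked; cannot estimate CoM")
    return _frame_centroid(frame.positions)


def com_tbcm(frame: SkeletonFrame, table: SegmentTable) -> np.ndarray:
    """Segmental total-body CoM: mass-fraction-weighted mean of segment CoMs.

    Each segment CoM lies on the proximal→distal line at the tabulated
    fraction; the body CoM is the mass-weighted average over segments.
    """
    for j in table.joints():
        if not frame.is_tracked(j):
            raise ValueError(f"{j.value} not tracked; cannot compute TBCM")
    out = np.zeros(3)
    for s in table:
        p = frame.position(s.proximal)
        d = frame.position(s.distal)
        out += s.mass_fraction * (p + s.com_fraction * (d - p))
    return out


def interpolate_gaps(seq: SkeletonSequence, joints: Sequence[JointName | str]) -> SkeletonSequence:
    """Linearly interpolate short tracking dropouts of the given joints.

    Frames where a joint is ``not_tracked`` get positions interpolated in
    time from the nearest tracked neighbours (edge gaps are held constant).
    The repaired joints are marked ``inferred``.  Recordings with *long*
    dropouts should have been excluded by validation before reaching here.
    """
    pos = seq.positions.copy()
    states = seq.states.copy()
    t = seq.timestamps
    for j in joints:
        k = JointName.index(j)
        bad = states[:, k] == TrackingState.not_tracked
        if not bad.any():
            continue
        if bad.all():
            raise ValueError(f"{JointName(j).value} never tracked; cannot interpolate")
        good = ~bad
        for axis in range(3):
            pos[bad, k, axis] = np.interp(t[bad], t[good], pos[good, k, axis])
        states[bad, k] = TrackingState.inferred
    return replace(seq, positions=pos, states=states)


def com_path(
    seq: SkeletonSequence,
    method: str = "three_joint",
    table: SegmentTable | None = None,
    *,
    validate: bool = True,
    reference_duration_s: float | None = None,
) -> CoMPath:
    """Run the full recorder pipeline on a skeleton sequence.

    Mirrors the ML axis, aligns to the first frame, estimates the CoM per
    frame, then drops the SI axis and converts to millimetres.  Timestamps
    are preserved (no resampling).
    """
    if method == "three_joint":
        needed: tuple = ("hip_left", "hip_right", "spine_mid")
    elif method == "tbcm":
        table = table if table is not None else DEFAULT_SEGMENT_TABLE
        needed = tuple(table.joints())
    else:
        raise ValueError(f"method must be three_joint or tbcm, got {method!r}")

    if validate:
        verdict = validate_recording(
            seq, expected_duration_s=None, reference_duration_s=reference_duration_s
        )
        if not verdict.ok:
            raise ValueError(f"recording excluded: {verdict.reason.value} ({verdict.detail})")

    seq = interpolate_gaps(seq, needed)
    seq = align_to_first(flip_ml(seq))

    if method == "three_joint":
        com = seq.positions[:, CORE_JOINT_IDX, :].mean(axis=1)
    else:
        com = np.stack([com_tbcm(f, table) for f in seq])

    meta = {
        "subject_id": seq.subject_id,
        "condition": seq.condition,
        "repeat": seq.repeat,
        "height_cm": seq.height_cm,
    }
    return CoMPath(
        t=seq.timestamps.copy(),
        ml_mm=com[:, ML] * M_TO_MM,
        ap_mm=com[:, AP] * M_TO_MM,
        rate_hz=seq.rate_hz,
        method=method,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Path I/O (the on-disk form of the recorder's output)
# ---------------------------------------------------------------------------

def write_com_path(path: CoMPath, sink: IO | None = None) -> str:
    """CSV with header ``t,ml_mm,ap_mm``; metadata goes in a JSON sidecar."""
    lines = ["t,ml_mm,ap_mm"]
    for i in range(len(path)):
        lines.append(f"{path.t[i]:.6f},{path.ml_mm[i]:.6f},{path.ap_mm[i]:.6f}")
    text = "\n".join(lines) + "\n"
    if sink is not None:
        sink.write(text)
    return text


def path_sidecar(path: CoMPath) -> str:
    doc = {"method": path.method, "rate_hz": path.rate_hz, **path.meta}
    return json.dumps(doc) + "\n"


def read_com_path(
    source: IO | str,
    method: str = "three_joint",
    rate_hz: float | None = None,
    meta: Mapping | None = None,
) -> CoMPath:
    if isinstance(source, str):
        source = io.StringIO(source)
    df = pd.read_csv(source)
    if list(df.columns) != ["t", "ml_mm", "ap_mm"]:
        raise ValueError(f"bad CoM path header {list(df.columns)}")
    t = df["t"].to_numpy(dtype=float)
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    return CoMPath(
        t=t,
        ml_mm=df["ml_mm"].to_numpy(dtype=float),
        ap_mm=df["ap_mm"].to_numpy(dtype=float),
        rate_hz=float(rate_hz),
        method=method,
        meta=dict(meta or {}),
    )
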