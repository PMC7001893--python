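"""Data model, readers/writers and validity screening for skeleton recordings.

The skeleton container mirrors the 25-joint body model fitted by a Kinect V2
time-of-flight camera at a nominal 30 Hz.  Positions are stored in metres in
camera space with a fixed axis convention:

* axis 0 — mediolateral (ML),
* axis 1 — superior-inferior (SI),
* axis 2 — anterior-posterior (AP, the camera depth axis).

The camera never reports which way it faces; downstream stages assume the
rear-view convention (camera behind the subject) and mirror the ML axis
exactly once.  Force-plate centre-of-force traces, the comparator input, are
stored in millimetres in plate coordinates at 100 Hz.

Sequences are array-backed (one ``(n_frames, 25, 3)`` position block) so that
whole-recording operations are vectorised; :class:`SkeletonFrame` is a light
per-frame view.
"""

from __future__ import annotations

import enum
import io
import json
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JointName",
    "TrackingState",
    "ExclusionReason",
    "SkeletonFrame",
    "SkeletonSequence",
    "CoFTrace",
    "ValidationVerdict",
    "SkeletonParseError",
    "read_skeleton",
    "write_skeleton",
    "read_cof",
    "write_cof",
    "validate_recording",
]

#: Axis indices of the camera-space convention.
ML, SI, AP = 0, 1, 2

#: Joints whose centroid defines the simple CoM estimate.
CORE_JOINTS = ("hip_left", "hip_right", "spine_mid")


class JointName(str, enum.Enum):
    """The 25 joints of the Kinect V2 body model."""

    spine_base = "spine_base"
    spine_mid = "spine_mid"
    neck = "neck"
    head = "head"
    shoulder_left = "shoulder_left"
    elbow_left = "elbow_left"
    wrist_left = "wrist_left"
    hand_left = "hand_left"
    shoulder_right = "shoulder_right"
    elbow_right = "elbow_right"
    wrist_right = "wrist_right"
    hand_right = "hand_right"
    hip_left = "hip_left"
    knee_left = "knee_left"
    ankle_left = "ankle_left"
    foot_left = "foot_left"
    hip_right = "hip_right"
    knee_right = "knee_right"
    ankle_right = "ankle_right"
    foot_right = "foot_right"
    spine_shoulder = "spine_shoulder"
    hand_tip_left = "hand_tip_left"
    thumb_left = "thumb_left"
    hand_tip_right = "hand_tip_right"
    thumb_right = "thumb_right"

    @classmethod
    def index(cls, joint: "JointName | str") -> int:
        return _JOINT_INDEX[JointName(joint)]


JOINT_ORDER: tuple[JointName, ...] = tuple(JointName)
_JOINT_INDEX = {j: i for i, j in enumerate(JOINT_ORDER)}
N_JOINTS = len(JOINT_ORDER)
assert N_JOINTS == 25

CORE_JOINT_IDX = np.array([JointName.index(j) for j in CORE_JOINTS])


class TrackingState(enum.IntEnum):
    """Per-joint tracking quality reported by the camera."""

    not_tracked = 0
    inferred = 1
    tracked = 2


_STATE_NAMES = {s.name: s for s in TrackingState}


class ExclusionReason(str, enum.Enum):
    """Reason codes for excluding a recording from analysis."""

    none = "none"
    malformed_skeleton = "malformed_skeleton"
    out_of_sync = "out_of_sync"
    over_recording = "over_recording"
    harness_confusion = "harness_confusion"
    fall = "fall"
    extra_recording = "extra_recording"


@dataclass(frozen=True)
class ValidationVerdict:
    """Outcome of screening one recording: keep it or exclude with a reason."""

    status: str  # "ok" | "excluded"
    reason: ExclusionReason
    detail: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("ok", "excluded"):
            raise ValueError(f"bad status {self.status!r}")
        excluded = self.status == "excluded"
        if excluded != (self.reason is not ExclusionReason.none):
            raise ValueError("status=excluded iff reason != none")

    @property
    def ok(self) -> bool:
        return self.status == "ok"


class SkeletonParseError(ValueError):
    """Raised when a skeleton or CoF stream cannot be parsed."""


@dataclass(frozen=True)
class SkeletonFrame:
    """One timestamped skeleton: 25 joint positions (m) and tracking states."""

    timestamp: float
    positions: np.ndarray  # (25, 3) metres, axes (ML, SI, AP)
    states: np.ndarray  # (25,) TrackingState values

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        states = np.asarray(self.states, dtype=np.uint8)
        if pos.shape != (N_JOINTS, 3):
            raise ValueError(f"positions must be (25, 3), got {pos.shape}")
        if states.shape != (N_JOINTS,):
            raise ValueError(f"states must be (25,), got {states.shape}")
        if not np.isfinite(self.timestamp):
            raise ValueError("timestamp must be finite")
        live = states != TrackingState.not_tracked
        if not np.all(np.isfinite(pos[live])):
            raise ValueError("non-finite position for a tracked/inferred joint")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "states", states)

    def position(self, joint: JointName | str) -> np.ndarray:
        return self.positions[JointName.index(joint)]

    def state(self, joint: JointName | str) -> TrackingState:
        return TrackingState(int(self.states[JointName.index(joint)]))

    def is_tracked(self, joint: JointName | str) -> bool:
        return self.state(joint) is not TrackingState.not_tracked


@dataclass
class SkeletonSequence:
    """An ordered skeleton recording with subject and trial metadata.

    Invariants: at least two frames, strictly increasing finite timestamps,
    positive nominal rate.
    """

    timestamps: np.ndarray  # (n,) seconds
    positions: np.ndarray  # (n, 25, 3) metres
    states: np.ndarray  # (n, 25)
    rate_hz: float = 30.0
    height_cm: float | None = None
    mass_kg: float | None = None
    subject_id: str | None = None
    condition: str | None = None  # SOT condition "a".."f"
    repeat: int | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.states = np.asarray(self.states, dtype=np.uint8)
        n = len(self.timestamps)
        if n < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if self.positions.shape != (n, N_JOINTS, 3):
            raise ValueError(
                f"positions must be ({n}, 25, 3), got {self.positions.shape}"
            )
        if self.states.shape != (n, N_JOINTS):
            raise ValueError(f"states must be ({n}, 25)")
        if not np.all(np.isfinite(self.timestamps)):
            raise ValueError("timestamps must be finite")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.rate_hz > 0:
            raise ValueError("nominal rate must be positive")
        if self.condition is not None and self.condition not in "abcdef":
            raise ValueError(f"SOT condition must be a..f, got {self.condition!r}")
        live = self.states != TrackingState.not_tracked
        if not np.all(np.isfinite(self.positions[live])):
            raise ValueError("non-finite position for a tracked/inferred joint")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.timestamps)

    def __iter__(self) -> Iterator[SkeletonFrame]:
        return (self.frame(i) for i in range(len(self)))

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(
            timestamp=float(self.timestamps[i]),
            positions=self.positions[i],
            states=self.states[i],
        )

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @classmethod
    def from_frames(
        cls, frames: Sequence[SkeletonFrame], **meta
    ) -> "SkeletonSequence":
        if len(frames) < 2:
            raise ValueError("a sequence needs at least 2 frames")
        return cls(
            timestamps=np.array([f.timestamp for f in frames]),
            positions=np.stack([f.positions for f in frames]),
            states=np.stack([f.states for f in frames]),
            **meta,
        )

    def with_positions(self, positions: np.ndarray) -> "SkeletonSequence":
        """Copy of the sequence with positions replaced (metadata kept)."""
        return replace(self, positions=np.asarray(positions, dtype=float))

    def untracked_fraction(self, joint: JointName | str) -> float:
        col = self.states[:, JointName.index(joint)]
        return float(np.mean(col == TrackingState.not_tracked))


@dataclass
class CoFTrace:
    """Force-plate centre-of-force trace: 2D (ML, AP) samples in mm at 100 Hz.

    ``height_cm`` is the subject's stature, needed by the inverted-pendulum
    projection to centre of mass.
    """

    ml_mm: np.ndarray
    ap_mm: np.ndarray
    rate_hz: float = 100.0
    height_cm: float | None = None

    def __post_init__(self) -> None:
        self.ml_mm = np.asarray(self.ml_mm, dtype=float)
        self.ap_mm = np.asarray(self.ap_mm, dtype=float)
        if self.ml_mm.shape != self.ap_mm.shape or self.ml_mm.ndim != 1:
            raise ValueError("ml_mm and ap_mm must be 1-D and equally long")
        if not self.rate_hz > 0:
            raise ValueError("rate must be positive")
        if self.height_cm is not None and not self.height_cm > 0:
            raise ValueError("height must be positive")

    def __len__(self) -> int:
        return len(self.ml_mm)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) / self.rate_hz


# ---------------------------------------------------------------------------
# Skeleton I/O
# ---------------------------------------------------------------------------

#: Decimal places kept for positions (m) and timestamps (s) on disk.
PRECISION = 6


def _csv_columns() -> list[str]:
    cols = ["timestamp"]
    for j in JOINT_ORDER:
        cols += [f"{j.value}_x", f"{j.value}_y", f"{j.value}_z", f"{j.value}_state"]
    return cols


def _as_text(source: IO | str) -> IO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_skeleton(source: IO | str, dialect: str = "csv", **meta) -> SkeletonSequence:
    """Parse a skeleton recording from a text stream (or string).

    ``dialect`` is ``"csv"`` (wide per-joint columns, no metadata) or
    ``"json"`` (frames plus a ``meta`` block).  Keyword arguments override or
    supply sequence metadata (``rate_hz``, ``height_cm``, ...).
    """
    if dialect == "csv":
        return _read_skeleton_csv(_as_text(source), meta)
    if dialect == "json":
        return _read_skeleton_json(_as_text(source), meta)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_skeleton(seq: SkeletonSequence, sink: IO | None = None, dialect: str = "csv") -> str:
    """Serialise a sequence; returns the text (and writes to ``sink`` if given).

    Deterministic and lossless at 6 decimal places (micrometre resolution for
    positions in metres).
    """
    if dialect == "csv":
        text = _write_skeleton_csv(seq)
    elif dialect == "json":
        text = _write_skeleton_json(seq)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if sink is not None:
        sink.write(text)
    return text


def _read_skeleton_csv(stream: IO, meta: dict) -> SkeletonSequence:
    try:
        df = pd.read_csv(stream)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SkeletonParseError(f"cannot parse skeleton CSV: {exc}") from exc
    expected = _csv_columns()
    if list(df.columns) != expected:
        unknown = [c for c in df.columns if c not in expected]
        missing = [c for c in expected if c not in df.columns]
        raise SkeletonParseError(
            f"bad skeleton CSV header: unknown columns {unknown[:5]}, "
            f"missing {missing[:5]}"
        )
    n = len(df)
    positions = np.empty((n, N_JOINTS, 3))
    states = np.empty((n, N_JOINTS), dtype=np.uint8)
    ts = _numeric_column(df, "timestamp")
    for k, j in enumerate(JOINT_ORDER):
        positions[:, k, 0] = _numeric_column(df, f"{j.value}_x")
        positions[:, k, 1] = _numeric_column(df, f"{j.value}_y")
        positions[:, k, 2] = _numeric_column(df, f"{j.value}_z")
        states[:, k] = _state_column(df, f"{j.value}_state")
    return SkeletonSequence(timestamps=ts, positions=positions, states=states, **meta)


def _numeric_column(df: pd.DataFrame, name: str) -> np.ndarray:
    col = pd.to_numeric(df[name], errors="coerce")
    # NaN is a legal value only where the sequence invariant allows it
    # (not_tracked joints); a NaN produced by a non-numeric token is a parse
    # error and must name its line.
    bad = col.isna() & df[name].notna() & (df[name].astype(str).str.strip() != "")
    bad &= ~df[name].astype(str).str.lower().isin(["nan"])
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise SkeletonParseError(
            f"malformed value {df[name][bad.idxmax()]!r} in column {name}, line {line}"
        )
    return col.to_numpy(dtype=float)


def _state_column(df: pd.DataFrame, name: str) -> np.ndarray:
    vals = df[name].astype(str).str.strip()
    out = np.empty(len(vals), dtype=np.uint8)
    for i, v in enumerate(vals):
        if v not in _STATE_NAMES:
            raise SkeletonParseError(
                f"unknown tracking state {v!r} in column {name}, line {i + 2}"
            )
        out[i] = _STATE_NAMES[v]
    return out


def _fmt(x: float) -> str:
    if np.isnan(x):
        return "nan"
    return f"{x:.{PRECISION}f}"


def _write_skeleton_csv(seq: SkeletonSequence) -> str:
    lines = [",".join(_csv_columns())]
    for i in range(len(seq)):
        parts = [_fmt(seq.timestamps[i])]
        for k in range(N_JOINTS):
            x, y, z = seq.positions[i, k]
            parts += [_fmt(x), _fmt(y), _fmt(z), TrackingState(int(seq.states[i, k])).name]
        lines.append(",".join(parts))
    return "\n".join(lines) + "\n"


def _read_skeleton_json(stream: IO, meta: dict) -> SkeletonSequence:
    try:
        doc = json.load(stream)
    except json.JSONDecodeError as exc:
        raise SkeletonParseError(f"cannot parse skeleton JSON: {exc}") from exc
    if not isinstance(doc, dict) or "frames" not in doc:
        raise SkeletonParseError("skeleton JSON must be an object with 'frames'")
    m = dict(doc.get("meta", {}))
    m.update(meta)
    m = {k: v for k, v in m.items() if k in
         ("rate_hz", "height_cm", "mass_kg", "subject_id", "condition", "repeat")}
    frames = doc["frames"]
    n = len(frames)
    if n < 2:
        raise SkeletonParseError("skeleton JSON needs at least 2 frames")
    ts = np.empty(n)
    positions = np.full((n, N_JOINTS, 3), np.nan)
    states = np.zeros((n, N_JOINTS), dtype=np.uint8)
    for i, fr in enumerate(frames):
        try:
            ts[i] = float(fr["t"])
            joints = fr["joints"]
        except (KeyError, TypeError, ValueError) as exc:
            raise SkeletonParseError(f"malformed frame record {i}: {exc}") from exc
        for name, rec in joints.items():
            try:
                k = JointName.index(name)
            except (ValueError, KeyError):
                raise SkeletonParseError(f"unknown joint name {name!r} in frame {i}")
            x, y, z, state = rec
            positions[i, k] = (float(x), float(y), float(z))
            if state not in _STATE_NAMES:
                raise SkeletonParseError(
                    f"unknown tracking state {state!r} for {name} in frame {i}"
                )
            states[i, k] = _STATE_NAMES[state]
    return SkeletonSequence(timestamps=ts, positions=positions, states=states, **m)


def _write_skeleton_json(seq: SkeletonSequence) -> str:
    frames = []
    for i in range(len(seq)):
        joints = {}
        for k, j in enumerate(JOINT_ORDER):
            x, y, z = (round(float(v), PRECISION) for v in seq.positions[i, k])
            joints[j.value] = [x, y, z, TrackingState(int(seq.states[i, k])).name]
        frames.append({"t": round(float(seq.timestamps[i]), PRECISION), "joints": joints})
    doc = {
        "meta": {
            "rate_hz": seq.rate_hz,
            "height_cm": seq.height_cm,
            "mass_kg": seq.mass_kg,
            "subject_id": seq.subject_id,
            "condition": seq.condition,
            "repeat": seq.repeat,
        },
        "frames": frames,
    }
    return json.dumps(doc, indent=None, separators=(",", ":")) + "\n"


# ---------------------------------------------------------------------------
# CoF I/O
# ---------------------------------------------------------------------------

def read_cof(
    source: IO | str,
    height_cm: float | None = None,
    rate_hz: float | None = None,
) -> CoFTrace:
    """Parse a CoF CSV (columns ``t,ml_mm,ap_mm``).

    Height comes from the caller (CLI flag or metadata sidecar); the rate is
    inferred from the time column unless given.
    """
    try:
        df = pd.read_csv(_as_text(source))
    except Exception as exc:
        raise SkeletonParseError(f"cannot parse CoF CSV: {exc}") from exc
    if list(df.columns) != ["t", "ml_mm", "ap_mm"]:
        raise SkeletonParseError(
            f"bad CoF CSV header {list(df.columns)}, expected ['t','ml_mm','ap_mm']"
        )
    t = _numeric_column(df, "t")
    if rate_hz is None:
        if len(t) < 2:
            raise SkeletonParseError("cannot infer rate from fewer than 2 samples")
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    return CoFTrace(
        ml_mm=_numeric_column(df, "ml_mm"),
        ap_mm=_numeric_column(df, "ap_mm"),
        rate_hz=float(rate_hz),
        height_cm=height_cm,
    )


def write_cof(trace: CoFTrace, sink: IO | None = None) -> str:
    lines = ["t,ml_mm,ap_mm"]
    t = trace.t
    for i in range(len(trace)):
        lines.append(f"{t[i]:.{PRECISION}f},{trace.ml_mm[i]:.{PRECISION}f},{trace.ap_mm[i]:.{PRECISION}f}")
    text = "\n".join(lines) + "\n"
    if sink is not None:
        sink.write(text)
    return text


# ---------------------------------------------------------------------------
# Recording validation
# ---------------------------------------------------------------------------

def validate_recording(
    seq: SkeletonSequence,
    expected_duration_s: float | None = 20.0,
    reference_duration_s: float | None = None,
    *,
    core_untracked_fraction: float = 0.05,
    sync_tolerance_s: float = 0.5,
    over_recording_factor: float = 1.5,
    annotations: Iterable[str] = (),
) -> ValidationVerdict:
    """Screen one recording; always returns a verdict, never raises.

    Automated rules, applied in a fixed precedence order:

    1. ``out_of_sync`` — recording duration differs from the paired reference
       recording by more than ``sync_tolerance_s`` (default 0.5 s).
    2. ``malformed_skeleton`` — any core joint (both hips, mid spine) is
       ``not_tracked`` in more than ``core_untracked_fraction`` of frames
       (default 5%).
    3. ``fall`` — annotation-only (the camera cannot detect harness reliance).
    4. ``over_recording`` — duration exceeds ``over_recording_factor`` times
       the expected trial length, i.e. one trial recorded over another.
    5. ``harness_confusion`` — annotation-only.

    The verdict depends only on durations and tracking states, so it is
    invariant to a uniform shift of all timestamps.
    """
    ann = set(annotations)
    dur = seq.duration_s
    if reference_duration_s is not None and abs(dur - reference_duration_s) > sync_tolerance_s:
        return ValidationVerdict(
            "excluded", ExclusionReason.out_of_sync,
            f"duration {dur:.2f}s vs reference {reference_duration_s:.2f}s "
            f"(tolerance {sync_tolerance_s}s)",
        )
    for j in CORE_JOINTS:
        frac = seq.untracked_fraction(j)
        if frac > core_untracked_fraction:
            return ValidationVerdict(
                "excluded", ExclusionReason.malformed_skeleton,
                f"{j} not tracked in {frac:.0%} of frames "
                f"(threshold {core_untracked_fraction:.0%})",
            )
    if "fall" in ann:
        return ValidationVerdict("excluded", ExclusionReason.fall, "annotated fall")
    if expected_duration_s is not None and dur > over_recording_factor * expected_duration_s:
        return ValidationVerdict(
            "excluded", ExclusionReason.over_recording,
            f"duration {dur:.2f}s exceeds {over_recording_factor}x expected "
            f"{expected_duration_s:.2f}s",
        )
    if "harness_confusion" in ann:
        return ValidationVerdict(
            "excluded", ExclusionReason.harness_confusion, "annotated harness confusion"
        )
    if "extra_recording" in ann:
        return ValidationVerdict(
            "excluded", ExclusionReason.extra_recording, "annotated extra recording"
        )
    return ValidationVerdict("ok", ExclusionReason.none)
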