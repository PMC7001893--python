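"""Seeded simulator of paired skeleton + force-plate recordings.

No raw recordings from the comparison study are published, so the package
ships a generative stand-in: for each of the six Sensory Organisation Test
conditions it draws a ground-truth 2D CoM trajectory, then renders the two
measurement channels that the real study recorded simultaneously —

* a 25-joint skeleton stream at 30 Hz seen by a rear-facing depth camera
  (ML axis mirrored, per-joint Gaussian sensor noise), and
* a 100 Hz centre-of-force trace manufactured by inverting the rigid
  inverted-pendulum model (plus plate noise).

The sway process is a stationary mean-reverting (Ornstein-Uhlenbeck)
Gaussian process, independent in ML and AP, sampled exactly on a common
300 Hz grid and decimated to both instrument rates so the two channels see
one underlying movement.  Its stationary resultant RMS is calibrated to the
per-condition targets (quiet stance ~3 mm up to ~17 mm under support-surface
perturbation).

Between-method bias injection is *calibrated on the measured scale*: the
expected measured RMS of each channel — finite-window variance shrinkage of
the OU process plus white measurement-noise inflation, both exact in closed
form — is inverted to find the camera-channel amplitude scale that realises
a requested additive/multiplicative bias between the two methods' sway
readings.  With zero requested bias the channels agree in expectation even
though their noise levels differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import config as cfg
from .com_pipeline import CoMPath, com_path
from .forceplate_model import PendulumParams, cof_to_com, com_to_cof
from .skeleton_io import (
    JOINT_ORDER,
    JointName,
    CoFTrace,
    SkeletonSequence,
    TrackingState,
)
from .sway_metrics import sway_from_path

__all__ = [
    "SotPreset",
    "GroundTruth",
    "SubjectMeta",
    "BiasModel",
    "TrialRecording",
    "StudyResult",
    "default_presets",
    "generate_com_process",
    "synthesize_skeleton",
    "synthesize_cof",
    "generate_study",
    "expected_measured_rms",
    "calibrate_channel_scale",
    "predicted_repeat_sd",
    "window_shrinkage",
]


@dataclass(frozen=True)
class SotPreset:
    """Generator settings for one SOT condition."""

    condition: str
    target_rms_mm: float
    hip_mix: float = 0.0  # 0 = pure ankle strategy, 1 = pure hip strategy
    bandwidth_hz: float = 0.3
    duration_s: float = cfg.DEFAULT_TRIAL_DURATION_S
    joint_noise_mm: float = cfg.DEFAULT_JOINT_NOISE_MM
    cof_noise_mm: float = cfg.DEFAULT_COF_NOISE_MM
    skeleton_rate_hz: int = 30
    cof_rate_hz: int = 100
    base_rate_hz: int = 300

    def __post_init__(self) -> None:
        if not self.target_rms_mm > 0:
            raise ValueError("target RMS must be positive")
        if not 0.0 <= self.hip_mix <= 1.0:
            raise ValueError("hip_mix must lie in [0, 1]")
        if self.condition not in "abcdef":
            raise ValueError(f"condition must be a..f, got {self.condition!r}")
        if not (self.duration_s > 0 and self.bandwidth_hz > 0):
            raise ValueError("duration and bandwidth must be positive")
        if self.base_rate_hz % self.skeleton_rate_hz or self.base_rate_hz % self.cof_rate_hz:
            raise ValueError("base rate must be a common multiple of both channel rates")


def default_presets(
    duration_s: float = cfg.DEFAULT_TRIAL_DURATION_S,
    joint_noise_mm: float = cfg.DEFAULT_JOINT_NOISE_MM,
    cof_noise_mm: float = cfg.DEFAULT_COF_NOISE_MM,
) -> dict[str, SotPreset]:
    """The six study conditions at their default sway targets."""
    return {
        c: SotPreset(
            condition=c,
            target_rms_mm=cfg.SOT_TARGET_RMS_MM[c],
            hip_mix=cfg.SOT_HIP_MIX[c],
            bandwidth_hz=cfg.SOT_BANDWIDTH_HZ[c],
            duration_s=duration_s,
            joint_noise_mm=joint_noise_mm,
            cof_noise_mm=cof_noise_mm,
        )
        for c in "abcdef"
    }


@dataclass
class GroundTruth:
    """One trial's true CoM trajectory, sampled on both instrument grids."""

    condition: str
    t30: np.ndarray
    xy30_mm: np.ndarray  # (n30, 2) ML, AP
    t100: np.ndarray
    xy100_mm: np.ndarray
    target_rms_mm: float
    theta: float  # mean-reversion rate (1/s)
    axis_sd_mm: float  # stationary per-axis SD

    @property
    def true_rms_30hz_mm(self) -> float:
        """Realised (de-meaned) resultant RMS on the camera grid."""
        c = self.xy30_mm - self.xy30_mm.mean(axis=0)
        return float(np.sqrt(np.mean(c[:, 0] ** 2) + np.mean(c[:, 1] ** 2)))


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    height_cm: float
    mass_kg: float


@dataclass(frozen=True)
class BiasModel:
    """Requested between-method measurement bias per condition.

    For condition c the camera channel is calibrated so that in expectation
    ``E[pendulum sway] - E[camera sway] = additive + (1 - multiplicative) *
    E[pendulum sway]`` — i.e. camera reads ``multiplicative * pendulum -
    additive``.  Defaults to perfect agreement.
    """

    additive_mm: Mapping[str, float] = field(default_factory=dict)
    multiplicative: Mapping[str, float] = field(default_factory=dict)

    def get(self, condition: str) -> tuple[float, float]:
        return (
            float(self.additive_mm.get(condition, 0.0)),
            float(self.multiplicative.get(condition, 1.0)),
        )


# ---------------------------------------------------------------------------
# Ground-truth sway process
# ---------------------------------------------------------------------------

def generate_com_process(
    preset: SotPreset, seed, diffusion_scale: float = 1.0
) -> GroundTruth:
    """Draw one 2D Ornstein-Uhlenbeck sway path on both instrument grids.

    The process ``dX = -theta X dt + sigma dW`` per axis is sampled exactly
    (AR(1) with coefficient ``exp(-theta dt)``), started from the stationary
    distribution; the per-axis SD is ``target / sqrt(2)`` so the resultant
    RMS matches the preset target in the long-duration limit.
    ``diffusion_scale = 0`` degenerates to a motionless path.
    """
    if diffusion_scale < 0:
        raise ValueError("diffusion_scale must be non-negative")
    rng = np.random.default_rng(seed)
    base = preset.base_rate_hz
    n = round(preset.duration_s * base)
    if n < 2:
        raise ValueError("duration too short for the base grid")
    theta = 2.0 * math.pi * preset.bandwidth_hz
    phi = math.exp(-theta / base)
    s = diffusion_scale * preset.target_rms_mm / math.sqrt(2.0)

    eps = rng.standard_normal((n, 2))
    w = eps * (s * math.sqrt(1.0 - phi * phi))
    w[0] = eps[0] * s  # stationary start
    x = lfilter([1.0], [1.0, -phi], w, axis=0)

    k30 = base // preset.skeleton_rate_hz
    k100 = base // preset.cof_rate_hz
    n30 = n // k30
    n100 = n // k100
    return GroundTruth(
        condition=preset.condition,
        t30=np.arange(n30) / preset.skeleton_rate_hz,
        xy30_mm=x[::k30][:n30],
        t100=np.arange(n100) / preset.cof_rate_hz,
        xy100_mm=x[::k100][:n100],
        target_rms_mm=preset.target_rms_mm,
        theta=theta,
        axis_sd_mm=s,
    )


# ---------------------------------------------------------------------------
# Measurement channels
# ---------------------------------------------------------------------------

_TEMPLATE = np.array(
    [cfg.TEMPLATE_SKELETON_FRACTIONS[j.value] for j in JOINT_ORDER]
)  # (25, 3) fractions of stature, plate frame

# Joints carried by the trunk during a hip-strategy lean (everything above
# the pelvis except the three centroid-defining hip joints' peer spine_base).
_UPPER_JOINTS = [
    "spine_mid", "spine_shoulder", "neck", "head",
    "shoulder_left", "elbow_left", "wrist_left", "hand_left",
    "hand_tip_left", "thumb_left",
    "shoulder_right", "elbow_right", "wrist_right", "hand_right",
    "hand_tip_right", "thumb_right",
]
_UPPER_IDX = np.array([JointName.index(j) for j in _UPPER_JOINTS])

_ML, _SI, _AP = 0, 1, 2


def synthesize_skeleton(
    truth: GroundTruth,
    preset: SotPreset,
    subject: SubjectMeta,
    seed,
    channel_scale: float = 1.0,
    repeat: int | None = None,
) -> SkeletonSequence:
    """Render the camera channel for one trial.

    A template standing body scaled to the subject's stature is driven so
    that the three-joint centroid (left hip, right hip, mid spine) follows
    the ground-truth CoM exactly: a fraction ``1 - hip_mix`` of the
    displacement translates the whole body (ankle strategy) and the rest is
    carried by the trunk alone (hip strategy), with the trunk displacement
    tripled so the centroid — one third of which is the mid spine — still
    moves by the full amount.  The result is expressed in the rear camera's
    frame (ML mirrored, constant depth offset) and per-joint Gaussian noise
    is added.
    """
    if not subject.height_cm > 0:
        raise ValueError("subject height must be positive")
    rng = np.random.default_rng(seed)
    h_m = subject.height_cm / 100.0
    template = _TEMPLATE * h_m  # (25, 3) metres
    n = len(truth.t30)
    d = channel_scale * truth.xy30_mm / 1000.0  # (n, 2) metres, plate frame

    pos = np.broadcast_to(template, (n, 25, 3)).copy()
    lam = preset.hip_mix
    # whole-body (ankle) share
    pos[:, :, _ML] += (1.0 - lam) * d[:, None, 0]
    pos[:, :, _AP] += (1.0 - lam) * d[:, None, 1]
    # trunk (hip) share: x3 because only spine_mid of the three centroid
    # joints rides with the trunk
    pos[:, _UPPER_IDX, _ML] += 3.0 * lam * d[:, None, 0]
    pos[:, _UPPER_IDX, _AP] += 3.0 * lam * d[:, None, 1]

    # plate frame -> rear-camera frame
    pos[:, :, _ML] = -pos[:, :, _ML]
    pos[:, :, _AP] += cfg.CAMERA_DISTANCE_M

    if preset.joint_noise_mm > 0:
        pos += rng.normal(0.0, preset.joint_noise_mm / 1000.0, size=pos.shape)

    return SkeletonSequence(
        timestamps=truth.t30.copy(),
        positions=pos,
        states=np.full((n, 25), TrackingState.tracked, dtype=np.uint8),
        rate_hz=float(preset.skeleton_rate_hz),
        height_cm=subject.height_cm,
        mass_kg=subject.mass_kg,
        subject_id=subject.subject_id,
        condition=preset.condition,
        repeat=repeat,
    )


def synthesize_cof(
    truth: GroundTruth,
    preset: SotPreset,
    subject: SubjectMeta,
    seed,
    params: PendulumParams = PendulumParams(),
) -> CoFTrace:
    """Render the force-plate channel: invert the pendulum model, add noise.

    The static anterior-lean offset is included, so the trace looks like a
    real plate recording (CoF displaced anteriorly at rest).
    """
    rng = np.random.default_rng(seed)
    path = CoMPath(
        t=truth.t100,
        ml_mm=truth.xy100_mm[:, 0],
        ap_mm=truth.xy100_mm[:, 1],
        rate_hz=float(preset.cof_rate_hz),
        method="pendulum",
        meta={"height_cm": subject.height_cm},
    )
    trace = com_to_cof(path, subject.height_cm, params)
    if preset.cof_noise_mm > 0:
        trace.ml_mm = trace.ml_mm + rng.normal(0.0, preset.cof_noise_mm, len(trace))
        trace.ap_mm = trace.ap_mm + rng.normal(0.0, preset.cof_noise_mm, len(trace))
    return trace


# ---------------------------------------------------------------------------
# Closed-form measurement model (used for bias calibration and tests)
# ---------------------------------------------------------------------------

def window_shrinkage(n: int, phi: float) -> float:
    """Expected shrinkage of the de-meaned sample variance of an AR(1) path.

    For a stationary AR(1) with lag-one coefficient ``phi`` observed at
    ``n`` points, ``E[(1/n) sum (x_i - xbar)^2] = kappa * var(x)`` with
    ``kappa = 1 - [n + 2 sum_{k=1..n-1} (n-k) phi^k] / n^2``.  Approaches 1
    for windows much longer than the correlation time.
    """
    k = np.arange(1, n)
    return float(1.0 - (n + 2.0 * np.sum((n - k) * phi**k)) / n**2)


def _channel_constants(preset: SotPreset, channel: str) -> tuple[int, float, float]:
    """(n samples, kappa, per-axis noise variance mm^2) for a channel."""
    theta = 2.0 * math.pi * preset.bandwidth_hz
    if channel == "camera":
        rate = preset.skeleton_rate_hz
        # centroid of three joints, each with iid per-axis noise
        noise_var = preset.joint_noise_mm**2 / 3.0
    elif channel == "plate":
        rate = preset.cof_rate_hz
        noise_var = preset.cof_noise_mm**2
    else:
        raise ValueError(f"channel must be camera or plate, got {channel!r}")
    n = round(preset.duration_s * rate)
    kappa = window_shrinkage(n, math.exp(-theta / rate))
    return n, kappa, noise_var


def expected_measured_rms(
    preset: SotPreset, channel: str, channel_scale: float = 1.0
) -> float:
    """Expected measured RMS sway (mm) of a channel, noise included.

    Root of the expected de-meaned mean-square: OU variance shrunk by the
    finite window plus white measurement noise (its own de-meaning loses a
    1/n share).  The sqrt-of-expectation (Jensen) gap is below 1% at these
    window lengths and is ignored.
    """
    n, kappa, noise_var = _channel_constants(preset, channel)
    s2 = (preset.target_rms_mm**2) / 2.0  # per-axis stationary variance
    per_axis = kappa * channel_scale**2 * s2 + noise_var * (1.0 - 1.0 / n)
    return math.sqrt(2.0 * per_axis)


def calibrate_channel_scale(
    preset: SotPreset, additive_mm: float = 0.0, multiplicative: float = 1.0
) -> float:
    """Camera-channel amplitude scale realising a requested method bias.

    Solves ``E[camera sway] = multiplicative * E[plate sway] - additive``
    for the scale applied to the camera channel's driving trajectory.
    Raises if the request falls below the camera noise floor.
    """
    s_plate = expected_measured_rms(preset, "plate")
    target = multiplicative * s_plate - additive_mm
    if target <= 0:
        raise ValueError(f"requested camera sway {target:.3f} mm is not positive")
    n, kappa, noise_var = _channel_constants(preset, "camera")
    s2 = (preset.target_rms_mm**2) / 2.0
    num = target**2 / 2.0 - noise_var * (1.0 - 1.0 / n)
    if num <= 0:
        raise ValueError(
            f"requested camera sway {target:.3f} mm is below the joint-noise floor"
        )
    return math.sqrt(num / (kappa * s2))


def predicted_repeat_sd(
    preset: SotPreset, channel: str, channel_scale: float = 1.0
) -> float:
    """Within-subject SD expected from measurement noise alone (delta method).

    Applies when repeats share one ground-truth trajectory and differ only
    in sensor noise: the repeat-difference variance comes from the noise
    variance estimate and the signal-noise cross term, each O(1/n).
    """
    n, kappa, noise_var = _channel_constants(preset, channel)
    s2 = (preset.target_rms_mm**2) / 2.0
    v_axis = kappa * channel_scale**2 * s2
    s_meas2 = 2.0 * (v_axis + noise_var)
    var_x1_minus_x2 = 2.0 * (8.0 * v_axis * noise_var + 4.0 * noise_var**2) / n
    var_d = var_x1_minus_x2 / (4.0 * s_meas2)
    return math.sqrt(var_d / 2.0)


# ---------------------------------------------------------------------------
# Full factorial study
# ---------------------------------------------------------------------------

@dataclass
class TrialRecording:
    trial_id: str
    subject: SubjectMeta
    condition: str
    repeat: int
    skeleton: SkeletonSequence
    cof: CoFTrace
    truth: GroundTruth
    channel_scale: float


@dataclass
class StudyResult:
    """Long-format sway table plus per-trial ground truth.

    ``long`` columns: trial_id, subject, condition, repeat, method,
    sway_rms_mm — the input format of the agreement analysis.
    """

    long: pd.DataFrame
    truth: pd.DataFrame
    recordings: list[TrialRecording] = field(default_factory=list)


def generate_study(
    n_subjects: int,
    repeats: int = 2,
    presets: Mapping[str, SotPreset] | None = None,
    bias: BiasModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    conditions: Sequence[str] | None = None,
    share_truth_across_repeats: bool = False,
    keep_recordings: bool = False,
    pendulum: PendulumParams = PendulumParams(),
) -> StudyResult:
    """Simulate a full factorial agreement study and measure it end to end.

    Every subject performs every condition ``repeats`` times; each trial is
    recorded by both channels, pushed through its measurement pipeline
    (camera: mirror/align/three-joint CoM; plate: pendulum projection), and
    summarised as RMS sway.  Randomness is split per trial from the master
    seed, so any subset of trials is reproducible.

    ``share_truth_across_repeats`` reuses one ground-truth trajectory for a
    subject's repeats (sensor noise stays independent) — useful to isolate
    noise-driven repeatability.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    presets = dict(presets) if presets is not None else default_presets()
    conditions = list(conditions) if conditions is not None else sorted(presets)
    bias = bias or BiasModel()

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    subj_ss, trial_root = ss.spawn(2)
    subj_rng = np.random.default_rng(subj_ss)

    subjects = []
    for i in range(n_subjects):
        h = float(np.clip(
            subj_rng.normal(cfg.SUBJECT_HEIGHT_MEAN_CM, cfg.SUBJECT_HEIGHT_SD_CM),
            145.0, 205.0,
        ))
        m = float(np.clip(
            subj_rng.normal(cfg.SUBJECT_MASS_MEAN_KG, cfg.SUBJECT_MASS_SD_KG),
            40.0, 140.0,
        ))
        subjects.append(SubjectMeta(subject_id=f"S{i+1:03d}", height_cm=h, mass_kg=m))

    scales = {c: calibrate_channel_scale(presets[c], *bias.get(c)) for c in conditions}

    n_trials = n_subjects * len(conditions) * repeats
    trial_seeds = iter(trial_root.spawn(2 * n_trials))

    long_rows: list[dict] = []
    truth_rows: list[dict] = []
    recordings: list[TrialRecording] = []

    for subject in subjects:
        for c in conditions:
            preset = presets[c]
            shared_truth: GroundTruth | None = None
            for r in range(1, repeats + 1):
                truth_seed = next(trial_seeds)
                noise_seed = next(trial_seeds)
                if share_truth_across_repeats:
                    if shared_truth is None:
                        shared_truth = generate_com_process(preset, truth_seed)
                    truth = shared_truth
                else:
                    truth = generate_com_process(preset, truth_seed)
                skel_seed, cof_seed = noise_seed.spawn(2)
                skel = synthesize_skeleton(
                    truth, preset, subject, skel_seed,
                    channel_scale=scales[c], repeat=r,
                )
                cof = synthesize_cof(truth, preset, subject, cof_seed, params=pendulum)

                trial_id = f"{subject.subject_id}-{c}-r{r}"
                pp = sway_from_path(com_path(skel, "three_joint"))
                bm = sway_from_path(cof_to_com(cof, pendulum))
                for method, res in (("three_joint", pp), ("pendulum", bm)):
                    long_rows.append({
                        "trial_id": trial_id,
                        "subject": subject.subject_id,
                        "condition": c,
                        "repeat": r,
                        "method": method,
                        "sway_rms_mm": res.sway_rms_mm,
                    })
                truth_rows.append({
                    "trial_id": trial_id,
                    "subject": subject.subject_id,
                    "condition": c,
                    "repeat": r,
                    "target_rms_mm": preset.target_rms_mm,
                    "true_rms_30hz_mm": truth.true_rms_30hz_mm,
                    "channel_scale": scales[c],
                })
                if keep_recordings:
                    recordings.append(TrialRecording(
                        trial_id=trial_id, subject=subject, condition=c, repeat=r,
                        skeleton=skel, cof=cof, truth=truth,
                        channel_scale=scales[c],
                    ))

    return StudyResult(
        long=pd.DataFrame(long_rows),
        truth=pd.DataFrame(truth_rows),
        recordings=recordings,
    )
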