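"""Default parameters: anthropometry, SOT presets, validation thresholds.

Everything here is a documented, overridable constant.  The template
skeleton expresses each joint position as a fraction of stature in the
plate frame (ML, SI, AP); values follow standard anthropometric proportions
(ankle at 3.9% of stature, knee at 28.5%, hip at 53.0%, shoulder at 81.8%)
with plausible limb widths.  They control only where the synthetic joints
sit — the pipeline itself never consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .forceplate_model import PendulumParams

__all__ = [
    "TEMPLATE_SKELETON_FRACTIONS",
    "CAMERA_DISTANCE_M",
    "SOT_TARGET_RMS_MM",
    "SOT_HIP_MIX",
    "SOT_BANDWIDTH_HZ",
    "ValidationConfig",
    "RunConfig",
]

#: Rear camera distance behind the subject (m); enters only as a constant
#: depth offset that frame alignment removes.
CAMERA_DISTANCE_M = 2.5

# (ML, SI, AP) as fractions of stature, upright stance, plate frame
# (+ML = subject's left, +SI = up, +AP = anterior).
TEMPLATE_SKELETON_FRACTIONS: dict[str, tuple[float, float, float]] = {
    "spine_base": (0.000, 0.555, 0.000),
    "spine_mid": (0.000, 0.690, 0.000),
    "neck": (0.000, 0.855, 0.000),
    "head": (0.000, 0.936, 0.010),
    "shoulder_left": (0.129, 0.818, 0.000),
    "elbow_left": (0.145, 0.630, 0.000),
    "wrist_left": (0.155, 0.485, 0.010),
    "hand_left": (0.158, 0.430, 0.020),
    "shoulder_right": (-0.129, 0.818, 0.000),
    "elbow_right": (-0.145, 0.630, 0.000),
    "wrist_right": (-0.155, 0.485, 0.010),
    "hand_right": (-0.158, 0.430, 0.020),
    "hip_left": (0.048, 0.530, 0.000),
    "knee_left": (0.053, 0.285, 0.000),
    "ankle_left": (0.053, 0.039, 0.000),
    "foot_left": (0.053, 0.020, 0.100),
    "hip_right": (-0.048, 0.530, 0.000),
    "knee_right": (-0.053, 0.285, 0.000),
    "ankle_right": (-0.053, 0.039, 0.000),
    "foot_right": (-0.053, 0.020, 0.100),
    "spine_shoulder": (0.000, 0.818, 0.000),
    "hand_tip_left": (0.160, 0.400, 0.030),
    "thumb_left": (0.150, 0.440, 0.030),
    "hand_tip_right": (-0.160, 0.400, 0.030),
    "thumb_right": (-0.150, 0.440, 0.030),
}

# Per-condition sway targets (mm RMS) for the six SOT conditions, set to the
# scale of the cohort means reported for each condition (average of the two
# methods, to the nearest 0.1 mm): quiet stance ~3 mm rising to ~15-17 mm
# under support-surface perturbation.
SOT_TARGET_RMS_MM: dict[str, float] = {
    "a": 2.9, "b": 4.2, "c": 4.0, "d": 5.8, "e": 17.1, "f": 15.3,
}

# Hip-strategy mix: 0 = pure ankle pivot (whole-body translation), rising
# with task difficulty as balance recovery shifts toward hip flexion.
SOT_HIP_MIX: dict[str, float] = {
    "a": 0.0, "b": 0.1, "c": 0.1, "d": 0.3, "e": 0.5, "f": 0.5,
}

# Mean-reversion bandwidth of the sway process (Hz).  Quiet-stance sway is
# dominated by slow (<0.5 Hz) drift; perturbed support raises the tempo.
SOT_BANDWIDTH_HZ: dict[str, float] = {
    "a": 0.30, "b": 0.35, "c": 0.35, "d": 0.60, "e": 0.70, "f": 0.70,
}

#: Standard SOT trial length (s).
DEFAULT_TRIAL_DURATION_S = 20.0

#: Default per-joint camera noise SD (mm, each axis) and plate CoF noise SD.
DEFAULT_JOINT_NOISE_MM = 2.0
DEFAULT_COF_NOISE_MM = 0.5

#: Cohort anthropometry used when drawing synthetic subjects.
SUBJECT_HEIGHT_MEAN_CM = 172.0
SUBJECT_HEIGHT_SD_CM = 11.0
SUBJECT_MASS_MEAN_KG = 75.1
SUBJECT_MASS_SD_KG = 14.2


@dataclass
class ValidationConfig:
    """Thresholds of the recording screen."""

    core_untracked_fraction: float = 0.05
    sync_tolerance_s: float = 0.5
    over_recording_factor: float = 1.5
    expected_duration_s: float = DEFAULT_TRIAL_DURATION_S


@dataclass
class RunConfig:
    """Bundle of everything a CLI run needs; serialisable to YAML."""

    seed: int = 0
    dialect: str = "csv"
    method: str = "three_joint"
    average_repeats: bool = False
    extras: bool = False
    round_digits: int = 2
    pendulum: PendulumParams = field(default_factory=PendulumParams)
    validation: ValidationConfig = field(default_factory=ValidationConfig)

    def to_yaml(self) -> str:
        doc = {
            "seed": self.seed,
            "dialect": self.dialect,
            "method": self.method,
            "average_repeats": self.average_repeats,
            "extras": self.extras,
            "round_digits": self.round_digits,
            "pendulum": {
                "com_height_fraction": self.pendulum.com_height_fraction,
                "static_lean_deg": self.pendulum.static_lean_deg,
            },
            "validation": {
                "core_untracked_fraction": self.validation.core_untracked_fraction,
                "sync_tolerance_s": self.validation.sync_tolerance_s,
                "over_recording_factor": self.validation.over_recording_factor,
                "expected_duration_s": self.validation.expected_duration_s,
            },
            "sot_presets": {
                "target_rms_mm": SOT_TARGET_RMS_MM,
                "hip_mix": SOT_HIP_MIX,
                "bandwidth_hz": SOT_BANDWIDTH_HZ,
                "trial_duration_s": DEFAULT_TRIAL_DURATION_S,
                "joint_noise_mm": DEFAULT_JOINT_NOISE_MM,
                "cof_noise_mm": DEFAULT_COF_NOISE_MM,
            },
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        doc = yaml.safe_load(text) or {}
        pend = doc.get("pendulum", {})
        val = doc.get("validation", {})
        return cls(
            seed=int(doc.get("seed", 0)),
            dialect=doc.get("dialect", "csv"),
            method=doc.get("method", "three_joint"),
            average_repeats=bool(doc.get("average_repeats", False)),
            extras=bool(doc.get("extras", False)),
            round_digits=int(doc.get("round_digits", 2)),
            pendulum=PendulumParams(
                com_height_fraction=pend.get("com_height_fraction", 0.5527),
                static_lean_deg=pend.get("static_lean_deg", -2.3),
            ),
            validation=ValidationConfig(
                core_untracked_fraction=val.get("core_untracked_fraction", 0.05),
                sync_tolerance_s=val.get("sync_tolerance_s", 0.5),
                over_recording_factor=val.get("over_recording_factor", 1.5),
                expected_duration_s=val.get("expected_duration_s", DEFAULT_TRIAL_DURATION_S),
            ),
        )
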