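"""Resultant-distance series and RMS postural sway.

Sway is summarised method-agnostically from a 2D CoM path.  De-meaning both
axes first puts the mean position of the whole movement at the origin, which
removes the (uncontrollable) absolute foot placement and any constant model
offset, so paths from the camera pipeline and the force-plate pendulum model
are directly comparable:

    RD_i    = sqrt((ML_i - mean(ML))^2 + (AP_i - mean(AP))^2)
    swayRMS = sqrt( sum(RD_i^2) / N )

Note the population (1/N) normalisation: swayRMS is exactly
sqrt(popvar(ML) + popvar(AP)).  No detrending, filtering or resampling is
applied; each method is summarised at its native rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .com_pipeline import CoMPath

__all__ = ["SwayResult", "resultant_distance", "sway_rms", "sway_from_path", "extra_metrics"]


@dataclass
class SwayResult:
    """RMS sway (mm) and the resultant-distance series it came from."""

    rd_mm: np.ndarray
    sway_rms_mm: float
    n: int
    method: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rd_mm = np.asarray(self.rd_mm, dtype=float)
        if np.any(self.rd_mm < 0) or self.sway_rms_mm < 0:
            raise ValueError("resultant distances and RMS sway are non-negative")
        if self.n != len(self.rd_mm):
            raise ValueError("n must equal the series length")
        if len(self.rd_mm) and self.sway_rms_mm > self.rd_mm.max() + 1e-12:
            raise ValueError("RMS cannot exceed the maximum resultant distance")


def resultant_distance(path: CoMPath) -> np.ndarray:
    """Per-sample euclidean distance from the path's mean position (mm)."""
    if len(path) < 2:
        raise ValueError("need at least 2 samples to centre a path")
    dml = path.ml_mm - path.ml_mm.mean()
    dap = path.ap_mm - path.ap_mm.mean()
    return np.hypot(dml, dap)


def sway_rms(rd_mm: np.ndarray) -> float:
    """Root-mean-square of a resultant-distance series (population 1/N)."""
    rd_mm = np.asarray(rd_mm, dtype=float)
    if rd_mm.size == 0:
        raise ValueError("empty resultant-distance series")
    return float(np.sqrt(np.mean(rd_mm**2)))


def sway_from_path(path: CoMPath) -> SwayResult:
    """Convenience wrapper: RD series plus RMS sway for one trial/method."""
    rd = resultant_distance(path)
    return SwayResult(
        rd_mm=rd,
        sway_rms_mm=sway_rms(rd),
        n=len(rd),
        method=path.method,
        meta=dict(path.meta),
    )


def extra_metrics(path: CoMPath) -> dict:
    """Additional stabilometric descriptors (outside the core surface).

    ``path_length_mm`` — total excursion of the 2D trajectory;
    ``mean_velocity_mm_s`` — path length over duration;
    ``ellipse_area_mm2`` — 95% prediction-ellipse area from the 2D sample
    covariance (chi-square with 2 df).
    """
    xy = path.xy
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    path_length = float(steps.sum())
    duration = float(path.t[-1] - path.t[0]) if len(path) > 1 else 0.0
    cov = np.cov(xy.T, ddof=1)
    # chi2.ppf(0.95, 2) = 5.9915; area = pi * chi2 * sqrt(det(cov))
    det = max(float(np.linalg.det(cov)), 0.0)
    ellipse = float(np.pi * 5.991464547107979 * np.sqrt(det))
    return {
        "path_length_mm": path_length,
        "mean_velocity_mm_s": path_length / duration if duration > 0 else float("nan"),
        "ellipse_area_mm2": ellipse,
    }
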