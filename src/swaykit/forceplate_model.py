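"""Inverted-pendulum projection between centre of force and centre of mass.

The force-plate comparator treats the standing body as a rigid rod pivoting
at the ankle.  The CoM rides at a fixed fraction of stature (0.5527 by
default) above the pivot; the plate's centre of force (CoF), after removing
a modelled constant anterior lean of -2.3 degrees, determines the sway angle
and hence the horizontal CoM excursion:

    a' = a_AP - c * tan(lean)         (lean correction, AP axis only)
    theta = arctan(a' / c)            (sway angle; ML uses a_ML directly)
    com  = c * tan(theta)

with ``c`` the pendulum length in mm.  Because tan and arctan cancel, the
map is affine; it is written in the angle form because the sway angle is the
physically meaningful intermediate and the bound |theta| < 90 deg is where
the rigid-rod model lives.  The de-meaning step of the sway statistics makes
every constant-offset convention equivalent downstream.

``com_to_cof`` is the exact inverse and is what the synthetic generator uses
to manufacture plate traces from a known CoM trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .com_pipeline import CoMPath
from .skeleton_io import CoFTrace

__all__ = ["PendulumParams", "com_height", "cof_to_com", "com_to_cof"]

CM_TO_MM = 10.0


@dataclass(frozen=True)
class PendulumParams:
    """Parameters of the rigid-pendulum CoF→CoM projection.

    ``com_height_fraction`` — CoM height as a fraction of stature (default
    0.5527).  ``static_lean_deg`` — modelled average anterior lean of quiet
    stance, in degrees (default -2.3; negative = forward).
    """

    com_height_fraction: float = 0.5527
    static_lean_deg: float = -2.3

    def __post_init__(self) -> None:
        if not 0.0 < self.com_height_fraction < 1.0:
            raise ValueError("com_height_fraction must be in (0, 1)")
        if abs(self.static_lean_deg) >= 30.0:
            raise ValueError("|static_lean_deg| must be below 30 degrees")


def com_height(height_cm: float, params: PendulumParams = PendulumParams()) -> float:
    """Pendulum length: the modelled CoM height in cm for a given stature."""
    if not height_cm > 0:
        raise ValueError("height must be positive")
    return params.com_height_fraction * height_cm


def _pendulum_length_mm(height_cm: float | None, params: PendulumParams) -> float:
    if height_cm is None:
        raise ValueError("subject height is required for the pendulum model")
    return com_height(height_cm, params) * CM_TO_MM


def cof_to_com(trace: CoFTrace, params: PendulumParams = PendulumParams()) -> CoMPath:
    """Project a CoF trace to a CoM path under the rigid-pendulum model."""
    c = _pendulum_length_mm(trace.height_cm, params)
    lean = math.radians(params.static_lean_deg)
    ap_corrected = trace.ap_mm - c * math.tan(lean)
    theta_ap = np.arctan2(ap_corrected, c)
    theta_ml = np.arctan2(trace.ml_mm, c)
    return CoMPath(
        t=trace.t,
        ml_mm=c * np.tan(theta_ml),
        ap_mm=c * np.tan(theta_ap),
        rate_hz=trace.rate_hz,
        method="pendulum",
        meta={"height_cm": trace.height_cm},
    )


def com_to_cof(
    path: CoMPath,
    height_cm: float | None = None,
    params: PendulumParams = PendulumParams(),
) -> CoFTrace:
    """Exact inverse of :func:`cof_to_com`: manufacture the CoF that the
    pendulum model would project back onto the given CoM path."""
    height_cm = height_cm if height_cm is not None else path.meta.get("height_cm")
    c = _pendulum_length_mm(height_cm, params)
    lean = math.radians(params.static_lean_deg)
    return CoFTrace(
        ml_mm=np.asarray(path.ml_mm, dtype=float).copy(),
        ap_mm=path.ap_mm + c * math.tan(lean),
        rate_hz=path.rate_hz,
        height_cm=height_cm,
    )
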