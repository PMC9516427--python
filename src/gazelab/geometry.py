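"""Floor-intercept trigonometry for gaze expressed in the lab frame.

The point of gaze on the floor is fully determined by four quantities: the
eye height A (origin z), the eye's anterior position B (origin x), the
viewing angle a between the gaze vector and the downward vertical, and the
look-ahead distance C = A tan(a). The floor intercept along the
anterior-posterior axis is D = B + C. This module also maps world-space
error spans to the visual angle they subtend and back, for both floor-based
and wall-based (eye-height) targets.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .model import NoInterceptError, UNIT_TOL

__all__ = [
    "viewing_angle",
    "lookahead_distance",
    "floor_intercept",
    "visual_angle_of_mae",
    "floor_span_for_angle",
    "wall_span_for_angle",
    "target_separation_angle",
]


def viewing_angle(gaze: np.ndarray) -> np.ndarray | float:
    """Angle between gaze and the downward vertical (0, 0, -1), degrees.

    Accepts a single 3-vector or an (n, 3) array of unit vectors; NaN rows
    propagate to NaN. 0 deg is straight down, 90 deg horizontal.
    """
    g = np.asarray(gaze, dtype=float)
    scalar = g.ndim == 1
    g = np.atleast_2d(g)
    norms = np.linalg.norm(g, axis=1)
    finite = np.isfinite(norms)
    if np.any(np.abs(norms[finite] - 1.0) > 1e-3):
        raise ValueError("gaze vectors must be unit length")
    ang = np.degrees(np.arccos(np.clip(-g[:, 2] / np.where(finite, norms, 1.0), -1.0, 1.0)))
    ang = np.where(finite, ang, np.nan)
    return float(ang[0]) if scalar else ang


def lookahead_distance(eye_height_A: float, viewing_angle_a) -> np.ndarray | float:
    """Horizontal distance C = A tan(a) from the eye to the floor intercept."""
    a = np.asarray(viewing_angle_a, dtype=float)
    if eye_height_A <= 0:
        raise ValueError("eye height must be positive")
    with np.errstate(invalid="ignore"):
        if np.any(a[np.isfinite(a)] >= 90.0):
            raise NoInterceptError("viewing angle >= 90 deg never meets the floor")
    out = eye_height_A * np.tan(np.radians(a))
    return float(out) if np.ndim(viewing_angle_a) == 0 else out


def floor_intercept(origin: np.ndarray, gaze: np.ndarray):
    """Intersection of the ray origin + t*gaze (t > 0) with the z = 0 plane.

    Vectorized over leading axes. Rays with non-negative vertical component
    return NaN (missing intercept) rather than raising, so upward gaze and
    upstream data loss are handled uniformly.

    Returns
    -------
    (x, y) : floor coordinates, same leading shape as the inputs.
    """
    o = np.atleast_2d(np.asarray(origin, dtype=float))
    g = np.atleast_2d(np.asarray(gaze, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = -o[:, 2] / g[:, 2]
        hit = np.isfinite(t) & (g[:, 2] < 0)
        t = np.where(hit, t, np.nan)
        x = o[:, 0] + t * g[:, 0]
        y = o[:, 1] + t * g[:, 1]
    if np.ndim(origin) == 1:
        return float(x[0]), float(y[0])
    return x, y


def visual_angle_of_mae(lookahead_L: float, mae: float, eye_height_h: float) -> float:
    """Visual angle (deg) subtended by a floor span of ``mae`` centered at L.

    The span is split symmetrically about the target in world distance:
    atan((L + mae/2)/h) - atan((L - mae/2)/h).
    """
    if eye_height_h <= 0:
        raise ValueError("eye height must be positive")
    if mae < 0 or lookahead_L < 0:
        raise ValueError("look-ahead and MAE must be non-negative")
    far = np.arctan((lookahead_L + mae / 2.0) / eye_height_h)
    near = np.arctan((lookahead_L - mae / 2.0) / eye_height_h)
    return float(np.degrees(far - near))


def floor_span_for_angle(lookahead_L: float, angle: float, eye_height_h: float) -> float:
    """World-space floor span centered at L that subtends ``angle`` degrees.

    Inverse of :func:`visual_angle_of_mae`, solved by monotone root finding
    to 1e-9 m. Raises if the angle is so large the span's near edge would
    pass behind the observer (span > 2 L).
    """
    if eye_height_h <= 0:
        raise ValueError("eye height must be positive")
    if angle < 0:
        raise ValueError("angle must be non-negative")
    if angle == 0:
        return 0.0
    max_angle = np.degrees(np.arctan(2.0 * lookahead_L / eye_height_h))
    if angle >= max_angle:
        raise ValueError(
            f"angle {angle} deg needs a span reaching behind the observer "
            f"(max {max_angle:.3f} deg at L={lookahead_L} m)"
        )
    f = lambda s: visual_angle_of_mae(lookahead_L, s, eye_height_h) - angle
    return float(brentq(f, 0.0, 2.0 * lookahead_L, xtol=1e-9))


def wall_span_for_angle(distance_d: float, angle: float) -> float:
    """Span on a vertical plane at distance d subtending ``angle`` degrees,
    symmetric about an eye-height target: 2 d tan(angle/2)."""
    if distance_d <= 0:
        raise ValueError("distance must be positive")
    if not 0 <= angle < 180:
        raise ValueError("angle must be in [0, 180) degrees")
    return float(2.0 * distance_d * np.tan(np.radians(angle) / 2.0))


def target_separation_angle(x1: float, x2: float, eye_height_h: float) -> float:
    """Gaze amplitude (deg) between floor targets at x1 and x2 for an eye
    directly above the lab origin at height h."""
    if eye_height_h <= 0:
        raise ValueError("eye height must be positive")
    if x1 < 0 or x2 < 0:
        raise ValueError("target distances must be non-negative")
    return float(abs(np.degrees(np.arctan(x2 / eye_height_h) - np.arctan(x1 / eye_height_h))))
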