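"""Muscle, tendon, muscle-tendon and joint stiffness estimation.

Fiber (short-range) stiffness scales with muscle force,

    Km = gamma * Fm / lm0,        gamma = 23.4 (dimensionless),

tendon stiffness is the slope of the tendon force-length curve,
Kt = dFt/dlt, and the two act in series:

    Kmt = Km Kt / (Km + Kt).

Joint stiffness adds the geometric term from the angle-dependence of
the moment arm:

    Kj = Kmt * rmt^2 + (d rmt / d q) * Fmt.

``lm0`` in Km is ambiguous between the optimal fiber length at the
*current* activation (the activation-shifted length used elsewhere in
the model) and the plain optimal length l0; both readings are
implemented behind ``lm0_mode`` and the activation-shifted one is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .musculotendon import (
    GeometryParams,
    HillParams,
    MuscleTrajectory,
    TENDON_EPS_KNEE,
    TENDON_LIN_SLOPE,
    TENDON_QUAD,
    moment_arm_gradient,
    optimal_fiber_length,
)

__all__ = [
    "GAMMA",
    "StiffnessEstimate",
    "muscle_stiffness",
    "tendon_stiffness",
    "series_stiffness",
    "joint_stiffness",
    "stiffness_series",
]

#: Dimensionless fiber-stiffness scaling constant.
GAMMA = 23.4


@dataclass
class StiffnessEstimate:
    """Stiffness decomposition at one time instant."""

    Km: float      # fiber stiffness, N/m
    Kt: float      # tendon stiffness, N/m
    Kmt: float     # series combination, N/m
    Kj: float      # joint stiffness, N*m/rad
    drmt_dq: float  # moment-arm gradient, m/rad
    gamma: float = GAMMA


def muscle_stiffness(Fm, lm0, gamma: float = GAMMA):
    """Fiber stiffness Km = gamma * Fm / lm0."""
    lm0_arr = np.asarray(lm0, dtype=float)
    if np.any(lm0_arr <= 0):
        raise ValueError("lm0 must be positive")
    out = gamma * np.asarray(Fm, dtype=float) / lm0_arr
    return float(out) if np.ndim(out) == 0 else out


def tendon_stiffness(lt, p: HillParams):
    """Analytic slope of the tendon force-length curve.

    Zero for slack tendon; at the breakpoints (eps = 0 and the
    quadratic/linear knee) the right branch is used, keeping Kt
    right-continuous and non-decreasing.
    """
    lt_arr = np.asarray(lt, dtype=float)
    eps = (lt_arr - p.lst) / p.lst
    quad = 2.0 * TENDON_QUAD * p.Fmx * eps / p.lst
    lin = TENDON_LIN_SLOPE * p.Fmx / p.lst
    k = np.where(eps >= TENDON_EPS_KNEE, lin, quad)
    k = np.where(eps < 0.0, 0.0, k)
    return float(k) if np.ndim(lt) == 0 else k


def series_stiffness(Km, Kt):
    """Series (harmonic) combination Kmt = Km Kt / (Km + Kt)."""
    Km_arr = np.asarray(Km, dtype=float)
    Kt_arr = np.asarray(Kt, dtype=float)
    s = Km_arr + Kt_arr
    out = np.where(s > 0, Km_arr * Kt_arr / np.where(s > 0, s, 1.0), 0.0)
    return float(out) if np.ndim(out) == 0 else out


def joint_stiffness(Kmt, rmt, drmt_dq, Fmt, floor: bool = False):
    """Joint stiffness Kj = Kmt rmt^2 + (drmt/dq) Fmt.

    ``floor=True`` clamps negative values at zero (used before gain
    adaptation; a negative geometric term is possible in principle).
    """
    out = (np.asarray(Kmt, dtype=float) * np.asarray(rmt, dtype=float) ** 2
           + np.asarray(drmt_dq, dtype=float) * np.asarray(Fmt, dtype=float))
    if floor:
        out = np.maximum(out, 0.0)
    return float(out) if np.ndim(out) == 0 else out


def stiffness_series(traj: MuscleTrajectory, a_series, q_series,
                     p: HillParams, g: GeometryParams,
                     lm0_mode: str = "eq12_current_a",
                     gamma: float = GAMMA, floor: bool = True) -> dict:
    """Stiffness pipeline along a simulated muscle trajectory.

    Returns a dict of arrays ``Km, Kt, Kmt, Kj, drmt_dq`` aligned with
    the trajectory samples.  ``lm0_mode`` selects the fiber-stiffness
    length scale: the activation-shifted optimal length
    (``"eq12_current_a"``, default) or the plain optimal length
    (``"l0"``).
    """
    a = np.asarray(a_series, dtype=float)
    q = np.asarray(q_series, dtype=float)
    if lm0_mode == "eq12_current_a":
        lm0 = optimal_fiber_length(np.clip(a, 0.0, 1.0), p)
    elif lm0_mode == "l0":
        lm0 = np.full_like(a, p.l0)
    else:
        raise ValueError(f"unknown lm0_mode {lm0_mode!r}")
    Km = muscle_stiffness(traj.Fm, lm0, gamma)
    Kt = tendon_stiffness(traj.lt, p)
    Kmt = series_stiffness(Km, Kt)
    drmt = np.array([moment_arm_gradient(qi, g) for qi in q])
    Kj = joint_stiffness(Kmt, traj.rmt, drmt, traj.Fmt, floor=floor)
    return {"Km": Km, "Kt": Kt, "Kmt": Kmt, "Kj": Kj, "drmt_dq": drmt}
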