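"""Hill-type muscle–tendon model of the tibialis anterior and its joint torque.

Geometry
--------
The TA spans the ankle as a straight line from origin ``A`` (tibia) to
insertion ``B`` (foot) past the joint centre ``O``.  With the anatomical
ankle angle ``q`` (radians; neutral = pi/2, dorsiflexion decreases q),
the muscle-tendon length follows the law of cosines,

    lmt(q) = sqrt(OA^2 + OB^2 - 2 OA OB cos q),

and the moment arm is its angular derivative, rmt = OA OB sin q / lmt.

Muscle mechanics
----------------
The unit is a contractile element (CE) and a parallel passive element
(PE), in series with a nonlinear-spring tendon, at pennation angle phi
(constant-width assumption: lm sin phi = l0 sin phi0).  Force balance:

    Fmt = (Fce + Fpe) cos phi = Ft

with Fce = f(l) f(v) Fmx a, Fpe = fp(l) Fmx, and the tendon a piecewise
quadratic/linear function of strain eps = (lt - lst)/lst.  The active
force-length curve is f(l) = sin(-1.317 l^2 - 0.403 l + 2.454) (argument
in radians; the peak sits near l = 0.68), the force-velocity curve is
hyperbolic with maximum shortening at v = -1 and a lengthening asymptote
of 1.8, and the optimal fiber length shifts with activation,
lm0 = l0 (lambda (1 - a) + 1), lambda = 0.15.

Fiber dynamics invert the force balance: given (a, q) the tendon force
fixes the required f(v), whose algebraic inverse yields the normalized
fiber velocity; d lm/dt = v * vmax with vmax = 10 l0 per second.  The
resulting ODE is integrated with an adaptive Runge-Kutta scheme (the
classic choice for this stiff-ish balance), or solved quasi-statically
when the activation bandwidth (2 Hz envelope) is far below the fiber
time constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import SolverError

__all__ = [
    "GeometryParams",
    "HillParams",
    "MuscleState",
    "MuscleTrajectory",
    "TorqueEstimate",
    "geometry",
    "moment_arm_gradient",
    "pennation",
    "active_force_length",
    "force_velocity",
    "invert_force_velocity",
    "passive_force_length",
    "tendon_force",
    "tendon_strain",
    "optimal_fiber_length",
    "fiber_velocity",
    "simulate_muscle",
    "isometric_equilibrium",
    "isometric_state",
    "joint_torque",
]

# Tendon force-strain curve constants (dimensionless, scaled by Fmx).
TENDON_QUAD = 1480.3
TENDON_LIN_SLOPE = 37.5
TENDON_LIN_OFFSET = 0.2375
TENDON_EPS_KNEE = 0.0127


@dataclass
class GeometryParams:
    """Straight-line muscle path geometry (metres)."""

    OA: float  # origin-to-joint-centre distance
    OB: float  # insertion-to-joint-centre distance

    def __post_init__(self) -> None:
        if self.OA <= 0 or self.OB <= 0:
            raise ValueError("OA and OB must be positive")


@dataclass
class HillParams:
    """Subject constants of the Hill-type muscle-tendon unit.

    ``vmax`` defaults to 10 * l0 per second.  ``a_min`` and ``fl_min``
    are numerical floors applied only inside the force-velocity
    inversion to keep it well conditioned near rest; reported forces and
    activations are not floored.  ``fv_cap`` caps the required f(v)
    just below its lengthening asymptote (1.8).
    """

    Fmx: float
    lst: float
    l0: float
    phi0: float
    lam: float = 0.15
    vmax: float | None = None
    a_min: float = 0.01
    fl_min: float = 1e-3
    fv_cap: float = 1.78

    def __post_init__(self) -> None:
        if min(self.Fmx, self.lst, self.l0) <= 0:
            raise ValueError("Fmx, lst and l0 must be positive")
        if not (0.0 <= self.phi0 < math.pi / 2):
            raise ValueError("phi0 must lie in [0, pi/2)")
        if self.vmax is None:
            self.vmax = 10.0 * self.l0

    @property
    def width(self) -> float:
        """Constant muscle width l0 * sin(phi0)."""
        return self.l0 * math.sin(self.phi0)


@dataclass
class MuscleState:
    """Muscle-tendon state at one instant."""

    lm: float
    lt: float
    phi: float
    v: float
    l: float
    Fce: float
    Fpe: float
    Fm: float
    Ft: float
    Fmt: float


@dataclass
class MuscleTrajectory:
    """Time series of the simulated muscle-tendon state."""

    t: np.ndarray
    lm: np.ndarray
    lt: np.ndarray
    phi: np.ndarray
    v: np.ndarray
    l: np.ndarray
    Fce: np.ndarray
    Fpe: np.ndarray
    Fm: np.ndarray
    Ft: np.ndarray
    Fmt: np.ndarray
    rmt: np.ndarray
    Mp: np.ndarray

    def state(self, i: int) -> MuscleState:
        return MuscleState(
            lm=self.lm[i], lt=self.lt[i], phi=self.phi[i], v=self.v[i],
            l=self.l[i], Fce=self.Fce[i], Fpe=self.Fpe[i], Fm=self.Fm[i],
            Ft=self.Ft[i], Fmt=self.Fmt[i],
        )


@dataclass
class TorqueEstimate:
    """Joint torque Mp = rmt * Fmt with its geometric context."""

    Mp: float
    rmt: float
    lmt: float
    q: float


def geometry(q: float, g: GeometryParams) -> tuple[float, float]:
    """Muscle-tendon length and moment arm at joint angle ``q`` (rad)."""
    if not (0.0 < q < math.pi):
        raise ValueError(f"q={q} outside (0, pi)")
    lmt2 = g.OA**2 + g.OB**2 - 2.0 * g.OA * g.OB * math.cos(q)
    if lmt2 <= 0:
        raise ValueError("degenerate geometry: lmt = 0")
    lmt = math.sqrt(lmt2)
    rmt = g.OA * g.OB * math.sin(q) / lmt
    return lmt, rmt


def moment_arm_gradient(q: float, g: GeometryParams) -> float:
    """Analytic d(rmt)/dq of the straight-line geometry."""
    lmt, rmt = geometry(q, g)
    return g.OA * g.OB * (math.cos(q) * lmt - math.sin(q) * rmt) / lmt**2


def pennation(lm: float, p: HillParams) -> float:
    """Pennation angle from the constant-width assumption."""
    w = p.width
    if lm < w:
        raise ValueError(
            f"lm={lm} shorter than the constant muscle width {w}"
        )
    return math.asin(w / lm) if w > 0 else 0.0


def active_force_length(l):
    """Active force-length curve, clamped at zero outside its lobe."""
    l_arr = np.asarray(l, dtype=float)
    if np.any(l_arr <= 0):
        raise ValueError("normalized fiber length must be positive")
    f = np.sin(-1.317 * l_arr**2 - 0.403 * l_arr + 2.454)
    f = np.maximum(f, 0.0)
    return float(f) if np.ndim(l) == 0 else f


def force_velocity(v):
    """Hyperbolic force-velocity curve; v < 0 shortening, f(0) = 1."""
    v_arr = np.asarray(v, dtype=float)
    lower = 0.3 * (v_arr + 1.0) / (-v_arr + 0.3)
    upper = (2.34 * v_arr + 0.039) / (1.3 * v_arr + 0.039)
    f = np.where(v_arr < 0, lower, upper)
    f = np.where(v_arr <= -1.0, 0.0, f)
    f = np.where(v_arr == 0.0, 1.0, f)
    return float(f) if np.ndim(v) == 0 else f


def invert_force_velocity(f_v: float, v_cap: float | None = None) -> float:
    """Exact algebraic inverse of the force-velocity curve.

    For f_v at or beyond the lengthening asymptote region (>= fv_cap of
    the default Hill parameters, 1.78) the result is clamped to the
    velocity at the cap, with a warning: the asymptote (1.8) is
    unreachable.
    """
    cap = 1.78
    if f_v >= cap:
        v_at_cap = 0.039 * (cap - 1.0) / (2.34 - 1.3 * cap)
        warnings.warn(
            f"f_v={f_v} at/beyond the lengthening asymptote; "
            f"clamping to v={v_at_cap:.4f}",
            RuntimeWarning,
            stacklevel=2,
        )
        return v_cap if v_cap is not None else v_at_cap
    if f_v <= 0.0:
        return -1.0
    if f_v < 1.0:
        return 0.3 * (f_v - 1.0) / (f_v + 0.3)
    if f_v == 1.0:
        return 0.0
    return 0.039 * (f_v - 1.0) / (2.34 - 1.3 * f_v)


def passive_force_length(l):
    """Passive (parallel-elastic) force-length curve, zero below l = 1."""
    l_arr = np.asarray(l, dtype=float)
    f = 0.129 * (np.exp(4.525 * (l_arr - 1.0)) - 1.0)
    f = np.maximum(f, 0.0)
    return float(f) if np.ndim(l) == 0 else f


def tendon_strain(lt: float, p: HillParams) -> float:
    return (lt - p.lst) / p.lst


def tendon_force(lt, p: HillParams):
    """Piecewise quadratic/linear tendon force (newtons)."""
    lt_arr = np.asarray(lt, dtype=float)
    eps = (lt_arr - p.lst) / p.lst
    quad = TENDON_QUAD * p.Fmx * eps**2
    lin = (TENDON_LIN_SLOPE * eps - TENDON_LIN_OFFSET) * p.Fmx
    f = np.where(eps < TENDON_EPS_KNEE, quad, lin)
    f = np.where(eps <= 0.0, 0.0, f)
    return float(f) if np.ndim(lt) == 0 else f


def optimal_fiber_length(a, p: HillParams):
    """Activation-dependent optimal fiber length lm0 = l0 (lam (1-a) + 1)."""
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < -1e-12) or np.any(a_arr > 1.0 + 1e-12):
        raise ValueError("activation outside [0, 1]")
    out = p.l0 * (p.lam * (1.0 - a_arr) + 1.0)
    return float(out) if np.ndim(a) == 0 else out


def _fiber_rhs(lm: float, a: float, lmt: float, p: HillParams) -> tuple:
    """Scalar core: fiber velocity from the force balance.

    Returns (dlm_dt, state tuple).  Used by both the ODE integrator and
    the closed-loop simulator's fixed-step integrator.
    """
    w = p.width
    if lm <= w:
        lm = w * (1.0 + 1e-9) if w > 0 else 1e-9
    ratio = w / lm if lm > 0 else 0.0
    cosphi = math.sqrt(max(1.0 - ratio * ratio, 1e-12))
    lt = lmt - lm * cosphi
    eps = (lt - p.lst) / p.lst
    if eps <= 0.0:
        Ft = 0.0
    elif eps < TENDON_EPS_KNEE:
        Ft = TENDON_QUAD * p.Fmx * eps * eps
    else:
        Ft = (TENDON_LIN_SLOPE * eps - TENDON_LIN_OFFSET) * p.Fmx
    lm0 = p.l0 * (p.lam * (1.0 - a) + 1.0)
    l = lm / lm0
    fl = math.sin(-1.317 * l * l - 0.403 * l + 2.454)
    if fl < p.fl_min:
        fl = p.fl_min
    fpe = 0.129 * (math.exp(4.525 * (l - 1.0)) - 1.0)
    if fpe < 0.0:
        fpe = 0.0
    Fpe = fpe * p.Fmx
    a_eff = a if a > p.a_min else p.a_min
    denom = fl * p.Fmx * a_eff
    fv = (Ft / cosphi - Fpe) / denom
    if fv < 0.0:
        fv = 0.0
    elif fv > p.fv_cap:
        fv = p.fv_cap
    if fv < 1.0:
        v = 0.3 * (fv - 1.0) / (fv + 0.3)
    elif fv == 1.0:
        v = 0.0
    else:
        v = 0.039 * (fv - 1.0) / (2.34 - 1.3 * fv)
    return v * p.vmax, (lt, cosphi, l, Ft, Fpe, fv, v)


def tendon_stiffness_scalar(lt: float, p: HillParams) -> float:
    """Scalar dFt/dlt for the real-time loop (right-continuous at the
    breakpoints, matching the vectorized version in the stiffness module)."""
    eps = (lt - p.lst) / p.lst
    if eps < 0.0:
        return 0.0
    if eps >= TENDON_EPS_KNEE:
        return TENDON_LIN_SLOPE * p.Fmx / p.lst
    return 2.0 * TENDON_QUAD * p.Fmx * eps / p.lst


def fiber_velocity(lm: float, a: float, lmt: float, p: HillParams) -> float:
    """Normalized fiber velocity solving the force balance (see _fiber_rhs)."""
    dlmdt, aux = _fiber_rhs(lm, a, lmt, p)
    return dlmdt / p.vmax


def _equilibrium_residual(lm: float, a: float, lmt: float, p: HillParams) -> float:
    """Ft - (Fce(v=0) + Fpe) cos(phi), the isometric force imbalance."""
    w = p.width
    ratio = w / lm
    cosphi = math.sqrt(max(1.0 - ratio * ratio, 1e-12))
    lt = lmt - lm * cosphi
    Ft = tendon_force(lt, p)
    lm0 = p.l0 * (p.lam * (1.0 - a) + 1.0)
    l = lm / lm0
    fl = max(math.sin(-1.317 * l * l - 0.403 * l + 2.454), 0.0)
    fpe = max(0.129 * (math.exp(4.525 * (l - 1.0)) - 1.0), 0.0)
    return Ft - (fl * a + fpe) * p.Fmx * cosphi


def isometric_equilibrium(a: float, q: float, p: HillParams,
                          g: GeometryParams) -> float:
    """Fiber length at which tendon and muscle forces balance with v = 0."""
    lmt, _ = geometry(q, g)
    lo = p.width * (1.0 + 1e-6) if p.width > 0 else 1e-6 * p.l0
    lo = max(lo, 0.05 * p.l0)
    hi = lmt  # generous upper bound; lt would be negative beyond
    f_lo = _equilibrium_residual(lo, a, lmt, p)
    f_hi = _equilibrium_residual(hi, a, lmt, p)
    if f_lo <= 0.0:
        # tendon slack even at the shortest admissible fiber: zero-force
        # equilibrium where eps = 0 and the fiber carries no load
        if f_hi < 0:
            return min(max(lmt - p.lst, lo), hi)
    if f_lo * f_hi > 0:
        raise SolverError(
            f"cannot bracket isometric equilibrium (a={a}, q={q})",
            residual=min(abs(f_lo), abs(f_hi)),
        )
    return brentq(_equilibrium_residual, lo, hi, args=(a, lmt, p),
                  xtol=1e-12, rtol=1e-14)


def _state_from_lm(lm: float, a: float, lmt: float, p: HillParams,
                   v: float = 0.0) -> MuscleState:
    phi = pennation(lm, p)
    cosphi = math.cos(phi)
    lt = lmt - lm * cosphi
    Ft = tendon_force(lt, p)
    lm0 = p.l0 * (p.lam * (1.0 - a) + 1.0)
    l = lm / lm0
    Fpe = passive_force_length(l) * p.Fmx
    Fce = active_force_length(l) * force_velocity(v) * p.Fmx * a
    Fm = Fce + Fpe
    return MuscleState(lm=lm, lt=lt, phi=phi, v=v, l=l, Fce=Fce, Fpe=Fpe,
                       Fm=Fm, Ft=Ft, Fmt=Ft)


def isometric_state(a: float, q: float, p: HillParams,
                    g: GeometryParams) -> tuple[MuscleState, TorqueEstimate]:
    """Equilibrium state and torque for constant activation and angle."""
    lmt, rmt = geometry(q, g)
    lm = isometric_equilibrium(a, q, p, g)
    st = _state_from_lm(lm, a, lmt, p)
    return st, TorqueEstimate(Mp=rmt * st.Ft, rmt=rmt, lmt=lmt, q=q)


def rigid_tendon_initial_lm(lmt: float, p: HillParams) -> float:
    """Initial fiber length guess: rigid tendon, projected into domain."""
    lm = (lmt - p.lst) / math.cos(p.phi0)
    lo = max(p.width * (1.0 + 1e-6), 0.3 * p.l0)
    return min(max(lm, lo), 1.7 * p.l0)


def simulate_muscle(a_series, q_series, fs: float, p: HillParams,
                    g: GeometryParams, lm_init: float | str | None = None,
                    method: str = "rk45", rtol: float = 1e-6,
                    atol: float = 1e-9) -> MuscleTrajectory:
    """Integrate fiber dynamics along given activation and angle series.

    Parameters
    ----------
    a_series, q_series : array-like
        Activation and anatomical joint angle, sampled at ``fs``.
    lm_init : float, "equilibrium", or None
        Initial fiber length.  ``None`` uses the rigid-tendon estimate;
        ``"equilibrium"`` solves the isometric balance at the first
        sample (recommended for trials starting from steady state).
    method : {"rk45", "quasistatic"}
        ``rk45`` integrates the fiber ODE with an adaptive Runge-Kutta
        scheme; ``quasistatic`` solves the v = 0 equilibrium sample by
        sample (valid when activation varies far more slowly than the
        ~30 ms fiber time constant, e.g. 2 Hz envelopes).
    """
    a = np.asarray(a_series, dtype=float)
    q = np.asarray(q_series, dtype=float)
    if a.shape != q.shape:
        raise ValueError("a_series and q_series must have equal length")
    n = len(a)
    t = np.arange(n) / fs
    lmt_arr = np.empty(n)
    rmt_arr = np.empty(n)
    for i in range(n):
        lmt_arr[i], rmt_arr[i] = geometry(q[i], g)

    if method == "quasistatic":
        lm_arr = np.empty(n)
        guess = None
        for i in range(n):
            lm_arr[i] = _quasistatic_lm(a[i], lmt_arr[i], p, guess)
            guess = lm_arr[i]
        v_arr = np.gradient(lm_arr, t) / p.vmax if n > 1 else np.zeros(n)
    elif method == "rk45":
        if lm_init is None:
            lm0 = rigid_tendon_initial_lm(lmt_arr[0], p)
        elif lm_init == "equilibrium":
            lm0 = _quasistatic_lm(a[0], lmt_arr[0], p, None)
        else:
            lm0 = float(lm_init)

        def rhs(tt, y):
            ai = np.interp(tt, t, a)
            li = np.interp(tt, t, lmt_arr)
            dlm, _ = _fiber_rhs(y[0], ai, li, p)
            return [dlm]

        sol = solve_ivp(rhs, (t[0], t[-1]), [lm0], t_eval=t, method="RK45",
                        rtol=rtol, atol=atol, max_step=0.05)
        if not sol.success:
            raise SolverError(
                f"fiber integration failed at t={sol.t[-1]:.4f}s: "
                f"{sol.message}"
            )
        lm_arr = sol.y[0]
        v_arr = np.array([
            _fiber_rhs(lm_arr[i], a[i], lmt_arr[i], p)[0] / p.vmax
            for i in range(n)
        ])
    else:
        raise ValueError(f"unknown method {method!r}")

    # Reconstruct dependent state along the trajectory.
    phi = np.arcsin(np.clip(p.width / lm_arr, 0.0, 1.0))
    cosphi = np.cos(phi)
    lt = lmt_arr - lm_arr * cosphi
    Ft = tendon_force(lt, p)
    lm0_arr = p.l0 * (p.lam * (1.0 - a) + 1.0)
    l = lm_arr / lm0_arr
    Fpe = passive_force_length(l) * p.Fmx
    Fce = active_force_length(l) * force_velocity(v_arr) * p.Fmx * a
    Fm = Fce + Fpe
    Fmt = np.asarray(Ft, dtype=float)
    Mp = rmt_arr * Fmt
    return MuscleTrajectory(t=t, lm=lm_arr, lt=np.asarray(lt), phi=phi,
                            v=v_arr, l=l, Fce=Fce, Fpe=Fpe, Fm=Fm,
                            Ft=np.asarray(Ft), Fmt=Fmt, rmt=rmt_arr, Mp=Mp)


def _quasistatic_lm(a: float, lmt: float, p: HillParams,
                    guess: float | None) -> float:
    """Per-sample isometric equilibrium, warm-started Newton with
    bisection fallback."""
    lo = max(p.width * (1.0 + 1e-6), 0.05 * p.l0)
    hi = lmt
    if guess is not None and lo < guess < hi:
        lm = guess
        for _ in range(30):
            r = _equilibrium_residual(lm, a, lmt, p)
            if abs(r) < 1e-9 * p.Fmx:
                return lm
            h = 1e-7 * p.l0
            dr = (_equilibrium_residual(lm + h, a, lmt, p) - r) / h
            if dr == 0:
                break
            lm_new = lm - r / dr
            if not (lo < lm_new < hi):
                break
            lm = lm_new
    f_lo = _equilibrium_residual(lo, a, lmt, p)
    f_hi = _equilibrium_residual(hi, a, lmt, p)
    if f_lo <= 0.0 and f_hi <= 0.0:
        return min(max(lmt - p.lst, lo), hi)
    if f_lo * f_hi > 0:
        raise SolverError("cannot bracket quasistatic equilibrium",
                          residual=min(abs(f_lo), abs(f_hi)))
    return brentq(_equilibrium_residual, lo, hi, args=(a, lmt, p),
                  xtol=1e-12, rtol=1e-14)


def joint_torque(state: MuscleState, rmt: float, lmt: float = math.nan,
                 q: float = math.nan) -> TorqueEstimate:
    """Joint torque from the muscle-tendon force and moment arm."""
    return TorqueEstimate(Mp=rmt * state.Fmt, rmt=rmt, lmt=lmt, q=q)
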