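"""Admittance filter, inner PD position loop, and the stiffness-adaptive
gain law (AACS) with its fixed-gain counterpart (NAACS).

The admittance filter maps the estimated joint torque Mp to an intended
position offset around the current angle,

    qi(s) = q(s) + Mp(s) / (k + b s + m s^2),

with defaults k = 2 N*m/rad, b = 0.1 N*m*s/rad, m = 0 (end-effector
accelerations are small).  With m = 0 the offset x = qi - q obeys the
first-order ODE b dx/dt + k x = Mp, discretized exactly (zero-order
hold) per control step, so the DC gain is Mp/k and the time constant
b/k (50 ms with the defaults).

The inner loop is a PD controller on the intended-position error,

    tau = K dq + B dq_dot,     B = 0.2 K.

NAACS holds K fixed (levels 0, 0.1, 0.3, 0.5); AACS maps the estimated
joint stiffness Kj affinely onto [Kmin, Kmax]:

    K = (Kmax - Kmin) (Kj - Kjmin)/(Kjmax - Kjmin) + Kmin,

clamped to the interval, where (Kjmin, Kjmax) are the extremes of Kj
predicted by the calibrated model during an assistance-free tracking
trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "AdmittanceParams",
    "AdmittanceFilter",
    "GainSchedule",
    "ControllerConfig",
    "pd_assist",
    "adapt_gain",
    "calibrate_gain_bounds",
]


@dataclass
class AdmittanceParams:
    """Admittance filter constants (stiffness, damping, mass) and step."""

    k_adm: float = 2.0
    b_adm: float = 0.1
    m_adm: float = 0.0
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.k_adm <= 0:
            raise ValueError("k_adm must be positive")
        if self.b_adm < 0 or self.m_adm < 0:
            raise ValueError("b_adm and m_adm must be non-negative")
        if self.m_adm != 0 and self.b_adm == 0 and self.k_adm == 0:
            raise ValueError("invalid filter: pure mass with no k or b")


class AdmittanceFilter:
    """Stateful discrete admittance filter qi = q + x, x driven by Mp.

    With m = 0 the update is the exact zero-order-hold discretization

        x[n+1] = E x[n] + (1 - E) Mp[n]/k,   E = exp(-k dt / b),

    which is BIBO stable for every dt (0 < E < 1).  For m > 0 the
    second-order continuous filter is discretized once by zero-order
    hold on its state-space form.
    """

    def __init__(self, params: AdmittanceParams | None = None, **kw):
        self.p = params or AdmittanceParams(**kw)
        p = self.p
        if p.m_adm == 0.0:
            if p.b_adm > 0:
                self._E = math.exp(-p.k_adm * p.dt / p.b_adm)
            else:
                self._E = 0.0  # static map x = Mp/k
            self._x = 0.0
            self._second_order = False
        else:
            A = np.array([[0.0, 1.0],
                          [-p.k_adm / p.m_adm, -p.b_adm / p.m_adm]])
            B = np.array([[0.0], [1.0 / p.m_adm]])
            (Ad, Bd, *_), _dt = _sig.cont2discrete(
                (A, B, np.eye(2), np.zeros((2, 1))), p.dt), p.dt
            self._Ad, self._Bd = Ad, Bd
            self._z = np.zeros(2)
            self._second_order = True

    @property
    def offset(self) -> float:
        return self._x if not self._second_order else float(self._z[0])

    def reset(self) -> None:
        if self._second_order:
            self._z[:] = 0.0
        else:
            self._x = 0.0

    def step(self, q: float, Mp: float) -> float:
        """Advance one control step; returns the intended angle qi."""
        if self._second_order:
            self._z = self._Ad @ self._z + self._Bd[:, 0] * Mp
            return q + float(self._z[0])
        self._x = self._E * self._x + (1.0 - self._E) * Mp / self.p.k_adm
        return q + self._x

    def run(self, q_series, Mp_series) -> np.ndarray:
        """Vector convenience: filter whole series, returning qi."""
        q_arr = np.asarray(q_series, dtype=float)
        Mp_arr = np.asarray(Mp_series, dtype=float)
        out = np.empty_like(q_arr)
        for i in range(len(q_arr)):
            out[i] = self.step(q_arr[i], Mp_arr[i])
        return out


@dataclass
class GainSchedule:
    """Inner-loop gain bounds and the joint-stiffness mapping range."""

    mode: str = "aacs"          # "aacs" | "naacs"
    K_fixed: float = 0.0        # NAACS level
    Kmin: float = 0.0
    Kmax: float = 0.5
    Kjmin: float | None = None  # from the assistance-free trial
    Kjmax: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("aacs", "naacs"):
            raise ValueError(f"unknown mode {self.mode!r}")


def pd_assist(delta_q: float, delta_qdot: float, K: float) -> float:
    """Assist torque tau = K dq + B dq_dot with B = 0.2 K."""
    if K < 0:
        raise ValueError("K must be non-negative")
    return K * delta_q + 0.2 * K * delta_qdot


def adapt_gain(Kj: float, sched: GainSchedule) -> float:
    """Affine map of joint stiffness onto [Kmin, Kmax], clamped."""
    if sched.Kjmin is None or sched.Kjmax is None:
        raise ValueError("gain schedule has no joint-stiffness bounds")
    if sched.Kjmax <= sched.Kjmin:
        raise ValueError("degenerate joint-stiffness bounds")
    K = ((sched.Kmax - sched.Kmin)
         * (Kj - sched.Kjmin) / (sched.Kjmax - sched.Kjmin)
         + sched.Kmin)
    return min(max(K, sched.Kmin), sched.Kmax)


def calibrate_gain_bounds(assist_free_log,
                          window_deg: float = 20.0) -> tuple[float, float]:
    """(Kjmin, Kjmax) from an assistance-free trial's stiffness series.

    The extremes are taken over the analysis window (target angle within
    +/- ``window_deg`` of neutral), which is where all indicators are
    evaluated.  A constant stiffness series is degenerate and raises.
    """
    from .metrics import crop_analysis_window  # local import, no cycle at load

    cropped = crop_analysis_window(assist_free_log, threshold_deg=window_deg)
    kj = np.asarray(cropped.kj, dtype=float)
    if kj.size == 0:
        raise ValueError("empty analysis window")
    kj_min, kj_max = float(np.min(kj)), float(np.max(kj))
    if kj_max <= kj_min:
        raise ValueError("degenerate joint-stiffness bounds: constant Kj")
    return kj_min, kj_max


@dataclass
class ControllerConfig:
    """Everything the closed-loop simulator needs about the controller."""

    mode: str = "naacs"           # "aacs" | "naacs"
    K_fixed: float = 0.0
    Kmin: float = 0.0
    Kmax: float = 0.5
    kj_min: float | None = None
    kj_max: float | None = None
    kj_override: float | None = None  # pin the stiffness input (testing)
    k_adm: float = 2.0
    b_adm: float = 0.1
    m_adm: float = 0.0
    loop_hz: float = 1000.0
    deriv_smooth_hz: float = 10.0  # first-difference smoothing for dq_dot
    b_ratio: float = 0.2           # B = b_ratio * K (protocol value 0.2)

    def schedule(self) -> GainSchedule:
        return GainSchedule(mode=self.mode, K_fixed=self.K_fixed,
                            Kmin=self.Kmin, Kmax=self.Kmax,
                            Kjmin=self.kj_min, Kjmax=self.kj_max)
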