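"""Subject-specific model calibration from MVC trials.

Three parameters are refit per subject — the activation-curve shape
``A``, the tendon slack length ``lst`` and the maximum isometric force
``Fmx`` — by minimizing the mean squared error between the model torque
and the measured torque,

    Er = (1/N) * sum_i (Mp(i) - Mm(i))^2,

pooled over all MVC trials (two fixed ankle angles, 90 and 120 deg),
with the Nelder-Mead simplex.  The EMG-to-neural-activation stage does
not depend on the fitted parameters, so envelopes and u(t) are
precomputed once per trial; only the activation curve and the
muscle-tendon forward model are re-evaluated per candidate.

Trials are trimmed to their effort plateau (the central 3 s of the 5 s
trial) before fitting, excluding ramp transients, and the fit runs on a
decimated grid (the envelope is band-limited to 2 Hz).  The default
optimization is two-stage: a fast quasi-static forward model (the
equilibrium fiber state, accurate wherever activation varies far more
slowly than the ~30 ms fiber time constant) pins the force-scale
parameters, then the fiber-ODE forward refines — its ramp transients
carry most of the information about A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import activation as _act
from .exceptions import DegenerateDataError
from .musculotendon import simulate_muscle
from .subject import SubjectParams

__all__ = ["MvcTrial", "CalibrationResult", "calibration_error", "calibrate"]


@dataclass
class MvcTrial:
    """One MVC trial: fixed ankle angle, EMG and measured torque.

    Either raw EMG (``emg``) or a pre-normalized envelope
    (``envelope``) must be present; the torque series ``torque`` (N*m)
    is aligned sample-for-sample with it at ``fs``.
    """

    angle_rad: float
    torque: np.ndarray
    fs: float
    emg: _act.RawEmg | None = None
    envelope: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.torque = np.asarray(self.torque, dtype=float)
        n = (len(self.emg.samples) if self.emg is not None
             else len(self.envelope))
        if n != len(self.torque):
            raise ValueError("EMG and torque series must be equal length")


@dataclass
class CalibrationResult:
    """Fitted parameters and the final pooled torque error."""

    A: float
    lst_m: float
    Fmx_N: float
    Er: float          # mean squared torque error, (N*m)^2
    n_iter: int
    converged: bool


def calibration_error(Mp_series, Mm_series) -> float:
    """Mean squared torque-prediction error (note: MSE, not RMS)."""
    Mp = np.asarray(Mp_series, dtype=float)
    Mm = np.asarray(Mm_series, dtype=float)
    if Mp.shape != Mm.shape or Mp.size == 0:
        raise ValueError("torque series must be non-empty and equal length")
    d = Mp - Mm
    return float(np.mean(d * d))


def _prepare_trial(trial: MvcTrial, mvc_peak: float | None,
                   plateau: tuple[float, float], fs_fit: float):
    """Precompute the parameter-independent u(t) on the fit grid."""
    if trial.envelope is not None:
        e = np.asarray(trial.envelope, dtype=float)
    else:
        raw = trial.emg
        env = _act.processed_envelope(raw.samples, raw.fs)
        e = env / mvc_peak
    u = np.clip(_act.neural_activation(
        _act.EnvelopeSignal(e=e, fs=trial.fs)), 0.0, 1.0)
    step = max(1, int(round(trial.fs / fs_fit)))
    u_dec = u[::step]
    mm_dec = trial.torque[::step]
    t_dec = np.arange(len(u_dec)) * step / trial.fs
    sel = (t_dec >= plateau[0]) & (t_dec <= plateau[1])
    # nothing after the fit window contributes: truncate the simulation
    last = int(np.max(np.flatnonzero(sel))) + 1
    return u_dec[:last], mm_dec[:last], sel[:last], trial.fs / step


def calibrate(trials: list[MvcTrial], subject: SubjectParams,
              bounds: dict | None = None, init: dict | None = None,
              plateau: tuple[float, float] = (1.0, 4.0),
              fs_fit: float = 100.0, maxfev: int = 400,
              xatol: float = 1e-4, fatol: float = 1e-9,
              forward: str = "hybrid") -> CalibrationResult:
    """Fit (A, lst, Fmx) to MVC trials by Nelder-Mead.

    ``bounds`` may override the defaults (A in [0, 0.35], lst within
    0.5-1.5x the subject default, Fmx in [100, 3000] N); ``init`` the
    starting point (defaults to the subject's current values).  lst and
    Fmx are searched on a log scale.  Deterministic given ``init``.

    ``forward`` selects the muscle forward model inside the objective:
    ``"hybrid"`` (default) first converges with the fast quasi-static
    equilibrium forward — which pins lst and Fmx almost exactly — and
    then refines with the fiber-ODE forward, whose ramp transients are
    what identify A; ``"rk45"`` and ``"quasistatic"`` use a single
    stage.
    """
    if not trials:
        raise ValueError("need at least one MVC trial")
    if all(float(np.max(np.abs(t.torque))) == 0.0 for t in trials):
        raise DegenerateDataError("all-zero measured torque")

    b = {
        "A": (0.0, 0.35),
        "lst": (0.5 * subject.lst, 1.5 * subject.lst),
        "Fmx": (100.0, 3000.0),
    }
    if bounds:
        b.update(bounds)
    x0 = {
        "A": subject.A, "lst": subject.lst, "Fmx": subject.Fmx,
    }
    if init:
        x0.update(init)

    mvc_peak = None
    if any(t.envelope is None for t in trials):
        mvc_peak = _act.mvc_peak_from_trials(
            [t.emg for t in trials if t.emg is not None])

    prepared = [_prepare_trial(t, mvc_peak, plateau, fs_fit) for t in trials]
    angles = [t.angle_rad for t in trials]

    def make_objective(method: str):
        def objective(x: np.ndarray) -> float:
            A, lst, Fmx = x[0], math.exp(x[1]), math.exp(x[2])
            cand = subject.with_fit(A=A, lst=lst, Fmx=Fmx)
            try:
                curve = cand.curve
            except ValueError:
                return 1e12
            p, g = cand.hill, cand.geometry
            sq_sum, n_tot = 0.0, 0
            for (u_dec, mm_dec, sel, fsd), angle in zip(prepared, angles):
                a = curve(u_dec)
                q = np.full(len(a), angle)
                traj = simulate_muscle(a, q, fsd, p, g, method=method,
                                       lm_init="equilibrium")
                d = traj.Mp[sel] - mm_dec[sel]
                sq_sum += float(np.dot(d, d))
                n_tot += int(np.count_nonzero(sel))
            return sq_sum / max(n_tot, 1)
        return objective

    x_init = np.array([x0["A"], math.log(x0["lst"]), math.log(x0["Fmx"])])
    opt_bounds = [b["A"],
                  (math.log(b["lst"][0]), math.log(b["lst"][1])),
                  (math.log(b["Fmx"][0]), math.log(b["Fmx"][1]))]
    if forward == "hybrid":
        stages = [("quasistatic", maxfev, 1e-6, None),
                  ("rk45", max(maxfev // 2, 200), xatol, 2e-3)]
    else:
        stages = [(forward, maxfev, xatol, None)]
    n_ev = 0
    res = None
    coarse_fun = math.inf
    for method, mf, xa, simplex_step in stages:
        options = {"maxfev": mf, "xatol": xa, "fatol": fatol,
                   "adaptive": True}
        if simplex_step is not None:
            # refinement stage: restart from a tight simplex around the
            # previous optimum instead of scipy's 5% default
            coarse_fun = float(res.fun)
            simplex = [np.array(x_init)]
            for k in range(3):
                v = np.array(x_init)
                v[k] += simplex_step
                simplex.append(v)
            options["initial_simplex"] = np.array(simplex)
        res = minimize(make_objective(method), x_init, method="Nelder-Mead",
                       bounds=opt_bounds, options=options)
        n_ev += int(res.nfev)
        x_init = res.x
    # The refinement objective's A-direction is nearly flat, so the
    # simplex rarely meets the formal stopping rule; an improvement over
    # the converged coarse stage is the meaningful convergence signal.
    converged = bool(res.success) or float(res.fun) <= coarse_fun
    if not converged:
        import warnings
        warnings.warn(
            f"calibration did not converge after {n_ev} evaluations; "
            "returning best point so far", RuntimeWarning, stacklevel=2)
    return CalibrationResult(
        A=float(res.x[0]), lst_m=float(math.exp(res.x[1])),
        Fmx_N=float(math.exp(res.x[2])), Er=float(res.fun),
        n_iter=n_ev, converged=converged)
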