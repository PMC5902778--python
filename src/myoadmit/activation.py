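"""EMG-to-activation pipeline for the tibialis anterior (TA).

Raw surface EMG is turned into a muscle activation signal in three stages:

1. **Envelope extraction** — band-pass 20–450 Hz (4th-order Butterworth),
   full-wave rectification, low-pass 2 Hz (2nd-order Butterworth), and
   normalization by the maximal envelope amplitude recorded in maximum
   voluntary contraction (MVC) trials.
2. **Neural activation** — a second-order recursive filter with an
   electromechanical delay ``d`` (default 80 ms) maps the envelope
   ``e(t)`` to neural activation ``u(t)``:

       u(t) = alpha * e(t - d) - beta1 * u(t-1) - beta2 * u(t-2)

   with alpha = 0.9486, beta1 = -0.052, beta2 = 0.000627.  The recursion
   runs per sample at the envelope sampling rate and is stable (both
   characteristic roots lie well inside the unit circle).
3. **Activation nonlinearity** — a piecewise logarithmic/linear curve
   maps ``u`` to muscle activation ``a``, capturing the amplified force
   response at low excitation:

       a = b * ln(c*u + 1)   for 0 <= u < u0
       a = m * u + n         for u0 <= u <= 1

   The node (u0, a0) is placed by a single shape parameter ``A``:
   u0 = 0.3085 - A cos45°, a0 = 0.3085 + A sin45°.  The linear branch is
   fixed by the points (u0, a0) and (1, 1); ``b`` is solved so the two
   branches share their slope at the node (safeguarded Newton iteration),
   and ``c`` follows from continuity: c = (exp(a0/b) - 1) / u0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from .exceptions import NormalizationError, SamplingRateError, SolverError

__all__ = [
    "RawEmg",
    "EnvelopeSignal",
    "NeuralActivationParams",
    "ActivationCurve",
    "compute_envelope",
    "mvc_peak_from_trials",
    "neural_activation",
    "solve_activation_curve",
    "muscle_activation",
]

#: Band-pass edges for surface EMG conditioning, Hz.
BAND_HZ = (20.0, 450.0)
#: Envelope low-pass cutoff, Hz.
ENVELOPE_HZ = 2.0


@dataclass
class RawEmg:
    """Raw surface EMG record.

    Parameters
    ----------
    samples : ndarray
        EMG samples in volts.
    fs : float
        Sampling rate in Hz (the hardware default is 1000).
    mvc_peak : float
        Maximal processed-envelope amplitude (volts) recorded during MVC
        trials; used to normalize the envelope to fraction-of-MVC units.
    """

    samples: np.ndarray
    fs: float = 1000.0
    mvc_peak: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise SamplingRateError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")
        if self.mvc_peak <= 0:
            raise NormalizationError(
                f"mvc_peak must be positive, got {self.mvc_peak}"
            )


@dataclass
class EnvelopeSignal:
    """Normalized EMG envelope e(t), dimensionless (fraction of MVC)."""

    e: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)


@dataclass
class NeuralActivationParams:
    """Coefficients of the envelope-to-neural-activation recursion."""

    alpha: float = 0.9486
    beta1: float = -0.052
    beta2: float = 0.000627
    delay_s: float = 0.080

    def poles(self) -> np.ndarray:
        """Roots of z^2 + beta1 z + beta2; stable iff all |z| < 1."""
        return np.roots([1.0, self.beta1, self.beta2])

    def is_stable(self) -> bool:
        return bool(np.all(np.abs(self.poles()) < 1.0))

    def steady_state_gain(self) -> float:
        """DC gain of the recursion: alpha / (1 + beta1 + beta2)."""
        return self.alpha / (1.0 + self.beta1 + self.beta2)


@dataclass
class ActivationCurve:
    """Piecewise log/linear neural-to-muscle activation map.

    Attributes mirror the curve definition: node abscissa ``u0`` and
    ordinate ``a0``, log-branch coefficients ``b`` and ``c``, linear
    branch ``a = m u + n``, plus the shape parameter ``A`` that placed
    the node.
    """

    A: float
    u0: float
    a0: float
    b: float
    c: float
    m: float
    n: float

    def __call__(self, u):
        return muscle_activation(u, self)

    def slope_gap(self) -> float:
        """Left-minus-right derivative at the node (should be ~0)."""
        return self.b * self.c / (self.c * self.u0 + 1.0) - self.m

    def inverse(self, a: float) -> float:
        """Neural activation u producing muscle activation ``a`` (exact
        branch-wise inverse, clamped to [0, 1])."""
        if a <= 0.0:
            return 0.0
        if a >= 1.0:
            return 1.0
        if a < self.a0:
            return (math.exp(a / self.b) - 1.0) / self.c
        return (a - self.n) / self.m


@lru_cache(maxsize=8)
def _band_sos(fs: float) -> tuple:
    sos = signal.butter(4, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    return tuple(map(tuple, sos))


@lru_cache(maxsize=8)
def _low_sos(fs: float) -> tuple:
    sos = signal.butter(2, ENVELOPE_HZ, btype="lowpass", fs=fs, output="sos")
    return tuple(map(tuple, sos))


def band_sos(fs: float) -> np.ndarray:
    """20–450 Hz 4th-order Butterworth band-pass as second-order sections."""
    return np.array(_band_sos(fs))


def low_sos(fs: float) -> np.ndarray:
    """2 Hz 2nd-order Butterworth low-pass as second-order sections."""
    return np.array(_low_sos(fs))


def _check_fs(fs: float) -> None:
    # The 450 Hz band edge needs headroom below Nyquist.
    if fs <= 2 * BAND_HZ[1]:
        raise SamplingRateError(
            f"fs={fs} Hz too low: band-pass upper edge {BAND_HZ[1]} Hz "
            "must lie below Nyquist"
        )


def processed_envelope(samples: np.ndarray, fs: float,
                       zero_phase: bool = False) -> np.ndarray:
    """Band-pass, rectify and low-pass; **no** MVC normalization.

    Causal (forward-only) by default, matching the real-time controller;
    ``zero_phase=True`` applies each filter forward-backward for offline
    analysis.
    """
    _check_fs(fs)
    x = np.asarray(samples, dtype=float)
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    x = filt(band_sos(fs), x)
    x = np.abs(x)
    x = filt(low_sos(fs), x)
    return np.maximum(x, 0.0)  # clamp low-pass ringing below zero


def compute_envelope(raw: RawEmg, zero_phase: bool = False) -> EnvelopeSignal:
    """Full EMG conditioning: filter bank plus MVC normalization."""
    if raw.mvc_peak <= 0:
        raise NormalizationError("mvc_peak must be positive")
    env = processed_envelope(raw.samples, raw.fs, zero_phase=zero_phase)
    return EnvelopeSignal(e=env / raw.mvc_peak, fs=raw.fs)


def mvc_peak_from_trials(trials: list[RawEmg], zero_phase: bool = False) -> float:
    """Maximal processed-envelope amplitude pooled across MVC trials.

    The maximum is taken across all supplied trials (both calibration
    angles), mirroring how the maximal EMG amplitude is recorded during
    the MVC protocol.
    """
    if not trials:
        raise ValueError("need at least one MVC trial")
    peak = max(
        float(np.max(processed_envelope(t.samples, t.fs, zero_phase)))
        for t in trials
    )
    if peak <= 0:
        raise NormalizationError("MVC trials produced a zero envelope")
    return peak


def neural_activation(env: EnvelopeSignal,
                      p: NeuralActivationParams | None = None) -> np.ndarray:
    """Apply the delayed second-order recursion e(t) -> u(t).

    The electromechanical delay is converted to a whole number of samples
    by rounding; the recursion then runs per sample at ``env.fs``.
    Output is clamped to be non-negative (the impulse response of the
    default recursion is positive, so this only guards edge cases).
    """
    p = p or NeuralActivationParams()
    e = np.asarray(env.e, dtype=float)
    d = int(round(p.delay_s * env.fs))
    if d > 0:
        e = np.concatenate([np.zeros(d), e[: len(e) - d] if d < len(e) else e[:0]])
        e = e[: len(env.e)]
    u = signal.lfilter([p.alpha], [1.0, p.beta1, p.beta2], e)
    return u


def solve_activation_curve(A: float, tol: float = 1e-10,
                           max_iter: int = 100) -> ActivationCurve:
    """Solve the activation-curve coefficients for shape parameter ``A``.

    ``b`` is found by a bisection-safeguarded Newton iteration on the
    slope-matching residual

        h(b) = b (1 - exp(-a0/b)) / u0 - m,

    which equals the log-branch slope at the node minus the linear slope
    (``c`` is eliminated through the continuity relation).  ``h`` is
    strictly increasing in ``b`` with limit a0/u0, so a root exists iff
    m < a0/u0, i.e. A > 0.  A = 0 is the exact linear limit (u0 = a0,
    m = 1): the log branch degenerates into the line a = u, represented
    here by a very large ``b`` (slope gap < 1e-6, node identity exact).

    Raises
    ------
    ValueError
        If the node leaves the unit square or A < 0 (for which the
        concave log branch cannot match the linear slope).
    SolverError
        If the Newton iteration fails to converge.
    """
    s45 = math.sqrt(0.5)
    u0 = 0.3085 - A * s45
    a0 = 0.3085 + A * s45
    if not (0.0 < u0 < 1.0 and 0.0 < a0 < 1.0):
        raise ValueError(
            f"A={A} places the node ({u0:.4f}, {a0:.4f}) outside (0,1)^2"
        )
    if A < 0:
        raise ValueError(
            "A must be >= 0: for A < 0 the required linear slope exceeds "
            "the chord slope a0/u0 and the concave log branch cannot "
            "match it"
        )
    m = (1.0 - a0) / (1.0 - u0)
    n = 1.0 - m

    def h(b: float) -> float:
        return b * (1.0 - math.exp(-a0 / b)) / u0 - m

    def hprime(b: float) -> float:
        x = a0 / b
        return (1.0 - math.exp(-x) * (1.0 + x)) / u0

    if A < 1e-6 or m >= (a0 / u0) * (1.0 - 1e-12):
        # Linear limit (A -> 0): the required slope approaches the chord
        # slope a0/u0 and b diverges; below A ~ 1e-6 the Newton residual
        # derivative underflows, and the curve is linear to ~1e-6 anyway.
        b = 1e6
    else:
        lo, hi = 1e-8, 1.0
        while h(hi) < 0:
            hi *= 2.0
            if hi > 1e9:  # pragma: no cover - unreachable for valid A
                raise SolverError("failed to bracket b", residual=h(1e9))
        b = 0.5 * (lo + hi)
        converged = False
        for _ in range(max_iter):
            r = h(b)
            if r > 0:
                hi = b
            else:
                lo = b
            hp = hprime(b)
            b_new = b - r / hp if hp > 0 else 0.5 * (lo + hi)
            if not (lo < b_new < hi):  # safeguard: bisect
                b_new = 0.5 * (lo + hi)
            if abs(b_new - b) < tol * max(1.0, abs(b)):
                b = b_new
                converged = True
                break
            b = b_new
        if not converged and abs(h(b)) > 1e-8:
            raise SolverError(
                f"Newton iteration for b did not converge (A={A})",
                residual=h(b),
            )
    c = (math.exp(a0 / b) - 1.0) / u0
    return ActivationCurve(A=A, u0=u0, a0=a0, b=b, c=c, m=m, n=n)


def muscle_activation(u, curve: ActivationCurve):
    """Map neural activation u in [0, 1] to muscle activation a in [0, 1]."""
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < -1e-12) or np.any(u_arr > 1.0 + 1e-12):
        raise ValueError("u outside [0, 1]")
    u_arr = np.clip(u_arr, 0.0, 1.0)
    a = np.where(
        u_arr < curve.u0,
        curve.b * np.log(curve.c * u_arr + 1.0),
        curve.m * u_arr + curve.n,
    )
    a = np.clip(a, 0.0, 1.0)
    if np.isscalar(u) or np.ndim(u) == 0:
        return float(a)
    return a
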