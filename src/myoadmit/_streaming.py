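"""Sample-by-sample (streaming) filter primitives for the real-time loop.

These mirror the vectorized scipy filters exactly: :class:`StreamingSOS`
runs the same direct-form-II-transposed recursion as ``scipy.signal.sosfilt``
with zero initial state, so offline and in-the-loop processing agree to
round-off.  Everything here operates on plain Python floats — the closed
loop runs at 1 kHz and per-sample numpy scalars would dominate the cost.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["StreamingSOS", "OnePole", "DelayLine", "NeuralRecursion"]


class StreamingSOS:
    """Cascaded biquads (second-order sections), scalar per-sample step."""

    def __init__(self, sos: np.ndarray):
        sos = np.asarray(sos, dtype=float)
        self._sections = [tuple(row) for row in sos]
        self._z = [[0.0, 0.0] for _ in self._sections]

    def reset(self) -> None:
        for z in self._z:
            z[0] = z[1] = 0.0

    def step(self, x: float) -> float:
        for (b0, b1, b2, _a0, a1, a2), z in zip(self._sections, self._z):
            y = b0 * x + z[0]
            z[0] = b1 * x - a1 * y + z[1]
            z[1] = b2 * x - a2 * y
            x = y
        return x


class OnePole:
    """First-order low-pass y' = (x - y)/tau, exact pole discretization."""

    def __init__(self, cutoff_hz: float, dt: float, y0: float = 0.0):
        self._a = math.exp(-2.0 * math.pi * cutoff_hz * dt)
        self.y = y0

    def reset(self, y0: float = 0.0) -> None:
        self.y = y0

    def step(self, x: float) -> float:
        self.y = self._a * self.y + (1.0 - self._a) * x
        return self.y


class DelayLine:
    """Fixed integer-sample delay (ring buffer), zero-initialized."""

    def __init__(self, n: int):
        self.n = int(n)
        self._buf = [0.0] * max(self.n, 1)
        self._i = 0

    def step(self, x: float) -> float:
        if self.n == 0:
            return x
        out = self._buf[self._i]
        self._buf[self._i] = x
        self._i = (self._i + 1) % self.n
        return out


class NeuralRecursion:
    """Second-order neural-activation recursion (see activation module)."""

    def __init__(self, alpha: float = 0.9486, beta1: float = -0.052,
                 beta2: float = 0.000627):
        self.alpha, self.beta1, self.beta2 = alpha, beta1, beta2
        self._u1 = 0.0
        self._u2 = 0.0

    def reset(self) -> None:
        self._u1 = self._u2 = 0.0

    def step(self, e_delayed: float) -> float:
        u = self.alpha * e_delayed - self.beta1 * self._u1 - self.beta2 * self._u2
        self._u2 = self._u1
        self._u1 = u
        return u
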