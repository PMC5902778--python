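"""Movement-quality indicators on trial logs, restricted to the
analysis window.

Four indicators summarize a tracking trial:

* **jerk value** — RMS of the third time-derivative of the actual
  angle (rad/s^3; lower = smoother movement),
* **position error** — RMS of (target - actual) angle (rad),
* **interaction torque** — RMS of the torque sensed between motor and
  footplate (N*m; lower = more compliant interaction),
* **EMG level** — RMS of the processed TA envelope (fraction of MVC;
  lower = less muscular effort).

Near the movement extremes the drive reverses and static friction
dominates the real device, so only samples where the *target* angle
lies within +/-20 deg of neutral enter the analysis.  Cropping is keyed
to the target (not the actual) angle so the retained window does not
depend on the controller under test.  The third derivative is computed
by cascaded central differences after a 20 Hz low-pass pre-filter (raw
triple differencing at 1 kHz amplifies quantization noise), separately
on each contiguous segment of the cropped log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = ["IndicatorSet", "crop_analysis_window", "jerk_value",
           "rms_indicators"]

#: Samples discarded at each segment edge after differentiation
#: (filter + one-sided-difference transients).
_EDGE_TRIM_S = 0.1


@dataclass
class IndicatorSet:
    """The four evaluation indicators of one (cropped) trial."""

    jerk_value: float          # rad/s^3
    position_error: float      # rad
    interaction_torque: float  # N*m
    emg_level: float           # fraction of MVC
    n_samples: int


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8),
                                                 [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def crop_analysis_window(log, threshold_deg: float = 20.0):
    """Retain samples whose target angle is within +/-threshold of neutral.

    Contiguous segments are preserved (recorded in ``segments`` as
    [start, stop) pairs into the cropped arrays) so derivatives are
    never taken across gaps.
    """
    thr = math.radians(threshold_deg)
    mask = np.abs(np.asarray(log.target, dtype=float)) <= thr
    if not np.any(mask):
        raise ValueError("empty analysis window")
    runs = _contiguous_runs(mask)
    segments, start = [], 0
    for a, b in runs:
        segments.append((start, start + (b - a)))
        start += b - a

    def take(x):
        return np.asarray(x)[mask]

    return replace(
        log, t=take(log.t), target=take(log.target), q=take(log.q),
        qdot=take(log.qdot), qi=take(log.qi),
        torque_human=take(log.torque_human),
        torque_est=take(log.torque_est),
        torque_assist=take(log.torque_assist),
        torque_interaction=take(log.torque_interaction),
        emg=take(log.emg), envelope=take(log.envelope), kj=take(log.kj),
        gain_k=take(log.gain_k), segments=segments,
    )


def jerk_value(q_series, fs: float, prefilter_hz: float | None = 20.0
               ) -> float:
    """RMS of the third finite-difference derivative of the angle."""
    q = np.asarray(q_series, dtype=float)
    if len(q) < 4:
        raise ValueError("need at least 4 samples for a third derivative")
    if prefilter_hz is not None and fs > 4 * prefilter_hz:
        sos = signal.butter(2, prefilter_hz, fs=fs, output="sos")
        q = signal.sosfiltfilt(sos, q)
    dt = 1.0 / fs
    j = np.gradient(np.gradient(np.gradient(q, dt), dt), dt)
    trim = min(int(_EDGE_TRIM_S * fs), max((len(j) - 4) // 2, 0))
    if trim > 0:
        j = j[trim:-trim]
    return float(np.sqrt(np.mean(j * j)))


def _rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(x * x)))


def rms_indicators(log) -> IndicatorSet:
    """Compute the four indicators on a (cropped) trial log.

    Jerk is evaluated per contiguous segment and pooled by the sum of
    squares, so gaps introduced by cropping never enter a derivative.
    """
    for ch in ("q", "target", "torque_interaction", "envelope"):
        if getattr(log, ch, None) is None:
            raise ValueError(f"trial log is missing channel {ch!r}")
    segments = log.segments or [(0, len(log.q))]
    sq_sum, n_sq = 0.0, 0
    for a, b in segments:
        if b - a < 4:
            continue
        seg = np.asarray(log.q[a:b], dtype=float)
        jv = jerk_value(seg, log.fs)
        # reconstruct the per-segment sample count used after trimming
        m = b - a - 2 * min(int(_EDGE_TRIM_S * log.fs),
                            max((b - a - 4) // 2, 0))
        sq_sum += jv * jv * m
        n_sq += m
    if n_sq == 0:
        raise ValueError("no segment long enough for a jerk estimate")
    return IndicatorSet(
        jerk_value=float(np.sqrt(sq_sum / n_sq)),
        position_error=_rms(np.asarray(log.target) - np.asarray(log.q)),
        interaction_torque=_rms(log.torque_interaction),
        emg_level=_rms(log.envelope),
        n_samples=len(log.q),
    )
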