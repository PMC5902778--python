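"""Higher-level analyses: stiffness-verification correlation and the
adaptive-vs-fixed-gain controller comparison on simulated subjects.

The stiffness-verification reference values (measured and model-
estimated ankle stiffness of one subject at seven TA activation
levels, N*m/rad) are shipped as a packaged fixture so the correlation
check runs without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .controller import ControllerConfig, calibrate_gain_bounds
from .metrics import IndicatorSet, crop_analysis_window, rms_indicators
from .simulator import AnklePlant, VirtualSubject, run_tracking_trial

__all__ = [
    "STIFFNESS_TABLE_MVC_PCT",
    "STIFFNESS_TABLE_MEASURED",
    "STIFFNESS_TABLE_ESTIMATED",
    "StiffnessComparison",
    "pearson_correlation",
    "reference_stiffness_correlation",
    "compare_controllers",
]

#: Reference stiffness-verification data (one subject): TA activation
#: level (% MVC), stiffness measured by sinusoidal perturbation +
#: regression, and stiffness estimated by the calibrated EMG-driven
#: model (N*m/rad).
STIFFNESS_TABLE_MVC_PCT = (0.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)
STIFFNESS_TABLE_MEASURED = (15.18, 28.20, 39.58, 46.20, 54.84, 59.88, 71.07)
STIFFNESS_TABLE_ESTIMATED = (14.19, 34.49, 46.37, 53.50, 59.40, 65.41, 75.51)


@dataclass
class StiffnessComparison:
    """Measured vs model-estimated stiffness across activation levels."""

    levels_pct: np.ndarray
    measured_K: np.ndarray
    estimated_K: np.ndarray
    pearson_r: float


def pearson_correlation(x_series, y_series) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series of at least 3 points")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(stats.pearsonr(x, y).statistic)


def reference_stiffness_correlation() -> StiffnessComparison:
    """Correlation between the packaged measured/estimated stiffness rows."""
    m = np.array(STIFFNESS_TABLE_MEASURED)
    e = np.array(STIFFNESS_TABLE_ESTIMATED)
    return StiffnessComparison(
        levels_pct=np.array(STIFFNESS_TABLE_MVC_PCT),
        measured_K=m, estimated_K=e,
        pearson_r=pearson_correlation(m, e),
    )


def _aacs_bounds(subject: VirtualSubject, plant: AnklePlant | None,
                 seed: int, n_cycles: int, fs: float) -> tuple[float, float]:
    """Joint-stiffness bounds from an assistance-free (K = 0) trial."""
    free = run_tracking_trial(
        subject, ControllerConfig(mode="naacs", K_fixed=0.0),
        plant=plant, seed=seed, n_cycles=n_cycles, fs=fs)
    return calibrate_gain_bounds(free)


def compare_controllers(configs: dict[str, ControllerConfig],
                        subject: VirtualSubject,
                        seeds,
                        plant: AnklePlant | None = None,
                        n_cycles: int = 11,
                        fs: float = 1000.0,
                        bounds_seed: int | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every controller configuration over every seed and tabulate
    the four indicators.

    AACS configurations missing their joint-stiffness bounds get them
    from one assistance-free trial (seed ``bounds_seed``, defaulting to
    the first seed), mirroring the protocol in which the first trial is
    always unassisted and fixes the gain mapping.

    Returns ``(summary, raw)``: the summary holds ``mean (sd)`` strings
    per indicator and configuration (rows = indicators, columns =
    configuration names, insertion order); ``raw`` one row per trial.
    Output is invariant to the ordering of ``configs``.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    bseed = bounds_seed if bounds_seed is not None else seeds[0]
    bounds_cache: tuple[float, float] | None = None

    rows = []
    for name, cfg in configs.items():
        if cfg.mode == "aacs" and (cfg.kj_min is None or cfg.kj_max is None):
            if bounds_cache is None:
                bounds_cache = _aacs_bounds(subject, plant, bseed,
                                            n_cycles, fs)
            cfg = replace(cfg, kj_min=bounds_cache[0],
                          kj_max=bounds_cache[1])
        for seed in seeds:
            log = run_tracking_trial(subject, cfg, plant=plant, seed=seed,
                                     n_cycles=n_cycles, fs=fs)
            ind = rms_indicators(crop_analysis_window(log))
            rows.append({
                "config": name, "seed": seed,
                "jerk_value": ind.jerk_value,
                "position_error": ind.position_error,
                "interaction_torque": ind.interaction_torque,
                "emg_level": ind.emg_level,
            })
    raw = pd.DataFrame(rows)

    indicators = ["jerk_value", "position_error", "interaction_torque",
                  "emg_level"]
    summary = pd.DataFrame(index=indicators, columns=list(configs), dtype=object)
    for name in configs:
        sub = raw[raw["config"] == name]
        for ind_name in indicators:
            mu = sub[ind_name].mean()
            sd = sub[ind_name].std(ddof=1) if len(sub) > 1 else 0.0
            summary.loc[ind_name, name] = f"{mu:.4g} ({sd:.3g})"
    return summary, raw
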