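"""Plain-text I/O for signals and trial logs.

Signal files are two-column CSV (``time_s, value``) with a header
comment line ``# fs=<rate>``; trial logs are multi-column CSV with the
same dialect.  Subject parameter YAML lives in :mod:`myoadmit.subject`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulator import TrialLog

__all__ = ["read_signal", "write_signal", "write_trial_log",
           "read_trial_log"]


def _read_fs(path) -> float:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "fs=" in first:
        return float(first.split("fs=")[1].split()[0])
    raise ValueError(f"{path}: missing '# fs=<rate>' header line")


def read_signal(path) -> tuple[np.ndarray, float]:
    """Read a ``time_s, value`` CSV; returns (values, fs)."""
    fs = _read_fs(path)
    df = pd.read_csv(path, comment="#")
    return df["value"].to_numpy(dtype=float), fs


def write_signal(path, values, fs: float) -> None:
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) / fs
    with open(path, "w") as fh:
        fh.write(f"# fs={fs}\n")
        pd.DataFrame({"time_s": t, "value": values}).to_csv(fh, index=False)


_LOG_COLUMNS = ("target", "q", "qdot", "qi", "torque_human", "torque_est",
                "torque_assist", "torque_interaction", "emg", "envelope",
                "kj", "gain_k")


def write_trial_log(path, log: TrialLog) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={log.fs}\n")
        data = {"time_s": log.t}
        data.update({c: getattr(log, c) for c in _LOG_COLUMNS})
        pd.DataFrame(data).to_csv(fh, index=False)


def read_trial_log(path) -> TrialLog:
    fs = _read_fs(path)
    df = pd.read_csv(path, comment="#")
    return TrialLog(fs=fs, t=df["time_s"].to_numpy(),
                    **{c: df[c].to_numpy() for c in _LOG_COLUMNS})
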