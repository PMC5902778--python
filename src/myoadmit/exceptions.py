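"""Package-specific exception types.

All inherit from builtins so callers can catch broad categories
(``ValueError`` for bad inputs, ``RuntimeError`` for numerical failures).
"""


class SamplingRateError(ValueError):
    """Sampling rate too low for the configured filter bank."""


class NormalizationError(ValueError):
    """EMG normalization is impossible (e.g. zero MVC peak)."""


class SolverError(RuntimeError):
    """An iterative solver failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateDataError(ValueError):
    """Input data carry no usable signal (e.g. all-zero measured torque)."""


class TrialAbortedError(RuntimeError):
    """A simulated trial left its validity envelope (e.g. plant blow-up)."""
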