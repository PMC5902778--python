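"""Subject parameter sets: geometry, Hill constants and activation shape.

A :class:`SubjectParams` bundles everything the EMG-driven model needs
for one muscle (the TA): straight-line path geometry (OA, OB), Hill
constants (Fmx, lst, l0, phi0), the activation-curve shape parameter A
and the stiffness constant gamma.  Parameter files are plain YAML with
the keys ``OA_m, OB_m, l0_m, phi0_rad, Fmx_N, lst_m, A, lambda, gamma``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import yaml

from .activation import ActivationCurve, solve_activation_curve
from .musculotendon import GeometryParams, HillParams
from .stiffness import GAMMA

__all__ = ["SubjectParams", "default_subject", "load_subject", "save_subject"]


@dataclass
class SubjectParams:
    """Complete parameter set for one muscle-joint pair."""

    OA: float
    OB: float
    l0: float
    phi0: float
    Fmx: float
    lst: float
    A: float
    lam: float = 0.15
    gamma: float = GAMMA

    _curve: ActivationCurve | None = field(default=None, repr=False,
                                           compare=False)

    @property
    def geometry(self) -> GeometryParams:
        return GeometryParams(OA=self.OA, OB=self.OB)

    @property
    def hill(self) -> HillParams:
        return HillParams(Fmx=self.Fmx, lst=self.lst, l0=self.l0,
                          phi0=self.phi0, lam=self.lam)

    @property
    def curve(self) -> ActivationCurve:
        if self._curve is None or self._curve.A != self.A:
            self._curve = solve_activation_curve(self.A)
        return self._curve

    def with_fit(self, A: float, lst: float, Fmx: float) -> "SubjectParams":
        """Copy with the three calibrated parameters replaced."""
        return replace(self, A=A, lst=lst, Fmx=Fmx, _curve=None)

    def to_dict(self) -> dict:
        return {
            "OA_m": self.OA, "OB_m": self.OB, "l0_m": self.l0,
            "phi0_rad": self.phi0, "Fmx_N": self.Fmx, "lst_m": self.lst,
            "A": self.A, "lambda": self.lam, "gamma": self.gamma,
        }


def _from_dict(d: dict) -> SubjectParams:
    return SubjectParams(
        OA=float(d["OA_m"]), OB=float(d["OB_m"]), l0=float(d["l0_m"]),
        phi0=float(d["phi0_rad"]), Fmx=float(d["Fmx_N"]),
        lst=float(d["lst_m"]), A=float(d["A"]),
        lam=float(d.get("lambda", 0.15)),
        gamma=float(d.get("gamma", GAMMA)),
    )


def default_subject() -> SubjectParams:
    """Generic adult TA parameter set shipped with the package."""
    text = (importlib.resources.files("myoadmit") / "data" /
            "ta_default.yaml").read_text()
    return _from_dict(yaml.safe_load(text))


def load_subject(path) -> SubjectParams:
    with open(path) as fh:
        return _from_dict(yaml.safe_load(fh))


def save_subject(subject: SubjectParams, path, extra: dict | None = None) -> None:
    d = subject.to_dict()
    if extra:
        d.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
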