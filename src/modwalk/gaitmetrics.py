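"""Propulsion and step-length symmetry metrics from treadmill ground
reaction forces.

Paretic propulsion (Pp) is the paretic leg's positive anterior impulse
(time integral of the anterior GRF where it is positive) divided by the sum
of both legs' positive anterior impulses; paretic step ratio (PSR) is the
paretic step length over the stride length.  Both equal 0.5 for symmetric
walking; the deviation from symmetry is |value - 0.5|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, UndefinedMetricError


@dataclass
class GRFTrace:
    """Per-belt vertical (fz) and anterior-posterior (fy, anterior positive)
    force time series in newtons."""

    fz_paretic: np.ndarray
    fz_nonparetic: np.ndarray
    fy_paretic: np.ndarray
    fy_nonparetic: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        arrays = [
            np.asarray(a, dtype=float)
            for a in (
                self.fz_paretic,
                self.fz_nonparetic,
                self.fy_paretic,
                self.fy_nonparetic,
            )
        ]
        (self.fz_paretic, self.fz_nonparetic,
         self.fy_paretic, self.fy_nonparetic) = arrays
        lengths = {a.size for a in arrays}
        if len(lengths) != 1:
            raise ValueError("all GRF channels must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")


@dataclass
class StepLengths:
    """Per-step paretic and nonparetic step lengths (m)."""

    paretic: np.ndarray
    nonparetic: np.ndarray

    def __post_init__(self) -> None:
        self.paretic = np.atleast_1d(np.asarray(self.paretic, dtype=float))
        self.nonparetic = np.atleast_1d(np.asarray(self.nonparetic, dtype=float))


@dataclass
class PropulsionMetrics:
    pp: float
    psr: float

    @property
    def pp_deviation(self) -> float:
        return symmetry_deviation(self.pp)

    @property
    def psr_deviation(self) -> float:
        return symmetry_deviation(self.psr)


def anterior_impulse(trace: GRFTrace, leg: str) -> float:
    """Trapezoidal integral of the positive part of the anterior GRF (N*s)."""
    fy = getattr(trace, f"fy_{leg}")
    if fy.size < 2:
        raise InsufficientDataError("anterior force trace too short to integrate")
    return float(np.trapezoid(np.clip(fy, 0.0, None), dx=1.0 / trace.fs_hz))


def paretic_propulsion(trace: GRFTrace) -> float:
    """Pp = I_paretic / (I_paretic + I_nonparetic)."""
    ip = anterior_impulse(trace, "paretic")
    inp = anterior_impulse(trace, "nonparetic")
    total = ip + inp
    if total <= 0:
        raise UndefinedMetricError("both positive anterior impulses are zero")
    return ip / total


def paretic_step_ratio(steps: StepLengths) -> float:
    """PSR = mean paretic step length / mean stride length."""
    p = float(np.mean(steps.paretic))
    np_ = float(np.mean(steps.nonparetic))
    stride = p + np_
    if stride <= 0:
        raise ValueError("stride length must be positive")
    return p / stride


def symmetry_deviation(value: float) -> float:
    """|value - 0.5|; 0 means perfect symmetry."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"value must be in [0, 1], got {value}")
    return abs(value - 0.5)


def propulsion_metrics(trace: GRFTrace, steps: StepLengths) -> PropulsionMetrics:
    return PropulsionMetrics(paretic_propulsion(trace), paretic_step_ratio(steps))
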