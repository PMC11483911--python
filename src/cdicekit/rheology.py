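"""Viscometry-ramp analysis: Newtonian plateau check and reported viscosity.

The measurement protocol is a 2 min logarithmic shear ramp from 0.5 to
100 1/s sampled every 5 s (24 points).  Simple viscous liquids show a
constant viscosity at high shear; the value at 100 1/s is reported.  The
synthetic generator adds an optional low-shear artifact ``eta (1 +
c/shear_rate)`` — the signature of surface films or instrument torque
limits at low rates — and multiplicative noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RheologyTrace",
    "ViscosityResult",
    "generate_ramp",
    "report_viscosity",
    "fold_change",
]

RAMP_SHEAR_MIN = 0.5  # 1/s
RAMP_SHEAR_MAX = 100.0  # 1/s
RAMP_DURATION = 120.0  # s
RAMP_INTERVAL = 5.0  # s


@dataclass(frozen=True)
class RheologyTrace:
    """One shear ramp: strictly increasing rates and positive viscosities."""

    shear_rates: np.ndarray  # 1/s
    viscosities: np.ndarray  # Pa s
    sample_interval: float = RAMP_INTERVAL  # s

    def __post_init__(self) -> None:
        rates = np.asarray(self.shear_rates, dtype=float)
        visc = np.asarray(self.viscosities, dtype=float)
        if rates.shape != visc.shape or rates.ndim != 1 or rates.size < 2:
            raise ValueError("shear_rates and viscosities must be matching 1-D series")
        if np.any(np.diff(rates) <= 0):
            raise ValueError("shear rates must be strictly increasing")
        if np.any(visc <= 0):
            raise ValueError("viscosities must be > 0")
        object.__setattr__(self, "shear_rates", rates)
        object.__setattr__(self, "viscosities", visc)


@dataclass(frozen=True)
class ViscosityResult:
    eta_at_100: float  # Pa s, value at the highest shear point
    newtonian: bool
    plateau_cv: float  # coefficient of variation over the upper half-decade


def generate_ramp(
    eta_true: float,
    noise_cv: float = 0.0,
    low_shear_artifact: float = 0.0,
    seed: int | None = None,
    duration: float = RAMP_DURATION,
    interval: float = RAMP_INTERVAL,
    shear_min: float = RAMP_SHEAR_MIN,
    shear_max: float = RAMP_SHEAR_MAX,
) -> RheologyTrace:
    """Simulate a logarithmic viscometry ramp.

    ``eta(shear) = eta_true (1 + artifact/shear) (1 + noise)`` at
    ``duration/interval`` log-spaced rates (24 for the default protocol).
    """
    if eta_true <= 0:
        raise ValueError("eta_true must be > 0")
    n = int(round(duration / interval))
    rates = np.logspace(math.log10(shear_min), math.log10(shear_max), n)
    eta = eta_true * (1.0 + low_shear_artifact / rates)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        eta = eta * (1.0 + rng.normal(0.0, noise_cv, size=n))
    eta = np.clip(eta, 1e-9, None)
    return RheologyTrace(rates, eta, sample_interval=interval)


def report_viscosity(
    trace: RheologyTrace,
    plateau_cv_max: float = 0.05,
    average_plateau: bool = False,
    expected_max_shear: float = RAMP_SHEAR_MAX,
) -> ViscosityResult:
    """Reported viscosity and Newtonian plateau check.

    The reported value is the sample at the highest shear rate (or the
    plateau average with ``average_plateau=True``).  The fluid is called
    Newtonian when the coefficient of variation over the upper half-decade
    of shear rates stays below ``plateau_cv_max``.  A trace that never
    reaches ``expected_max_shear`` is still reported (highest available
    point) with a warning.
    """
    rates, eta = trace.shear_rates, trace.viscosities
    if rates[-1] < expected_max_shear * (1 - 1e-9):
        warnings.warn(
            f"trace tops out at {rates[-1]:.3g} 1/s, below the protocol maximum "
            f"{expected_max_shear:.3g} 1/s; using the highest available point",
            stacklevel=2,
        )
    plateau = eta[rates >= rates[-1] / math.sqrt(10.0)]
    cv = float(plateau.std(ddof=1) / plateau.mean()) if plateau.size > 1 else 0.0
    value = float(plateau.mean()) if average_plateau else float(eta[-1])
    return ViscosityResult(eta_at_100=value, newtonian=cv < plateau_cv_max, plateau_cv=cv)


def fold_change(eta_sample: float, eta_reference: float) -> float:
    """Viscosity ratio of a sample to its reference buffer."""
    if eta_reference <= 0:
        raise ValueError("eta_reference must be > 0")
    if eta_sample <= 0:
        raise ValueError("eta_sample must be > 0")
    return eta_sample / eta_reference
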