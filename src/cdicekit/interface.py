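"""Droplet-fate statistics at the oil--water interface and the
production-to-GUV ledger.

When droplets reach the rotating oil / outer-solution interface they
either stall (incomplete lipid coverage prevents monolayer zipping) or
punch through dragging an oil filament — a comet tail — behind them.
Counts of these fates over sampled frames give the fate fractions; the
ledger compares the enormous droplet production rate at the capillary to
the far smaller number of GUVs a run actually yields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .physics import droplet_frequency, total_droplet_count

__all__ = [
    "FateCounts",
    "FateReport",
    "ProductionLedger",
    "wilson_interval",
    "fate_fractions",
    "production_ledger",
]


@dataclass(frozen=True)
class FateCounts:
    """Droplet fate counts from frame-sampled interface recordings."""

    n_total: int
    n_stalled: int
    n_comet: int
    every_kth_frame: int = 5
    n_frames: int = 50

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_stalled, self.n_comet) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_stalled + self.n_comet != self.n_total:
            raise ValueError(
                f"inconsistent counts: {self.n_stalled} + {self.n_comet} "
                f"!= {self.n_total}"
            )


@dataclass(frozen=True)
class FateReport:
    stalled_pct: float
    comet_pct: float
    stalled_ci_pct: tuple[float, float]  # Wilson 95%
    comet_ci_pct: tuple[float, float]
    n_total: int


_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def wilson_interval(successes: int, n: int, z: float = _Z95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (as fractions)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    p = successes / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(centre - half, 0.0), min(centre + half, 1.0))


def fate_fractions(counts: FateCounts) -> FateReport:
    """Stalled / comet-tail percentages with Wilson 95% intervals."""
    if counts.n_total <= 0:
        raise ValueError("n_total must be > 0")
    stalled = 100.0 * counts.n_stalled / counts.n_total
    comet = 100.0 * counts.n_comet / counts.n_total
    lo_s, hi_s = wilson_interval(counts.n_stalled, counts.n_total)
    lo_c, hi_c = wilson_interval(counts.n_comet, counts.n_total)
    return FateReport(
        stalled_pct=stalled,
        comet_pct=comet,
        stalled_ci_pct=(100 * lo_s, 100 * hi_s),
        comet_ci_pct=(100 * lo_c, 100 * hi_c),
        n_total=counts.n_total,
    )


@dataclass(frozen=True)
class ProductionLedger:
    droplets_per_second: float
    droplets_total: float
    guvs_reported: float
    conversion_ratio: float  # GUVs per droplet
    run_duration_s: float  # time to dispense the total volume


def production_ledger(
    flow_rate: float,
    total_volume: float,
    mean_diameter: float,
    reported_guv_count: float,
) -> ProductionLedger:
    """Connect droplet production to the final GUV count.

    Uses the volumetric frequency ``f = Q / (pi d^3/6)`` and total count
    ``N = V / (pi d^3/6)``; the conversion ratio ``GUVs / N`` quantifies
    how few produced droplets end up as vesicles.
    """
    if min(flow_rate, total_volume, mean_diameter, reported_guv_count) <= 0:
        raise ValueError("all inputs must be > 0")
    f = droplet_frequency(flow_rate, mean_diameter)
    n = total_droplet_count(total_volume, mean_diameter)
    return ProductionLedger(
        droplets_per_second=f,
        droplets_total=n,
        guvs_reported=reported_guv_count,
        conversion_ratio=reported_guv_count / n,
        run_duration_s=total_volume / flow_rate,
    )
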