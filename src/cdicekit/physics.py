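"""Closed-form fluid-dynamic scaling model for droplet formation in cDICE.

cDICE (continuous droplet interface crossing encapsulation) produces
water-in-oil droplets at a capillary orifice inside a rotating chamber;
centrifugal force then drives the droplets through an oil--water interface
where they acquire a second lipid monolayer and become giant unilamellar
vesicles (GUVs).  This module evaluates every dimensionless group and
regime criterion needed to interpret one operating point of such a device:

* tangential flow speed at the orifice ``U = Omega * R_i``,
* capillary number ``Ca = mu U / gamma`` (viscous shear vs. tension),
* Reynolds number ``Re_D = rho U D / mu`` of the cross-flow past the
  capillary and the associated wake regime (steady / vortex shedding /
  three-dimensional),
* critical flow rate separating dripping from inertial jetting,
* predicted droplet diameter from the force balance ``a/D ~ (6 Ca)^-1``,
* slow radial migration speed of droplets under centrifugation,
* wake shear rate and the tension at which shear can no longer break
  droplets of a given radius (``Ca_shear = 1``),
* Bond number and the centrifugal breakthrough condition at the
  oil--outer-solution interface,
* droplet production frequency and total count bookkeeping.

All functions take and return coherent SI units unless stated otherwise;
rotation rates are accepted in rpm (the lab-facing unit) and converted to
rad/s internally.  Every dimensionless output is invariant under a global
change of coherent unit system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable

__all__ = [
    "FluidPhase",
    "DeviceGeometry",
    "OperatingPoint",
    "DimensionlessReport",
    "omega_rad_per_s",
    "tangential_speed",
    "capillary_number",
    "reynolds_number",
    "wake_regime",
    "critical_jetting_flow_rate",
    "breakup_regime",
    "predicted_droplet_diameter",
    "radial_migration_speed",
    "wake_shear_analysis",
    "bond_number",
    "breakthrough_min_tension",
    "breakthrough_condition",
    "droplet_frequency",
    "total_droplet_count",
    "mixture_density",
    "evaluate_operating_point",
    "CA_DRIPPING_THRESHOLD",
    "RE_VORTEX_SHEDDING",
    "RE_THREE_DIMENSIONAL",
]

# Regime thresholds for flow past a circular cylinder: periodic vortex
# shedding above Re ~ 47, three-dimensional wake instabilities above ~150.
RE_VORTEX_SHEDDING = 47.0
RE_THREE_DIMENSIONAL = 150.0

# Order-of-magnitude cut between dripping and shear-dominated breakup.
# "Low Ca" is not quantified by the underlying force balance; 0.1 is an
# order-of-magnitude choice and every caller can override it.
CA_DRIPPING_THRESHOLD = 0.1

_RPM_TO_RAD_S = 2.0 * math.pi / 60.0


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


def omega_rad_per_s(rotation_rate_rpm: float) -> float:
    """Convert a rotation rate from rpm to rad/s."""
    _require(rotation_rate_rpm >= 0, "rotation rate must be >= 0")
    return rotation_rate_rpm * _RPM_TO_RAD_S


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluidPhase:
    """A liquid phase characterised by density and dynamic viscosity.

    Parameters
    ----------
    name : str
        Human-readable label ("LOD", "G-buffer + 18.5% OptiPrep", ...).
    density : float
        Mass density in kg m^-3.  Must be positive.
    viscosity : float
        Dynamic viscosity in Pa s.  Must be positive.
    """

    name: str
    density: float
    viscosity: float

    def __post_init__(self) -> None:
        _require(self.density > 0, f"density must be > 0, got {self.density}")
        _require(self.viscosity > 0, f"viscosity must be > 0, got {self.viscosity}")


@dataclass(frozen=True)
class DeviceGeometry:
    """Geometry of one rotating-chamber device, all lengths in metres.

    Attributes
    ----------
    capillary_inner_diameter, capillary_outer_diameter : float
        Inner bore and outer (coated) diameter of the injection capillary.
    r_inner : float
        Distance from the rotation axis to the capillary orifice.
    r_outer : float
        Distance from the rotation axis to the oil / outer-solution
        interface.
    wake_length_min, wake_length_max : float
        Bounds on the characteristic length scale of the shear layer in the
        capillary wake (capillary outer diameter up to the capillary-to-wall
        distance).
    total_inner_volume : float
        Total dispensed inner-solution volume per experiment, in m^3.
    """

    capillary_inner_diameter: float
    capillary_outer_diameter: float
    r_inner: float
    r_outer: float
    wake_length_min: float
    wake_length_max: float
    total_inner_volume: float

    def __post_init__(self) -> None:
        for name in (
            "capillary_inner_diameter",
            "capillary_outer_diameter",
            "r_inner",
            "r_outer",
            "wake_length_min",
            "wake_length_max",
            "total_inner_volume",
        ):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(
            self.wake_length_min <= self.wake_length_max,
            "wake_length_min must be <= wake_length_max",
        )
        _require(self.r_inner < self.r_outer, "r_inner must be < r_outer")


@dataclass(frozen=True)
class OperatingPoint:
    """One run condition: rotation rate, flow rate and tension bracket.

    ``rotation_rate`` is in rpm; ``flow_rate`` in m^3 s^-1; the interfacial
    tension between inner solution and oil is specified as a
    (low, high) bracket in N m^-1 because only its order of magnitude is
    known for surfactant-laden interfaces.
    """

    rotation_rate: float
    flow_rate: float
    interfacial_tension_low: float
    interfacial_tension_high: float
    name: str = ""

    def __post_init__(self) -> None:
        _require(self.rotation_rate >= 0, "rotation_rate must be >= 0")
        _require(self.flow_rate >= 0, "flow_rate must be >= 0")
        _require(
            0 < self.interfacial_tension_low <= self.interfacial_tension_high,
            "need 0 < tension_low <= tension_high",
        )


@dataclass
class DimensionlessReport:
    """All scaling quantities evaluated for one operating point.

    Dimensionless groups are unit-system invariant; dimensional entries are
    SI.  ``ca`` and droplet-size-dependent groups are evaluated at the low
    end of the tension bracket (the physically relevant, surfactant-covered
    limit); ranges over the wake length bracket are stored as (min, max).
    """

    u: float
    u_r: float
    ca: float
    re_d: float
    shear_rate_range: tuple[float, float]
    ca_shear_range: tuple[float, float]
    limiting_tension_range: tuple[float, float]
    bo: float
    breakthrough_tension: float
    breakup_regime: str
    wake_regime: str
    jetting_flow_rate: float
    predicted_diameter: float
    droplet_radius: float
    operating_point: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def to_flat_dict(self) -> dict:
        """Flatten range tuples for CSV serialisation."""
        d = self.to_dict()
        for key in ("shear_rate_range", "ca_shear_range", "limiting_tension_range"):
            lo, hi = d.pop(key)
            base = key.replace("_range", "")
            d[f"{base}_min"] = lo
            d[f"{base}_max"] = hi
        return d


# ---------------------------------------------------------------------------
# Scaling relations
# ---------------------------------------------------------------------------


def tangential_speed(rotation_rate: float, r_inner: float) -> float:
    """Tangential flow speed ``U = Omega R_i`` at the capillary orifice.

    Parameters
    ----------
    rotation_rate : float
        Chamber rotation rate in rpm.
    r_inner : float
        Orifice-to-axis distance in metres.

    Returns
    -------
    float
        Speed in m s^-1.
    """
    _require(rotation_rate >= 0 and r_inner >= 0, "inputs must be >= 0")
    return omega_rad_per_s(rotation_rate) * r_inner


def capillary_number(viscosity: float, speed: float, tension: float) -> float:
    """Capillary number ``Ca = mu U / gamma`` (viscous vs. tension forces)."""
    _require(tension > 0, "tension must be > 0")
    _require(viscosity >= 0 and speed >= 0, "inputs must be >= 0")
    return viscosity * speed / tension


def reynolds_number(density: float, speed: float, diameter: float, viscosity: float) -> float:
    """Reynolds number ``Re_D = rho U D / mu`` of flow past the capillary."""
    _require(viscosity > 0, "viscosity must be > 0")
    _require(density >= 0 and speed >= 0 and diameter >= 0, "inputs must be >= 0")
    return density * speed * diameter / viscosity


def wake_regime(re_d: float) -> str:
    """Classify the capillary wake from the cylinder-flow Reynolds number.

    ``steady`` below Re = 47, ``vortex_shedding`` for 47 <= Re < 150
    (periodic Karman shedding) and ``three_dimensional`` above 150.
    """
    _require(re_d >= 0, "Re_D must be >= 0")
    if re_d < RE_VORTEX_SHEDDING:
        return "steady"
    if re_d < RE_THREE_DIMENSIONAL:
        return "vortex_shedding"
    return "three_dimensional"


def critical_jetting_flow_rate(
    capillary_inner_diameter: float, tension: float, inner_density: float
) -> float:
    """Critical flow rate ``pi (D^3 gamma / 2 rho_i)^(1/2)`` above which
    droplet formation transitions from dripping/shear to inertial jetting.

    ``tension = 0`` is allowed and returns 0 (no tension, no dripping
    threshold); all other inputs must be positive.
    """
    _require(capillary_inner_diameter > 0, "capillary diameter must be > 0")
    _require(inner_density > 0, "inner density must be > 0")
    _require(tension >= 0, "tension must be >= 0")
    return math.pi * math.sqrt(capillary_inner_diameter**3 * tension / (2.0 * inner_density))


def breakup_regime(
    flow_rate: float,
    critical_flow_rate: float,
    ca: float,
    ca_dripping_threshold: float = CA_DRIPPING_THRESHOLD,
) -> str:
    """Label the droplet formation mechanism.

    ``jetting`` when the flow rate reaches the inertial-jetting threshold,
    otherwise ``dripping`` for low capillary number (monodisperse pinch-off
    at the orifice) and ``shear_unstable`` when viscous shear deforms the
    emerging drop and breakup happens at the end of a liquid filament.
    """
    _require(flow_rate >= 0 and critical_flow_rate >= 0 and ca >= 0, "inputs must be >= 0")
    if flow_rate >= critical_flow_rate:
        return "jetting"
    if ca < ca_dripping_threshold:
        return "dripping"
    return "shear_unstable"


def predicted_droplet_diameter(capillary_outer_diameter: float, ca: float) -> float:
    """Droplet diameter from the force balance ``a/D ~ (6 Ca)^-1``.

    Balancing the retaining tension force ``~ pi D gamma`` against the
    viscous drag ``~ 6 pi mu a U`` gives the radius above which breakup is
    expected, ``a = D / (6 Ca)``; the returned diameter is ``D / (3 Ca)``.
    """
    _require(capillary_outer_diameter > 0, "capillary diameter must be > 0")
    _require(ca > 0, "Ca must be > 0")
    return capillary_outer_diameter / (3.0 * ca)


def radial_migration_speed(
    delta_density: float,
    droplet_radius: float,
    rotation_rate: float,
    r_inner: float,
    viscosity: float,
) -> float:
    """Radial (outward) droplet speed ``U_r = drho a^2 Omega^2 R_i / mu``.

    Balance of centrifugal buoyancy against Stokes drag; this is the slow
    transport that carries droplets from the capillary to the oil--water
    interface, two orders of magnitude below the tangential speed.
    """
    _require(viscosity > 0, "viscosity must be > 0")
    _require(droplet_radius >= 0 and r_inner >= 0, "lengths must be >= 0")
    omega = omega_rad_per_s(rotation_rate)
    return delta_density * droplet_radius**2 * omega**2 * r_inner / viscosity


def wake_shear_analysis(
    rotation_rate: float,
    r_inner: float,
    wake_length_range: tuple[float, float],
    viscosity: float,
    droplet_radius: float,
    tension: float | None = None,
) -> tuple[tuple[float, float], tuple[float, float] | None, tuple[float, float]]:
    """Shear-rate bracket in the capillary wake and the breakup-limiting tension.

    The characteristic shear rate is ``eps = Omega R_i / l`` with ``l``
    spanning ``wake_length_range``.  A droplet of radius ``a`` stops being
    broken up by this shear when ``Ca_shear = mu eps a / gamma`` drops to 1,
    i.e. for tensions above ``gamma_lim = mu eps a``.

    Returns
    -------
    (shear_rate_range, ca_shear_range, limiting_tension_range)
        Each a (min, max) tuple; ``ca_shear_range`` is None unless a
        tension is supplied.  Ranges are ordered by magnitude (the shortest
        wake length gives the largest shear rate).
    """
    l_min, l_max = wake_length_range
    _require(l_min > 0 and l_max > 0, "wake lengths must be > 0")
    _require(l_min <= l_max, "wake_length_range must be ordered")
    _require(r_inner > 0, "r_inner must be > 0")
    _require(viscosity > 0, "viscosity must be > 0")
    _require(droplet_radius >= 0, "droplet radius must be >= 0")
    omega = omega_rad_per_s(rotation_rate)
    eps_lo = omega * r_inner / l_max
    eps_hi = omega * r_inner / l_min
    gamma_lim = (viscosity * eps_lo * droplet_radius, viscosity * eps_hi * droplet_radius)
    ca_shear = None
    if tension is not None:
        _require(tension > 0, "tension must be > 0")
        ca_shear = (
            viscosity * eps_lo * droplet_radius / tension,
            viscosity * eps_hi * droplet_radius / tension,
        )
    return (eps_lo, eps_hi), ca_shear, gamma_lim


def bond_number(
    delta_density: float,
    rotation_rate: float,
    r_outer: float,
    droplet_radius: float,
    tension: float,
) -> float:
    """Centrifugal Bond number ``Bo = drho (Omega^2 R_o) r^2 / gamma``.

    Ratio of the centrifugal body force on a droplet of radius ``r`` at the
    oil--outer-solution interface (acceleration ``Omega^2 R_o``) to the
    restoring interfacial-tension force.  ``Bo ~ 1`` marks the onset of
    interface deformation (comet-tail formation).
    """
    _require(tension > 0, "tension must be > 0")
    _require(droplet_radius >= 0 and r_outer >= 0, "lengths must be >= 0")
    omega = omega_rad_per_s(rotation_rate)
    return delta_density * omega**2 * r_outer * droplet_radius**2 / tension


def breakthrough_min_tension(
    delta_density: float,
    rotation_rate: float,
    r_outer: float,
    droplet_radius: float,
) -> float:
    """Largest tension a droplet of radius ``a`` can still cross.

    The breakthrough condition for a sphere to pass an interface of tension
    ``gamma`` under centrifugal forcing is
    ``drho Omega^2 R_o a^2 / gamma >= 3/2``; solving for the tension gives
    ``gamma_max = (2/3) drho Omega^2 R_o a^2``.
    """
    _require(
        delta_density >= 0 and rotation_rate >= 0 and r_outer >= 0 and droplet_radius >= 0,
        "inputs must be >= 0",
    )
    omega = omega_rad_per_s(rotation_rate)
    return (2.0 / 3.0) * delta_density * omega**2 * r_outer * droplet_radius**2


def breakthrough_condition(
    delta_density: float,
    rotation_rate: float,
    r_outer: float,
    droplet_radius: float,
    tension: float,
) -> bool:
    """True when a droplet of radius ``a`` can cross the interface."""
    _require(tension >= 0, "tension must be >= 0")
    return tension <= breakthrough_min_tension(
        delta_density, rotation_rate, r_outer, droplet_radius
    )


def droplet_frequency(flow_rate: float, mean_diameter: float) -> float:
    """Droplet production frequency ``f = Q / (pi d^3 / 6)`` in s^-1."""
    _require(mean_diameter > 0, "mean diameter must be > 0")
    _require(flow_rate >= 0, "flow rate must be >= 0")
    return flow_rate / (math.pi * mean_diameter**3 / 6.0)


def total_droplet_count(total_volume: float, mean_diameter: float) -> float:
    """Number of droplets in a dispensed volume, ``N = V / (pi d^3 / 6)``."""
    _require(mean_diameter > 0, "mean diameter must be > 0")
    _require(total_volume >= 0, "total volume must be >= 0")
    return total_volume / (math.pi * mean_diameter**3 / 6.0)


def mixture_density(
    components: Iterable[tuple[float, float]], tolerance: float = 1e-6
) -> float:
    """Volume-weighted mean density of a mixture.

    Parameters
    ----------
    components : iterable of (density, volume_fraction)
        Fractions must be non-negative and sum to 1 within ``tolerance``.
    """
    comps = list(components)
    _require(len(comps) > 0, "need at least one component")
    total = 0.0
    rho = 0.0
    for density, fraction in comps:
        _require(fraction >= 0, "volume fractions must be >= 0")
        _require(density > 0, "densities must be > 0")
        total += fraction
        rho += density * fraction
    _require(abs(total - 1.0) <= tolerance, f"volume fractions sum to {total}, not 1")
    return rho


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------


def evaluate_operating_point(
    inner: FluidPhase,
    oil: FluidPhase,
    geometry: DeviceGeometry,
    op: OperatingPoint,
    droplet_radius: float | None = None,
    small_droplet_radius: float = 5e-6,
) -> DimensionlessReport:
    """Evaluate every scaling quantity for one operating point.

    Tension-dependent groups (Ca, Bo) use the low end of the tension
    bracket.  ``droplet_radius`` defaults to half the diameter predicted by
    the ``a/D ~ (6 Ca)^-1`` balance and feeds the radial-migration and Bond
    numbers; ``small_droplet_radius`` (default 5 um, the GUV scale) feeds
    the wake-shear and breakthrough analyses, which ask what it takes to
    make and transfer GUV-sized droplets.
    """
    gamma = op.interfacial_tension_low
    u = tangential_speed(op.rotation_rate, geometry.r_inner)
    ca = capillary_number(oil.viscosity, u, gamma)
    re_d = reynolds_number(oil.density, u, geometry.capillary_outer_diameter, oil.viscosity)
    d_pred = predicted_droplet_diameter(geometry.capillary_outer_diameter, ca)
    a = droplet_radius if droplet_radius is not None else d_pred / 2.0
    delta_rho = inner.density - oil.density
    u_r = radial_migration_speed(delta_rho, a, op.rotation_rate, geometry.r_inner, oil.viscosity)
    shear_range, ca_shear_range, gamma_lim_range = wake_shear_analysis(
        op.rotation_rate,
        geometry.r_inner,
        (geometry.wake_length_min, geometry.wake_length_max),
        oil.viscosity,
        small_droplet_radius,
        tension=gamma,
    )
    bo = bond_number(delta_rho, op.rotation_rate, geometry.r_outer, a, gamma)
    gamma_max = breakthrough_min_tension(
        delta_rho, op.rotation_rate, geometry.r_outer, small_droplet_radius
    )
    q_crit = critical_jetting_flow_rate(
        geometry.capillary_inner_diameter, gamma, inner.density
    )
    return DimensionlessReport(
        u=u,
        u_r=u_r,
        ca=ca,
        re_d=re_d,
        shear_rate_range=shear_range,
        ca_shear_range=ca_shear_range,
        limiting_tension_range=gamma_lim_range,
        bo=bo,
        breakthrough_tension=gamma_max,
        breakup_regime=breakup_regime(op.flow_rate, q_crit, ca),
        wake_regime=wake_regime(re_d),
        jetting_flow_rate=q_crit,
        predicted_diameter=d_pred,
        droplet_radius=a,
        operating_point=op.name,
    )
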