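"""Named fluid/geometry constants, run presets and YAML config loading.

The YAML schema mirrors the dataclasses in :mod:`cdicekit.physics`::

    fluids:
      inner: {name: ..., density: <kg/m^3>, viscosity: <Pa s>}
      oil:   {name: ..., density: <kg/m^3>, viscosity: <Pa s>}
    geometry:
      capillary_inner_diameter: <m>
      capillary_outer_diameter: <m>
      r_inner: <m>
      r_outer: <m>
      wake_length_min: <m>
      wake_length_max: <m>
      total_inner_volume: <m^3>
    operating_points:
      - name: ...
        rotation_rate: <rpm>
        flow_rate_ul_per_min: <uL/min>      # or flow_rate: <m^3/s>
        interfacial_tension_low: <N/m>
        interfacial_tension_high: <N/m>

Two density conventions circulate for the oil and sugar-laden buffers
(a nominal main-text value and a weighed laboratory value); both are kept
as named constants and the nominal ones drive the default presets.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .physics import DeviceGeometry, FluidPhase, OperatingPoint

__all__ = [
    "RunConfig",
    "PRESETS",
    "DEFAULT_GEOMETRY",
    "LOD",
    "GBUFFER_OPTIPREP",
    "MRB80_SUCROSE",
    "LOD_DENSITY_NOMINAL",
    "LOD_DENSITY_WEIGHED",
    "MRB80_SUCROSE_DENSITY_NOMINAL",
    "MRB80_SUCROSE_DENSITY_WEIGHED",
    "GBUFFER_OPTIPREP_DENSITY_WEIGHED",
    "UL_PER_MIN",
    "load_config",
    "dump_config",
]

#: 1 uL/min in m^3/s.
UL_PER_MIN = 1e-9 / 60.0

# Lipid-in-oil dispersion (4:1 silicone:mineral oil).  Nominal density from
# the scaling analysis; weighed density from tensiometry sample prep.
LOD_DENSITY_NOMINAL = 934.0
LOD_DENSITY_WEIGHED = 868.5
LOD_VISCOSITY = 4e-3

# Inner solutions.  MRB80 + 1.75% w/v sucrose: nominal vs. weighed;
# G-buffer + 18.5% v/v OptiPrep: weighed (matches the volume-weighted
# mixture estimate of 1320/998 kg/m^3 components to 0.02%).
MRB80_SUCROSE_DENSITY_NOMINAL = 1018.3
MRB80_SUCROSE_DENSITY_WEIGHED = 1006.6
GBUFFER_OPTIPREP_DENSITY_WEIGHED = 1057.4

LOD = FluidPhase("LOD (4:1 silicone:mineral oil)", LOD_DENSITY_NOMINAL, LOD_VISCOSITY)
GBUFFER_OPTIPREP = FluidPhase(
    "G-buffer + 18.5% v/v OptiPrep", GBUFFER_OPTIPREP_DENSITY_WEIGHED, 1.58e-3
)
MRB80_SUCROSE = FluidPhase(
    "MRB80 + 1.75% w/v sucrose", MRB80_SUCROSE_DENSITY_NOMINAL, 1.57e-3
)

# 100 um ID fused-silica capillary, 363 um polyimide-coated OD; orifice
# ~1 cm from the axis; oil/outer-solution interface placed 2.5 mm inboard
# of the 17.5 mm chamber radius; wake shear length between the capillary
# OD scale (~0.5 mm) and the capillary-to-wall distance (~5 mm).
DEFAULT_GEOMETRY = DeviceGeometry(
    capillary_inner_diameter=100e-6,
    capillary_outer_diameter=363e-6,
    r_inner=0.01,
    r_outer=0.015,
    wake_length_min=0.5e-3,
    wake_length_max=5e-3,
    total_inner_volume=100e-9,  # 100 uL
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to evaluate one cDICE run."""

    inner: FluidPhase
    oil: FluidPhase
    geometry: DeviceGeometry
    operating_points: tuple[OperatingPoint, ...]


def _op(name: str, rpm: float) -> OperatingPoint:
    return OperatingPoint(
        rotation_rate=rpm,
        flow_rate=25.0 * UL_PER_MIN,
        interfacial_tension_low=1e-3,
        interfacial_tension_high=1e-2,
        name=name,
    )


PRESETS: dict[str, RunConfig] = {
    "default_1900rpm": RunConfig(
        GBUFFER_OPTIPREP, LOD, DEFAULT_GEOMETRY, (_op("default_1900rpm", 1900.0),)
    ),
    "low_1000rpm": RunConfig(
        GBUFFER_OPTIPREP, LOD, DEFAULT_GEOMETRY, (_op("low_1000rpm", 1000.0),)
    ),
    "high_2700rpm": RunConfig(
        GBUFFER_OPTIPREP, LOD, DEFAULT_GEOMETRY, (_op("high_2700rpm", 2700.0),)
    ),
}


def _parse_op(entry: dict) -> OperatingPoint:
    entry = dict(entry)
    if "flow_rate_ul_per_min" in entry:
        entry["flow_rate"] = float(entry.pop("flow_rate_ul_per_min")) * UL_PER_MIN
    return OperatingPoint(
        rotation_rate=float(entry["rotation_rate"]),
        flow_rate=float(entry["flow_rate"]),
        interfacial_tension_low=float(entry["interfacial_tension_low"]),
        interfacial_tension_high=float(entry["interfacial_tension_high"]),
        name=str(entry.get("name", "")),
    )


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file (schema in module docs)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    fluids = raw["fluids"]
    inner = FluidPhase(**fluids["inner"])
    oil = FluidPhase(**fluids["oil"])
    geometry = DeviceGeometry(**{k: float(v) for k, v in raw["geometry"].items()})
    ops = tuple(_parse_op(e) for e in raw["operating_points"])
    if not ops:
        raise ValueError("config must define at least one operating point")
    return RunConfig(inner, oil, geometry, ops)


def dump_config(config: RunConfig, path) -> None:
    """Write a :class:`RunConfig` back to YAML (inverse of :func:`load_config`)."""
    raw = {
        "fluids": {
            "inner": vars(config.inner).copy(),
            "oil": vars(config.oil).copy(),
        },
        "geometry": {
            k: getattr(config.geometry, k)
            for k in (
                "capillary_inner_diameter",
                "capillary_outer_diameter",
                "r_inner",
                "r_outer",
                "wake_length_min",
                "wake_length_max",
                "total_inner_volume",
            )
        },
        "operating_points": [
            {
                "name": op.name,
                "rotation_rate": op.rotation_rate,
                "flow_rate": op.flow_rate,
                "interfacial_tension_low": op.interfacial_tension_low,
                "interfacial_tension_high": op.interfacial_tension_high,
            }
            for op in config.operating_points
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
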