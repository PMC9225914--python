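"""Physical scenario definitions for the mild-moxibustion thermal model.

A scenario bundles everything the solver needs: the layered tissue block
(skin / fat / muscle with Pennes coefficients), the moxa stick geometry,
its burning-temperature schedule, the stick-to-skin distance, the ambient
temperature and the treatment duration.  Temperatures are stored in degrees
Celsius throughout; conversion to Kelvin happens only inside the radiation
routines.  Lengths on tissue objects are metres; the stick diameter and the
stick-to-skin distance are millimetres because that is how practitioners
quote them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import yaml

from .source import BurnSchedule

__all__ = [
    "TissueLayer",
    "BloodProperties",
    "TissueBlock",
    "MoxaStick",
    "SurfaceExchange",
    "ScenarioConfig",
    "ConfigError",
    "default_tissue_block",
    "standard_condition",
    "validation_condition",
    "load_scenario",
    "dump_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
]


class ConfigError(ValueError):
    """Raised when a scenario configuration is malformed or non-physical."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigError(field_name, message)


@dataclass(frozen=True)
class TissueLayer:
    """One tissue stratum with its thermal and Pennes perfusion properties.

    ``perfusion_rate`` is the blood mass flow per unit tissue volume
    (kg·m⁻³·s⁻¹) and ``metabolic_heat`` the volumetric metabolic source
    (W·m⁻³); both enter the bioheat equation as
    ``ω_b·C_b·(T_b − T) + q_m``.
    """

    name: str
    thickness: float  # m
    density: float  # kg m^-3
    specific_heat: float  # J kg^-1 K^-1
    conductivity: float  # W m^-1 K^-1
    perfusion_rate: float = 0.0  # kg m^-3 s^-1
    metabolic_heat: float = 0.0  # W m^-3

    def __post_init__(self) -> None:
        _require(self.thickness > 0, "thickness", "must be positive")
        _require(self.density > 0, "density", "must be positive")
        _require(self.specific_heat > 0, "specific_heat", "must be positive")
        _require(self.conductivity > 0, "conductivity", "must be positive")
        _require(self.perfusion_rate >= 0, "perfusion_rate", "must be non-negative")
        _require(self.metabolic_heat >= 0, "metabolic_heat", "must be non-negative")

    @property
    def volumetric_heat_capacity(self) -> float:
        """ρ·c in J m^-3 K^-1."""
        return self.density * self.specific_heat

    @property
    def diffusivity(self) -> float:
        """k/(ρ·c) in m² s^-1."""
        return self.conductivity / self.volumetric_heat_capacity


@dataclass(frozen=True)
class BloodProperties:
    """Arterial blood entering the perfusion sink: C_b and T_b."""

    specific_heat: float = 3617.0  # J kg^-1 K^-1
    temperature: float = 37.0  # degC

    def __post_init__(self) -> None:
        _require(self.specific_heat > 0, "blood.specific_heat", "must be positive")
        _require(30.0 <= self.temperature <= 42.0, "blood.temperature",
                 "must lie in [30, 42] degC")


@dataclass(frozen=True)
class TissueBlock:
    """Ordered tissue layers from the surface downward, plus boundary data.

    ``core_temperature`` is the Dirichlet temperature at the bottom of the
    block; ``initial_surface_temperature``, when set, is the disk-average
    surface temperature the pre-treatment steady state is matched to.
    """

    layers: tuple[TissueLayer, ...]
    blood: BloodProperties = field(default_factory=BloodProperties)
    lateral_radius: float = 0.050  # m
    core_temperature: float = 37.0  # degC
    initial_surface_temperature: float | None = None  # degC disk average

    def __post_init__(self) -> None:
        _require(len(self.layers) >= 1, "layers", "at least one layer required")
        _require(self.lateral_radius >= 0.040, "lateral_radius",
                 "surface probes extend to 40 mm; radius must be >= 0.040 m")

    @property
    def total_depth(self) -> float:
        return sum(layer.thickness for layer in self.layers)

    def layer_boundaries(self) -> list[float]:
        """z-coordinates of layer interfaces, z = 0 at the bottom of the block
        and z = total_depth at the skin surface."""
        zs = [self.total_depth]
        for layer in self.layers:
            zs.append(zs[-1] - layer.thickness)
        zs[-1] = 0.0  # clamp rounding
        return zs[::-1]

    def layer_at(self, z: float) -> TissueLayer:
        """Layer containing depth coordinate z (0 = bottom)."""
        depth_from_surface = self.total_depth - z
        acc = 0.0
        for layer in self.layers:
            acc += layer.thickness
            if depth_from_surface <= acc + 1e-12:
                return layer
        return self.layers[-1]


@dataclass(frozen=True)
class MoxaStick:
    """Moxa stick whose glowing end is modelled as a sphere of radius
    diameter/2 hovering above the skin."""

    diameter: float = 18.0  # mm
    emissivity: float = 0.90

    def __post_init__(self) -> None:
        _require(self.diameter > 0, "stick.diameter", "must be positive")
        _require(0.0 < self.emissivity <= 1.0, "stick.emissivity",
                 "must lie in (0, 1]")

    @property
    def radius_m(self) -> float:
        return self.diameter * 1e-3 / 2.0


@dataclass(frozen=True)
class SurfaceExchange:
    """Radiative surface properties for the skin/source/surroundings system.

    The skin radiosity follows J = ε·e_b(T) + ρ_d·G with e_b = n²·σ·T⁴.
    """

    source_emissivity: float = 0.90
    skin_emissivity: float = 0.98
    skin_reflectance: float = 0.02
    refractive_index: float = 1.0

    def __post_init__(self) -> None:
        _require(0.0 < self.source_emissivity <= 1.0, "surfaces.source_emissivity",
                 "must lie in (0, 1]")
        _require(0.0 < self.skin_emissivity <= 1.0, "surfaces.skin_emissivity",
                 "must lie in (0, 1]")
        _require(0.0 <= self.skin_reflectance < 1.0, "surfaces.skin_reflectance",
                 "must lie in [0, 1)")
        _require(self.skin_emissivity + self.skin_reflectance <= 1.0 + 1e-12,
                 "surfaces.skin_reflectance",
                 "emissivity + reflectance must not exceed 1")
        _require(self.refractive_index > 0, "surfaces.refractive_index",
                 "must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one mild-moxibustion run."""

    stick: MoxaStick
    schedule: BurnSchedule
    block: TissueBlock
    distance: float  # mm, burning end to skin surface
    ambient_temperature: float  # degC
    duration: float  # s
    surfaces: SurfaceExchange = field(default_factory=SurfaceExchange)

    def __post_init__(self) -> None:
        _require(self.distance > 0, "distance", "must be positive")
        _require(self.duration > 0, "duration", "must be positive")

    @property
    def distance_m(self) -> float:
        return self.distance * 1e-3


# Table of material parameters for the three tissue strata: specific heat
# (J kg^-1 K^-1), density (kg m^-3), conductivity (W m^-1 K^-1).  Perfusion
# rates and metabolic heats are literature-typical defaults exposed to
# calibration; blood C_b = 3617 J kg^-1 K^-1, T_b = 37 degC.
_SKIN = dict(specific_heat=3391.0, density=1109.0, conductivity=0.37,
             perfusion_rate=0.5, metabolic_heat=368.0)
_FAT = dict(specific_heat=2348.0, density=911.0, conductivity=0.21,
            perfusion_rate=0.3, metabolic_heat=180.0)
_MUSCLE = dict(specific_heat=3421.0, density=1090.0, conductivity=0.49,
               perfusion_rate=0.7, metabolic_heat=420.0)

SKIN_THICKNESS = 2.2e-3
FAT_THICKNESS = 12.4e-3
MUSCLE_THICKNESS = 10.4e-3


def default_tissue_block() -> TissueBlock:
    """Three-layer skin/fat/muscle block (2.2 / 12.4 / 10.4 mm, 25 mm total)
    with the standard material parameters."""
    return TissueBlock(layers=(
        TissueLayer(name="skin", thickness=SKIN_THICKNESS, **_SKIN),
        TissueLayer(name="fat", thickness=FAT_THICKNESS, **_FAT),
        TissueLayer(name="muscle", thickness=MUSCLE_THICKNESS, **_MUSCLE),
    ))


def standard_condition() -> ScenarioConfig:
    """Standard operating condition: 600 degC peak burning temperature,
    18 mm stick, 35 mm distance, 25 degC ambient, 15 min treatment."""
    return ScenarioConfig(
        stick=MoxaStick(diameter=18.0),
        schedule=BurnSchedule(max_temperature=600.0),
        block=default_tissue_block(),
        distance=35.0,
        ambient_temperature=25.0,
        duration=900.0,
    )


def validation_condition() -> ScenarioConfig:
    """The in-vivo validation scenario: 18 mm stick held 4 cm above the
    skin for 15 min, with the measured pre-treatment disk-average surface
    temperature of 34.3 degC."""
    base = standard_condition()
    block = replace(base.block, initial_surface_temperature=34.3)
    return replace(base, distance=40.0, block=block)


# ---------------------------------------------------------------------------
# Serialization (YAML key/value dialect)

_SCHEDULE_KEYS = {"max_temperature", "amplitude", "period", "clean_interval",
                  "clean_duration", "clean_temperature"}
_LAYER_KEYS = {"name", "thickness", "density", "specific_heat", "conductivity",
               "perfusion_rate", "metabolic_heat"}
_BLOOD_KEYS = {"specific_heat", "temperature"}
_BLOCK_KEYS = {"layers", "blood", "lateral_radius", "core_temperature",
               "initial_surface_temperature"}
_STICK_KEYS = {"diameter", "emissivity"}
_SURFACE_KEYS = {"source_emissivity", "skin_emissivity", "skin_reflectance",
                 "refractive_index"}
_TOP_KEYS = {"stick", "schedule", "block", "distance", "ambient_temperature",
             "duration", "surfaces"}


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(context, "expected a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(context, f"unknown keys {sorted(unknown)}")


def scenario_from_dict(data: dict[str, Any]) -> ScenarioConfig:
    """Build a validated ScenarioConfig from plain nested mappings.

    Unknown keys anywhere in the tree are rejected; every dataclass
    invariant is enforced on construction.
    """
    _check_keys(data, _TOP_KEYS, "scenario")
    for key in ("stick", "schedule", "block", "distance",
                "ambient_temperature", "duration"):
        if key not in data:
            raise ConfigError(key, "missing required key")

    _check_keys(data["stick"], _STICK_KEYS, "stick")
    stick = MoxaStick(**data["stick"])

    _check_keys(data["schedule"], _SCHEDULE_KEYS, "schedule")
    schedule = BurnSchedule(**data["schedule"])

    block_data = dict(data["block"])
    _check_keys(block_data, _BLOCK_KEYS, "block")
    if "layers" not in block_data:
        raise ConfigError("block.layers", "missing required key")
    layers = []
    for i, layer_data in enumerate(block_data.pop("layers")):
        _check_keys(layer_data, _LAYER_KEYS, f"block.layers[{i}]")
        layers.append(TissueLayer(**layer_data))
    blood_data = block_data.pop("blood", {})
    _check_keys(blood_data, _BLOOD_KEYS, "block.blood")
    block = TissueBlock(layers=tuple(layers), blood=BloodProperties(**blood_data),
                        **block_data)

    surfaces_data = data.get("surfaces", {})
    _check_keys(surfaces_data, _SURFACE_KEYS, "surfaces")
    surfaces = SurfaceExchange(**surfaces_data)

    return ScenarioConfig(
        stick=stick,
        schedule=schedule,
        block=block,
        distance=float(data["distance"]),
        ambient_temperature=float(data["ambient_temperature"]),
        duration=float(data["duration"]),
        surfaces=surfaces,
    )


def scenario_to_dict(scenario: ScenarioConfig) -> dict[str, Any]:
    """Plain nested-mapping form of a scenario (inverse of
    :func:`scenario_from_dict`)."""
    sc = scenario
    return {
        "stick": {"diameter": sc.stick.diameter, "emissivity": sc.stick.emissivity},
        "schedule": {
            "max_temperature": sc.schedule.max_temperature,
            "amplitude": sc.schedule.amplitude,
            "period": sc.schedule.period,
            "clean_interval": sc.schedule.clean_interval,
            "clean_duration": sc.schedule.clean_duration,
            "clean_temperature": sc.schedule.clean_temperature,
        },
        "block": {
            "layers": [
                {
                    "name": layer.name,
                    "thickness": layer.thickness,
                    "density": layer.density,
                    "specific_heat": layer.specific_heat,
                    "conductivity": layer.conductivity,
                    "perfusion_rate": layer.perfusion_rate,
                    "metabolic_heat": layer.metabolic_heat,
                }
                for layer in sc.block.layers
            ],
            "blood": {
                "specific_heat": sc.block.blood.specific_heat,
                "temperature": sc.block.blood.temperature,
            },
            "lateral_radius": sc.block.lateral_radius,
            "core_temperature": sc.block.core_temperature,
            "initial_surface_temperature": sc.block.initial_surface_temperature,
        },
        "distance": sc.distance,
        "ambient_temperature": sc.ambient_temperature,
        "duration": sc.duration,
        "surfaces": {
            "source_emissivity": sc.surfaces.source_emissivity,
            "skin_emissivity": sc.surfaces.skin_emissivity,
            "skin_reflectance": sc.surfaces.skin_reflectance,
            "refractive_index": sc.surfaces.refractive_index,
        },
    }


def load_scenario(source: str) -> ScenarioConfig:
    """Parse a YAML scenario document (text content or a path to a file)."""
    text = source
    if "\n" not in source and source.endswith((".yaml", ".yml")):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("scenario", "document must be a mapping")
    return scenario_from_dict(data)


def dump_scenario(scenario: ScenarioConfig) -> str:
    """Serialize a scenario to its YAML document form."""
    return yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False)
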