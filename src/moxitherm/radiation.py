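"""Surface-to-surface radiative exchange between the burning end and the skin.

The burning end is a sphere of the stick radius hovering ``distance`` above
the skin; each skin-surface element exchanges radiation with that sphere
(view factor F) and with the surroundings at ambient temperature (view
factor 1 − F).  The element irradiation is

    G = F · ε_source · e_b(T_source) + (1 − F) · e_b(T_ambient),

with the blackbody emissive power e_b(T) = n²·σ·T⁴, and the net flux
absorbed by the skin is q_r = ε_skin · (G − e_b(T_skin)).  Skin reflection
(ρ_d ≈ 0.02) is not returned to the source — a single-bounce closure whose
error is far below a percent; the skin radiosity J = ε·e_b + ρ_d·G is
available for diagnostics.

The element→sphere view factor has a closed form when the sphere lies
entirely above the element's plane (always true here, since the centre
height exceeds the sphere radius):  F = R²·H / (H² + r²)^{3/2}, where R is
the sphere radius, H the centre height above the plane and r the element's
radial offset from the axis.  On axis this reduces to (R/d)² with d the
centre distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MoxaStick, ScenarioConfig, SurfaceExchange

__all__ = [
    "STEFAN_BOLTZMANN",
    "SourceGeometry",
    "celsius_to_kelvin",
    "blackbody_emissive_power",
    "view_factor",
    "skin_irradiation",
    "net_absorbed_flux",
    "skin_radiosity",
]

STEFAN_BOLTZMANN = 5.67e-8  # W m^-2 K^-4


@dataclass(frozen=True)
class SourceGeometry:
    """Sphere (the glowing end) above the skin plane."""

    sphere_radius: float  # m
    center_height: float  # m above the skin surface

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.center_height <= self.sphere_radius:
            raise ValueError("center_height must exceed sphere_radius (no contact)")

    @classmethod
    def from_scenario(cls, scenario: ScenarioConfig) -> "SourceGeometry":
        return cls.from_stick(scenario.stick, scenario.distance_m)

    @classmethod
    def from_stick(cls, stick: MoxaStick, distance_m: float) -> "SourceGeometry":
        return cls(sphere_radius=stick.radius_m,
                   center_height=distance_m + stick.radius_m)


def celsius_to_kelvin(temp_c):
    return np.asarray(temp_c, dtype=float) + 273.15


def blackbody_emissive_power(temperature_k, refractive_index: float = 1.0):
    """e_b(T) = n²·σ·T⁴ for an absolute temperature in Kelvin."""
    t = np.asarray(temperature_k, dtype=float)
    if np.any(t < 0):
        raise ValueError("absolute temperature must be non-negative")
    out = refractive_index**2 * STEFAN_BOLTZMANN * t**4
    return out if out.ndim else float(out)


def view_factor(radial_offset, geometry: SourceGeometry):
    """View factor from a skin-surface element at ``radial_offset`` (m)
    from the stick axis to the spherical burning end.

    F = R²·H / (H² + r²)^{3/2}; bounded by (R/H)² on axis and monotonically
    decreasing in both offset and centre height.
    """
    r = np.asarray(radial_offset, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial offset must be non-negative")
    h = geometry.center_height
    f = geometry.sphere_radius**2 * h / (h**2 + r**2) ** 1.5
    return f if f.ndim else float(f)


def skin_irradiation(node_offset, source_temp_c, ambient_temp_c,
                     geometry: SourceGeometry, surfaces: SurfaceExchange):
    """Irradiation G (W m^-2) at skin elements from source plus surroundings."""
    n = surfaces.refractive_index
    f = view_factor(node_offset, geometry)
    j_source = surfaces.source_emissivity * blackbody_emissive_power(
        celsius_to_kelvin(source_temp_c), n)
    e_ambient = blackbody_emissive_power(celsius_to_kelvin(ambient_temp_c), n)
    return f * j_source + (1.0 - f) * e_ambient


def net_absorbed_flux(skin_temp_c, irradiation, surfaces: SurfaceExchange):
    """Net radiative flux absorbed by the skin, q_r = ε·(G − e_b(T_skin));
    negative when the skin is a net emitter."""
    e_skin = blackbody_emissive_power(celsius_to_kelvin(skin_temp_c),
                                      surfaces.refractive_index)
    return surfaces.skin_emissivity * (irradiation - e_skin)


def skin_radiosity(skin_temp_c, irradiation, surfaces: SurfaceExchange):
    """Diagnostic skin radiosity J = ε·e_b(T) + ρ_d·G."""
    e_skin = blackbody_emissive_power(celsius_to_kelvin(skin_temp_c),
                                      surfaces.refractive_index)
    return surfaces.skin_emissivity * e_skin + surfaces.skin_reflectance * irradiation
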