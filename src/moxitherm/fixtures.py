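"""Packaged reference tables, synthetic orthogonal-experiment responses, and
analytic conduction problems used as solver oracles.

The reference tables (materials, factor levels, validation temperature
series, L9 design and its two response columns) ship as CSV inside the
package so every analysis stage runs without any download.  The synthetic
response generator emulates the statistical structure the orthogonal
experiment assumes — additive per-factor level effects on the reference
temperature plus Gaussian noise — with a known ground truth, so the range
analysis and ANOVA can be tested for recovery.  The analytic problems are
closed-form solutions of the bioheat equation in solvable limits, used as
independent oracles for the finite-volume solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "FIXTURE_NAMES",
    "load_fixture",
    "SyntheticDoeSpec",
    "generate_doe_responses",
    "AnalyticProblem",
    "analytic_problem",
]

_FIXTURE_FILES = {
    "table1": "table1_materials.csv",
    "table2": "table2_levels.csv",
    "table3": "table3_validation.csv",
    "table4": "table4_factor_levels.csv",
    "table5": "table5_design.csv",
    "table6": "table6_responses.csv",
    "table7": "table7_responses.csv",
}
FIXTURE_NAMES = tuple(_FIXTURE_FILES)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables by short name
    (``table1`` ... ``table7``)."""
    try:
        filename = _FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}") from None
    path = resources.files("moxitherm.data").joinpath(filename)
    with resources.as_file(path) as p:
        return pd.read_csv(p)


# ---------------------------------------------------------------------------
# Synthetic orthogonal-experiment responses


@dataclass(frozen=True)
class SyntheticDoeSpec:
    """Planted additive model for L9 responses: response = grand_mean +
    Σ_factors effect[factor][level] + N(0, noise_sd).  Effects per factor
    must sum to zero (identifiable parameterization)."""

    grand_mean: float = 40.0  # degC
    effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"A": (-0.5, 0.0, 0.5),
                                 "B": (-1.5, 0.0, 1.5),
                                 "C": (1.2, 0.0, -1.2),
                                 "D": (-1.0, 0.0, 1.0)})
    noise_sd: float = 0.2  # degC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name, eff in self.effects.items():
            if len(eff) != 3:
                raise ValueError(f"factor {name}: exactly 3 level effects required")
            if abs(sum(eff)) > 1e-9:
                raise ValueError(f"factor {name}: effects must sum to zero")

    def planted_optimum(self) -> dict[str, int]:
        """Ground-truth optimal level (1-based) per factor."""
        return {name: int(np.argmax(eff)) + 1
                for name, eff in self.effects.items()}


def generate_doe_responses(spec: SyntheticDoeSpec, design) -> np.ndarray:
    """Nine responses for an orthogonal design under the planted additive
    model; reproducible for a given spec seed."""
    rng = np.random.default_rng(spec.seed)
    responses = np.full(9, spec.grand_mean)
    for col, name in enumerate(design.factor_names):
        eff = spec.effects.get(name, (0.0, 0.0, 0.0))
        responses += np.array([eff[lv - 1] for lv in design.levels[:, col]])
    responses += rng.normal(0.0, spec.noise_sd, size=9)
    return responses


# ---------------------------------------------------------------------------
# Analytic conduction problems (solver oracles)


@dataclass(frozen=True)
class AnalyticProblem:
    """A closed-form reference solution T(z, t) with the parameters the
    matching numerical setup must use."""

    name: str
    description: str
    parameters: dict
    evaluate: Callable[[float, float], float]  # (z_below_surface_m, t_s) -> degC


def analytic_problem(name: str, **overrides) -> AnalyticProblem:
    """Closed-form bioheat solutions in solvable limits.

    - ``uniform_equilibrium``: perfused, insulated tissue relaxes to the
      constant T_b + q_m/(ω_b·C_b).
    - ``semi_infinite_flux``: homogeneous half-space under constant surface
      flux q0; surface rise ΔT(0,t) = (2·q0/k)·sqrt(α·t/π), and at depth
      ΔT(z,t) = (2·q0/k)·sqrt(α·t)·ierfc(z/(2·sqrt(α·t))).
    - ``two_slab_steady``: two slabs in series between fixed temperatures;
      piecewise-linear profile with continuous flux.
    - ``perfusion_relaxation``: spatially uniform tissue approaches its
      equilibrium exponentially at rate ω_b·C_b/(ρ·c).
    """
    if name == "uniform_equilibrium":
        p = dict(blood_temperature=37.0, metabolic_heat=420.0,
                 perfusion_rate=0.7, blood_specific_heat=3617.0)
        p.update(overrides)
        t_eq = p["blood_temperature"] + p["metabolic_heat"] / (
            p["perfusion_rate"] * p["blood_specific_heat"])

        return AnalyticProblem(
            name=name,
            description="uniform perfused equilibrium T_b + q_m/(omega_b C_b)",
            parameters=p,
            evaluate=lambda z, t: t_eq,
        )

    if name == "semi_infinite_flux":
        p = dict(flux=1000.0, conductivity=0.37, density=1109.0,
                 specific_heat=3391.0, initial_temperature=34.0)
        p.update(overrides)
        alpha = p["conductivity"] / (p["density"] * p["specific_heat"])

        def evaluate(z: float, t: float) -> float:
            if t <= 0:
                return p["initial_temperature"]
            s = math.sqrt(alpha * t)
            x = z / (2.0 * s)
            # ierfc(x) = exp(-x^2)/sqrt(pi) - x*erfc(x)
            ierfc = math.exp(-x * x) / math.sqrt(math.pi) - x * math.erfc(x)
            return p["initial_temperature"] + (2.0 * p["flux"] / p["conductivity"]
                                               ) * s * ierfc

        return AnalyticProblem(
            name=name,
            description="half-space under constant surface flux",
            parameters={**p, "diffusivity": alpha},
            evaluate=evaluate,
        )

    if name == "two_slab_steady":
        p = dict(k1=0.37, d1=0.01, k2=0.21, d2=0.015,
                 top_temperature=30.0, bottom_temperature=37.0)
        p.update(overrides)
        r1, r2 = p["d1"] / p["k1"], p["d2"] / p["k2"]
        flux = (p["bottom_temperature"] - p["top_temperature"]) / (r1 + r2)
        t_interface = p["top_temperature"] + flux * r1

        def evaluate(z: float, t: float = 0.0) -> float:
            # z measured downward from the top surface; slab 1 on top
            if z <= p["d1"]:
                return p["top_temperature"] + flux * z / p["k1"]
            return t_interface + flux * (z - p["d1"]) / p["k2"]

        return AnalyticProblem(
            name=name,
            description="series slabs between fixed temperatures",
            parameters={**p, "flux": flux, "interface_temperature": t_interface},
            evaluate=evaluate,
        )

    if name == "perfusion_relaxation":
        p = dict(blood_temperature=37.0, metabolic_heat=0.0,
                 perfusion_rate=0.7, blood_specific_heat=3617.0,
                 density=1090.0, specific_heat=3421.0,
                 initial_temperature=30.0)
        p.update(overrides)
        rate = p["perfusion_rate"] * p["blood_specific_heat"] / (
            p["density"] * p["specific_heat"])
        t_eq = p["blood_temperature"] + p["metabolic_heat"] / (
            p["perfusion_rate"] * p["blood_specific_heat"])

        return AnalyticProblem(
            name=name,
            description="pointwise exponential relaxation toward equilibrium",
            parameters={**p, "rate": rate, "equilibrium": t_eq},
            evaluate=lambda z, t: t_eq + (p["initial_temperature"] - t_eq)
            * math.exp(-rate * t),
        )

    raise KeyError(f"unknown analytic problem {name!r}")
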