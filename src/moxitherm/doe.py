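"""L9(3^4) orthogonal experiment: design, range analysis and ANOVA.

Four factors at three levels each — A: peak burning temperature (600 /
625 / 650 degC), B: stick diameter (12 / 15 / 18 mm), C: stick-to-skin
distance (25 / 30 / 35 mm), D: ambient temperature (17 / 25 / 32 degC) —
assigned to the standard L9 array, so nine simulations stand in for the
full 81-run factorial.  The response is the reference-point temperature
5 mm below the moxibustion point at the end of treatment.

Range analysis (R-method): per factor, K_l is the mean response of the
three runs at level l (the normalized variant K̄_l is the level sum over
all nine runs), R = max_l K_l − min_l K_l ranks the factors, and the
optimal level per factor maximizes K_l.

ANOVA: the factor sum of squares is SS = 3·Σ_l (K_l − grand mean)² with
2 degrees of freedom per factor.  The design is saturated (Σ factor SS
equals the total SS, zero residual df), so no exact error term exists;
F ratios use a pooled error mean square — the mean of the four factor
mean squares by default, or the smallest factor's mean square under the
``pool-smallest-factor`` strategy — and the significance stars are a
display convention keyed to the F ranking, not an inferential claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .config import MoxaStick, ScenarioConfig, standard_condition
from .source import schedule_for_max

__all__ = [
    "FACTOR_NAMES",
    "FACTOR_LEVELS",
    "OrthogonalDesign",
    "RangeAnalysisResult",
    "AnovaResult",
    "build_L9",
    "range_analysis",
    "rank_factors",
    "anova",
    "run_doe",
]

FACTOR_NAMES = ("A", "B", "C", "D")
FACTOR_LABELS = {
    "A": "max_burning_temperature_C",
    "B": "stick_diameter_mm",
    "C": "distance_mm",
    "D": "ambient_C",
}
FACTOR_LEVELS = {
    "A": (600.0, 625.0, 650.0),
    "B": (12.0, 15.0, 18.0),
    "C": (25.0, 30.0, 35.0),
    "D": (17.0, 25.0, 32.0),
}

# standard L9 array, 1-based level indices
_L9 = np.array([
    [1, 1, 1, 1],
    [1, 2, 2, 2],
    [1, 3, 3, 3],
    [2, 1, 2, 3],
    [2, 2, 3, 1],
    [2, 3, 1, 2],
    [3, 1, 3, 2],
    [3, 2, 1, 3],
    [3, 3, 2, 1],
])


@dataclass(frozen=True)
class OrthogonalDesign:
    """A 9-run, 4-factor, 3-level orthogonal array plus the physical level
    values each index decodes to."""

    levels: np.ndarray  # (9, 4) of 1..3
    factor_names: tuple[str, ...] = FACTOR_NAMES
    level_values: dict = None  # factor -> (v1, v2, v3)

    def decoded(self) -> pd.DataFrame:
        """Runs with the physical factor values."""
        data = {"run": np.arange(1, len(self.levels) + 1)}
        for col, name in enumerate(self.factor_names):
            values = self.level_values[name]
            data[name] = [values[lv - 1] for lv in self.levels[:, col]]
        return pd.DataFrame(data)

    def is_balanced(self) -> bool:
        """Every level 3x per factor; every factor-pair covers all 9
        level combinations exactly once."""
        for col in range(self.levels.shape[1]):
            if sorted(np.bincount(self.levels[:, col], minlength=4)[1:]) != [3, 3, 3]:
                return False
        ncols = self.levels.shape[1]
        for a in range(ncols):
            for b in range(a + 1, ncols):
                pairs = {(i, j) for i, j in zip(self.levels[:, a],
                                                self.levels[:, b])}
                if len(pairs) != 9:
                    return False
        return True


def build_L9() -> OrthogonalDesign:
    """The standard L9(3^4) design with the study's factor level values."""
    return OrthogonalDesign(levels=_L9.copy(), factor_names=FACTOR_NAMES,
                            level_values=dict(FACTOR_LEVELS))


@dataclass(frozen=True)
class RangeAnalysisResult:
    """Per-factor level statistics of the R-method."""

    factor_names: tuple[str, ...]
    level_sums: dict  # factor -> array of 3 level sums (sum of 3 responses)
    level_means: dict  # factor -> array of 3 level means (reported as K)
    kbar: dict  # factor -> level sum / 9 (reported as K-bar)
    ranges: dict  # factor -> R = max level mean - min level mean
    optimal_levels: dict  # factor -> 1-based argmax of the level means
    ranking: tuple[str, ...]  # factors by descending R

    @property
    def optimal_combination(self) -> str:
        """Compact label like 'A3B3C1D3'."""
        return "".join(f"{f}{self.optimal_levels[f]}" for f in self.factor_names)

    def table(self, decimals: int = 2) -> pd.DataFrame:
        """Display table mirroring the published layout (half-up rounding
        to ``decimals``; full precision is retained on the result object)."""
        def disp(x):
            return float(np.floor(np.asarray(x) * 10**decimals + 0.5) / 10**decimals)

        rows = {}
        for l in range(3):
            rows[f"K{l + 1}"] = [disp(self.level_means[f][l])
                                 for f in self.factor_names]
        for l in range(3):
            rows[f"Kbar{l + 1}"] = [disp(self.kbar[f][l])
                                    for f in self.factor_names]
        rows["optimal"] = [f"{f}{self.optimal_levels[f]}"
                           for f in self.factor_names]
        rows["R"] = [disp(self.ranges[f]) for f in self.factor_names]
        return pd.DataFrame(rows, index=list(self.factor_names)).T


def range_analysis(design: OrthogonalDesign,
                   responses) -> RangeAnalysisResult:
    """Taguchi range analysis of nine responses ordered as the design rows."""
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (len(design.levels),):
        raise ValueError(f"expected {len(design.levels)} responses, "
                         f"got shape {responses.shape}")
    n_runs = len(responses)
    sums, means, kbar, ranges, optimal = {}, {}, {}, {}, {}
    for col, name in enumerate(design.factor_names):
        level_sum = np.array([responses[design.levels[:, col] == l].sum()
                              for l in (1, 2, 3)])
        count = np.array([(design.levels[:, col] == l).sum() for l in (1, 2, 3)])
        level_mean = level_sum / count
        sums[name] = level_sum
        means[name] = level_mean
        kbar[name] = level_sum / n_runs
        ranges[name] = float(level_mean.max() - level_mean.min())
        optimal[name] = int(np.argmax(level_mean)) + 1
    result = RangeAnalysisResult(
        factor_names=design.factor_names, level_sums=sums, level_means=means,
        kbar=kbar, ranges=ranges, optimal_levels=optimal,
        ranking=())
    return _dc_replace(result, ranking=rank_factors(result))


def rank_factors(result: RangeAnalysisResult) -> tuple[str, ...]:
    """Factors ordered by descending range R; ties fall back to factor-name
    order with a warning."""
    names = list(result.factor_names)
    rs = [result.ranges[f] for f in names]
    if len(set(rs)) < len(rs):
        warnings.warn("tied ranges; ranking ties broken by factor name order",
                      stacklevel=2)
    order = sorted(names, key=lambda f: (-result.ranges[f], names.index(f)))
    return tuple(order)


@dataclass(frozen=True)
class AnovaResult:
    """Saturated-design variance analysis."""

    factor_names: tuple[str, ...]
    sum_squares: dict  # factor -> SS
    dof: dict  # factor -> 2
    mean_squares: dict
    error_mean_square: float
    error_strategy: str
    f_ratios: dict  # factor -> F (NaN for a pooled factor)
    significance: dict  # factor -> display marker
    total_ss: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "SS": [self.sum_squares[f] for f in self.factor_names],
            "df": [self.dof[f] for f in self.factor_names],
            "MS": [self.mean_squares[f] for f in self.factor_names],
            "F": [self.f_ratios[f] for f in self.factor_names],
            "significance": [self.significance[f] for f in self.factor_names],
        }, index=list(self.factor_names))


# display convention: stars by descending F, mirroring the published table
_STARS = ("***", "**", "**", "")


def anova(design: OrthogonalDesign, responses,
          error_strategy: str = "pooled-mean") -> AnovaResult:
    """Variance analysis of the L9 responses.

    ``error_strategy`` is one of ``pooled-mean`` (error MS = mean of the
    four factor MS) or ``pool-smallest-factor`` (the factor with the
    smallest SS is pooled into the error and not tested itself).
    """
    if error_strategy not in ("pooled-mean", "pool-smallest-factor"):
        raise ValueError(f"unknown error_strategy {error_strategy!r}")
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (len(design.levels),):
        raise ValueError("exactly one response per design run required")
    grand = responses.mean()
    total_ss = float(np.sum((responses - grand) ** 2))
    ss, ms = {}, {}
    for col, name in enumerate(design.factor_names):
        level_means = np.array([responses[design.levels[:, col] == l].mean()
                                for l in (1, 2, 3)])
        ss[name] = float(3.0 * np.sum((level_means - grand) ** 2))
        ms[name] = ss[name] / 2.0
    dof = {name: 2 for name in design.factor_names}

    if error_strategy == "pooled-mean":
        error_ms = float(np.mean([ms[f] for f in design.factor_names]))
        pooled = set()
    else:
        smallest = min(design.factor_names, key=lambda f: ss[f])
        error_ms = ms[smallest]
        pooled = {smallest}

    f_ratios = {f: (np.nan if f in pooled or error_ms == 0.0
                    else ms[f] / error_ms)
                for f in design.factor_names}
    tested = [f for f in design.factor_names if f not in pooled]
    by_f = sorted(tested, key=lambda f: -f_ratios[f])
    significance = {f: "" for f in design.factor_names}
    for rank, f in enumerate(by_f):
        significance[f] = _STARS[min(rank, len(_STARS) - 1)]
    return AnovaResult(
        factor_names=design.factor_names, sum_squares=ss, dof=dof,
        mean_squares=ms, error_mean_square=error_ms,
        error_strategy=error_strategy, f_ratios=f_ratios,
        significance=significance, total_ss=total_ss)


def scenario_for_run(design: OrthogonalDesign, row: int,
                     base: ScenarioConfig | None = None) -> ScenarioConfig:
    """Scenario for one design row (0-based) with the row's A/B/C/D values
    substituted into the base scenario."""
    base = base or standard_condition()
    decoded = design.decoded().iloc[row]
    return _dc_replace(
        base,
        schedule=schedule_for_max(float(decoded["A"]), base.schedule),
        stick=MoxaStick(diameter=float(decoded["B"]),
                        emissivity=base.stick.emissivity),
        distance=float(decoded["C"]),
        ambient_temperature=float(decoded["D"]),
    )


def run_doe(base: ScenarioConfig | None = None, settings=None,
            responses=None, error_strategy: str = "pooled-mean"):
    """Execute (or ingest) the nine-run orthogonal experiment and analyze it.

    When ``responses`` is given (e.g. a published response column) the
    simulations are skipped and the statistics are computed on it directly.
    Returns ``(responses, RangeAnalysisResult, AnovaResult)``.
    """
    design = build_L9()
    if responses is None:
        from .solver import run as run_simulation

        out = []
        for row in range(len(design.levels)):
            scenario = scenario_for_run(design, row, base)
            out.append(run_simulation(scenario, settings)
                       .reference_point_temperature)
        responses = np.array(out)
    else:
        responses = np.asarray(responses, dtype=float)
    ra = range_analysis(design, responses)
    an = anova(design, responses, error_strategy=error_strategy)
    return responses, ra, an
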