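"""Finite-volume bioheat solver: grid construction, conservation, analytic
conduction oracles and probe extraction."""

import numpy as np
import pytest

from moxitherm.config import (BloodProperties, TissueBlock, TissueLayer,
                              default_tissue_block, standard_condition)
from moxitherm.fixtures import analytic_problem
from moxitherm.solver import (BioheatSystem, SolverSettings, TemperatureField,
                              build_grid, disk_average, initial_state, run)
from dataclasses import replace


def single_layer_block(*, perfusion=0.0, metabolic=0.0, thickness=0.025,
                       material="skin"):
    props = {
        "skin": dict(density=1109.0, specific_heat=3391.0, conductivity=0.37),
        "muscle": dict(density=1090.0, specific_heat=3421.0, conductivity=0.49),
    }[material]
    return TissueBlock(layers=(TissueLayer(
        name=material, thickness=thickness, perfusion_rate=perfusion,
        metabolic_heat=metabolic, **props),))


class TestGrid:
    def test_interfaces_and_reference_plane_are_vertices(self):
        block = default_tissue_block()
        grid = build_grid(block)
        for plane in (0.0, 10.4e-3, 20.0e-3, 22.8e-3, 25.0e-3):
            assert np.min(np.abs(grid.z - plane)) < 1e-12

    def test_surface_disk_refinement(self):
        settings = SolverSettings()
        grid = build_grid(default_tissue_block(), settings)
        dr_fine = np.diff(grid.r[grid.r <= settings.fine_radius + 1e-12])
        assert np.all(dr_fine <= settings.dr / 2 + 1e-12)
        dz_surface = np.diff(grid.z)[-1]
        assert dz_surface <= settings.dz / 2 + 1e-12

    def test_layer_assignment(self):
        block = default_tissue_block()
        grid = build_grid(block)
        mids = 0.5 * (grid.z[:-1] + grid.z[1:])
        names = [block.layers[i].name for i in grid.layer_index]
        assert names[0] == "muscle" and names[-1] == "skin"
        assert names[int(np.searchsorted(mids, 0.015))] == "fat"


class TestOperator:
    def test_conduction_annihilates_constant_field(self):
        grid = build_grid(default_tissue_block())
        system = BioheatSystem(default_tissue_block(), grid)
        residual = system.K @ np.full(system.n, 36.0)
        assert np.max(np.abs(residual)) < 1e-8

    def test_perfusion_sink_vanishes_at_blood_temperature(self):
        block = default_tissue_block()
        system = BioheatSystem(block, build_grid(block))
        t = np.full(system.n, block.blood.temperature)
        sink = system.perfusion * (block.blood.temperature - t)
        assert np.allclose(sink, 0.0)

    def test_enthalpy_conserved_when_insulated(self):
        """No sources, no perfusion, all boundaries insulated: the total
        enthalpy is constant to 1e-8 relative per step."""
        block = single_layer_block()
        grid = build_grid(block, SolverSettings(dr=2e-3, dz=2e-3))
        system = BioheatSystem(block, grid, bottom_dirichlet=False,
                               surface_mode="insulated")
        rng = np.random.default_rng(3)
        values = 34.0 + 8.0 * rng.random((grid.nz, grid.nr))
        field = TemperatureField(values=values, grid=grid)
        settings = SolverSettings(dt=1.0)
        h0 = system.total_enthalpy(field)
        for _ in range(20):
            before = system.total_enthalpy(field)
            field = system.step(field, settings.dt, settings)
            after = system.total_enthalpy(field)
            assert abs(after - before) <= 1e-8 * abs(before)
        assert abs(system.total_enthalpy(field) - h0) <= 1e-7 * abs(h0)

    def test_bounds_preserved_without_sources(self):
        """With no sources the implicit step respects the discrete maximum
        principle: the field stays inside its initial bounds."""
        block = single_layer_block()
        grid = build_grid(block, SolverSettings(dr=2e-3, dz=2e-3))
        system = BioheatSystem(block, grid, bottom_dirichlet=False,
                               surface_mode="insulated")
        rng = np.random.default_rng(4)
        values = 30.0 + 10.0 * rng.random((grid.nz, grid.nr))
        field = TemperatureField(values=values, grid=grid)
        lo, hi = values.min(), values.max()
        for _ in range(10):
            field = system.step(field, 2.0, SolverSettings(dt=2.0))
            assert field.values.min() >= lo - 1e-9
            assert field.values.max() <= hi + 1e-9


class TestAnalyticOracles:
    def test_uniform_perfused_equilibrium(self):
        """Perfusion only, insulated: every node relaxes to
        T_b + q_m/(omega_b C_b), reached to solver tolerance."""
        problem = analytic_problem("uniform_equilibrium", perfusion_rate=0.7,
                                   metabolic_heat=420.0)
        block = single_layer_block(perfusion=0.7, metabolic=420.0,
                                   material="muscle")
        grid = build_grid(block, SolverSettings(dr=2e-3, dz=2e-3))
        system = BioheatSystem(block, grid, bottom_dirichlet=False,
                               surface_mode="insulated")
        field = TemperatureField(values=np.full((grid.nz, grid.nr), 30.0),
                                 grid=grid)
        settings = SolverSettings(dt=50.0)
        for _ in range(500):  # 25000 s, ~17 relaxation times
            field = system.step(field, settings.dt, settings)
        expected = problem.evaluate(0.0, 0.0)
        assert np.max(np.abs(field.values - expected)) < 1e-3

    def test_perfusion_relaxation_rate(self):
        """Uniform insulated tissue approaches equilibrium exponentially at
        rate omega_b*C_b/(rho*c), matched within 1%."""
        problem = analytic_problem("perfusion_relaxation")
        block = single_layer_block(perfusion=0.7, material="muscle")
        grid = build_grid(block, SolverSettings(dr=4e-3, dz=4e-3))
        system = BioheatSystem(block, grid, bottom_dirichlet=False,
                               surface_mode="insulated")
        field = TemperatureField(values=np.full((grid.nz, grid.nr), 30.0),
                                 grid=grid)
        dt = 2.0
        for _ in range(250):
            field = system.step(field, dt, SolverSettings(dt=dt))
        expected = problem.evaluate(0.0, 500.0)
        value = float(field.values[0, 0])
        assert abs((value - 37.0) - (expected - 37.0)) \
            <= 0.01 * abs(expected - 37.0)

    def test_semi_infinite_constant_flux(self):
        """Homogeneous half-space under constant surface flux: surface rise
        follows (2 q0 / k) sqrt(alpha t / pi) within 2% at early times."""
        q0 = 1000.0
        problem = analytic_problem("semi_infinite_flux", flux=q0)
        block = single_layer_block()
        grid = build_grid(block)
        system = BioheatSystem(block, grid, bottom_dirichlet=False,
                               surface_mode="flux", surface_flux=q0)
        t0 = 34.0
        field = TemperatureField(values=np.full((grid.nz, grid.nr), t0),
                                 grid=grid)
        settings = SolverSettings(dt=0.1)
        checks = {10.0: None, 20.0: None, 30.0: None}
        for n in range(300):
            field = system.step(field, settings.dt, settings)
            if round(field.time, 6) in checks:
                checks[round(field.time, 6)] = float(field.values[-1, 0])
        for t, simulated in checks.items():
            expected = problem.evaluate(0.0, t)
            assert simulated - t0 == pytest.approx(expected - t0, rel=0.02)

    def test_two_slab_steady_profile(self):
        """Series slabs between fixed temperatures: the discrete steady
        state reproduces the piecewise-linear profile (flux continuity at
        the interface) to well under 0.5%."""
        problem = analytic_problem("two_slab_steady")
        p = problem.parameters
        layers = (
            TissueLayer(name="top", thickness=p["d1"], density=1000.0,
                        specific_heat=3500.0, conductivity=p["k1"]),
            TissueLayer(name="bottom", thickness=p["d2"], density=1000.0,
                        specific_heat=3500.0, conductivity=p["k2"]),
        )
        block = TissueBlock(layers=layers, core_temperature=p["bottom_temperature"])
        grid = build_grid(block)
        system = BioheatSystem(block, grid, surface_mode="dirichlet",
                               surface_temperature=p["top_temperature"])
        t = system.steady_state()
        field = t.reshape(grid.nz, grid.nr)
        depth = grid.surface_z - grid.z  # measured downward from the top
        for j in range(grid.nz):
            expected = problem.evaluate(float(depth[j]))
            assert field[j, 0] == pytest.approx(expected, abs=1e-6)
        i_int = int(np.argmin(np.abs(depth - p["d1"])))
        assert field[i_int, 0] == pytest.approx(p["interface_temperature"],
                                                abs=1e-6)


class TestInitialState:
    def test_isothermal_scenario_is_uniform(self):
        """Ambient at core temperature with no metabolic heat: the steady
        state is uniform at the blood temperature."""
        base = standard_condition()
        layers = tuple(replace(l, metabolic_heat=0.0) for l in base.block.layers)
        block = replace(base.block, layers=layers, core_temperature=37.0)
        sc = replace(base, block=block, ambient_temperature=37.0)
        field = initial_state(sc, SolverSettings(dr=2e-3, dz=2e-3))
        assert np.max(np.abs(field.values - 37.0)) < 1e-6

    def test_bottom_row_is_core_temperature(self):
        sc = standard_condition()
        field = initial_state(sc, SolverSettings(dr=2e-3, dz=2e-3))
        assert np.allclose(field.values[0], sc.block.core_temperature)

    def test_validation_surface_match(self, validation):
        """The pre-treatment steady state hits the measured 34.3 degC disk
        average within 0.1 degC."""
        field = initial_state(validation)
        assert disk_average(field, 5e-3) == pytest.approx(34.3, abs=0.1)


class TestDiskAverage:
    def test_uniform_surface(self):
        grid = build_grid(default_tissue_block())
        field = TemperatureField(values=np.full((grid.nz, grid.nr), 40.0),
                                 grid=grid)
        assert disk_average(field, 5e-3) == pytest.approx(40.0)

    def test_linear_profile_matches_area_weighted_integral(self):
        """T = a + b r: the disk mean is a + (2/3) b R by the closed-form
        integral of 2 pi r T(r) over the disk."""
        grid = build_grid(default_tissue_block())
        a, b = 35.0, 100.0
        values = np.tile(a + b * grid.r, (grid.nz, 1))
        field = TemperatureField(values=values, grid=grid)
        radius = 5e-3
        assert disk_average(field, radius) == pytest.approx(
            a + 2.0 / 3.0 * b * radius, rel=1e-3)

    def test_small_radius_limit_is_axis_value(self):
        grid = build_grid(default_tissue_block())
        values = np.tile(35.0 + 100.0 * grid.r, (grid.nz, 1))
        field = TemperatureField(values=values, grid=grid)
        assert disk_average(field, 1e-4) == pytest.approx(values[-1, 0],
                                                          abs=0.02)

    def test_radius_beyond_extent_rejected(self):
        grid = build_grid(default_tissue_block())
        field = TemperatureField(values=np.zeros((grid.nz, grid.nr)), grid=grid)
        with pytest.raises(ValueError):
            disk_average(field, 1.0)


class TestRun:
    def test_vanishing_duration_returns_initial_probes(self):
        sc = replace(standard_condition(), duration=1e-9)
        settings = SolverSettings(dr=2e-3, dz=2e-3)
        res = run(sc, settings)
        field = initial_state(sc, settings)
        assert res.times[-1] == 0.0
        assert res.point_series[-1] == pytest.approx(field.values[-1, 0])
        assert res.disk_average_series[-1] == pytest.approx(
            disk_average(field, 5e-3))
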