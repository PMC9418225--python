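import numpy as np
import pytest
from dataclasses import replace

from vasotherm.domain import Material, VoxelGrid
from vasotherm.errors import AssemblyError, ConfigurationError
from vasotherm.fixtures import make_single_vessel_slab
from vasotherm.heat import (
    ThermalParams,
    assemble_heat_system,
    build_advection_graph,
    overall_U,
    solve_heat,
)
from vasotherm.pipeline import solve_problem

T = int(Material.TISSUE)


class TestOverallU:
    def test_tissue_face_value(self):
        # ds = 64 um, K_t = 0.49 -> K/ds = 7656.25
        assert overall_U("tissue", 64e-6, 0.49) == pytest.approx(7656.25)

    def test_air_face_value(self):
        # series of half-cell conduction and ambient film
        u = overall_U("air", 64e-6, 0.49, 20.0)
        assert u == pytest.approx(1.0 / (64e-6 / 0.98 + 0.05), rel=1e-6)
        assert u == pytest.approx(19.974, rel=1e-4)

    def test_infinite_film_recovers_half_cell_limit(self):
        u = overall_U("vessel", 64e-6, 0.49, 1e12)
        assert u == pytest.approx(2 * 0.49 / 64e-6, rel=1e-6)

    def test_zero_film_seals_face(self):
        assert overall_U("air", 64e-6, 0.49, 0.0) == 0.0
        assert overall_U("vessel", 64e-6, 0.49, 0.0) == 0.0


class TestConductionOnly:
    def make_bar(self, n=9):
        spacing = (1e-3, 1e-3, 1e-3)
        grid = VoxelGrid((1, 1, n), spacing, np.full((1, 1, n), T, dtype=np.int8))
        return grid

    def test_pinned_bar_has_linear_interior_profile(self):
        grid = self.make_bar(9)
        params = ThermalParams(h_inf=0.0, qdot_m=0.0, h_b=0.0)
        graph = build_advection_graph(None, grid, None)
        hsys = assemble_heat_system(grid, None, graph, params, trees={},
                                    voxel_dirichlet=[(0, 35.0), (8, 20.0)])
        sol = solve_heat(hsys, method="dense")
        Tt = sol.T_t.ravel()
        expected = 35.0 + (20.0 - 35.0) * np.arange(9) / 8
        np.testing.assert_allclose(Tt, expected, rtol=1e-12)

    def test_all_adiabatic_with_generation_is_detected(self):
        grid = self.make_bar(4)
        params = ThermalParams(h_inf=0.0, qdot_m=100.0, h_b=0.0)
        graph = build_advection_graph(None, grid, None)
        with pytest.raises(AssemblyError):
            hsys = assemble_heat_system(grid, None, graph, params, trees={})
            solve_heat(hsys, method="dense")

    def test_uniform_equilibrium_at_ambient(self):
        grid = self.make_bar(5)
        params = ThermalParams(h_inf=20.0, qdot_m=0.0, h_b=0.0, T_inf=22.0)
        graph = build_advection_graph(None, grid, None)
        sol = solve_heat(assemble_heat_system(grid, None, graph, params, trees={}),
                         method="dense")
        np.testing.assert_allclose(sol.T_t.ravel(), 22.0, rtol=1e-12)


class TestAdvectionGraph:
    def test_zero_flow_gives_empty_graph(self):
        grid = VoxelGrid((2, 2, 2), (1e-3,) * 3,
                         np.full((2, 2, 2), T, dtype=np.int8))
        g = build_advection_graph(None, grid, None)
        assert all(not lst for lst in g.voxel_inflows)
        assert not g.elem_keys

    def test_mass_rates_nonnegative_and_closure(self, toy_result, toy_problem):
        g = build_advection_graph(toy_result.flow, toy_problem.grid,
                                  toy_result.coupling)
        for lists in (g.voxel_inflows, g.voxel_sources, g.voxel_sinks):
            for lst in lists:
                assert all(m >= 0 for _, m in lst)
        for contribs in g.elem_contrib.values():
            assert all(m >= 0 for _, m in contribs)
        assert g.max_closure_error < 1e-8

    def test_chain_voxel_receives_source_at_terminal_mass(self, chain_result,
                                                          chain_problem):
        g = build_advection_graph(chain_result.flow, chain_problem.grid,
                                  chain_result.coupling)
        # the single tissue voxel has exactly one arterial source whose
        # mass rate is rho_b times the terminal flow
        sources = g.voxel_sources[0]
        assert len(sources) == 1
        key, m = sources[0]
        assert key == ("artery", "ae0")
        q = chain_result.flow.element_flows[("artery", "ae0")]
        assert m == pytest.approx(1050.0 * q, rel=1e-12)

    def test_stale_flow_rejected(self, toy_result, toy_problem):
        flow = toy_result.flow
        # corrupt one element flow to break closure
        key = next(iter(flow.element_flows))
        original = flow.element_flows[key]
        flow.element_flows[key] = original * 3.0 + 1e-9
        try:
            with pytest.raises(AssemblyError, match="closure"):
                build_advection_graph(flow, toy_problem.grid, toy_result.coupling)
        finally:
            flow.element_flows[key] = original


class TestHeatSolve:
    def test_dimension_formula_and_sparsity(self, toy_result, toy_problem):
        hsys = toy_result.heat.system
        nt = toy_problem.grid.tissue_linear.size
        n_elems = len(toy_problem.arterial.elements) + len(toy_problem.venous.elements)
        assert hsys.system.n == nt + n_elems
        assert hsys.system.A.nnz / hsys.system.n**2 < 0.1

    def test_equilibrium_when_inlet_equals_ambient(self, toy_problem):
        tp = replace(toy_problem.thermal_params, T_in=20.0, T_inf=20.0, qdot_m=0.0)
        res = solve_problem(toy_problem.with_params(thermal_params=tp),
                            method="dense")
        assert np.nanmax(np.abs(res.heat.T_t - 20.0)) < 1e-9
        assert max(abs(t - 20.0) for t in res.heat.T_elem.values()) < 1e-9

    def test_linearity_in_inlet_offset(self, toy_problem):
        """With zero metabolic generation the steady system is linear: scaling
        the inlet offset scales every temperature offset exactly."""
        tp1 = replace(toy_problem.thermal_params, T_inf=20.0, T_in=30.0)
        tp2 = replace(toy_problem.thermal_params, T_inf=20.0, T_in=40.0)
        r1 = solve_problem(toy_problem.with_params(thermal_params=tp1), method="dense")
        r2 = solve_problem(toy_problem.with_params(thermal_params=tp2), method="dense")
        th1 = r1.heat.all_temperatures() - 20.0
        th2 = r2.heat.all_temperatures() - 20.0
        np.testing.assert_allclose(th2, 2.0 * th1, rtol=1e-9)

    def test_monotone_response_to_inlet_temperature(self, toy_problem):
        tp_lo = replace(toy_problem.thermal_params, T_in=33.0)
        tp_hi = replace(toy_problem.thermal_params, T_in=37.0)
        r_lo = solve_problem(toy_problem.with_params(thermal_params=tp_lo), method="dense")
        r_hi = solve_problem(toy_problem.with_params(thermal_params=tp_hi), method="dense")
        assert np.all(r_hi.heat.all_temperatures()
                      >= r_lo.heat.all_temperatures() - 1e-12)

    def test_temperature_bounds_on_toy(self, toy_result, toy_problem):
        tp = toy_problem.thermal_params
        temps = toy_result.heat.all_temperatures()
        assert temps.min() >= min(tp.T_in, tp.T_inf) - 1e-9
        assert temps.max() <= max(tp.T_in, tp.T_inf) + 1e-9

    def test_energy_balance_closes(self, toy_result):
        eb = toy_result.energy_balance
        assert eb["closure_relative"] < 1e-6

    def test_energy_residual_is_small_in_watts(self, toy_result):
        assert toy_result.heat.energy_residual < 1e-10


class TestVesselTissueExchange:
    def test_pbm_artery_isothermal_and_sources_at_inlet_temperature(self):
        slab = make_single_vessel_slab(8)
        prob = slab.with_params(thermal_params=ThermalParams.preset("pbm"))
        res = solve_problem(prob, method="dense")
        artery_T = [t for (k, _), t in res.heat.T_elem.items() if k == "artery"]
        assert max(abs(t - 35.0) for t in artery_T) < 0.01

    def test_wjm_artery_cools_along_flow(self):
        slab = make_single_vessel_slab(8)
        prob = slab.with_params(thermal_params=ThermalParams.preset("wjm"))
        res = solve_problem(prob, method="dense")
        temps = [res.heat.T_elem[("artery", f"ae{i}")] for i in range(7)]
        assert all(a >= b - 1e-12 for a, b in zip(temps, temps[1:]))
        assert temps[-1] < temps[0]  # strictly cooled overall

    def test_wjm_outlet_blood_warmer_than_pbm(self):
        """Finite wall convection warms tissue near the inlet, which heats
        the venous return: the outlet enthalpy exceeds the PBM case."""
        slab = make_single_vessel_slab(8)
        out = {}
        for mode in ("pbm", "wjm"):
            prob = slab.with_params(thermal_params=ThermalParams.preset(mode))
            res = solve_problem(prob, method="dense")
            out[mode] = res.energy_balance["advective_out"]
        assert out["wjm"] > out["pbm"]


class TestParams:
    def test_presets(self):
        assert ThermalParams.preset("pbm").h_b == 0.001
        assert ThermalParams.preset("wjm").h_b == 10.0
        with pytest.raises(ConfigurationError):
            ThermalParams.preset("other")

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigurationError):
            ThermalParams(K_t=0.0)
        with pytest.raises(ConfigurationError):
            ThermalParams(h_b=-1.0)
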