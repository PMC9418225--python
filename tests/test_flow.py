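import numpy as np
import pytest
from dataclasses import replace

from vasotherm.domain import Face
from vasotherm.errors import AssemblyError, ConfigurationError
from vasotherm.fixtures import expected_chain_flow, make_darcy_slab
from vasotherm.flow import (
    FlowParams,
    assemble_flow_system,
    perfusion_flux,
    solve_flow,
    tpfa_transmissibility,
)
from vasotherm.pipeline import solve_problem
from vasotherm.soi import build_coupling_map


class TestTransmissibility:
    def test_table_value(self):
        face = Face(0, 1, 64e-6 * 333e-6, 64e-6, 0)
        t = tpfa_transmissibility(face, 1e-12, 1e-12, 3e-3)
        assert t == pytest.approx(1e-12 * 64e-6 * 333e-6 / (3e-3 * 64e-6), rel=1e-14)

    def test_equal_permeability_harmonic_mean_identity(self):
        face = Face(0, 1, 1e-8, 1e-4, 2)
        k = 5e-10
        assert tpfa_transmissibility(face, k, k, 3e-3) == pytest.approx(
            1e-8 * k / (3e-3 * 1e-4))

    def test_sealed_when_either_side_impermeable(self):
        face = Face(0, 1, 1e-8, 1e-4, 2)
        assert tpfa_transmissibility(face, 0.0, 1e-12, 3e-3) == 0.0
        assert tpfa_transmissibility(face, 1e-12, 0.0, 3e-3) == 0.0

    def test_symmetry(self):
        face = Face(0, 1, 1e-8, 1e-4, 1)
        assert tpfa_transmissibility(face, 1e-12, 5e-10, 3e-3) == pytest.approx(
            tpfa_transmissibility(face, 5e-10, 1e-12, 3e-3), rel=1e-15)


class TestPerfusionFlux:
    def test_magnitude_and_antisymmetry(self):
        assert perfusion_flux(9600.0, 1600.0, 1e-6) == pytest.approx(8e-3)
        assert perfusion_flux(5000.0, 5000.0, 1e-6) == 0.0
        assert perfusion_flux(1600.0, 9600.0, 1e-6) == pytest.approx(-8e-3)


class TestDarcySlab:
    @pytest.mark.parametrize("n", [3, 7, 20])
    def test_linear_profile_and_flux(self, n):
        slab = make_darcy_slab(n)
        fsys = assemble_flow_system(slab.grid, None, None, None, slab.params,
                                    voxel_dirichlet=slab.dirichlet)
        sol = solve_flow(fsys, method="dense")
        Pa = sol.P_a.ravel()
        np.testing.assert_allclose(Pa, slab.expected_profile, rtol=1e-12)
        t = (slab.grid.face_area(2) * slab.params.k_a
             / (slab.params.mu * slab.grid.spacing[2]))
        flux = t * (Pa[0] - Pa[1])
        assert flux == pytest.approx(slab.expected_flux, rel=1e-12)

    def test_zero_pressure_drop_means_zero_flux(self):
        slab = make_darcy_slab(5, P_left=5000.0, P_right=5000.0)
        fsys = assemble_flow_system(slab.grid, None, None, None, slab.params,
                                    voxel_dirichlet=slab.dirichlet)
        sol = solve_flow(fsys, method="dense")
        assert np.nanmax(np.abs(sol.P_a - 5000.0)) < 1e-9


class TestVesselVoxelChain:
    def test_total_flow_matches_series_resistance_oracle(self, chain_result,
                                                         chain_problem):
        q = chain_result.flow.element_flows[("artery", "ae0")]
        q_exp = expected_chain_flow(chain_problem)
        assert q == pytest.approx(q_exp, rel=1e-6)
        # same flow everywhere along the chain: artery = perfusion = vein
        V = chain_problem.grid.voxel_volume
        u = np.nansum(chain_result.flow.u_perf) * V
        assert u == pytest.approx(q_exp, rel=1e-6)
        q_v = chain_result.flow.element_flows[("vein", "ve0")]
        assert -q_v == pytest.approx(q_exp, rel=1e-6)

    def test_equilibrium_when_no_pressure_drop(self, chain_problem):
        fp = replace(chain_problem.flow_params, P_in=5000.0, P_out=5000.0)
        prob = chain_problem.with_params(flow_params=fp)
        res = solve_problem(prob, method="dense")
        # flow is zero up to conductance * pressure round-off
        kappa = prob.arterial.elements[0].conductance(fp.mu)
        assert abs(res.flow.element_flows[("artery", "ae0")]) < 1e-12 * kappa * 5000.0
        assert np.nanmax(np.abs(res.flow.P_a - 5000.0)) < 1e-9


class TestAssembly:
    def test_rows_sum_to_zero_except_dirichlet(self, chain_problem):
        cm = build_coupling_map(chain_problem.grid, chain_problem.arterial,
                                chain_problem.venous, chain_problem.epsilon)
        fsys = assemble_flow_system(chain_problem.grid, chain_problem.arterial,
                                    chain_problem.venous, cm,
                                    chain_problem.flow_params)
        A = fsys.system.A.toarray()
        b = fsys.system.b
        row_sums = A.sum(axis=1)
        dirichlet = b != 0
        # conservation rows (including terminal continuity, whose gamma
        # terms cancel through the unit weight sum) sum to zero
        free = ~dirichlet
        scale = np.abs(A).max(axis=1)
        assert np.all(np.abs(row_sums[free]) <= 1e-9 * scale[free])
        assert np.all(row_sums[dirichlet] == 1.0)

    def test_dimension_formula(self, toy_problem):
        cm = build_coupling_map(toy_problem.grid, toy_problem.arterial,
                                toy_problem.venous, toy_problem.epsilon)
        fsys = assemble_flow_system(toy_problem.grid, toy_problem.arterial,
                                    toy_problem.venous, cm,
                                    toy_problem.flow_params)
        nt = toy_problem.grid.tissue_linear.size
        n_nodes = len(toy_problem.arterial.nodes) + len(toy_problem.venous.nodes)
        assert fsys.system.n == 2 * nt + n_nodes
        # sparse indeed
        nnz = fsys.system.A.nnz
        assert nnz / fsys.system.n**2 < 0.05

    def test_no_dirichlet_anywhere_is_singular_structure(self):
        slab = make_darcy_slab(4)
        with pytest.raises(AssemblyError, match="Dirichlet"):
            assemble_flow_system(slab.grid, None, None, None, slab.params)

    def test_missing_terminal_in_coupling_rejected(self, toy_problem):
        cm = build_coupling_map(toy_problem.grid, toy_problem.arterial,
                                toy_problem.venous, toy_problem.epsilon)
        key = cm.terminals("artery")[0]
        del cm.weights[key]
        with pytest.raises(AssemblyError, match=key[1]):
            assemble_flow_system(toy_problem.grid, toy_problem.arterial,
                                 toy_problem.venous, cm, toy_problem.flow_params)


class TestSolvedFields:
    def test_maximum_principle_on_toy(self, toy_result, toy_problem):
        lo, hi = toy_result.flow.pressure_bounds()
        assert lo >= toy_problem.flow_params.P_out - 1e-9
        assert hi <= toy_problem.flow_params.P_in + 1e-9

    def test_mass_balance_closes(self, toy_result):
        mb = toy_result.mass_balance
        assert mb["global_mismatch_relative"] < 1e-6
        assert mb["max_voxel_divergence_relative"] < 1e-6
        assert mb["max_terminal_mismatch"] <= 1e-12 * abs(mb["arterial_root_inflow"]) + 1e-25

    def test_perfusion_increases_with_alpha(self, toy_problem):
        """More permeable capillary beds carry more total flow at fixed
        boundary pressures."""
        flows = []
        for factor in (1.0, 2.0):
            fp = replace(toy_problem.flow_params,
                         alpha=toy_problem.flow_params.alpha * factor)
            res = solve_problem(toy_problem.with_params(flow_params=fp),
                                method="dense")
            flows.append(res.mass_balance["arterial_root_inflow"])
        assert flows[1] > flows[0]

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            FlowParams(mu=-1.0)
        with pytest.raises(ConfigurationError):
            FlowParams(P_in=1000.0, P_out=2000.0)
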