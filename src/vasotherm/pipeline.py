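"""Problem container and the flow -> heat solution pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .domain import VoxelGrid
from .flow import FlowParams, FlowSolution, assemble_flow_system, solve_flow, mass_balance_report
from .heat import (
    ThermalParams,
    ThermalSolution,
    assemble_heat_system,
    build_advection_graph,
    energy_balance_report,
    solve_heat,
)
from .soi import CouplingMap, build_coupling_map
from .vessels import VesselTree

__all__ = ["Problem", "PipelineResult", "solve_problem"]


@dataclass
class Problem:
    """A complete simulation problem: domain, trees, SoI radius, parameters."""

    grid: VoxelGrid
    arterial: VesselTree
    venous: VesselTree
    epsilon: float
    flow_params: FlowParams = field(default_factory=FlowParams)
    thermal_params: ThermalParams = field(default_factory=ThermalParams)
    name: str = "problem"

    def with_params(self, flow_params=None, thermal_params=None, epsilon=None) -> "Problem":
        return replace(
            self,
            flow_params=flow_params or self.flow_params,
            thermal_params=thermal_params or self.thermal_params,
            epsilon=self.epsilon if epsilon is None else epsilon,
        )


@dataclass
class PipelineResult:
    coupling: CouplingMap
    flow: FlowSolution
    heat: ThermalSolution
    mass_balance: dict
    energy_balance: dict


def solve_problem(
    problem: Problem,
    tol: float = 1e-8,
    method: str = "auto",
    coupling: CouplingMap | None = None,
    flow: FlowSolution | None = None,
    warn=None,
    **solver_kwargs,
) -> PipelineResult:
    """Run the coupled pipeline: SoI coupling, flow solve, then heat solve.

    ``coupling`` and ``flow`` allow re-using cached stages (e.g. during
    sensitivity analysis when only thermal parameters change).
    """
    if coupling is None:
        coupling = build_coupling_map(
            problem.grid, problem.arterial, problem.venous, problem.epsilon, warn=warn
        )
    if flow is None:
        fsys = assemble_flow_system(
            problem.grid, problem.arterial, problem.venous, coupling, problem.flow_params
        )
        flow = solve_flow(fsys, tol=tol, method=method, **solver_kwargs)
    graph = build_advection_graph(
        flow, problem.grid, coupling, rho_b=problem.thermal_params.rho_b,
        closure_rtol=max(1e-6, 100 * tol),
    )
    hsys = assemble_heat_system(problem.grid, flow, graph, problem.thermal_params)
    heat = solve_heat(hsys, tol=tol, method=method, **solver_kwargs)
    return PipelineResult(
        coupling, flow, heat,
        mass_balance_report(flow),
        energy_balance_report(heat),
    )
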