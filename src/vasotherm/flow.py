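"""Coupled 1D vessel / 3D two-compartment Darcy flow solver.

Unknown vector layout (fixed, reproducible):

    [ P_a per tissue voxel | P_v per tissue voxel | p per arterial node
      | p per venous node ]

with tissue voxels in ascending linear (z-fastest) order and nodes in
ascending id order.  Rows:

* arterial compartment balance per tissue voxel i:
      sum_j t_ij (P_a,i - P_a,j) + alpha (P_a,i - P_v,i) V_i
      - sum_k w_{k,i} kappa_k (p_{n_k} - p_{t_k}) = 0
  where w_{k,i} are the calibrated SoI weights and kappa_k the terminal
  element's Hagen-Poiseuille conductance;
* venous compartment balance, with the perfusion term's sign flipped and
  sinks entering with opposite sign;
* Kirchhoff mass balance at internal vessel nodes;
* pressure continuity at each terminal node k: the element flow into the
  terminal equals the flow through the virtual unresolved network,
  kappa_k (p_{n_k} - p_{t_k}) + (gamma/mu) (sum_i w_{k,i} P_i - p_{t_k}) = 0;
* Dirichlet rows p = P_in at arterial roots and p = P_out at venous roots.

The perfusion coupling term is alpha (P_a - P_v) V, consistent with the
compartmental continuity equations.  Face transmissibilities use the
standard TPFA harmonic average.  Vessel-labeled voxels carry no porous
unknowns: all resolved vessel flow is 1D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._solve import LinearSystem, solve_linear
from .domain import Material, VoxelGrid, face_arrays
from .errors import AssemblyError, ConfigurationError
from .soi import CouplingMap
from .vessels import VesselTree, element_conductance

__all__ = [
    "FlowParams",
    "FlowSystem",
    "FlowSolution",
    "tpfa_transmissibility",
    "assemble_flow_system",
    "solve_flow",
    "perfusion_flux",
    "mass_balance_report",
    "solve_vessel_network",
]


@dataclass(frozen=True)
class FlowParams:
    """Hydraulic parameters.

    Defaults are the study's tongue/blood values: permeabilities in m^2,
    viscosity in Pa s, boundary pressures in Pa.  ``alpha`` and ``gamma``
    are the proportionality coefficients of the compartmental perfusion
    law u_perf = alpha (P_a - P_v) and of the virtual-network pressure
    continuity q = (gamma/mu) (p_terminal - <P>); their derived units
    follow from those laws.  With gamma = 1e14 the virtual-network
    resistance is negligible next to the resolved elements, so the
    terminal node pressure tracks the SoI-averaged tissue pressure.
    """

    k_a: float = 1e-12
    k_v: float = 5e-10
    alpha: float = 1e-6
    mu: float = 3e-3
    gamma_a: float = 1e14
    gamma_v: float = 1e14
    P_in: float = 10600.0
    P_out: float = 1600.0

    def __post_init__(self):
        for name in ("k_a", "k_v", "alpha", "mu", "gamma_a", "gamma_v"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"flow parameter {name} must be > 0")
        if self.P_in < self.P_out:
            raise ConfigurationError("P_in must not be below P_out")


def tpfa_transmissibility(face, k_i: float, k_j: float, mu: float) -> float:
    """Two-point flux transmissibility of one face, m^3 Pa^-1 s^-1.

    t = (A / (mu d)) * harmonic_mean(k_i, k_j); symmetric in (i, j), and
    zero (a sealed face) if either permeability is zero.
    """
    if mu <= 0 or face.area <= 0 or face.center_distance <= 0:
        raise ConfigurationError("tpfa_transmissibility requires positive A, d, mu")
    if k_i < 0 or k_j < 0:
        raise ConfigurationError("permeabilities must be non-negative")
    if k_i == 0.0 or k_j == 0.0:
        return 0.0
    k_h = 2.0 * k_i * k_j / (k_i + k_j)
    return face.area * k_h / (mu * face.center_distance)


@dataclass
class _TerminalInfo:
    key: tuple[str, str]           # (kind, terminal node id)
    terminal_col: int              # unknown index of the terminal node
    neighbor_col: int              # unknown index of the element's other node
    kappa: float                   # terminal element conductance
    gamma_over_mu: float
    voxel_rows: np.ndarray         # P-block rows of the in-SoI voxels
    weights: np.ndarray
    element_id: str


@dataclass
class FlowSystem:
    """Assembled flow system plus the index context needed to interpret it."""

    system: LinearSystem
    grid: VoxelGrid
    params: FlowParams
    coupling: CouplingMap | None
    trees: dict[str, VesselTree]
    tissue_linear: np.ndarray              # voxel linear index per P-row
    node_cols: dict[tuple[str, str], int]  # (kind, node id) -> unknown index
    terminals: list[_TerminalInfo]
    faces: dict[str, tuple] = field(default_factory=dict)  # per-compartment face arrays

    @property
    def n_tissue(self) -> int:
        return self.tissue_linear.size


def _tissue_faces(grid: VoxelGrid):
    """Tissue-tissue interior faces as (area, dist, lo_rows, hi_rows) per axis."""
    lab = grid.labels.ravel()
    tissue = lab == int(Material.TISSUE)
    pos = -np.ones(grid.n_voxels, dtype=int)
    tl = grid.tissue_linear
    pos[tl] = np.arange(tl.size)
    out = []
    for axis, area, dist, lo, hi, _amb in face_arrays(grid):
        keep = tissue[lo] & tissue[hi]
        out.append((area, dist, pos[lo[keep]], pos[hi[keep]]))
    return out


def assemble_flow_system(
    grid: VoxelGrid,
    arterial_tree: VesselTree | None,
    venous_tree: VesselTree | None,
    coupling: CouplingMap | None,
    params: FlowParams,
    voxel_dirichlet: list[tuple[int, str, float]] | None = None,
) -> FlowSystem:
    """Assemble the sparse coupled flow system.

    ``voxel_dirichlet`` optionally pins compartment pressures at given
    voxels as ``(voxel linear index, "a"|"v", pressure)``; it exists for
    verification fixtures (e.g. pure Darcy slabs without any tree).
    """
    tl = grid.tissue_linear
    nt = tl.size
    if nt == 0:
        raise AssemblyError("grid contains no tissue voxels")
    pos = -np.ones(grid.n_voxels, dtype=int)
    pos[tl] = np.arange(nt)
    V = grid.voxel_volume

    trees = {}
    for tree in (arterial_tree, venous_tree):
        if tree is not None:
            trees[tree.kind] = tree
    if coupling is None and trees:
        raise AssemblyError("a coupling map is required when trees are present")

    # unknown layout
    node_cols: dict[tuple[str, str], int] = {}
    col = 2 * nt
    for kind in ("artery", "vein"):
        if kind in trees:
            for nid in sorted(trees[kind].nodes):
                node_cols[(kind, nid)] = col
                col += 1
    n = col
    blocks = {"P_a": (0, nt), "P_v": (nt, 2 * nt)}
    if trees:
        blocks["nodes"] = (2 * nt, n)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b = np.zeros(n)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    # Dirichlet bookkeeping: rows replaced entirely at the end.
    dirichlet: dict[int, float] = {}

    # ---- TPFA face terms ----------------------------------------------
    tfaces = _tissue_faces(grid)
    face_store = {}
    for comp, k_comp, offset in (("a", params.k_a, 0), ("v", params.k_v, nt)):
        comp_faces = []
        for area, dist, lo, hi in tfaces:
            t = area * k_comp / (params.mu * dist)  # uniform k: harmonic mean = k
            comp_faces.append((t, lo, hi))
            for a_row, b_row in zip(lo, hi):
                ra, rb = offset + a_row, offset + b_row
                add(ra, ra, t)
                add(ra, rb, -t)
                add(rb, rb, t)
                add(rb, ra, -t)
        face_store[comp] = comp_faces

    # ---- compartmental perfusion alpha (P_a - P_v) V -------------------
    aV = params.alpha * V
    for i in range(nt):
        add(i, i, aV)
        add(i, nt + i, -aV)
        add(nt + i, nt + i, aV)
        add(nt + i, i, -aV)

    # ---- vessel network ------------------------------------------------
    terminals: list[_TerminalInfo] = []
    for kind, tree in trees.items():
        g = tree.graph()
        roots = set(tree.roots)
        term_set = set(tree.terminals)
        gamma = params.gamma_a if kind == "artery" else params.gamma_v
        p_dir = params.P_in if kind == "artery" else params.P_out
        comp_offset = 0 if kind == "artery" else nt

        # Kirchhoff at internal (non-root, non-terminal) nodes
        for nid in tree.nodes:
            c_self = node_cols[(kind, nid)]
            if nid in roots:
                dirichlet[c_self] = p_dir
                continue
            if nid in term_set:
                continue
            for nbr in g.neighbors(nid):
                el = g.edges[nid, nbr]["element"]
                kappa = el.conductance(params.mu)
                add(c_self, c_self, kappa)
                add(c_self, node_cols[(kind, nbr)], -kappa)

        # terminal rows: element inflow + virtual-network inflow = 0
        for tid, el in tree.terminal_elements().items():
            key = (kind, tid)
            if coupling is None or key not in coupling.weights:
                raise AssemblyError(
                    f"coupling map lacks terminal {tid} of the {kind} tree"
                )
            nbr = el.node_j if el.node_i == tid else el.node_i
            c_t = node_cols[(kind, tid)]
            c_n = node_cols[(kind, nbr)]
            kappa = el.conductance(params.mu)
            vox_lin, w = coupling.weights[key]
            vrows = pos[vox_lin]
            if np.any(vrows < 0):
                raise AssemblyError(
                    f"coupling of terminal {tid} references non-tissue voxels"
                )
            g_over_mu = gamma / params.mu
            # kappa (p_n - p_t) + (gamma/mu) (sum w P - p_t) = 0
            add(c_t, c_n, kappa)
            add(c_t, c_t, -kappa - g_over_mu)
            for r, wi in zip(vrows, w):
                add(c_t, comp_offset + r, g_over_mu * wi)
            terminals.append(
                _TerminalInfo(key, c_t, c_n, kappa, g_over_mu, vrows, w, el.id)
            )
            # voxel-row source/sink.  Arterial: subtract the distributed
            # source w kappa (p_n - p_t); venous: add the distributed sink
            # w kappa (p_t - p_n).  Both give the same coefficients.
            for r, wi in zip(vrows, w):
                add(comp_offset + r, c_n, -wi * kappa)
                add(comp_offset + r, c_t, wi * kappa)

    # ---- voxel Dirichlet (fixtures) -------------------------------------
    for lin, comp, value in voxel_dirichlet or ():
        r = pos[lin]
        if r < 0:
            raise AssemblyError(f"voxel Dirichlet at non-tissue voxel {lin}")
        dirichlet[int(r) + (0 if comp == "a" else nt)] = float(value)

    if not dirichlet:
        raise AssemblyError(
            "system has no Dirichlet condition (no tree roots, no pinned "
            "voxels); the pure-Neumann problem is singular"
        )

    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    # replace Dirichlet rows with identity rows
    dir_rows = np.fromiter(dirichlet.keys(), dtype=int)
    keep_diag = np.ones(n)
    keep_diag[dir_rows] = 0.0
    A = (sp.diags(keep_diag) @ A).tocsr() + sp.coo_matrix(
        (np.ones(dir_rows.size), (dir_rows, dir_rows)), shape=(n, n)
    ).tocsr()
    A.eliminate_zeros()
    for r, v in dirichlet.items():
        b[r] = v

    system = LinearSystem(A, b, blocks)
    return FlowSystem(system, grid, params, coupling, trees, tl, node_cols,
                      terminals, face_store)


@dataclass
class FlowSolution:
    """Solved pressure/flow fields.

    ``P_a``/``P_v`` are full rasters (NaN outside tissue); ``Q_a``/``Q_v``
    are absolute per-voxel volumetric source/sink rates in m^3/s (both
    positive in normal operation: Q_a enters the arterial compartment,
    Q_v leaves the venous compartment); ``u_perf`` is the compartmental
    perfusion flux alpha (P_a - P_v).
    """

    system: FlowSystem
    x: np.ndarray
    P_a: np.ndarray
    P_v: np.ndarray
    node_pressures: dict[tuple[str, str], float]
    element_flows: dict[tuple[str, str], float]
    soi_flows: dict[tuple[str, str], float]
    Q_a: np.ndarray
    Q_v: np.ndarray
    u_perf: np.ndarray
    solver_info: dict

    @property
    def grid(self) -> VoxelGrid:
        return self.system.grid

    def pressure_bounds(self) -> tuple[float, float]:
        vals = [self.x[: 2 * self.system.n_tissue]]
        if self.node_pressures:
            vals.append(np.array(list(self.node_pressures.values())))
        allv = np.concatenate(vals)
        return float(allv.min()), float(allv.max())


def perfusion_flux(P_a, P_v, alpha: float):
    """Compartmental perfusion flux u_perf = alpha (P_a - P_v); signed,
    positive when the arterial compartment is at higher pressure."""
    return alpha * (np.asarray(P_a) - np.asarray(P_v))


def solve_flow(
    fsys: FlowSystem,
    tol: float = 1e-8,
    method: str = "auto",
    preconditioner: str = "ilu",
    **solver_kwargs,
) -> FlowSolution:
    """Solve the assembled system and derive flows and source fields."""
    x, info = solve_linear(fsys.system, tol=tol, method=method,
                           preconditioner=preconditioner, **solver_kwargs)
    grid = fsys.grid
    nt = fsys.n_tissue
    params = fsys.params

    P_a = np.full(grid.n_voxels, np.nan)
    P_v = np.full(grid.n_voxels, np.nan)
    P_a[fsys.tissue_linear] = x[:nt]
    P_v[fsys.tissue_linear] = x[nt: 2 * nt]

    node_pressures = {key: float(x[c]) for key, c in fsys.node_cols.items()}
    element_flows: dict[tuple[str, str], float] = {}
    for kind, tree in fsys.trees.items():
        for el in tree.elements:
            pj = node_pressures[(kind, el.node_j)]
            pi = node_pressures[(kind, el.node_i)]
            element_flows[(kind, el.id)] = el.conductance(params.mu) * (pj - pi)

    soi_flows: dict[tuple[str, str], float] = {}
    Q_a = np.zeros(grid.n_voxels)
    Q_v = np.zeros(grid.n_voxels)
    for term in fsys.terminals:
        # Flow handed to the virtual network equals the terminal element
        # flow (pressure continuity row).  Recovering it from the element
        # is well conditioned; the equivalent (gamma/mu)(p_t - <P>) form
        # amplifies pressure round-off by gamma/mu and is avoided.
        q = term.kappa * (x[term.neighbor_col] - x[term.terminal_col])
        soi_flows[term.key] = float(q)  # > 0: node delivers to tissue
        lin = fsys.tissue_linear[term.voxel_rows]
        if term.key[0] == "artery":
            Q_a[lin] += term.weights * q
        else:
            Q_v[lin] += term.weights * (-q)  # positive = sink out of voxel

    u_perf = perfusion_flux(P_a, P_v, params.alpha)
    shape = grid.shape
    return FlowSolution(
        fsys, x,
        P_a.reshape(shape), P_v.reshape(shape),
        node_pressures, element_flows, soi_flows,
        Q_a.reshape(shape), Q_v.reshape(shape),
        u_perf.reshape(shape), info,
    )


def root_flows(sol: FlowSolution) -> dict[str, float]:
    """Net volumetric inflow at arterial roots / outflow at venous roots."""
    out = {"arterial_in": 0.0, "venous_out": 0.0}
    for kind, tree in sol.system.trees.items():
        g = tree.graph()
        for r in tree.roots:
            p_r = sol.node_pressures[(kind, r)]
            for nbr in g.neighbors(r):
                el = g.edges[r, nbr]["element"]
                q = el.conductance(sol.system.params.mu) * (
                    p_r - sol.node_pressures[(kind, nbr)]
                )
                if kind == "artery":
                    out["arterial_in"] += q        # flow away from root
                else:
                    out["venous_out"] += -q        # flow into root
    return out


def mass_balance_report(sol: FlowSolution) -> dict:
    """Audit mass conservation of a solved flow field.

    Reports per-terminal mismatch between the terminal element flow and
    the SoI-distributed total, the worst per-voxel net divergence
    (combined compartments), and the global root inflow/outflow mismatch,
    all normalized by total root inflow where meaningful.
    """
    fsys = sol.system
    nt = fsys.n_tissue
    x = sol.x

    per_terminal = {}
    for term in fsys.terminals:
        q_el = term.kappa * (x[term.neighbor_col] - x[term.terminal_col])
        q_dist = q_el * float(term.weights.sum())  # total distributed to voxels
        per_terminal[f"{term.key[0]}:{term.key[1]}"] = abs(q_el - q_dist)

    # per-voxel divergence: Darcy net outflow (both compartments)
    # + venous sink - arterial source
    div = np.zeros(nt)
    for comp, offset in (("a", 0), ("v", nt)):
        p = x[offset: offset + nt]
        for t, lo, hi in fsys.faces[comp]:
            f = t * (p[lo] - p[hi])  # lo -> hi
            np.add.at(div, lo, f)
            np.add.at(div, hi, -f)
    div += sol.Q_v.ravel()[fsys.tissue_linear]
    div -= sol.Q_a.ravel()[fsys.tissue_linear]

    roots = root_flows(sol)
    q_in = roots["arterial_in"]
    q_out = roots["venous_out"]
    scale = max(abs(q_in), abs(q_out), 1e-300)
    return {
        "per_terminal_mismatch": per_terminal,
        "max_terminal_mismatch": max(per_terminal.values(), default=0.0),
        "max_voxel_divergence": float(np.abs(div).max()),
        "max_voxel_divergence_relative": float(np.abs(div).max()) / scale,
        "arterial_root_inflow": q_in,
        "venous_root_outflow": q_out,
        "global_mismatch": abs(q_in - q_out),
        "global_mismatch_relative": abs(q_in - q_out) / scale,
    }


def solve_vessel_network(
    tree: VesselTree,
    dirichlet: dict[str, float],
    mu: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """Solve a standalone 1D vessel network with prescribed node pressures.

    Kirchhoff balances at free nodes, p fixed at ``dirichlet`` nodes.
    Returns ``(node pressures, element flows q_ji = kappa (p_j - p_i))``.
    Used as the resolved-network building block and as a verification
    oracle for series/parallel element compositions.
    """
    ids = sorted(tree.nodes)
    idx = {nid: i for i, nid in enumerate(ids)}
    n = len(ids)
    g = tree.graph()
    rows, cols, vals = [], [], []
    b = np.zeros(n)
    for nid in ids:
        i = idx[nid]
        if nid in dirichlet:
            rows.append(i); cols.append(i); vals.append(1.0)
            b[i] = dirichlet[nid]
            continue
        for nbr in g.neighbors(nid):
            el = g.edges[nid, nbr]["element"]
            kappa = el.conductance(mu)
            rows.append(i); cols.append(i); vals.append(kappa)
            rows.append(i); cols.append(idx[nbr]); vals.append(-kappa)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    x, _ = solve_linear(LinearSystem(A, b, {"p": (0, n)}), method="dense")
    pressures = {nid: float(x[idx[nid]]) for nid in ids}
    flows = {
        el.id: el.conductance(mu) * (pressures[el.node_j] - pressures[el.node_i])
        for el in tree.elements
    }
    return pressures, flows
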