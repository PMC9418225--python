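"""Steady-state coupled bioheat solver on the multiscale voxel/element mesh.

Thermal unknowns are one temperature per tissue voxel and one per resolved
vessel element (all voxels covered by an element are isothermal with it).
Per tissue voxel the steady balance sums:

* face exchange U A (T_neighbor - T) over the 6 faces, with the overall
  coefficient U depending on the neighbor: K_t/ds for tissue-tissue
  conduction, [ds/2K_t + 1/h_inf]^-1 for ambient faces, and
  [ds/2K_t + 1/h_b]^-1 for blood-vessel faces (convective exchange with
  the owning element's temperature);
* donor-cell upwinded advection m c_pb (T_upstream - T) restricted to the
  neighbors blood flows in from -- outflow enthalpy at the local
  temperature cancels by per-voxel mass closure of the flow solution;
* sphere-of-influence source advection m_k c_pb (T_element - T) from each
  arterial terminal supplying the voxel;
* metabolic generation qdot_m * V.

Per vessel element the balance sums advection from upstream contributors
(parent elements, or in-SoI voxels for venous terminals) and exchange with
the tissue voxels in contact.  For energy conservation the element-side
exchange uses the same overall coefficient (tissue half-cell resistance in
series with 1/h_b) as the voxel-side term.  Arterial root elements are
pinned to the inlet blood temperature (Dirichlet); the venous root outflow
is advective only.

Inter-voxel advected mass sums both compartments' face flows: the voxel is
a single thermal node (arterial blood, venous blood and tissue in a voxel
are taken to be in local thermal equilibrium), and intra-voxel
arterial-to-venous perfusion therefore carries no heat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._solve import LinearSystem, solve_linear
from .domain import Material, VoxelGrid, face_arrays
from .errors import AssemblyError, ConfigurationError
from .flow import FlowSolution, root_flows
from .soi import CouplingMap

__all__ = [
    "ThermalParams",
    "AdvectionGraph",
    "HeatSystem",
    "ThermalSolution",
    "overall_U",
    "build_advection_graph",
    "assemble_heat_system",
    "solve_heat",
    "energy_balance_report",
]

#: Convective-coefficient presets: "pbm" treats vessel walls as effectively
#: adiabatic (blood equilibrates only on delivery to tissue), "wjm" gives
#: finite counter-current vessel-tissue exchange.
MODE_HB = {"pbm": 0.001, "wjm": 10.0}


@dataclass(frozen=True)
class ThermalParams:
    """Thermal parameters (SI, temperatures in deg C).

    ``K_b`` (blood thermal conductivity) is accepted for completeness but
    enters no equation of the steady model: vessel elements exchange heat
    only by advection and wall convection.
    """

    K_t: float = 0.49
    c_pt: float = 3421.0
    c_pb: float = 3617.0
    rho_t: float = 1090.0
    rho_b: float = 1050.0
    qdot_m: float = 0.0
    h_b: float = 0.001
    h_inf: float = 20.0
    T_inf: float = 20.0
    T_in: float = 35.0
    K_b: float = 0.52

    def __post_init__(self):
        for name in ("K_t", "c_pt", "c_pb", "rho_t", "rho_b"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"thermal parameter {name} must be > 0")
        for name in ("h_b", "h_inf"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"thermal parameter {name} must be >= 0")

    @classmethod
    def preset(cls, mode: str, **overrides) -> "ThermalParams":
        if mode not in MODE_HB:
            raise ConfigurationError(f"unknown mode {mode!r}; use pbm|wjm")
        overrides.setdefault("h_b", MODE_HB[mode])
        return cls(**overrides)


def overall_U(neighbor_kind: str, ds: float, K_t: float, h: float = 0.0) -> float:
    """Overall heat transfer coefficient of one voxel face (W m^-2 C^-1).

    tissue neighbor: two half-cell conductive resistances in series,
    U = K_t/ds; air or vessel neighbor: half-cell resistance in series
    with the convective film, U = [ds/2K_t + 1/h]^-1.  h = 0 seals the
    face (U = 0).
    """
    if ds <= 0 or K_t <= 0:
        raise ConfigurationError("overall_U requires ds > 0 and K_t > 0")
    if neighbor_kind == "tissue":
        return K_t / ds
    if neighbor_kind in ("air", "vessel"):
        if h < 0:
            raise ConfigurationError("h must be >= 0")
        if h == 0.0:
            return 0.0
        return 1.0 / (ds / (2.0 * K_t) + 1.0 / h)
    raise ConfigurationError(f"unknown neighbor kind {neighbor_kind!r}")


# source keys in contributor lists
INLET = ("inlet",)  # domain inlet at T_in


@dataclass
class AdvectionGraph:
    """Direction-resolved blood mass-flow topology of a flow solution.

    All mass rates are kg/s and non-negative (direction already resolved).
    ``voxel_inflows[r]`` lists ``(source tissue row, m)``;
    ``voxel_sources[r]`` lists ``(element key or INLET, m)``;
    ``elem_contrib[key]`` lists ``(("elem", key)|("voxel", row)|INLET, m)``;
    ``exits`` lists the contributors whose enthalpy leaves at venous roots.
    """

    elem_keys: list[tuple[str, str]]
    voxel_inflows: list[list[tuple[int, float]]]
    voxel_sources: list[list[tuple[tuple, float]]]
    voxel_sinks: list[list[tuple[tuple, float]]]
    elem_contrib: dict[tuple[str, str], list[tuple[tuple, float]]]
    pinned: set[tuple[str, str]]
    exits: list[tuple[tuple, float]]
    max_closure_error: float
    rho_b: float


def _element_flow_dirs(tree, kind, element_flows):
    """Per node: lists of (element key, mass-rate sign info).

    Returns (delivers, draws): delivers[node] = [(key, |q|)] elements whose
    flow enters the node; draws[node] = [(key, |q|)] elements drawing from
    the node.
    """
    delivers: dict[str, list] = {}
    draws: dict[str, list] = {}
    for el in tree.elements:
        q = element_flows[(kind, el.id)]
        key = (kind, el.id)
        if q >= 0:  # j -> i
            src, dst = el.node_j, el.node_i
        else:
            src, dst = el.node_i, el.node_j
        draws.setdefault(src, []).append((key, abs(q)))
        delivers.setdefault(dst, []).append((key, abs(q)))
    return delivers, draws


def build_advection_graph(
    flow: FlowSolution | None,
    grid: VoxelGrid,
    coupling: CouplingMap | None,
    rho_b: float = 1050.0,
    closure_rtol: float = 1e-6,
) -> AdvectionGraph:
    """Resolve the solved flow field into donor-cell mass-flow lists.

    ``flow=None`` yields an empty graph (pure-conduction problems).
    Raises :class:`AssemblyError` if per-node or per-voxel mass closure of
    the supplied flow solution is violated beyond ``closure_rtol`` of the
    total root inflow (a stale or inconsistent solution).
    """
    if flow is None:
        nt = grid.tissue_linear.size
        return AdvectionGraph([], [[] for _ in range(nt)], [[] for _ in range(nt)],
                              [[] for _ in range(nt)], {}, set(), [], 0.0, rho_b)

    fsys = flow.system
    nt = fsys.n_tissue
    trees = fsys.trees
    voxel_inflows: list[list] = [[] for _ in range(nt)]
    voxel_sources: list[list] = [[] for _ in range(nt)]
    voxel_sinks: list[list] = [[] for _ in range(nt)]

    # ---- inter-voxel advection: net of both compartments, upwinded ----
    x = flow.x
    p_a = x[:nt]
    p_v = x[nt: 2 * nt]
    face_net: dict[tuple[int, int], float] = {}
    for comp, p in (("a", p_a), ("v", p_v)):
        for t, lo, hi in fsys.faces[comp]:
            f = t * (p[lo] - p[hi])
            for a, b_, fi in zip(lo, hi, f):
                face_net[(int(a), int(b_))] = face_net.get((int(a), int(b_)), 0.0) + float(fi)
    inflow_tot = np.zeros(nt)
    outflow_tot = np.zeros(nt)
    for (a, b_), f in face_net.items():
        if f == 0.0:
            continue
        src, dst = (a, b_) if f > 0 else (b_, a)
        m = rho_b * abs(f)
        voxel_inflows[dst].append((src, m))
        inflow_tot[dst] += abs(f)
        outflow_tot[src] += abs(f)

    # ---- vessel topology ----------------------------------------------
    elem_keys: list[tuple[str, str]] = []
    for kind in ("artery", "vein"):
        if kind in trees:
            elem_keys += [(kind, el.id) for el in trees[kind].elements]
    elem_contrib: dict = {k: [] for k in elem_keys}
    pinned: set = set()
    exits: list = []
    max_err = 0.0
    # scale closure errors by the largest volumetric rate in the solution,
    # floored at the round-off level of the rate computations themselves
    # (rates are conductance * pressure differences: near equilibrium every
    # rate is noise and closure is trivially satisfied)
    rates = [abs(root_flows(flow)["arterial_in"])]
    rates += [abs(q) for q in flow.element_flows.values()]
    rates += [abs(q) for q in flow.soi_flows.values()]
    rates += [abs(f) for f in face_net.values()]
    max_kappa = max(
        (el.conductance(fsys.params.mu) for tree in trees.values()
         for el in tree.elements), default=0.0,
    )
    p_scale = max((abs(p) for p in flow.node_pressures.values()), default=0.0)
    noise_floor = 1e-8 * max_kappa * p_scale
    scale = max([noise_floor] + rates)
    if scale == 0.0:
        scale = np.inf  # no vessels and no flow: nothing to close

    for kind, tree in trees.items():
        delivers, draws = _element_flow_dirs(tree, kind, flow.element_flows)
        roots = set(tree.roots)
        term_elems = tree.terminal_elements()

        # node pools
        for nid in tree.nodes:
            node_in: list[tuple[tuple, float]] = [
                (("elem", key), rho_b * q) for key, q in delivers.get(nid, [])
            ]
            out_elems = draws.get(nid, [])
            out_total = rho_b * sum(q for _, q in out_elems)
            tissue_m = 0.0
            if nid in term_elems:
                q_soi = flow.soi_flows[(kind, nid)]
                vox_lin, w = fsys.coupling.weights[(kind, nid)]
                pos = np.searchsorted(fsys.tissue_linear, vox_lin)
                if q_soi < 0:  # tissue delivers into the node
                    for r, wi in zip(pos, w):
                        m = rho_b * wi * (-q_soi)
                        node_in.append((("voxel", int(r)), m))
                        voxel_sinks[int(r)].append(((kind, nid), m))
                else:
                    tissue_m = rho_b * q_soi
            if nid in roots:
                if kind == "artery":
                    # boundary inflow feeds the tree at T_in
                    net = out_total - sum(m for _, m in node_in)
                    if net > 0:
                        node_in.append((INLET, net))
                else:
                    # venous root: node pool exits the domain
                    exits.extend(node_in)
                    continue
            total_in = sum(m for _, m in node_in)
            total_out = out_total + tissue_m
            if total_in + total_out > 0:
                max_err = max(max_err, abs(total_in - total_out) / (rho_b * scale))
            if total_in <= 0.0:
                continue
            # distribute the pool proportionally to the drawers
            for key, q in out_elems:
                m_draw = rho_b * q
                for src, m_src in node_in:
                    elem_contrib[key].append((src, m_draw * m_src / total_in))
            if tissue_m > 0.0:
                q_soi = flow.soi_flows[(kind, nid)]
                vox_lin, w = fsys.coupling.weights[(kind, nid)]
                pos = np.searchsorted(fsys.tissue_linear, vox_lin)
                for r, wi in zip(pos, w):
                    m_vox = rho_b * wi * q_soi
                    for src, m_src in node_in:
                        m_part = m_vox * m_src / total_in
                        if src == INLET:
                            voxel_sources[int(r)].append((INLET, m_part))
                        elif src[0] == "elem":
                            voxel_sources[int(r)].append((src[1], m_part))
                        else:  # voxel-to-voxel through a node: fold back
                            voxel_inflows[int(r)].append((src[1], m_part))
                    inflow_tot[int(r)] += wi * q_soi

        # pin arterial root elements to T_in
        if kind == "artery":
            g = tree.graph()
            for r in roots:
                for nbr in g.neighbors(r):
                    pinned.add((kind, g.edges[r, nbr]["element"].id))

    # ---- per-voxel closure against the flow solution -------------------
    for r in range(nt):
        src = sum(m for _, m in voxel_sources[r]) / rho_b
        snk = sum(m for _, m in voxel_sinks[r]) / rho_b
        net = inflow_tot[r] + 0.0 - outflow_tot[r] - snk
        # inflow_tot already includes sources folded in above
        err = abs(net) / scale
        max_err = max(max_err, err)
        del src
    if max_err > closure_rtol:
        raise AssemblyError(
            f"advection-graph mass closure violated: max relative error "
            f"{max_err:.3e} exceeds {closure_rtol:.1e}; the flow solution is "
            f"inconsistent or under-converged"
        )
    return AdvectionGraph(elem_keys, voxel_inflows, voxel_sources, voxel_sinks,
                          elem_contrib, pinned, exits, max_err, rho_b)


@dataclass
class HeatSystem:
    """Assembled thermal system plus index context."""

    system: LinearSystem
    grid: VoxelGrid
    params: ThermalParams
    graph: AdvectionGraph
    tissue_linear: np.ndarray
    elem_cols: dict[tuple[str, str], int]
    ambient_faces: list[tuple[int, float]]        # (tissue row, U*A)
    contact_faces: list[tuple[int, int, float]]   # (tissue row, elem col, U*A)
    trees: dict = field(default_factory=dict)


def assemble_heat_system(
    grid: VoxelGrid,
    flow: FlowSolution | None,
    graph: AdvectionGraph,
    params: ThermalParams,
    trees: dict | None = None,
    voxel_dirichlet: list[tuple[int, float]] | None = None,
) -> HeatSystem:
    """Assemble the sparse steady-state thermal system.

    ``trees`` defaults to the flow system's trees; it supplies the
    member-voxel -> element ownership needed for wall-convection faces.
    ``voxel_dirichlet`` pins tissue temperatures at given linear voxel
    indices (verification fixtures).
    """
    if trees is None:
        trees = flow.system.trees if flow is not None else {}
    tl = grid.tissue_linear
    nt = tl.size
    pos = -np.ones(grid.n_voxels, dtype=int)
    pos[tl] = np.arange(nt)
    V = grid.voxel_volume

    elem_cols = {key: nt + i for i, key in enumerate(graph.elem_keys)}
    n = nt + len(graph.elem_keys)

    owner: dict[int, tuple[str, str]] = {}
    for kind, tree in trees.items():
        for vox, eid in tree.voxel_owner().items():
            owner[vox] = (kind, eid)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b = np.zeros(n)

    def exchange(r, c, coeff):
        # adds coeff*(T_c - T_r) to row r  ==>  diag += coeff, off -= coeff
        rows.append(r); cols.append(r); vals.append(coeff)
        rows.append(r); cols.append(c); vals.append(-coeff)

    lab = grid.labels.ravel()
    tissue_lab = int(Material.TISSUE)
    ambient_faces: list[tuple[int, float]] = []
    contact_faces: list[tuple[int, int, float]] = []

    for axis, area, ds, lo, hi, amb in face_arrays(grid):
        U_t = overall_U("tissue", ds, params.K_t)
        U_inf = overall_U("air", ds, params.K_t, params.h_inf)
        U_b = overall_U("vessel", ds, params.K_t, params.h_b)
        for a, b_ in zip(lo, hi):
            la, lb = lab[a], lab[b_]
            if la == tissue_lab and lb == tissue_lab:
                ra, rb = pos[a], pos[b_]
                exchange(ra, rb, U_t * area)
                exchange(rb, ra, U_t * area)
            elif la == tissue_lab or lb == tissue_lab:
                t_lin, v_lin = (a, b_) if la == tissue_lab else (b_, a)
                if U_b == 0.0:
                    continue
                key = owner.get(int(v_lin))
                if key is None:
                    raise AssemblyError(
                        f"vessel voxel {int(v_lin)} is not covered by any "
                        f"tree element (member_voxels incomplete)"
                    )
                r, c = pos[t_lin], elem_cols[key]
                exchange(r, c, U_b * area)
                exchange(c, r, U_b * area)
                contact_faces.append((int(pos[t_lin]), c, U_b * area))
            # vessel-vessel faces: interior to the isothermal elements
        if U_inf > 0.0:
            for a in amb:
                if lab[a] != tissue_lab:
                    continue
                r = pos[a]
                rows.append(r); cols.append(r); vals.append(U_inf * area)
                b[r] += U_inf * area * params.T_inf
                ambient_faces.append((int(r), U_inf * area))

    # ---- advection ------------------------------------------------------
    cpb = params.c_pb
    for r in range(nt):
        for src, m in graph.voxel_inflows[r]:
            exchange(r, src, m * cpb)
        for key, m in graph.voxel_sources[r]:
            if key == INLET:
                rows.append(r); cols.append(r); vals.append(m * cpb)
                b[r] += m * cpb * params.T_in
            else:
                exchange(r, elem_cols[key], m * cpb)
        b[r] += params.qdot_m * V

    for key in graph.elem_keys:
        c = elem_cols[key]
        if key in graph.pinned:
            continue
        for src, m in graph.elem_contrib[key]:
            if src == INLET:
                rows.append(c); cols.append(c); vals.append(m * cpb)
                b[c] += m * cpb * params.T_in
            elif src[0] == "elem":
                exchange(c, elem_cols[src[1]], m * cpb)
            else:
                exchange(c, int(src[1]), m * cpb)

    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    dirichlet: dict[int, float] = {elem_cols[k]: params.T_in for k in graph.pinned}
    for lin, value in voxel_dirichlet or ():
        r = pos[lin]
        if r < 0:
            raise AssemblyError(f"voxel Dirichlet at non-tissue voxel {lin}")
        dirichlet[int(r)] = float(value)
    if dirichlet:
        dir_rows = np.fromiter(dirichlet.keys(), dtype=int)
        keep = np.ones(n)
        keep[dir_rows] = 0.0
        A = (sp.diags(keep) @ A).tocsr() + sp.coo_matrix(
            (np.ones(dir_rows.size), (dir_rows, dir_rows)), shape=(n, n)
        ).tocsr()
        A.eliminate_zeros()
        for r, v in dirichlet.items():
            b[r] = v

    # structural singularity: nothing anchors the temperature level
    has_inlet = any(
        src == INLET for lst in graph.voxel_sources for src, _ in lst
    ) or any(
        src == INLET for lst in graph.elem_contrib.values() for src, _ in lst
    )
    if not (dirichlet or ambient_faces or has_inlet):
        raise AssemblyError(
            "thermal system has no anchor (no Dirichlet temperature, no "
            "ambient face, no inlet blood): the steady problem is singular"
        )

    # detect isolated thermal unknowns early
    row_counts = np.diff(A.indptr)
    if np.any(row_counts == 0):
        bad = np.flatnonzero(row_counts == 0)[:5]
        raise AssemblyError(
            f"isolated thermal unknowns (zero rows) at indices {bad.tolist()}; "
            f"the domain has no heat path (all faces sealed and no advection)"
        )
    blocks = {"T_t": (0, nt), "T_elem": (nt, n)}
    return HeatSystem(LinearSystem(A, b, blocks), grid, params, graph, tl,
                      elem_cols, ambient_faces, contact_faces, trees)


@dataclass
class ThermalSolution:
    """Solved temperature fields.

    ``T_t`` is a full raster (NaN outside tissue); ``T_elem`` maps
    element key -> temperature; ``energy_residual`` is the maximum
    absolute row residual of the physical (unscaled) system in watts.
    """

    system: HeatSystem
    x: np.ndarray
    T_t: np.ndarray
    T_elem: dict[tuple[str, str], float]
    energy_residual: float
    solver_info: dict

    def element_raster(self) -> np.ndarray:
        """Full raster with element temperatures broadcast to member voxels."""
        out = np.array(self.T_t, copy=True).ravel()
        for kind, tree in self.system.trees.items():
            for el in tree.elements:
                for vox in el.member_voxels:
                    out[vox] = self.T_elem[(kind, el.id)]
        return out.reshape(self.system.grid.shape)

    def all_temperatures(self) -> np.ndarray:
        """Concatenated tissue + element temperatures (the thermal unknowns)."""
        return self.x.copy()


def solve_heat(
    hsys: HeatSystem,
    tol: float = 1e-8,
    method: str = "auto",
    preconditioner: str = "ilu",
    **solver_kwargs,
) -> ThermalSolution:
    x, info = solve_linear(hsys.system, tol=tol, method=method,
                           preconditioner=preconditioner, **solver_kwargs)
    grid = hsys.grid
    nt = hsys.tissue_linear.size
    T_t = np.full(grid.n_voxels, np.nan)
    T_t[hsys.tissue_linear] = x[:nt]
    T_elem = {key: float(x[c]) for key, c in hsys.elem_cols.items()}
    resid = float(np.abs(hsys.system.residual(x)).max()) if hsys.system.n else 0.0
    return ThermalSolution(hsys, x, T_t.reshape(grid.shape), T_elem, resid, info)


def energy_balance_report(sol: ThermalSolution) -> dict:
    """Audit steady-state energy conservation of a solved thermal field.

    Totals (W): advective enthalpy entering at arterial roots (at T_in),
    advective enthalpy leaving at venous roots, convective exchange from
    pinned (inlet-temperature) elements into tissue, net ambient loss,
    and metabolic generation.  ``closure`` should vanish to solver
    tolerance; ``closure_relative`` is normalized by the gross input.
    """
    hsys = sol.system
    graph = hsys.graph
    params = hsys.params
    cpb = params.c_pb
    nt = hsys.tissue_linear.size
    x = sol.x

    def src_temp(src) -> float:
        if src == INLET:
            return params.T_in
        if src[0] == "elem":
            return sol.T_elem[src[1]]
        return float(x[int(src[1])])

    adv_in = 0.0
    for r in range(nt):
        for key, m in graph.voxel_sources[r]:
            if key == INLET:
                adv_in += m * cpb * params.T_in
            elif key in graph.pinned:
                adv_in += m * cpb * params.T_in
    for key, contribs in graph.elem_contrib.items():
        if key in graph.pinned:
            continue
        for src, m in contribs:
            if src == INLET or (src[0] == "elem" and src[1] in graph.pinned):
                adv_in += m * cpb * params.T_in

    adv_out = sum(m * cpb * src_temp(src) for src, m in graph.exits)
    conv_pinned = sum(
        UA * (params.T_in - x[r])
        for r, c, UA in hsys.contact_faces
        if _col_key(hsys, c) in graph.pinned
    )
    ambient_loss = sum(UA * (x[r] - params.T_inf) for r, UA in hsys.ambient_faces)
    metabolic = params.qdot_m * hsys.grid.voxel_volume * nt

    closure = adv_in + conv_pinned + metabolic - adv_out - ambient_loss
    gross_in = abs(adv_in) + max(conv_pinned, 0.0) + max(metabolic, 0.0)
    return {
        "advective_in": adv_in,
        "advective_out": adv_out,
        "convective_from_pinned": conv_pinned,
        "ambient_loss": ambient_loss,
        "metabolic": metabolic,
        "closure": closure,
        "closure_relative": abs(closure) / max(gross_in, 1e-300),
    }


def _col_key(hsys: HeatSystem, col: int):
    for key, c in hsys.elem_cols.items():
        if c == col:
            return key
    return None
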