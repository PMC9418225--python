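"""Desk-scale synthetic problems with known closed-form behavior.

Every solver in the package is testable against these fixtures without
any external dataset:

* :func:`make_darcy_slab` -- a 1xXxn tissue bar with pinned end pressures
  and the exact linear Darcy solution attached;
* :func:`make_vessel_voxel_chain` -- one artery element, one tissue voxel,
  one vein element; the total flow follows a hand-computable series
  resistance chain (element, virtual network, compartmental perfusion,
  virtual network, element);
* :func:`make_single_vessel_slab` -- an unbranched artery over a tissue
  slab over an unbranched vein (the minimal layered configuration);
* :func:`make_three_layer_toy` -- a miniature layered organ analogue:
  an arterial comb in layer 1, tissue in layer 2, an interdigitated
  venous comb in layer 3, with default parameter magnitudes typical of a
  thin amphibian-tongue preparation (kPa pressure drops, deg-C fields).

Tree geometry is axis-aligned so member-voxel assignment is unambiguous;
labels are painted from the member-voxel sets, which guarantees every
vessel voxel has an owning element.  All fixtures regenerate
deterministically from their arguments (and seed, where one applies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .domain import Material, VoxelGrid
from .errors import ConfigurationError
from .flow import FlowParams
from .heat import ThermalParams
from .pipeline import Problem
from .vessels import VesselElement, VesselNode, VesselTree

__all__ = [
    "DarcySlab",
    "make_darcy_slab",
    "make_vessel_voxel_chain",
    "make_single_vessel_slab",
    "make_three_layer_toy",
]

#: Default voxel spacing (m): in-plane 64 um, one third of a 333 um slice.
DEFAULT_SPACING = (64e-6, 64e-6, 111e-6)


@dataclass
class DarcySlab:
    """1D porous bar with pinned end pressures and its exact solution."""

    grid: VoxelGrid
    params: FlowParams
    dirichlet: list[tuple[int, str, float]]
    expected_profile: np.ndarray  # pressure per voxel along the bar
    expected_flux: float          # volumetric flow through the bar, m^3/s
    expected_darcy_velocity: float  # u = k dP / (mu L), m/s


def make_darcy_slab(
    n_voxels: int,
    k: float = 1e-12,
    mu: float = 3e-3,
    P_left: float = 10600.0,
    P_right: float = 1600.0,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> DarcySlab:
    """1x1xn tissue slab with both compartments pinned at the two ends.

    The discrete solution is the linear profile between the end-voxel
    centers; the flux is k A dP / (mu L) with L the center-to-center
    length (n-1) dz.
    """
    if n_voxels < 2:
        raise ConfigurationError("slab needs at least 2 voxels")
    labels = np.full((1, 1, n_voxels), int(Material.TISSUE), dtype=np.int8)
    grid = VoxelGrid((1, 1, n_voxels), spacing, labels)
    params = FlowParams(k_a=k, k_v=k, mu=mu, P_in=max(P_left, P_right) + 1.0,
                        P_out=min(P_left, P_right))
    dirichlet = [
        (0, "a", P_left), (n_voxels - 1, "a", P_right),
        (0, "v", P_left), (n_voxels - 1, "v", P_right),
    ]
    profile = P_left + (P_right - P_left) * np.arange(n_voxels) / (n_voxels - 1)
    dz = spacing[2]
    area = spacing[0] * spacing[1]
    L = (n_voxels - 1) * dz
    u = k * (P_left - P_right) / (mu * L)
    return DarcySlab(grid, params, dirichlet, profile, u * area, u)


def _chain_tree(kind, xs, y, z, radius, spacing, grid, root_first=True,
                node_prefix=""):
    """Unbranched tree along consecutive x voxel positions at fixed (y, z)."""
    dx, dy, dz = spacing
    nodes = {}
    for i, x in enumerate(xs):
        nid = f"{node_prefix}n{i}"
        pos = ((x + 0.5) * dx, (y + 0.5) * dy, (z + 0.5) * dz)
        nodes[nid] = VesselNode(nid, pos, is_root=(i == 0 if root_first else i == len(xs) - 1))
    elements = []
    for i in range(len(xs) - 1):
        member = [grid.linear_index(xs[i + 1], y, z)]
        if i == 0:
            member.insert(0, grid.linear_index(xs[0], y, z))
        elements.append(
            VesselElement(
                f"{node_prefix}e{i}", f"{node_prefix}n{i}", f"{node_prefix}n{i+1}",
                radius, dx * (xs[i + 1] - xs[i]), tuple(member),
            )
        )
    return VesselTree(kind, nodes, elements)


def expected_chain_flow(problem: Problem) -> float:
    """Series-resistance total flow for a single-tissue-voxel chain.

    q = dP / (1/kappa_a + mu/gamma_a + 1/(alpha V) + mu/gamma_v + 1/kappa_v)
    with kappa_beta the series conductance of each tree's elements.
    """
    p = problem.flow_params
    V = problem.grid.voxel_volume
    r = 0.0
    for tree in (problem.arterial, problem.venous):
        r += sum(1.0 / el.conductance(p.mu) for el in tree.elements)
    r += p.mu / p.gamma_a + p.mu / p.gamma_v + 1.0 / (p.alpha * V)
    return (p.P_in - p.P_out) / r


def make_vessel_voxel_chain(
    flow_params: FlowParams | None = None,
    thermal_params: ThermalParams | None = None,
    radius: float = 30e-6,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> Problem:
    """Single artery element -> one tissue voxel -> single vein element.

    Grid is 1x1x3: artery voxel on top, tissue in the middle, vein below.
    The arterial root node sits on the top face of the artery voxel; the
    terminal at its center (likewise mirrored for the vein), so the SoI
    of each terminal holds exactly the one tissue voxel.
    Use :func:`expected_chain_flow` for the closed-form total flow.
    """
    dx, dy, dz = spacing
    labels = np.array(
        [[[int(Material.ARTERY), int(Material.TISSUE), int(Material.VEIN)]]],
        dtype=np.int8,
    )
    grid = VoxelGrid((1, 1, 3), spacing, labels)
    cx, cy = 0.5 * dx, 0.5 * dy
    a_nodes = {
        "a0": VesselNode("a0", (cx, cy, 0.0), is_root=True),
        "a1": VesselNode("a1", (cx, cy, 0.5 * dz)),
    }
    a_el = [VesselElement("ae0", "a0", "a1", radius, 0.5 * dz, (grid.linear_index(0, 0, 0),))]
    v_nodes = {
        "v0": VesselNode("v0", (cx, cy, 3.0 * dz), is_root=True),
        "v1": VesselNode("v1", (cx, cy, 2.5 * dz)),
    }
    v_el = [VesselElement("ve0", "v0", "v1", radius, 0.5 * dz, (grid.linear_index(0, 0, 2),))]
    artery = VesselTree("artery", a_nodes, a_el)
    vein = VesselTree("vein", v_nodes, v_el)
    # only one tissue voxel exists, a voxel spacing away from each terminal
    eps = 1.5 * dz
    return Problem(grid, artery, vein, eps,
                   flow_params or FlowParams(),
                   thermal_params or ThermalParams(),
                   name="vessel_voxel_chain")


def make_single_vessel_slab(
    nx: int = 8,
    epsilon: float | None = None,
    flow_params: FlowParams | None = None,
    thermal_params: ThermalParams | None = None,
    artery_radius: float = 30e-6,
    vein_radius: float = 40e-6,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> Problem:
    """Unbranched artery row over a tissue row over an unbranched vein row.

    Grid is (nx, 1, 3).  Both roots are at x = 0 and both terminals at
    x = nx-1, giving a multi-element unbranched artery whose temperature
    profile along the flow direction is monotone under finite wall
    convection.
    """
    if nx < 3:
        raise ConfigurationError("slab needs nx >= 3")
    dx, dy, dz = spacing
    labels = np.full((nx, 1, 3), int(Material.TISSUE), dtype=np.int8)
    labels[:, 0, 0] = int(Material.ARTERY)
    labels[:, 0, 2] = int(Material.VEIN)
    grid = VoxelGrid((nx, 1, 3), spacing, labels)
    xs = list(range(nx))
    artery = _chain_tree("artery", xs, 0, 0, artery_radius, spacing, grid, node_prefix="a")
    vein = _chain_tree("vein", xs, 0, 2, vein_radius, spacing, grid, node_prefix="v")
    if epsilon is None:
        # terminal at x = nx-1 must reach the farthest tissue voxel (x = 0)
        epsilon = 1.05 * np.hypot((nx - 1) * dx, dz)
    return Problem(grid, artery, vein, epsilon,
                   flow_params or FlowParams(),
                   thermal_params or ThermalParams(),
                   name="single_vessel_slab")


def _comb_tree(kind, grid, trunk_y, teeth_x, tooth_span, z, radii, spacing,
               root_x, prefix):
    """Axis-aligned comb: a trunk row with vertical teeth; terminals at
    tooth tips.  Returns the tree; member voxels cover every painted
    vessel voxel exactly once."""
    dx, dy, dz = spacing
    trunk_r, tooth_r = radii
    y0, y1 = tooth_span

    def npos(x, y):
        return ((x + 0.5) * dx, (y + 0.5) * dy, (z + 0.5) * dz)

    nodes: dict[str, VesselNode] = {}
    elements: list[VesselElement] = []
    trunk_xs = sorted({root_x, *teeth_x})
    for i, x in enumerate(trunk_xs):
        nid = f"{prefix}t{i}"
        nodes[nid] = VesselNode(nid, npos(x, trunk_y), is_root=(x == root_x))
    x_to_nid = {x: f"{prefix}t{i}" for i, x in enumerate(trunk_xs)}
    for i in range(len(trunk_xs) - 1):
        xa, xb = trunk_xs[i], trunk_xs[i + 1]
        member = [grid.linear_index(x, trunk_y, z) for x in range(xa + 1, xb + 1)]
        if i == 0:
            member.insert(0, grid.linear_index(xa, trunk_y, z))
        elements.append(
            VesselElement(f"{prefix}tr{i}", x_to_nid[xa], x_to_nid[xb],
                          trunk_r, (xb - xa) * dx, tuple(member))
        )
    for j, x in enumerate(teeth_x):
        tip_y = y1 if y1 != trunk_y else y0
        nid = f"{prefix}tip{j}"
        nodes[nid] = VesselNode(nid, npos(x, tip_y))
        ys = range(min(trunk_y, tip_y) + 1, max(trunk_y, tip_y) + 1) \
            if tip_y > trunk_y else range(tip_y, trunk_y)
        member = [grid.linear_index(x, y, z) for y in ys]
        elements.append(
            VesselElement(f"{prefix}th{j}", x_to_nid[x], nid,
                          tooth_r, abs(tip_y - trunk_y) * dy, tuple(member))
        )
    return VesselTree(kind, nodes, elements)


def make_three_layer_toy(
    nx: int = 16,
    ny: int = 16,
    tree_levels: int = 2,
    seed: int | None = None,
    epsilon: float | None = None,
    flow_params: FlowParams | None = None,
    thermal_params: ThermalParams | None = None,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
) -> Problem:
    """Miniature layered organ analogue with interdigitated vessel combs.

    Layer 1 (z=0) holds an arterial comb rooted at the left, layer 3
    (z=2) a venous comb rooted at the right; teeth alternate in x so the
    two trees never overlap in plan view.  ``tree_levels`` controls the
    number of teeth (terminals) per tree.  With an integer ``seed`` the
    boundary conditions, radii, exchange coefficients and SoI radius are
    jittered to produce randomized-but-reproducible study variants; with
    ``seed=None`` the defaults are exactly the study's magnitudes.
    """
    if nx < 8 or ny < 8:
        raise ConfigurationError("toy domain needs nx, ny >= 8")
    dx, dy, dz = spacing
    fp = flow_params or FlowParams()
    tp = thermal_params or ThermalParams()
    trunk_r, tooth_r = 30e-6, 20e-6
    eps_scale = 1.0
    if seed is not None:
        rng = np.random.default_rng(seed)
        fp = replace(
            fp,
            P_in=float(rng.uniform(8000.0, 12000.0)),
            alpha=float(fp.alpha * rng.uniform(0.5, 2.0)),
        )
        tp = replace(
            tp,
            T_in=float(rng.uniform(30.0, 40.0)),
            T_inf=float(rng.uniform(15.0, 25.0)),
            h_b=float(10.0 ** rng.uniform(-3.0, 1.0)),
            h_inf=float(rng.uniform(5.0, 50.0)),
        )
        trunk_r *= float(rng.uniform(0.8, 1.25))
        tooth_r *= float(rng.uniform(0.8, 1.25))
        eps_scale = float(rng.uniform(0.8, 1.3))

    n_teeth = max(2, tree_levels + 1)
    # arterial teeth on even x, venous on odd x, interleaved
    xa_all = list(range(2, nx - 2, 2))
    xv_all = list(range(3, nx - 2, 2))
    teeth_a = [xa_all[int(i)] for i in np.linspace(0, len(xa_all) - 1, min(n_teeth, len(xa_all)))]
    teeth_v = [xv_all[int(i)] for i in np.linspace(0, len(xv_all) - 1, min(n_teeth, len(xv_all)))]
    teeth_a = sorted(set(teeth_a))
    teeth_v = sorted(set(teeth_v))

    labels = np.full((nx, ny, 3), int(Material.TISSUE), dtype=np.int8)
    grid = VoxelGrid((nx, ny, 3), spacing, labels)

    artery = _comb_tree("artery", grid, trunk_y=1, teeth_x=teeth_a,
                        tooth_span=(1, ny - 3), z=0, radii=(trunk_r, tooth_r),
                        spacing=spacing, root_x=1, prefix="a")
    vein = _comb_tree("vein", grid, trunk_y=ny - 2, teeth_x=teeth_v,
                      tooth_span=(2, ny - 2), z=2, radii=(trunk_r, tooth_r),
                      spacing=spacing, root_x=nx - 2, prefix="v")

    # paint labels from member voxels so ownership is complete by construction
    lab = labels.ravel()
    for tree, mat in ((artery, Material.ARTERY), (vein, Material.VEIN)):
        for el in tree.elements:
            lab[list(el.member_voxels)] = int(mat)
    grid = VoxelGrid((nx, ny, 3), spacing, lab.reshape(nx, ny, 3))

    if epsilon is None:
        centers = grid.centers()
        tissue = centers[grid.tissue_linear]
        eps = 0.0
        for tree in (artery, vein):
            tpos = np.array([tree.nodes[t].position for t in tree.terminals])
            d = np.linalg.norm(tissue[:, None, :] - tpos[None, :, :], axis=2)
            eps = max(eps, float(d.min(axis=1).max()))
        epsilon = 1.1 * eps
    epsilon *= eps_scale
    return Problem(grid, artery, vein, float(epsilon), fp, tp,
                   name=f"three_layer_toy_{nx}x{ny}_L{tree_levels}_s{seed}")
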