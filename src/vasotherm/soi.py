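"""Sphere-of-influence (SoI) coupling between vessel terminals and tissue.

Each terminal of a resolved vessel tree exchanges blood with the tissue
voxels inside a ball of characteristic radius epsilon around it, standing
in for the unresolved pre-capillary network.  The exchange is distributed
by a smooth compact-support mollifier

    eta^eps(x) = (C / eps^n) * exp(1 / (|x/eps|^2 - 1))   for |x| < eps,
    eta^eps(x) = 0                                        otherwise,

normalized so that the discrete voxel-center quadrature
sum_i eta^eps(x_i - x_k) V_i equals 1 for every terminal k.  Calibrating
the constant C against the discrete quadrature (rather than the continuous
integral) makes the distribution exactly mass-conservative on the mesh,
including where the ball is clipped by the domain boundary.

The spatial dimension n only rescales C; because C is re-calibrated
discretely it has no effect on the normalized weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .domain import VoxelGrid
from .errors import CouplingError
from .vessels import VesselTree

__all__ = [
    "Mollifier",
    "CouplingMap",
    "mollifier_value",
    "calibrate_constant",
    "build_coupling_map",
    "save_coupling_json",
    "load_coupling_json",
]


@dataclass(frozen=True)
class Mollifier:
    """Compact-support bump of radius ``epsilon`` with normalization ``C``."""

    epsilon: float
    C: float = 1.0
    n: int = 3

    def __post_init__(self):
        if self.epsilon <= 0:
            raise CouplingError("mollifier epsilon must be > 0")
        if self.C <= 0:
            raise CouplingError("mollifier constant C must be > 0")


def _bump(scaled_sq: np.ndarray) -> np.ndarray:
    """exp(1/(s-1)) for s = |x/eps|^2 < 1, else 0 (vectorized, total)."""
    s = np.asarray(scaled_sq, dtype=float)
    out = np.zeros_like(s)
    inside = s < 1.0
    with np.errstate(divide="ignore"):
        out[inside] = np.exp(1.0 / (s[inside] - 1.0))
    return out


def mollifier_value(r, mollifier: Mollifier):
    """Evaluate eta^eps at displacement(s) ``r`` (meters).

    ``r`` may be a single 3-vector, an (m, 3) array of displacements, or
    an array of radial distances.  Returns density values in m^-n:
    (C/eps^n) exp(1/(|r/eps|^2 - 1)) inside the support, exactly 0 at and
    beyond |r| = eps.  The function is continuous, radially symmetric and
    strictly decreasing in |r|.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim >= 1 and r.shape[-1] == 3 and r.ndim <= 2:
        dist_sq = np.sum(r * r, axis=-1)
    else:
        dist_sq = r * r
    scaled = dist_sq / mollifier.epsilon**2
    vals = mollifier.C / mollifier.epsilon**mollifier.n * _bump(scaled)
    if np.isscalar(scaled) or vals.ndim == 0:
        return float(vals)
    return vals


def _raw_quadrature(grid: VoxelGrid, terminal_position, epsilon: float,
                    tissue_linear: np.ndarray):
    """Unnormalized bump values at eligible tissue voxel centers.

    Returns (voxel linear indices inside the support, raw values with the
    voxel volume folded in, i.e. (1/eps^3) * bump * V_i).
    """
    pos = np.asarray(terminal_position, dtype=float)
    centers = grid.centers()[tissue_linear]
    d_sq = np.sum((centers - pos) ** 2, axis=1)
    inside = d_sq < epsilon**2
    raw = _bump(d_sq[inside] / epsilon**2) / epsilon**3 * grid.voxel_volume
    return tissue_linear[inside], raw


def calibrate_constant(
    grid: VoxelGrid,
    terminal_position,
    epsilon: float,
    tissue_mask: np.ndarray | None = None,
) -> float:
    """Normalization constant C for one terminal on a given grid.

    C is chosen so that the voxel-center quadrature
    sum_i eta^eps(x_i - x_k) V_i over eligible tissue voxels equals 1
    exactly (to round-off).

    Raises
    ------
    CouplingError
        If no tissue voxel center lies strictly inside the support --
        the SoI radius is too small for the grid.
    """
    if tissue_mask is None:
        tissue_linear = grid.tissue_linear
    else:
        tissue_linear = np.flatnonzero(np.asarray(tissue_mask).ravel())
    idx, raw = _raw_quadrature(grid, terminal_position, epsilon, tissue_linear)
    total = float(raw.sum())
    if idx.size == 0 or total <= 0.0:
        raise CouplingError(
            f"empty sphere of influence at terminal position "
            f"{np.asarray(terminal_position).tolist()} with epsilon={epsilon}"
        )
    return 1.0 / total


@dataclass
class CouplingMap:
    """Per-terminal SoI weights plus the voxel -> terminal reverse index.

    ``weights`` maps a terminal key ``(kind, node_id)`` to a pair of
    arrays ``(voxel linear indices, weights)`` with the weights summing
    to 1.  ``mollifiers`` records the calibrated constant per terminal.
    The map is treated as immutable after construction.
    """

    epsilon: float
    weights: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    mollifiers: dict[tuple[str, str], Mollifier]
    reverse: dict[int, list[tuple[str, str]]] = field(repr=False)
    coverage: dict[str, float] = field(default_factory=dict)

    def terminals(self, kind: str | None = None):
        keys = sorted(self.weights)
        if kind is None:
            return keys
        return [k for k in keys if k[0] == kind]

    def weight_sum(self, key) -> float:
        return float(self.weights[key][1].sum())


def _terminal_weights(grid, tree, epsilon, tissue_linear):
    out = {}
    mols = {}
    for tid in tree.terminals:
        pos = tree.nodes[tid].position
        idx, raw = _raw_quadrature(grid, pos, epsilon, tissue_linear)
        total = float(raw.sum())
        if idx.size == 0 or total <= 0.0:
            raise CouplingError(
                f"terminal {tid} of {tree.kind} tree has an empty sphere of "
                f"influence (epsilon={epsilon} too small for the grid)"
            )
        out[(tree.kind, tid)] = (idx, raw / total)
        mols[(tree.kind, tid)] = Mollifier(epsilon, C=1.0 / total, n=3)
    return out, mols


def build_coupling_map(
    grid: VoxelGrid,
    arterial_tree: VesselTree,
    venous_tree: VesselTree,
    epsilon: float,
    warn=None,
) -> CouplingMap:
    """Build the calibrated terminal -> voxel weight map for both trees.

    Weights are computed over TISSUE voxels only (vessel-labeled and
    ambient voxels are excluded from SoI membership), each terminal's
    weight list normalized to sum to 1.  Coverage statistics record the
    fraction of tissue voxels with at least one arterial source and at
    least one venous sink; incomplete coverage triggers ``warn`` (a
    callable receiving a message) but is not an error.
    """
    if epsilon <= 0:
        raise CouplingError("epsilon must be > 0")
    tissue_linear = grid.tissue_linear
    weights: dict = {}
    mols: dict = {}
    for tree in (arterial_tree, venous_tree):
        if tree is None:
            continue
        w, m = _terminal_weights(grid, tree, epsilon, tissue_linear)
        weights.update(w)
        mols.update(m)

    reverse: dict[int, list] = {}
    a_covered = np.zeros(grid.n_voxels, dtype=bool)
    v_covered = np.zeros(grid.n_voxels, dtype=bool)
    for key, (idx, _) in weights.items():
        for i in idx:
            reverse.setdefault(int(i), []).append(key)
        if key[0] == "artery":
            a_covered[idx] = True
        else:
            v_covered[idx] = True

    nt = tissue_linear.size
    coverage = {
        "arterial_source_fraction": float(a_covered[tissue_linear].mean()) if nt else 0.0,
        "venous_sink_fraction": float(v_covered[tissue_linear].mean()) if nt else 0.0,
    }
    if warn is not None:
        for name, frac in coverage.items():
            if frac < 1.0:
                warn(
                    f"SoI coverage incomplete: {name} = {frac:.3f} "
                    f"(epsilon={epsilon}); some voxels rely on cross-voxel "
                    f"permeability alone"
                )
    return CouplingMap(epsilon, weights, mols, reverse, coverage)


def save_coupling_json(cmap: CouplingMap, path) -> None:
    data = {
        "schema": "vasotherm-coupling-v1",
        "epsilon": cmap.epsilon,
        "coverage": cmap.coverage,
        "terminals": {
            f"{kind}:{tid}": {
                "C": cmap.mollifiers[(kind, tid)].C,
                "voxels": idx.tolist(),
                "weights": w.tolist(),
            }
            for (kind, tid), (idx, w) in sorted(cmap.weights.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def load_coupling_json(path) -> CouplingMap:
    with open(path) as fh:
        data = json.load(fh)
    eps = float(data["epsilon"])
    weights = {}
    mols = {}
    reverse: dict[int, list] = {}
    for key_str, rec in data["terminals"].items():
        kind, tid = key_str.split(":", 1)
        idx = np.asarray(rec["voxels"], dtype=int)
        w = np.asarray(rec["weights"], dtype=float)
        weights[(kind, tid)] = (idx, w)
        mols[(kind, tid)] = Mollifier(eps, C=float(rec["C"]), n=3)
        for i in idx:
            reverse.setdefault(int(i), []).append((kind, tid))
    return CouplingMap(eps, weights, mols, reverse, data.get("coverage", {}))
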