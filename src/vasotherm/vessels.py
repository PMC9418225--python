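"""Resolved 1D vessel trees.

Arterial and venous trees are directed graphs of pressure nodes connected
by cylindrical elements.  Element flow obeys the Hagen-Poiseuille law
q_ji = kappa_ji * (p_j - p_i) with conductance kappa = pi R^4 / (8 mu L);
flow direction is determined by the solved pressure field, so q may be
negative relative to the file's (j, i) orientation.

Terminal nodes (degree-1, non-root) are where the resolved tree hands
flow to the unresolved microvasculature, modeled elsewhere via the
sphere-of-influence coupling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigurationError

__all__ = [
    "VesselNode",
    "VesselElement",
    "VesselTree",
    "element_conductance",
    "find_terminals",
    "load_tree_json",
    "save_tree_json",
]

#: Relative tolerance for checking stored element length against the
#: Euclidean node distance.
LENGTH_RTOL = 1e-6


def element_conductance(radius: float, length: float, mu: float) -> float:
    """Hagen-Poiseuille conductance pi R^4 / (8 mu L) in m^3 Pa^-1 s^-1.

    Its reciprocal is the element's hydraulic resistance.
    """
    if radius <= 0 or length <= 0 or mu <= 0:
        raise ConfigurationError(
            f"element_conductance requires positive R, L, mu; got "
            f"R={radius}, L={length}, mu={mu}"
        )
    return math.pi * radius**4 / (8.0 * mu * length)


@dataclass(frozen=True)
class VesselNode:
    id: str
    position: np.ndarray  # (3,) meters
    is_root: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ConfigurationError(f"node {self.id}: position must be 3D")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class VesselElement:
    """Cylindrical vessel segment between nodes ``node_j`` (inlet side by
    file convention) and ``node_i`` (outlet side)."""

    id: str
    node_j: str
    node_i: str
    radius: float
    length: float
    member_voxels: tuple[int, ...] = ()

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigurationError(f"element {self.id}: radius must be > 0")
        if self.length <= 0:
            raise ConfigurationError(f"element {self.id}: length must be > 0")
        object.__setattr__(self, "member_voxels", tuple(int(v) for v in self.member_voxels))

    def conductance(self, mu: float) -> float:
        return element_conductance(self.radius, self.length, mu)


@dataclass
class VesselTree:
    """A connected vessel tree with at least one Dirichlet root node."""

    kind: str  # "artery" or "vein"
    nodes: dict[str, VesselNode]
    elements: list[VesselElement]
    length_override: bool = False
    _graph: nx.Graph = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.kind not in ("artery", "vein"):
            raise ConfigurationError(f"tree kind must be artery|vein, got {self.kind!r}")
        self.validate()

    # ---- structure ------------------------------------------------------
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(self.nodes)
            for el in self.elements:
                g.add_edge(el.node_j, el.node_i, element=el)
            self._graph = g
        return self._graph

    @property
    def roots(self) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.is_root)

    @property
    def terminals(self) -> list[str]:
        return find_terminals(self)

    def validate(self) -> None:
        if not self.nodes:
            raise ConfigurationError(f"{self.kind} tree has no nodes")
        if not self.elements:
            raise ConfigurationError(f"{self.kind} tree has no elements")
        for el in self.elements:
            for nid in (el.node_j, el.node_i):
                if nid not in self.nodes:
                    raise ConfigurationError(
                        f"{self.kind} tree: element {el.id} references unknown node {nid}"
                    )
            if not self.length_override:
                dist = float(
                    np.linalg.norm(
                        self.nodes[el.node_j].position - self.nodes[el.node_i].position
                    )
                )
                if dist > 0 and abs(el.length - dist) > LENGTH_RTOL * max(dist, el.length):
                    raise ConfigurationError(
                        f"{self.kind} tree: element {el.id} length {el.length} "
                        f"differs from node distance {dist} (set length_override "
                        f"to accept file lengths)"
                    )
        roots = self.roots
        if not roots:
            raise ConfigurationError(f"{self.kind} tree has no root node")
        g = self.graph()
        for r in roots:
            if g.degree(r) == 0:
                raise ConfigurationError(
                    f"{self.kind} tree: root {r} has no incident element"
                )
        reachable = set()
        for r in roots:
            reachable |= nx.node_connected_component(g, r)
        missing = set(self.nodes) - reachable
        if missing:
            raise ConfigurationError(
                f"{self.kind} tree: nodes unreachable from any root: {sorted(missing)[:5]}"
            )

    # ---- convenience ----------------------------------------------------
    def element_by_id(self, eid: str) -> VesselElement:
        for el in self.elements:
            if el.id == eid:
                return el
        raise KeyError(eid)

    def terminal_elements(self) -> dict[str, VesselElement]:
        """Map terminal node id -> its unique incident element."""
        g = self.graph()
        out = {}
        for t in self.terminals:
            nbrs = list(g.neighbors(t))
            out[t] = g.edges[t, nbrs[0]]["element"]
        return out

    def node_positions(self) -> dict[str, np.ndarray]:
        return {nid: n.position for nid, n in self.nodes.items()}

    def voxel_owner(self) -> dict[int, str]:
        """Map member voxel linear index -> owning element id."""
        owner: dict[int, str] = {}
        for el in self.elements:
            for v in el.member_voxels:
                owner[v] = el.id
        return owner


def find_terminals(tree: VesselTree) -> list[str]:
    """Degree-1 non-root nodes, sorted by id.

    For an arterial tree these are outflow points into tissue; for a
    venous tree they are inflow points collecting from tissue.
    """
    g = tree.graph()
    return sorted(
        nid for nid in tree.nodes
        if g.degree(nid) == 1 and not tree.nodes[nid].is_root
    )


# ---------------------------------------------------------------------------
# JSON schema (versioned):
# {"schema": "vasotherm-tree-v1", "kind": "artery",
#  "nodes": [{"id", "x", "y", "z", "root": bool}],
#  "elements": [{"id", "node_j", "node_i", "radius",
#                "length"?, "member_voxels"?}]}
# All coordinates/lengths in meters.
# ---------------------------------------------------------------------------

SCHEMA = "vasotherm-tree-v1"


def load_tree_json(path) -> VesselTree:
    with open(path) as fh:
        data = json.load(fh)
    return tree_from_dict(data)


def tree_from_dict(data: dict) -> VesselTree:
    if data.get("schema", SCHEMA) != SCHEMA:
        raise ConfigurationError(f"unsupported tree schema {data.get('schema')!r}")
    try:
        nodes = {
            n["id"]: VesselNode(n["id"], (n["x"], n["y"], n["z"]), bool(n.get("root", False)))
            for n in data["nodes"]
        }
    except KeyError as exc:
        raise ConfigurationError(f"tree node missing field {exc}") from exc
    elements = []
    any_override = False
    for e in data.get("elements", []):
        try:
            length = e.get("length")
            if length is None:
                length = float(
                    np.linalg.norm(nodes[e["node_j"]].position - nodes[e["node_i"]].position)
                )
            else:
                any_override = True
            elements.append(
                VesselElement(
                    str(e["id"]), e["node_j"], e["node_i"],
                    float(e["radius"]), float(length),
                    tuple(e.get("member_voxels", ())),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(
                f"tree element {e.get('id', '?')} missing field {exc}"
            ) from exc
    return VesselTree(data["kind"], nodes, elements, length_override=any_override)


def save_tree_json(tree: VesselTree, path) -> None:
    data = {
        "schema": SCHEMA,
        "kind": tree.kind,
        "nodes": [
            {
                "id": n.id,
                "x": float(n.position[0]),
                "y": float(n.position[1]),
                "z": float(n.position[2]),
                "root": bool(n.is_root),
            }
            for n in tree.nodes.values()
        ],
        "elements": [
            {
                "id": el.id,
                "node_j": el.node_j,
                "node_i": el.node_i,
                "radius": el.radius,
                "length": el.length,
                "member_voxels": list(el.member_voxels),
            }
            for el in tree.elements
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
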