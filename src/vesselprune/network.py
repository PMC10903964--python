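"""Spatial vascular-graph data model and topology computations.

A vascular network is an undirected spatial graph: nodes carry 2-D
positions (μm) and a boundary role, vessels (edges) carry a diameter and
a length (μm).  The number of independent loops is obtained through the
Euler–Poincaré formula ``β1 = β0 − N_N + N_V``, where β0 is the number
of connected components, N_N the node count and N_V the vessel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Tuple

import networkx as nx

__all__ = [
    "Node",
    "Vessel",
    "VascularNetwork",
    "TopologySummary",
    "NetworkValidationError",
    "degree_census",
    "betti_numbers",
    "beta1_per_vessel_from_degrees",
]

#: minimum admissible vessel diameter (μm); the diameter-dependent blood
#: viscosity law contains the factor d/(d − 1.1) and is undefined below it.
MIN_DIAMETER_UM = 1.1

ROLES = ("interior", "inlet", "outlet")


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


@dataclass(frozen=True)
class Node:
    """A network node: junction, boundary node, or sprout tip."""

    id: int
    x: float
    y: float
    role: str = "interior"

    @property
    def position(self) -> Tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Vessel:
    """A vessel segment joining two nodes.

    Diameter and length are in μm.  Endpoints are stored as an
    unordered pair; ``node_a < node_b`` is not required.
    """

    id: int
    node_a: int
    node_b: int
    diameter: float
    length: float

    @property
    def endpoints(self) -> Tuple[int, int]:
        return (self.node_a, self.node_b)


@dataclass
class VascularNetwork:
    """An undirected spatial graph of vessels.

    The class stores nodes and vessels keyed by id and offers the
    bookkeeping needed by the flow solver and the pruning loop:
    degree census, connected components, Betti numbers, and vessel
    removal with orphan-node cleanup.
    """

    nodes: Dict[int, Node] = field(default_factory=dict)
    vessels: Dict[int, Vessel] = field(default_factory=dict)
    _edges: set = field(default_factory=set, repr=False, compare=False)

    def _edge_set(self) -> set:
        if not self._edges and self.vessels:
            self._edges = {frozenset(v.endpoints) for v in self.vessels.values()}
        return self._edges

    # -- construction -------------------------------------------------

    def add_node(self, id: int, x: float, y: float, role: str = "interior") -> Node:
        if id in self.nodes:
            raise NetworkValidationError(f"duplicate node id {id}")
        if role not in ROLES:
            raise NetworkValidationError(f"unknown node role {role!r}")
        node = Node(id, float(x), float(y), role)
        self.nodes[id] = node
        return node

    def add_vessel(self, id: int, node_a: int, node_b: int,
                   diameter: float, length: float) -> Vessel:
        if id in self.vessels:
            raise NetworkValidationError(f"duplicate vessel id {id}")
        if node_a == node_b:
            raise NetworkValidationError(f"vessel {id} is a self-loop at node {node_a}")
        for n in (node_a, node_b):
            if n not in self.nodes:
                raise NetworkValidationError(f"vessel {id} references missing node {n}")
        if diameter <= 0:
            raise NetworkValidationError(f"vessel {id} has non-positive diameter {diameter}")
        if length <= 0:
            raise NetworkValidationError(f"vessel {id} has non-positive length {length}")
        key = frozenset((node_a, node_b))
        if key in self._edge_set():
            raise NetworkValidationError(
                f"vessel {id} duplicates the edge {node_a}-{node_b}")
        vessel = Vessel(id, node_a, node_b, float(diameter), float(length))
        self.vessels[id] = vessel
        self._edges.add(key)
        return vessel

    # -- basic counts -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_vessels(self) -> int:
        return len(self.vessels)

    def mean_diameter(self) -> float:
        if not self.vessels:
            raise NetworkValidationError("empty network has no mean diameter")
        return sum(v.diameter for v in self.vessels.values()) / self.n_vessels

    def mean_length(self) -> float:
        if not self.vessels:
            raise NetworkValidationError("empty network has no mean length")
        return sum(v.length for v in self.vessels.values()) / self.n_vessels

    # -- graph views --------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        """Topology as a :class:`networkx.Graph` (vessel ids on edges)."""
        g = nx.Graph()
        for node in self.nodes.values():
            g.add_node(node.id, x=node.x, y=node.y, role=node.role)
        for v in self.vessels.values():
            g.add_edge(v.node_a, v.node_b, vessel_id=v.id,
                       diameter=v.diameter, length=v.length)
        return g

    def connected_components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    # -- mutation -----------------------------------------------------

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(dict(self.nodes), dict(self.vessels))

    def remove_vessel(self, vessel_id: int, drop_orphans: bool = True) -> None:
        """Delete a vessel; nodes left with no incident vessel are removed.

        Orphan deletion keeps the node count in step with the visible
        structure so that the Euler-formula loop count tracks the
        remaining network.
        """
        if vessel_id not in self.vessels:
            raise KeyError(f"no vessel with id {vessel_id}")
        self._edges.discard(frozenset(self.vessels[vessel_id].endpoints))
        del self.vessels[vessel_id]
        if drop_orphans:
            used: set[int] = set()
            for v in self.vessels.values():
                used.add(v.node_a)
                used.add(v.node_b)
            for nid in [n for n in self.nodes if n not in used]:
                del self.nodes[nid]

    def with_roles(self, roles: Mapping[int, str]) -> "VascularNetwork":
        """Return a copy with node roles replaced according to ``roles``."""
        net = self.copy()
        for nid, role in roles.items():
            if role not in ROLES:
                raise NetworkValidationError(f"unknown node role {role!r}")
            net.nodes[nid] = replace(net.nodes[nid], role=role)
        return net

    def nodes_with_role(self, role: str) -> list[int]:
        return [n.id for n in self.nodes.values() if n.role == role]

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants, raising on the first violation."""
        seen_edges = set()
        incident: Dict[int, int] = {n: 0 for n in self.nodes}
        for v in self.vessels.values():
            if v.node_a == v.node_b:
                raise NetworkValidationError(f"vessel {v.id} is a self-loop")
            for n in v.endpoints:
                if n not in self.nodes:
                    raise NetworkValidationError(
                        f"vessel {v.id} references missing node {n}")
                incident[n] += 1
            key = frozenset(v.endpoints)
            if key in seen_edges:
                raise NetworkValidationError(f"parallel edge at vessel {v.id}")
            seen_edges.add(key)
            if v.diameter <= 0 or v.length <= 0:
                raise NetworkValidationError(
                    f"vessel {v.id} has non-positive dimensions")
        for nid, deg in incident.items():
            if deg == 0:
                raise NetworkValidationError(f"node {nid} has no incident vessels")


@dataclass(frozen=True)
class TopologySummary:
    """Betti numbers and degree-census statistics of one network state."""

    beta0: int
    beta1: int
    beta0_per_vessel: float
    beta1_per_vessel: float
    n_degree1: int
    n_degree1_per_vessel: float


def degree_census(network: VascularNetwork) -> Dict[int, int]:
    """Map each node id to the number of incident vessels."""
    census = {n: 0 for n in network.nodes}
    for v in network.vessels.values():
        census[v.node_a] += 1
        census[v.node_b] += 1
    return census


def betti_numbers(network: VascularNetwork) -> TopologySummary:
    """Betti numbers via the Euler–Poincaré formula.

    β0 is the number of connected components; β1 follows from the Euler
    characteristic of a graph, ``β1 = β0 − N_N + N_V``.  Per-vessel
    normalisations divide by the vessel count, so the result is
    undefined (raises) for an empty network.
    """
    if network.n_vessels == 0:
        raise NetworkValidationError(
            "Betti normalisation undefined for an empty network")
    beta0 = len(network.connected_components())
    beta1 = beta0 - network.n_nodes + network.n_vessels
    census = degree_census(network)
    n_deg1 = sum(1 for d in census.values() if d == 1)
    nv = network.n_vessels
    return TopologySummary(
        beta0=beta0,
        beta1=beta1,
        beta0_per_vessel=beta0 / nv,
        beta1_per_vessel=beta1 / nv,
        n_degree1=n_deg1,
        n_degree1_per_vessel=n_deg1 / nv,
    )


def beta1_per_vessel_from_degrees(network: VascularNetwork) -> float:
    """Loops per vessel from the degree census alone.

    For a graph whose nodes all have degree 1 (boundary nodes and
    sprout tips) or degree 3 (bifurcations), counting vessels by looping
    over nodes gives ``N_V = (N_1 + 3 N_3)/2`` and the loops-per-vessel
    identity ``β1/N_V = 1/3 + β0/N_V − (2/3)(N_1/N_V)``.  This is an
    independent route to the Euler-formula value and must agree with it
    exactly.

    Raises if any node has a degree other than 1 or 3.
    """
    if network.n_vessels == 0:
        raise NetworkValidationError(
            "degree-census identity undefined for an empty network")
    census = degree_census(network)
    for nid, deg in census.items():
        if deg not in (1, 3):
            raise NetworkValidationError(
                f"node {nid} has degree {deg}; identity requires degree 1 or 3")
    n1 = sum(1 for d in census.values() if d == 1)
    nv = network.n_vessels
    beta0 = len(network.connected_components())
    return 1.0 / 3.0 + beta0 / nv - (2.0 / 3.0) * (n1 / nv)
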