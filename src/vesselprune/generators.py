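"""Synthetic vascular network generators.

Three families are provided:

* **Forking networks** — hierarchical, deterministic trees that branch
  symmetrically by Murray's law for a configurable number of
  generations and then converge, mirror-fashion, into a single outlet.
* **Hexagonal networks** — non-hierarchical honeycomb lattices with
  normally distributed vessel diameters.
* **Tumour-like fixtures** — random planar loopy graphs with attached
  blunt-ended sprouts, tuned to requested vessel counts, mean
  diameters, and loops-per-vessel values emulating the statistics of
  imaged tumour vasculature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .network import MIN_DIAMETER_UM, NetworkValidationError, VascularNetwork

__all__ = [
    "ForkingSpec",
    "HexSpec",
    "TumourFixtureSpec",
    "generate_forking",
    "forking_generation_diameter",
    "offset_mean_diameter",
    "generate_hexagonal",
    "generate_tumour_fixture",
]


# ---------------------------------------------------------------------
# forking networks
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class ForkingSpec:
    """Parameters of the symmetric forking network.

    Attributes
    ----------
    generations:
        Number of branching generations G; the inlet vessel is
        generation 0 and the tree branches down to generation G − 1
        before mirroring into the converging half.
    inlet_diameter:
        Diameter of the generation-0 vessel (μm) before any offset.
    alpha:
        Daughter-diameter heterogeneity: at every bifurcation the upper
        daughter is ``alpha`` times thicker than the lower one.  With
        ``alpha = 1`` the network is homogeneous.
    lambda_ratio:
        Length-to-diameter ratio λ; vessel lengths are λ times the
        *reference* (homogeneous, pre-offset) generation diameters so
        that diameter variations never alter the geometry.
    v1_factor:
        Sets the first-generation y-extent ``V_1 = v1_factor · L_1``;
        extents halve every subsequent generation.
    target_mean_diameter:
        If given, all diameters are shifted additively after
        construction so the network mean equals this value (μm).
    """

    generations: int = 7
    inlet_diameter: float = 75.0
    alpha: float = 1.0
    lambda_ratio: float = 4.0
    v1_factor: float = 0.9
    target_mean_diameter: Optional[float] = None

    def validate(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.alpha < 1.0:
            raise ValueError("alpha must be >= 1 (thick/thin daughter ratio)")
        if self.inlet_diameter <= 0 or self.lambda_ratio <= 0:
            raise ValueError("inlet_diameter and lambda_ratio must be positive")
        if not (0.0 < self.v1_factor <= 1.0):
            raise ValueError("v1_factor must lie in (0, 1]")


def forking_generation_diameter(inlet_diameter: float, alpha: float,
                                generation: int, n_thick: int) -> float:
    """Closed-form diameter of a generation-``i`` vessel.

    Murray's law ``d_parent³ = d_A³ + d_B³`` with a fixed daughter
    ratio ``d_A = α d_B`` gives, for a vessel reached through
    ``n_thick`` thick daughters,

        d_i = d_inlet · α^{n_thick} / (1 + α³)^{i/3}.
    """
    return inlet_diameter * alpha ** n_thick / (1.0 + alpha ** 3) ** (generation / 3.0)


def generate_forking(spec: ForkingSpec) -> VascularNetwork:
    """Build the symmetric diverging/converging forking network.

    The diverging half contains ``2**i`` vessels in generation ``i``
    for ``i = 0..G−1``; a mirror image across the midline converges
    back into a single outlet vessel, sharing the midline tip nodes,
    for a total of ``2(2**G − 1)`` vessels.

    Vessel ids are deterministic: the diverging half is numbered
    breadth-first (generation by generation, top to bottom within a
    generation) as ``0..2**G − 2``; the mirror twin of diverging vessel
    ``v`` gets id ``(2**G − 1) + v``.  Equal-diameter pruning ties are
    broken on these ids.
    """
    spec.validate()
    G = spec.generations
    # reference (homogeneous) geometry: lengths and extents never vary
    d_ref = [spec.inlet_diameter / 2.0 ** (i / 3.0) for i in range(G)]
    lengths = [spec.lambda_ratio * d for d in d_ref]
    extents = [0.0] * G
    if G > 1:
        extents[1] = spec.v1_factor * lengths[1]
        for i in range(2, G):
            extents[i] = extents[i - 1] / 2.0
    dx = [lengths[0]] + [
        math.sqrt(lengths[i] ** 2 - extents[i] ** 2) for i in range(1, G)
    ]

    net = VascularNetwork()
    next_node = 0

    def new_node(x: float, y: float) -> int:
        nonlocal next_node
        net.add_node(next_node, x, y)
        next_node += 1
        return next_node - 1

    inlet = new_node(0.0, 0.0)
    first = new_node(dx[0], 0.0)
    vid = 0
    net.add_vessel(vid, inlet, first, spec.inlet_diameter, lengths[0])
    vid += 1
    # frontier kept in top-to-bottom order; entries are (node, n_thick)
    frontier = [(first, 0)]
    for i in range(1, G):
        new_frontier = []
        for node, n_thick in frontier:
            x, y = net.nodes[node].x, net.nodes[node].y
            upper = new_node(x + dx[i], y + extents[i])
            lower = new_node(x + dx[i], y - extents[i])
            # the upper daughter is the thick one
            net.add_vessel(vid, node, upper,
                           forking_generation_diameter(
                               spec.inlet_diameter, spec.alpha, i, n_thick + 1),
                           lengths[i])
            vid += 1
            net.add_vessel(vid, node, lower,
                           forking_generation_diameter(
                               spec.inlet_diameter, spec.alpha, i, n_thick),
                           lengths[i])
            vid += 1
            new_frontier.append((upper, n_thick + 1))
            new_frontier.append((lower, n_thick))
        frontier = new_frontier

    # mirror the diverging half across the midline; tips are shared
    x_mid = sum(dx)
    n_div = 2 ** G - 1
    mirror = {}
    for nid in range(next_node):
        node = net.nodes[nid]
        if abs(node.x - x_mid) < 1e-9:
            mirror[nid] = nid
        else:
            mirror[nid] = new_node(2.0 * x_mid - node.x, node.y)
    for v in range(n_div):
        vessel = net.vessels[v]
        net.add_vessel(n_div + v, mirror[vessel.node_a], mirror[vessel.node_b],
                       vessel.diameter, vessel.length)

    if spec.target_mean_diameter is not None:
        net = offset_mean_diameter(net, spec.target_mean_diameter)
    return net


def offset_mean_diameter(network: VascularNetwork,
                         target: float) -> VascularNetwork:
    """Shift every vessel diameter by a constant so the mean hits ``target``.

    The shift is additive, leaving lengths, positions, and branching
    angles untouched and preserving the diameter ordering (and hence
    the pruning order) of the input network.
    """
    offset = target - network.mean_diameter()
    out = network.copy()
    for vid, v in list(out.vessels.items()):
        d = v.diameter + offset
        if d <= MIN_DIAMETER_UM:
            raise NetworkValidationError(
                f"offset {offset:+.3f} μm drives vessel {vid} to diameter "
                f"{d:.3f} μm <= {MIN_DIAMETER_UM} μm (viscosity-law domain)")
        out.vessels[vid] = type(v)(v.id, v.node_a, v.node_b, d, v.length)
    return out


# ---------------------------------------------------------------------
# hexagonal networks
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class HexSpec:
    """Parameters of the honeycomb-lattice network.

    Each hexagon edge is one vessel of length ``edge_length``;
    diameters are drawn independently from a normal distribution with
    the given mean and SD, resampled until above ``min_diameter``.
    """

    rows: int = 5
    cols: int = 5
    edge_length: float = 100.0
    mean_diameter: float = 28.5
    diameter_sd: float = 8.68
    min_diameter: float = 2.0
    seed: int = 0
    #: attach horizontal feeder vessels to the leftmost (inlet side) and
    #: rightmost (outlet side) lattice nodes so the lattice has degree-1
    #: boundary nodes to drive flow through
    boundary_stubs: bool = True

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be positive")
        if self.edge_length <= 0 or self.mean_diameter <= 0:
            raise ValueError("edge_length and mean_diameter must be positive")
        if self.diameter_sd < 0:
            raise ValueError("diameter_sd must be non-negative")
        if self.min_diameter <= MIN_DIAMETER_UM:
            raise ValueError(
                f"min_diameter must exceed {MIN_DIAMETER_UM} μm "
                "(viscosity-law validity)")


def generate_hexagonal(spec: HexSpec) -> VascularNetwork:
    """Honeycomb lattice of ``rows × cols`` hexagonal cells."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lattice = nx.hexagonal_lattice_graph(spec.rows, spec.cols)
    pos = nx.get_node_attributes(lattice, "pos")
    relabel = {n: i for i, n in enumerate(sorted(lattice.nodes()))}
    net = VascularNetwork()
    for n, i in relabel.items():
        x, y = pos[n]
        net.add_node(i, x * spec.edge_length, y * spec.edge_length)
    edges = sorted((min(relabel[a], relabel[b]), max(relabel[a], relabel[b]))
                   for a, b in lattice.edges())
    for vid, (a, b) in enumerate(edges):
        net.add_vessel(vid, a, b, _truncated_normal(rng, spec),
                       spec.edge_length)
    if spec.boundary_stubs:
        _attach_boundary_stubs(net, rng, spec)
    return net


def _attach_boundary_stubs(net: VascularNetwork, rng: np.random.Generator,
                           spec: HexSpec) -> None:
    xs = [n.x for n in net.nodes.values()]
    x_min, x_max = min(xs), max(xs)
    next_node = max(net.nodes) + 1
    vid = max(net.vessels) + 1
    for node in sorted(net.nodes.values(), key=lambda n: n.id):
        if abs(node.x - x_min) < 1e-9:
            dx = -spec.edge_length
        elif abs(node.x - x_max) < 1e-9:
            dx = spec.edge_length
        else:
            continue
        net.add_node(next_node, node.x + dx, node.y)
        net.add_vessel(vid, node.id, next_node,
                       _truncated_normal(rng, spec), spec.edge_length)
        next_node += 1
        vid += 1


def _truncated_normal(rng: np.random.Generator, spec: HexSpec) -> float:
    if spec.diameter_sd == 0.0:
        return spec.mean_diameter
    while True:
        d = rng.normal(spec.mean_diameter, spec.diameter_sd)
        if d > spec.min_diameter:
            return float(d)


# ---------------------------------------------------------------------
# tumour-like fixtures
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class TumourFixtureSpec:
    """Targets for a random tumour-like network.

    The fixture emulates the coarse statistics of imaged tumour
    vasculature: vessel count, mean diameter, loops per vessel, and the
    fraction of blunt-ended angiogenic sprouts.  Loops per vessel above
    1/3 are infeasible for graphs whose nodes have degree at most 3.
    """

    n_vessels: int = 1000
    target_mean_diameter: float = 25.0
    target_beta1_per_vessel: float = 0.03
    sprout_fraction: float = 0.2
    seed: int = 0
    lattice_spacing: float = 110.0
    diameter_cv: float = 0.2

    def validate(self) -> None:
        if self.n_vessels < 10:
            raise ValueError("n_vessels must be at least 10")
        if not (0.0 <= self.target_beta1_per_vessel <= 1.0 / 3.0):
            raise ValueError(
                "target_beta1_per_vessel must lie in [0, 1/3] "
                "(degree-3 graphs cannot exceed 1/3 loops per vessel)")
        if not (0.0 <= self.sprout_fraction < 1.0):
            raise ValueError("sprout_fraction must lie in [0, 1)")
        if self.target_mean_diameter <= MIN_DIAMETER_UM:
            raise ValueError("target_mean_diameter too small")


def generate_tumour_fixture(spec: TumourFixtureSpec) -> VascularNetwork:
    """Grow a random planar loopy graph with attached sprout vessels.

    Construction: take a breadth-first spanning tree over a patch of a
    triangular lattice, add back exactly ``round(target · n)`` chord
    edges (each adds one independent loop), then attach degree-1 sprout
    vessels until the requested vessel count is reached.  The loop
    count is exact by the Euler formula, so the achieved loops per
    vessel is within rounding (0.5/n) of the target.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_vessels
    loops = int(round(spec.target_beta1_per_vessel * n))
    sprouts = int(round(spec.sprout_fraction * n))
    tree_edges = n - loops - sprouts
    if tree_edges < 1:
        raise ValueError("sprout_fraction and loop target leave no room "
                         "for a connected core")
    n_core = tree_edges + 1

    side = int(math.ceil(math.sqrt(2.0 * n_core))) + 2
    lattice = nx.triangular_lattice_graph(side, side)
    pos = nx.get_node_attributes(lattice, "pos")
    start = next(iter(sorted(lattice.nodes())))
    order = list(nx.bfs_tree(lattice, start))[:n_core]
    core = set(order)
    sub = lattice.subgraph(core)
    tree = nx.bfs_tree(sub, start)
    chords = [e for e in sub.edges()
              if not tree.has_edge(*e) and not tree.has_edge(e[1], e[0])]
    if len(chords) < loops:
        raise ValueError(
            f"requested {loops} loops but only {len(chords)} chords available; "
            "increase n_vessels or lower target_beta1_per_vessel")
    chosen_idx = rng.choice(len(chords), size=loops, replace=False) if loops else []
    chosen = [chords[i] for i in sorted(np.atleast_1d(chosen_idx).tolist())]

    relabel = {node: i for i, node in enumerate(order)}
    net = VascularNetwork()
    s = spec.lattice_spacing
    for node, i in relabel.items():
        x, y = pos[node]
        net.add_node(i, x * s, y * s)
    vid = 0
    for a, b in tree.edges():
        net.add_vessel(vid, relabel[a], relabel[b], 10.0, _edge_length(net, relabel[a], relabel[b]))
        vid += 1
    for a, b in chosen:
        net.add_vessel(vid, relabel[a], relabel[b], 10.0, _edge_length(net, relabel[a], relabel[b]))
        vid += 1
    # attach blunt-ended sprouts to randomly chosen core nodes
    next_node = len(relabel)
    anchors = rng.integers(0, len(relabel), size=sprouts)
    for k, anchor in enumerate(np.atleast_1d(anchors).tolist()):
        angle = rng.uniform(0.0, 2.0 * math.pi)
        length = 0.5 * s
        ax, ay = net.nodes[int(anchor)].x, net.nodes[int(anchor)].y
        net.add_node(next_node, ax + length * math.cos(angle),
                     ay + length * math.sin(angle))
        net.add_vessel(vid, int(anchor), next_node, 10.0, length)
        vid += 1
        next_node += 1

    # diameters: truncated normal around the target, then an additive
    # shift to land the mean exactly on target
    sd = spec.diameter_cv * spec.target_mean_diameter
    draws = []
    floor = MIN_DIAMETER_UM + 1.0
    for _ in range(net.n_vessels):
        while True:
            d = rng.normal(spec.target_mean_diameter, sd)
            if d > floor:
                draws.append(float(d))
                break
    shift = spec.target_mean_diameter - float(np.mean(draws))
    for vid_, v in list(net.vessels.items()):
        d = max(draws[vid_] + shift, floor)
        net.vessels[vid_] = type(v)(v.id, v.node_a, v.node_b, d, v.length)
    return net


def _edge_length(net: VascularNetwork, a: int, b: int) -> float:
    na, nb = net.nodes[a], net.nodes[b]
    return math.hypot(na.x - nb.x, na.y - nb.y)
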