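"""Blood rheology, Poiseuille network flow, and perfusion classification.

Flow in each vessel obeys Poiseuille's law ``Q = Δp / R`` with
``R = 128 L μ_eff / (π d⁴)``.  The effective viscosity follows the
diameter-dependent in vivo law (Fåhræus–Lindqvist effect): with
diameters nondimensionalised by 1 μm,

    μ_eff = μ_p [1 + (μ45 − 1) · ((1−H)^C − 1)/((1−0.45)^C − 1)
                 · (d/(d−1.1))²] · (d/(d−1.1))²

where μ45 and C are empirical functions of diameter and H is the
discharge haematocrit, held uniform across the network so the flow
problem stays linear.  Mass conservation at every interior node closes
a sparse linear system for the nodal pressures under Dirichlet
pressures at inlets and outlets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import VascularNetwork, degree_census

__all__ = [
    "RheologyParams",
    "BoundaryConditions",
    "PerfusionConfig",
    "FlowSolution",
    "PerfusionSummary",
    "mu45",
    "c_exponent",
    "effective_viscosity",
    "poiseuille_resistance",
    "assign_boundaries",
    "solve_flow",
    "classify_perfusion",
]

#: positional tolerance (μm) for grouping nodes at the minimal x-coordinate
LEFTMOST_TOL_UM = 1e-6


@dataclass(frozen=True)
class RheologyParams:
    """Blood composition entering the viscosity law.

    ``haematocrit`` is the discharge haematocrit (red-cell volume
    fraction), uniform across the network; ``plasma_viscosity`` is in
    mPa·s.
    """

    haematocrit: float = 0.45
    plasma_viscosity: float = 1.2

    def validate(self) -> None:
        if not (0.0 <= self.haematocrit < 1.0):
            raise ValueError("haematocrit must lie in [0, 1)")
        if self.plasma_viscosity <= 0:
            raise ValueError("plasma_viscosity must be positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet pressures (Pa) at inlet and outlet nodes."""

    inlet_pressure: float = 3333.0
    outlet_pressure: float = 2000.0

    def validate(self) -> None:
        if self.inlet_pressure <= self.outlet_pressure:
            raise ValueError("inlet pressure must exceed outlet pressure")


@dataclass(frozen=True)
class PerfusionConfig:
    """Perfusion threshold: minimum flow magnitude (m³/s) for a vessel
    to count as perfused.  Defaults to the forking-network value; the
    hexagonal lattice uses an order of magnitude less."""

    q_min: float = 3e-12

    FORKING: float = 3e-12
    HEXAGONAL: float = 3e-13

    def validate(self) -> None:
        if self.q_min <= 0:
            raise ValueError("q_min must be positive")


@dataclass
class FlowSolution:
    """Nodal pressures and signed per-vessel flows for one network state."""

    node_pressure: Dict[int, float]
    vessel_flow: Dict[int, float]
    vessel_viscosity: Dict[int, float]
    vessel_resistance: Dict[int, float]


@dataclass(frozen=True)
class PerfusionSummary:
    perfused: Dict[int, bool]
    perfused_count: int
    hypoperfused_count: int
    perfusion_fraction: float


# ---------------------------------------------------------------------
# viscosity law
# ---------------------------------------------------------------------


def mu45(d: float) -> float:
    """Relative apparent viscosity at haematocrit 0.45 for diameter ``d`` (μm)."""
    return 6.0 * math.exp(-0.085 * d) + 3.2 - 2.44 * math.exp(-0.06 * d ** 0.645)


def c_exponent(d: float) -> float:
    """Shape exponent of the haematocrit dependence.

    The term ``1/(1 + 1e-11 d¹²)`` is evaluated in log space for large
    diameters so that it underflows to zero instead of overflowing.
    """
    # log(1e-11 d^12) = 12 log d - 11 log 10
    log_t = 12.0 * math.log(d) - 11.0 * math.log(10.0)
    if log_t > 700.0:  # d^12 term overwhelms: 1/(1 + huge) -> 0
        inv = 0.0
    else:
        inv = 1.0 / (1.0 + math.exp(log_t))
    return (0.8 + math.exp(-0.075 * d)) * (-1.0 + inv) + inv


def effective_viscosity(d: float, params: RheologyParams = RheologyParams()) -> float:
    """Effective in vivo blood viscosity (mPa·s) in a vessel of diameter ``d`` μm.

    Undefined for ``d <= 1.1`` μm.  At the reference haematocrit 0.45
    the haematocrit ratio equals 1 exactly and the expression reduces
    to ``μ_p [1 + (μ45 − 1)(d/(d−1.1))²](d/(d−1.1))²``.
    """
    params.validate()
    if d <= 1.1:
        raise ValueError(f"viscosity law undefined for diameter {d} μm <= 1.1 μm")
    H = params.haematocrit
    if H == 0.45:
        ratio = 1.0
    else:
        C = c_exponent(d)
        ratio = ((1.0 - H) ** C - 1.0) / (0.55 ** C - 1.0)
    wall = (d / (d - 1.1)) ** 2
    return params.plasma_viscosity * (1.0 + (mu45(d) - 1.0) * ratio * wall) * wall


def poiseuille_resistance(d_um: float, length_um: float,
                          mu_eff_mpas: float) -> float:
    """Hydraulic resistance ``128 L μ / (π d⁴)`` in SI units (Pa·s·m⁻³).

    Inputs are in μm (diameter, length) and mPa·s (viscosity).
    """
    if d_um <= 0 or length_um <= 0 or mu_eff_mpas <= 0:
        raise ValueError("diameter, length and viscosity must be positive")
    d = d_um * 1e-6
    L = length_um * 1e-6
    mu = mu_eff_mpas * 1e-3
    return 128.0 * L * mu / (math.pi * d ** 4)


# ---------------------------------------------------------------------
# boundary assignment and flow solution
# ---------------------------------------------------------------------


def assign_boundaries(network: VascularNetwork) -> VascularNetwork:
    """Label inlets and outlets on an unpruned network.

    Nodes at the minimal x-coordinate (within a small positional
    tolerance) become inlets; every other degree-1 node becomes an
    outlet; the rest are interior.  Roles are assigned once on the
    unpruned network and are meant to be kept through pruning.
    """
    census = degree_census(network)
    if not any(d == 1 for d in census.values()):
        raise ValueError("network has no degree-1 node; no flow can be driven")
    x_min = min(node.x for node in network.nodes.values())
    roles = {}
    for node in network.nodes.values():
        if node.x <= x_min + LEFTMOST_TOL_UM:
            roles[node.id] = "inlet"
        elif census[node.id] == 1:
            roles[node.id] = "outlet"
        else:
            roles[node.id] = "interior"
    return network.with_roles(roles)


def solve_flow(network: VascularNetwork,
               bc: BoundaryConditions = BoundaryConditions(),
               rheology: RheologyParams = RheologyParams()) -> FlowSolution:
    """Solve the linear pressure problem and return signed vessel flows.

    Conductances ``1/R`` from the Poiseuille/viscosity laws assemble a
    weighted graph Laplacian; inlet and outlet nodes carry Dirichlet
    pressures, interior pressures are solved for with a sparse direct
    solver.  Connected components containing no boundary node are
    pinned to the outlet pressure and therefore carry no flow.
    """
    bc.validate()
    rheology.validate()
    node_ids = sorted(network.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)

    fixed: Dict[int, float] = {}
    for node in network.nodes.values():
        if node.role == "inlet":
            fixed[index[node.id]] = bc.inlet_pressure
        elif node.role == "outlet":
            fixed[index[node.id]] = bc.outlet_pressure
    if not fixed:
        raise ValueError("no inlet or outlet nodes; assign boundaries first")

    conductance: Dict[int, float] = {}
    viscosity: Dict[int, float] = {}
    resistance: Dict[int, float] = {}
    rows, cols, vals = [], [], []
    for v in network.vessels.values():
        mu = effective_viscosity(v.diameter, rheology)
        R = poiseuille_resistance(v.diameter, v.length, mu)
        viscosity[v.id] = mu
        resistance[v.id] = R
        g = 1.0 / R
        conductance[v.id] = g
        ia, ib = index[v.node_a], index[v.node_b]
        rows += [ia, ib, ia, ib]
        cols += [ia, ib, ib, ia]
        vals += [g, g, -g, -g]
    laplacian = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    # pin one node of any component that has no boundary node
    for comp in network.connected_components():
        if not any(index[nid] in fixed for nid in comp):
            fixed[index[min(comp)]] = bc.outlet_pressure

    pressure = np.zeros(n)
    fixed_idx = sorted(fixed)
    for i in fixed_idx:
        pressure[i] = fixed[i]
    free = np.array([i for i in range(n) if i not in fixed], dtype=int)
    if free.size:
        a_ff = laplacian[free][:, free].tocsc()
        a_fd = laplacian[free][:, fixed_idx]
        rhs = -a_fd @ np.array([fixed[i] for i in fixed_idx])
        try:
            pressure[free] = spla.spsolve(a_ff, rhs)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"singular flow system ({n} nodes, {network.n_vessels} "
                f"vessels, {len(fixed_idx)} fixed): {exc}") from exc
        if not np.all(np.isfinite(pressure[free])):
            raise RuntimeError("flow solve produced non-finite pressures")

    flow = {}
    for v in network.vessels.values():
        dp = pressure[index[v.node_a]] - pressure[index[v.node_b]]
        flow[v.id] = conductance[v.id] * dp
    pressures = {nid: float(pressure[index[nid]]) for nid in node_ids}
    return FlowSolution(pressures, flow, viscosity, resistance)


def classify_perfusion(network: VascularNetwork, flow: FlowSolution,
                       cfg: PerfusionConfig = PerfusionConfig()) -> PerfusionSummary:
    """Flag vessels with flow magnitude at or above the threshold.

    The perfusion fraction is the number of perfused vessels over the
    number of remaining vessels.
    """
    cfg.validate()
    flags = {vid: abs(flow.vessel_flow[vid]) >= cfg.q_min
             for vid in network.vessels}
    perfused = sum(flags.values())
    total = len(flags)
    return PerfusionSummary(
        perfused=flags,
        perfused_count=perfused,
        hypoperfused_count=total - perfused,
        perfusion_fraction=perfused / total if total else 0.0,
    )
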