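# Methods

## Flow model

Blood flow is modelled as laminar Poiseuille flow on an undirected
spatial graph.  Vessel *i* with diameter *dᵢ* and length *Lᵢ* (both in
μm) has hydraulic resistance

    Rᵢ = 128 Lᵢ μ_eff(dᵢ) / (π dᵢ⁴)      [Pa·s·m⁻³ after SI conversion]

The effective viscosity implements the in vivo diameter-dependent
rheology law

    μ_eff = μ_p [1 + (μ45 − 1)·((1−H)^C − 1)/((1−0.45)^C − 1)·(d/(d−1.1))²]·(d/(d−1.1))²
    μ45   = 6 e^(−0.085 d) + 3.2 − 2.44 e^(−0.06 d^0.645)
    C     = (0.8 + e^(−0.075 d))(−1 + 1/(1+10⁻¹¹d¹²)) + 1/(1+10⁻¹¹d¹²)

with all diameters nondimensionalised by 1 μm inside these three
expressions.  The law is undefined for d ≤ 1.1 μm; the package rejects
such diameters everywhere (generation, offsetting, I/O).  The
``1/(1+10⁻¹¹d¹²)`` term is evaluated in log space so large diameters
saturate cleanly instead of overflowing.  At the reference haematocrit
H = 0.45 the haematocrit ratio is set to exactly 1 rather than
evaluated, avoiding 0/0 noise.

Mass conservation at every node yields a weighted graph-Laplacian
system for the nodal pressures.  Inlet and outlet nodes carry Dirichlet
pressures (defaults 3333 Pa and 2000 Pa); the interior block is solved
with scipy's sparse direct solver.  Connected components containing no
boundary node (possible after pruning) are pinned to the outlet
pressure, which makes their flows exactly zero.  Conservation residuals
at interior nodes are below 10⁻⁶ of the peak flow in all tested
configurations (the test suite checks this).

**Parameters.**  Haematocrit H = 0.45 (uniform; splitting rules at
bifurcations are out of scope, keeping the problem linear).  Plasma
viscosity μ_p = 1.2 mPa·s; this value reproduces the reference initial
perfusion fractions 0.24/0.50/1.00 of the homogeneous forking network
at the three cohort mean-diameter offsets, which is the package's
calibration anchor.  Perfusion threshold Q_min = 3 × 10⁻¹² m³ s⁻¹
(forking) and 3 × 10⁻¹³ m³ s⁻¹ (hexagonal).  Perfusion uses the flow
*magnitude*: a fluorescent tracer detects movement irrespective of
direction.

## Boundary roles

Inlets are the nodes at the minimal x-coordinate (tolerance 10⁻⁶ μm);
every other degree-1 node is an outlet.  Roles are assigned once on the
unpruned network and never reassigned during pruning, so degree-1 nodes
created by vessel removal act as blunt ends (zero flow), not as new
outlets.

## Forking networks

Generation 0 is the inlet vessel; each vessel bifurcates until G
generations exist (default G = 7), after which the tree mirrors across
the midline into a single outlet, sharing the 2^(G−1) midline tip
nodes.  The network has N_V = 2(2^G − 1) vessels (254 for G = 7),
N_N = 2(2^(G−1) − 1) + 2^(G−1) + 2 nodes (192), and
β₁ = 2^(G−1) − 1 loops (63), which the Euler formula and an
independent spanning-forest oracle agree on in the tests.  Midline tips
have degree 2 by construction (every straight segment is one vessel);
all other interior nodes have degree 3.

Diameters follow Murray's law with a fixed daughter ratio α (the upper
daughter is the thicker): generation *i* on a path with n_thick thick
steps has d = d_inlet α^n_thick/(1+α³)^(i/3), d_inlet = 75 μm.
Lengths are λ = 4 times the *homogeneous reference* diameters
(α = 1, pre-offset), and the planar layout uses y-extents
V₁ = 0.9 L₁, V_{i+1} = Vᵢ/2 — so neither α nor diameter offsetting
ever changes lengths, angles, or the loop structure.

**Offsetting.**  Matching a target mean diameter adds a constant to
every diameter (additive, not multiplicative): it is the minimal
interpretation of "offsetting the mean", keeps lengths fixed, and
preserves the strict diameter ordering — hence the pruning order — of
the reference network.  Offsets that would push any vessel to
d ≤ 1.1 μm are rejected.

**Vessel ids.**  Ids are assigned breadth-first through the diverging
half (generation by generation, top to bottom within a generation),
0 … 2^G−2; the mirror twin of diverging vessel v is (2^G−1) + v.  The
scheme is deterministic and documented because equal-diameter pruning
ties are broken on it.  The original implementation's id scheme is not
public; dosage-response values at sampling points that fall *inside* an
equal-diameter class depend on this choice (see Limitations).

## Hexagonal networks

A rows × cols honeycomb of hexagon edges, each edge one vessel of fixed
length, with diameters drawn i.i.d. from a normal distribution
truncated below (resampling) at `min_diameter`.  Because a bare
honeycomb has no degree-1 node to act as a boundary, horizontal feeder
stubs are attached to the leftmost (inlet side) and rightmost (outlet
side) lattice nodes by default; stub diameters are drawn from the same
distribution.  Lattice size, inlet/outlet placement, and the σ values
are config-driven; the published lattice dimensions are not public, so
these defaults are the package's own choices.

## Tumour-like fixtures

Random planar networks matched to summary statistics: a breadth-first
spanning tree over a triangular-lattice patch, plus exactly
round(β₁̄·N_V) chord edges (each adds one loop), plus degree-1 sprout
vessels up to the requested sprout fraction.  The loop count is exact
by construction, so the achieved loops per vessel is within 0.5/N_V of
target; diameters are truncated-normal draws shifted additively onto
the target mean (tolerance 5%).  The fixture reproduces the count-based
identities of the imaged cohort (e.g. 22 loops/1000 vessels
→ β₁̄ = 2.20 × 10⁻², 247/4087 → 6.04 × 10⁻²) but makes no claim to
reproduce its resistances, which depend on the unavailable imaging
geometry.

## Pruning

Vessels are removed one at a time in order of increasing diameter
(ties by ascending vessel id), or — in `batch_ties` mode — all vessels
of the current smallest diameter simultaneously.  After each step,
orphaned degree-0 nodes are deleted, the flow system is re-solved from
scratch, and the record stores perfusion counts, Δ%P relative to the
unpruned network, loops per vessel, and mean geometric resistance.
Isolated fragments are retained: they count in the denominator of P
and carry zero flow.  Re-solving from scratch costs ≤ 254 solves of a
≤ 192-unknown sparse system per trajectory (well under a second), so
no incremental update is attempted.

Each step is attributed to a mechanism by comparing consecutive
records: a rising perfused count is *rerouting* (mechanism 1); a flat
count with rising P is *removal_only* (mechanism 2, the count
identity); falling P is *decrease*; anything else *neutral*.

## Response classification

For day-indexed series (Day 0 = irradiation), the pruning phase ends on
the last day the vessel count decreased before the first subsequent
increase (the onset of regrowth); a never-decreasing count raises a
dedicated error, mirroring the exclusion of corrupted series.  The
classification ΔP = P(final) − P(Day 0) assigns group A to strict
increases; the ΔP = 0 boundary goes to group B (the published
definition covers only strict increase/decrease; the tie rule is this
package's choice).  When both raw counts and precomputed fractions are
supplied, counts win.  Appending post-phase regrowth days never changes
the classification.

The descriptor-based *prediction* (`group_prediction`) thresholds the
viscosity-weighted resistance per loop at 0.73 cP·μm⁻³ — midway
between the observed group extremes of the six-tumour cohort — falling
back to a mean-diameter rule (threshold 28.8 μm) with a warning when a
network has no loops.  These thresholds are calibrated on tumour-like
topologies; strongly hierarchical forking networks have far higher β₁̄
than imaged tumours and the cohort thresholds do not transfer to them.

## Numerical choices

* Internal unit system: SI for the solver (flows m³/s, pressures Pa,
  resistances Pa·s·m⁻³); μm and cP·μm⁻³/μm⁻³ in the reported
  descriptor suite, matching the conventions of the source tables.
* Per-loop metrics for loop-free networks are `None` (undefined
  sentinel), not an exception or infinity.
* Degenerate pruning states (no path from inlet to outlet, empty
  network) are recorded as zero-flow / P = 0 states rather than
  aborting the trajectory.
* Determinism: the stochastic generators consume a single
  `numpy.random.default_rng(seed)`; identical configs and seeds give
  byte-identical outputs.

## Problem sizes

The test suite and the acceptance script run forking networks at
G = 4–7 (30–254 vessels), honeycombs up to 5 × 5 cells, fixtures up to
4087 vessels, and full 200-step pruning trajectories; the whole suite
completes in a few seconds.

## Limitations

* Uniform haematocrit: no phase-separation at bifurcations, hence no
  haematocrit heterogeneity and no oxygen-transport statement.
* Synthetic geometries are planar and regular; imaged tumour networks
  are 3-D, irregular, and contain degree-2 chains that the fixture does
  not emulate.  Passing tests therefore validate the flow/pruning
  machinery and the count-based identities, not the absolute resistance
  scale of real vasculature.
* Dosage-response values at sampling points inside an equal-diameter
  tie class depend on the vessel-id scheme.  With the documented
  scheme, the α = 1.1, d̄ = 28.50 μm network gives Δ%P = 5.72 at
  25 vessels pruned, against a published 15.66 computed with a
  different (non-public) id assignment; an exhaustive scan over tie
  orders shows the achievable values form a lattice with ~1.7-point
  spacing that does not contain 15.66, so the discrepancy is
  attributable to the id scheme (and possibly other non-public
  defaults), not to the flow model.  Endpoint cells (complete
  perfusion loss at high dosage) and the initial perfusion fractions
  are insensitive to the tie-break and reproduce exactly.
* Angiogenic regrowth, vessel dilation, and stochastic pruning rules
  are out of scope.
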