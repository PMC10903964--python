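"""Viscosity law, Poiseuille resistance, flow solver, perfusion."""

import math

import numpy as np
import pytest

from vesselprune import (BoundaryConditions, ForkingSpec, PerfusionConfig,
                         RheologyParams, assign_boundaries, c_exponent,
                         classify_perfusion, effective_viscosity,
                         generate_forking, generate_hexagonal, HexSpec, mu45,
                         poiseuille_resistance, solve_flow)

from conftest import make_network


class TestViscosityLaw:
    def test_mu45_large_diameter_limit(self):
        assert mu45(1e6) == pytest.approx(3.2, abs=1e-3)

    @pytest.mark.parametrize("d,expected", [
        # frozen from a symbolic arbitrary-precision evaluation
        (10.0, 3.8923989981081205),
        (100.0, 2.4438548599071881),
    ])
    def test_mu45_oracle_values(self, d, expected):
        assert mu45(d) == pytest.approx(expected, rel=1e-12)

    def test_c_exponent_small_diameter_limit(self):
        assert c_exponent(1e-6) == pytest.approx(1.0, abs=1e-4)

    def test_c_exponent_large_diameter_limit(self):
        assert c_exponent(1e3) == pytest.approx(-0.8, abs=1e-3)

    def test_c_exponent_oracle_value(self):
        # frozen from a symbolic arbitrary-precision evaluation
        assert c_exponent(10.0) == pytest.approx(-1.0657877752191043, rel=1e-12)

    def test_c_exponent_no_overflow_for_huge_diameter(self):
        assert math.isfinite(c_exponent(1e9))

    def test_reference_haematocrit_ratio_is_exactly_one(self):
        """At H = 0.45 the haematocrit ratio cancels and the viscosity is
        mu_p [1 + (mu45 − 1)(d/(d−1.1))²](d/(d−1.1))²."""
        params = RheologyParams(haematocrit=0.45, plasma_viscosity=1.2)
        for d in (5.0, 25.0, 80.0):
            wall = (d / (d - 1.1)) ** 2
            direct = 1.2 * (1 + (mu45(d) - 1) * wall) * wall
            assert effective_viscosity(d, params) == pytest.approx(direct, rel=1e-14)

    def test_large_diameter_viscosity_limit(self):
        params = RheologyParams(haematocrit=0.45, plasma_viscosity=1.2)
        assert effective_viscosity(1e6, params) == pytest.approx(3.2 * 1.2, abs=1e-3)

    @pytest.mark.parametrize("d,H,mu_p,expected", [
        # frozen from a symbolic arbitrary-precision evaluation
        (25.0, 0.45, 1.2, 3.3306288112706404),
        (10.0, 0.30, 1.2, 4.3860474985016891),
    ])
    def test_effective_viscosity_oracle(self, d, H, mu_p, expected):
        params = RheologyParams(haematocrit=H, plasma_viscosity=mu_p)
        assert effective_viscosity(d, params) == pytest.approx(expected, rel=1e-12)

    def test_viscosity_domain_error(self):
        with pytest.raises(ValueError, match="1.1"):
            effective_viscosity(1.0)


class TestPoiseuilleResistance:
    def test_fourth_power_diameter_law(self):
        assert poiseuille_resistance(20, 40, 1.0) == \
            pytest.approx(poiseuille_resistance(10, 40, 1.0) / 16, rel=1e-12)

    def test_linear_in_length(self):
        assert poiseuille_resistance(10, 80, 1.0) == \
            pytest.approx(2 * poiseuille_resistance(10, 40, 1.0), rel=1e-12)

    def test_si_unit_conversion(self):
        # 128 · 40e-6 m · 1e-3 Pa·s / (π (10e-6 m)^4)
        assert poiseuille_resistance(10, 40, 1.0) == \
            pytest.approx(1.6297466172610078e14, rel=1e-12)


class TestBoundaryAssignment:
    def test_forking_single_inlet_outlet(self):
        net = assign_boundaries(generate_forking(ForkingSpec(generations=5)))
        inlets = net.nodes_with_role("inlet")
        outlets = net.nodes_with_role("outlet")
        assert len(inlets) == 1 and len(outlets) == 1
        assert net.nodes[inlets[0]].x == 0.0
        assert net.nodes[outlets[0]].x == max(n.x for n in net.nodes.values())

    def test_hexagonal_leftmost_nodes_are_inlets(self):
        net = assign_boundaries(generate_hexagonal(HexSpec(rows=3, cols=3, seed=0)))
        x_min = min(n.x for n in net.nodes.values())
        expected = {n.id for n in net.nodes.values() if n.x <= x_min + 1e-6}
        assert set(net.nodes_with_role("inlet")) == expected

    def test_no_degree1_node_is_an_error(self, four_cycle):
        with pytest.raises(ValueError, match="degree-1"):
            assign_boundaries(four_cycle)


class TestFlowSolver:
    def test_single_vessel_ohms_law(self):
        net = make_network([(0, 1)], positions={0: (0, 0), 1: (100, 0)},
                           diameters={0: 20.0}, lengths={0: 100.0})
        net = assign_boundaries(net)
        sol = solve_flow(net)
        R = sol.vessel_resistance[0]
        assert sol.vessel_flow[0] == pytest.approx((3333 - 2000) / R, rel=1e-12)

    def test_two_identical_parallel_paths_split_evenly(self):
        # diamond: inlet 0, outlet 3, two identical 2-vessel paths
        net = make_network([(0, 1), (1, 3), (0, 2), (2, 3), (3, 4)],
                           positions={0: (0, 0), 1: (50, 40), 2: (50, -40),
                                      3: (100, 0), 4: (150, 0)},
                           diameters={i: 15.0 for i in range(5)},
                           lengths={i: 64.0 for i in range(5)})
        net = assign_boundaries(net)
        sol = solve_flow(net)
        assert abs(sol.vessel_flow[0]) == pytest.approx(abs(sol.vessel_flow[2]),
                                                        rel=1e-10)
        assert abs(sol.vessel_flow[4]) == pytest.approx(
            abs(sol.vessel_flow[0]) + abs(sol.vessel_flow[2]), rel=1e-10)

    def test_homogeneous_forking_flow_halves_per_generation(self):
        net = assign_boundaries(generate_forking(
            ForkingSpec(generations=6, alpha=1.0, target_mean_diameter=28.5)))
        sol = solve_flow(net)
        q_in = abs(sol.vessel_flow[0])
        lengths = {round(v.length, 6) for v in net.vessels.values()}
        for gen, L in enumerate(sorted(lengths, reverse=True)):
            flows = [abs(sol.vessel_flow[v.id]) for v in net.vessels.values()
                     if round(v.length, 6) == L]
            assert flows == pytest.approx([q_in / 2 ** gen] * len(flows),
                                          rel=1e-9)

    def test_conservation_at_interior_nodes(self):
        net = assign_boundaries(generate_forking(
            ForkingSpec(generations=6, alpha=1.2, target_mean_diameter=28.5)))
        sol = solve_flow(net)
        q_max = max(abs(q) for q in sol.vessel_flow.values())
        residual = {n: 0.0 for n in net.nodes}
        for v in net.vessels.values():
            residual[v.node_a] -= sol.vessel_flow[v.id]
            residual[v.node_b] += sol.vessel_flow[v.id]
        for node in net.nodes.values():
            if node.role == "interior":
                assert abs(residual[node.id]) < 1e-6 * q_max

    def test_boundary_pressures_imposed_exactly(self):
        net = assign_boundaries(generate_forking(ForkingSpec(generations=4)))
        bc = BoundaryConditions(inlet_pressure=3000.0, outlet_pressure=1000.0)
        sol = solve_flow(net, bc)
        for nid in net.nodes_with_role("inlet"):
            assert sol.node_pressure[nid] == 3000.0
        for nid in net.nodes_with_role("outlet"):
            assert sol.node_pressure[nid] == 1000.0

    def test_reversing_pressures_negates_flows(self):
        net = assign_boundaries(generate_forking(
            ForkingSpec(generations=5, alpha=1.1)))
        fwd = solve_flow(net, BoundaryConditions(3333, 2000))
        # swap roles to reverse the driving pressure
        roles = {nid: "outlet" for nid in net.nodes_with_role("inlet")}
        roles.update({nid: "inlet" for nid in net.nodes_with_role("outlet")})
        rev = solve_flow(net.with_roles(roles), BoundaryConditions(3333, 2000))
        for vid in net.vessels:
            assert rev.vessel_flow[vid] == pytest.approx(-fwd.vessel_flow[vid],
                                                         rel=1e-9, abs=1e-25)

    def test_series_parallel_oracle_random_circuits(self):
        """Solver flows match closed-form series/parallel reduction on
        randomly parameterised ladder circuits."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            d = rng.uniform(8, 40, size=6)
            L = rng.uniform(30, 120, size=6)
            # circuit: vessel0 in series with (1+2 series || 3+4 series),
            # then vessel 5 in series to the outlet
            net = make_network(
                [(0, 1), (1, 2), (2, 4), (1, 3), (3, 4), (4, 5)],
                positions={0: (0, 0), 1: (50, 0), 2: (100, 30), 3: (100, -30),
                           4: (150, 0), 5: (200, 0)},
                diameters=dict(enumerate(d)), lengths=dict(enumerate(L)))
            net = assign_boundaries(net)
            sol = solve_flow(net)
            R = [sol.vessel_resistance[i] for i in range(6)]
            upper = R[1] + R[2]
            lower = R[3] + R[4]
            total = R[0] + upper * lower / (upper + lower) + R[5]
            q_total = (3333 - 2000) / total
            assert sol.vessel_flow[0] == pytest.approx(q_total, rel=1e-10)
            assert sol.vessel_flow[5] == pytest.approx(q_total, rel=1e-10)
            assert abs(sol.vessel_flow[1]) == pytest.approx(
                q_total * lower / (upper + lower), rel=1e-10)

    def test_component_without_boundary_carries_no_flow(self):
        net = make_network([(0, 1), (2, 3), (3, 4), (4, 2)],
                           positions={0: (0, 0), 1: (100, 0), 2: (0, 50),
                                      3: (50, 80), 4: (100, 50)})
        roles = {0: "inlet", 1: "outlet"}
        net = net.with_roles(roles)
        sol = solve_flow(net)
        for vid in (1, 2, 3):
            assert sol.vessel_flow[vid] == pytest.approx(0.0, abs=1e-20)

    def test_removing_zero_flow_vessel_leaves_flows_unchanged(self):
        """A blunt-ended (dead-end) vessel carries no flow; deleting it
        must not perturb any other vessel's flow."""
        net = make_network([(0, 1), (1, 2), (1, 3)],
                           positions={0: (0, 0), 1: (100, 0), 2: (200, 0),
                                      3: (150, 80)},
                           diameters={0: 20.0, 1: 18.0, 2: 6.0})
        roles = {0: "inlet", 2: "outlet", 1: "interior", 3: "interior"}
        net = net.with_roles(roles)
        before = solve_flow(net)
        assert before.vessel_flow[2] == pytest.approx(0.0, abs=1e-20)
        pruned = net.copy()
        pruned.remove_vessel(2)
        after = solve_flow(pruned)
        for vid in (0, 1):
            assert after.vessel_flow[vid] == pytest.approx(
                before.vessel_flow[vid], rel=1e-12)


class TestPerfusionClassification:
    def test_all_zero_flows_give_zero_fraction(self, four_cycle):
        net = four_cycle.with_roles({0: "inlet"})
        sol = solve_flow(net)
        summary = classify_perfusion(net, sol)
        assert summary.perfusion_fraction == 0.0

    def test_fraction_is_count_ratio(self):
        net = make_network([(0, 1)], diameters={0: 30.0})
        net = assign_boundaries(net)
        sol = solve_flow(net)
        high = classify_perfusion(net, sol, PerfusionConfig(q_min=1e-30))
        assert high.perfusion_fraction == 1.0
        low = classify_perfusion(net, sol, PerfusionConfig(q_min=1e30))
        assert low.perfusion_fraction == 0.0
        assert low.hypoperfused_count == 1
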