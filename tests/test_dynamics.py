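"""Continuous interpolations and the convergence integrator."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from grncontrol import (
    SimulationSettings,
    TruthTable,
    boolecube,
    build_network,
    converge,
    converge_batch,
    derivative_field,
    hillcube,
    simulate,
    sqds_derivative,
)
from grncontrol.dynamics import CompiledNetwork, sqds_sigmoid, sqds_omega
from grncontrol.examples import mutual_inhibition
from grncontrol.network import NodeSpec


def random_table(k: int, bits: int) -> TruthTable:
    outputs = tuple((bits >> i) & 1 for i in range(2**k))
    return TruthTable(tuple(f"i{j}" for j in range(k)), outputs)


class TestBooleCube:
    @given(k=st.integers(1, 4), data=st.data())
    @hyp_settings(max_examples=40, deadline=None)
    def test_vertices_reproduce_rule(self, k, data):
        bits = data.draw(st.integers(0, 2 ** (2**k) - 1))
        rule = random_table(k, bits)
        for vertex in itertools.product((0, 1), repeat=k):
            assert boolecube(rule, vertex) == pytest.approx(rule(vertex))

    def test_or_rule_midpoint(self):
        rule = TruthTable(("x", "y"), (0, 1, 1, 1))
        assert boolecube(rule, [0.5, 0.5]) == pytest.approx(0.75)

    def test_and_rule_midpoint(self):
        rule = TruthTable(("x", "y"), (0, 0, 0, 1))
        assert boolecube(rule, [0.5, 0.5]) == pytest.approx(0.25)

    def test_output_stays_in_unit_interval(self, rng):
        rule = random_table(3, 0b10110010)
        for _ in range(50):
            val = boolecube(rule, rng.uniform(size=3))
            assert 0.0 <= val <= 1.0


class TestHillCube:
    def test_normalised_vertices_reproduce_rule(self):
        rule = TruthTable(("x", "y"), (1, 0, 0, 1))
        for vertex in itertools.product((0, 1), repeat=2):
            assert hillcube(rule, vertex, normalised=True) == pytest.approx(
                rule(vertex)
            )

    def test_unnormalised_identity_at_threshold(self):
        rule = TruthTable(("x",), (0, 1))
        assert hillcube(rule, [0.5], hill_k=0.5, normalised=False) == pytest.approx(0.5)

    def test_monotone_in_activating_input(self):
        rule = TruthTable(("x", "y"), (0, 1, 1, 1))  # OR: monotone in both
        grid = np.linspace(0, 1, 21)
        for y in (0.2, 0.7):
            vals = [hillcube(rule, [x, y]) for x in grid]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestSqds:
    @pytest.mark.parametrize("h", [0.5, 2.0, 10.0, 50.0])
    def test_sigmoid_fixes_half(self, h):
        assert sqds_sigmoid(0.5, h) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("h", [1.0, 10.0])
    def test_sigmoid_monotone_and_bounded(self, h):
        omega = np.linspace(0, 1, 101)
        f = sqds_sigmoid(omega, h)
        assert np.all(np.diff(f) > 0)
        assert f[0] >= -1e-6 and f[-1] <= 1.0 + 1e-4

    def test_large_gain_saturates(self):
        assert sqds_sigmoid(1.0, 100.0) == pytest.approx(1.0, abs=1e-3)

    def test_neutral_point_has_zero_derivative(self):
        node = NodeSpec("x", h=10.0, gamma=1.0)
        # a single unit-weight activator at 1/3 standardises to omega = 1/2,
        # where f_h = 1/2 exactly; with x = 1/2 production balances decay
        d = sqds_derivative(node, [(1.0 / 3.0, 1.0, "+")], 0.5)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_input_node_has_zero_derivative(self):
        assert sqds_derivative(NodeSpec("x"), [], 0.7) == 0.0

    def test_steady_state_matches_bisection_root(self):
        # single activator clamped at 1: dx/dt = f_h(omega(1)) - x
        net = build_network(
            [NodeSpec("S", constant=True), "X"], [("S", "X", "+")]
        )
        settings = SimulationSettings(mc_samples=1, seed=0)
        final = converge(net, {"S": 1.0, "X": 0.2}, settings)
        f_const = float(sqds_sigmoid(sqds_omega(1.0, 1.0, 0.0, 0.0), 10.0))
        lo, hi = 0.0, 1.0
        for _ in range(60):  # bisection on g(x) = f - x
            mid = 0.5 * (lo + hi)
            if f_const - mid > 0:
                lo = mid
            else:
                hi = mid
        assert final[1] == pytest.approx(min(1.0, lo), abs=1e-5)


class TestDerivativeField:
    def test_fixed_point_of_all_zero_rules(self):
        rule = TruthTable(("A",), (0, 0))
        net = build_network(
            [NodeSpec("A", rule=TruthTable(("B",), (0, 0))),
             NodeSpec("B", rule=rule)],
            [("A", "B", "+"), ("B", "A", "+")],
            interpolation="boolecube",
        )
        assert np.allclose(derivative_field(net, [0.0, 0.0]), 0.0)

    def test_toggle_corner_is_stable(self, toggle):
        d = derivative_field(toggle, [1.0, 0.0])
        assert np.abs(d).max() < 1e-6

    def test_trajectory_consistent_with_field(self, toggle):
        settings = SimulationSettings(mc_samples=1, seed=0, dt=0.01, t_max=1.0)
        traj = simulate(toggle, [0.8, 0.3], settings)
        # central finite differences along the recorded path match the field
        for i in range(1, min(len(traj.times) - 1, 40)):
            numeric = (traj.states[i + 1] - traj.states[i - 1]) / (
                traj.times[i + 1] - traj.times[i - 1]
            )
            analytic = derivative_field(toggle, traj.states[i])
            assert np.allclose(numeric, analytic, atol=1e-3)


class TestIntegration:
    def test_constant_network_converges_immediately(self):
        net = build_network(["A", "B"], [], interpolation="sqds")
        settings = SimulationSettings(mc_samples=1, seed=0, input_behavior="hold")
        traj = simulate(net, [0.3, 0.9], settings)
        assert traj.converged
        assert np.allclose(traj.final, [0.3, 0.9])

    def test_toggle_resolves_to_corner(self, toggle):
        settings = SimulationSettings(mc_samples=1, seed=0)
        final = converge(toggle, [0.9, 0.1], settings)
        assert final == pytest.approx([1.0, 0.0], abs=1e-3)

    def test_stronger_inhibition_expands_winning_basin(self):
        even = mutual_inhibition("sqds")
        biased = mutual_inhibition("sqds", w_ba=2.0)
        settings = SimulationSettings(mc_samples=1, seed=0)
        # a state the balanced toggle resolves in favour of A ...
        final_even = converge(even, [0.55, 0.45], settings)
        # ... falls to B once B's inhibition of A is doubled
        final_biased = converge(biased, [0.55, 0.45], settings)
        assert final_even[0] > final_even[1]
        assert final_biased[1] > final_biased[0]

    def test_halving_dt_barely_moves_the_final_state(self, toggle):
        coarse = SimulationSettings(mc_samples=1, seed=0, dt=0.1, t_max=200.0)
        fine = coarse.with_(dt=0.05)
        v0 = [0.8, 0.3]
        assert np.abs(
            converge(toggle, v0, coarse) - converge(toggle, v0, fine)
        ).max() < 1e-4

    def test_states_remain_in_unit_cube(self, toy, rng):
        comp = CompiledNetwork(toy)
        x0 = rng.uniform(size=(64, 6))
        settings = SimulationSettings(mc_samples=64, seed=0, t_max=50.0)
        final, _, _ = comp.integrate(x0, settings)
        assert final.min() >= 0.0 and final.max() <= 1.0

    def test_converge_is_idempotent(self, toggle):
        settings = SimulationSettings(mc_samples=1, seed=0)
        once = converge(toggle, [0.7, 0.4], settings)
        twice = converge(toggle, once, settings)
        assert np.abs(once - twice).max() < 1e-4

    def test_identical_settings_are_bit_identical(self, toy, rng):
        x0 = rng.uniform(size=(32, 6))
        settings = SimulationSettings(mc_samples=32, seed=3)
        a, _ = converge_batch(toy, x0.copy(), settings)
        b, _ = converge_batch(toy, x0.copy(), settings)
        assert np.array_equal(a, b)

    def test_numpy_and_compiled_paths_agree(self, toy, rng):
        from grncontrol import _fastpath

        if not _fastpath.HAVE_NUMBA:
            pytest.skip("compiled path unavailable")
        comp = CompiledNetwork(toy)
        x0 = rng.uniform(size=(16, 6))
        settings = SimulationSettings(mc_samples=16, seed=0, t_max=60.0)
        fast, _, _ = comp.integrate(x0.copy(), settings)
        _fastpath.HAVE_NUMBA = False
        try:
            ref, _, _ = comp.integrate(x0.copy(), settings)
        finally:
            _fastpath.HAVE_NUMBA = True
        assert np.abs(fast - ref).max() < 1e-12

    def test_non_finite_initial_state_rejected(self, toy):
        with pytest.raises(ValueError, match="non-finite"):
            converge(toy, [np.nan] * 6, SimulationSettings(mc_samples=1))
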