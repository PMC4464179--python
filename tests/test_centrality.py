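"""Convergence difference, the three centralities, and distribution statistics."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from grncontrol import (
    SimulationSettings,
    TruthTable,
    aggregate_report,
    build_network,
    convergence_difference,
    cumulative_share,
    dynamic_centrality_connection,
    dynamic_centrality_node,
    gini,
    min_nodes_for_share,
    pairwise_influence,
    total_centrality_node,
    value_centrality_node,
)
from grncontrol.centrality import Workspace, node_centralities
from grncontrol.examples import mutual_inhibition
from grncontrol.network import NodeSpec, split_connection_input


def brute_force_gini(values):
    v = np.asarray(values, dtype=float)
    return float(
        np.sum(np.abs(v[:, None] - v[None, :])) / (2 * v.size**2 * v.mean())
    )


class TestGini:
    def test_reference_value(self):
        assert gini([3, 1, 0, 0]) == pytest.approx(0.625)

    def test_uniform_distribution_scores_zero(self):
        assert gini([2.5] * 6) == 0.0

    @pytest.mark.parametrize("n", [2, 5, 20])
    def test_single_holder_closed_form(self, n):
        values = [0.0] * (n - 1) + [1.0]
        assert gini(values) == pytest.approx((n - 1) / n)

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=30))
    @hyp_settings(max_examples=60, deadline=None)
    def test_matches_brute_force_pairwise_sum(self, values):
        if sum(values) == 0:
            assert gini(values) == 0.0
        else:
            assert gini(values) == pytest.approx(brute_force_gini(values))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            gini([1.0, -0.5])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gini([])


class TestCumulativeShare:
    def test_top_one_share(self):
        assert cumulative_share([3, 1, 0, 0], 1) == pytest.approx(0.75)

    def test_full_share_is_one(self):
        assert cumulative_share([3, 1, 0, 0], 4) == 1.0

    def test_out_of_range_k_rejected(self):
        with pytest.raises(ValueError):
            cumulative_share([1.0], 5)

    def test_min_nodes_for_half(self):
        assert min_nodes_for_share([3, 1, 0, 0], 0.5) == 1
        assert min_nodes_for_share([1, 1, 1, 1], 0.5) == 3


class TestConvergenceDifference:
    def test_self_difference_is_exactly_zero(self, toy, fast_settings):
        assert convergence_difference(toy, toy, fast_settings) == 0.0

    def test_symmetric_under_argument_swap(self, fast_settings):
        n1 = mutual_inhibition("sqds")
        n2 = mutual_inhibition("sqds", w_ba=2.0)
        d12 = convergence_difference(n1, n2, fast_settings)
        d21 = convergence_difference(n2, n1, fast_settings)
        assert d12 == pytest.approx(d21, rel=1e-9)
        assert d12 > 0

    def test_no_shared_nodes_rejected(self, fast_settings):
        n1 = build_network(["A"], [])
        n2 = build_network(["B"], [])
        with pytest.raises(ValueError, match="share"):
            convergence_difference(n1, n2, fast_settings)

    def test_held_constant_vs_forced_one_integrates_to_third(self):
        # a held input node keeps v; a tautology self-loop drives the node
        # to 1: D = integral of (1 - v)^2 dv = 1/3
        free = build_network(["X"], [], interpolation="boolecube")
        forced = build_network(
            [NodeSpec("X", rule=TruthTable(("X",), (1, 1)))],
            [("X", "X", "+")],
            interpolation="boolecube",
        )
        settings = SimulationSettings(
            mc_samples=2000, seed=5, input_behavior="hold", t_max=100.0
        )
        d = convergence_difference(free, forced, settings)
        assert d == pytest.approx(1 / 3, abs=0.03)


class TestCentralities:
    def test_sink_has_zero_total_and_dynamic_centrality(self, toy, fast_settings):
        assert total_centrality_node(toy, "F", fast_settings) == 0.0
        assert dynamic_centrality_node(toy, "F", fast_settings) == 0.0

    def test_all_centralities_nonnegative(self, toy, fast_settings):
        table = node_centralities(toy, fast_settings)
        assert (table[["TC", "VC", "DC"]] >= 0).all().all()

    def test_hub_dominates_relay(self, toy, fast_settings):
        tc_b = total_centrality_node(toy, "B", fast_settings)
        tc_e = total_centrality_node(toy, "E", fast_settings)
        assert tc_b > 2 * tc_e > 0

    def test_unknown_node_rejected(self, toy, fast_settings):
        with pytest.raises(Exception):
            total_centrality_node(toy, "Q", fast_settings)

    def test_dc_never_exceeds_any_grid_evaluation(self, toy, fast_settings):
        dc = dynamic_centrality_connection(toy, "B", "E", fast_settings)
        ws = Workspace(toy, fast_settings)
        base = ws.base_states()
        split_net, split_name = split_connection_input(toy, "B", "E")
        for c in np.linspace(0.0, 1.0, 7):
            states, _, _ = ws._compile(split_net).integrate(
                ws.initial_matrix(split_net, {split_name: float(c)}), fast_settings
            )
            d_c = float(
                np.mean(
                    ws.mu_samples(
                        base, ws.names, states, split_net.node_names, list(ws.names)
                    )
                )
            )
            assert dc <= d_c + 1e-12

    def test_connection_from_saturated_source_is_neutralisable(self, fast_settings):
        # S is forced on by a tautology loop; the constant surrogate at 1
        # reproduces its signal, so the connection has no dynamic influence
        net = build_network(
            [NodeSpec("S", rule=TruthTable(("S",), (1, 1))), "X"],
            [("S", "S", "+"), ("S", "X", "+")],
            interpolation="boolecube",
        )
        dc = dynamic_centrality_connection(net, "S", "X", fast_settings)
        assert dc < 1e-8

    def test_monte_carlo_error_shrinks_consistently(self, toy):
        small = SimulationSettings(mc_samples=100, seed=3, t_max=120.0,
                                   relax_dt=0.5, relax_after=20.0, dc_tol=1e-2)
        big = small.with_(mc_samples=200)
        est_small = total_centrality_node(toy, "B", small, return_stderr=True)
        est_big = total_centrality_node(toy, "B", big, return_stderr=True)
        tol = 3 * (est_small.stderr + est_big.stderr)
        assert abs(est_small.value - est_big.value) <= tol


class TestPairwiseInfluence:
    def test_disconnected_node_has_no_influence(self, fast_settings):
        net = build_network(
            ["A", "B", "L"], [("A", "A", "+"), ("A", "B", "+")]
        )
        for kind in ("TC", "VC", "DC"):
            assert pairwise_influence(net, "L", "B", kind, fast_settings) == 0.0

    def test_chain_influence_attenuates_downstream(self, chain, fast_settings):
        on_self = pairwise_influence(chain, "A", "A", "TC", fast_settings)
        on_tail = pairwise_influence(chain, "A", "C", "TC", fast_settings)
        assert on_self > 0
        assert on_tail > 0
        assert on_self >= on_tail * 0.5  # relay damping keeps self-influence comparable


class TestAggregateReport:
    def test_single_constant_node_yields_empty_flagged_report(self, fast_settings):
        net = build_network(["X"], [])
        report = aggregate_report(net, fast_settings)
        assert report.vulnerability == 0.0
        assert report.controllability == 0.0
        assert not report.rc_defined
        assert np.isnan(report.relative_controllability)

    def test_vulnerability_is_mean_of_node_tc(self, chain, fast_settings):
        report = aggregate_report(chain, fast_settings, include_connections=False)
        assert report.vulnerability == pytest.approx(
            report.nodes["TC"].mean(), rel=1e-12
        )
        assert report.robustness == pytest.approx(1 - report.vulnerability)

    def test_report_invariant_under_node_reordering(self, fast_settings):
        net1 = build_network(
            ["A", "B", "C"], [("A", "A", "+"), ("A", "B", "+"), ("B", "C", "-")]
        )
        net2 = build_network(
            ["C", "B", "A"], [("A", "A", "+"), ("A", "B", "+"), ("B", "C", "-")]
        )
        r1 = aggregate_report(net1, fast_settings, include_connections=False)
        r2 = aggregate_report(net2, fast_settings, include_connections=False)
        for name in ("A", "B", "C"):
            assert r1.nodes.loc[name, "TC"] == pytest.approx(
                r2.nodes.loc[name, "TC"], abs=1e-12
            )
            assert r1.nodes.loc[name, "VC"] == pytest.approx(
                r2.nodes.loc[name, "VC"], abs=1e-12
            )

    def test_tsv_export_lists_nodes_and_connections(self, chain, fast_settings):
        report = aggregate_report(chain, fast_settings)
        lines = report.to_tsv().strip().splitlines()
        kinds = [line.split("\t")[0] for line in lines[1:]]
        assert kinds.count("node") == 3
        assert kinds.count("connection") == 3
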