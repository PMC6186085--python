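"""Score initialization, score-flow propagation and fold-change calls."""

import numpy as np
import pandas as pd
import pytest

from p53netval import (
    ExpressionMatrix,
    InteractionNetwork,
    Scenario,
    StsfaConfig,
    flow_scores,
    initialize_scores,
    random_network,
    stsfa_emod,
    topological_flow_scores,
)
from p53netval.stsfa import ConvergenceError, ScoreMap


def _net(edges, input_node="DNA_damage", p53="TP53"):
    return InteractionNetwork.from_edges(edges, input_node=input_node, p53_node=p53)


def _intensity_matrix(values: dict[str, float]):
    return ExpressionMatrix(
        values=pd.DataFrame({"s1": values}), scale="intensity"
    )


class TestInitializeScores:
    def _map_net(self):
        return _net(
            [("DNA_damage", "A", 1), ("A", "B", 1), ("A", "C", 1)], p53="A"
        )

    def test_mapped_scores_and_damage_mean_when_on(self):
        init = initialize_scores(
            _intensity_matrix({"A": 4.0, "B": 16.0}),
            "s1", self._map_net(), Scenario("wt", "ON"),
        )
        assert init["A"] == pytest.approx(200.0)
        assert init["B"] == pytest.approx(400.0)
        assert init["DNA_damage"] == pytest.approx(300.0)

    def test_damage_minimum_when_off(self):
        init = initialize_scores(
            _intensity_matrix({"A": 4.0, "B": 16.0}),
            "s1", self._map_net(), Scenario("wt", "OFF"),
        )
        assert init["DNA_damage"] == pytest.approx(200.0)

    def test_unmapped_node_gets_minimum(self):
        init = initialize_scores(
            _intensity_matrix({"A": 4.0, "B": 16.0}),
            "s1", self._map_net(), Scenario("wt", "ON"),
        )
        assert init["C"] == pytest.approx(200.0)

    def test_no_mapped_genes_is_error(self):
        with pytest.raises(ValueError, match="map"):
            initialize_scores(
                _intensity_matrix({"Z": 4.0}),
                "s1", self._map_net(), Scenario("wt", "ON"),
            )

    def test_counts_use_log2_plus_one(self):
        m = ExpressionMatrix(
            values=pd.DataFrame({"s1": {"A": 3, "B": 15}}), scale="counts"
        )
        init = initialize_scores(m, "s1", self._map_net(), Scenario("wt", "OFF"))
        assert init["A"] == pytest.approx(200.0)
        assert init["B"] == pytest.approx(400.0)


class TestFlowScores:
    def test_chain_propagation(self):
        net = _net([("S", "A", 1), ("A", "B", 1)], input_node="S", p53="A")
        out = flow_scores(net, {"S": 100.0, "A": 50.0, "B": 10.0}).final
        assert out == pytest.approx({"S": 100.0, "A": 150.0, "B": 160.0})

    def test_inhibition_clamped_at_zero(self):
        net = _net([("S", "A", 1), ("A", "B", -1)], input_node="S", p53="A")
        out = flow_scores(net, {"S": 100.0, "A": 50.0, "B": 10.0}).final
        assert out["B"] == 0.0

    def test_all_zero_init_is_fixpoint(self):
        net = _net([("S", "A", 1), ("A", "B", 1)], input_node="S", p53="A")
        out = flow_scores(net, {"S": 0.0, "A": 0.0, "B": 0.0})
        assert all(v == 0.0 for v in out.final.values())
        assert out.n_iterations == 1

    def test_outdegree_normalization_splits_hub_score(self):
        net = _net([("S", "A", 1), ("S", "B", 1)], input_node="S", p53="A")
        out = flow_scores(net, {"S": 100.0, "A": 0.0, "B": 0.0}).final
        assert out["A"] == pytest.approx(50.0)
        assert out["B"] == pytest.approx(50.0)

    def test_missing_init_rejected(self):
        net = _net([("S", "A", 1)], input_node="S", p53="A")
        with pytest.raises(ValueError):
            flow_scores(net, {"S": 1.0})

    def test_divergent_positive_loop_raises_convergence_error(self):
        net = _net([("S", "A", 1), ("A", "B", 1), ("B", "A", 1)],
                   input_node="S", p53="A")
        with pytest.raises(ConvergenceError, match="residual"):
            flow_scores(net, {"S": 10.0, "A": 10.0, "B": 10.0})

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_topological_oracle_on_acyclic_networks(self, seed, rng):
        net = random_network(25, 0.12, 0.3, seed=seed, acyclic=True)
        init = {v: float(x) for v, x in
                zip(net.nodes, rng.uniform(0, 500, len(net.nodes)))}
        iterative = flow_scores(net, init).final
        single_pass = topological_flow_scores(net, init)
        assert iterative == pytest.approx(single_pass, abs=1e-6)

    def test_scale_equivariance_without_clamping(self, rng):
        net = random_network(20, 0.15, 0.0, seed=3, acyclic=True)  # all activating
        init = {v: float(x) for v, x in
                zip(net.nodes, rng.uniform(10, 100, len(net.nodes)))}
        base = flow_scores(net, init).final
        scaled = flow_scores(net, {v: 7.0 * x for v, x in init.items()}).final
        for v in net.nodes:
            assert scaled[v] == pytest.approx(7.0 * base[v], rel=1e-6)

    def test_topological_oracle_rejects_cycles(self, toy_net):
        init = {v: 1.0 for v in toy_net.nodes}
        with pytest.raises(Exception):
            topological_flow_scores(toy_net, init)

    def test_toy_network_cycle_converges(self, toy_net):
        init = {v: 100.0 for v in toy_net.nodes}
        out = flow_scores(toy_net, init)
        assert out.residual < 1e-9


class TestStsfaEmod:
    def _maps(self, fc_values, genes):
        s1 = ScoreMap(Scenario(), {}, {g: 0.0 for g in genes})
        s2 = ScoreMap(Scenario(), {}, {g: 10.0**v - 1.0 for g, v in
                                       zip(genes, fc_values)})
        return s1, s2

    def test_hand_computed_mean_sd_limits(self):
        genes = list("abcde")
        s1, s2 = self._maps([1.0, 0.0, -1.0, 0.2, -0.2], genes)
        emod, fc = stsfa_emod(s1, s2, genes)
        assert fc.mean_fc == pytest.approx(0.0, abs=1e-12)
        assert fc.sd_fc == pytest.approx(0.7211, abs=1e-3)
        assert [emod[g] for g in genes] == [1, 0, -1, 0, 0]

    def test_uniform_fold_change_gives_no_calls(self):
        genes = list("abc")
        s1, s2 = self._maps([0.5, 0.5, 0.5], genes)
        emod, fc = stsfa_emod(s1, s2, genes)
        assert fc.sd_fc == 0.0
        assert all(v == 0 for v in emod.values())

    def test_identical_scores_give_zero_fold_changes(self):
        genes = list("abcd")
        s = ScoreMap(Scenario(), {}, {g: float(i) for i, g in enumerate(genes)})
        emod, fc = stsfa_emod(s, s, genes)
        assert (fc.log10fc == 0).all()
        assert all(v == 0 for v in emod.values())

    def test_fewer_than_two_genes_rejected(self):
        s = ScoreMap(Scenario(), {}, {"a": 1.0})
        with pytest.raises(ValueError):
            stsfa_emod(s, s, ["a"])

    def test_gaussian_fold_changes_call_at_most_thirty_percent_per_side(self, rng):
        genes = [f"g{i}" for i in range(500)]
        s1, s2 = self._maps(rng.normal(0, 0.3, 500), genes)
        emod, _ = stsfa_emod(s1, s2, genes)
        calls = np.array(list(emod.values()))
        assert (calls == 1).mean() <= 0.30
        assert (calls == -1).mean() <= 0.30
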