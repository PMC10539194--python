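"""Network data model, validation, and exact inference against enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamdiag.network import (
    CPT,
    DiagnosticNetwork,
    ImpossibleEvidenceError,
    Node,
    NodeState,
    StateScheme,
    infer_posteriors,
    joint_probability,
    pairwise_joint,
    validate_network,
)

from conftest import brute_posteriors, random_network


def _simple_pair(p_a=0.5, p_b_given=None):
    a = Node("A", "stressor", (NodeState("a0"), NodeState("a1")))
    b = Node("B", "metric", (NodeState("b0"), NodeState("b1")))
    if p_b_given is None:
        p_b_given = {("a0",): [0.5, 0.5], ("a1",): [0.5, 0.5]}
    cpts = {
        "A": CPT("A", (), {(): np.array([p_a, 1 - p_a])}),
        "B": CPT("B", ("A",), {k: np.asarray(v) for k, v in p_b_given.items()}),
    }
    return DiagnosticNetwork([a, b], cpts)


class TestValidation:
    def test_well_formed_network_passes(self, chain_net):
        assert validate_network(chain_net) == []

    def test_unnormalized_row_reported_with_row_name(self):
        net = _simple_pair(p_b_given={("a0",): [0.5, 0.4], ("a1",): [0.5, 0.5]})
        problems = validate_network(net)
        assert len(problems) == 1
        assert "'B'" in problems[0] and "a0" in problems[0]

    def test_cycle_reported(self):
        a = Node("A", "metric", (NodeState("a0"), NodeState("a1")))
        b = Node("B", "metric", (NodeState("b0"), NodeState("b1")))
        rows = {("b0",): np.array([0.5, 0.5]), ("b1",): np.array([0.5, 0.5])}
        rows_a = {("a0",): np.array([0.5, 0.5]), ("a1",): np.array([0.5, 0.5])}
        net = DiagnosticNetwork(
            [a, b], {"A": CPT("A", ("B",), rows), "B": CPT("B", ("A",), rows_a)}
        )
        assert any("cycle" in p for p in validate_network(net))

    def test_metric_parent_of_stressor_rejected(self):
        b = Node("B", "metric", (NodeState("b0"), NodeState("b1")))
        a = Node("A", "stressor", (NodeState("a0"), NodeState("a1")))
        net = DiagnosticNetwork(
            [b, a],
            {
                "B": CPT("B", (), {(): np.array([0.5, 0.5])}),
                "A": CPT(
                    "A",
                    ("B",),
                    {("b0",): np.array([1.0, 0.0]), ("b1",): np.array([0.0, 1.0])},
                ),
            },
        )
        assert any("stressor" in p and "metric" in p for p in validate_network(net))

    @pytest.mark.parametrize("n_states", [1, 4])
    def test_state_count_bounds(self, n_states):
        states = tuple(NodeState(f"s{i}") for i in range(n_states))
        node = Node("A", "stressor", states)
        table = {(): np.ones(n_states) / n_states}
        net = DiagnosticNetwork([node], {"A": CPT("A", (), table)})
        assert any("states" in p for p in validate_network(net))

    def test_missing_cpt_row_reported(self):
        net = _simple_pair()
        del net.cpts["B"].table[("a1",)]
        assert any("missing row" in p for p in validate_network(net))


class TestJointProbability:
    def test_independent_product(self):
        net = _simple_pair(p_a=0.5)
        assert joint_probability(net, {"A": "a0", "B": "b0"}) == pytest.approx(0.25)

    def test_chain_product(self):
        net = _simple_pair(
            p_a=0.3, p_b_given={("a0",): [0.9, 0.1], ("a1",): [0.1, 0.9]}
        )
        assert joint_probability(net, {"A": "a0", "B": "b0"}) == pytest.approx(0.27)

    def test_sums_to_one_over_all_assignments(self, two_stressor_net):
        names = two_stressor_net.node_names
        labels = [two_stressor_net.node(n).state_labels for n in names]
        total = sum(
            joint_probability(two_stressor_net, dict(zip(names, combo)))
            for combo in itertools.product(*labels)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_missing_node_raises(self, chain_net):
        with pytest.raises(KeyError):
            joint_probability(chain_net, {"A": "a0"})


class TestInference:
    def test_no_evidence_root_posterior_equals_prior(self, chain_net):
        post = infer_posteriors(chain_net, {})
        np.testing.assert_allclose(post["A"], [0.7, 0.3], atol=1e-12)

    def test_evidence_node_returns_indicator(self, chain_net):
        post = infer_posteriors(chain_net, {"B": "b1"})
        np.testing.assert_array_equal(post["B"], [0.0, 1.0])

    def test_chain_matches_enumeration(self, chain_net):
        for evidence in [{}, {"C": "c1"}, {"B": "b0"}, {"B": "b1", "C": "c0"}]:
            post = infer_posteriors(chain_net, evidence)
            oracle = brute_posteriors(chain_net, evidence)
            for name in chain_net.node_names:
                np.testing.assert_allclose(post[name], oracle[name], atol=1e-9)

    def test_impossible_evidence_raises(self):
        net = _simple_pair(
            p_a=1.0, p_b_given={("a0",): [1.0, 0.0], ("a1",): [0.5, 0.5]}
        )
        with pytest.raises(ImpossibleEvidenceError):
            infer_posteriors(net, {"B": "b1"})

    def test_posteriors_normalized(self, two_stressor_net):
        post = infer_posteriors(two_stressor_net, {"EPT taxa": "low"})
        for vec in post.values():
            assert abs(vec.sum() - 1.0) <= 1e-9

    def test_elimination_order_independence(self, two_stressor_net):
        rng = np.random.default_rng(7)
        names = two_stressor_net.node_names
        reference = infer_posteriors(two_stressor_net, {"KLIWA Index": "above"})
        for _ in range(10):
            order = list(rng.permutation(names))
            post = infer_posteriors(
                two_stressor_net, {"KLIWA Index": "above"}, elimination_order=order
            )
            for name in names:
                np.testing.assert_allclose(post[name], reference[name], atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 5))
    def test_random_networks_match_enumeration(self, seed, n_evidence):
        rng = np.random.default_rng(seed)
        net = random_network(rng, max_nodes=6)
        names = net.node_names
        k = min(n_evidence, 3, len(names) - 1)
        chosen = list(rng.choice(names, size=k, replace=False))
        evidence = {
            n: net.node(n).state_labels[rng.integers(net.node(n).n_states)]
            for n in chosen
        }
        try:
            post = infer_posteriors(net, evidence)
        except ImpossibleEvidenceError:
            with pytest.raises(ZeroDivisionError):
                brute_posteriors(net, evidence)
            return
        oracle = brute_posteriors(net, evidence)
        for name in names:
            np.testing.assert_allclose(post[name], oracle[name], atol=1e-9)

    def test_pairwise_joint_matches_enumeration(self, two_stressor_net):
        joint = pairwise_joint(two_stressor_net, "Fine sediments", "EPT taxa")
        oracle = np.zeros((2, 2))
        names = two_stressor_net.node_names
        labels = [two_stressor_net.node(n).state_labels for n in names]
        for combo in itertools.product(*labels):
            assignment = dict(zip(names, combo))
            i = two_stressor_net.node("Fine sediments").state_index(
                assignment["Fine sediments"]
            )
            j = two_stressor_net.node("EPT taxa").state_index(assignment["EPT taxa"])
            oracle[i, j] += joint_probability(two_stressor_net, assignment)
        np.testing.assert_allclose(joint, oracle, atol=1e-12)


class TestStateScheme:
    def test_break_boundary_goes_to_upper_state(self):
        scheme = StateScheme.from_breaks("x", [2.0, 5.0], lower=0.0, upper=10.0)
        assert scheme.assign(2.0) == "mid"
        assert scheme.assign(4.999) == "mid"
        assert scheme.assign(5.0) == "high"

    def test_range_maximum_belongs_to_top_state(self):
        scheme = StateScheme.from_breaks("x", [5.0], lower=0.0, upper=10.0)
        assert scheme.assign(10.0) == "high"
        with pytest.raises(ValueError):
            scheme.assign(10.5)

    def test_at_most_two_breaks(self):
        with pytest.raises(ValueError):
            StateScheme.from_breaks("x", [1.0, 2.0, 3.0])
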