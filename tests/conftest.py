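"""Shared fixtures: small hand-specified networks and a brute-force oracle.

The brute-force posterior oracle enumerates every full assignment through
``joint_probability`` (the plain product rule) and normalizes — it shares
no code path with the variable-elimination engine it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from streamdiag.network import (
    CPT,
    DiagnosticNetwork,
    Node,
    NodeState,
    joint_probability,
)


def brute_posteriors(
    net: DiagnosticNetwork, evidence: dict[str, str]
) -> dict[str, np.ndarray]:
    """Posteriors by full enumeration of the joint (independent oracle)."""
    names = net.node_names
    labels = {n: net.node(n).state_labels for n in names}
    totals = {n: np.zeros(len(labels[n])) for n in names}
    z = 0.0
    for combo in itertools.product(*(labels[n] for n in names)):
        assignment = dict(zip(names, combo))
        if any(assignment[k] != v for k, v in evidence.items()):
            continue
        p = joint_probability(net, assignment)
        z += p
        for n in names:
            totals[n][labels[n].index(assignment[n])] += p
    if z <= 0:
        raise ZeroDivisionError("evidence impossible under brute force")
    return {n: totals[n] / z for n in names}


def random_network(rng: np.random.Generator, max_nodes: int = 12) -> DiagnosticNetwork:
    """A random stressor→metric network with 2-3 states per node."""
    n_nodes = int(rng.integers(3, max_nodes + 1))
    n_stressors = int(rng.integers(1, n_nodes))
    nodes = []
    for i in range(n_nodes):
        role = "stressor" if i < n_stressors else "metric"
        k = int(rng.integers(2, 4))
        states = tuple(NodeState(f"s{j}") for j in range(k))
        nodes.append(Node(f"N{i}", role, states))
    cpts = {}
    for i, node in enumerate(nodes):
        if node.role == "stressor":
            parent_pool = [n.name for n in nodes[:i] if n.role == "stressor"]
        else:
            parent_pool = [n.name for n in nodes[:i]]
        n_par = int(rng.integers(0, min(3, len(parent_pool)) + 1))
        parents = tuple(
            sorted(rng.choice(parent_pool, size=n_par, replace=False))
        ) if n_par else ()
        table = {}
        parent_labels = [
            next(n for n in nodes if n.name == p).state_labels for p in parents
        ]
        for combo in itertools.product(*parent_labels):
            vec = rng.dirichlet(np.ones(node.n_states))
            table[combo] = vec
        cpts[node.name] = CPT(node.name, parents, table)
    return DiagnosticNetwork(nodes, cpts)


def known_three_node_net() -> DiagnosticNetwork:
    """A fixed stressor → two-metric network with hand-chosen CPTs, used as
    the generating model in parameter-recovery studies."""
    s = Node("S", "stressor", (NodeState("low"), NodeState("high")))
    m1 = Node("M1", "metric", (NodeState("low"), NodeState("high")))
    m2 = Node("M2", "metric", (NodeState("low"), NodeState("mid"), NodeState("high")))
    cpts = {
        "S": CPT("S", (), {(): np.array([0.35, 0.65])}),
        "M1": CPT(
            "M1",
            ("S",),
            {("low",): np.array([0.8, 0.2]), ("high",): np.array([0.3, 0.7])},
        ),
        "M2": CPT(
            "M2",
            ("S",),
            {
                ("low",): np.array([0.6, 0.3, 0.1]),
                ("high",): np.array([0.15, 0.35, 0.5]),
            },
        ),
    }
    return DiagnosticNetwork([s, m1, m2], cpts)


@pytest.fixture
def chain_net() -> DiagnosticNetwork:
    """Stressor → metric → metric chain with simple stated CPTs."""
    a = Node("A", "stressor", (NodeState("a0"), NodeState("a1")), degraded_state="a1")
    b = Node("B", "metric", (NodeState("b0"), NodeState("b1")))
    c = Node("C", "metric", (NodeState("c0"), NodeState("c1")))
    cpts = {
        "A": CPT("A", (), {(): np.array([0.7, 0.3])}),
        "B": CPT("B", ("A",), {("a0",): np.array([0.9, 0.1]), ("a1",): np.array([0.2, 0.8])}),
        "C": CPT("C", ("B",), {("b0",): np.array([0.6, 0.4]), ("b1",): np.array([0.25, 0.75])}),
    }
    return DiagnosticNetwork([a, b, c], cpts)


@pytest.fixture
def two_stressor_net() -> DiagnosticNetwork:
    """Two stressors feeding one shared metric, plus a private metric each."""
    s1 = Node("Fine sediments", "stressor", (NodeState("low"), NodeState("high")), "high")
    s2 = Node("Warming", "stressor", (NodeState("absent"), NodeState("present")), "present")
    m1 = Node("Psammal preference", "metric", (NodeState("low"), NodeState("high")))
    m2 = Node("KLIWA Index", "metric", (NodeState("below"), NodeState("above")))
    m3 = Node("EPT taxa", "metric", (NodeState("low"), NodeState("high")))
    cpts = {
        "Fine sediments": CPT("Fine sediments", (), {(): np.array([0.6, 0.4])}),
        "Warming": CPT("Warming", (), {(): np.array([0.5, 0.5])}),
        "Psammal preference": CPT(
            "Psammal preference",
            ("Fine sediments",),
            {("low",): np.array([0.85, 0.15]), ("high",): np.array([0.2, 0.8])},
        ),
        "KLIWA Index": CPT(
            "KLIWA Index",
            ("Warming",),
            {("absent",): np.array([0.9, 0.1]), ("present",): np.array([0.15, 0.85])},
        ),
        "EPT taxa": CPT(
            "EPT taxa",
            ("Fine sediments", "Warming"),
            {
                ("low", "absent"): np.array([0.1, 0.9]),
                ("low", "present"): np.array([0.45, 0.55]),
                ("high", "absent"): np.array([0.55, 0.45]),
                ("high", "present"): np.array([0.85, 0.15]),
            },
        ),
    }
    return DiagnosticNetwork([s1, s2, m1, m2, m3], cpts)
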