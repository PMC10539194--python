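"""Discrete Bayesian belief network data model and exact inference.

The networks used for stream diagnosis are small (roughly 20--25 nodes),
discrete (two or three states per node) and shallow: stressor nodes
(degradation causes) are parents, biological-metric nodes are children.
Exact inference by variable elimination is therefore cheap and is the only
inference scheme provided; there is no approximate sampling.

State boundaries on continuous variables follow a left-closed, right-open
convention ``[lower, upper)``, with the topmost interval right-closed, so
discretization at a break point is deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "NodeState",
    "Node",
    "CPT",
    "DiagnosticNetwork",
    "StateScheme",
    "ImpossibleEvidenceError",
    "validate_network",
    "validate_evidence",
    "joint_probability",
    "infer_posteriors",
    "pairwise_joint",
]

#: Probability vectors must sum to one within this tolerance.
PROB_TOL = 1e-9

# Roles a node can play in a diagnostic network.
ROLE_STRESSOR = "stressor"
ROLE_METRIC = "metric"


class ImpossibleEvidenceError(ValueError):
    """Raised when the supplied evidence has probability zero under the network."""


@dataclass(frozen=True)
class NodeState:
    """One discrete state of a node.

    For nodes discretized from a continuous variable, ``lower``/``upper``
    give the interval on the variable's native scale (``-inf``/``+inf``
    allowed).  For categorical nodes both bounds are ``None`` and the label
    alone identifies the state.
    """

    label: str
    lower: float | None = None
    upper: float | None = None

    @property
    def is_interval(self) -> bool:
        return self.lower is not None or self.upper is not None

    def contains(self, value: float) -> bool:
        """Interval membership under the [lower, upper) convention.

        The topmost state (``upper == +inf`` or ``None`` treated as +inf)
        is right-closed by construction.
        """
        lo = -math.inf if self.lower is None else self.lower
        hi = math.inf if self.upper is None else self.upper
        return lo <= value < hi or (value == hi and hi == math.inf)


@dataclass(frozen=True)
class Node:
    """A network variable: a degradation cause (stressor) or a biological metric.

    ``degraded_state`` optionally names the state read as "cause present":
    the posterior probability of this state is what diagnosis reports for
    the stressor.
    """

    name: str
    role: str
    states: tuple[NodeState, ...]
    degraded_state: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def state_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        try:
            return self.state_labels.index(label)
        except ValueError:
            raise KeyError(f"node {self.name!r} has no state {label!r}") from None


@dataclass(frozen=True)
class StateScheme:
    """Break-point boundaries mapping a continuous variable to ordered states.

    Boundaries equal the detected (or expert-supplied) break values; the
    resulting states tile the variable's declared range.
    """

    variable: str
    states: tuple[NodeState, ...]

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))

    @classmethod
    def from_breaks(
        cls,
        variable: str,
        breaks: list[float],
        labels: list[str] | None = None,
        lower: float = -math.inf,
        upper: float = math.inf,
    ) -> "StateScheme":
        """Build a scheme from 0--2 ascending break values.

        ``k`` breaks yield ``k + 1`` ordered states covering
        ``[lower, upper]``; default labels are ``low``/``high`` or
        ``low``/``mid``/``high``.
        """
        breaks = sorted(float(b) for b in breaks)
        if len(breaks) > 2:
            raise ValueError("at most two break values (three states) are supported")
        bounds = [lower, *breaks, upper]
        k = len(bounds) - 1
        if labels is None:
            labels = ["low", "high"] if k == 2 else ["low", "mid", "high"] if k == 3 else ["all"]
        if len(labels) != k:
            raise ValueError(f"need {k} labels, got {len(labels)}")
        states = tuple(
            NodeState(lab, bounds[i], bounds[i + 1]) for i, lab in enumerate(labels)
        )
        return cls(variable, states)

    @property
    def breaks(self) -> tuple[float, ...]:
        return tuple(s.upper for s in self.states[:-1])

    def assign(self, value: float) -> str:
        """Map a value to its state label; raises if outside the total range.

        Intervals are [lower, upper) with the topmost interval right-closed,
        so a value sitting exactly on a break goes to the upper state and the
        range maximum still belongs to the top state.
        """
        top = self.states[-1]
        top_hi = math.inf if top.upper is None else top.upper
        if value == top_hi:
            return top.label
        for s in self.states:
            if s.contains(value):
                return s.label
        raise ValueError(
            f"value {value!r} outside the declared range of variable {self.variable!r}"
        )


@dataclass
class CPT:
    """Conditional probability table of one child node.

    ``table`` maps each combination of parent-state labels (a tuple in
    ``parents`` order; the empty tuple for root nodes) to a probability
    vector over the child's states.
    """

    child: str
    parents: tuple[str, ...]
    table: dict[tuple[str, ...], np.ndarray]

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.table = {tuple(k): np.asarray(v, dtype=float) for k, v in self.table.items()}

    def row(self, combo: tuple[str, ...]) -> np.ndarray:
        return self.table[tuple(combo)]


@dataclass
class DiagnosticNetwork:
    """A directed acyclic network of stressor (parent) and metric (child) nodes.

    Edges are implied by the CPT parent lists; the joint distribution is the
    product of all CPTs.  ``meta`` carries provenance annotations such as
    expert-override notes and zero-support flags from CPT fitting.
    """

    nodes: list[Node]
    cpts: dict[str, CPT]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = list(self.nodes)
        self._by_name = {n.name: n for n in self.nodes}

    def node(self, name: str) -> Node:
        return self._by_name[name]

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def parents_of(self, name: str) -> tuple[str, ...]:
        return self.cpts[name].parents

    @property
    def stressors(self) -> list[Node]:
        return [n for n in self.nodes if n.role == ROLE_STRESSOR]

    @property
    def metrics(self) -> list[Node]:
        return [n for n in self.nodes if n.role == ROLE_METRIC]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for cpt in self.cpts.values():
            for p in cpt.parents:
                g.add_edge(p, cpt.child)
        return g

    def connected_pairs(self) -> list[tuple[str, str]]:
        """(stressor, metric) pairs joined by an edge, in either direction."""
        pairs = []
        for cpt in self.cpts.values():
            child = self._by_name.get(cpt.child)
            for p in cpt.parents:
                parent = self._by_name.get(p)
                if parent is None or child is None:
                    continue
                if parent.role == ROLE_STRESSOR and child.role == ROLE_METRIC:
                    pairs.append((parent.name, child.name))
                elif parent.role == ROLE_METRIC and child.role == ROLE_STRESSOR:
                    pairs.append((child.name, parent.name))
        return sorted(set(pairs))


# ---------------------------------------------------------------------------
# Validation


def validate_network(net: DiagnosticNetwork) -> list[str]:
    """Check every structural invariant; returns violation descriptions.

    An empty list means the network is well formed.  Violations are
    reported, never raised, so callers can aggregate them (e.g., a file
    loader reporting all problems at once).
    """
    problems: list[str] = []
    seen = set()
    for node in net.nodes:
        if node.name in seen:
            problems.append(f"duplicate node name {node.name!r}")
        seen.add(node.name)
        if node.role not in (ROLE_STRESSOR, ROLE_METRIC):
            problems.append(f"node {node.name!r}: unknown role {node.role!r}")
        if not (2 <= node.n_states <= 3):
            problems.append(
                f"node {node.name!r}: {node.n_states} states (2 or 3 required)"
            )
        labels = node.state_labels
        if len(set(labels)) != len(labels):
            problems.append(f"node {node.name!r}: duplicate state labels")
        if node.degraded_state is not None and node.degraded_state not in labels:
            problems.append(
                f"node {node.name!r}: degraded_state {node.degraded_state!r} "
                "is not one of its states"
            )
        # interval states must be disjoint, ordered and contiguous
        ivals = [s for s in node.states if s.is_interval]
        if ivals and len(ivals) != node.n_states:
            problems.append(f"node {node.name!r}: mixes interval and categorical states")
        for a, b in zip(ivals, ivals[1:]):
            lo_a = -math.inf if a.lower is None else a.lower
            hi_a = math.inf if a.upper is None else a.upper
            lo_b = -math.inf if b.lower is None else b.lower
            if hi_a != lo_b:
                problems.append(
                    f"node {node.name!r}: states {a.label!r}/{b.label!r} are not "
                    "contiguous ordered intervals"
                )
            if lo_a >= hi_a:
                problems.append(f"node {node.name!r}: state {a.label!r} is an empty interval")

    for name in net.node_names:
        if name not in net.cpts:
            problems.append(f"node {name!r} has no CPT")
    for child, cpt in net.cpts.items():
        if child != cpt.child:
            problems.append(f"CPT keyed {child!r} declares child {cpt.child!r}")
        if child not in net._by_name:
            problems.append(f"CPT child {child!r} is not a node")
            continue
        child_node = net.node(child)
        missing_parent = False
        for p in cpt.parents:
            if p not in net._by_name:
                problems.append(f"CPT of {child!r}: parent {p!r} is not a node")
                missing_parent = True
        if missing_parent:
            continue
        if child_node.role == ROLE_STRESSOR and any(
            net.node(p).role == ROLE_METRIC for p in cpt.parents
        ):
            problems.append(
                f"CPT of {child!r}: metric node used as parent of a stressor "
                "(edges must point stressor → metric)"
            )
        expected = set(
            itertools.product(*(net.node(p).state_labels for p in cpt.parents))
        )
        got = set(cpt.table)
        for combo in sorted(expected - got):
            problems.append(f"CPT of {child!r}: missing row for parents {combo!r}")
        for combo in sorted(got - expected):
            problems.append(f"CPT of {child!r}: row {combo!r} names unknown parent states")
        for combo in sorted(got & expected):
            vec = cpt.table[combo]
            if len(vec) != child_node.n_states:
                problems.append(
                    f"CPT of {child!r}, row {combo!r}: {len(vec)} probabilities "
                    f"for {child_node.n_states} states"
                )
                continue
            if np.any(vec < 0):
                problems.append(f"CPT of {child!r}, row {combo!r}: negative probability")
            if abs(float(vec.sum()) - 1.0) > PROB_TOL:
                problems.append(
                    f"CPT of {child!r}, row {combo!r}: probabilities sum to "
                    f"{float(vec.sum()):.12g}, not 1"
                )

    try:
        graph = net.graph()
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            problems.append(f"network contains a cycle: {cycle}")
    except Exception:  # a CPT naming unknown nodes was already reported
        pass
    return problems


def validate_evidence(net: DiagnosticNetwork, evidence: dict[str, str]) -> None:
    """Raise ``KeyError`` if evidence names an unknown node or state."""
    for name, label in evidence.items():
        if name not in net._by_name:
            raise KeyError(f"evidence names unknown node {name!r}")
        net.node(name).state_index(label)  # raises on unknown state


# ---------------------------------------------------------------------------
# Joint probability and factors


def joint_probability(net: DiagnosticNetwork, assignment: dict[str, str]) -> float:
    """Probability of a full state assignment: the product of CPT entries."""
    missing = set(net.node_names) - set(assignment)
    if missing:
        raise KeyError(f"assignment misses nodes: {sorted(missing)}")
    prob = 1.0
    for name in net.node_names:
        cpt = net.cpts[name]
        combo = tuple(assignment[p] for p in cpt.parents)
        idx = net.node(name).state_index(assignment[name])
        prob *= float(cpt.row(combo)[idx])
    return prob


class _Factor:
    """A multidimensional table over a tuple of variables (internal)."""

    __slots__ = ("vars", "values")

    def __init__(self, variables: tuple[str, ...], values: np.ndarray):
        self.vars = tuple(variables)
        self.values = np.asarray(values, dtype=float)

    @classmethod
    def from_cpt(cls, net: DiagnosticNetwork, cpt: CPT) -> "_Factor":
        variables = cpt.parents + (cpt.child,)
        shape = tuple(net.node(v).n_states for v in variables)
        values = np.empty(shape)
        parent_labels = [net.node(p).state_labels for p in cpt.parents]
        for combo_idx in itertools.product(*(range(len(pl)) for pl in parent_labels)):
            combo = tuple(pl[i] for pl, i in zip(parent_labels, combo_idx))
            values[combo_idx] = cpt.row(combo)
        return cls(variables, values)

    def reduce(self, var: str, index: int) -> "_Factor":
        if var not in self.vars:
            return self
        axis = self.vars.index(var)
        values = np.take(self.values, index, axis=axis)
        return _Factor(self.vars[:axis] + self.vars[axis + 1 :], values)

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._expand(out_vars)
        b = other._expand(out_vars)
        return _Factor(out_vars, a * b)

    def _expand(self, out_vars: tuple[str, ...]) -> np.ndarray:
        # move own axes into out_vars order, add singleton axes for new vars
        src = [self.vars.index(v) for v in out_vars if v in self.vars]
        arr = np.transpose(self.values, src) if src else self.values
        shape = tuple(
            arr.shape[sum(1 for u in out_vars[:i] if u in self.vars)]
            if v in self.vars
            else 1
            for i, v in enumerate(out_vars)
        )
        return arr.reshape(shape)

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            self.vars[:axis] + self.vars[axis + 1 :], self.values.sum(axis=axis)
        )


def _eliminate(factors: list[_Factor], keep: set[str], order: list[str] | None) -> _Factor:
    """Sum all variables not in ``keep`` out of the factor product.

    ``order`` optionally fixes the elimination sequence; by default a greedy
    min-size heuristic is used.  Each elimination step renormalizes nothing:
    probabilities stay in linear space, which is numerically safe at this
    scale, and the caller normalizes the final factor.
    """
    factors = list(factors)
    to_eliminate = {v for f in factors for v in f.vars} - keep
    if order is not None:
        sequence = [v for v in order if v in to_eliminate]
        sequence += sorted(to_eliminate - set(sequence))
    else:
        sequence = None

    while to_eliminate:
        if sequence is not None:
            var = sequence.pop(0)
        else:
            # greedy: eliminate the variable whose product factor is smallest
            def cost(v: str) -> int:
                involved_vars = {
                    u for f in factors if v in f.vars for u in f.vars
                }
                return len(involved_vars)

            var = min(sorted(to_eliminate), key=cost)
        to_eliminate.discard(var)
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        if not involved:
            continue
        product = involved[0]
        for f in involved[1:]:
            product = product.multiply(f)
        factors = rest + [product.sum_out(var)]

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    # order axes canonically by `keep` membership order of appearance
    return result


def _reduced_factors(
    net: DiagnosticNetwork, evidence: dict[str, str]
) -> list[_Factor]:
    factors = [_Factor.from_cpt(net, cpt) for cpt in net.cpts.values()]
    for name, label in evidence.items():
        idx = net.node(name).state_index(label)
        factors = [f.reduce(name, idx) for f in factors]
    return factors


def infer_posteriors(
    net: DiagnosticNetwork,
    evidence: dict[str, str] | None = None,
    elimination_order: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Exact per-node posterior distributions given evidence.

    Runs variable elimination once per query node.  Evidence nodes return
    indicator vectors.  Evidence that is impossible under the network
    (probability zero) raises :class:`ImpossibleEvidenceError` rather than
    silently dividing by zero.
    """
    evidence = dict(evidence or {})
    validate_evidence(net, evidence)
    factors = _reduced_factors(net, evidence)

    z = float(_eliminate(factors, set(), elimination_order).values)
    if z <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence!r} has probability 0 under the network"
        )

    posteriors: dict[str, np.ndarray] = {}
    for node in net.nodes:
        if node.name in evidence:
            vec = np.zeros(node.n_states)
            vec[node.state_index(evidence[node.name])] = 1.0
            posteriors[node.name] = vec
            continue
        marg = _eliminate(factors, {node.name}, elimination_order)
        values = marg.values.reshape(node.n_states)
        total = float(values.sum())
        if total <= 0.0:
            raise ImpossibleEvidenceError(
                f"evidence {evidence!r} leaves node {node.name!r} without support"
            )
        posteriors[node.name] = values / total
    return posteriors


def pairwise_joint(
    net: DiagnosticNetwork,
    a: str,
    b: str,
    evidence: dict[str, str] | None = None,
) -> np.ndarray:
    """Exact joint distribution of two nodes, shape (|states a|, |states b|)."""
    evidence = dict(evidence or {})
    validate_evidence(net, evidence)
    if a in evidence or b in evidence:
        raise ValueError("query nodes must not carry evidence")
    factors = _reduced_factors(net, evidence)
    marg = _eliminate(factors, {a, b}, None)
    # _eliminate returns axes in multiplication order; align to (a, b)
    vals = marg.values
    if marg.vars == (b, a):
        vals = vals.T
    elif marg.vars != (a, b):
        raise AssertionError(f"unexpected factor vars {marg.vars}")
    total = float(vals.sum())
    if total <= 0.0:
        raise ImpossibleEvidenceError("evidence has probability 0 under the network")
    return vals / total
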