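"""Discretize monitoring tables and populate CPTs from conditional frequencies.

Monitoring tables are plain :class:`pandas.DataFrame` objects: one row per
site, one numeric column per variable (land-use percentages, 1-7
hydromorphology assessment classes, concentrations, index values); missing
values are NaN.  A network skeleton (DAG plus state schemes) is turned into
a full :class:`~streamdiag.network.DiagnosticNetwork` by counting state
co-occurrences, with Dirichlet-style smoothing so no CPT row is ever exactly
zero, and expert knowledge can then override individual rows declaratively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import (
    CPT,
    DiagnosticNetwork,
    Node,
    StateScheme,
    validate_network,
)

__all__ = [
    "NetworkSkeleton",
    "ExpertOverride",
    "discretize",
    "fit_cpts",
    "apply_overrides",
]

ZERO_SUPPORT_KEY = "zero_support_rows"


@dataclass
class NetworkSkeleton:
    """Network structure before parameter learning: nodes, edges, schemes.

    ``edges`` point stressor → metric.  Each node's states come from its
    :class:`~streamdiag.network.StateScheme` (break-point boundaries or
    expert-supplied ranges).
    """

    nodes: list[Node]
    edges: list[tuple[str, str]]

    def __post_init__(self):
        self.nodes = list(self.nodes)
        self.edges = [tuple(e) for e in self.edges]
        self._by_name = {n.name: n for n in self.nodes}

    @classmethod
    def from_schemes(
        cls,
        schemes: dict[str, StateScheme],
        roles: dict[str, str],
        edges: list[tuple[str, str]],
        degraded_states: dict[str, str] | None = None,
    ) -> "NetworkSkeleton":
        degraded_states = degraded_states or {}
        nodes = [
            Node(name, roles[name], scheme.states, degraded_states.get(name))
            for name, scheme in schemes.items()
        ]
        return cls(nodes, edges)

    def node(self, name: str) -> Node:
        return self._by_name[name]

    def parents_of(self, name: str) -> tuple[str, ...]:
        return tuple(sorted(p for p, c in self.edges if c == name))

    def validate(self) -> list[str]:
        problems = []
        for p, c in self.edges:
            for end in (p, c):
                if end not in self._by_name:
                    problems.append(f"edge ({p!r}, {c!r}) names unknown node {end!r}")
        g = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            problems.append("skeleton edges contain a cycle")
        return problems


@dataclass
class ExpertOverride:
    """One expert-assigned CPT row, with provenance.

    ``row`` maps the parent-state combination (by parent name) to the
    replacement probability vector over the child's states.  Overrides are
    data, not code, so the iterative expert-feedback loop stays reproducible
    and diffable.
    """

    child: str
    given: dict[str, str]
    probabilities: list[float]
    note: str = ""


def discretize(
    table: pd.DataFrame, schemes: dict[str, StateScheme] | list[StateScheme]
) -> pd.DataFrame:
    """Map continuous monitoring values to node-state labels.

    Values fall into ``[lower, upper)`` intervals (topmost right-closed);
    missing values stay missing.  A value outside a scheme's total range is
    an error naming the site and variable, since it signals a unit or
    range-declaration problem rather than legitimate data.
    """
    if not isinstance(schemes, dict):
        schemes = {s.variable: s for s in schemes}
    missing_cols = [v for v in schemes if v not in table.columns]
    if missing_cols:
        raise KeyError(f"monitoring table lacks variables: {missing_cols}")
    out = pd.DataFrame(index=table.index, columns=list(schemes), dtype=object)
    for var, scheme in schemes.items():
        values = table[var].to_numpy(dtype=float)
        observed = ~np.isnan(values)
        lo = scheme.states[0].lower
        hi = scheme.states[-1].upper
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        bad = observed & ((values < lo) | (values > hi))
        if bad.any():
            site = table.index[np.flatnonzero(bad)[0]]
            raise ValueError(
                f"site {site!r}, variable {var!r}: value "
                f"{table.at[site, var]!r} outside the declared range of its "
                "state scheme"
            )
        # [lower, upper) per state, topmost right-closed
        idx = np.searchsorted(np.asarray(scheme.breaks), values[observed], side="right")
        labels = np.array([s.label for s in scheme.states], dtype=object)
        col = np.full(len(values), np.nan, dtype=object)
        col[observed] = labels[idx]
        out[var] = col
    return out


def fit_cpts(
    skeleton: NetworkSkeleton,
    data: pd.DataFrame,
    alpha_prior: float = 1.0,
) -> DiagnosticNetwork:
    """Populate every CPT from conditional state frequencies.

    Each row is ``(count(child state, parent combo) + α) /
    (count(parent combo) + α·|child states|)`` — Dirichlet smoothing with a
    symmetric prior (default α = 1) so sparse parent combinations never
    produce exact zeros that would break inference downstream.  Counting is
    complete-case per child-parent family: a site contributes to a family
    only if the child and all its parents are observed there.  Parent
    combinations with zero support fall back to the child's smoothed
    marginal distribution (closer to how practitioners read the overall data
    distribution than a flat uniform) and are flagged in
    ``net.meta["zero_support_rows"]``.
    """
    problems = skeleton.validate()
    if problems:
        raise ValueError("invalid skeleton: " + "; ".join(problems))
    if alpha_prior < 0:
        raise ValueError("alpha_prior must be non-negative")

    cpts: dict[str, CPT] = {}
    zero_support: list[tuple[str, tuple[str, ...]]] = []
    for node in skeleton.nodes:
        if node.name not in data.columns:
            raise KeyError(
                f"node {node.name!r} absent from the discretized data and has "
                "no expert override"
            )
        parents = skeleton.parents_of(node.name)
        child_labels = node.state_labels
        k = len(child_labels)

        family_cols = [node.name, *parents]
        family = data[family_cols].dropna()
        child_counts = family[node.name].value_counts()
        marginal = np.array(
            [child_counts.get(lab, 0) + alpha_prior for lab in child_labels],
            dtype=float,
        )
        if marginal.sum() == 0:  # alpha 0 and no data at all
            marginal = np.ones(k)
        marginal = marginal / marginal.sum()

        parent_labels = [skeleton.node(p).state_labels for p in parents]
        table: dict[tuple[str, ...], np.ndarray] = {}
        for combo in itertools.product(*parent_labels):
            if parents:
                mask = np.ones(len(family), dtype=bool)
                for p, lab in zip(parents, combo):
                    mask &= (family[p] == lab).to_numpy()
                sub = family.loc[mask, node.name]
            else:
                sub = family[node.name]
            n_combo = len(sub)
            if n_combo == 0 and alpha_prior == 0:
                table[combo] = marginal.copy()
                zero_support.append((node.name, combo))
                continue
            counts = sub.value_counts()
            vec = np.array(
                [counts.get(lab, 0) + alpha_prior for lab in child_labels],
                dtype=float,
            )
            if n_combo == 0:
                # prior-only row: record the fallback to the marginal
                table[combo] = marginal.copy()
                zero_support.append((node.name, combo))
                continue
            table[combo] = vec / vec.sum()
        cpts[node.name] = CPT(node.name, parents, table)

    net = DiagnosticNetwork(list(skeleton.nodes), cpts)
    net.meta[ZERO_SUPPORT_KEY] = zero_support
    problems = validate_network(net)
    if problems:  # defensive: fitting should always produce a valid network
        raise AssertionError("fit produced an invalid network: " + "; ".join(problems))
    return net


def apply_overrides(
    net: DiagnosticNetwork, overrides: list[ExpertOverride]
) -> DiagnosticNetwork:
    """Replace named CPT rows with expert-assigned probability vectors.

    Returns a new network; provenance notes are retained in
    ``net.meta["overrides"]`` and any zero-support flag on a replaced row is
    cleared.  An override must target an existing parent combination.
    """
    cpts = {
        name: CPT(c.child, c.parents, {k: v.copy() for k, v in c.table.items()})
        for name, c in net.cpts.items()
    }
    zero_support = list(net.meta.get(ZERO_SUPPORT_KEY, []))
    notes = list(net.meta.get("overrides", []))
    for ov in overrides:
        if ov.child not in cpts:
            raise KeyError(f"override targets unknown node {ov.child!r}")
        cpt = cpts[ov.child]
        if set(ov.given) != set(cpt.parents):
            raise KeyError(
                f"override for {ov.child!r} must specify exactly its parents "
                f"{cpt.parents!r}, got {sorted(ov.given)!r}"
            )
        combo = tuple(ov.given[p] for p in cpt.parents)
        if combo not in cpt.table:
            raise KeyError(
                f"override for {ov.child!r} names unknown parent combination {combo!r}"
            )
        vec = np.asarray(ov.probabilities, dtype=float)
        if len(vec) != net.node(ov.child).n_states or np.any(vec < 0):
            raise ValueError(f"override for {ov.child!r}: invalid probability vector")
        if abs(float(vec.sum()) - 1.0) > 1e-9:
            raise ValueError(
                f"override for {ov.child!r}: probabilities sum to {vec.sum()!r}"
            )
        cpt.table[combo] = vec
        if (ov.child, combo) in zero_support:
            zero_support.remove((ov.child, combo))
        notes.append({"child": ov.child, "given": dict(ov.given), "note": ov.note})

    out = DiagnosticNetwork(list(net.nodes), cpts, dict(net.meta))
    out.meta[ZERO_SUPPORT_KEY] = zero_support
    out.meta["overrides"] = notes
    problems = validate_network(out)
    if problems:
        raise ValueError("overrides broke the network: " + "; ".join(problems))
    return out
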