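"""Evidence-driven diagnosis of degradation causes.

Observed biological-metric states are entered as evidence and propagated
through the network; each candidate cause (stressor) is then scored by how
far its posterior moved away from the no-evidence baseline, and causes are
ranked from the strongest to the weakest change.  A separate
value-of-information score ("entropy reduction") quantifies, per
metric-stressor pair, how much observing the metric would reduce
uncertainty about the cause, prior to seeing any data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    ROLE_METRIC,
    ROLE_STRESSOR,
    DiagnosticNetwork,
    infer_posteriors,
    pairwise_joint,
)

__all__ = [
    "StressorChange",
    "DiagnosisResult",
    "entropy",
    "diagnose",
    "diagnostic_value",
    "diagnostic_value_matrix",
]


def entropy(p) -> float:
    """Shannon entropy of a probability vector, in bits (0·log 0 := 0)."""
    p = np.asarray(p, dtype=float)
    if abs(float(p.sum()) - 1.0) > 1e-6 or np.any(p < -1e-12):
        raise ValueError("entropy requires a normalized probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass(frozen=True)
class StressorChange:
    """Posterior movement of one stressor under evidence."""

    stressor: str
    delta: np.ndarray  # posterior − baseline, one entry per state
    magnitude: float  # total variation distance, in [0, 1]
    direction: str  # state with the largest probability increase
    degraded_delta: float | None  # signed Δp of the degraded state, if declared


@dataclass
class DiagnosisResult:
    """Baseline and evidence posteriors plus the ranked stressor hierarchy."""

    baseline: dict[str, np.ndarray]
    posterior: dict[str, np.ndarray]
    changes: dict[str, StressorChange]
    ranking: list[str]  # stressor names, strongest → weakest change

    def top(self, k: int | None = None) -> list[StressorChange]:
        names = self.ranking if k is None else self.ranking[:k]
        return [self.changes[n] for n in names]


def diagnose(net: DiagnosticNetwork, evidence: dict[str, str]) -> DiagnosisResult:
    """Rank candidate degradation causes by posterior change under evidence.

    Evidence must name metric nodes only (diagnosis runs from symptoms to
    causes).  The change magnitude is the total variation distance
    ``½·Σ|posterior − baseline|`` per stressor — symmetric, bounded in
    [0, 1], and equal to ``|Δp(degraded)|`` for two-state nodes.  Ties in
    the ranking break alphabetically, so results are deterministic.
    """
    for name in evidence:
        if net.node(name).role != ROLE_METRIC:
            raise ValueError(
                f"evidence must be on metric nodes; {name!r} is a "
                f"{net.node(name).role}"
            )
    baseline = infer_posteriors(net, {})
    posterior = infer_posteriors(net, evidence)

    changes: dict[str, StressorChange] = {}
    for node in net.stressors:
        delta = posterior[node.name] - baseline[node.name]
        magnitude = 0.5 * float(np.abs(delta).sum())
        direction = node.state_labels[int(np.argmax(delta))]
        degraded_delta = None
        if node.degraded_state is not None:
            degraded_delta = float(delta[node.state_index(node.degraded_state)])
        changes[node.name] = StressorChange(
            node.name, delta, magnitude, direction, degraded_delta
        )
    ranking = sorted(changes, key=lambda n: (-changes[n].magnitude, n))
    return DiagnosisResult(baseline, posterior, changes, ranking)


def _binary_event_score(joint: np.ndarray, s: int) -> float:
    """Normalized mutual information of the event {C = s} with the metric.

    ``joint`` is the exact (stressor, metric) joint.  The binary variable
    B = 1{C = s} is formed by collapsing the remaining stressor states;
    the score is I(B; M) / H(B), or 0 when H(B) = 0 (degenerate event).
    """
    p_event = joint[s, :]
    p_rest = joint.sum(axis=0) - p_event
    b_joint = np.vstack([p_rest, p_event])  # shape (2, |M|)
    h_b = entropy(b_joint.sum(axis=1))
    if h_b == 0.0:
        return 0.0
    h_m = entropy(b_joint.sum(axis=0))
    nz = b_joint[b_joint > 0]
    h_bm = float(-(nz * np.log2(nz)).sum())
    mi = h_b + h_m - h_bm
    return max(mi, 0.0) / h_b


def diagnostic_value(
    net: DiagnosticNetwork,
    metric: str,
    stressor: str,
    variant: str = "state_averaged",
) -> float:
    """Entropy-reduction diagnostic value of a metric for a cause, in [0, 1].

    The default ``state_averaged`` variant forms, for every stressor state
    ``s``, the binary event C = s versus C ≠ s and computes the normalized
    mutual information I(1{C=s}; M) / H(1{C=s}) from the network's exact
    joint of the pair, averaging over the states (events with a degenerate
    prior contribute 0).  The ``global`` variant is plain normalized mutual
    information I(C; M) / H(C).  Both are 0 under independence and 1 when
    the metric pins the cause down exactly.
    """
    m_node = net.node(metric)
    c_node = net.node(stressor)
    if m_node.role != ROLE_METRIC:
        raise ValueError(f"{metric!r} has role {m_node.role!r}, expected metric")
    if c_node.role != ROLE_STRESSOR:
        raise ValueError(f"{stressor!r} has role {c_node.role!r}, expected stressor")

    joint = pairwise_joint(net, stressor, metric)  # rows: stressor states
    if variant == "state_averaged":
        scores = [_binary_event_score(joint, s) for s in range(joint.shape[0])]
        return float(np.mean(scores))
    if variant == "global":
        h_c = entropy(joint.sum(axis=1))
        if h_c == 0.0:
            return 0.0
        h_m = entropy(joint.sum(axis=0))
        nz = joint[joint > 0]
        h_cm = float(-(nz * np.log2(nz)).sum())
        return max(h_c + h_m - h_cm, 0.0) / h_c
    raise ValueError(f"unknown variant {variant!r}")


def diagnostic_value_matrix(
    net: DiagnosticNetwork, variant: str = "state_averaged"
) -> pd.DataFrame:
    """Diagnostic values for every connected metric-stressor pair.

    Rows are metric nodes, columns stressor nodes; pairs without a network
    edge are left as NaN (a metric carries no declared diagnostic link to
    that cause).
    """
    metrics = [n.name for n in net.metrics]
    stressors = [n.name for n in net.stressors]
    mat = pd.DataFrame(np.nan, index=metrics, columns=stressors, dtype=float)
    for stressor, metric in net.connected_pairs():
        mat.loc[metric, stressor] = diagnostic_value(net, metric, stressor, variant)
    return mat
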