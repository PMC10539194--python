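"""Validation of diagnostic networks.

Three complementary checks are provided: k-fold cross-validation of node
state predictions (k = 3 by default), scoring of expert feedback on
diagnosed stressors, and the comparison of diagnoses driven by assessment
metrics alone against diagnoses using the full diagnostic metric set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpt import NetworkSkeleton, fit_cpts
from .diagnosis import diagnose
from .network import (
    ROLE_METRIC,
    DiagnosticNetwork,
    infer_posteriors,
)

__all__ = [
    "CVReport",
    "ComparisonRow",
    "ComparisonReport",
    "UndefinedAccuracyError",
    "cross_validate",
    "score_expert_feedback",
    "classify_probability_change",
    "compare_metric_sets",
]

FEEDBACK_LABELS = frozenset(
    {"correct", "incorrect", "overestimated", "underestimated", "no_feedback"}
)


class UndefinedAccuracyError(ValueError):
    """No correct/incorrect labels at all — expert accuracy is undefined."""


@dataclass
class CVReport:
    node_accuracy: dict[str, float]  # mean accuracy across folds, per node
    model_accuracy: float  # mean over nodes
    k: int
    seed: int
    fold_sizes: list[int]


def _fold_assignment(index: pd.Index, k: int, seed: int) -> list[pd.Index]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(index))
    return [index[np.sort(chunk)] for chunk in np.array_split(order, k)]


def cross_validate(
    skeleton: NetworkSkeleton,
    data: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    alpha_prior: float = 1.0,
    evidence_mode: str = "all",
) -> CVReport:
    """k-fold cross-validated state-prediction accuracy per node.

    Sites are randomly partitioned into ``k`` folds; for each fold the CPTs
    are fitted on the remaining folds and every held-out site's node states
    are predicted as the modal posterior given the site's other observed
    states as evidence.  Accuracy is the share of predictions matching the
    observed state, averaged over folds; the model accuracy averages over
    nodes.

    ``evidence_mode='all'`` conditions on every other observed node (the
    strongest reading of observed-vs-predicted alignment);
    ``'metrics_only'`` conditions only on observed biological metrics, the
    situation a field diagnosis faces.
    """
    if k < 2:
        raise ValueError("cross-validation needs k >= 2")
    if evidence_mode not in ("all", "metrics_only"):
        raise ValueError(f"unknown evidence_mode {evidence_mode!r}")
    folds = _fold_assignment(data.index, k, seed)
    if any(len(f) == 0 for f in folds):
        raise ValueError(f"{k} folds over {len(data)} sites leaves an empty fold")

    node_names = [n.name for n in skeleton.nodes]
    metric_names = {n.name for n in skeleton.nodes if n.role == ROLE_METRIC}
    hits: dict[str, list[float]] = {n: [] for n in node_names}

    for test_idx in folds:
        train = data.drop(index=test_idx)
        net = fit_cpts(skeleton, train, alpha_prior=alpha_prior)
        fold_hits = {n: [0, 0] for n in node_names}  # [correct, total]
        cache: dict[tuple, dict[str, np.ndarray]] = {}
        for site in test_idx:
            row = data.loc[site]
            observed = {n: row[n] for n in node_names if pd.notna(row[n])}
            for target, actual in observed.items():
                evidence = {
                    n: s
                    for n, s in observed.items()
                    if n != target
                    and (evidence_mode == "all" or n in metric_names)
                }
                key = (target, tuple(sorted(evidence.items())))
                if key not in cache:
                    cache[key] = infer_posteriors(net, evidence)
                post = cache[key][target]
                node = skeleton.node(target)
                predicted = node.state_labels[int(np.argmax(post))]
                fold_hits[target][1] += 1
                fold_hits[target][0] += int(predicted == actual)
        for n in node_names:
            correct, total = fold_hits[n]
            if total > 0:
                hits[n].append(correct / total)

    node_accuracy = {
        n: float(np.mean(acc)) for n, acc in hits.items() if acc
    }
    model_accuracy = float(np.mean(list(node_accuracy.values())))
    return CVReport(node_accuracy, model_accuracy, k, seed, [len(f) for f in folds])


# ---------------------------------------------------------------------------
# Expert feedback


def score_expert_feedback(feedback: pd.DataFrame) -> dict:
    """Expert-based diagnostic accuracy and label tallies.

    ``feedback`` has columns ``site``, ``stressor``, ``label`` with labels
    from {correct, incorrect, overestimated, underestimated, no_feedback}.
    The accuracy is correct / (correct + incorrect): over- and
    underestimated diagnoses and entries without feedback are tallied but
    excluded from the denominator.  If no correct/incorrect label exists
    the accuracy is undefined and an explicit error is raised.
    """
    if len(feedback) == 0:
        raise ValueError("feedback table is empty")
    labels = feedback["label"]
    unknown = sorted(set(labels) - FEEDBACK_LABELS)
    if unknown:
        raise ValueError(f"unknown feedback labels: {unknown}")
    tally = {lab: int((labels == lab).sum()) for lab in sorted(FEEDBACK_LABELS)}
    denom = tally["correct"] + tally["incorrect"]
    if denom == 0:
        raise UndefinedAccuracyError(
            "no correct/incorrect labels — expert accuracy is undefined"
        )
    return {"accuracy": tally["correct"] / denom, "tally": tally, "n_scored": denom}


# ---------------------------------------------------------------------------
# Assessment metrics vs. diagnostic metrics


@dataclass
class ComparisonRow:
    stressor: str
    p_assessment: float
    p_all: float
    delta_pp: float  # percentage points on the degraded state
    classification: str


@dataclass
class ComparisonReport:
    rows: list[ComparisonRow]
    excluded: list[str] = field(default_factory=list)  # no degraded state declared

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stressor": r.stressor,
                    "p_assessment": r.p_assessment,
                    "p_all": r.p_all,
                    "delta_pp": r.delta_pp,
                    "classification": r.classification,
                }
                for r in self.rows
            ]
        )


def classify_probability_change(
    p_assessment: float, p_all: float, no_change_pp: float = 10.0
) -> str:
    """Decision rule for one stressor's probability change.

    A change of less than ``no_change_pp`` percentage points (default 10)
    means no change in diagnostic outcome.  A larger change that exceeds
    half of the assessment-only probability marks the stressor as
    overestimated (increase) or underestimated (decrease) by the
    assessment-only diagnosis.  Anything in between is a candidate for
    "correctly diagnosed", pending expert confirmation — whether a changed
    hierarchy moved closer to the truth is an expert judgment, not a rule.
    """
    delta = p_all - p_assessment
    if abs(delta) * 100.0 < no_change_pp:
        return "no_change"
    if abs(delta) > 0.5 * p_assessment:
        return "overestimated" if delta > 0 else "underestimated"
    return "correctly_diagnosed_candidate"


def compare_metric_sets(
    net: DiagnosticNetwork,
    evidence_all: dict[str, str],
    assessment_metrics: list[str],
    no_change_pp: float = 10.0,
) -> ComparisonReport:
    """Assessment-metric diagnosis versus full diagnostic-metric diagnosis.

    Runs the diagnosis twice — evidence restricted to the assessment
    metrics, then the full evidence — and compares the posterior
    probability of each stressor's degraded state.  Stressors without a
    declared degraded state cannot be compared on a single probability and
    are excluded with a warning entry.
    """
    unknown = [m for m in assessment_metrics if m not in net.node_names]
    if unknown:
        raise KeyError(f"unknown assessment metrics: {unknown}")
    missing = [m for m in assessment_metrics if m not in evidence_all]
    if missing:
        raise ValueError(
            f"evidence must cover all assessment metrics; missing: {missing}"
        )
    evidence_assessment = {
        m: s for m, s in evidence_all.items() if m in set(assessment_metrics)
    }
    d_assess = diagnose(net, evidence_assessment)
    d_all = diagnose(net, evidence_all)

    rows, excluded = [], []
    for node in net.stressors:
        if node.degraded_state is None:
            excluded.append(node.name)
            continue
        idx = node.state_index(node.degraded_state)
        p_a = float(d_assess.posterior[node.name][idx])
        p_f = float(d_all.posterior[node.name][idx])
        rows.append(
            ComparisonRow(
                node.name,
                p_a,
                p_f,
                (p_f - p_a) * 100.0,
                classify_probability_change(p_a, p_f, no_change_pp),
            )
        )
    return ComparisonReport(rows, excluded)
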