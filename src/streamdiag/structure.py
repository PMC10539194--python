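"""Data-driven selection of stressor-metric relationships and break points.

The candidate structure of a diagnostic network is derived from monitoring
data in four steps:

1. collinearity screening drops redundant stressors (|Spearman ρ| above a
   threshold, 0.8 by default);
2. an ensemble-of-trees regressor ranks the surviving stressors by
   permutation importance for each biological metric, keeping the top
   quarter;
3. break points — sharp shifts of the metric along a stressor gradient —
   are located by recursive binary partitioning with a permutation test,
   restricted to at most two splits so no node ever has more than three
   states;
4. a stressor-metric edge enters the skeleton only if the stressor is in
   the metric's top importance quartile AND a sufficiently sharp break
   exists.

Visual break-point reading is deliberately replaced by the quantitative
sharpness criterion (minimum jump relative to the response's interquartile
range): eyeballing partial-dependence plots is biased by the viewer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

__all__ = [
    "CorrelationScreenResult",
    "ImportanceRanking",
    "BreakPointSet",
    "collinearity_screen",
    "importance_rank",
    "partial_dependence",
    "detect_breakpoints",
    "select_relationships",
    "discover_structure",
]


@dataclass
class CorrelationScreenResult:
    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped, retained partner, ρ)
    constant: list[str] = field(default_factory=list)  # ρ undefined, kept


@dataclass
class ImportanceRanking:
    """Permutation-importance hierarchy of stressors for one metric."""

    response: str
    ranking: list[tuple[str, float]]  # (predictor, importance), descending
    selected: list[str]  # top-quartile subset, ceil(p/4) entries
    response_iqr: float
    model: RandomForestRegressor | None = None
    train_X: pd.DataFrame | None = None
    medians: pd.Series | None = None


@dataclass
class BreakPointSet:
    """Accepted break points of a metric along one stressor gradient."""

    predictor: str
    breaks: list[float]  # 0-2 ascending values inside the observed range
    sharpness: list[float]  # response jump across each break
    p_values: list[float]  # permutation-test p per break

    def __bool__(self) -> bool:
        return bool(self.breaks)


# ---------------------------------------------------------------------------
# Collinearity screening


def collinearity_screen(
    table: pd.DataFrame,
    variables: list[str],
    threshold: float = 0.8,
) -> CorrelationScreenResult:
    """Greedy removal of collinear variables by Spearman rank correlation.

    Pairs are scanned in descending |ρ| (pairwise-complete observations);
    while the strongest pair exceeds the threshold, the member with the
    larger mean |ρ| to all other survivors is dropped (ties break
    alphabetically, keeping the alphabetically first).  All-constant
    variables have undefined ρ and are treated as uncorrelated but
    reported.
    """
    if len(variables) < 2:
        raise ValueError("collinearity screening needs at least two variables")
    sub = table[list(variables)]
    corr = sub.corr(method="spearman", min_periods=3)
    constant = sorted(v for v in variables if sub[v].dropna().nunique() <= 1)
    corr = corr.fillna(0.0)

    kept = sorted(variables)
    dropped: list[tuple[str, str, float]] = []
    while True:
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                r = abs(float(corr.loc[a, b]))
                if best is None or r > best[0]:
                    best = (r, a, b)
        if best is None or best[0] <= threshold:
            break
        _, a, b = best
        others = [v for v in kept if v not in (a, b)]
        mean_a = np.mean([abs(float(corr.loc[a, o])) for o in others]) if others else 0.0
        mean_b = np.mean([abs(float(corr.loc[b, o])) for o in others]) if others else 0.0
        # drop the more globally redundant member; on a tie keep the
        # alphabetically first (a < b by construction)
        victim, partner = (a, b) if mean_a > mean_b else (b, a)
        kept.remove(victim)
        dropped.append((victim, partner, float(corr.loc[a, b])))
    return CorrelationScreenResult(kept, dropped, constant)


# ---------------------------------------------------------------------------
# Importance ranking and partial dependence


def importance_rank(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    n_trees: int = 300,
    seed: int = 0,
    min_rows: int = 30,
) -> ImportanceRanking:
    """Rank candidate stressors by permutation importance for one metric.

    Fits a random-forest regressor on rows where the response is observed
    (missing predictor values are median-imputed — forests tolerate this
    coarse imputation well) and computes permutation importances on the
    training data.  The ``selected`` subset is the top quarter of the
    hierarchy, ``ceil(p / 4)`` predictors.  Deterministic for a fixed seed.
    """
    rows = table.loc[table[response].notna(), [response, *predictors]]
    if len(rows) < min_rows:
        raise ValueError(
            f"only {len(rows)} rows with observed {response!r}; need ≥ {min_rows}"
        )
    y = rows[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"response {response!r} is constant")
    medians = rows[predictors].median()
    X = rows[predictors].fillna(medians)

    model = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, min_samples_leaf=5, n_jobs=1
    )
    model.fit(X, y)
    imp = permutation_importance(model, X, y, n_repeats=10, random_state=seed, n_jobs=1)
    scores = dict(zip(predictors, imp.importances_mean))
    ranking = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    n_sel = math.ceil(len(predictors) / 4)
    selected = [name for name, _ in ranking[:n_sel]]
    q75, q25 = np.percentile(y, [75, 25])
    return ImportanceRanking(
        response, ranking, selected, float(q75 - q25), model, X, medians
    )


def partial_dependence(
    ranking: ImportanceRanking, predictor: str, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Partial-dependence curve of the fitted model along one predictor.

    Returns ``(curve, extrapolated)``: the mean prediction over the training
    data with the predictor clamped to each grid value, and a boolean flag
    per grid point marking values outside the observed predictor range
    (those are extrapolations and a warning is emitted).
    """
    if ranking.model is None or ranking.train_X is None:
        raise ValueError("ranking does not carry a fitted model")
    grid = np.asarray(grid, dtype=float)
    observed = ranking.train_X[predictor]
    extrapolated = (grid < observed.min()) | (grid > observed.max())
    if extrapolated.any():
        warnings.warn(
            f"{int(extrapolated.sum())} grid values outside the observed range of "
            f"{predictor!r}; partial dependence there is extrapolated",
            stacklevel=2,
        )
    curve = np.empty_like(grid)
    X = ranking.train_X.copy()
    for i, g in enumerate(grid):
        X[predictor] = g
        curve[i] = float(ranking.model.predict(X).mean())
    return curve, extrapolated


# ---------------------------------------------------------------------------
# Break-point detection by recursive partitioning


def _max_t_statistics(
    y_sorted: np.ndarray, split_idx: np.ndarray
) -> np.ndarray:
    """|Welch t| at each candidate split of a response ordered by the predictor.

    ``y_sorted`` may be 2-D (permutations in rows); returns the statistic
    per row and candidate split, shape ``(rows, len(split_idx))``.
    """
    y2 = np.atleast_2d(y_sorted)
    n = y2.shape[1]
    cs = np.cumsum(y2, axis=1)
    cs2 = np.cumsum(y2 * y2, axis=1)
    n1 = split_idx.astype(float)
    n2 = n - n1
    s1 = cs[:, split_idx - 1]
    s2 = cs[:, -1][:, None] - s1
    q1 = cs2[:, split_idx - 1]
    q2 = cs2[:, -1][:, None] - q1
    m1, m2 = s1 / n1, s2 / n2
    v1 = np.maximum(q1 - s1 * m1, 0.0) / np.maximum(n1 - 1, 1)
    v2 = np.maximum(q2 - s2 * m2, 0.0) / np.maximum(n2 - 1, 1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m2) / se
    t[~np.isfinite(t)] = 0.0
    return t


def _segment_split(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_perm: int,
    min_leaf: int,
    rng: np.random.Generator,
    max_candidates: int = 50,
) -> tuple[float, float, float] | None:
    """Best permutation-tested split of one segment.

    Candidate cut points sit between distinct sorted predictor values, at
    least ``min_leaf`` observations from either end (capped at
    ``max_candidates`` evenly spaced candidates).  The test statistic is
    the maximum absolute studentized mean difference over the candidates;
    its null distribution comes from permuting the response.  Returns
    ``(split value, p-value, jump)`` or None if no candidate exists.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    if n < 2 * min_leaf:
        return None
    candidates = np.arange(min_leaf, n - min_leaf + 1)
    candidates = candidates[xs[candidates] > xs[candidates - 1]]
    if len(candidates) == 0:
        return None
    if len(candidates) > max_candidates:
        pick = np.linspace(0, len(candidates) - 1, max_candidates).round().astype(int)
        candidates = candidates[np.unique(pick)]

    t_obs_all = _max_t_statistics(ys, candidates)[0]
    best = int(np.argmax(t_obs_all))
    t_obs = float(t_obs_all[best])
    i = candidates[best]
    split_value = float((xs[i - 1] + xs[i]) / 2.0)
    jump = float(abs(ys[i:].mean() - ys[:i].mean()))

    perm = rng.permuted(np.tile(ys, (n_perm, 1)), axis=1)
    t_null = _max_t_statistics(perm, candidates).max(axis=1)
    p = float((1 + np.sum(t_null >= t_obs)) / (n_perm + 1))
    return split_value, p, jump


def detect_breakpoints(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    alpha: float = 0.05,
    max_states: int = 3,
    n_perm: int = 9999,
    seed: int = 0,
    min_leaf: int = 15,
    min_rows: int = 30,
) -> BreakPointSet:
    """Locate break points of a metric along a stressor gradient.

    Recursive binary partitioning on the single predictor: at each step the
    split maximizing the studentized two-sample mean difference is tested by
    a permutation test (9,999 permutations by default) and accepted if
    ``p < alpha``; splitting proceeds best-first and stops at
    ``max_states`` leaves (default 3, i.e., at most two break points) or
    when no segment splits significantly.  A response with no significant
    structure yields an empty break set — the variable is then unusable for
    state definition and the caller decides what to do.
    """
    rows = table[[response, predictor]].dropna()
    if len(rows) < min_rows:
        raise ValueError(f"only {len(rows)} complete pairs; need ≥ {min_rows}")
    x = rows[predictor].to_numpy(dtype=float)
    y = rows[response].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    segments: list[tuple[np.ndarray, np.ndarray]] = [(x, y)]
    accepted: list[tuple[float, float, float]] = []  # (split, p, jump)
    while len(segments) < max_states:
        tested = []
        for idx, (sx, sy) in enumerate(segments):
            if np.ptp(sy) == 0:
                continue
            res = _segment_split(sx, sy, alpha, n_perm, min_leaf, rng)
            if res is not None and res[1] < alpha:
                tested.append((res[1], idx, res))
        if not tested:
            break
        tested.sort(key=lambda t: t[0])
        _, idx, (split, p, jump) = tested[0]
        sx, sy = segments.pop(idx)
        left = sx < split
        segments.append((sx[left], sy[left]))
        segments.append((sx[~left], sy[~left]))
        accepted.append((split, p, jump))

    accepted.sort(key=lambda t: t[0])
    return BreakPointSet(
        predictor,
        [a[0] for a in accepted],
        [a[2] for a in accepted],
        [a[1] for a in accepted],
    )


# ---------------------------------------------------------------------------
# Relationship selection


def select_relationships(
    rankings: dict[str, ImportanceRanking],
    breaksets: dict[tuple[str, str], BreakPointSet],
    min_sharpness_frac: float = 0.25,
) -> list[tuple[str, str]]:
    """Candidate stressor → metric edges from the conjunction rule.

    An edge enters iff the stressor sits in the metric's top importance
    quartile AND its break set is non-empty AND the sharpest break jumps by
    at least ``min_sharpness_frac`` of the response's interquartile range
    (default 25%).  ``breaksets`` is keyed by ``(metric, stressor)``.
    """
    edges: list[tuple[str, str]] = []
    for metric, ranking in sorted(rankings.items()):
        floor = min_sharpness_frac * ranking.response_iqr
        for stressor in ranking.selected:
            bset = breaksets.get((metric, stressor))
            if bset is None or not bset.breaks:
                continue
            if max(bset.sharpness) >= floor:
                edges.append((stressor, metric))
    return sorted(edges)


def discover_structure(
    table: pd.DataFrame,
    metrics: list[str],
    stressors: list[str],
    collinearity_threshold: float = 0.8,
    alpha: float = 0.05,
    n_trees: int = 300,
    n_perm: int = 999,
    min_sharpness_frac: float = 0.25,
    seed: int = 0,
) -> dict:
    """Full structure pipeline: screen → rank → break points → edges.

    Break points are only computed for top-quartile (metric, stressor)
    pairs, as only those can become edges.  Returns a dict with the screen
    result, per-metric rankings, per-pair break sets, and the selected edge
    list; identical seed and data give an identical edge list.
    """
    screen = collinearity_screen(table, stressors, collinearity_threshold)
    rankings: dict[str, ImportanceRanking] = {}
    breaksets: dict[tuple[str, str], BreakPointSet] = {}
    for metric in metrics:
        ranking = importance_rank(table, metric, screen.kept, n_trees=n_trees, seed=seed)
        rankings[metric] = ranking
        for stressor in ranking.selected:
            breaksets[(metric, stressor)] = detect_breakpoints(
                table, metric, stressor, alpha=alpha, n_perm=n_perm, seed=seed
            )
    edges = select_relationships(rankings, breaksets, min_sharpness_frac)
    return {
        "screen": screen,
        "rankings": rankings,
        "breaksets": breaksets,
        "edges": edges,
    }
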