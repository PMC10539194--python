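# Methods

`streamdiag` implements a diagnostic workflow for running waters: from a
site-by-variable monitoring table it derives a discrete Bayesian belief
network (BBN) that links candidate degradation causes (stressors) to
biological metrics, and then uses that network to rank probable causes for
a site from the observed metric states alone. This note records the model,
the tunable parameters, the numerical choices, and what the synthetic test
bed does and does not demonstrate.

## Model

The network is a DAG over discrete nodes with two or three ordered states
each. Stressor nodes (land-use shares, 1–7 hydromorphology assessment
classes, fine-sediment cover, latent warming/nutrient causes) are parents;
biological metrics (% EPT taxa, German Fauna Index, KLIWA Index, Trophic
Diatom Index, habitat- and feeding-type shares, …) are children. The joint
distribution factorizes into one conditional probability table (CPT) per
node:

    P(X_1, …, X_n) = ∏_i P(X_i | pa(X_i))

Diagnosis is Bayesian inversion: metric states entered as evidence
propagate back to the stressor posteriors. For each stressor C the change
against the no-evidence baseline is summarized by the total variation
distance

    Δ(C) = ½ · Σ_s | P(C = s | e) − P(C = s) |

and stressors are ranked by descending Δ (ties alphabetical, so output is
deterministic). TV was chosen because it is symmetric, bounded in [0, 1],
and collapses to |Δp(degraded)| for two-state causes; the signed change of
the declared degraded state is reported alongside for interpretability.
Ranking by the degraded-state change only is available from the same
result object.

### Inference

Inference is exact variable elimination, run once per query node.
Networks in this domain are small (~20–25 nodes, ≤3 states, shallow
bipartite-ish structure), so exactness costs little and removes an entire
class of approximation-tuning questions. Probabilities stay in linear
space (no log-space accumulation is needed at this scale); the final
factor is normalized once. Evidence with probability zero raises an
explicit error instead of emitting NaNs — silent division by zero is the
classic failure mode of belief-network code, and callers are forced to
handle it.

### Diagnostic value of information

The diagnostic value of a metric M for a cause C is an entropy-reduction
score in [0, 1]. For every cause state s we form the binary event
B = 1{C = s}, take the exact pair joint P(C, M) from the network, and
compute the normalized mutual information I(B; M) / H(B); the score is the
mean over states, with degenerate events (H(B) = 0) contributing 0. This
state-averaged form honors the averaged-over-all-states reading of entropy
reduction while keeping the [0, 1] range; plain normalized mutual
information I(C; M) / H(C) is available as `variant="global"`. Entropy is
measured in bits; the normalization cancels the base. The score is 0
exactly under independence and 1 when the metric determines the cause.

## Structure pipeline

1. **Collinearity screen.** Spearman rank correlations on
   pairwise-complete observations; while any kept pair exceeds the
   threshold (default |ρ| > 0.8) the member with the larger mean |ρ| to
   the other survivors is dropped (tie → keep the alphabetically first).
   All-constant variables have undefined ρ, are treated as uncorrelated,
   and are reported.
2. **Importance ranking.** A random-forest regressor per metric
   (complete-case on the response, median imputation of missing
   predictors, `min_samples_leaf=5`, default 300 trees) with permutation
   importance (10 repeats). The top quarter of the hierarchy — `ceil(p/4)`
   predictors — is retained; ceil was chosen so small predictor sets keep
   at least one candidate.
3. **Break points.** Recursive binary partitioning of the response along a
   single predictor. At each segment the candidate split maximizing the
   absolute studentized (Welch) mean difference is tested by a permutation
   test (default 9,999 permutations, vectorized over cumulative sums;
   candidate cuts sit between distinct predictor values, ≥15 observations
   per side, capped at 50 evenly spaced candidates). Splits are accepted
   best-first at p < α (default 0.05) until three leaves exist — never
   more, so no node gets more than three states. Sharpness of a break is
   the jump in mean response across it.
4. **Edge rule.** A stressor→metric edge is kept iff the stressor is in
   the metric's top importance quartile AND has a non-empty break set AND
   its sharpest break jumps by at least 25% of the response's
   interquartile range. The sharpness floor replaces visual inspection of
   partial-dependence plots, which is viewer-biased; 25% of the IQR is a
   deliberately conservative default for "a shift from low to high
   values" that a practitioner would accept by eye.

α, the permutation count, and the sharpness floor are package defaults,
exposed in `RunConfig`.

## CPT learning

CPT rows are conditional state frequencies with symmetric Dirichlet
smoothing, default α₀ = 1:

    P(child = j | combo) = (n_{combo,j} + α₀) / (n_combo + α₀·k)

Counting is complete-case per child–parent family (a site contributes only
where the child and all its parents are observed); EM over missing values
is deliberately out of scope. Parent combinations with zero support fall
back to the child's smoothed marginal — closer to how a practitioner reads
the overall data distribution than a flat uniform — and are flagged in
`net.meta["zero_support_rows"]` so they can be reviewed or overridden.
Expert knowledge enters as declarative override files (child, parent
combination, probability vector, provenance note), never as code, so the
iterative expert-feedback loop stays reproducible and diffable.

## Validation

- **Cross-validation** (default k = 3): sites are randomly partitioned,
  CPTs are fitted on k−1 folds, and each held-out site's node states are
  predicted as the modal posterior given the site's other observed states.
  By default every other observed node serves as evidence (the strongest
  reading of observed-vs-predicted alignment); `evidence_mode=
  "metrics_only"` restricts evidence to biological metrics, the situation
  an actual field diagnosis faces. Both modes are first-class because the
  choice genuinely changes per-node accuracy for stressor nodes.
- **Expert feedback** is scored as correct / (correct + incorrect);
  overestimated, underestimated, and no-feedback entries are tallied but
  excluded from the denominator. An empty denominator raises an explicit
  undefined-accuracy error.
- **Assessment vs. diagnostic metrics**: the diagnosis runs twice
  (assessment-metric evidence only, then all evidence) and each stressor's
  degraded-state probability change is classified: |Δ| < 10 percentage
  points → `no_change`; |Δ| exceeding half the assessment-only probability
  → `overestimated`/`underestimated` by sign; otherwise
  `correctly_diagnosed_candidate`, because deciding whether a changed
  hierarchy moved *closer to the truth* requires expert labels, which the
  API consumes as a separate feedback table rather than guessing. The 10%
  rule is read as percentage points, since the quantities compared are
  probabilities on a common scale.

## Synthetic test bed

The generator emulates what state-agency monitoring tables look like
statistically: stressor gradients on native scales (uniform percentages,
continuous 1–7 class means, log-normal concentrations, latent
present/absent causes), inter-stressor rank correlation via a Gaussian
copula (target Spearman ρ converted by r = 2·sin(πρ/6); infeasible targets
are rejected with the nearest feasible matrix suggested), metric responses
that are step-shaped (the threshold form the break-point detector
assumes), linear, gated by a latent cause, or null, plus
missing-completely-at-random gaps. Ground truth (latent states, true break
points, the generating network) is returned with every draw; the
generating network's CPTs are tabulated by a 40,000-site Monte Carlo draw
from the same generative model, which converges to the exact conditional
distributions at far below the testing tolerances. For parameter-recovery
studies where generating CPTs must be exact, `sample_states` forward-samples
from an explicitly specified network instead.

Bundled scenarios mirror the three stream-type groups' variable rosters
and printed native ranges (e.g., agriculture 0–73.8% of catchment for
streams of the low mountain ranges; KLIWA Index 3.6–25.0), with one-break
state schemes and effect sizes of four noise standard deviations — strong
but realistic threshold responses. The `deterministic_threshold` scenario
reproduces the two-state cause-present/cause-absent construction used for
warming and nutrients: the index metric deterministically separates the
two cause states, so three-fold cross-validation must score 100% for that
cause node, which the acceptance script verifies end to end (n = 300
sites). The `recovery` scenario (3 stressors, 5 single-parent metrics,
n = 500) exercises the whole discover→fit→diagnose chain; with
`ceil(3/4) = 1` stressor selected per metric, recovering ≥90% of true
edges requires the importance ranking, the break-point detector, and the
sharpness rule to all work at once.

What passing these tests does *not* show: real monitoring data have
non-threshold dose–response shapes, informative missingness (chemical
parameters are observed at far fewer sites than hydromorphology),
spatially autocorrelated sites, and multi-parent interactions that the
additive step responses only approximate. Accuracy figures on synthetic
scenarios therefore bound mechanism correctness, not field performance.

## Numerical choices and degenerate inputs

- Interval states are left-closed right-open `[lower, upper)`, topmost
  interval right-closed: discretization at a break point is deterministic,
  and the range maximum belongs to the top state.
- Probability vectors must sum to 1 within 1e-9; posterior checks use the
  same tolerance.
- Ranking ties (equal TV change, equal importance) break alphabetically.
- Degenerate priors contribute 0 to the diagnostic-value average, not NaN.
- Modal-state prediction ties resolve to the first state in declared
  order.
- Problem sizes used in the shipped studies: 200 random networks (≤12
  nodes) for the inference oracle with evidence subsets exhaustive at
  sizes 0–1 and sampled (12 each) at sizes 2–3; 50 replicates for
  break-point recovery and false-positive rate; 20 seeds for CPT and
  structure recovery. These sizes give stable medians while keeping the
  default suite quick to run.

## Known limitations

- No structure learning by search-and-score, no continuous or hybrid
  nodes, no temporal dynamics — out of scope by design.
- The conditional-inference partitioning is single-predictor only (no
  multivariable or surrogate splits): that is all the break-point
  alignment task requires.
- The three published group networks are shipped only as a node catalog
  plus qualitative edge notes; the full published edge lists and CPTs are
  not available in machine-readable form, and reconstructed structure is
  never presented as the authors'. Group placements that are
  typographically ambiguous in the published stressor table are marked
  `unconfirmed` in the catalog rather than guessed.
- XMLBIF export carries roles, interval bounds, and degraded-state markers
  in PROPERTY strings; other tools will read states and CPTs but ignore
  those annotations.
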