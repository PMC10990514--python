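# Methods

This note records the statistical and algorithmic choices behind
`alert-tuner`: what each stage assumes, the defaults and why, what the
simulator does and does not emulate, and the numerical conventions for
degenerate inputs.

## Data model and preprocessing

An alert log is a table with one row per firing: `bpa_id`, `fired_at`
(ISO-8601), `action` (free text), and arbitrary feature columns (strings →
categorical, numeric dtype → numeric; missing values are empty cells).

**Outcome derivation.** The action labels
"Acknowledge/override Warning", "Cancel Warning", "No Action Taken",
"Accept BPA (No Action Taken)" and "Cancel BPA" map to *not accepted*
(y = 1, the positive class throughout); every other label maps to
*accepted*. Labels outside the known accepted set ("single order",
"remove order set") still map to accepted but raise a log warning, because
a production log drifts and silent misclassification of a new button would
bias every downstream count.

**Alert-level filtering.** A BPA is retained only if it has more than 100
firings *and* more than 10 acceptances (strict inequalities; the boundary
cases 100 firings or 10 acceptances are excluded). Below these counts the
2×2 screening statistics are too unstable to be worth reviewing.

**Encoding.** Numeric features are imputed and then cut into 10 equal-width
bins spanning the training range: value *v* maps to bin
`⌊n·(v−min)/(max−min)⌋`, clamped so the maximum (and any out-of-range value
at transform time) lands in a terminal bin; the last bin is right-closed. A
constant column degenerates to a single bin. Imputation happens *before*
binning so bin edges are always defined; the default statistic is the
median (mean and most-frequent are available) — with skewed lab values and
utilisation counts the median is the conventional robust choice.
Categoricals are one-hot encoded over the training vocabulary; a category
unseen at transform time encodes as all zeros for its feature rather than
an error. The whole encoding recipe (edges, imputation values,
vocabularies) is a `FeatureSchema` fitted on the training split only —
never on evaluation rows — and serialised to JSON so a transform is
bit-reproducible. Bins, like imputation values, are therefore per-split
quantities.

Every design-matrix column name decodes back to a (feature, value-or-bin)
predicate; rules and suggestions are expressed in that predicate algebra,
so anything the miners emit is directly readable as an exclusion criterion.

## The simulator

The generator emulates the study conditions the pipeline is meant for:

- 5 BPAs × 10 000 firings each (defaults; both configurable),
- per-BPA base acceptance drawn from Beta(6, 44) — mean 0.12, matching the
  ~12% overall acceptance typical of production alert systems — or pinned
  to a fixed value,
- 5 categorical features (cardinality 8) and 3 numeric features
  (normal, μ = 50, σ = 15) drawn independently per firing, numerics with 5%
  missingness,
- planted rules: feature-defined subgroups with low acceptance (default
  scenario: three single-predicate categorical subgroups with coverages
  0.10 / 0.05 / 0.15 and subgroup acceptance 0.01).

Coverage is achieved construction-first rather than by rejection: a planted
predicate's marginal probability is set to `coverage^(1/k)` for a k-predicate
rule, so that under feature independence the joint coverage equals the
target. A firing covered by several planted rules uses the *minimum*
subgroup acceptance. Accepted firings receive an accepting action label;
others one of the five overriding labels, so outcome derivation is
exercised end to end. All randomness flows through one numpy PCG64
generator; the same config and seed reproduce the log byte for byte.

What the simulator does **not** emulate: correlated features, temporal
autocorrelation or seasonality of firings, label noise in the action
mapping, and realistic clinical feature distributions. Passing the
planted-rule recovery test therefore demonstrates that the machinery finds
feature-defined low-acceptance subgroups under clean conditions; it does
not certify performance on real EHR logs, where correlated features can
make several syntactically different rules cover near-identical firing
sets.

**Recovery scoring.** A selected rule matches a planted rule when their
covered firing sets have Jaccard overlap ≥ 0.9. Precision is the fraction
of selected rules that match some planted rule (null when nothing was
selected); recall the fraction of planted rules matched.

## Classifier

One global model predicts non-acceptance across all BPAs, with the BPA
identity one-hot among the features (the alternative — one model per BPA —
is available by filtering the log first). Four families are supported:
gradient-boosted trees (LightGBM, the default), random forest, a small
feed-forward network, and an SVM with probability outputs. Hyperparameters
are chosen by seeded random search (default budget 8 configurations) over
compact grids, scored by AUC on an inner stratified validation split, then
refitted on the full training data. LightGBM runs single-threaded,
row-wise and deterministic so that a seed fully reproduces the model.

The train/test split is stratified 80/20 by outcome with a fixed seed; a
temporal split (first 80% of firings by timestamp) is available since logs
are time-stamped and deployment is always forward in time. Evaluation
reports sensitivity, precision, F1 and accuracy at a 0.5 probability
cutoff plus AUC, each with a 95% percentile-bootstrap interval over rows
(default 1000 replicates). The 0.5 cutoff and the bootstrap are
conventions, not claims: nothing downstream consumes the cutoff except the
anchor search.

## Rule extraction

All three explainers emit conjunctions of positive predicates
(`feature = value` or `feature ∈ bin`), scoped to one BPA.

**Ensemble path mining** grows bagged depth-≤3 decision trees on bootstrap
samples of a BPA's training rows and enumerates root-to-leaf paths whose
leaf majority is non-acceptance. A path survives only if, on the tree's
out-of-bag rows, its precision is ≥ 0.95 with coverage ≥ 0.01. Surviving
paths are then *generalised*: predicates are greedily pruned while the
shortened rule still clears both out-of-bag thresholds. This mirrors the
minimality principle of anchors and matters in practice — a tree will
happily refine `dept = X` into `dept = X AND unit = u2` on noise, and the
refined rule would otherwise survive screening as a redundant shard of the
true subgroup. A final simplification pass drops predicates that leave the
covered set unchanged (this pass, unlike generalisation, provably never
changes what the rule covers). One-hot paths contain negated conditions
(column = 0); negations on two-valued features are rewritten to the
complementary positive predicate, and rules still containing negations are
discarded, since a deployable exclusion criterion is a positive
conjunction. Stored precision/coverage are recomputed on all training rows
of the BPA.

**Boosted rule set** is discrete AdaBoost with depth-1 tree stumps as weak
learners (depth 2 available): each round fits a stump under the current
sample weights, emits its non-accepted leaves as rules carrying the round
weight α = ½·log((1−ε)/ε), and re-weights rows by exponential loss.
Boosting stops at the round budget (default 10), on a perfect weak learner,
or when a round is no better than chance (an empty first round yields an
empty rule set with a warning). Depth-1 stumps emit single-predicate rules
— the shape the screens and suggestion templates are designed around —
while re-weighting lets later rounds surface subgroups masked by earlier
ones.

**Anchors** explain individual firings the global model predicts as not
accepted (a seeded sample of up to 10 per BPA). A candidate anchor is a
subset of the instance's own (feature, value/bin) predicates; its precision
is the fraction of perturbed samples — anchored features fixed, all others
resampled independently from the BPA's empirical marginals — that the model
still labels not accepted. Beam search (width 3) returns the smallest
anchor with estimated precision ≥ 0.95, ties broken by larger coverage and
then lexicographically. Precision is estimated by plain Monte-Carlo with a
fixed 500 samples per candidate rather than an adaptive bandit scheme: at
these problem sizes the fixed-budget estimate is cheap and the screening
stage re-validates every rule on exact counts anyway. If the empty anchor
already clears the threshold (the model predicts non-acceptance regardless
of features — common when the base acceptance rate is low), the instance
yields no rule; this is reported, not hidden, because it says the local
explanation degenerates to the base rate. Perturbation uses independent
marginals; no joint feature model is attempted.

**Merging.** Rule sets are unioned with two deduplication passes:
syntactic (identical canonical predicate sets within a scope collapse, with
provenance concatenated) and semantic (rules covering exactly the same
firings on the full log collapse to the shortest, then lexicographically
first).

## Screening metrics

Each candidate is evaluated on the full filtered log of its BPA via the
2×2 table (a = covered ∧ not accepted, b = covered ∧ accepted, c/d the
uncovered counterparts, N = a+b+c+d):

| metric | formula | threshold |
|---|---|---|
| odds ratio | ad / bc | > 1.25 |
| prob. of low acceptance | I_θ(1+b, 1+a), θ = 0.02 | > 0.5 |
| decrease rate | (a+b)/N | < 0.4 |
| confidence | a/(a+b) | > 0.98 |
| interest (lift) | [a/(a+b)] / [(a+c)/N] | > 1 |
| conviction | (a+b)(b+d) / (N·b) | > 1.2 |
| Pearson χ² | 2×2 test, no continuity correction | p < 0.01 |

All inequalities are strict, and selection is the intersection of all
seven. Conventions for degenerate tables: when any cell is zero the odds
ratio uses the Haldane–Anscombe +0.5 adjustment on every cell; b = 0 gives
confidence exactly 1 and conviction +∞ (which passes its screen); a table
with an all-zero row or column has χ² p = 1; a rule covering nothing
(a+b = 0) is an error at the metric level and is silently skipped by the
batch screeners. Interest is read as the lift of non-acceptance — rule
confidence over the marginal non-acceptance rate — consistent with its
threshold of 1. The χ² test is Pearson's without Yates correction (a flag
enables it). The posterior probability of low acceptance treats the
covered firings as a binomial sample with a uniform prior on the
acceptance rate, so the posterior is Beta(1+b, 1+a); θ = 0.02 ("would fewer
than 2% accept?") is the default decision threshold and is deliberately
prominent in the config, as it is a policy choice, not an estimate.

No multiple-testing adjustment is applied across rules: the raw p < 0.01
sits inside an intersection of seven simultaneous screens, which is already
far more conservative than any single test. The caveat stands that the
selected set's error rates are not calibrated in the FDR sense; the
suggestions are review candidates, not automatic changes.

## Suggestions and impact

Selected rules render as `Do not fire when: <feature> = <value> [AND …]`;
bin predicates render as `feature in [lo, hi)` (closed on the right for the
terminal bin). Applying suggestions removes the union of covered firings
per BPA (each firing counted once). The impact report gives, per BPA:
original and predicted firing counts and acceptance rates, firings
eliminated (count and %), and the relative acceptance-rate change
(AR_pred − AR_orig)/AR_orig — reported twice, once from raw rates and once
from rates rounded to two decimals, because published report tables use the
rounded convention and the two can differ noticeably when acceptances are
concentrated outside the removed subgroup. Dataset-level averages are
unweighted means over the BPAs that carry suggestions. Percentages are
rounded to one decimal in tables; raw values stay in the JSON artifacts.

The temporal holdout check re-matches each suggestion against a later
firing window: `bpa_retired` (the BPA no longer fires), `likely_implemented`
(it fires, but never in the suggested scenario), or `still_firing` with the
match count.

## Reproducibility and problem sizes

Every stochastic stage draws its seed from one pipeline seed through
numpy's `SeedSequence`, and the CLI refuses configs without a seed. Two
identical seeded runs produce byte-identical `suggestions.json`.

The test suite exercises the full pipeline at 5 BPAs × 10 000 firings
(the simulator's default scenario, ~15 s single-threaded) and the
statistical oracles at 1000 random contingency tables and 10⁵ Monte-Carlo
posterior draws; these sizes were chosen as the smallest at which the
binomial noise floors sit comfortably below the effects being tested.

## Known limitations

- Rules are conjunctions of positive predicates; irreducibly negative
  criteria ("any department except X") on features with more than two
  values are out of reach by design.
- The anchor stage degenerates (correctly, but unhelpfully) when the
  classifier predicts non-acceptance everywhere; in low-acceptance regimes
  the global miners carry the discovery.
- Feature independence in the simulator flatters semantic deduplication;
  real logs with correlated features will surface families of
  near-duplicate rules that reviewers must reconcile.
- Selection is per-rule; there is no joint optimisation of a suggestion
  *set* (overlapping rules are only reconciled at impact-accounting time).
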