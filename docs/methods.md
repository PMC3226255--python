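# Methods

This note documents the statistical model behind `fuzzpat`, the
parameters that matter, the synthetic benchmark generator, and the
numerical and design choices made where the design was genuinely open.

## Interdependence redundancy

All similarity between attributes is the normalized interdependence
redundancy `R(G_i : G_j) = I(G_i : G_j) / H(G_i : G_j)`: plug-in mutual
information divided by plug-in joint entropy of the pair's contingency
table, in bits (the ratio is base-invariant). Properties used
throughout: `0 ≤ I ≤ H` hence `R ∈ [0, 1]`; symmetry (same table both
ways); `R = 1` iff the two attributes determine each other;
normalization by H makes pairs with different state counts comparable.
Constant attributes get `R = 0` against everything, including
themselves — they carry no information and can never become modes.  A
pair of constant attributes has `H = 0` and `R` is defined as 0.

**Binning.** Continuous attributes enter the contingency table through
equal-frequency (quantile) bins, computed once per attribute and cached;
ties go to the lower bin, and duplicated quantiles collapse bins (a
constant vector occupies a single bin). Equal-frequency bins are the
maximum-entropy choice and spread the `α`-points-per-cell budget most
evenly.

**Bin count.** `m = max(2, ⌊ln(|T|/α)⌋)` with `α` the minimum points
per cell (default 3, "2 or 3" being the usual rule of thumb). The
logarithmic growth is deliberate and is the load-bearing choice of this
module. In mixed-mode data R must rank categorical–categorical,
categorical–continuous and continuous–continuous pairs on one scale,
and the joint entropy in R's denominator grows like `log₂ m` for a
binned attribute. Any rule that lets m grow as a power of |T| (for
example `⌊√(|T|/α)⌋`, which gives m = 24 at |T| = 1800) caps a
binary-vs-continuous pair at `R ≤ 1/log₂ m` regardless of how
deterministic the relationship is, systematically starves every
cluster anchored on a low-cardinality attribute, and in our experiments
distorts model selection itself (the k-modes objective splits
genuinely coherent clusters). Logarithmic growth keeps binned
cardinalities commensurate with typical categorical alphabets (2–3
symbols) and with the 3-state expression model used downstream, while
still refining with sample size: 6 bins at |T| = 1800, 3 bins at the
~60-sample scale of classic expression studies — matching the interval
count one would pick there by hand.

**Open choice.** Binning is global per attribute, not per pair:
deterministic, cache-friendly, and it keeps the full R matrix a single
reusable artifact.

## Attribute clustering (MACA)

k-modes over the R matrix. Assignment sends each attribute to the
cluster whose mode it is most redundant with; update re-elects each
cluster's mode as the member with maximal
`MR(G_i) = Σ_{j ∈ cluster, j≠i} R(G_i : G_j)`. Model selection
maximizes `SR = Σ_clusters MR(mode)` over `k ∈ [k_min, k_max]`
(defaults 2 and `min(N−1, 10)`) with `restarts` (default 10) seeded
random initializations per k.

Numerical choices: assignment ties go to the lowest cluster index and
mode ties to the lowest attribute index (full determinism given the
seed); SR comparisons use a 1e-12 tolerance with ties resolved toward
smaller k (parsimony); iteration stops on a stable assignment or after
`max_iter = 100`; each run returns its best-SR iterate, so the returned
SR dominates every intermediate one; an emptied cluster is repaired by
re-seeding its mode with the attribute least similar to every current
mode. SR sums the modes' MR only (not all members'): the objective
scores how well each representative summarizes its group, and summing
all members would simply reward large clusters.

## Fuzzification

`μ_r(G_i) = R(G_i : G^r)^{1/(f−1)} / Σ_c R(G_i : G^c)^{1/(f−1)}`, the
fuzzy-c-means membership form with similarity in place of inverse
distance. Two anchors pin the exponent: at `f = 2` it is 1, i.e. plain
linear normalization of the redundancies; as `f → 1⁺` the row sharpens
to the indicator of the best mode. `f → ∞` flattens rows toward `1/k`.
Rows always sum to one; an all-zero similarity row (only possible for a
constant attribute) falls back to uniform `1/k` to avoid 0/0. Default
`f = 1.5` (exponent 2), sharp enough that crisp members dominate while
genuinely coupled outsiders retain workable membership. Memberships do
not feed back into mode selection — fuzzification decorates a fixed
crisp clustering; there is no iterative fuzzy re-clustering.

## Mode-driven discretization

Cluster r's working attribute set is `{i : μ_r(G_i) ≥ τ}` (threshold
gating; the weights are kept for reporting). Default `τ = 0.003`:
small enough to admit cross-cluster memberships of a few tenths of a
percent — the regime where genuinely overlapping genes live under
`f = 1.5` — while excluding the 1e-5-and-below noise floor.  A τ that
would exclude a cluster's own mode is a configuration error.

The mode, if continuous, is cut into 3 equal-frequency intervals
labelled L/N/H (maximum-entropy partition; cut-points sit strictly
between distinct-value blocks so tied values fall in the lower
interval); a categorical mode keeps its symbols. The mode is never
re-discretized within its own cluster.

Every other continuous member is discretized by **OCDD** against the
mode's states: candidate boundaries are midpoints between consecutive
distinct values; for each interval count `q ∈ 2..max_intervals`
(default 3, mirroring the 3-state mode) the boundary set maximizing
`R(discretized values : mode states)` is found by exhaustive search —
vectorized single-cut scan at q = 2, scan-over-first-cut at q = 3,
batched combination evaluation beyond — and the globally best R wins,
ties toward fewer intervals (1e-12 tolerance). When an attribute has
very many distinct values the candidate list is thinned to
`max_candidates` (default 256) evenly spaced midpoints; the search is
exact whenever the distinct-value count is small, which is the regime
the brute-force conformance test exercises. Fewer than two distinct
values yield a single-interval passthrough. Because more intervals only
enlarge the searched space, the optimal R is non-decreasing in
`max_intervals` up to the tie rule.

## Pattern discovery

Within each cluster event table, candidates grow level-wise over event
combinations from distinct attributes (each combination generated
once, in attribute order). A candidate with events of marginal
probabilities `p₁..p_o` is scored only when its independence
expectation `e = n·Πpᵢ` is at least `min_expected` (default 3, the
usual validity floor for the normal approximation) and retained when
`|d| ≥ d_threshold` with `d = (o − e)/√(e·Π(1 − pᵢ))` (default 1.96,
95% two-sided). This variance reduces the statistic exactly to the
classical adjusted residual of a two-way table at order 2, which is the
conformance property the tests pin against an independent
implementation. If some `pᵢ = 1` the variance vanishes and the
residual is reported as 0 with a degeneracy flag.

Growth is pruned below unobserved candidates (their extensions are all
unobserved by anti-monotonicity of support); the consequence is that
deeply nested *under*-represented associations beyond the first
unobserved level are not enumerated — negative patterns are retained
with their sign where scored, but are not mined for rules. No multiple-
testing correction is applied by default; `d_threshold` is the single
knob. `max_order` defaults to 4. Duplicate event sets rediscovered in
several fuzzy clusters (same events and interval cut-points equal
within 1e-9, implemented by rounding to 9 decimals) are collapsed,
keeping the largest-|d| instance and the union of source clusters.

## Rules and classification

Rule mining is pattern mining with the class attribute appended as one
more event: an antecedent is promoted to a rule for class c when the
joined association has `d ≥ d_threshold` (over-representation only).
Weight of evidence uses log base 2 and Laplace smoothing (+1 on matched
counts, +number-of-classes on conditioning totals), keeping weights
finite when an antecedent never occurs outside its class. Antecedents
down to order 1 are allowed (the class event makes the association
order ≥ 2); `rule_max_order` defaults to 3.

Classification sums, per class, the WofE of matched rules, visiting
higher-order rules first and skipping any rule whose antecedent is a
subset of an already-counted antecedent for that class (nested rules
restate the same evidence). Ties go to the larger prior; a sample
matching no rule falls back to the majority class, flagged. The
protocol is honest by construction: clustering, fuzzification and
discretization are pure functions of the unlabelled table, which the
test suite asserts by pipeline equality under label deletion and label
permutation.

## Synthetic benchmark generator

The generator emulates a mixed-mode expression table with known ground
truth: 20 attributes (A1, A2 ∈ {T, F}; A3–A5 ∈ {X, Y, Z}; A6–A20 ∈
[0, 1]) wired into three groups by drivers A1 (→ A7–A12 via half-range
coupling), A13 (→ A2, A3 by thresholds 0.2/0.4; → A14–A20 via
three-band coupling with breakpoints 0.3/0.6) and A6 (→ A4, A5 by
thresholds 0.3/0.6 and 0.2/0.4), with A6 itself range-coupled to A1 and
A13. Five classes are imposed through (A1, A13): T with A13 in [0, .2),
[.2, .4), [.4, .7); F with A13 in [.7, 1] or [0, .5) — a reconstruction
chosen so the classes are distinguishable by (A1, A6, A13) while every
conditional rule holds; it is config-overridable. Class sizes default
to (500, 300, 300, 400, 300) and noise to 25%: ⌊0.25·|T|⌋ tuples,
sampled without replacement, have *all attribute values* (not their
labels) replaced by uniform draws over each attribute's domain. Output
is byte-identical given the seed, and `validate_structure` re-checks
every conditional rule tuple by tuple.

What the generator does **not** emulate: real expression scale and
skew (values are uniform on [0, 1], not log-intensities), gene-gene
correlation beyond the three driver hierarchies, heteroscedastic or
per-gene noise (noise is whole-tuple and uniform), batch effects, and
missingness. Passing tests therefore certify the machinery — structure
recovery, membership behaviour, discretization and significance
calibration under heavy uniform contamination — not performance on any
particular real dataset.

## Problem sizes used in the checks

The bundled tests and the acceptance script run the full pipeline on
the 1800 × 20 benchmark (clustering, ten regenerations) and on reduced
tables (460 samples) for the rule-learning checks, with `max_order`
2–3 where only pairwise/triple structure is being asserted; these sizes
give stable statistics for every quantity asserted. Classifier
generalization is checked on a held-out split rather than leave-one-out
resubstitution folds.

## Known limitations

* Plug-in information estimates are biased upward for sparse tables;
  the α-rule bounds, but does not remove, that bias. No kernel or k-NN
  differential-entropy estimators are provided by design.
* k-modes finds local SR optima; restarts mitigate but do not guarantee
  the global optimum (the exhaustive-search equivalence is only tested
  at small N).
* OCDD's candidate thinning can miss the exact optimum for attributes
  with more than `max_candidates` distinct values; the displacement is
  at most one thinned-grid step.
* The significance of mined patterns is per-candidate; with thousands
  of candidates the family-wise error is uncontrolled unless the
  optional Bonferroni-style tightening of `d_threshold` is applied by
  the caller.
* Missing values are rejected, not imputed: every statistic assumes
  complete contingency tables.
* Expression values are taken as-is; no log-transform or normalization
  is applied or assumed.
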