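# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `maxsdm`, in the order the pipeline runs them.

## Maximum-entropy habitat model

The model is the standard presence-only maxent formulation: a Gibbs
distribution over landscape cells, q_λ(x) = exp(λ·f(x))/Z, normalized over
the background sample, with features f(x) ∈ [0,1]. Feature classes follow
the usual vocabulary — linear (L), quadratic (Q), product (P), threshold (T),
hinge (H) for continuous predictors, one-hot class indicators (C) for
categorical ones. Continuous features are min–max scaled on the pooled
training support (presences plus background); those scaling bounds are
frozen into the model, and projection-time values outside them are clamped
back into [0, 1]. Clamping is the extrapolation rule for scenario stacks:
a future cell more extreme than anything in training behaves like the
training extreme rather than extrapolating the exponential. Threshold and
hinge knots sit at the 10 equally spaced interior quantiles of each
variable's training support (deciles; configurable); hinges are normalized
by (max − knot) so they stay in [0, 1].

### Objective and penalties

Fitting maximizes Σ_presence log q_λ(x) − Σ_j β_j|λ_j| with
β_j = reg_multiplier × class_default × sd_j/√n, where sd_j is the feature's
standard deviation over presence sites and n the presence count. The
per-class defaults live in one editable table
(`maxsdm.model.DEFAULT_CLASS_PENALTIES`; hinge 0.5, all others 1.0). A
larger multiplier produces sparser models; multiplier 0 gives the pure
maximum-likelihood maxent whose feature expectations over the background
match the presence means exactly (this constraint is tested).

### Optimization

Coordinate-wise sequential ascent: each iteration updates the coordinate
with the largest penalty-adjusted gradient (ties to the lowest feature
index) by a proximal Newton step — soft-thresholding of λ_j + g_j/h_j with
curvature h_j = Var_q(f_j) — backtracked until the penalized objective does
not decrease. Convergence is declared at first-order optimality: maximum
penalty-adjusted gradient of the mean-form objective ≤ tol (default 10⁻⁶),
with an iteration cap of 5,000 (non-convergence is flagged on the model,
not raised). The improvement-based alternative (stop when one step gains
less than tol) was rejected: it leaves solution-quality differences between
tuning candidates of the same order as their AICc differences, which
corrupts model selection.

The stored gain trajectory is the *regularized* gain (mean presence
log-probability minus log-uniform minus the penalty), which the update rule
makes non-decreasing by construction. The unpenalized training gain is
exposed separately (`gain_`); at β = 0 the two coincide, and the
monotonicity of the exact gain is tested there. Per-feature objective
improvements are accumulated as gain credits during the ascent; percent
variable contribution sums these credits per source variable (product
features split evenly between their two variables), floors negatives at
zero, and normalizes to 100.

### Logistic output

Suitability is reported as c·q/(1 + c·q) with c = exp(H), H the entropy of
the fitted distribution over the background: a cell with "typical" raw
probability exp(−H) scores exactly 0.5. Raw output sums to 1 over the
training background and is the quantity used for AICc.

## Preprocessing

Occurrence cleaning drops non-finite coordinates, exact duplicates (first
occurrence kept), and points on masked or out-of-grid cells, then thins to
one record per cell — the first in input order, so rarefaction is
deterministic. Points bin to cells by half-open intervals
[edge, edge + cell_size) on a north-up planar grid; no CRS handling is
attempted. Background points are uniform draws of valid cell centres without
replacement (all cells, with a warning, if more are requested than exist);
presence cells are not excluded by default, matching common maxent practice,
and correlation screening runs on the union of presence and background
cells. The collinearity filter greedily drops, from the worst-correlated
pair, the member with the higher mean absolute correlation against the
other retained layers until every retained pair satisfies |r| ≤ 0.85; a
user-supplied priority list (earlier = keep) substitutes for expert
judgment, which is not otherwise implementable. Constant layers are dropped
with a warning; categorical layers bypass the filter. The greedy tie-break
is a documented choice — nothing in the underlying method fixes how chains
of >2 mutually correlated variables resolve.

## Model selection

Candidates are every non-empty subset of {L, Q, H, P, T} crossed with the
regularization grid {0.1, 1, 2, …, 10} (31 × 11 = 341 by default). Each
candidate is fitted on the full occurrence set; partitioned evaluation
happens downstream, after selection. The score is
AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) with k the count of *nonzero* fitted
weights (the lasso-maxent convention) and lnL the sum of log raw
probabilities at the occurrence cells after standardizing the raw output to
sum to 1 over the landscape cells (the Warren–Seifert convention). The
standardization support is the set of unique cells among the supplied rows:
occurrence cells drawn repeatedly, or duplicated into the background, count
once — otherwise duplicated high-suitability rows flatten the likelihood
differences between candidates. Candidates with n ≤ k + 1 are invalid. Ties
break toward smaller k, then smaller multiplier, then lexicographic feature
set.

## Evaluation

* **AUC** is the exact rank statistic (Mann–Whitney, ties ½): the
  probability a random presence outranks a random background point. Bands
  follow the conventional scale (0.5–0.6 Failed … 0.9–1 Excellent);
  boundary values go to the upper band, values below 0.5 are labelled
  "worse than random". On presence/background data AUC is bounded below 1
  because background cells include genuinely suitable habitat; synthetic
  experiments here show honest values near 0.65–0.85 even for
  well-specified models.
* **Continuous Boyce Index**: 101 overlapping windows of width 10% of the
  landscape suitability range (both configurable — the continuous variant
  requires *some* window scheme and none is canonical); per window,
  P = fraction of presences inside, E = fraction of landscape cells inside;
  windows with E = 0 are dropped; CBI is the Spearman correlation of P/E
  against window midpoints, and a flat P/E profile reports 0 (a model
  indistinguishable from random). Fewer than three usable windows is an
  error. The pipeline computes CBI on the replicate-mean map; per-replicate
  computation is available by calling `boyce_index` on any map.
* **Jackknife** refits the selected specification with each variable
  omitted and each variable alone (β and feature classes fixed) and reports
  training gains against the full-model gain.

## Replicates, thresholding, scenarios

Calibration runs n (default 20) seeded random 75/25 train/validation splits
of the occurrences — implemented as without-replacement splits because the
customary "bootstrap 75/25" phrasing is internally contradictory; a
with-replacement option (`bootstrap=True`) resamples the training partition.
The working suitability surface is the cell-wise arithmetic mean of the
replicate logistic maps. The binary threshold τ₁₀ is the ascending order
statistic at rank ⌈0.10·n⌉ of the training-presence suitabilities — no
interpolation, so at most 10% of training presences fall strictly below it
and the threshold is always an observed value. τ₁₀ is computed once from
current-condition data and reused for every scenario: range change must be
measured against a fixed decision rule (re-thresholding per scenario is
possible by calling `binarize_and_measure` directly). Scenario stacks shift
climate layers and swap in the simulated future land-cover map while
topographic layers stay fixed; every replicate model is projected with
clamping, maps are averaged, binarized at τ₁₀, and the percent range change
is Δ = 100 × (suitable_future − suitable_current)/suitable_current. An
identity scenario yields Δ = 0 exactly.

## Land-cover simulation

The transition matrix is the cross-tabulation of two dated maps
(P[i,j] = cells moving i→j / cells of i; classes absent at the first date
get identity rows). Scaling to the projection horizon assumes stationary
transition probabilities and takes the real matrix power
P^(horizon/interval) via eigendecomposition, clipping entries below 10⁻⁸ in
magnitude and renormalizing rows; when that route yields materially
negative or complex entries the code falls back to integer powers with
linear interpolation of the fractional step and flags the result. Change
demand integerizes (class count × row probability) by largest-remainder
rounding within each row, conserving totals exactly.

Transition potentials use one feed-forward network per source class
(single hidden layer of 10 logistic units, softmax over destination
classes, Adam, learning rate 0.01, up to 1,000 epochs, fixed seed) trained
on a balanced, capped subsample of transitioned and persistent cells with
standardized drivers; the potential raster of pair (i, j) is the predicted
probability of destination j at every cell. Only transitions observed
between the two dates are modelled. Allocation processes transitions in
descending demand order and converts the demanded number of source-class
cells with the highest potential, ties broken by a seeded random draw, each
cell converting at most once — so cross-tabulating (current, allocated)
reproduces the demanded counts exactly and total cell count is conserved.

## Synthetic data: what it emulates and what it does not

Continuous predictors are Gaussian-smoothed white-noise fields
(σ = 3 cells by default), standardized and mixed through the symmetric
square root of a target correlation matrix; empirical pairwise correlations
converge to the target as the grid grows (tested at 300×300 within 0.05).
Positive semi-definite targets are accepted (r = 1 is a legitimate
degenerate request); indefinite matrices are rejected. The categorical
layer quantile-bins an independent smooth field, so classes are spatially
coherent and all present. Presences are multinomial draws of cell centres
from the exact normalized log-linear truth — no within-cell jitter, so
rarefaction behaviour is exactly predictable. Land-cover pairs draw the
first map i.i.d. from a class prior (uniform by default) and the second
from the per-cell transition row, optionally re-weighted by non-negative
driver effects and renormalized.

The generator reproduces the *structure* the pipeline consumes, not any
real geography: marginals are Gaussian-ish, autocorrelation is isotropic
and single-scale, presence sampling is unbiased, and the land-cover process
is exactly Markov with the stated drivers. Passing tests therefore
demonstrate the statistical machinery is correct under its own assumptions;
they say nothing about survey bias, non-equilibrium occupancy,
non-stationary transitions, or predictor measurement error in real data.

## Problem sizes and numerical notes

Test experiments use landscapes from 20×20 (parameter recovery, 400 cells,
2,000 presences) to 300×300 (correlation convergence and Markov round
trips); the selection-recovery experiment runs 20 seeded repetitions of a
31-candidate tuning sweep. These sizes were chosen as the smallest at which
the targeted effects are statistically resolvable. Two numerical points
deserve emphasis. First, linear and quadratic features of one variable are
strongly collinear (corr(s, s²) ≈ 0.97 on typical supports), so individual
weights are weakly identified along one eigendirection; parameter-recovery
assessments therefore average the estimate over seeded presence draws,
which isolates systematic error from that scatter. Second, AICc comparisons
between nested candidates hinge on lnL differences of order 1, so the fit
must be converged to first-order optimality well below that scale — the
default gradient tolerance of 10⁻⁶ suffices.

## Known limitations

* No CRS/projection support, geodesic distances, or vector formats; rasters
  are plain-text ESRI ASCII grids on a planar grid.
* No sample-bias ("bias file") weighting and no cumulative output format.
* The MLP training protocol is a documented default, not a reproduction of
  any proprietary land-change tool's internals; no cellular-automata
  contiguity filtering is applied to allocated change.
* AICc is computed on penalized fits (the standard practical convention);
  with heavy regularization k undercounts effective complexity.
* Percent contribution depends on the coordinate-update path, as in any
  gain-credit scheme; jackknife gains are the path-independent complement.
* The class-label tables in bundled reports follow the first-date map's
  class identifiers; semantic naming of classes is the caller's
  responsibility (`class_area_report` accepts a name mapping).
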