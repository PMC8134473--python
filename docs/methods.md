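# Methods

## Model

All estimators assume a linear (constant-rate) birth–death process with
speciation rate λ and extinction rate μ (per lineage per my), started from
a single lineage at the stem origin and conditioned on survival to the
observation time. Under that conditioning, richness *N(t)* follows a
geometric distribution on {1, 2, …} with success parameter 1 − β:

* r = λ − μ > 0:  β = (e^{rt} − 1)/(e^{rt} − ε), with ε = μ/λ ∈ [0, 1);
* r = 0 (balanced): β = λt/(1 + λt).

The conditional mean is 1/(1 − β): (e^{rt} − ε)/(1 − ε) for r > 0 and
1 + λt for r = 0. Maximizing the conditional pmf of one (n, t) datum over
r at fixed ε yields the closed-form ARR estimator
r̂ = (1/t)·log[n(1 − ε) + ε]; substituting it back reduces β to
(n − 1)/n, so the maximized probability is (1/n)((n − 1)/n)^{n−1},
independent of t and ε. The same value is attained by the balanced process
at λ̂ = (n − 1)/t and, for any fixed r with 1 ≤ e^{rt} ≤ n, at
ε̂ = (n − e^{rt})/(n − 1). These identities are the non-identifiability
result the package verifies numerically; the ε-profile test maximizes the
log pmf over r ∈ [0, log(10n)/t] by bounded scalar optimization
(xatol 10⁻¹²) and checks flatness to 10⁻⁶.

Domain restrictions: ε is confined to [0, 1] (μ ≤ λ). ε = 1 is accepted by
the rate estimator (where the expression collapses to r̂ = 0 for any n)
but excluded from likelihood and prediction paths, because the geometric
parameterization degenerates there; a balanced-process entry point covers
r = 0 properly. n = 1 uses the 0⁰ = 1 convention, the limit of the
maximized-probability expression and the survival-conditioned point mass
at 1.

## Numerical choices

* All pmf values are computed and stored as natural logs; β can sit within
  10⁻³⁰⁰ of 1 at fossil scales, so β^{n−1} underflows long before the log
  form loses accuracy. Linear-scale probabilities and means are
  materialized on demand and overflow cleanly to `inf`.
* β is evaluated through the algebraically equivalent form
  (1 − e^{−rt}) / ((1 − e^{−rt}) + (1 − ε)e^{−rt}) with `expm1`, which is
  accurate to machine precision over the whole rt range; no series branch
  near r = 0 is needed, and the r → 0 limit agrees with the balanced form
  to first order in (λ − μ)t (verified to < 10⁻⁷ relative at rt = 10⁻⁸).
  log β switches to a log1p-of-complement form when β > 1/2.
* Akaike weights (equal parameter counts, so P_A/(P_A + P_B)) are computed
  as a sigmoid of the log-probability difference; −∞ log-probabilities are
  legal inputs on one side, and a pair where every model assigns zero
  probability (monotypic focal timepoint predicting n₂ > 1) is flagged
  degenerate rather than aborting a batch.
* The extinction-fraction MLE tolerates e^{rt} exceeding n by ≤ 10⁻¹²
  relative (floating-point slack on the boundary case) and clips the
  estimate into [0, 1].

## Predictions across timepoints

The ARR prediction is anchored at the clade origin: the rate r₁ fitted at
(n₁, t₁) parameterizes the survival-conditioned distribution at elapsed
time t₂ measured from the stem origin, rather than compounding growth from
n₁ over t₂ − t₁. This is the reading under which the fitted trajectory
passes exactly through the focal observation (all three parametric models
reproduce mean n₁ at t₂ = t₁ identically) and the pmf of n₂ keeps the
single-lineage geometric form. The zero model fits λ₁ = (n₁ − 1)/t₁ and
predicts the linear mean 1 + λ₁t₂; the constant model reuses n₁ as the
geometric mean with no time dependence. The random model draws uniform
integers on [1, N_max] with N_max the focal clade's maximum observed
richness; it has no comparable fitted-likelihood structure and enters
absolute-error comparisons only.

Support thresholds follow the 0.95/0.05 convention for "strongly favored"
and "strongly rejected".

## Pipeline conventions

* Timepoints are ordered oldest-first (strictly decreasing age in Ma);
  when a series arrives as interval bins, the representative age of a bin
  is its midpoint, decided upstream of the CSV.
* Rescaling of proportional (SQS-like) richness: `present_day_ratio`
  multiplies the series by (calibration richness)/(most recent raw value);
  `peak_calibration` by (calibration richness)/(series maximum);
  `none` passes lineage counts through. Scaled values are rounded to the
  nearest integer and floored at 1, since the survival-conditioned support
  starts at 1.
* Lag = t₂ − t₁, positive meaning forward in time; a k-point series yields
  k(k − 1) ordered pairs, half of them forward. Lag bins are half-open
  [k·w, (k + 1)·w) aligned to multiples of the width on both sides of
  zero; the default width is 15 my. Medians use the standard
  middle-element convention at odd counts.
* Headline support fractions pool pairs unweighted across clades; per-clade
  rows are emitted alongside. Extinct clades are truncated at the last
  positive-richness sample before analysis.
* The full study runner derives one RNG stream per (clade, ε) from the
  study seed via CRC-32 of the clade name, making outputs byte-identical
  across reruns and independent of clade order.

## Synthetic data

The simulator is an exact event-driven (Gillespie) implementation of the
lineage count — no time discretization — because it doubles as the
brute-force oracle for the geometric kernel: forward simulations filtered
on survival are compared with the closed-form pmf by total-variation
distance (≈ 0.005 at 3 × 10⁵ replicates for the parameter sets exercised
in the tests, against a 0.01 acceptance bound).

Conditioning on present-day diversity is by rejection: a trajectory is
accepted when its most recent sampled richness falls within a relative
tolerance window (default ±10%; the push-of-the-past experiments in the
tests and examples use ±50% to keep acceptance rates practical at
richness targets of a few hundred). Rejection is exact up to the window
width.

The fixture battery emulates the qualitative shapes of Phanerozoic
diversity curves on ~10-my bins spanning 140–530 my: exponential rises,
logistic plateaus, a flat trajectory, symmetric waxing–waning clades,
extinct clades (truncated at the last bin resolving ≥ 2 species after
rounding — sampled fossil series do not bottom out at a final singleton
bin), mass-extinction survivors with an abrupt proportional drop, and a
time-offset pair of identical trajectories. Optional multiplicative
log-normal noise (sd 0.1–0.25 in the battery) stands in for sampling
error. What the battery does **not** emulate: occurrence-level sampling
and subsampling (series are consumed already standardized), secular
evenness trends, correlated errors between adjacent bins, and
geological-timescale uncertainty in bin ages. Tests passing on the battery
therefore demonstrate the estimator's intrinsic time-scaling and
predictive pathologies, not the sampling robustness of any particular
empirical series.

Problem sizes used by the test suite were chosen to keep every check
well-resolved at desk scale: 3 × 10⁵ replicates per parameter set for the
oracle comparison, 100 replicate series for the uniform null (sampled on
a log-spaced time grid, the natural design for probing a 1/t power law),
40 accepted trajectories for the push-of-the-past experiment, and the
15-clade battery (~17,000 ordered pairs) for pipeline-level summaries.

## Known limitations

* Crown-clade variants of the estimator (two ancestral lineages) are out
  of scope, as are unconditioned likelihoods and phylogenetic branching
  processes.
* The AIC-weight machinery covers single-clade, single-pair comparisons;
  joint multi-clade model selection is deliberately absent.
* Rejection-based conditioning becomes impractical when the target window
  mass is very small (the runner reports acceptance diagnostics and asks
  for a wider tolerance rather than biasing the sample).
* Printed projections for real clades depend on the origin-anchored
  prediction convention described above; other anchoring conventions
  (e.g., compounding from the focal richness) give different absolute
  projections, though the same qualitative failure modes.
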