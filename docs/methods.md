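# Methods

## Model

Responses are modelled by Samejima's graded response model. For item *j*
with discrimination *aⱼ* > 0 and strictly ordered thresholds
*b*ⱼ₁ < … < *b*ⱼ,ₖ₋₁, the boundary probability of scoring in category
*k* or above at latent severity θ is the two-parameter logistic
σ(aⱼ(θ − bⱼₖ)), and category probabilities are adjacent differences of
boundary probabilities. The metric is logistic **without** the 1.702
normal-ogive scaling constant. This convention is a substantive commitment,
not a cosmetic one: the packaged BDI-II bank reproduces the calibration
sample's observed score-0 proportions (e.g. 81.2% vs the observed 81.3% on
the sadness item) only without the constant; with it, the same parameters
would imply 84.3%. The source calibration did not state its metric, so the
bank documents this inference in its metadata.

Local independence and unidimensionality are assumed throughout. A formal
factor-analytic check of those assumptions is out of scope; the latent
trait is identified by fixing its distribution to N(0,1) during
calibration (no post-hoc standardization).

## Estimation

Calibration is marginal maximum likelihood via EM. The E-step computes each
observed response pattern's posterior weights over a fixed quadrature grid —
61 equally spaced nodes on [−5, 5] with weights proportional to the standard
normal density, renormalized to sum to one. Patterns are deduplicated first,
so per-iteration cost scales with distinct patterns, not persons. The M-step
maximizes each item's expected complete-data log-likelihood by L-BFGS-B with
analytic gradients in the reparameterization (log a, b₁, log-gaps), which
enforces threshold ordering by construction rather than by post-fit checks.
Convergence is declared when the largest absolute parameter change falls
below 1e-4 (cap 500 iterations); the marginal log-likelihood is asserted
non-decreasing at every iteration and recomputed at the returned parameters.
Starting values are a = 1 with thresholds at inverse-logits of observed
cumulative endorsement proportions.

Standard errors use the outer-product-of-gradients (empirical cross-product)
approximation of the information matrix, with per-pattern scores obtained as
posterior-weighted complete-data gradients. These are approximate; on
study-sized simulations they agree closely with the generating calibration's
published standard errors (e.g. 0.084 vs 0.09 for the highest-discrimination
item).

Categories never observed for an item are merged into the adjacent lower
category when `on_empty="collapse"` is requested (the default refuses and
names the item). A collapsed item keeps fewer categories in the returned
bank; probability arrays zero-pad the categories it cannot produce. Missing
responses are ignorable: they are skipped in the pattern likelihood, and an
all-missing pattern scores at the prior (EAP 0, posterior SD 1, flagged).

Trait scores are EAP means over the same grid, with posterior standard
deviations. Quadrature is stable: implied marginals move by < 1e-6 between
41 and 61 nodes.

## Synthetic data

The generator draws, from one seeded stream in fixed order (gender, age
group, θ, then item responses left to right), datasets with the structure
the analyses assume: GRM responses at each person's θ, binary gender and age
groups drawn independently, group trait-mean shifts entering additively with
unit SD, and optional injected DIF. Uniform DIF subtracts a constant δ from
every threshold of the focal group's item; non-uniform DIF multiplies its
discrimination. Persons are partitioned by which injections apply so each
subset is scored under a single bank; uniforms are drawn before partitioning
so the stream is independent of the DIF configuration.

The study fixture emulates the college-student survey the packaged bank
comes from: N = 12,677; 44.9% men / 55.1% women; 85.9% younger / 14.1%
older. Group θ means are obtained by inverting the population expected total
score (monotone root-finding on E[T | θ~N(μ,1)], tolerance 1e-6) at the
published group mean totals (men 5.92, women 7.85, younger 7.17, older
5.83); gender carries the location and age enters as a deviation from the
overall calibrated mean, added per person. The source study did not publish
group θ distributions, so these calibrated shifts are a modelling choice:
fixture group *means* match the study, but cut-off exceedance proportions
depend on distributional detail the study did not print and are only
directionally comparable. What the generator deliberately does not emulate:
the survey's two-stage cluster design, item-level missingness patterns,
any gender-age correlation, and any real DIF magnitudes (the study did not
estimate generating effect sizes for its two flagged items; injected δ
values are user choices). Passing tests therefore demonstrate correctness
of the machinery under the model's own assumptions, not robustness to the
ways real survey data violate them.

## DIF procedure

Per item, four nested proportional-odds models of the 0–3 response:
intercepts; + θ; + θ and group; + θ×group. Fits are exact ML with analytic
gradients (L-BFGS-B over (first cutpoint, log-gaps, slopes)); the
intercept-only fit equals the observed cumulative logits, and fits were
validated against statsmodels' `OrderedModel` (log-likelihood agreement to
1e-6) and a brute-force grid oracle. Group coding: reference = men/younger,
focal = women/older.

Pseudo-R² changes are computed in three flavors — McFadden (default),
Cox–Snell, Nagelkerke — all reported. McFadden is the default because it is
guaranteed non-negative for nested ML fits, so the 0.02 flag rule cannot be
triggered in reverse. An item is flagged when ΔR²(model 1 vs 3) > 0.02;
ΔR²(1 vs 2) > 0.02 classifies uniform, ΔR²(2 vs 3) > 0.02 non-uniform,
both mixed. An alternative significance rule (2-df LR test of 1 vs 3 at
α = 0.01, Bonferroni over 21 items) is selectable. Categories with fewer
than `min_cell = 5` observations in either group are merged downward before
fitting. Note the ΔR² rule is conservative at large N: on null simulations
at N = 12,677 observed per-item flag rates are far below 1%.

Purification re-estimates trait scores treating flagged items as
group-specific: each flagged item is split into two columns observed only in
its group, the augmented matrix is recalibrated (anchors shared, fixing the
metric), and the scan repeats until the flagged set repeats itself (cap 10
passes; an `anchors_only` mode instead drops flagged items from scoring).
If every item flags, there is no anchor and the analysis aborts with a
diagnostic.

## Curves and impact

Item characteristic curves report E[X|θ] and the per-category probability
curves; the test characteristic curve sums item ICCs (default grid: 201
points on [−4, 4]). DIF impact compares the TCCs implied by reference and
focal banks sharing anchors, over all items and over the DIF items alone,
summarized by the maximum absolute difference and its location. A single
four-category item bounds the impact by 3 raw-score points; the δ = 0.75
uniform-shift scenario moves the expected total by at most ~0.7 points on
the 0–63 scale — the quantitative sense in which flagged DIF can be real
but negligible.

One caution on curve-reading: the population expected total under
θ ~ N(μ, 1) is *not* the TCC evaluated at μ. Near the scale floor the TCC
is convex, so E[TCC(θ)] exceeds TCC(E[θ]) by several raw-score points.
Group-mean calibration inverts the population expectation, which is the
quantity that matches observed group means.

## Problem sizes and tolerances in the test suite

Deterministic model-implied checks use the 61-node grid. Parameter-recovery
and reliability checks simulate one N = 12,677 dataset (the calibration
study's size) and refit it (~10 s). DIF operating characteristics run the
full hybrid cycle (fresh data, refit, EAP, scan) per replicate: 50 null
replicates at N = 2,000 for the false-flag rate (< 1% per item), and 15
injected replicates (δ = 0.75 on the crying item) at N = 12,677 for power
(≥ 95% flagged-and-uniform). The null arm tolerates the smaller N because a
null ΔR² is near zero at any size, but the power arm must run at the study
size: the injected effect lands near ΔR² ≈ 0.03, and at N = 2,000 boundary
noise around the 0.02 rule materially lowers power. These sizes keep the
whole suite in the minutes range while leaving the binomial noise of the
estimated rates well inside the asserted margins. The Welch-comparison level check uses 300 replicates
of N = 300 on a 5-item toy bank.

## Known limitations

- OPG standard errors understate uncertainty when the model is misspecified;
  no sandwich correction is offered.
- The DIF threshold 0.02 is a convention, not a calibrated quantity; no
  Monte-Carlo threshold calibration is implemented.
- Only two-group DIF is supported; no Mantel–Haenszel, SIBTEST or IRT-LR
  alternatives.
- Group comparisons ignore any survey design effect (the emulated survey was
  a two-stage cluster sample; its design is not simulated, and unweighted
  comparisons replicate the original analysis choice).
- Finite-sample MML bias is visible on items whose top category is very
  sparse (the interest-in-sex item's third threshold sits at 4.44 SD, ~0.6%
  endorsement): recovered discriminations run slightly low at N = 12,677,
  within about one standard error.
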