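# Methods

This note documents the models, estimators, numerical choices and
simulation design implemented in `tigersynth`, and what the test suite
does and does not establish about behaviour on real data.

## Data model

A study is four tables. The outcome panel holds cumulative forest loss
(ha since the first panel year) per reserve × calendar year; years form
one contiguous range shared by every reserve, and cumulative loss is
non-decreasing within a reserve. The covariate table carries eleven
numeric reserve-level deforestation drivers plus a landscape-group
label used for donor stratification. The treatment table records each
treated reserve's intervention year (blank = donor); the carbon table
holds above-/belowground carbon densities and their prediction
standard errors (tC/ha, reference year 2010) with forest cover in 2010
and at the intervention year.

Period convention: the pre-intervention period is years strictly
before the intervention year; the post period includes the
intervention year itself (gazettement takes effect within its year).
Treated reserves excluded by a filter (the 2007–2015 treatment window,
or an anticipation flag) are demoted with a recorded reason — they are
neither treated nor donors, but never silently dropped.

## Synthetic-control estimator

Predictors are the eleven covariates plus the mean pre-intervention
cumulative loss, standardised to zero mean and unit sample variance
(ddof = 1) over the treated unit pooled with its donors; constant
predictors are dropped with a warning. The landscape-group label is a
stratification device, never a predictor.

**Inner problem.** For predictor weights v on the k-simplex, donor
weights w minimise `(X1 − X0 w)' diag(v) (X1 − X0 w)` over the
J-simplex. The solver is non-negative least squares on the
penalty-augmented system `[diag(√v)·X0 ; μ·1'] w ≈ [diag(√v)·x1 ; μ]`
with μ = 1e6 × the design scale, followed by renormalisation of w.
This is deterministic, accurate to well below the 1e-6 tolerance the
oracle tests demand (verified against exhaustive simplex grid search at
step 0.005), and roughly two orders of magnitude faster than a
sequential quadratic programming call — which matters because placebo
inference refits the model once per donor.

**Outer problem.** v minimises the pre-intervention MSPE of the
implied counterfactual. The search is Nelder–Mead over a softmax
reparameterisation of v (k−1 free parameters, adaptive simplex
coefficients for k > 9, `fatol` 1e-8, at most 500 iterations by
default). Two candidate starts are evaluated — uniform v and a v
placing 0.9 of its mass on the pre-loss predictor, whose inner match
directly targets the outer objective — and the search starts from the
better one while a best-so-far record retains the uniform baseline, so
the reported pre-MSPE never exceeds the uniform-v value. The
pre-loss-heavy start matters: on near-noiseless panels it improves the
attained objective by 3–4 orders of magnitude at a fixed budget.

The outer objective is internally normalised by the variance of the
treated pre-period series, making the search path invariant to
rescaling the outcome; effects therefore scale exactly linearly and
MSPEs quadratically with the outcome unit. Reported MSPEs are
unnormalised (ha²). Fits are deterministic: donors sorted by id, fixed
starts, no randomness.

Degenerate cases: a pre-MSPE of numerically zero is floored at
1e-8 × var(treated pre-period series) (1e-8 if that variance is zero)
whenever it enters a ratio denominator; k = 1 after constant-predictor
drops skips the outer search.

## Placebo inference

Each donor is refit as a pseudo-treated unit with the true treated
reserve added to its donor pool, at the same intervention year and
configuration. The test statistic is the post/pre MSPE ratio; the
p-value is the descending rank of the treated ratio among all
treated+placebo ratios divided by their count, ties taking the worst
rank (conservative). The attainable floor is 1/(n+1), which is the
reason donor groupings must exceed 20 units for p < 0.05 to be
reachable; pools below `min_placebos` (default 20) return their
p-value with a cannot-reach-alpha flag. Placebos whose fit fails are
recorded and excluded from the rank with a warning. No pre-fit-quality
filtering of placebos is applied by default; an optional filter
dropping placebos with pre-MSPE above c × the treated unit's is
available but off.

Under exchangeability of the treated unit with its donors the p-value
is exactly uniform on {1/(n+1), …, 1}; the calibration test verifies
this on 200 simulated null studies (χ² goodness of fit at the 1%
level). Because uniformity follows from symmetry of the construction,
it holds at any optimizer budget; the calibration test runs at a
reduced outer budget (80 iterations) purely for speed.

**Group fit comparison.** Pre-intervention MSPEs of reserve groups are
compared with a two-independent-sample bootstrap test (default 9,999
iterations): both groups are resampled with replacement from the
pooled, mean-aligned sample, and the statistic is the studentised
absolute mean difference; p = (1 + #{null ≥ observed})/(iterations+1).
Studentising is deliberate: the raw mean-difference variant over-rejects
noticeably at the n ≈ 15 group sizes this test is used at (~8 % at a
nominal 5 %), while the studentised version is calibrated (~5–6 %).

**Covariate balance.** Pairwise Pearson correlations over all units
flag collinear predictor pairs at |r| ≥ 0.8. ANOSIM runs on Euclidean
distances of the standardised covariates: R = (mean between-group
rank − mean within-group rank) / (n(n−1)/4), with a seeded label-
permutation p-value. The statistic is cross-checked against
scikit-bio's implementation in the test suite.

## Robustness battery

**Anticipation.** For reserves whose main test is significant, the
panel is truncated to years strictly before the true intervention
(so the genuine response cannot contaminate the check), and the full
fit + placebo machinery reruns with a backdated pseudo-intervention
(default 2005, the year the national tiger authority was constituted):
training on years before the pseudo-year, evaluation on the pseudo-post
years. A p-value below α flags the reserve as anticipating and excludes
it. The check is skipped (with a warning, excluded = False) when fewer
than `min_pre_years` (default 3) training years exist or the testing
window is empty. With a 2005 backdate the training window is short
(four years from a 2001 panel start), so per-replicate power against
a 50 % built-in anticipation is real but far from certain (~40 % at
40 donors in simulation); the test suite asserts detection well above
the nominal rate rather than near-certain exclusion.

**Area trimming.** Donor pools are restricted to donors at least
`factor` × the treated area (inclusive boundary; factors 0.1 and 0.25
by default; monotone in the factor by construction). Trimmed refits
are scored against the untrimmed result: same effect sign (sign(0)
matches only 0), |Δeffect| ≤ 20 % of the untrimmed effect (recorded
False when the untrimmed effect is 0), and significance — reported as
not-assessable rather than False when the trimmed pool has ≤ 20
donors, since the placebo floor then sits above 0.05.

## Carbon accounting

Densities (and their standard errors) are scaled from the 2010
reference year to the intervention year proportionally to the
forest-cover ratio, `d_interv = d_2010 × cover_interv / cover_2010`.
The per-year effect increments Δha(t) (first post year keeps its own
cumulative value) convert as:

* aboveground: `Σ_t Δha(t) × d_AGB × 3.67` — committed in full;
* belowground: `Σ_t Δha(t) × d_BGB × 3.67 × min(1, (T_eval − t)/10)` —
  the fraction of the 10-year linear decay elapsed by the evaluation
  year (forest lost in the evaluation year itself contributes no
  belowground emissions yet).

Uncertainty is |averted ha| × 3.67 × (SE_AGB + SE_BGB): additive over
the two pools, matching the way the published component uncertainties
add to the total. At the portfolio level, uncertainties combine
additively over signed hectares, so the net uncertainty is the
gains-side minus the losses-side uncertainty — the only rule consistent
with the published net ± bands. Negative effects (reserves losing more
than their counterfactual) flow through identical formulas and appear
as damages/foregone revenue. Valuations are emissions × price / 1000
(thousand US$), computed at full precision and reported at two
decimals. No future land-use scenario, regrowth, degradation or
discounting term exists. When only a terminal averted-hectare figure
is available (no per-year series), increments are distributed
uniformly over the post-intervention years.

## Synthetic-data generator

Annual loss for reserve r in landscape group g is

    loss_r(t) = area_r × base_rate × m_g × exp(β'z_r + ε_rt)

with cumulative loss its running sum (monotone by construction).
Covariates: log-normal population density, road length, purchasing
power and area (median area ≈ 40,000 ha, log-sd 0.25); normal
precipitation, elevation, slope, baseline biomass; uniform aspect, age
and travel time. z_r are the generating-distribution standard scores
(log scale for the log-normal ones), so treated and donor units are
exchangeable draws. Defaults: base_rate 0.001/yr of reserve area
(≈ tens of ha/yr on typical reserves, consistent with reported losses
of a few hundred ha per reserve over two decades), group multipliers
(1.0, 0.4, 2.5), coefficient vector of norm ≈ 0.20 concentrated on
pressure/accessibility proxies, AR(1) log-noise with stationary sd
0.15 and φ = 0.5. Carbon densities are drawn per reserve
(AGB 60 ± 15, BGB 20 ± 5 tC/ha) with fixed prediction SEs (10, 5);
forest cover starts at 80 % of area and declines with simulated loss.

Heterogeneity is deliberately split: within a group the combined
rate spread (area × covariates) is ≈ 4× across the central 95 %,
while the group multipliers widen the study-wide range to roughly an
order of magnitude. Regional pressure differences dominating
within-landscape differences is both what real deforestation data
show and what keeps a treated draw representable as a convex
combination of its donors — the overlap assumption the estimator
needs, and the reason the evaluation design matches within landscape
groupings in the first place. With all heterogeneity at the reserve
level the treated unit regularly lands outside the donor envelope and
no convex counterfactual exists; the generator retains that failure
mode at a realistic low rate (~5 % of draws), and those draws are the
dominant residual error source in the recovery tests.

Treated units multiply their annual loss by (1 − effect_rho) from the
intervention year (or an earlier override year for anticipation
variants). The counterfactual path shares the treated unit's noise,
so the injected truth is exact: per-year averted hectares equal
effect_rho/(1 − effect_rho) × observed post-intervention loss. All
randomness flows from one seed through named child streams
(covariates / noise / carbon / assignment), making every component
independently reproducible and (config, seed) bit-stable.

What the generator does not emulate: spatial structure, India-specific
covariate magnitudes, forest-cover saturation, degradation, or
reporting artefacts of satellite loss products. Passing recovery and
calibration tests therefore demonstrates internal validity of the
estimator-inference chain under the stated generating process, not
performance guarantees on any particular real dataset.

## Problem sizes and budgets in the test suite

Parameter-recovery tests run 50 replicates of a 40-donor,
single-group study with a 2007 intervention (six pre-years) and
ρ = 0.3 at the default outer budget; inference-calibration tests run
200 placebo ensembles of 21 donors at a reduced outer budget (80
iterations — exactness of the permutation construction does not depend
on fit quality) and 500 bootstrap tests of n = 15 groups at 499
iterations. The QP oracle comparison uses 100 random instances with
2–4 donors and 1–4 predictors against the full 0.005-step simplex
grid. These sizes are the package's chosen trade-off between
statistical resolution and a test suite that runs in a few minutes.

## Known limitations

* Convex counterfactuals cannot extrapolate beyond the donor envelope;
  units outside it produce attenuated or sign-flipped effects. Such
  units are flagged indirectly by poor pre-fit (large pre-MSPE) and, in
  the pipeline, rarely reach significance.
* The placebo p-value's granularity is 1/(n+1); with the conventional
  α = 0.05 nothing below 21 donors can ever reject.
* Anticipation screening power is limited by the backdated training
  window, not by donor count.
* The bootstrap group test assumes exchangeable fit-quality values
  within groups; MSPEs are heavy-tailed, which the studentised
  statistic tolerates but does not eliminate.
* Carbon accounts inherit the effect estimate's sampling error, which
  the reported ± band does not include — it propagates only the
  carbon-density prediction error, matching the published convention.
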