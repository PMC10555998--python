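# Methods

This note records the statistical models implemented in `tipstress`, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## The experiment being modeled

One experimental unit is a tank of 15 zebra mussels held for two months at
one of 13 fertilizer masses (0–120 g, a sustained nutrient-enrichment
"press") under one of two salinity regimes: stable freshwater, or a weekly
four-hour saltwater-intrusion "pulse". Five replicate tanks per treatment
give 13 × 2 × 5 = 130 units, distributed over 6 temperature-controlled
water baths (a blocking factor). The response is end-of-experiment
mortality, reported as a percentage of the 15 individuals.

The analysis asks three questions: does mortality change slope abruptly
somewhere along the gradient (a threshold / tipping point)? do independent
diagnostics corroborate that the threshold is a genuine transition (rising
variance on approach; multimodality of the response distribution)? and how
do the two stressors interact along the gradient (synergy vs. antagonism
relative to an independence null)?

## Synthetic data generator

`synthetic.make_design` reproduces the factorial layout above; all design
constants are constructor arguments, with the reference values as
defaults. The 13 default fertilizer masses are an even 10-g grid over
0–120 g; the endpoints and span are fixed by the reference experiment, the
even spacing is an assumption (the exact masses can be passed in when
known). Bath assignment is round-robin by default — a deterministic
balanced partition — with a seeded random balanced assignment available.

`simulate_experiment` draws, per tank,

    n_dead ~ Binomial(15, p),   p = clip(m(x) + b_bath, 0, 1),

where `m(x)` is a per-treatment piecewise-linear mean mortality fraction
and `b_bath ~ N(0, bath_sd)` is drawn once per bath (default
`bath_sd = 0.02`, a small block effect consistent with the bath factor
being reported non-significant). Three preset truths are provided:

* `stable_single_threshold` — both arms flat at 5% mortality up to
  ψ = 70 g, then rising at 1.1 percentage points per gram;
* `intrusion_double_threshold` — the two-stressor scenario: the stable arm
  as above, the intrusion arm rising from 8% at 1.2 pp/g to ψ₁ = 26.91 g,
  falling at −0.4 pp/g to ψ₂ = 84.13 g, then rising at 1.0 pp/g
  (a rise–fall–rise shape);
* `null_flat` — 15% mortality everywhere (calibration null).

Slopes and intercepts are the package's own choices of plausible
magnitudes for the reported response shapes; the breakpoint locations are
the reference values.

Near-threshold variance inflation is optional: within a window
(default 20 g) of a true breakpoint, the tank probability receives
logit-normal noise whose sd rises linearly from 0 at the window edge to
`inflation_sd` at the breakpoint. The default `inflation_sd = 2.5`
emulates flickering between alternative states close to the tipping point.
The magnitude matters: at the presets' low pre-threshold mortality
(~5%), the logit-scale noise is strongly damped by the factor p(1 − p), so
a small sd produces extra-binomial variance comparable to the ordinary
binomial background of the post-threshold arm and no detectable
early-warning signature; 2.5 makes the near-threshold variance clearly
dominate. With it, the smoothed variance profile is higher inside the
window than outside in ≈95% of simulated experiments.

What the generator does **not** emulate: water chemistry and
nutrient-release kinetics, within-experiment replacement of dead
individuals (only end-of-experiment counts are modeled), temporal
autocorrelation, and overdispersion away from thresholds. Passing tests
therefore demonstrate correctness of the estimators under binomial
sampling with the stated mean structures, not robustness to every feature
of real tank data.

## Broken-line regression

`SegmentedModel` fits

    E[y] = β₀ + β₁ x + Σⱼ βUⱼ (x − ψⱼ)₊ ,   j = 1..K, K ∈ {0, 1, 2},

by iterative linearization: given working breakpoints, least squares on
`{1, x, Uⱼ, Vⱼ}` with `Uⱼ = (x − ψⱼ)₊` and `Vⱼ = −1[x > ψⱼ]` yields a gap
coefficient γⱼ, and `ψⱼ ← ψⱼ + γⱼ/βUⱼ` until `max|γⱼ| < tol`
(default 1e-4 in response units, `max_iter = 50`). Numerical safeguards:
steps are accepted only if the fixed-ψ RSS does not increase (otherwise
halved, up to 8 times); updates leaving the observed x-range are pulled
back to the nearest interior midpoint between distinct x values and the
step is damped ×0.5; exactly coincident breakpoints trigger one restart
from perturbed initials; non-convergence is flagged on the results object,
never raised.

Single-start linearization is prone to local optima, so the default fit is
multistart: candidate breakpoints (midpoints between adjacent distinct x,
subsampled to at most 12–30) are ranked by fixed-ψ RSS, the best three
placements plus the quantile default are refined, and the best final RSS
wins; the best grid candidate itself is the floor, so the fit never
returns worse than the coarse scan. On random instances of ≤ 30 points
this matches the exhaustive oracle `brute_force_breakpoints` to within
0.1% RSS (usually exactly).

`SE(ψ̂ⱼ) = SE(γ̂ⱼ)/|β̂Uⱼ|` by the delta method, with Gaussian 95%
intervals. Under the stable preset the intervals cover the true 70 g in
≈91% of simulated experiments. The reported RSS is from the final fit
with breakpoints held fixed, which nests the straight line, so
RSS(ψ̂) ≤ RSS(line) always.

Breakpoint-count selection in the pipeline is explicit configuration: the
Davies test gates existence (p < α keeps the straight line otherwise), and
among the gated 1- and 2-breakpoint fits BIC
(`n log(RSS/n) + k log n`, k = 2 + 2K parameters) decides. This automates
a choice the analysis would otherwise make by inspection.

## Davies test

At K candidate locations ψ_k (default 10 evenly spaced interior quantiles
of x), the Wald t-statistic t_k for adding `(x − ψ_k)₊` to the straight
line is computed; with `M = max_k |t_k|`, the reported p-value is Davies'
upper bound for the maximum of a t-process with ν = n − 3 degrees of
freedom,

    p = P(|T_ν| > M) + V · (1 + M²/ν)^(−(ν−1)/2) / √(8π),

where V is the total variation of the signed t_k across the grid. The
Gaussian version of the bound (`exp(−M²/2)` in place of the power term) is
the ν → ∞ limit but is slightly anti-conservative when the variance is
estimated at these sample sizes; with the t form the rejection rate under
the flat-truth null is 5.9% at nominal 5% over 1000 simulated experiments
(within Monte-Carlo error of nominal; the bound itself is conservative in
M but the grid search and non-normal binomial responses push the other
way), and power against the single-threshold preset is ≈1. If the
straight line already fits to rounding error, all t_k are set to 0 and
p = 1.

## Dixon outlier screening

Dixon's Q for the most extreme point, with the ratio family chosen by
sample size as in standard practice (r10 for n ≤ 7, r11 for 8–10, r21 for
11–13, r22 for n ≥ 14) and the published two-tailed critical values for
α = 0.05 and 0.01, n = 3–30. At most one point is flagged per call; the
pipeline applies the screen within each treatment cell (level × salinity,
n = 5) before fitting, since breakpoint estimates are sensitive to single
extreme tanks. Simulated false-positive rate at n = 5 is 5.2% at nominal
5%.

## Variance profile

Unbiased sample variance of mortality across replicate tanks per level
(percent² units), one salinity treatment at a time; levels with fewer than
two replicates are dropped with a warning. The smooth is a local-linear
tricube-weighted fit (lowess, no robustness iterations), span 0.75 of the
level count by default and floored so each window spans at least three
levels, evaluated on an even grid over the observed range only. A
local-linear smoother reproduces constants exactly, so a flat variance
profile is rendered flat.

## Dip statistic and test

The dip is `D = min_G sup_x |F_n − G|` over unimodal CDFs G (convex up to
a mode, concave after, at most one atom, at the mode). The implementation
works on the distinct-value ECDF: for each candidate mode position — an
atom at a data value, or a mode strictly between adjacent values — the
greatest convex minorant of the ECDF's left limits and the least concave
majorant of its right values give a closed-form lower bound on the
achievable sup distance for that candidate; candidates are then resolved
exactly in order of increasing bound by a small linear program over the
knot values of a piecewise-linear unimodal CDF, stopping once the running
minimum is below the next bound. The result is exact and deterministic;
the LP step is needed because the two hull branches must also join
monotonically, a constraint that binds for some bimodal samples. By
convention the reported value is floored at the minimum attainable 1/(2n)
(an all-equal sample is a point mass, itself unimodal). Known exact
values — balanced two-point sample D = 1/4, evenly spaced sample
D = 1/(2n) — and agreement with a no-shortcut exhaustive formulation are
enforced in the tests.

`dip_test` calibrates by Monte Carlo against Uniform(0, 1) samples of the
same size, `p = (1 + #{D_b ≥ D_obs})/(B + 1)` with B = 999 by default; the
uniform is the least-favourable unimodal null, so the test is conservative
for lighter-tailed unimodal data (rejection ≈0.2% at nominal 5% for
normal samples, n = 65). The flip side is limited power at moderate n:
a balanced mixture of unit normals 4 SDs apart has population dip ≈0.046,
below the n = 65 uniform-null critical value ≈0.056, so rejection is
≈50% there and approaches 1 only at larger n or separation. The pipeline
applies the test to tank-level mortality pooled within one salinity
treatment (n = 65).

## Interaction metrics

All metrics work on cell means converted to survival `W = 100 − M` and
relative responses `w = W/W₀` (control = 0 g, stable salinity; the
intrusion-only cell is 0 g under intrusion). `DA = w_XY − w_X w_Y` is the
deviation from Bliss independence. The rescaled form divides by the
distance to the relevant anchor: `DA/E` with `E = w_X w_Y` when DA < 0
(−1 ⇔ total mortality) and `DA/(min(w_X, w_Y) − E)` when DA > 0 (1 ⇔ the
combined response equals the strongest single stressor), clipped to
[−1, 2]; |DA| < ε (default 1e-9) maps to 0, and a vanishing denominator
returns the clip boundary matching the sign of DA with a degenerate flag
(e.g. when one stressor has no effect, w = 1, the buffering anchor
coincides with the independence expectation and the direction, not the
magnitude, is identifiable). Class bins are left-closed with the last bin
closed: synergy [−1, −0.5), additive [−0.5, 0.5), buffering [0.5, 1.3),
suppression [1.3, 2] — the boundary assignment is a convention.

The multiplicative null `(N + SV) − N·SV` is computed on mortality
proportions (on that scale the formula is exactly the complement of
survival independence, which is what caps combined mortality at 100%);
`DA < 0` if and only if observed combined mortality exceeds the null
prediction, so the two presentations always agree in direction.

## Two-way interaction test

A fixed-effects two-way linear model `mortality ~ level * salinity` fitted
by one-step weighted least squares, F-test for the interaction
(numerator df = (13 − 1)(2 − 1) = 12 on the reference design). The
heterogeneous variance of percentage mortality is modeled through the
binomial variance function: the additive (main-effects) fit supplies
mortality fractions p̂ and each tank gets weight `n/(p̂(1 − p̂))`.
Estimating weights under the additive model keeps them nearly independent
of the interaction contrast; weighting by raw per-cell variances (4 df
each) inflates the test size severely (type-I ≈0.16), while this scheme
gives 5.4% at nominal 5% over 1000 additive-truth simulations. The
water-bath variance component is tested by an ML likelihood ratio between
the random-intercept model (baths as groups) and the fixed-effects model,
referred to the 50:50 χ²₀/χ²₁ mixture appropriate for a variance bounded
at zero. This is a deliberate simplification of a heterogeneous-variance
mixed model: the full covariance machinery is not reproduced, which is
acceptable here because the block effect is small by design.

## Pipeline

Stages run in the order: Dixon screening per cell → per-treatment Davies
test, 0/1/2-breakpoint fits and selection → variance profile and dip test
→ interaction table and two-way test (skipped, with a logged stage error,
when only one salinity treatment is present; any stage failure is recorded
in the report rather than aborting the run). All randomness derives from
one root seed split per stage through named `numpy` SeedSequences, so the
JSON report is byte-identical across reruns of the same configuration and
stage-level reruns are reproducible. Provenance (seed, config hash,
package version) is embedded in the report.

## Problem sizes used in the test suite

Simulation-based checks run at: 500 experiments per preset for breakpoint
recovery and CI coverage; 1000 experiments for Davies size and for
interaction-F size; 1000 normal samples (n = 65) against a 999-sample
uniform null for dip size and 500 mixture samples for dip power; 200
random small instances for the fit-vs-oracle equivalence; 10,000 draws for
the Dixon false-positive rate. These sizes put Monte-Carlo error well
inside the asserted margins while keeping the default suite fast.

## Known limitations

* Breakpoint intervals are pointwise delta-method intervals; no
  simultaneous bands, and no non-Gaussian segmented models.
* The dip test's uniform calibration is conservative, with the power
  consequences quantified above.
* The two-way test approximates, not reproduces, a heterogeneous-variance
  mixed model; denominator df are those of the fixed-effects fit.
* The interaction table uses raw cell means; bath-adjusted means are not
  implemented (the generator's bath effects are small and zero-mean).
* The generator's variance inflation is one stylized mechanism
  (logit-normal flicker in a linear window); real early-warning behavior
  near thresholds need not follow it.
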