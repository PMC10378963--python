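# Methods

## The model

`accelcox` fits a smooth additive Cox model for all-cause mortality in
which wrist-accelerometer physical activity enters through two coupled
exposures. For participant *i* with PA volume *v_i* (mean acceleration in
milligravities over the full wear period, sleep-level epochs included) and
sleep-excluded intensity-distribution histogram *p_i = (p_i1 … p_iK)* over
bins with representatives *z_1 … z_K*,

    h_i(t) = h_0(t) · exp( f(v_i) + Σ_k w(z_k) p_ik + x_i'β + b_c(i) )

* **f** — thin plate regression spline (TPRS) of volume; its affine part is
  unpenalized, so straight-line log-hazard trends are never shrunk.
* **w** — the intensity weight function, also a TPRS over the bin
  representatives, entering as a *functional* (scalar-on-function) term:
  the histogram row is the integrand, Σ_k w(z_k) p_ik the design response.
* **x'β** — parametric confounders (sex, age, education, Townsend
  deprivation, self-reported poor health, longstanding illness, current
  smoking, exceeding alcohol guidelines, BMI category).
* **b_c** — assessment-center effects, i.i.d. Gaussian, implemented as a
  ridge-penalized dummy block with its own smoothing parameter.

### Identifiability: removing the affine part of w

PA volume is (essentially) a linear functional of the intensity
distribution, so a weight function with any constant or linear-in-*z*
component duplicates information carried by the volume term. The package
removes the span {1, z} from the weight-function basis: basis columns are
reparameterized onto the orthogonal complement of that span under the
uniform inner product over the bin representatives. Consequences, verified
to machine precision in the tests:

* projecting any *w* and *w + a + b·z* onto the constrained basis yields
  identical coefficients;
* shifting histogram mass along the affine direction leaves the functional
  term unchanged;
* the fitted ŵ regresses to exactly zero on {1, z}.

The projection is applied to the eigen-reduced TPRS basis (projecting
before reduction is the other defensible order; at these basis dimensions
the spans differ negligibly, and the reduced-basis projection keeps the
penalty congruence exact). The volume smooth receives only the usual
sum-to-zero identifiability constraint over the data; its linear component
is retained, because that is where mean-intensity information belongs.

### Thin plate regression splines

One-dimensional TPRS of order 2: radial kernel |x−x'|³ on the (thinned)
unique data values, side conditions T'δ = 0 with T = [1, x], wiggliness
penalty δ'Eδ, eigen-reduced to `basis_dim` (default 10 for both smooths;
the sensitivity runner refits over a grid of dimensions). Index variables
are rescaled to [0, 1] before kernel evaluation, so penalty magnitudes —
and therefore fixed smoothing-parameter values — are comparable across
cohorts. Knots are thinned to at most 200 quantiles of the data.

### Estimation

The penalized Breslow partial log-likelihood
ℓ(β) − ½ Σ_j λ_j β'S_jβ is maximized by Newton iteration with step
halving (gradient tolerance 1e-6, at most 200 iterations). The partial
likelihood is invariant to a constant shift of the linear predictor, which
is used to keep the exponentials bounded. Smoothing parameters are chosen
by maximizing the Laplace-approximate marginal likelihood (LAML) over
log-λ with Nelder-Mead, warm-starting the inner Newton solve. The LAML is
evaluated on the partial likelihood directly; this equals the criterion of
the counting-process Poisson representation (one free intercept per event
time, Breslow ties) after profiling the intercepts, and the package also
ships the explicit risk-set-expanded penalized Poisson fit
(`fit_poisson_expanded`), which reproduces the direct coefficients to
about 1e-10 and serves as a permanent internal consistency check.

The posterior covariance is V = (Ĥ + S_λ)^{-1} (inverse penalized
information), the standard Bayesian-spline interpretation. All Wald
intervals, smooth confidence bands and the simulation-based credible
intervals below derive from it.

### Risk profiles and credible intervals

Participants are ranked by their fitted intensity contribution
Σ_k ŵ(z_k) p_ik within PA-volume quartiles (and overall). The high-risk
profile is the mean histogram of the top decile of that ranking, low-risk
the bottom decile, average the middle quintile — averages of observed
histograms, so profiles are realistic activity patterns by construction
(cutoffs configurable). Profile hazard ratios draw β ~ N(β̂, V) (default
10,000 draws, seeded) and report the median and the 2.5/97.5 percentiles
of exp(Σ_k w_β(z_k)(p_k^a − p_k^b)). Because the log-HR draws are
Gaussian, the median equals the plug-in estimate up to Monte-Carlo error.
Profile-by-volume curves interpolate low→high-risk profiles within each
quartile and are referenced to the overall median volume with the overall
average-risk profile (that reference maps to HR = 1 exactly); they add the
volume-smooth difference between the quartile mean volume and the
reference volume.

## Feature extraction

Epochs below 3 mg are classified as sleep: excluded from the histogram
(tracked as `sleep_fraction`) but included in volume. Values above
2000 mg are capped, and everything above 500 mg is pooled into a terminal
500–2000 mg bin whose representative is pulled in to 600 mg — the
midpoint (1250 mg) would hand the nearly empty tail extreme leverage.
Default bin edges: 5-mg bins up to 100 mg (where most mass and the
high-risk region lie), ~10-mg bins to 250 mg, 25-mg bins to 500 mg, with
60, 125 and 300 mg forced to be edges so the sedentary / slow / moderate /
brisk walking-equivalent time budgets align exactly with bin boundaries.
Wear validity requires ≥3 distinct days and coverage of all 24 hours of
the day, pooled across days. Time-in-range summaries allocate
(1 − sleep_fraction)·1440 minutes per day across bins by relative
frequency.

## The synthetic cohort generator

Ground-truth data for every stage. Per person, epoch intensities follow a
five-component mixture — sleep (<3 mg), sedentary (3–60), light (60–125),
moderate (125–300), vigorous (300–2000) — with truncated log-normal
intensities within components and Dirichlet person-level variation in the
component time budget. The Dirichlet mean reproduces the published overall
time budget (7.2 h sleep, 13.2 h sedentary, 140/62/7 min in the three
walking-equivalent ranges); concentration 35 gives a population volume SD
near 8 mg; the component medians/spreads put the median volume near 28 mg
and ~0.2% of epochs above 500 mg. Mortality is proportional hazards with
constant baseline hazard (inverse-transform sampling; closed-form survivor
function for oracle tests), administrative censoring at 6.4 years, and
defaults calibrated to a marginal mortality rate near 22 per 1000.

The default true volume effect is piecewise linear in the published per-mg
segment log-HRs (log 0.91 below 20 mg, log 1.01 to 30 mg, log 1.05 to
80 mg, log 0.98 beyond), centered at 28.4 mg. The default true weight
function is a smooth two-bump shape — positive below ~100 mg, negative
above ~250 mg — vertically centered so the population-mean contribution is
~0 (a constant shift is unidentifiable anyway) and scaled so that the
*constrained* (affine-removed) weight function separates the top- and
bottom-decile profile histograms by log(1/0.67) ≈ 0.40, matching the
published adjusted high-vs-low profile contrast. The constrained quantity
is the right calibration target: a large share of the raw contribution
Σ w(z) p(z) is collinear with volume and invisible to the profile
contrast. Covariate log-HRs and marginals follow the published adjusted
model and cohort table; covariates are drawn independently of activity,
so (unlike a real cohort) unadjusted and adjusted activity effects
coincide in expectation.

Two sampling routes are distributionally equivalent and share the
histogram definition: exact per-epoch sampling (small n, epoch CSV
export), and multinomial counts over a 1-mg fine grid (large n; within-bin
placement at cell midpoints is the only approximation, immaterial at 1 mg
resolution).

**What the generator does not emulate:** device noise and non-wear,
circadian autocorrelation, covariate–activity confounding, delayed entry,
competing risks. Passing tests therefore validate the estimation
machinery under a proportional-hazards world with realistic marginals,
not robustness to those real-data features.

## Validation-experiment design and numerical choices

* Ties: Breslow everywhere (keeps the Poisson equivalence exact); KM and
  log-rank order deaths before censorings at tied times; volume-quartile
  ties go to the lower quartile.
* The recovery and calibration simulations fix the smoothing parameters at
  the light fallback values (λ_vol = 1e-3, λ_int = 0.03 on the rescaled
  penalties; edf ≈ 8–9 and ≈ 4) rather than re-selecting by LAML in every
  replicate. At the calibrated effect size and a few hundred events, LAML
  legitimately prefers the null model in a share of replicates (and
  mgcv's REML behaves the same way on matched data) — informative about
  power, but it would turn a shape-recovery comparison into noise and put
  model selection inside the coverage experiment. With selection active,
  intervals for the profile contrast should be read as conditional on the
  smooth being retained.
* Segment hazard ratios are chords of the fitted volume smooth,
  exp[(f̂(b) − f̂(a))/(b − a)]; the low segment is evaluated from the
  observed minimum volume to 20 mg, since below ~10 mg the synthetic
  cohort has no data and the spline would extrapolate linearly.
* Cholesky solves fall back to a jittered factorization when the penalized
  information is near-singular (extreme λ); convergence below the 1e-6
  gradient norm is then reported honestly via the `converged` flag and a
  warning rather than an exception (hard failure only above 1e-2).
* Posterior draws use a jittered Cholesky of the relevant covariance
  block; identical profiles short-circuit to HR = 1 with a zero-width
  interval.
* Empty histograms (no epochs ≥3 mg) are dropped from model fits — they
  carry no intensity information — and flagged, not errored, in feature
  extraction.

## Known limitations

* Interval coverage inherits the usual penalized-smoother caveat: bands
  are approximately across-the-function, not pointwise-exact, and REML/
  LAML smoothing biases steep features in data-sparse regions (the low
  end of the volume range) toward flatness at modest event counts.
* The center-effect variance is recovered only to within roughly ±50% with
  22 centers — a small-number-of-levels limit, not an implementation one.
* Profile construction reuses the data that fitted ŵ; the published
  decile/quintile construction is followed, but the contrast between
  selected extremes is mildly optimistic by construction. The credible
  interval quantifies posterior uncertainty in ŵ, not the selection step.
* Efron ties, stratified baselines, time-varying effects and non-Gaussian
  frailties are out of scope.
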