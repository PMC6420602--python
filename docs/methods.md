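# Methods

## Problem

Glaucomatous visual-field (VF) progression must be distinguished from
test–retest variability in longitudinal perimetry. `vfprog` implements two
families of per-eye progression predictors on Humphrey 24-2 series —
classical trend-based metrics, and a spatiotemporal boundary-detection
predictor that looks for *change in the spatial correlation structure* of
the field rather than change in its mean — together with the evaluation
framework used to compare them against a clinical reference label.

## The 24-2 grid and the anatomical dissimilarity

The 24-2 pattern has 54 locations on a 6° lattice; the two blind-spot
locations (ids 26 and 35 in reading order) are excluded, leaving 52.
Each retained location carries its Garway-Heath optic-disc entry angle (the
angle at which the location's nerve-fiber bundle enters the disc, in
degrees), shipped as a packaged table.  For adjacent locations i, j (queen
adjacency by default — both rules are supported; rook is a strict subset)
the dissimilarity is

    z_ij = circ(|angle_i − angle_j|) / max over adjacent pairs,

with `circ(d) = min(d, 360 − d)`, so z ∈ [0, 1] and the grid maximum is
exactly 1.  Normalizing by the grid-wide (cohort-independent) maximum gives
the spatial-smoothness parameter α a stable scale.  Locations straddling the
temporal raphe have very different entry angles, so raphe-crossing pairs
have z near 1 while pairs within a nerve-fiber bundle have z near 0.

Left-eye (OS) input is mirrored onto right-eye orientation at read time by
reversing each row of the reading order, which maps blind spot onto blind
spot; the 24-2 point set is not mirror-symmetric in coordinates (nasal
extension), so coordinate reflection would not work.

## Trend metrics

* **GI** — per-test mean sensitivity regressed on time by OLS; predictors
  are the slope (dB/year), its two-sided p-value, and their product.
* **PLR / P1–P4** — per-location OLS with one-sided p-values for
  deterioration (slope < 0); the four smallest p-values are the predictors.
  One-sidedness follows the permutation-of-PLR construction; a two-sided GI
  p is kept because the GI slope's sign enters separately.
* **MS** — mean of location slopes with p < 0.01; defined as 0 when no
  location qualifies ("no evidence of change").
* **PoPLR** — S = Σ −ln p over locations with p < 0.05; the null permutes
  the visit order jointly across locations (whole fields move together,
  preserving within-test spatial correlation).  With T visits and
  T! ≤ n_perm all orderings are enumerated exactly (p = #{S* ≥ S}/T!);
  otherwise p = (1 + #{S* ≥ S})/(n_perm + 1) over random permutations
  (default n_perm = 1999).

Degenerate conventions keep predictors defined on short truncated series:
fewer than 3 time points → slope 0, p 1; exact fit with negative slope →
p 0; exact fit otherwise → p 1.  These conventions matter at early
truncation cutoffs, where many eyes have only a handful of visits.

## The boundary-detection model

Each visit's 52-vector y_t is modelled as a conditional-autoregressive
(CAR) Gaussian field:

    y_t ~ N(μ_t · 1, τ²_t · Q(α_t)⁻¹)
    W_ij(α) = exp(−α z_ij)  on adjacent pairs, else 0
    Q(α) = ρ (D(α) − W(α)) + (1 − ρ) I,   D = diag(row sums of W)

ρ = 0.99 is fixed (not estimated): it guarantees Q is positive definite
(smallest eigenvalue ≥ 1 − ρ) while keeping the field close to an intrinsic
CAR.  Large α kills the weights across dissimilar pairs — boundaries in the
correlation surface; α near 0 gives uniform smoothing.

The per-visit parameters θ_t = (μ_t, ln τ²_t, ln α_t) get a separable
matrix-normal prior

    Θ ~ MN(δ 1ᵀ, Σ, Ψ(φ)),   Ψ(φ)_ts = exp(−φ |v_t − v_s|),

with δ ~ N(0, 1000 I), Σ ~ inverse-Wishart(df 5, scale I), and φ uniform on
(−ln 0.999 / max-gap, −ln 0.01 / min-gap) — i.e. from "temporal correlation
at least 0.999 across the farthest visits" to "at most 0.01 across the
closest".  Log transforms keep τ² and α positive.

Inference is Metropolis-within-Gibbs: conjugate Gaussian updates for δ,
conjugate inverse-Wishart updates for Σ, 3-dimensional random-walk
Metropolis per θ_t block, and a logit-space random walk for φ, with
adaptive proposal scaling during burn-in targeting ≈ 35% acceptance.
Chains start at the per-visit profile likelihood (μ at the field mean; τ²
profiled analytically over a coarse α grid), which removes a long burn-in
transient.  Defaults: 10,000 burn-in, 10,000 kept, thin 10 (1,000 stored
draws); tests and the pipeline use reduced presets (stated below).  A Tobit
variant (left-censoring at the 0 dB floor, handled by Gibbs refreshing the
latent values from their univariate truncated conditionals) is available
behind `likelihood="tobit"`; the default is Gaussian since the simulated
cohorts rarely touch the floor.

The progression predictor is computed per posterior draw:
CV⁽ˢ⁾ = sd({α_t}) / mean({α_t}) with the (T−1)-denominator sd, summarized
as cv_mean, cv_sd, and cv_mean × cv_sd.  Computing the CV per draw (rather
than the CV of posterior means) is what makes a posterior SD of the CV
well-defined.  The model needs only two visits; the trend metrics need
three.

## Synthetic cohorts

The simulator draws each visit's field from the same CAR law and adds
heteroscedastic measurement noise sd = σ0 + σ1·max(0, 30 − true dB) — a
hinge capturing the inverse sensitivity–variability relationship — then
clamps to the 0–50 dB instrument range (clamping, not redrawing, so means
are only negligibly biased; < 1% of values are affected at the defaults).

Mechanisms: `stable` (flat mean, constant α), `global_trend` (whole-field
mean declining, default −1.5 dB/year), `sector_trend` (only a superior-nasal
wedge declines), `correlation_shift` (flat means, log-linear α drift,
default 3-fold over the 2.6-year mean follow-up).  The last mechanism is
the one the boundary-detection predictor targets, and its per-visit means
do not trend with time — which is why the CV predictor is uncorrelated with
the trend metrics on mixed cohorts.

Cohort defaults mirror the clinical descriptives the toolkit was designed
around: 26% progressing, visit counts 2 + Poisson(5.4) clipped to [2, 21]
(mean 7.4), follow-up Gamma(2) with mean 2.6 years clipped to [0.2, 9.4].
Visit times: baseline at 0, final visit at the configured follow-up,
interior visits uniform.  Mechanism mix among progressors defaults to 1/3
each.

**Parameter scales.** τ² = 1 dB² gives ≈ 3 dB of median between-location SD
after propagation through Q⁻¹ at the default smoothness.  α0 = 40 places
the smoothness parameter where a single 52-location field is informative
about it: most adjacent pairs have z ≈ 0.02–0.2, so the weights
exp(−α z) respond to α only when α·z is order 1; at α ≈ 40 the per-visit
posterior sd of ln α is ≈ 0.24, comparable to the ln 3 ≈ 1.1 drift the
`correlation_shift` mechanism spreads across visits.  At α near 1 the
weights are insensitive to α and no method could recover the drift from
data of this size.

What the simulator does **not** emulate: staircase psychophysics (noise is
Gaussian, not frequency-of-seeing), learning and fatigue effects,
floor-inflated variability beyond the hinge, long-tailed visit spacing, or
eyes mixing several mechanisms.  Passing tests therefore show the
machinery is correct under the stated generative assumptions, not that the
predictors attain any particular accuracy on clinical data.

## Diagnostic evaluation

Every metric's predictors are combined by logistic regression against the
binary progression label; the fitted probability is the diagnostic score.
Models are compared by AIC = 2k − 2 logL, the full AUC (Mann–Whitney, ties
at 0.5), and the partial AUC over the clinically relevant specificity band
85–100%, normalized by the band width (0.15), so chance = 0.075 and a
perfect classifier = 1.  Marginal and added-over-GI significance are
likelihood-ratio tests of nested fits.  AUC differences use the paired
DeLong test; pAUC differences use a paired, class-stratified bootstrap
(default 2,000 resamples).  Operating thresholds maximize sensitivity
subject to specificity ≥ 85% over midpoint candidates, ties broken toward
higher specificity then lower threshold.  All fits and ROC summaries are
in-sample (a development-cohort analysis); no cross-validation is
performed, and the reported performance should be read accordingly.

Eyes missing a metric (too few visits) are dropped listwise per model fit,
with the retained count recorded.

## Longitudinal early detection

Metrics are recomputed on truncated series at half-year cutoffs (0.5–4.5
years by default).  At each cutoff, AUC and pAUC come from logistic models
*refit* at that cutoff, while sensitivity and specificity apply the
*final-study* coefficients and thresholds to the cutoff predictors — the
operating rule is fixed once at the end of model development, as it would
be in clinical deployment.  Eyes enter a metric's summary once they accrue
its minimum visits (2 for the boundary-detection predictor, 3 for trend
metrics); cells where a class vanishes are reported missing.  Per-eye
randomness (MCMC and permutation seeds) derives from the eye id, never
from cohort order or cutoff, so the final cutoff reproduces the full-study
summaries exactly.

Time to first diagnosis walks each progressing eye's visits in order,
recomputes predictors on the accumulated history, and records the first
visit at which the fixed model crosses its threshold (days = years ×
365.25); undetected eyes carry the last-visit day.

## Problem sizes used by the test suite and acceptance script

The bundled checks run the sampler at reduced presets chosen as the
package's own desk-scale defaults: 2,000/2,000/thin 4 for the
parameter-recovery study (20 + 20 eyes, 10 visits), 200–400 burn/keep for
pipeline-level runs over ~100–190 eyes, and n_perm = 199 for permutation
tests inside simulations.  The acceptance script simulates a 191-eye
cohort at the default study conditions and reports cohort descriptives,
AIC/AUC/pAUC per model, the correlation between the boundary-detection and
GI scores, operating characteristics at the specificity ≥ 85% threshold,
and mean detection days for GI and GI+STBound.

## Known limitations

* The boundary-detection observation model has no independent
  measurement-noise (nugget) term; measurement noise attenuates α
  estimates.  Parameter-recovery checks therefore simulate from the
  model's own law; cohort-level runs use the noisy generator and inherit
  the attenuation.
* φ (temporal decay) is weakly identified from a single eye's series; its
  posterior often resembles the prior.  The CV predictor does not depend
  on φ being well identified.
* In-sample evaluation overstates absolute performance; the framework is
  for *comparing* metrics under identical conditions.
* The Tobit likelihood refreshes latent censored values one location at a
  time, which mixes slowly for heavily censored fields.
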