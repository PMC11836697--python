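# Methods notes

## The decomposition model

Individual first nest date (FND, day-of-year) for female *i* in year *t* is
modelled with within-subject centring: every covariate *x* is replaced by
the female's own mean x̄ᵢ and her deviation from it, Δx = x − x̄ᵢ. Regressing
FND on Δt and t̄ separates the mean within-individual change per year
(b_FND,Δt: plasticity plus within-life change) from the change associated
with females that breed on average later in the study (b_FND,t̄: population
composition). Because t = t̄ + Δt column-wise, the model `FND ~ t̄ + t` is an
exact linear reparameterization whose t̄ coefficient estimates the
within−among difference directly, with a standard error; the package
verifies this identity to machine precision on every dataset it is given.

Individual means are grand-centred by subtracting the mean of the per-female
means over *females* (each female counted once, so an unbalanced panel does
not tilt the centring toward frequently-observed females). Per-female Δ
columns sum to zero exactly; year stays in calendar units so slopes read as
days per year.

Assumptions inherited from this framework: effects are linear and additive;
the within-individual slope is common across females (no random slopes); an
individual's mean covariate is measured by her observed seasons (females
seen once contribute no within-individual information but still inform the
among-individual slopes).

## Attribution by slope products

The contribution of predictor *x* to the FND trend at a level is the product
of (i) the predictor's own temporal trend at that level — OLS of Δx on Δt,
and of x̄ on t̄, one row per observation — and (ii) its effect on FND from
the full centred model. The effect slopes come from the *OLS* variant of the
full model: with crossed random effects and unbalanced data the partial
contributions would not add up exactly to the totals, whereas with OLS the
omitted-variable-bias algebra closes. Two "unexplained" remainders are
reported: the totals minus the sum of products (the quantity that completes
the decomposition by construction) and the full model's own Δt / t̄
coefficient (the direct estimate of the trend not mediated by the
predictors). On balanced designs with Δ-components orthogonal to
mean-components the two coincide; the test suite checks the closure at
1e−6. Percentage shares are computed from unrounded products and rounded
only at display time.

Contributions carry no uncertainty intervals; a delta-method or bootstrap
band would be a natural extension but is out of scope.

## Mixed-model machinery

Inference fits use crossed random intercepts for year of breeding and for
female. The solver is a profiled (RE)ML criterion specialised to two
crossed random-intercept factors: with variance ratios γ = (σ²_f, σ²_y)/σ²
fixed, β and σ² have closed forms via the Woodbury identity, and because
Z'Z is block-diagonal-plus-incidence ([diag(counts_f), N; N', diag(counts_y)]),
every solve Schur-complements onto the year block, so one likelihood
evaluation is O(q_f·q_y²) — milliseconds at ~1400 females × 31 years. The
2-D profiled surface is minimized by Nelder–Mead on the log-ratio scale
(derivative-free, so no numeric-gradient noise near the boundary) from two
starts, with the γ = 0 boundary — either or both variances exactly zero —
scored as explicit additional candidates; convergence is certified by a
successful search at the optimum or by two independent searches agreeing
there (tolerances: xatol 1e−8 on log γ, fatol 1e−9; iteration cap 2000).
The solver reproduces `lme4::lmer` REML and ML log-likelihoods, fixed
effects, standard errors and variance components on a frozen 103-observation
panel to ≤ 2e−5 (frozen oracle values in the test suite). Per-term tests are
likelihood-ratio χ² (df = 1) from ML refits with and without the term.

Fixed-effect standard errors are the usual REML model-based ones; no
small-sample (Kenward–Roger type) correction is applied.

## Season metrics and filtering

* Day-of-year is 1-based (1 Jan = 1) with leap years counted (29 Feb = 60).
* Estimated clutch frequency adds 1 / 2 / 3 clutches for internesting gaps
  in (20, 30], (30, 45], (45, ∞) days; gaps are computed between consecutive
  observed clutches within one season, never across years, and no cap is
  imposed on the total added per season. Thresholds are configurable; the
  1/2/3 additions are fixed.
* Breeding experience is binary — 0 for a female's first recorded season, 1
  thereafter — and the history includes seasons in years excluded from the
  phenology analyses (a female first seen in a poorly-surveyed year is still
  a returner later).
* Mean size is the mean over all carapace readings of all her events that
  season, i.e. the size covariate is season-specific; career means are
  formed downstream by the centring step.
* Clutches with an unknown female feed only the population summaries (first,
  median — over all clutches —, last, duration, assignment proportion).
* Default year filters mirror a 1992–2022 programme: 1992/2000/2020/2021
  excluded from all phenology, 1993–1994 additionally from the
  individual-level dataset (unmarked females at the start of a study cannot
  be told from returners within one remigration interval).

## Window search

Candidate windows are all (open, close) day-of-year pairs with width ≥ 7
inside doy 1–140 (before the nesting season) by default. Windows live on a
365-day grid; in leap years dates from 1 March onwards shift back one day
and 29 February shares slot 60. Each window is scored by the AICc of the
OLS regression of the annual metric on the window mean, counting k = 3
parameters (intercept, slope, residual variance); the intercept-only null
(k = 2) provides the delta. Years with a missing response or an incomplete
window (less than 50% of days by default) are dropped from the entire
search so that all windows — and the null — are scored on the same years.
Ties break toward narrower, then earlier windows. A permutation check
(shuffle response years, re-search, record the best delta; 100 permutations
by default, seeded) gauges how much an exhaustive search overfits noise.

## What the simulator does and does not emulate

The generator reproduces the statistical structure the analysis assumes:
geometric recruitment growth calibrated once so observed annual clutch
counts rise ≈55 → ≈400 (≈7-fold) across 31 seasons; careers of 1–10 seasons
(median 2) at 2–4-year remigration intervals; 1–6 clutches per season
(median 2) at 10–15-day internesting intervals; a daily SST series built as
a seasonal sinusoid + 0.05 °C/yr trend + year effects (sd 0.35 °C) + AR(1)
daily noise (sd 0.45, φ = 0.8), so the 29 Mar–29 Apr window mean follows
the planted linear trend; and an FND model with plasticity −6.47 d/°C on
the realized window mean, −3.75 d for returning breeders, −4.5 d per
additional clutch, −0.45 d/cm within-individual growth, +0.31 d/cm among
individuals, individual / year / residual sds of 8 / 3 / 9 d, and a 10%
chance that any clutch goes unobserved (identities are never lost, only
events — this is what exercises the ECF imputation and perturbs observed
first nest dates). Opposed size signals arise mechanistically: individuals
grow (0.21 ± 0.1 cm/yr between females; the spread is what makes the
within-size effect identifiable next to Δt) while later recruits are
smaller (−0.25 cm/yr), as in a recovering population.

It does not emulate: unassignable clutches (every simulated event carries
the female's identity), tag loss or detection modelling, spatial SST
structure, foraging-ground heterogeneity, survival, or any feedback of
phenology on fitness. Passing recovery tests therefore show that the
*estimator* is unbiased and its uncertainty calibrated under the assumed
data-generating process — not that real data meet those assumptions.

Calibration note: with purely geometric recruitment, matching the ≈55→≈400
endpoints yields more total clutches (~6900) and females (~1400) than a
real recovery whose middle years grew unevenly; the endpoint growth pattern
was prioritised since the trend decomposition operates on rates of change.

## Recovery testing: which slopes are checked, and why

The planted-parameter acceptance check (200 pipeline replicates at default
size, mixed full model, two reported standard errors) covers the
coefficients that map one-to-one onto planted parameters: ΔSST, ΔBE, ΔECF
and ΔSize effects, and the among-size effect (recruit size). The remaining
among-level coefficients are *structurally* confounded in this design and
are deliberately not treated as recovery targets: a female's mean
experience and mean clutch frequency are functions of her career length and
timing, which also carry the growth-since-recruitment signal that the
single mean-size regressor cannot absorb (the among-experience coefficient
is accordingly biased by about −1 d relative to the planted −3.75 d — an
analogue of the real-world observation that among-individual experience
effects exceed within-individual ones). The mixed model — not OLS — supplies
the standard errors here because SST and the year intercepts are year-level:
with ~25 distinct years, OLS per-row standard errors for SST-like covariates
understate the sampling variance several-fold.

Problem sizes used by the tests and the acceptance script: 200 replicates
for effect recovery, 50 for window recovery, 100–200 permutations where
permutation checks run, and a 14-year / ~500-event configuration for
structural unit tests.

## Numerical conventions

* OLS via statsmodels; rank deficiency is detected by QR and rejected with
  the offending column names rather than silently pseudo-inverted.
* Missing values: empty fields in CSV, null in JSON, NaN in memory; never
  sentinel numbers.
* All simulation randomness flows from one `numpy` `default_rng(seed)`;
  identical seeds give byte-identical pipeline outputs.
* FND values are integers (days); the simulator rounds the latent linear
  predictor, which adds ≤ 0.5 d of quantization to the residual.
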