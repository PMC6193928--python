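# Methods

This note documents the models and procedures implemented in `driftwatch`,
the defaults they ship with, and the choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Presence reconstruction

A detection is one antenna read (timestamp, antenna id, tag code). Readers
cycle at 10 energize/receive cycles per second, so a stationary fish
produces a read every 0.1 s; `dedupe_detections` thins these bursts with a
greedy anchored rule (keep the first read, then the next read at least
`min_spacing_s` — default 1 s — after the last *kept* read). Thinning is
idempotent and cannot move bout boundaries because the spacing is far below
the bout gap threshold.

`segment_bouts` applies the gap rule: consecutive detections of one
individual at most `gap_threshold` apart (default 2 h, **inclusive**
boundary — "within two hours" merges a gap of exactly two hours; the rule
must be fixed one way for determinism) share a bout, whose start/end are the
first/last detection instants. All three antennas are pooled as a presence
proxy; antenna identity is retained only as bout metadata. A
single-detection bout has zero duration but is kept — the animal was
demonstrably there — and counts as full membership of its containing hourly
bin for presence and egg allocation. All time between the first and last
detection of a bout is treated as presence; the array geometry offers no
defensible way to subtract within-bout absence.

Eligibility reflects the two species' lifespans: asp bouts enter the
analysis only when bout start − tagging date ≥ 365 days (capture,
anaesthesia and surgery disturb behaviour in the tagging season), bleak
bouts from one day after tagging. Only female asp feed the egg model; males
are tracked but excluded. Bouts straddling a configured season window are
clipped to it.

## Egg availability model

Egg output at the spawning season cannot be read off the length measured at
tagging (the fish has grown since), so:

1. **Population growth curve.** L(t) = L∞(1 − e^(−K(t−t₀))) is fit by
   least squares to the age–length pairs from scale readings at first
   capture (both same-season and earlier-tagged females contribute pairs).
   The initializer is fixed — L∞ = 1.05·max length, K = 0.2, t₀ = 0 — so
   the fit is deterministic and order-invariant; t₀ is bounded below the
   youngest observed age. At least four distinct ages are required. Note
   that t₀ (and through it K) is the weakly identified parameter of this
   curve when the observed age range starts well above 0; individual
   projections are robust to this because of the anchoring below.
2. **Individual anchoring.** Each female's curve is individualized by
   rescaling the asymptote through her observed tagging length:
   L∞ᵢ = TL_tag / (1 − e^(−K(age_tag−t₀))). Evaluating at
   age_tag + elapsed years gives the projected length; zero elapsed time
   returns the tagging length exactly. A re-measured length from a
   recapture in the spawning year replaces the prediction outright.
   Rescaling (rather than an additive offset) keeps projections positive
   and asymptotically bounded.
3. **Weight.** W = a·TLᵇ with a = 0.00744, b = 3.046. These coefficients
   are only dimensionally consistent with TL in centimetres and W in grams
   (with millimetres they produce tonne-scale fish); the package fixes
   those units.
4. **Fecundity.** eggs = GSI·W / egg mass, with defaults GSI = 0.12 and
   egg mass = 3.5 mg taken from the cyprinid literature range. Both are
   explicit configuration, not fitted quantities, and every reported
   *proportion* — diel shares, z-scored model coefficients, R², τ — is
   invariant to them (verified to 1e-9 by the acceptance suite).

Each female's eggs are then distributed at one uniform rate over the union
of her season bouts ("the time spent on the spawning ground"): a bout twice
as long receives twice the eggs, and per-bin amounts are normalized so the
binned series conserves her fecundity to float precision. A female whose
only presence is a zero-duration bout contributes her whole output to that
bin.

## Day/night geometry

Sunrise and sunset come from the NOAA solar-calculator algorithm
(Julian-century ephemeris: geometric mean longitude and anomaly, equation
of centre, apparent longitude, corrected obliquity, then declination and
the equation of time), iterated three times on the event hour, at zenith
90.833° — the conventional "official" sunrise (refraction plus solar disc).
The day/night boundary for "night spawning" is not defined anywhere
upstream of this package; official sunrise/sunset is the documented default
and civil twilight (zenith 96°) is an exposed alternative. Latitudes inside
the polar circles are refused. Each hourly UTC bin carries an exact day
fraction (day + night fractions sum to one); share computations use the
fractional weights, while the binary model covariate uses the majority
label (night = 1). Site default: 49.578497° N, 15.251671° E.

Diel shares are mean ± SD over groups: season days for eggs (dispersion
across nights), individuals for the predator (dispersion across fish);
groups with zero total are excluded and counted. The two dispersions are
deliberately different summaries — a day-level SD describes how variable
the nightly egg fraction is, an individual-level SD how variable predator
nocturnality is.

## Mixed models

Both study models are Gaussian LMMs with one grouping factor, fit by
profiled REML (ML for model comparison) over the relative random-effect
Cholesky factor Λ (Ψ = ΛΛ′ = G/σ²) — the lme4 parameterization, with β and
σ² profiled out analytically and all per-group quantities reduced to
cross-products. L-BFGS-B handles the bounded optimization (diagonal of
Λ ≥ 0); a short damped-Newton polish with numeric derivatives then pins the
optimum to ~1e-11 so that refits of numerically perturbed but equivalent
inputs agree far inside reporting precision. A fit whose random-effect
covariance lands on the boundary is flagged singular, never hidden. The
implementation reproduces R's `lmerTest` on reference fits (estimates, SEs,
Satterthwaite df, REML log-likelihood, ML AIC) and is cross-checked against
`statsmodels` MixedLM in the test suite.

- **Satterthwaite df** for each fixed effect: df = 2v²/(∇v′A∇v) with
  v(φ) = [C(φ)]ⱼⱼ, C(φ) = (X′V(φ)⁻¹X)⁻¹, φ = (vech G, σ²), A the inverse
  observed information of φ̂; gradient and information by central
  differences of the unprofiled REML log-likelihood. The df are clamped to
  [1, n − p], and a non-positive curvature denominator (boundary fits)
  falls back to the OLS residual df.
- **Nakagawa–Schielzeth R²**: σ²_f = var(Xβ̂),
  σ²_r = mean over observations of zᵢ′Ĝzᵢ (exact for random intercepts,
  the standard generalization under random slopes), R²m = σ²_f/(σ²_f +
  σ²_r + σ²_e), R²c = (σ²_f + σ²_r)/(σ²_f + σ²_r + σ²_e).
- **Stepwise selection**: backward elimination of fixed effects by ML-AIC
  with the random structure held fixed; every candidate AIC is logged; the
  selected model is refit by REML for reporting.

Model specifications: the egg model (one row per hourly bin) regresses egg
availability on period of day, day of year, per-bin predator presence
(sum of individual presence fractions) and temperature, with a random
intercept by year — year is the random effect named for this model, and the
alternative (predator identity) remains a configuration switch. The
predator model (one row per individual × bin) regresses the individual
presence fraction on period, day of year and eggs (temperature enters the
full model and is available to stepwise), with a correlated random
intercept and date slope by individual — date is the only continuous
within-individual covariate spanning the season, hence the slope variable.
It is a linear (not logistic) model on the presence fraction, mirroring
t-statistic-based reporting. All variables, response included (a
configuration flag), are centred and scaled; the binary period indicator is
coded night = 1 then z-scored like the rest so coefficients are comparable
across covariates of very different native range. Temperature joins the
design by nearest logger reading within 90 min; more distant bins are
flagged and dropped with a count.

**Kendall's τ-b** (tie-corrected) tests the daily egg–predator association.
The p-value is exact by enumeration for n ≤ 8, a seeded vectorized
permutation test (9999 permutations, add-one estimator) for n ≤ 30, and the
tie-corrected normal approximation above.

## The synthetic study

The generator emulates the study conditions: two consecutive 14-day
early-April seasons; per season 230 tagged females (mean total length
≈ 49.5 cm, SD ≈ 8, implied by ages 3–9 on a von Bertalanffy truth curve
L∞ = 85 cm, K = 0.13, t₀ = −0.8 with 5% individual asymptote variation),
150 males (47.0 ± 5.3 cm), 23 bleak; visits of gamma-distributed length
(shape 2, mean 6 h), each independently nocturnal with probability 0.63
(placed inside the night window sunset→sunrise, else inside daylight);
bleak attending ~90% of days, covering ~90% of the daylight window, leaving
before sunset and arriving around sunrise, with an 8% per-night chance of a
brief nocturnal excursion; detections as a thinned Poisson stream snapped
to the 10 Hz reader grid (so inter-read times never violate the cycle
ceiling), with a 2% chance a whole visit goes undetected; hourly
temperature with a +0.25 °C/day trend, a 1.2 °C diel cycle and AR(1) noise.

Planted mechanisms give the models a recoverable truth: female arrivals
decline across the season and rise with the daily temperature anomaly;
bleak attendance rises with date and with relative daily egg load. Visit
nocturnality is the planted diel contrast. The truth record stores every
individual's visits, fecundity, the realized detection spans, and the
aggregate nocturnal egg fraction.

What the generator does **not** emulate — and hence what green tests do not
establish about field data: river hydraulics and egg drift, antenna
detection-range physics (misses are Bernoulli per visit, not
distance-dependent), tag loss and mortality, inter-annual differences in
counts or behaviour (the year random intercept is therefore genuinely zero
at default conditions and the egg-model fit is reported singular with
marginal = conditional R²), within-visit movement between antennas, and any
correlation between a female's size and her diel preference.

Scales used by the checks, chosen to keep a laptop-class run fast: module
tests use a 40-female/7-day configuration; study-scale recovery uses the
full defaults over 20 seeds; mixed-model recovery uses 25 groups × 80
observations (50 replicates of 15 × 40 for stepwise); the pooled detection
rate defaults to 0.002 Hz, which bounds bout-edge error at a few minutes
against 6-hour visits.

## Numerical choices and degenerate inputs

- Gap boundary inclusive; dedupe strict ("closer than" drops).
- Zero-duration bouts: full membership of the containing bin; skipped in
  rate allocation when the female also has positive-duration bouts.
- Growth fit refuses fewer than four distinct ages; projection refuses
  age ≤ t₀.
- `centre_scale` refuses constant columns by name (their z-score is
  undefined).
- `night_share` excludes and counts zero-total groups instead of emitting
  NaN; an all-zero series yields an explicit empty summary.
- Grouping factors need ≥ 2 levels; with one observation per group the fit
  degenerates gracefully to OLS estimates.
- The only stochastic reporting step (the permutation p-value) is seeded
  from the run configuration, making whole-pipeline output byte-identical
  across reruns.

## Known limitations

- The individual-anchoring scheme (rescaled asymptote) is one defensible
  choice among several; it is isolated behind `project_length`.
- GSI and egg mass defaults are literature-scale placeholders; absolute egg
  counts should not be interpreted, only their distribution in time.
- The predator model is linear on a [0, 1] presence fraction; predictions
  are not bounded and the residuals are heteroscedastic near the bounds —
  acceptable for effect-direction inference, not for prediction.
- Satterthwaite df rely on numeric curvature of the REML surface; hard
  boundary fits fall back to conservative OLS residual df.
- Temperature is joined by nearest hour; sub-hourly thermal structure is
  invisible.
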