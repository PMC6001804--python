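# Methods

`rewarm` implements the statistical pipeline of a multicenter test–retest
study of the hand cold challenge in systemic sclerosis–related Raynaud's
phenomenon: patients attend on two consecutive days, both hands are
immersed for one minute in 15 °C water, and the rewarming/reperfusion
response is imaged for 15 minutes by laser speckle contrast imaging (LSCI,
15 frames/min, arbitrary perfusion units), standard infrared thermography
(4 frames/min, °C) and mobile-phone thermography (three single images:
baseline, 0 min, 15 min). Analysis starts from ROI-mean time series — the 8
distal phalanges (index–little, both hands) and the 2 dorsa — not from
pixels.

## Summary measures

Per patient × visit × modality, each finger's post-challenge series is
reduced to:

* **DDD** (distal dorsal difference): same-hand dorsum minus finger on the
  baseline image; positive when fingertips are cooler/less perfused.
* **AUC**: trapezoidal integral of the response over [0, 900] s. The one
  extra frame acquired beyond 15 min (for an end-of-run gradient) is
  excluded from the window. The integral uses the raw values, not
  baseline-subtracted values, and AUC is analyzed on the natural-log scale.
* **MAX**: maximum sampled value in [0, 900] s, analyzed on the log scale.
* **GRAD**: slope of value on time over the first 120 s, by OLS over all
  frames in the window (a two-point difference is available as an option).

The finger values are averaged (missing fingers are dropped, and the count
of contributors recorded); the mobile AUC is the mean of its two
post-challenge images times the 900 s window, which is exactly the
trapezoid through the two points and therefore shares units (and is exact
for linear rewarming). Mobile MAX and GRAD are not defined by a two-frame
acquisition and are reported as not applicable. Log transforms reject
non-positive inputs by flagging the record missing rather than zero-filling.

Choices made where the procedure was genuinely open: trapezoidal quadrature
(any reasonable rule agrees to ≪0.1% at these frame rates, which the tests
verify against the closed-form area of a mono-exponential curve); natural
log (ICCs and correlations are invariant to the base); whether DDD is
finger-averaged like the other measures (it is).

## Test–retest reliability

For each measure × modality, a linear mixed model is fitted by REML:

    y_{pv} = center fixed effects (+ optional covariates) + b_p + e_{pv},
    b_p ~ N(0, σ²_patient),  e_{pv} ~ N(0, σ²_resid)

with the largest center as the reference level and visits treated as
exchangeable repeats (no day-1/day-2 fixed effect; a visit effect can be
toggled on). The ICC is σ²_patient / (σ²_patient + σ²_resid); center
variation is excluded because center is fixed. Negative component estimates
are truncated at the boundary and flagged.

The restricted likelihood is profiled to a one-dimensional search over the
variance ratio λ = σ²_patient/σ²_resid, using per-patient sufficient
statistics, so a fit costs O(G·p²) per candidate λ. On balanced
single-center data this REML solution coincides with the classical ANOVA
moment estimators (σ̂²_resid = MSW, σ̂²_patient = (MSB − MSW)/2), which the
acceptance suite checks to 1e-6, and the implementation is cross-checked
against statsmodels MixedLM on unbalanced multicenter data.

95% CIs use a parametric bootstrap (resimulate from the fitted model,
refit, percentile; clipped to [0, 1]), which respects the boundary better
than a Wald interval; the CI method was an open choice. The ICC difference
between two modalities is bootstrapped nonparametrically over patients,
resampling each patient's rows in both modalities together so the pairing
is preserved. Qualitative bands (after rounding to 2 decimals): 0–0.20
slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80 substantial,
0.81–1.00 almost perfect.

## Convergent validity

Two modalities are modeled jointly: each observation gets
modality-specific center fixed effects and a modality-specific residual
variance, and the two patient random intercepts are bivariate normal with
covariance G. The latent correlation ρ = G₁₂/√(G₁₁G₂₂) is 1 when both
techniques measure the same patient-level construct. Residuals are
independent across modalities and visits; "separate random patient
intercepts" is implemented literally, and both visits enter as rows (no
pre-averaging).

G is parameterized through its Cholesky factor so positive
semi-definiteness holds by construction; the cross term uses the
scale-invariant ratio c = L₂₁/L₂₂ (then ρ = c/√(1+c²)), and each modality
is standardized to unit variance internally before optimization, with
estimates mapped back afterwards — together these make the fit insensitive
to the arbitrary units (°C versus perfusion flux), and ρ itself is
invariant to separate affine rescaling of each modality (tested). The
restricted likelihood is accumulated patient-blockwise and maximized by
L-BFGS-B from deterministic moment-based starts (Nelder–Mead polish if the
line search stalls). With G₁₂ pinned at 0 the restricted log-likelihood
equals the sum of the two univariate fits exactly — the bivariate model
nests the univariate one — which is an acceptance property. A dense-matrix
evaluation of the same likelihood serves as the oracle on a tiny dataset.

Confidence intervals for ρ are parametric-bootstrap percentiles clipped to
[−1, 1]. If a patient-level variance collapses to the zero boundary, ρ is
undefined and flagged rather than silently reported as 0. The mobile pair
is analyzed only for DDD and AUC.

The association between each measure and the Raynaud's condition score
(RCS, 0–10, reported each study day) is the RCS fixed-effect slope in the
univariate mixed model, with its standard error.

## Secondary analyses

* **Interobserver differences.** The design (one local observer per center,
  one central re-reader of saved images) cannot support an interobserver
  ICC, so agreement is summarized as the paired mean difference — central
  minus local, after averaging each patient over both visits — with a
  t-based 95% CI.
* **Room temperature.** The visit's mean room temperature is added as a
  fixed covariate to the reliability model and the ICC recomputed; the
  temperature coefficient is reported with a normal-approximation CI. A
  constant temperature makes the coefficient inestimable and the
  adjustment is skipped with a warning.
* **Edge effects.** LSCI flux is attenuated toward the image periphery
  (uneven laser illumination), so little-finger values are artificially
  depressed relative to index fingers; thermography has no such optical
  artifact. Finger-level measures are z-scored within modality × measure
  and regressed on finger position (index = 1 → little = 4 within each
  hand, both hands pooled as replicates) with per-patient random intercepts
  and slopes (statsmodels MixedLM, REML). Standardization makes the slopes
  comparable across modalities and scale-free (verified to 1e-10 under
  rescaling). The linear-in-position form is deliberately simple; whether
  fingers should instead be numbered 1–8 across the camera field is
  configurable, since the artifact is a property of image position.

## Synthetic data

No patient data accompany the analyses, so a generator reproduces the
study design: 6 centers (60 patients centrally, 16–20 at each other site;
159 in total), 2 visits, 10 ROIs, the three modalities at their frame
counts (225 + 1 extra for LSCI, 61 + 1 for thermography, 3 single mobile
images), room temperature ~N(23, 1²) °C, and an RCS per visit.

Rewarming follows a mono-exponential approach to plateau,
value(t) = plateau − drop·exp(−rate·t/60) — the simplest shape consistent
with observed rewarming curves and sufficient to give AUC, MAX and GRAD
distinct information. Patient-to-patient and visit-to-visit variation enter
as vertical shifts of the plateau, so MAX inherits the prescribed variance
components one-to-one and AUC inherits them times 900² (both tested
empirically). A shared latent "vasoreactivity" factor links the LSCI and
thermography patient effects with a prescribed correlation — exactly the
structure the bivariate model estimates, making ρ-recovery well posed. The
rewarming rate varies log-normally between patients and visits and is only
partially shared between modalities (skin temperature lags reperfusion),
giving GRAD its own, lower reliability and cross-modality correlation. DDD
has its own shared patient-level factor. Mobile thermography is the
thermography truth sampled at the three mobile time points plus sensor
noise and small patient/visit-level reading offsets. The edge effect is an
additive per-finger-position trend on the measure scale (negative for
LSCI, positive for thermography by default). An optional per-modality
missingness rate drops whole patient datasets (default 0), emulating
technical faults. The RCS effect on DDD (−0.15 per point by default) is
injected through the generating model.

Default generating values are fixed once to the study conditions: ICC-scale
variance components and latent correlations at the magnitudes the study
reported (e.g. AUC ICC ≈ 0.67, AUC latent correlation ≈ 0.94 LSCI–
thermography and ≈ 0.98 thermography–mobile), curve scales at plausible
physiology (thermography plateau ≈ 31 °C, drop ≈ 7 °C; LSCI plateau ≈ 200
pu, drop ≈ 120 pu; rate ≈ 0.35/min so many hands have not fully rewarmed by
15 min). The scale-free statistics (ICC, ρ, standardized slopes) do not
depend on the absolute scales.

Two additional generators draw summary measures directly from the
hierarchical model — finger-averaged values with exactly prescribed
variance components, correlations, RCS and room-temperature effects
(`simulate_summary_measures`), and finger-level values with a
linear-in-position trend and random slopes (`simulate_finger_measures`).
These are the instruments for parameter-recovery experiments, where the
generating truth must be controlled on the analyzed scale; in them the RCS
is drawn independently of the patient effects so the injected slope is the
only association. What the frame-level generator does **not** emulate:
pixel-level images, hand movement or registration error, non-exponential
(e.g. delayed or biphasic) rewarming, circadian or seasonal drift, and
center-by-patient interactions. Passing recovery tests therefore shows the
estimators are correct under the assumed hierarchical model, not that real
imaging data satisfy that model.

## Numerical choices and limitations

* The profiled univariate REML searches log λ ∈ [−9, +9]·ln 10 with
  endpoint evaluation; hitting an endpoint is reported as a boundary
  (σ²_patient = 0, or σ²_resid → 0 when visits are identical).
* Bivariate optimization uses tight tolerances for point fits and slightly
  relaxed ones inside bootstrap loops, where percentile intervals do not
  benefit from 1e-13 objective precision.
* All randomness flows from a single seed split into named substreams
  (simulation, reliability bootstrap, validity bootstrap, observer
  re-analysis); reruns with the same config and seed write byte-identical
  tables (floats serialized at %.10g).
* Simulation-based checks in the test suite use a few hundred replicate
  studies at the 159-patient design, balancing Monte Carlo error (SE of a
  mean ICC ≈ 0.003 at 200 replicates) against runtime.
* Bootstrap CIs are percentile intervals; they are approximately, not
  exactly, calibrated near the ρ = 1 and ICC = 1 boundaries (empirical
  coverage at the study design is verified to sit in [90%, 99%] at nominal
  95%).
* Whether the original CIs were Wald, profile or bootstrap is unknowable
  from the report they mimic; interval flavors can differ near boundaries.
* The residual-independence assumption between simultaneously imaged
  modalities is a simplification; a residual-correlation extension is a
  natural follow-up and is deliberately out of scope here.
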