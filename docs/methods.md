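# Methods

This note documents the models, conventions and design choices behind
`hubreserve`, in the order the pipeline applies them, and states what the
synthetic-data experiments do and do not demonstrate.

## Connectivity processing

**Framewise displacement.** The verbal definition "average spatial
displacement between adjacent volumes" admits several formulas; we use the
sum-of-absolute-differences convention, FD_t = Σ|Δd_x,y,z| + r·Σ|Δα,β,γ|
with rotations converted to arc length on an r = 50 mm sphere. This is the
convention under which the 0.5 mm scrubbing cutoff is calibrated. FD of the
first volume is 0 by definition.

**Scrubbing.** Volumes with FD strictly above 0.5 mm are censored together
with 1 preceding and 2 subsequent volumes; windows are clipped at run
boundaries and overlapping windows union. A subject is excluded when
strictly more than 30% of volumes are censored. All cutoffs in the package
(FD > 0.5, censored fraction > 0.30, grey-matter mean probability > 0.3) are
strict inequalities. Censoring is applied *after* filtering, by dropping
censored volumes before correlation — temporal filtering needs contiguous
series.

**Denoising order.** Per voxel: linear detrend → zero-phase band-pass →
confound regression. The band-pass is a forward–backward Butterworth of
order 2 per pass (effective order 4, zero phase), 0.01–0.08 Hz. Confounds
(six motion parameters, mean white-matter and CSF signals) are detrended and
filtered identically before the regression; otherwise the regression can
reintroduce frequencies the filter removed. Measured filter response at
TR = 2.23 s: gain 0.997 at 0.04 Hz, attenuation 99.9% at 0.2 Hz.

**Geometry.** All seed spheres are defined in world (MNI, RAS+) millimetres
through the image affine; a voxel is inside a sphere iff its centre lies
within the radius. There is no voxel-index arithmetic across grids, so
anisotropic and shifted grids behave correctly (smoothing sigma is likewise
converted to voxel units per axis from the affine). On a 2 mm grid the 8 mm
sphere contains 257 voxels (lattice count of i²+j²+k² ≤ 16).

**Score conventions.** The seed's own voxels are excluded from the global
average; voxels with r ≤ 0 drop out of numerator and denominator; r is
clipped to ±(1 − 10⁻⁷) before the Fisher transform so perfect correlations
stay finite; an empty positive set yields score 0 with a warning flag.
Zero-variance target voxels are treated as r = 0 (excluded).

## Statistical models

**Transforms.** CSF tau, p-tau, PiB uptake and all connectivity scores are
natural-log transformed and z-scored (per cohort, never pooled across
cohorts) before modelling. Within each model fit, every continuous variable
is (re-)z-scored on the fitted rows, so all reported coefficients are
standardized betas; interaction columns are products of the z-scored main
effects and are not re-standardized (a conventional choice; re-standardizing
the product would change the coefficient but not the test).

**Estimation.** All cohort models are linear mixed models with a random
intercept per acquisition site, fitted by maximum likelihood — ML rather
than REML because AIC comparisons across fixed-effect structures require it.
AIC = −2 log L + 2k with k counting fixed effects plus variance components.
Two numerical safeguards: (i) when the site variance is singular (one site,
or the ML estimate at the zero boundary) the fit falls back to a
fixed-intercept OLS model with a logged warning; within any AIC comparison
set (full vs. reduced; the polynomial order candidates) all models are
forced onto a common estimation path, since AICs computed under different
parameter counts are not comparable. (ii) ML profiles the residual variance
with an n denominator; with the dense family-dummy designs used here that
understates the scale, so mixed-model standard errors carry the n/(n−p)
small-sample correction and p-values use the t reference with n−p degrees
of freedom, matching the OLS path. Family affiliation enters as fixed
treatment-coded dummies; aliased family levels are dropped with a warning,
any other rank deficiency is an error naming the aliased terms.

**Covariates.** DIAN models adjust for gender and family affiliation (age is
deliberately excluded — it is collinear with EYO by construction); DELCODE
models adjust for age and gender. The education model predicts log-z
connectivity from education with those covariates plus EYO (DIAN); the
ANCOVA used for carrier-vs-non-carrier and scanner-model checks adds
age/gender/education and reports a joint Wald p over the group dummies.
The two cohorts are never pooled; any operation receiving mixed rows raises.

**Multiplicity.** The four primary tests (severity × LFC connectivity on
MMSE and delayed recall, one pair per cohort) are gated at the
Bonferroni-corrected α < 0.0125 (strict); all other tests at 0.05. The
education association additionally reports a one-sided p (direction: more
education → higher connectivity) because trend-level effects are
conventionally read directionally; sidedness is a presentation choice and
does not alter the stored two-sided value.

**Trajectories.** Candidates are the hierarchical polynomials of order 1, 2
and 3 in the stage axis (EYO, or z-scored log CSF-tau), centred and scaled
before powering to control collinearity — predictions are invariant to this
reparameterization. The AIC minimizer wins; note that AIC retains an
irreducible ≈25% probability of admitting a spurious higher-order term
(P(χ²₁ > 2) + P(χ²₂ > 4), minus overlap), which is inherent to the
criterion, not a defect of the implementation. Predictions for curves hold
gender at the sample proportion (equivalently, the proportion-weighted
average of the level predictions), family dummies at their sample means, the
site intercept at its zero mean, and — when the axis × connectivity
interaction is present — connectivity at a caller-chosen z value (0 = sample
mean; the median-split strata use each stratum's mean z). Difference curves
divide by the pooled-sample SD of the (transformed) outcome and are
restricted to EYO ∈ [−20, +10] (grid step 0.5 years). Median splits label
values strictly above the median "high", ties at the median "low", and are
used for stratified curves and plots only — inference always uses the
continuous measure.

## The synthetic-data generators

**BOLD runs.** A latent band-limited (0.01–0.08 Hz) unit-variance signal s
drives the seed sphere; a chosen fraction of the remaining grey-matter
voxels is ρ·s + √(1−ρ²)·ε with independent band-limited ε, so the population
seed correlation is exactly ρ; everything else is independent noise, plus a
baseline offset, per-voxel linear drift, and Bernoulli motion spikes on the
x-translation. Tissue layout is concentric (CSF shell, WM shell, grey-matter
interior) and the grid is placed in world space around the requested seed
(or an explicit centre, for multi-seed runs). Defaults: 16³ voxels at 4 mm,
160 volumes at TR 2.23 s, spike probability 0.05 at 1 mm.

**Cohorts.** Group sizes, biomarker group means/SDs and between-group effect
sizes default to the published DIAN and DELCODE baseline characteristics
(`hubreserve.reference`), which are internally consistent under the RMS
Cohen's d convention: each carrier-group mean is the non-carrier mean plus
d·√((s₁²+s₂²)/2). Skewed biomarkers are lognormal with both raw moments
matched in closed form given the realized trajectory profile (the exponent's
offset and variance solve the two moment equations using the empirical
moments of exp(b·profile)), guaranteeing positivity for the log transform.
Carrier biomarker courses are logistic in EYO with inflection at expected
onset and a width of 6 years (5 for hippocampal volume), carrying 60% of the
log-scale SD; EYO is normal (−9.8 ± 11, truncated to [−30, 15]).
Education and log connectivity share a Gaussian copula with correlation 0.25.
Cognition is generated on the standardized scale exactly as the moderation
model assumes — β_sev·z(severity) + β_conn·z(log conn) +
β_int·z(severity)·z(log conn) + gender and site effects + residual noise
scaled to unit total variance — with the published standardized coefficients
as defaults (e.g. 0.269 for EYO × gLFC on MMSE) in the affected stratum and
null effects in controls.

Cognition raw scales are chosen *inside* the instrument bounds (≥ 2.8 SD
from floor and ceiling) while reproducing the published between-group d
exactly; the published raw MMSE scale (27.0 ± 5.1 in carriers) would put a
quarter of a linear-normal outcome above the 30-point ceiling, and the
resulting Tobit-style truncation would bias every recovered coefficient.
Since the moderation models standardize the outcome, the raw scale is
irrelevant to the fitted betas — the choice preserves the linearity the
recovery experiments certify without distorting effect sizes. The DELCODE
CSF Aβ42/40 ratio is drawn truncated on the correct side of the 0.1
amyloid cutoff per stratum so the status/ratio invariant holds exactly.

**What the simulations do not emulate.** No hemodynamics, spatial
autocorrelation, scanner-specific noise, registration error, or longitudinal
within-subject structure; missingness is absent; diagnostic-group label
noise is absent; families carry no planted effect (their dummies only
consume degrees of freedom, as they would under the null). Passing tests
therefore certify the estimators and the pipeline plumbing under the stated
generative model — unbiased recovery, calibrated intervals, correct
thresholds and transforms — not robustness to real-data pathology.

## Acceptance experiments (problem sizes)

The acceptance script uses: 500 replicate carrier strata of n = 74 for
moderation recovery (mean recovered β and t-based 95% CI coverage); one
10×10×10×120 run for the brute-force oracle comparison; 20 replicate
500-subject two-group cohorts for trajectory recovery, where the *mean*
fitted difference curve is compared with the mean generating curve — the
averaging isolates bias from single-cohort estimation noise, which at
n = 500 with the dense family designs reaches ±0.3 SD at the grid edges —
and the right shift is the difference in grid crossings of the mean
high/low-connectivity curves at −1 pooled SD; 400-sample sinusoids for the
filter contract. All randomness derives from the single `--seed` argument
through a `SeedSequence`.

## Known limitations

The FD formula, the exclusion of seed-interior voxels, and pre-regression
confound filtering are conventions chosen where the protocol is underspecified
(documented above); alternative conventions would shift scores slightly but
coherently. Mixed-model inference uses the residual-df t correction rather
than Kenward–Roger/Satterthwaite. Chi-square tests are uncorrected
(no Yates continuity correction), which is what reproduces the published
contingency p-values. Bootstrap confidence bands for difference curves are
not implemented.
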