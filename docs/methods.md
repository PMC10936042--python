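# Methods

This note records the modelling assumptions, parameter choices, and
numerical decisions behind `actiprofile`.

## 1. Data model

A participant record is a 7-day grid of integer activity counts per
minute (cpm), indexed by weekday (1 = Monday … 7 = Sunday) and minute of
day (0–1439); 10,080 cells in total. Counts are non-negative and carry no
unit beyond "device counts per 60-s epoch". No sleep channel exists;
overnight periods appear as non-wear.

## 2. Preprocessing

All thresholds live in `preprocess.Thresholds` and are applied per
calendar day (day boundaries break runs).

| parameter | default | rationale |
|---|---|---|
| non-wear window | ≥60 consecutive min | standard hip-accelerometer rule for distinguishing device removal from sedentary time |
| non-wear ceiling | every minute <50 cpm | counts ≥50 indicate wear |
| allowance | ≤2 non-zero minutes (1–49 cpm) per window | tolerates spurious low counts during non-wear |
| short wear bout | ≤120 min reclassified as non-wear | isolated wear fragments are unreliable |
| sedentary cut-point | <100 cpm | conventional uniaxial cut-point |
| light range | 100–1951 cpm | between sedentary and MVPA cut-points |
| MVPA cut-point | ≥1952 cpm | conventional moderate-intensity threshold |
| valid day | ≥600 wear min | at least 10 h of wear |
| eligibility | ≥4 valid days | stable weekly estimate |

Non-wear semantics: a minute is non-wear iff it lies inside *some* window
of length ≥60 min in which every minute is <50 cpm and at most 2 minutes
are non-zero. The implementation is an O(n) two-pointer sweep; the test
suite checks exact agreement with an O(n²) brute-force window enumeration
on randomized traces.

Sedentary bouts are maximal runs of sedentary minutes of length ≥2.
Bout-duration categories [15, 30) and ≥30 minutes are reported as
percentages of total sedentary time. An *interruption* is a qualifying
bout that ends in an active (light/MVPA) minute rather than in non-wear
or the end of day; the rate is interruptions per sedentary hour over
valid days.

## 3. Behavior images

The labelled week maps onto a 168×60 categorical matrix: row =
(weekday−1)·24 + hour, column = minute within hour. Rendering uses a
fixed palette with non-wear constrained to black and the three intensity
colors required to remain distinct after 8-bit quantization, so
`render → decode` is exactly invertible at native resolution. All
resizing is nearest-neighbour: category colors must never blend, and every
resized pixel is an exact palette color. Minutes on invalid days are
drawn as non-wear.

## 4. Convolutional autoencoder

No deep-learning framework is assumed; the CAE is implemented in numpy
(im2col convolutions, transposed convolutions, Adam, mean squared error
on RGB in [0,1], sigmoid output). Architecture: four stride-2
convolutions (kernel 4, padding 1) halving the spatial side each layer,
a dense bottleneck, and a mirrored decoder of four transposed
convolutions. Kernel 4 / stride 2 / padding 1 was chosen so that every
layer exactly halves (encoder) or doubles (decoder) the side, keeping
the two halves symmetric without output-padding corrections; input sides
must be divisible by 16.

Per-channel batch normalization follows each hidden convolution
(`batch_norm=True` by default). At the short training budgets of the
reduced-scale configuration (30 epochs) it is the difference between
latents that separate behavioral composition and latents dominated by
low-frequency luminance; running statistics make inference-time encoding
deterministic. Backpropagation — including through batch normalization —
is verified against float64 central differences; the gradient test skips
points straddling a ReLU kink, where finite differences are undefined
rather than the analytic subgradient being wrong.

Defaults: paper-scale configuration 224×224 input, channels
(32, 64, 128, 256), latent 32, 200 epochs; reduced-scale pipeline default
64×64, channels (16, 32, 64, 128) (half the paper-scale widths), latent
8, 30 epochs, batch 32, Adam lr 1e-3. The narrower (8, 16, 32, 64)
encoder proved unreliable at 30 epochs (it merged two archetypes on some
seeds); halving the paper-scale widths restored stable recovery. Training
is full-cohort (no validation split); the learning curve reports training
loss. Representation learning and clustering are two separate stages — no
joint cluster-loss fine-tuning.

## 5. Clustering and model selection

K-means uses k-means++ seeding with 10 restarts and relative inertia
tolerance 1e-4 (scikit-learn). The number of profiles is selected
automatically: the elbow is the point of maximum perpendicular distance
to the chord joining the ends of the (k, inertia) curve; among candidate
k within ±1 of the elbow, the mean silhouette decides, subject to the
smallest cluster holding ≥10% of participants (configurable). A strictly
linear inertia curve has no elbow; selection then falls back to the
best-silhouette k with a warning. Manual override (`--k`) is first-class.

## 6. Profile characterization

Outcome differences across profiles are tested by one-way ANCOVA:
ordinary least squares of outcome on treatment-coded profile plus
covariates (age, sex, ethnicity, marital status, income-to-poverty
ratio), with the profile factor tested by partial F. Adjusted (marginal)
means are model predictions at the covariate sample means. Pairwise
comparisons use the Tukey–Kramer studentized-range test on
covariate-adjusted mean contrasts (q = |Δ|·√2 / SE against the
studentized-range distribution with k groups and residual df), run when
the overall test is significant. Temporal heatmaps give, per profile and
behavior, the percentage of members in that behavior at each of the
10,080 minutes; a 15-min moving average is available for display only.

## 7. Marker associations

HOMA-IR = fasting glucose (mmol/L) × fasting insulin (pmol/L) / 22.5.
All markers except LDL are modelled on the natural-log scale (an
alternative `test` policy applies a normality test instead). Confounders
are chosen per marker by backward elimination from a candidate pool
(smoking, alcohol, energy and saturated-fat intake, caffeine, disease
history, plus the core demographics): the model is refit iteratively and
the single worst covariate with P ≥ 0.2 is dropped (categorical
covariates as whole blocks, by partial F) until all survivors are below
the threshold; the profile factor is never eligible for removal. Final
models report adjusted means with 95% CIs against the least-active
referent profile (lowest mean MVPA + light minutes/day), back-transformed
by exponentiation for log-modelled markers. Significance tiers: ***
P<0.01, ** P<0.05, * P<0.1.

## 8. Synthetic cohort generator

Each archetype is a set of per-weekday, 30-minute-block sedentary /
light / MVPA probability weights plus wear habits: a normal wear window
(start/end minute), Poisson within-day non-wear gaps with
shifted-exponential lengths (minimum 60 min, so every planted gap is
detectable by the non-wear rule), and optional sub-50-cpm allowance
noise. Wear-minute categories are drawn from the minute weights and cpm
values uniformly within the category's range. The four default archetypes
are deliberately caricatured — separated in both overall composition and
timing (e.g. a weekday 06:00–08:00 MVPA burst for the morning-mover
archetype) — because the generator's job is to provide *recoverable*
planted structure for validation, not demographic realism. Wear-gap
rates are uniform across archetypes so that device-wear artifacts never
become the class signature. Covariates and log-normal markers (LDL
normal) have magnitudes in the range of published adult cohort tables;
planted marker effects are additive log-scale shifts per archetype.

Expected per-day sedentary/light/MVPA minutes have a closed form
(weights summed over the mean wear window, discounted by the expected
gap fraction), which the tests compare against processed output.

## 9. Validation design

- **Oracle-first preprocessing**: brute-force window enumeration as the
  non-wear reference; hand-enumerated bout fragments.
- **Recovery at reduced scale**: 200 participants from the 4 archetypes,
  64×64 images, latent 8, 30 epochs → adjusted Rand index vs planted
  labels at k=4 and automated selection of k, run end-to-end through the
  real pipeline. Across five probe seeds, four give ARI ≥ 0.97 with k=4
  selected; one gives ARI ≈ 0.65 (two archetypes merge at this training
  budget) — the variance of short training, not of the method.
- **Statistical calibration**: the association machinery is exercised on
  a designed simulation (n=500, four profiles, 100 replicates) with
  residual log-SD 0.3 fixed a priori by power analysis, checking null
  p-value uniformity and recovery of a −0.2 log-insulin planted effect.
  The cohort generator's own insulin spread (log-SD 0.6, matched to
  published dispersion) is intentionally *not* used here: at that spread
  the planted effect has only ~55% power at α=0.01 with n=500, which
  would test the effect size, not the estimator.
- **Closed forms**: two-group ANCOVA vs pooled t-test (F = t²), k=1
  inertia vs total sum of squares, HOMA-IR identity.

## 10. Limitations

- The generator emulates structure, not populations: covariate and
  marker distributions are plausible but not survey-weighted, and
  archetype separation is engineered for recoverability.
- The CAE is CPU-scale numpy; paper-scale settings (224×224, latent 32,
  200 epochs) are supported but slow. No GPU path, no pretrained
  backbones, no joint deep-clustering objectives.
- Uniaxial cpm cut-points are device- and population-specific; the
  defaults assume adult hip-worn uniaxial data.
- Cross-sectional associations only; no causal interpretation, no survey
  design adjustment, no sleep behavior.
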