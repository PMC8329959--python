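# Methods

`texsurv` implements a two-part analysis used in exploratory CT radiomics of
inflammatory breast cancer (IBC): (1) filtration-histogram texture
quantification of a single post-contrast CT slice, and (2) survival inference
for cutoff-dichotomized texture features. Because no patient-level data of
this kind are publicly available, the package ships a synthetic-data module
whose generating model is known exactly; every claim the test suite makes is
a claim about recovery of that known ground truth.

## Filtration-histogram texture analysis

The texture model is deliberately first-order. A single-slice HU raster is
optionally band-pass filtered with a Laplacian of Gaussian (LoG) kernel and
six statistics of the ROI histogram are computed.

**Spatial scale factor (SSF).** The SSF names the radius, in millimetres, of
the image structures the filter highlights; SSF 0 means no filtration and
the usable filtered band is 2–6 mm (fine to coarse). Commercial
implementations do not publish their SSF-to-kernel mapping, so this package
fixes a geometric convention: the zero-crossing radius of the LoG equals the
SSF value, i.e. `sigma = SSF / sqrt(2)` (a LoG of width `sigma` changes sign
at `r = sigma * sqrt(2)`). The kernel samples the continuous LoG
`-(1/(pi sigma^4)) (1 - r^2/(2 sigma^2)) exp(-r^2/(2 sigma^2))` at pixel
centres, truncated at 4 sigma, then shifts every entry by a constant so the
kernel sums to zero exactly — a constant image therefore maps to zero and
all filtered statistics are invariant to DC offsets. Numeric equality with
any proprietary implementation is not claimed.

**Filtering order.** The whole image is filtered first (FFT convolution,
symmetric reflection padding at the image border) and the ROI mask is
applied afterwards. Masking first would create a strong artificial edge at
the ROI boundary that the band-pass filter would amplify.

**The six statistics** are computed on the masked (filtered) values:
mean; sample SD (n−1); MPP, the mean of values strictly greater than zero
(values within 1e-9 of zero are treated as convolution round-off, ten
orders of magnitude below the 1-HU quantization); Shannon entropy in bits
over 1-HU-wide integer bins (bin width configurable), empty bins excluded;
skewness `g1 = m3/m2^1.5` and excess kurtosis `g2 = m4/m2^2 − 3` from
population central moments. Degenerate cases are flagged as undefined
(`None`), never silently zeroed: MPP with no positive pixels, and
skewness/kurtosis when all masked values are identical (`m2 = 0`). At least
9 ROI pixels are required. Pixel spacing must be isotropic in-plane;
anisotropic rasters are rejected rather than resampled. Analysis is strictly
2D single-slice.

## Survival inference chain

The chain mirrors the exploratory-study design it replicates:

1. **Comparison gate.** Each feature is compared between survivors and
   non-survivors with the Mann–Whitney U test (Levene's test reported
   alongside). The p-value is exact — full enumeration of label
   assignments — when the pooled n is at most 12, else the normal
   approximation with tie and continuity correction. Only features
   significant at `alpha` (default 0.05, no multiplicity correction;
   a Holm option exists) proceed.
2. **Cutoff.** ROC analysis with the orientation "lower value predicts
   death"; the cutoff is the observed value maximizing Youden's
   J = sensitivity + specificity − 1 for the rule `value < cutoff ⇒ death`,
   ties broken toward the larger cutoff (the more inclusive low group).
   AUC ties count one half, so AUC equals the normalized Mann–Whitney
   statistic exactly.
3. **Dichotomization.** Strict `<`: the low group is `value < cutoff`.
   Subjects with missing values are excluded listwise per analysis with
   logged counts; an empty group is flagged and downstream analyses refuse.
4. **Kaplan–Meier / log-rank.** Product-limit curves per group and the
   standard O−E chi-square with hypergeometric variance (df = 1).
5. **Cox models.** Univariate per clinical variable and per dichotomized
   feature, and bivariate models pairing each feature with M stage (one
   model per feature, not a joint six-feature model — the features are
   strongly collinear by construction and in practice). Efron tie
   correction, Wald 95% CIs and p-values. Fitting is delegated to
   `lifelines`; the test suite pins the estimates against a brute-force
   grid search of the explicit partial likelihood on tie-free data, and
   checks that the log-rank statistic equals the Cox score test at beta=0.
6. **Collinearity screen.** Pairwise Spearman rank correlations among the
   six features.

**A deliberate, measured property: cutoff-selection optimism.** Choosing
the cutoff that maximizes separation on the observed outcome and then
testing that same split inflates the log-rank type-I error. The test suite
measures this on null cohorts: taken conditionally on passing the
comparison gate, the cutoff-optimized log-rank rejects far above the
nominal 5% (around 60% in the shipped configuration), while the gated
pipeline's overall per-feature false-positive fraction stays near nominal
(≈3–4%) because the gate itself is calibrated. Users reading the output
tables should treat post-dichotomization p-values as exploratory.

## Observer agreement

ICC from the two-way ANOVA mean squares; the default form is two-way
random effects, absolute agreement, single measures
(`(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)`), with the consistency
form as an option. Qualitative bands: 1 perfect; 0.81–0.99 almost perfect;
0.61–0.80 substantial; 0.41–0.60 moderate; 0.21–0.40 fair; ≤0.20 slight.
The printed bands do not tile the interval, so gap values (e.g. 0.995) are
assigned to the nearest band below; values within 1e-12 of 1 count as
perfect to absorb floating-point round-off. Zero between-subject variance
makes the ICC undefined and is flagged, not reported as zero.

## Synthetic data: what it emulates and what it does not

**Phantoms.** A tumor is a disc of enhancing tissue (`rim_hu`, default
95 HU) with an optional concentric hypodense core (`core_hu`, default
30 HU; radius `core_fraction` of the tumor radius) on a background
(−60 HU), plus additive Gaussian HU noise (default 10 HU) truncated to the
signed 16-bit range, at 0.7 mm/pixel on a 96-pixel grid. The ROI mask is
the exact tumor disc. The noiseless disc has a closed-form masked mean,
`rim + (core − rim) · core_fraction²`, used as a test oracle. Phantoms
reproduce the *first-order* contrast between enhancing rim and necrotic
core; they have no anatomy, no partial-volume blur, no contrast kinetics
and no spatially correlated noise, so passing tests demonstrate correct
computation and ground-truth recovery, not performance on real CT.

**Cohorts.** Event times follow a Weibull proportional-hazards model with
linear predictor `log_hr_feature · I(low phenotype) + log_hr_m1 · I(M1)`.
The Weibull baseline (shape 1.2, scale 120 months) allows a rising hazard
and recovers the exponential at shape 1. Censoring is the minimum of an
exponential dropout time (mean 40 months, emulating a limited follow-up
window) and a 120-month administrative horizon. Defaults describe an IBC
staging cohort: n = 98, M1 prevalence 39%, phenotype prevalence 50%,
hazard ratios 3 (low phenotype) and 3.5 (M1); under these settings ~42% of
subjects die on study, with deaths concentrated in the first two years.
Remaining clinical covariates (age group, N stage, receptor status,
molecular subtype, treatment flags) are drawn with realistic prevalences
but carry no hazard effect; they exist so the clinical univariate table
has the right shape and a known null answer.

**Features.** When imaging is not needed, SSF-0 features are synthesized
from a single latent phenotype score (group means ±1, within-group SD 1)
with per-feature loadings and residual noise sized to post-contrast
breast-tumor histograms (mean ~61 HU, SD ~41, MPP ~74 HU, entropy
~5 bits). The latent separation of 2 SD makes the low-MPP phenotype
clearly distinguishable (classification accuracy ≈0.8 at the optimal
cutoff) — a deliberately prognostic phenotype chosen so that ground-truth
recovery through an *estimated* cutoff is testable with high power;
weaker, more realistic separations mainly attenuate the recovered hazard
ratio toward 1. The single-latent structure also reproduces the strong
mutual rank correlation (collinearity) of first-order features. The
imaging-based study route instead assigns each subject a phantom from
their phenotype (weakly enhancing, more necrotic rims for the low group:
68 vs 100 HU).

**Second reading.** Observer disagreement is emulated by a random
one-pixel erosion or dilation of the ROI contour. Because the phantom
background is uniform and far from the rim in HU, this perturbs
dispersion-type features (SD) much more than location-type features
(mean, MPP) — which is why the agreement table spans nearly the full ICC
range rather than sitting uniformly near 1.

## Numerical and design choices

- All randomness flows from explicit per-spec seeds (`numpy` Generator);
  no global RNG state. Identical spec + seed is bit-identical, and every
  CLI subcommand is byte-stable under identical config + seed (output CSVs
  carry a provenance comment with a config hash that excludes filesystem
  paths).
- The LoG kernel's zero-sum shift is applied twice (mean subtraction, then
  a one-entry residual correction) so the entry sum is zero to ~1e-17.
- FFT and direct spatial convolution agree below 1e-6 on 64×64 images at
  all scales; the spatial route is kept only as a test oracle.
- `lifelines` exposes only the Efron tie correction, so the config accepts
  only `efron` (which is also the preferred default; it is exact in the
  tie-free oracle tests).
- Simulation sizes in the test suite (100 replicates for coverage/power at
  n = 300–500, 200 replicates for null calibration at n = 98, 1,000
  permutations for log-rank calibration at n = 60) were chosen as the
  smallest designs whose pass/fail bands are statistically stable.

## Known limitations

- 2D, single-slice, isotropic rasters only; no DICOM ingestion, no
  auto-segmentation, no higher-order (GLCM/GLRLM) or volumetric texture.
- The survival module supports right censoring with common entry only: no
  delayed entry, time-varying covariates or competing risks.
- ICC confidence intervals and Bland–Altman analysis are out of scope.
- The synthetic cohort is a generative stand-in; numeric agreement with
  any particular clinical cohort's cutoffs, hazard ratios or ICCs is
  neither expected nor claimed.
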