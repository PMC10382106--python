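# Methods

## Normative model

Each region's volume is modelled as a Gaussian process over the covariates
postmenstrual age at scan (PMA, weeks), postnatal age (days) and sex, fitted
on the normative cohort only. Internally the covariates are mapped to the
feature vector `[(t), t²/5, pnd/7, male]` with `t = PMA − 40`, and the
kernel is

```
k = σ_f² · RBF_ARD(features) + σ_l² · ⟨features, features'⟩ + σ_n² · δ
```

The DotProduct term is a Bayesian linear model in the features, so the
prior family contains linear-plus-quadratic growth in PMA with additive
postnatal-age and sex offsets exactly; the RBF captures smooth departures
from that trend; the white-noise term carries the irreducible biological
and measurement scatter. Length-scale floors (2 weeks on PMA; effectively
inert floors on the curvature, postnatal and sex dimensions) keep the
smooth part smooth: at a few hundred training scans an unconstrained ARD
kernel happily absorbs noise into sub-week wiggles or sex-specific bends,
which deflates the fitted noise and mis-calibrates the scores.
Hyperparameters maximise the log marginal likelihood by L-BFGS with seeded
restarts (default: initial point plus 4 restarts; ties resolved by the
optimiser's best value). One model per region is fitted on both sexes
jointly — sex is a covariate, not a stratum — and volumes are modelled on
the raw mL scale (a log-scale run showed no calibration benefit for these
cohorts).

The predictive SD used for scoring is that of a *new observation* (latent
function variance plus observation noise). This is deliberate: deviation
scores `z = (v − μ)/σ` are then ≈ N(0,1) for typical infants, which is what
makes fixed thresholds interpretable as population tail fractions
(one-sided tail 0.00466 at 2.6, 0.0495 at 1.65). Predictions outside the
training PMA range (±0.5-week margin) warn by default and raise in strict
mode. Serialised models store hyperparameters plus training data and
recompute solve artifacts on load, so a round trip reproduces predictions
to float precision.

## Slopes, flags, census

`Δz = z_post − z_pre`, the raw difference — not divided by the inter-scan
interval, whose influence is tested separately as a covariate. Thresholds
(1.65, 2.3, 2.6) are applied to Δz with strict inequalities and no variance
rescaling, although the difference of two unit-normal scores has variance
2 under independence; this keeps single-scan and slope thresholds on one
scale and is a known conservatism/liberalism trade documented here rather
than silently corrected. The census counts a subject once per threshold
regardless of how many regions are flagged; its denominator is the number
of subjects with ≥1 non-missing Δz and is always recorded. Region-level
missingness (e.g. a segmentation corrupted by injury) propagates to that
region's Δz only.

## Statistical battery

All tests are two-sided with mid-ranked ties. The pre/post comparison is
the *paired* Wilcoxon signed-rank test (the scans are paired within
infant); zero differences are dropped. Exact small-sample paths: the
signed-rank null distribution is built by convolution over sign flips on
doubled mid-ranks (valid under ties) for ≤25 non-zero differences;
Mann–Whitney is exact for min(n,m) ≤ 8 without ties; Spearman p is a full
permutation enumeration for n ≤ 9, otherwise the t-approximation with n−2
df. Fisher's test is the hypergeometric point-probability rule for 2×2,
full table enumeration over fixed margins for R×C with N ≤ 40, and a
seeded Monte-Carlo beyond that (standard error reported). Partial Spearman
rank-transforms every variable, projects the covariate ranks out of both
sides by least squares with intercept, and tests the residual correlation
with n−2−k df; constant covariates are absorbed by the intercept (k
unchanged by them), so with no informative covariate it reduces exactly to
plain Spearman. Kruskal–Wallis reports epsilon-squared as its effect size
(a median difference is undefined across three groups). BH FDR is applied
within each 13-region family (one family per clinical predictor, mirroring
per-table reporting); regions with too few usable subjects are excluded
from the family size m with a warning, never silently dropped.

## Synthetic cohorts

The generator emulates (a) a normative cohort of term infants (GA at birth
truncated-normal 40.1 ± 1.3 weeks in [37, 42]; one scan per infant with
PMA in [37, 45], mixing early postnatal scans with scans spread across the
window so the curves are supported everywhere they are used) and (b) a
surgical cohort with paired scans whose timing, clinical covariates and
category mix follow published cohort medians/IQRs (surgery day ~12, bypass
~153 min in 31/36, intensive-care stay ~4 d, ventilation and inotropes
~3 d, renal replacement 6/36, necrotising enterocolitis 4/36, category
split 20/12/4). Durations are log-normal (right-skewed); only medians and
IQRs were available, so calibration to them is approximate by construction.

Each region's mean curve is `a + b·t + c·t² + s·male + d·pnd` (mL) with SD
`σ0·(1 + κ·t)`, κ = 0.05 shared across regions — linear heteroscedasticity
is the simplest shape that exercises the predictive-variance pathway. The
default constants are invented, documented configuration chosen for
anatomical plausibility (total tissue ≈ 390 mL at 40 weeks); they are not
measured values. Total tissue volume is never drawn: it is the exact sum
of cortical gray matter, white matter, cerebellum, brainstem, the six deep
nuclei and hippocampus+amygdala in every row, and its ground-truth Z is
the σ0-weighted combination of component Zs (exact under shared κ).
Injected effects therefore cannot target total tissue directly; they leak
into it with weight σ0ᵢ/σ0_total. Post-operative volumes are constructed
as `μ(x_post) + (z_pre + Δz)·σ(x_post)`, so the generative and scoring
models agree and injected deviations are recoverable in principle. Volumes
are physical: the rare Gaussian excursion implying a non-positive volume
(beyond −3.5 SD for every default region) is redrawn, leaving Δz and the
ground-truth identity untouched.

What the generator does **not** emulate: segmentation error structure,
spatially correlated noise between neighbouring regions, injury lesions
(injury is a boolean covariate only), cohort-level confounding between
clinical covariates, or non-Gaussian residuals. Passing tests therefore
show the pipeline's statistical machinery is correct under its stated
model, not that real scan data meet those assumptions.

## Calibration: what is achievable at these sample sizes

Scoring held-out scans with curves *estimated from n = 219 infants* leaves
an irreducible per-region level error of σ/√219 ≈ 0.068 Z-units (no
estimator can do better), and the fitted noise SD carries a relative
standard error of about √(2/219)/2 ≈ 4.8%. Held-out per-region mean-Z and
SD-Z therefore scatter at roughly those scales around 0 and 1 even for a
perfectly specified model, and the pooled |z| > 2.6 flag rate inherits the
SD error convexly (it lands somewhat above the nominal 2·Φ̄(2.6) on most
seeds). The calibration experiment in the validation suite reports these
quantities honestly; bands much tighter than ~±0.15 on the per-region mean
or ~±10% on the per-region SD are not attainable without a larger
normative cohort, which is itself a useful design fact for real studies.

## Validation experiments and problem sizes

The validation suite (also run by `scripts/acceptance.py`) uses: an atlas
fitted on 219 synthetic infants and 2000 held-out scans for calibration;
500 global-null replicates of the 13-region paired-Wilcoxon family for FDR
control (BH bounds the family false-positive rate by α under the null);
and 100 replicates of a 200-infant surgical cohort for effect recovery,
with a −0.12 Z per intensive-care-day coefficient injected into six
regions (both CSF compartments and four deep nuclei — a set whose
σ-weighted leakage into total tissue stays far below its slope noise, on
top of cohort-wide slope noise of 0.3) and a −0.8 baseline displacement.
Pipeline determinism is checked by running one configuration twice and
comparing byte-level digests of every serialised artifact; the
reproducibility check uses an 80-infant normative cohort to stay fast, a
size choice, not a modelling statement.

## Known limitations

- The kernel choice is a documented design decision; the method's source
  describes GP regression but not its kernel, and other encodings are
  plausible.
- Slope thresholds are not variance-corrected (see above).
- The R×C Monte-Carlo Fisher path trades exactness for tractability above
  N = 40; its standard error is reported in the result note.
- The surgical-cohort covariate simulator matches marginal medians/IQRs
  but not the joint dependence structure of real clinical courses.
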