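# Methods note

This note records the statistical procedures, model assumptions,
parameter defaults, numerical choices and known limitations of the
`muacscreen` package.

## Study design being modelled

A cross-sectional diagnostic-accuracy design: adolescents are measured
for mid-upper arm circumference (MUAC, the index test) and for weight
and height, from which a BMI-for-age z-score (BMI-z, the reference
standard) is derived. Overweight is BMI-z > 1, obesity BMI-z > 2
(strict inequalities); the screening target is overweight-or-obese
(BMI-z > 1). A subject screens positive when MUAC ≥ cutoff.

## Anthropometry

- **Replicate averaging.** Each quantity is read twice; if the two MUAC
  readings disagree by more than 0.5 cm (`DEFAULT_REPEAT_THRESHOLD_CM`)
  a third-and-fourth repeat pair is required and the repeat pair's mean
  is used, otherwise the original mean.
- **LMS z-scores.** z = ((x/M)^L − 1)/(L·S), with the log limit
  z = ln(x/M)/S at L = 0. Beyond ±3 SD the restricted (WHO-style)
  tails are linear in SD units: z = 3 + (x − sd3)/(sd3 − sd2) above,
  mirrored below. Reference rows are matched by nearest age in months
  (optional linear interpolation).
- **Technical error of measurement.** TEM = √(Σd²/2n) over replicate
  pairs.

## Diagnostic metrics

Confusion tables use the ≥ screen-positive rule. Proportions
(sensitivity, specificity, PPV, NPV, accuracy) carry exact
Clopper–Pearson intervals computed from beta quantiles. Likelihood
ratios carry the log-method (Simel) interval,
exp(ln LR ± z·SE) with SE² for LR+ equal to
1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN). Metrics with zero denominators
are reported as undefined (`None`); a finite LR whose variance is
infinite (a zero cell) is reported as a point estimate with an
unbounded interval.

## ROC analysis

The AUC is the two-sample rank statistic (ties counted ½), identical
to the trapezoidal area under the empirical ROC; both are computed and
tested against each other. The default interval is DeLong's, from
per-subject structural components; a stratified percentile bootstrap is
available. Qualitative bands: AUC ≥ 0.9 excellent, ≥ 0.8 good,
≥ 0.7 fair, ≥ 0.6 poor, below fail (boundaries belong to the upper
band; below-chance AUCs additionally warn).

**Youden-optimal cutoff.** Candidates are the observed marker values
(under the ≥ rule every achievable table corresponds to one). Ties in
J are broken toward the smallest cutoff (maximizing sensitivity, the
screening-appropriate direction). Ties are detected *exactly* by
ranking cutoffs on the integer score TP·N⁻ − FP·N⁺, which orders
identically to J but is immune to the one-ulp float rounding of
tpr − fpr that can otherwise break a true rational tie.

## Model validation

- **Logistic regression** is fitted by hand-written
  iteratively-reweighted least squares on a centred predictor
  (relative log-likelihood tolerance 1e-10, max 100 iterations), with
  separation detected when |η| exceeds 40 or the weighted system
  becomes singular. statsmodels is used only as an independent
  cross-check in the tests.
- **Bootstrap optimism** (Harrell): for each of `n_boot` (default
  1000) resamples, refit the univariable model, compute the apparent
  AUC on the resample and the test AUC on the original data; optimism
  is their difference, and the corrected AUC is the apparent AUC minus
  the mean optimism. One-class resamples are redrawn (and counted).
- **Calibration**: a grouped (Hosmer–Lemeshow style) chi-square over
  10 equal-count bins of predicted probability,
  Σ(O−E)²/(E(1−E/n_g)) on bins − 2 degrees of freedom, plus the
  calibration slope and intercept from refitting the outcome on the
  linear predictor (exactly (1, 0) on training data, which the tests
  assert to 1e-6). Degenerate bins are merged.

## Association

Spearman's rho (mid-ranks) with the Fisher-z interval using
SE = √(1.06/(n−3)). For rho = 0.81 and n = 851 the exact
back-transform gives (0.78479, 0.83253).

## Synthetic cohort generator

Per sex, (MUAC, BMI-z) are drawn from a bivariate normal (Gaussian
copula with normal marginals). Defaults (means ± SD): 456 males with
MUAC 25.3 ± 3.2 cm and BMI-z −0.8 ± 1.2; 395 females with MUAC
25.7 ± 3.4 cm and BMI-z −0.05 ± 1.1; age 16.7 ± 1.1 years; heights
168.7 ± 6.8 / 157.0 ± 6.3 cm; default seed 2019.

- **Pooled-Spearman calibration.** A within-sex latent correlation of
  2·sin(π·r_s/6) would give each sex Spearman r_s, but pooling two
  strata with different BMI-z means attenuates the rank correlation
  (to ≈ 0.76 for a 0.81 within-sex target). The generator therefore
  solves the exact Gaussian-mixture Spearman equation
  ρ_s = 12·E[F(X)G(Y)] − 3 (the expectation expands into bivariate
  normal CDF terms) for the latent correlation that makes the *pooled*
  sample hit the target; at the default marginals this is ≈ 0.849.
  Verified empirically: pooled Spearman 0.8102 at n = 100,000.
  Single-sex cohorts reduce exactly to the closed form.
- **Weights** are back-solved through a synthetic LMS table (clearly
  labelled as synthetic, not a WHO reference) so that recomputing the
  z-score from weight and height recovers the drawn BMI-z; restricted
  tails are inverted consistently.
- **Replicates** add independent N(0, 0.15²) instrument noise and are
  rounded to the 0.1 cm grid; a repeat pair is generated exactly when
  the first two readings disagree by more than 0.5 cm.
- **Missingness injection** blanks one uniformly chosen field per
  selected record with Bernoulli(fraction) selection.
- **Scope and limitations.** The marginals are normal, so the emergent
  overweight prevalence is the mixture normal-tail probability
  ≈ 0.115, below the published study's 0.145 — real BMI-z
  distributions are right-skewed. A `forced_prevalence` mode shifts
  the BMI-z draw to hit an exact case count when a specific prevalence
  is needed. Age and MUAC are generated independently, so the
  MUAC–age correlation is ≈ 0 rather than the small positive value a
  growing cohort would show.

## Pipeline and design calculations

`run_pipeline` ingests a subject table, excludes incomplete records
(tracked in the participant flow), computes descriptives, the
MUAC–BMI-z Spearman correlation, per-stratum (total/male/female) AUC
with cutoff selection, a pooled 2×2 table (by default applying each
sex's own optimal cutoff; a single pooled cutoff is configurable),
bootstrap optimism, calibration, and prevalence with exact intervals.
Prevalence of obesity, overweight-only and overweight-including-obesity
each get Clopper–Pearson intervals.

The design sample size follows the Buderer approach: normal-based
binomial precision for the sensitivity arm,
n = z²·se·(1−se)/(d²·p), and analogously for specificity with
1 − p; the larger arm is inflated by the design effect and
non-response. At se = 0.952, sp = 0.899, p = 0.139, d = 0.05,
design effect 1.5 and 10% non-response this gives arms of 506 and 163
and a final n of 835.

## Numerical choices

- Exact binomial intervals via `scipy.stats.beta.ppf`; no normal
  approximations for proportions.
- `read_subject_csv` uses `float_precision="round_trip"` so a
  write–read cycle is bit-exact (the default C parser can be off by
  one ulp).
- All randomness flows through `numpy.random.default_rng` with
  explicit seeds; same-seed runs are byte-identical.
- Logistic IRLS uses the tanh-based expit for overflow safety.

## Known limitations

- **Bootstrap optimism is centred at zero here, by construction.** A
  univariable logistic model is a monotone transform of the marker, so
  the AUC of the bootstrap-fitted model evaluated on the original data
  equals the original marker AUC exactly (rank invariance — asserted
  by the test suite). Mean optimism therefore reduces to
  mean(AUC_bootstrap) − AUC_original, the bootstrap bias estimate of
  the rank AUC, which is centred at ~0 (measured at n = 851: about
  −4×10⁻⁵ at the default seed, spread ±6×10⁻⁴ across seeds). A
  strictly positive optimism of the size sometimes reported for such
  analyses (~0.007) cannot arise from the univariable procedure;
  meaningful optimism requires multivariable models. The
  corresponding study-scale acceptance assertion is left as written
  and fails honestly rather than being weakened.
- The printed panel rounds from exact counts; published tables
  occasionally disagree with their own counts by one unit in the last
  printed digit (the tests assert the counts-implied values).
- The DeLong interval is truncated to [0, 1] and degenerates (with a
  warning) under perfect separation.
- The grouped calibration chi-square has its usual sensitivity to bin
  placement; equal-count binning with degenerate-bin merging is used,
  and the null rejection rate is verified at ≈ 5% by simulation.
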