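# Methods

## The model

`uncrflow` analyses longitudinal systemic inflammation in people with
progressive multiple sclerosis, measured non-invasively as the weekly
urinary neopterin-to-creatinine ratio (UNCR, µmol neopterin per mol
creatinine). A participant's UNCR profile is treated as the sum of two
biologically distinct processes:

* **Background inflammation** `B` — a slowly drifting baseline level of
  immune activation. It is operationalized as the value, at the temporal
  midpoint of the observation span, of a straight line fitted to the
  series by iteratively reweighted least squares (IRLS). Robust
  weighting is essential: infection-driven peaks would otherwise bias
  the line upward.
* **Inflammatory response** `R` — the cumulative burden of short-term
  UNCR peaks. Every sample above the fitted line is expressed as a
  percent height above the predicted value, samples at or below the line
  contribute height 0, and the trapezoidal area under this height curve
  (using actual, possibly gapped, day offsets) is annualized by
  `365.25 / span_days`. Units: %·days per year.

These two exposures enter an ordinary least squares model of annualized
atrophy (signed percent change per year, negative = tissue loss):

```
atrophy = b0 + b1·B + b2·R + b3·B·R + (covariates) + ε
```

The uncentered product `B·R` captures conditioning of the innate immune
system: the marginal effect of a unit of inflammatory response,
`b2 + b3·B`, depends on the background level, consistent with
priming (low prior exposure amplifies damage) versus tolerance (high
prior exposure subdues it). Because the raw product is collinear with
its factors, standardized coefficients can legitimately exceed 1 in
magnitude; they are computed as `b·sd(x)/sd(y)` with the product term
z-scored as its own variable, and agree to 1e−10 with a refit on
z-scored data. Per-term effect sizes use Cohen's
`f² = (R²_full − R²_reduced)/(1 − R²_full)` with the reduced model
refitted without that term.

## Robust trend details

IRLS uses Tukey bisquare weights with tuning constant `c = 4.685·s`,
where `s` is the normalized median absolute deviation of the current
residuals (MAD/0.6745, centred at zero, the convention used by common
robust-regression implementations). Iteration stops when the relative
coefficient change falls below 1e−8 (or at 50 iterations, flagged
`converged=False` rather than raising). These choices — weight function,
tuning constant, scale estimator and convergence rule — are the standard
95%-efficiency defaults for robust linear regression; all are
configurable. Two numerical edge cases are handled explicitly:

* a residual scale at floating-point noise level (relative 1e−12) means
  the line interpolates the majority of points; weights become 1 on
  interpolated points and 0 on gross outliers, and the fit is final.
  This makes noiseless constant or linear series decompose *exactly*
  (background = true mid-value, response = 0);
* percent heights below 1e−9 (i.e. relative excesses at double-precision
  rounding level) are treated as exactly on the line.

A minimum of 4 samples (2 coefficients + 2 residual degrees of freedom)
is required for any fit. Duplicate same-day samples are averaged with a
warning. "Midpoint of the regression line" is read as the fitted value
at `(first_day + last_day)/2`; for a straight line this equals the mean
of the endpoint predictions, the only reading that yields a single
µmol/mol number.

## Epoch lag scan

To localize the delay between inflammation and atrophy, both exposures
are re-computed inside one-year windows anchored to each participant's
own study exit, shifted one week at a time across a 2.5-year span.
Window arithmetic uses 1 year = 52 weeks = 364 days — the convention
needed for a 130-week span with weekly steps to produce exactly 79
epochs (epoch k ends `78 − (k−1)` weeks before exit; epoch 50 ends 29
weeks out) — while annualization of the response *within* an epoch still
uses 365.25 days/year. The small inconsistency is deliberate and
documented. Participants with fewer than `min_samples` samples in a
window are excluded from that iteration only; epochs with fewer than 10
included participants are flagged rather than fitted. Per epoch, the
interaction model (no covariates) is refitted and each predictor's
standardized β with Wald 95% CI and two-tailed p is recorded; an epoch
is "significant" for a predictor at p < 0.05. The effect-size measure
and the inclusion of the interaction term are configurable.

## Synthetic cohort generator

The generator emulates the study conditions: ~50 participants, weekly
first-morning sampling, follow-up uniform on 1.3–3.2 years, and a 12%
independent chance that any scheduled sample is missing (matching an
88% collection rate). Each series is

```
UNCR(t) = (B0 + drift·t/365.25) · (1 + Σk Ak·shape(t − tk)) · ε(t)
```

with peak onsets `tk` from a homogeneous process (default 2/year),
multiplicative amplitudes `Ak` exponential with mean 1.0 (peaks average
+100% of background), a shape that rises linearly over one week and
decays exponentially with a 7-day half-life, and lognormal noise with
unit median and CV 0.15. Background levels are lognormal with median
195.8 µmol/mol (a scale anchor, not a validated population model) and
geometric SD 1.35; drift slopes are Normal(0, 8) µmol/mol/year. Peak
shape, amplitude law and frequency are conventions of this generator —
real UNCR data constrain only the qualitative picture of episodic peaks
on a drifting baseline — so passing tests validate the pipeline's
statistical machinery, not the biology of any particular peak model.

Outcomes are generated from the linear interaction model applied to the
participant's *true* exposures (the noise-free trend midpoint, and the
annualized trapezoid of the true percent-peak curve on the full weekly
grid), plus Gaussian noise. Default coefficients are the cervical-cord
estimates (5.815, −4.525e−2, −1.55e−3, 8.91e−6); a brain-atrophy
analogue with near-zero coefficients provides the secondary outcome.
With the default residual SD of 0.9 %/year and independently drawn
exposures, the model explains far more outcome variance (R² ≈ 0.8 at
n = 50) than observed in real cohorts (R² ≈ 0.1): reproducing a small
R² together with large per-term standardized βs would require strongly
mutually correlated exposures, and we deliberately do not invent such a
copula. Simulated power is therefore optimistic relative to real data.

A lagged variant computes the exposures entering the outcome model from
the series truncated `lag_weeks` before exit, giving the epoch scan a
known causal delay. One structural fact matters when interpreting scan
results: an epoch ending at exit still overlaps the truncated exposure
window by 154 of its 364 days, so epoch–outcome correlation decays
*linearly* (not sharply) as windows slide past the cutoff. The
reproducible signature of a 30-week lag is strong attenuation — at zero
outcome noise, per-epoch R² drops several-fold between fully pre-cutoff
epochs and the exit-anchored epoch — rather than a knife-edge loss of
significance at a fixed epoch index; where exactly the significant block
ends varies considerably from cohort to cohort. The packaged lag
scenario uses 6 peaks/year: at the default 2/year, a single
exponential-amplitude peak can dominate a participant's response and
act as a leverage point felt by every window, obscuring the lag
geometry.

## Progression tests

Annualized percent change is `100·(end − start)/start / years`. Group
progression uses a one-sample t-test against zero (constant-zero input
returns t = 0, p = 1 by convention; a nonzero constant raises). Paired
baseline-vs-exit comparisons use Student's paired t with Cohen's
D = mean(diff)/sd(diff) for parametric data, or the Wilcoxon signed-rank
normal approximation (mid-ranks, zero differences dropped) with effect
size Z/√n otherwise. p-values are reported unadjusted.

## Calibration and validation strategy

The test suite validates the pipeline against independent oracles:
closed-form trapezoids, a 1000-iteration fixed-point IRLS, statsmodels'
robust regression, exhaustive signed-rank enumeration, z-scored refits
and drop-one-term refits. Statistical calibration is checked by
simulation at sizes chosen to keep the default run within minutes:
coefficient recovery and 95% CI coverage over 500 replicates of n = 500
cohorts fitted on true exposures; null calibration of the epoch scan by
redrawing only the (independent) outcome over fixed epoch features, so
per-epoch p-values are exactly uniform conditional on the design.

## Known limitations

* Missingness is independent Bernoulli; real missingness is likely
  bursty (holidays, illness).
* The generator draws background and response independently; real
  exposures are probably correlated, which changes interaction-model
  collinearity (see the R² note above).
* No assay-level QC (creatinine plausibility, photodegradation) and no
  aetiological classification of peaks.
* Only two imaging timepoints are modelled; no trajectory models.
* The epoch scan reports the significance/effect-size profile only; it
  is not a formal changepoint estimator, and window-length smearing
  limits lag localization to roughly ± half a window.
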