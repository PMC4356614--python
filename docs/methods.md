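# Methods

This note documents the models, defaults and design choices behind
`albunemia`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Synthetic cohort generator

### Model

The generator produces long-format visit panels for three cohorts modelled
on well-known aging studies: a women-only cohort of 65+ year-olds ("WHAS",
3 visits, 1.5-year gaps), an all-adult Tuscan cohort ("InCHIANTI", 3 visits,
3-year gaps) and an all-adult US cohort ("BLSA", 2 visits, 2-year gaps).
Default subject counts are 1000/1050/1200; `n_scale` shrinks all three
proportionally for tests.

Two latent factors drive the 43 markers. For subject *i* at visit age *a*:

    F = b0 + b1*a + b2*a^2 + u_i + e_ij,   u_i ~ N(0, sd_u^2), e_ij ~ N(0, sd_e^2)

* **F1** (multi-system, "integrated albunemia"): b = (2.0, −0.12, 0.0014),
  sd_u = 0.8, sd_e = 0.6. The quadratic gives a J-shaped trajectory with a
  shallow minimum near age 43 and acceleration into old age.
* **F2** (metabolic): b = (−1.4, 0.02, 0), sd_u = 0.8, sd_e = 0.7.

Each marker *m* has a standardized-scale deviate
z_m = λ1_m F1 + λ2_m F2 + r_m ε with residual SD r_m = 0.8 for every marker.
F1 loads on 12 markers (hemoglobin 0.70, hematocrit 0.70, RBC 0.60, iron
0.50, MCH 0.45, MCHC 0.45, RDW 0.40, CRP 0.40, IL-6 0.40; albumin −0.55,
calcium −0.50, albumin–globulin ratio −0.45), F2 on lipids/glucose/CRP/IL-6
(0.30–0.60, HDL negative). Factor SDs and loadings were fixed once, at
design time, so that the default configuration realizes a *strong-factor
regime*: the first principal component of the panel is dominated by F1 and
recoverable from ~2000 observations. They are study-design constants, not
tuning knobs.

`z_m` is mapped to the native scale with moments matched to per-cohort
reference means/SDs (gaussian: affine; right-skewed analytes such as CRP,
IL-6, ferritin, triglycerides, GGT: moment-matched lognormal — the marginal
families are a generator choice, since only means/SDs are constrained).
Because Var(z_m) depends on the cohort's age distribution, z_m is first
standardized by its realized per-cohort moments; this affine step preserves
all correlations and the latent geometry while making native moments match.
Albumin is generated in g/dL in WHAS/BLSA but as a percentage in InCHIANTI,
deliberately forcing per-cohort standardization to be exercised.

Outcomes: death times are exponential on the age timescale from study entry
with rate h0·exp(0.15·F1_entry), h0 = 0.02/yr, administratively censored at
the end of scheduled follow-up + 2 years; visits after death are dropped.
Frailty (0–5) and comorbidity (0–13) counts are truncated Poisson with
log-rate linear in F1; a diabetes-like flag is Bernoulli with logit linear
in F2, and 5% of recorded codes are replaced by "ambiguous". Missingness is
completely at random at 1% per cell by default (the analysis protocol is
complete-case, so MAR/MNAR mechanisms are out of scope).

### What the generator does and does not emulate

It reproduces first/second native moments per cohort, a two-factor
correlation structure, quadratic age dynamics entering through the factor,
unit heterogeneity, missingness, and factor-linked outcomes. It does **not**
reproduce higher-order dependence, informative dropout, recruitment bias,
cohort effects, or the full joint distribution of real panels. Passing tests
therefore demonstrate that the *pipeline* recovers known structure under
realistic dimensions and noise — not that any particular real-data estimate
is correct.

## 2. Preprocessing

"Transform toward normality" is operationalized as: per (cohort, marker),
pick the family among identity / sqrt(x+c) / log(x+c) minimizing |sample
skewness|, with shift c = max(0, 1e−6·SD − min) guaranteeing positivity.
Ties break toward the least aggressive family (identity, then sqrt, then
log). Sample SDs use the n−1 denominator. Estradiol is standardized within
sex, so each individual is scored relative to their own sex; strata are the
sex levels *present* in a cohort (a women-only cohort has one stratum). The
fitted spec is serialized as versioned JSON so stored axes can score new
data exactly. Pooled standardized columns have exactly mean 0 per cohort;
pooled SDs deviate from 1 only at O(1/n) through the ddof correction.

## 3. Axis engine

PCA is computed by SVD of the internally re-centered/re-scaled matrix —
equivalent to eigendecomposition of the sample correlation matrix, which
serves as the independent oracle in the tests. Variance fractions are
eigenvalues over p (the total standardized variance). Scoring is the plain
inner product of standardized rows with a loading column, reduced row-locally
so single-row and batch scoring agree bitwise.

Eigenvector signs are resolved in two stages: a deterministic default
(largest-|loading| marker positive) removes solver nondeterminism; the age
orientation then flips an axis iff corr(score, age) < 0, with the default
rule as fallback when |corr| < 1e−6 or ages are absent. Loading importance
uses |loading| in the numerator (stacked importance displays require
non-negative weights; the signed alternative was considered and rejected).

The 14-marker clinical axis is *refit* on the reduced marker set rather than
truncated from the 43-marker loadings, making it an independently usable
model; greedy backward elimination (drop the marker whose removal least
reduces |r| with the full-axis scores) replaces irreproducible "trial and
error". The exported clinical reference flattens a pooled (single-stratum)
transform recipe with the reduced loadings; scoring refuses partial input
and lists missing markers.

## 4. Stability and the resampling null

Cross-version correlations are always computed on scores re-projected onto
the full matrix — this is what makes correlations across *disjoint* subsets
well-defined — and each subset axis is independently age-oriented first,
since arbitrary eigen-sign flips would otherwise corrupt the statistic.
Random exclusive partitions have sizes differing by at most one. Subsets
with no more rows than markers are skipped with a logged reason rather than
erroring (demographic strata can be tiny). The IQR is reported as the
(25th, 75th) percentile pair with linear interpolation. The same-axis
verdict defaults to the r > 0.9 rule and is threshold-configurable.

One measurement subtlety: per-cohort standardization removes cohort-level
*location* of the latent factor by construction (every cohort's markers are
centered within cohort). Recovery of the true factor is therefore measured
against within-cohort-centered F1 — the component the protocol can see.
Correlation with raw pooled F1 is structurally capped by between-cohort mean
differences regardless of estimator quality.

## 5. Trajectory models

The trajectory contract is a fixed linear/quadratic polynomial in age plus a
subject random intercept (random slopes/quadratics are not offered; in this
design they add nothing identifiable from 2–3 visits). Estimation is
maximum likelihood via `statsmodels.MixedLM`, with an optimizer cascade
(bfgs → lbfgs → powell) for robustness; age is centered internally and
coefficients mapped back to the raw-age scale exactly, with their full
covariance. When every subject has one visit, or the mixed fit fails, the
model degrades to OLS and the fit is flagged (`fallback=True`, method
"OLS") — mirroring the cross-sectional special case of single-visit data.
Intervals are Wald 95%; the random-intercept SD interval uses a delta-method
approximation and is reported as descriptive, not inferential. Credibility-
style bands are pointwise 2.5/97.5 percentiles over multivariate-normal
parameter draws (1000 by default, seeded).

Spline age adjustment uses a cubic B-spline with interior knots at age
quantiles (5 by default; knot *placement* is immaterial at these smooth
trends, and linear control gives nearly identical downstream results). The
basis spans all cubics, so polynomial age trends of degree ≤ 3 are removed
exactly; residuals are re-standardized.

## 6. Outcome associations

Age control is structural for mortality — Cox proportional hazards with age
as the timescale, each visit contributing a left-truncated interval (entry =
visit age, exit = next visit age or death/censoring; covariates at entry) —
and spline-based for all other outcomes. A recorded death earlier than a
later visit is a data-consistency error, not something to repair silently.
Count outcomes use linear (readable effect sizes) and Poisson (correct
support) families; with repeated visits the linear family gets a subject
random intercept and the Poisson family an exchangeable GEE, both reducing
to ordinary fits for baseline-only data. Ambiguous disease codes map to
positive by default, with "negative" and a 0–0.5–1 linear scale as
sensitivity variants. The optionally reported Cox pseudo-R² is the
likelihood-ratio form 1 − exp(−LR/d) with d = events, labelled as such (no
claim of equivalence to other R² variants). Multiple testing is handled by
reporting the expected false-positive count m·α (independence assumption
noted) and by replication across cohorts, not by Bonferroni.

## 7. Pipeline

Stage order: transform → standardize → complete cases → visit selection →
axes/importance → stability (demographic + random-partition null) →
trajectories → outcomes → clinical reference. Visit selection (first / all /
random-per-subject) is a first-class option because cross-sectional and
replication analyses legitimately differ in it. All randomness derives from
one seed; a failed stage marks the bundle partial and skips dependents with
recorded reasons. Complete-case counts are logged per cohort (individuals
and visits) to keep attrition auditable.

## 8. Problem sizes and numerical choices

Tests run the default design at reduced scale: ~2000 complete observations
for recovery checks, 3200 observations × k = 10 × 20 replicates for the
stability null, 50 replicates of 1200 subjects × 2 visits for trajectory
coverage, and 20 replicates of 2000 subjects (≥300 events) for Cox
recovery — sizes chosen to keep Monte-Carlo error well below the margins
being asserted while the full suite stays fast. Orthonormality and variance-
fraction identities are asserted at 1e−10, oracle equivalence at 1e−8;
skewness ties break deterministically; degenerate inputs (constant columns,
empty strata, no events, k > n) raise typed errors naming the offender.

## Known limitations

* The generator's linear-Gaussian factor model cannot probe robustness to
  nonlinear marker-factor relationships or heavy-tailed contamination.
* The stability null on synthetic data is cleaner (≈0.99) than typical
  real-data values; it bounds sampling noise only under the generator's
  assumptions.
* Trajectory intervals are Wald-based ML approximations of what a fully
  Bayesian treatment would report; the random-intercept SD interval in
  particular is approximate.
* No multiple imputation, winsorization, competing risks, time-varying
  coefficients, or rotated/sparse PCA variants.
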