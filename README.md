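# albunemia

Discovery and validation of **integrated physiological axes** from
multi-cohort clinical biomarker panels.

Aging research often treats biomarkers one molecule at a time, yet regulatory
physiology is a network: the joint behaviour of many markers can expose
higher-order processes that no single marker measures. This package
implements the analysis protocol for detecting such processes in longitudinal
cohort data — most prominently a multi-system anemia/inflammation/albumin
gradient ("integrated albunemia") that strengthens with age and predicts
mortality and frailty — and for demonstrating that a detected axis is a
reproducible biological signal rather than a sampling artifact.

Because the human cohort data this style of analysis targets are
restricted-access, the package ships a first-class synthetic-cohort generator
that emulates their statistical structure (three cohorts, 43 markers with
cohort-specific units, a dominant latent factor with quadratic age dynamics,
a second metabolic factor, missingness, and factor-linked outcomes), so that
every stage of the pipeline is testable against known ground truth.

## The method

1. **Transformation protocol.** Per cohort and marker, choose among
   x, log(x + c), sqrt(x + c) the transform minimizing |sample skewness|,
   then standardize to mean 0 / SD 1 (within sex strata for estradiol):
   z_mi = (f(x_mi + c) − μ) / σ.
2. **Axis extraction.** PCA on the correlation scale of the standardized,
   complete-case matrix. The first axis w maximizes Var(z·w) subject to
   ‖w‖ = 1; its *variance fraction* is λ₁/p. Loading importance of marker m
   is |w_m| / Σ_j |w_j|. Axes are oriented to correlate positively with age.
3. **Replication.** An axis fitted in one population/subset is re-projected
   onto other data (standardized with its own per-cohort recipe); two axis
   versions whose re-projected scores correlate at r > 0.9 are operationally
   the same axis. A resampling null — k = 10 random mutually exclusive
   subsets, axis per subset, C(10,2) = 45 pairwise correlations, repeated —
   quantifies how much divergence pure sampling produces.
4. **Age trajectories.** Mixed models score ~ β₀ + β₁·age + β₂·age² + u_i
   with a subject random intercept u_i.
5. **Health outcomes.** Cox proportional hazards with **age as the
   timescale** (each visit contributes a left-truncated interval censored at
   the next visit), linear/Poisson models for frailty and comorbidity
   counts, and logistic models for disease flags, all controlling for age
   via a cubic B-spline. Per-unit hazard ratios compound exponentially:
   two individuals 5 units apart at HR 1.1/unit differ by 1.1⁵ ≈ 1.6×.
6. **Clinical score.** A reduced 14-marker axis (standard blood-panel
   markers) refit and validated against the full axis, exported as a
   self-contained scoring reference for new patients.

## Worked example

```python
import albunemia as ab

config = ab.default_config(seed=0, n_scale=0.38)
panel, truth = ab.generate_panel(config)
spec = ab.fit_transform_spec(panel, config.marker_names)
matrix, counts = ab.complete_cases(ab.standardize(panel, spec))

model, scores = ab.fit_oriented_axes(matrix, source="full")
print(f"PCA1 explains {100 * model.variance_fractions[0]:.1f}% of variance")
print("top loadings:", ab.importance(model).markers[:5])

null = ab.null_distribution(matrix, k=10, reps=20, seed=0)
print(f"stability null: mean r = {null.mean_of_means:.3f}, "
      f"min r = {null.mean_of_minima:.3f}")

reduced, r = ab.reduce_axis(model, matrix, required=ab.CLINICAL_14,
                            target_size=14)
print(f"14-marker clinical axis: r = {r:.2f} with the full axis")
```

prints

```
PCA1 explains 14.3% of variance
top loadings: ['hemoglobin', 'hematocrit', 'rbc', 'albumin', 'crp']
stability null: mean r = 0.993, min r = 0.987
14-marker clinical axis: r = 0.98 with the full axis
```

The first axis is led by red-cell markers with albumin loading opposite in
sign — the integrated-albunemia signature; the near-unit null correlations
say ten disjoint subsets each recover essentially the same axis, and the
14-marker reduction loses almost nothing.

There is also a CLI (`albunemia simulate | transform | axes | stability |
trajectories | outcomes | score | report`) operating on CSV panels and
JSON model files; `albunemia report --panel panel.csv --outdir out/` runs
the whole pipeline and writes a report bundle.

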