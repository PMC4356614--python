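import numpy as np
import pandas as pd
import pytest

import albunemia as ab


@pytest.fixture(scope="session")
def default_panel():
    """A mid-sized draw from the default three-cohort design (~2000 complete rows)."""
    cfg = ab.default_config(seed=0, n_scale=0.38)
    panel, truth = ab.generate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture(scope="session")
def default_matrix(default_panel):
    """Standardized complete-case matrix + row-aligned truth for the default draw."""
    cfg, panel, truth = default_panel
    spec = ab.fit_transform_spec(panel, cfg.marker_names)
    full = ab.standardize(panel, spec)
    keep = full.values.notna().all(axis=1).to_numpy()
    cc, counts = ab.complete_cases(full, cfg.marker_names)
    truth_cc = truth.loc[keep].reset_index(drop=True)
    return cfg, cc, truth_cc, counts


@pytest.fixture(scope="session")
def default_axis(default_matrix):
    cfg, cc, truth_cc, _ = default_matrix
    model, scores = ab.fit_oriented_axes(cc, source="full")
    return model, scores


def one_factor_config(n_subjects=500, loadings=(0.6, 0.5, 0.4), residual_sd=0.8,
                      seed=0, visits=1, family="gaussian", subject_sd=0.6,
                      noise_sd=0.8, loadings_f2=None):
    """Single-cohort config with a flat (age-free) factor of unit variance.

    subject_sd**2 + noise_sd**2 = 1 by default, so corr(marker, F1) has the
    closed form lam / sqrt(lam**2 + residual_sd**2).
    """
    markers = []
    for i, lam in enumerate(loadings):
        lam2 = 0.0 if loadings_f2 is None else loadings_f2[i]
        markers.append(ab.MarkerSpec(
            name=f"m{i}", mean={"A": 10.0 + i}, sd={"A": 2.0},
            family=family, loading_f1=lam, loading_f2=lam2,
            residual_sd=residual_sd))
    return ab.GeneratorConfig(
        cohorts=[ab.CohortSpec("A", n_subjects, (50.0, 80.0), visits=visits,
                               visit_gap=2.0)],
        markers=markers,
        f1_age_model=ab.FactorAgeModel(0.0, 0.0, 0.0, subject_sd=subject_sd,
                                       noise_sd=noise_sd),
        f2_age_model=ab.FactorAgeModel(0.0, 0.0, 0.0, subject_sd=subject_sd,
                                       noise_sd=noise_sd),
        missingness=0.0, seed=seed)


def exactly_standardized(values, columns=None) -> ab.StandardizedMatrix:
    """Wrap an array as a StandardizedMatrix with exactly mean-0/SD-1 columns."""
    X = np.asarray(values, dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    cols = columns or [f"m{i}" for i in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=cols)
    meta = pd.DataFrame({"subject": [f"s{i}" for i in range(len(frame))],
                         "age": np.linspace(50, 90, len(frame))})
    return ab.StandardizedMatrix(frame, meta, ab.TransformSpec(markers=cols))
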