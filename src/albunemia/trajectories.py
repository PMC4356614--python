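"""Population age trajectories of axis scores and spline age adjustment.

Trajectory model: fixed polynomial in age (linear or quadratic) plus a
subject-level random intercept — random slopes/quadratics are deliberately
not offered.  Estimation is maximum likelihood via a linear mixed model;
age is centered internally for conditioning and coefficients are mapped
back (exactly, with their full covariance) to the raw-age parameterization,
so the reported intercept/slope/quadratic read directly in score units,
score units per year, and per year^2.  When every subject contributes a
single visit (or the between-subject variance is not identifiable) the fit
degrades to an ordinary least-squares cross-sectional model and is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy import stats
import statsmodels.api as sm

from .axes import AxisModel, AxisScores
from .errors import DegenerateInputError, ValidationError


@dataclass
class TrajectoryFit:
    """Fixed polynomial coefficients with 95% intervals, raw-age scale."""

    form: str  # "linear" | "quadratic"
    method: str  # estimation method label
    beta: dict  # name -> (estimate, lci, uci)
    cov: np.ndarray  # covariance of the fixed effects (raw-age scale)
    random_intercept_sd: tuple  # (estimate, lci, uci); (0, nan, nan) if absent
    residual_sd: float
    n_obs: int
    n_subjects: int
    age_range: tuple
    fallback: bool = False  # True when degraded to fixed-effects-only
    dataset: str = ""

    @property
    def coef_names(self):
        return list(self.beta)

    def predict(self, ages, params=None) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if params is None:
            params = np.array([self.beta[k][0] for k in self.beta])
        X = _poly_design(ages, self.form)
        return X @ params

    def to_row(self) -> dict:
        """One flat row in the trajectory-table layout."""
        row = {"dataset": self.dataset, "form": self.form,
               "method": self.method, "n_obs": self.n_obs,
               "n_subjects": self.n_subjects}
        for name, (b, lo, hi) in self.beta.items():
            row[name] = b
            row[f"{name}_lci"] = lo
            row[f"{name}_uci"] = hi
        sd, lo, hi = self.random_intercept_sd
        row["random_intercept_sd"] = sd
        row["random_intercept_sd_lci"] = lo
        row["random_intercept_sd_uci"] = hi
        return row


def _poly_design(ages: np.ndarray, form: str) -> np.ndarray:
    if form == "linear":
        return np.column_stack([np.ones_like(ages), ages])
    if form == "quadratic":
        return np.column_stack([np.ones_like(ages), ages, ages ** 2])
    raise ValidationError(f"unknown trajectory form {form!r}")


def _raw_scale_transform(center: float, form: str) -> np.ndarray:
    """T with beta_raw = T @ beta_centered for u = age - center."""
    c = center
    if form == "linear":
        return np.array([[1.0, -c], [0.0, 1.0]])
    return np.array([[1.0, -c, c ** 2], [0.0, 1.0, -2 * c], [0.0, 0.0, 1.0]])


_COEF_NAMES = {"linear": ("intercept", "slope"),
               "quadratic": ("intercept", "slope", "quadratic")}


def fit_trajectory(scores, ages, subjects, form: str = "quadratic") -> TrajectoryFit:
    """Fit the mixed (or fallback cross-sectional) age-trajectory model."""
    y = np.asarray(scores.values if isinstance(scores, AxisScores) else scores,
                   dtype=float)
    ages = np.asarray(ages, dtype=float)
    subjects = np.asarray(subjects)
    if not (len(y) == len(ages) == len(subjects)):
        raise ValidationError("scores, ages and subjects must have equal length")
    if not np.all(np.isfinite(ages)):
        raise ValidationError("ages must be finite")
    if form not in _COEF_NAMES:
        raise ValidationError(f"unknown trajectory form {form!r}")

    center = float(ages.mean())
    u = ages - center
    X = _poly_design(u, form)
    names = _COEF_NAMES[form]

    counts = pd.Series(subjects).value_counts()
    has_repeats = bool((counts > 1).any())

    fallback = not has_repeats
    params_c = cov_c = None
    re_sd = (0.0, np.nan, np.nan)
    resid_sd = np.nan
    method = "OLS"
    if has_repeats:
        try:
            res = _fit_mixedlm(y, X, subjects)
            var_re = float(np.asarray(res.cov_re)[0, 0])
            params_c = np.asarray(res.fe_params)
            cov_c = np.asarray(res.cov_params())[: len(names), : len(names)]
            resid_sd = float(np.sqrt(res.scale))
            method = "MixedLM-ML"
            # delta-method interval for the random-intercept SD
            sd = float(np.sqrt(var_re))
            se_var = _re_variance_se(res)
            if sd > 0 and np.isfinite(se_var):
                se_sd = se_var / (2 * sd)
                re_sd = (sd, max(0.0, sd - 1.96 * se_sd), sd + 1.96 * se_sd)
            else:
                re_sd = (sd, np.nan, np.nan)
        except Exception:
            fallback = True
    if params_c is None:
        ols = sm.OLS(y, X).fit()
        params_c = np.asarray(ols.params)
        cov_c = np.asarray(ols.cov_params())
        resid_sd = float(np.sqrt(ols.scale))
        method = "OLS"
        re_sd = (0.0, np.nan, np.nan)

    T = _raw_scale_transform(center, form)
    params = T @ params_c
    cov = T @ cov_c @ T.T
    se = np.sqrt(np.diag(cov))
    beta = {
        name: (float(b), float(b - 1.96 * s), float(b + 1.96 * s))
        for name, b, s in zip(names, params, se)
    }
    return TrajectoryFit(
        form=form, method=method, beta=beta, cov=cov,
        random_intercept_sd=re_sd, residual_sd=resid_sd,
        n_obs=len(y), n_subjects=int(counts.size),
        age_range=(float(ages.min()), float(ages.max())),
        fallback=fallback,
    )


def _fit_mixedlm(y, X, groups):
    """Random-intercept LMM fit with an optimizer cascade for robustness."""
    last_err = None
    for method in ("bfgs", "lbfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(y, X, groups=groups).fit(reml=False,
                                                          method=method)
            if res.converged and np.isfinite(float(np.asarray(res.cov_re)[0, 0])):
                return res
            last_err = RuntimeError(f"{method}: did not converge")
        except Exception as err:  # singular hessian etc.; try next optimizer
            last_err = err
    raise RuntimeError(f"mixed model estimation failed: {last_err}")


def _re_variance_se(res) -> float:
    """SE of the random-intercept variance from the mixed-model fit."""
    try:
        # last entry of bse corresponds to the (scaled) RE variance parameter
        return float(res.bse[-1] * res.scale)
    except Exception:
        return np.nan


def trajectory_curve(fit: TrajectoryFit, ages, n_draws: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
    """Pointwise mean curve and 2.5/97.5 percentile band from parameter draws."""
    ages = np.asarray(ages, dtype=float)
    if n_draws < 100:
        warnings.warn("fewer than 100 draws gives unstable percentile bands")
    lo, hi = fit.age_range
    if ages.min() < lo - 1e-9 or ages.max() > hi + 1e-9:
        warnings.warn(
            f"age grid extrapolates beyond the fitted range ({lo:.1f}, {hi:.1f})"
        )
    rng = np.random.default_rng(seed)
    mean_params = np.array([fit.beta[k][0] for k in fit.beta])
    cov = np.asarray(fit.cov)
    if np.allclose(cov, 0):
        draws = np.tile(mean_params, (n_draws, 1))
    else:
        draws = rng.multivariate_normal(mean_params, cov, size=n_draws,
                                        method="svd")
    X = _poly_design(ages, fit.form)
    curves = draws @ X.T  # n_draws x n_ages
    lo_band, hi_band = np.percentile(curves, [2.5, 97.5], axis=0)
    point = X @ mean_params
    return pd.DataFrame({
        "age": ages,
        "estimate": point,
        "mean": curves.mean(axis=0),
        "lower": np.minimum(lo_band, point),
        "upper": np.maximum(hi_band, point),
    })


# --------------------------------------------------------------------------
# spline age adjustment
# --------------------------------------------------------------------------

def cubic_spline_basis(ages, n_interior_knots: int = 5,
                       knots: np.ndarray | None = None) -> np.ndarray:
    """Cubic B-spline design matrix with interior knots at age quantiles."""
    ages = np.asarray(ages, dtype=float)
    lo, hi = ages.min(), ages.max()
    if lo == hi:
        raise DegenerateInputError("age is constant; spline basis undefined")
    if knots is None:
        qs = np.linspace(0, 100, n_interior_knots + 2)[1:-1]
        knots = np.unique(np.percentile(ages, qs))
    knots = np.asarray(knots, dtype=float)
    t = np.concatenate([[lo] * 4, knots, [hi] * 4])
    return BSpline.design_matrix(np.clip(ages, lo, hi), t, 3,
                                 extrapolate=False).toarray()


def age_adjust(values, ages, n_interior_knots: int = 5) -> pd.DataFrame:
    """Residualize each marker on a cubic age spline; re-standardize residuals.

    The basis spans all cubics in age, so any polynomial age trend of degree
    <= 3 is removed exactly.
    """
    frame = pd.DataFrame(values)
    ages = np.asarray(ages, dtype=float)
    B = cubic_spline_basis(ages, n_interior_knots)
    out = {}
    for col in frame.columns:
        y = frame[col].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        resid = y - B @ coef
        sd = resid.std(ddof=1)
        out[col] = resid / sd if sd > 0 else resid
    return pd.DataFrame(out, index=frame.index)


def age_correlation_table(values, ages, model: AxisModel | None = None,
                          axis: int = 0) -> pd.DataFrame:
    """Pearson r and two-sided p of each variable with age.

    When an axis model is supplied the rows are ordered by |loading| on that
    axis (variables not in the model keep their input order, after the model's
    markers).
    """
    frame = pd.DataFrame(values)
    ages = np.asarray(ages, dtype=float)
    if len(frame) < 3:
        raise ValidationError("need at least 3 paired observations")
    rows = []
    for col in frame.columns:
        r, p = stats.pearsonr(frame[col].to_numpy(dtype=float), ages)
        rows.append({"variable": col, "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows).set_index("variable")
    if model is not None:
        load = model.loading_series(axis).abs().sort_values(ascending=False)
        ordered = [m for m in load.index if m in table.index]
        rest = [v for v in table.index if v not in set(ordered)]
        table = table.loc[ordered + rest]
    return table
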