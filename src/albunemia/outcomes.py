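"""Associations between axis scores and health outcomes, controlling for age.

Mortality uses Cox proportional hazards with *age as the timescale*: every
visit contributes one observation entering at the visit age (left truncation)
and exiting at the next visit (censored) or at death/end of follow-up.  Count
outcomes (frailty 0-5, comorbidities 0-13) use linear or Poisson regression;
binary disease flags use logistic regression with ambiguous codes mapped to
a configurable category.  All non-survival models control for age through a
cubic B-spline basis (survival models control for age by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from .axes import AxisScores
from .errors import DataConsistencyError, ValidationError
from .trajectories import cubic_spline_basis


@dataclass
class AssociationResult:
    """Effect of one axis on one outcome, age-controlled."""

    outcome: str
    family: str  # "cox" | "logistic" | "linear" | "poisson"
    effect: float  # HR / OR / slope per unit axis score
    ci: tuple  # 95% CI on the effect scale
    p: float
    n_obs: int
    n_subjects: int | None = None
    n_events: int | None = None
    axis: str = "pca1"
    dataset: str = ""
    age_control: str = ""
    method: str = ""
    converged: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def log_effect(self) -> float:
        if self.family in ("cox", "logistic", "poisson"):
            return float(np.log(self.effect))
        return self.effect

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome, "family": self.family, "axis": self.axis,
            "dataset": self.dataset, "effect": self.effect,
            "ci_low": self.ci[0], "ci_high": self.ci[1], "p": self.p,
            "n_obs": self.n_obs, "n_subjects": self.n_subjects,
            "n_events": self.n_events, "age_control": self.age_control,
            "method": self.method, "converged": self.converged,
        }


def association_table(results) -> pd.DataFrame:
    """Stack results into the flat export layout (model columns, effect/CI/p, n)."""
    return pd.DataFrame([r.to_row() for r in results])


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------

def build_intervals(visits: pd.DataFrame, score_column: str = "score",
                    covariate_columns=()) -> pd.DataFrame:
    """One left-truncated interval per visit, censored at the next visit.

    ``visits`` needs columns subject, age, the score column, and per-subject
    ``death_age`` (NaN when not observed) and ``censor_age``.  Each visit
    yields an interval from its age to the next visit age (censored) or, for
    the last visit, to the death/censoring age (event per the death flag).
    """
    required = {"subject", "age", score_column, "death_age", "censor_age"}
    missing = required - set(visits.columns)
    if missing:
        raise ValidationError(f"visits table missing columns {sorted(missing)}")
    rows = []
    for subject, grp in visits.groupby("subject", sort=True):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy(dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise DataConsistencyError(
                f"subject {subject!r}: visit ages not strictly increasing"
            )
        death = grp["death_age"].iloc[0]
        censor = grp["censor_age"].iloc[0]
        has_event = bool(pd.notna(death))
        end = float(death) if has_event else float(censor)
        if end < ages[-1]:
            raise DataConsistencyError(
                f"subject {subject!r}: death/censoring at {end} precedes a "
                f"visit at {ages[-1]}"
            )
        if end == ages[-1] and not has_event:
            # zero-length trailing interval carries no information; drop it
            ages = ages[:-1]
            if len(ages) == 0:
                continue
        for i, entry in enumerate(ages):
            last = i == len(ages) - 1
            exit_age = end if last else float(ages[i + 1])
            if exit_age <= entry:
                raise DataConsistencyError(
                    f"subject {subject!r}: empty interval at age {entry}"
                )
            row = {
                "subject": subject, "entry": float(entry), "exit": exit_age,
                "event": int(has_event and last),
                score_column: grp[score_column].iloc[i],
            }
            for c in covariate_columns:
                row[c] = grp[c].iloc[i]
            rows.append(row)
    return pd.DataFrame(rows)


def cox_axis(intervals: pd.DataFrame, score_column: str = "score",
             axis_label: str = "pca1", dataset: str = "",
             covariate_columns=(), report_r2: bool = False) -> AssociationResult:
    """Cox fit on visit intervals with age as the timescale (left truncation)."""
    n_events = int(intervals["event"].sum())
    if n_events == 0:
        raise ValidationError("no events: cannot fit a Cox model")
    if n_events < 10:
        warnings.warn(f"only {n_events} events; Cox estimates will be unstable")
    cols = ["entry", "exit", "event", score_column, *covariate_columns]
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(intervals[cols], duration_col="exit", event_col="event",
                    entry_col="entry")
        except Exception as err:
            raise ValidationError(f"Cox model failed to fit: {err}") from err
    summ = cph.summary.loc[score_column]
    extra = {}
    if report_r2:
        # pseudo-R^2 (likelihood-ratio form, per event); variant is labelled
        lr = cph.log_likelihood_ratio_test().test_statistic
        extra["pseudo_r2_lr_per_event"] = float(1.0 - np.exp(-lr / n_events))
    return AssociationResult(
        outcome="mortality", family="cox",
        effect=float(np.exp(summ["coef"])),
        ci=(float(np.exp(summ["coef lower 95%"])),
            float(np.exp(summ["coef upper 95%"]))),
        p=float(summ["p"]), n_obs=len(intervals),
        n_subjects=int(intervals["subject"].nunique()), n_events=n_events,
        axis=axis_label, dataset=dataset,
        age_control="age as timescale (left truncation)",
        method="CoxPHFitter", converged=converged, extra=extra,
    )


# --------------------------------------------------------------------------
# counts and binary outcomes
# --------------------------------------------------------------------------

def _age_design(scores, ages, n_knots: int):
    s = np.asarray(scores.values if isinstance(scores, AxisScores) else scores,
                   dtype=float)
    ages = np.asarray(ages, dtype=float)
    B = cubic_spline_basis(ages, n_knots)
    # drop the first spline column: the basis sums to one, so this yields a
    # full-rank design once the score column is prepended
    X = np.column_stack([s, B[:, 1:], np.ones(len(s))])
    return s, X


def count_association(scores, counts, ages, family: str = "linear",
                      subjects=None, outcome: str = "frailty",
                      dataset: str = "", n_knots: int = 5,
                      max_count: int | None = None) -> AssociationResult:
    """Regression of a count outcome on an axis score with spline age control.

    With repeated visits per subject the linear family uses a subject random
    intercept (mixed model) and the Poisson family uses a cluster-robust GEE
    with exchangeable working correlation; with one visit per subject both
    reduce to ordinary GLM fits.
    """
    c = np.asarray(counts, dtype=float)
    if family not in ("linear", "poisson"):
        raise ValidationError(f"unknown count family {family!r}")
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValidationError("counts must be non-negative integers")
    if max_count is not None and np.any(c > max_count):
        raise ValidationError(f"counts exceed the allowed maximum {max_count}")
    s, X = _age_design(scores, ages, n_knots)
    repeats = False
    if subjects is not None:
        subjects = np.asarray(subjects)
        repeats = bool((pd.Series(subjects).value_counts() > 1).any())
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "linear":
            if repeats:
                from .trajectories import _fit_mixedlm
                res = _fit_mixedlm(c, X, subjects)
                coef, se = float(res.fe_params[0]), float(res.bse_fe[0])
                p = float(res.pvalues[0])
                method = "MixedLM-ML"
                converged = bool(res.converged)
            else:
                res = sm.OLS(c, X).fit()
                coef, se, p = (float(res.params[0]), float(res.bse[0]),
                               float(res.pvalues[0]))
                method = "OLS"
        else:
            if repeats:
                res = sm.GEE(c, X, groups=subjects,
                             family=sm.families.Poisson(),
                             cov_struct=sm.cov_struct.Exchangeable()).fit()
                method = "GEE-Poisson"
            else:
                res = sm.GLM(c, X, family=sm.families.Poisson()).fit()
                method = "GLM-Poisson"
            coef, se, p = (float(res.params[0]), float(res.bse[0]),
                           float(res.pvalues[0]))
    if family == "poisson":
        effect = float(np.exp(coef))
        ci = (float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se)))
    else:
        effect = coef
        ci = (coef - 1.96 * se, coef + 1.96 * se)
    return AssociationResult(
        outcome=outcome, family=family, effect=effect, ci=ci, p=p,
        n_obs=len(c),
        n_subjects=int(pd.Series(subjects).nunique()) if subjects is not None else None,
        dataset=dataset, age_control=f"cubic spline, {n_knots} interior knots",
        method=method, converged=converged,
    )


AMBIGUOUS_POLICIES = ("positive", "negative", "half")


def resolve_flags(flags, ambiguous: str = "positive") -> np.ndarray:
    """Map {positive, negative, ambiguous} codes to a numeric outcome."""
    if ambiguous not in AMBIGUOUS_POLICIES:
        raise ValidationError(
            f"ambiguous policy must be one of {AMBIGUOUS_POLICIES}"
        )
    f = pd.Series(flags).astype(str).str.lower()
    known = {"positive", "negative", "ambiguous", "1", "0", "1.0", "0.0", "true", "false"}
    bad = sorted(set(f.unique()) - known)
    if bad:
        raise ValidationError(f"unrecognized disease codes: {bad}")
    out = np.where(f.isin(["positive", "1", "1.0", "true"]), 1.0, 0.0)
    amb = (f == "ambiguous").to_numpy()
    out[amb] = {"positive": 1.0, "negative": 0.0, "half": 0.5}[ambiguous]
    return out


def binary_association(scores, flags, ages, ambiguous: str = "positive",
                       outcome: str = "diabetes", dataset: str = "",
                       n_knots: int = 5) -> AssociationResult:
    """Logistic fit of a disease flag on an axis score with spline age control.

    Ambiguous codes are mapped to the positive class by default; "negative"
    and the 0-0.5-1 linear scale ("half") are the sensitivity variants.
    """
    y = resolve_flags(flags, ambiguous)
    s, X = _age_design(scores, ages, n_knots)
    if ambiguous == "half" and np.any((y > 0) & (y < 1)):
        res = sm.OLS(y, X).fit()
        coef, se, p = (float(res.params[0]), float(res.bse[0]),
                       float(res.pvalues[0]))
        return AssociationResult(
            outcome=outcome, family="linear", effect=coef,
            ci=(coef - 1.96 * se, coef + 1.96 * se), p=p, n_obs=len(y),
            dataset=dataset,
            age_control=f"cubic spline, {n_knots} interior knots",
            method="OLS-0/0.5/1",
        )
    if len(np.unique(y)) < 2:
        raise ValidationError(f"outcome {outcome!r} has a single class")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    coef, se, p = float(res.params[0]), float(res.bse[0]), float(res.pvalues[0])
    return AssociationResult(
        outcome=outcome, family="logistic", effect=float(np.exp(coef)),
        ci=(float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))),
        p=p, n_obs=len(y), n_events=int(y.sum()), dataset=dataset,
        age_control=f"cubic spline, {n_knots} interior knots",
        method="GLM-Binomial",
    )


# --------------------------------------------------------------------------
# arithmetic helpers
# --------------------------------------------------------------------------

def compound_hazard(hr: float, delta: float) -> float:
    """Risk ratio between two individuals ``delta`` score units apart.

    Per-unit hazard (or odds) ratios compound exponentially: hr ** delta.
    E.g. a per-unit HR of 1.1 over a 5-unit difference gives 1.1**5 = 1.61.
    """
    if hr <= 0:
        raise ValidationError("hazard ratio must be > 0")
    return float(hr ** delta)


def expected_false_positives(m: int, alpha: float) -> float:
    """Expected count of chance-significant tests among m independent tests."""
    if m < 0:
        raise ValidationError("number of tests must be >= 0")
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    return float(m * alpha)
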