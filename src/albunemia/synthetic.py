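"""Synthetic multi-cohort biomarker panels with known latent structure.

The generator emulates the statistical skeleton of three longitudinal aging
cohorts: per-cohort marker means/SDs in native units (including one marker
whose units differ between cohorts), a dominant multi-system latent factor F1
with a quadratic age trajectory and a subject-level random intercept, a
second metabolic factor F2, per-(cohort, marker) missingness, and outcomes
(mortality, frailty counts, comorbidity counts, a diabetes-like flag) linked
to the factors.

Model
-----
For subject *i* of a cohort at visit age ``a``::

    F1 = b0 + b1*a + b2*a^2 + u_i + e_ij       u_i ~ N(0, subject_sd^2)
                                               e_ij ~ N(0, noise_sd^2)

and analogously for F2.  Each marker *m* has a standardized-scale deviate::

    z_m = lam1_m * F1 + lam2_m * F2 + residual_sd_m * eps

which is re-expressed on the native scale so that the marker's first two
moments match the configured native mean/SD (gaussian: affine map; lognormal:
moment-matched exp transform).  Because F1/F2 variance depends on the cohort
age distribution, ``z_m`` is standardized by its realized first two moments
within each cohort before the native mapping; this is an affine operation, so
all correlations and the latent geometry are untouched.

Ground truth (factor values, subject intercepts, true death ages) is returned
alongside the panel for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .markers import COHORTS, MARKER_DEFS, MarkerDef

KEY_COLUMNS = ("cohort", "subject", "visit")
OUTCOME_COLUMNS = (
    "death_age", "censor_age", "death_observed", "frailty", "comorbidities",
    "diabetes",
)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of one synthetic cohort."""

    name: str
    n_subjects: int
    age_range: tuple[float, float]  # baseline entry ages, years
    visits: int = 2
    visit_gap: float = 2.0  # mean inter-visit gap, years
    female_fraction: float = 0.5
    strata: dict = field(default_factory=dict)  # e.g. {"race": ["white", "black"]}

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError(f"cohort {self.name}: n_subjects must be >= 1")
        if not self.age_range[0] < self.age_range[1]:
            raise ValidationError(f"cohort {self.name}: age_range must be increasing")
        if self.visits < 1:
            raise ValidationError(f"cohort {self.name}: visits must be >= 1")
        if self.visits > 1 and self.visit_gap <= 0:
            raise ValidationError(f"cohort {self.name}: visit_gap must be > 0")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValidationError(
                f"cohort {self.name}: female_fraction must be in [0, 1]"
            )


@dataclass
class MarkerSpec:
    """Generative description of one marker; defaults mirror the static panel."""

    name: str
    group: str = ""
    mean: dict = field(default_factory=dict)  # cohort -> native mean
    sd: dict = field(default_factory=dict)  # cohort -> native SD
    family: str = "gaussian"  # or "lognormal"
    loading_f1: float = 0.0
    loading_f2: float = 0.0
    residual_sd: float = 0.8
    sex_stratified: bool = False

    @classmethod
    def from_def(cls, d: MarkerDef, residual_sd: float = 0.8) -> "MarkerSpec":
        return cls(
            name=d.name, group=d.group, mean=dict(d.mean), sd=dict(d.sd),
            family=d.family, loading_f1=d.loading_f1, loading_f2=d.loading_f2,
            residual_sd=residual_sd, sex_stratified=d.sex_stratified,
        )

    def validate(self, cohort_names) -> None:
        for c in cohort_names:
            if c not in self.mean or c not in self.sd:
                raise ValidationError(
                    f"marker {self.name}: missing mean/sd for cohort {c}"
                )
            if self.sd[c] <= 0:
                raise ValidationError(f"marker {self.name}: sd must be > 0 ({c})")
            if self.family == "lognormal" and self.mean[c] <= 0:
                raise ValidationError(
                    f"marker {self.name}: lognormal mean must be > 0 ({c})"
                )
        if self.family not in ("gaussian", "lognormal"):
            raise ValidationError(f"marker {self.name}: unknown family {self.family}")
        if self.residual_sd < 0:
            raise ValidationError(f"marker {self.name}: residual_sd must be >= 0")
        if self.loading_f1 ** 2 + self.loading_f2 ** 2 > 1.0 + 1e-12:
            raise ValidationError(
                f"marker {self.name}: loadings imply standardized variance > 1"
            )


@dataclass
class FactorAgeModel:
    """Quadratic population age trend plus subject intercept for one factor."""

    beta0: float = 0.0
    beta1: float = 0.0  # per year
    beta2: float = 0.0  # per year^2
    subject_sd: float = 0.6
    noise_sd: float = 0.5

    def validate(self, label: str) -> None:
        if self.subject_sd < 0:
            raise ValidationError(f"{label}.subject_sd must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError(f"{label}.noise_sd must be >= 0")

    def trend(self, age: np.ndarray) -> np.ndarray:
        return self.beta0 + self.beta1 * age + self.beta2 * age ** 2


@dataclass
class MortalityModel:
    baseline_hazard: float = 0.02  # per year
    log_hr_f1: float = 0.15  # log hazard per unit F1
    follow_up_years: float | None = None  # default: span of scheduled visits + 2

    def validate(self) -> None:
        if self.baseline_hazard < 0:
            raise ValidationError("mortality.baseline_hazard must be >= 0")


@dataclass
class CountOutcomeModel:
    """Truncated-Poisson count outcome with log-rate linear in F1."""

    log_rate_intercept: float = -0.2
    log_rate_f1: float = 0.3
    max_count: int = 5

    def validate(self, label: str) -> None:
        if self.max_count < 0:
            raise ValidationError(f"{label}.max_count must be >= 0")


@dataclass
class DiseaseModel:
    """Bernoulli disease flag with logit linear in F2; some codes ambiguous."""

    logit_intercept: float = -2.0
    logit_f2: float = 0.5
    ambiguous_prob: float = 0.05

    def validate(self) -> None:
        if not 0.0 <= self.ambiguous_prob <= 1.0:
            raise ValidationError("disease.ambiguous_prob must be in [0, 1]")


@dataclass
class GeneratorConfig:
    cohorts: list
    markers: list
    f1_age_model: FactorAgeModel = field(default_factory=FactorAgeModel)
    f2_age_model: FactorAgeModel = field(default_factory=FactorAgeModel)
    mortality: MortalityModel = field(default_factory=MortalityModel)
    frailty: CountOutcomeModel = field(
        default_factory=lambda: CountOutcomeModel(-0.2, 0.3, 5)
    )
    comorbidity: CountOutcomeModel = field(
        default_factory=lambda: CountOutcomeModel(0.5, 0.2, 13)
    )
    disease: DiseaseModel = field(default_factory=DiseaseModel)
    #: scalar rate, or {(cohort, marker): rate}; cells set missing at random
    missingness: float | dict = 0.01
    seed: int = 0

    def validate(self) -> None:
        if not self.cohorts:
            raise ValidationError("cohorts must be non-empty")
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ValidationError("cohort names must be unique")
        for c in self.cohorts:
            c.validate()
        if not self.markers:
            raise ValidationError("markers must be non-empty")
        for m in self.markers:
            m.validate(names)
        self.f1_age_model.validate("f1_age_model")
        self.f2_age_model.validate("f2_age_model")
        self.mortality.validate()
        self.frailty.validate("frailty")
        self.comorbidity.validate("comorbidity")
        self.disease.validate()
        rates = (
            self.missingness.values()
            if isinstance(self.missingness, dict)
            else [self.missingness]
        )
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise ValidationError("missingness rates must be in [0, 1]")

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def missing_rate(self, cohort: str, marker: str) -> float:
        if isinstance(self.missingness, dict):
            return self.missingness.get((cohort, marker), 0.0)
        return self.missingness

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.missingness, dict):
            d["missingness"] = {f"{c}:{m}": r for (c, m), r in self.missingness.items()}
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=_json_default, **kw)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def default_config(seed: int = 0, n_scale: float = 1.0,
                   residual_sd: float = 0.8) -> GeneratorConfig:
    """The default three-cohort study design.

    ``n_scale`` rescales every cohort's subject count (floor at 10) so that
    smaller but structurally identical panels can be simulated for tests.
    """
    def n(base):
        return max(10, int(round(base * n_scale)))

    cohorts = [
        CohortSpec("WHAS", n(1000), (65.0, 96.0), visits=3, visit_gap=1.5,
                   female_fraction=1.0,
                   strata={"race": ["white", "black"],
                           "education": ["<10y", "10y+"]}),
        CohortSpec("InCHIANTI", n(1050), (21.0, 95.0), visits=3, visit_gap=3.0,
                   female_fraction=0.55,
                   strata={"village": ["Greve", "Bagno a Ripoli"]}),
        CohortSpec("BLSA", n(1200), (21.0, 96.0), visits=2, visit_gap=2.0,
                   female_fraction=0.5,
                   strata={"race": ["white", "black"]}),
    ]
    markers = [MarkerSpec.from_def(d, residual_sd=residual_sd) for d in MARKER_DEFS]
    return GeneratorConfig(
        cohorts=cohorts,
        markers=markers,
        # J-shaped age trajectory of F1: shallow minimum near age 43, then
        # accelerating increase into old age.
        f1_age_model=FactorAgeModel(2.0, -0.12, 0.0014, subject_sd=0.8,
                                    noise_sd=0.6),
        f2_age_model=FactorAgeModel(-1.4, 0.02, 0.0, subject_sd=0.8,
                                    noise_sd=0.7),
        seed=seed,
    )


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _draw_visits(cohort: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Subject ids, visit indices and strictly increasing visit ages."""
    n = cohort.n_subjects
    lo, hi = cohort.age_range
    span = (cohort.visits - 1) * cohort.visit_gap
    entry = rng.uniform(lo, max(lo + 1e-6, hi - span), size=n)
    # jittered gaps, bounded away from zero so visit ages strictly increase
    gaps = cohort.visit_gap * rng.uniform(0.8, 1.2, size=(n, max(cohort.visits - 1, 1)))
    ages = entry[:, None] + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(gaps[:, : cohort.visits - 1], axis=1)], axis=1
    )
    sex = np.where(rng.random(n) < cohort.female_fraction, "female", "male")
    rows = {
        "cohort": np.repeat(cohort.name, n * cohort.visits),
        "subject": np.repeat(
            [f"{cohort.name}-{i:05d}" for i in range(n)], cohort.visits
        ),
        "visit": np.tile(np.arange(cohort.visits), n),
        "age": ages.ravel(),
        "sex": np.repeat(sex, cohort.visits),
    }
    for var, levels in cohort.strata.items():
        rows[var] = np.repeat(rng.choice(levels, size=n), cohort.visits)
    return pd.DataFrame(rows)


def _draw_factor(model: FactorAgeModel, ages: np.ndarray, subj_idx: np.ndarray,
                 n_subjects: int, rng: np.random.Generator):
    u = rng.normal(0.0, model.subject_sd, size=n_subjects)
    e = rng.normal(0.0, model.noise_sd, size=ages.shape[0])
    return model.trend(ages) + u[subj_idx] + e, u


def _native_values(spec: MarkerSpec, zeta: np.ndarray, cohort: str) -> np.ndarray:
    """Map a zero-mean unit-variance deviate to the native scale."""
    m, s = spec.mean[cohort], spec.sd[cohort]
    if spec.family == "gaussian":
        return m + s * zeta
    sigma2 = np.log1p((s / m) ** 2)
    sigma = np.sqrt(sigma2)
    mu = np.log(m) - sigma2 / 2.0
    return np.exp(mu + sigma * zeta)


def generate_panel(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full visit panel plus the ground-truth table.

    Returns ``(panel, truth)``: the panel holds demographics, outcomes and
    native-unit marker columns (with missingness applied); the truth table is
    row-aligned with the panel and holds the latent factor values, subject
    intercepts and true death ages.  Identical configs (including seed) give
    byte-identical output.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    s_visits, s_factors, s_markers, s_outcomes, s_missing = root.spawn(5)

    panels, truths = [], []
    rng_v = np.random.default_rng(s_visits)
    rng_f = np.random.default_rng(s_factors)
    rng_m = np.random.default_rng(s_markers)
    for cohort in config.cohorts:
        frame = _draw_visits(cohort, rng_v)
        subj_codes, subj_idx = np.unique(frame["subject"], return_inverse=True)
        ages = frame["age"].to_numpy()

        f1, u1 = _draw_factor(config.f1_age_model, ages, subj_idx,
                              len(subj_codes), rng_f)
        f2, u2 = _draw_factor(config.f2_age_model, ages, subj_idx,
                              len(subj_codes), rng_f)

        truth = frame[list(KEY_COLUMNS) + ["age"]].copy()
        truth["f1"] = f1
        truth["f2"] = f2
        truth["f1_subject_intercept"] = u1[subj_idx]
        truth["f2_subject_intercept"] = u2[subj_idx]

        for spec in config.markers:
            struct = spec.loading_f1 * f1 + spec.loading_f2 * f2
            var = struct.var() + spec.residual_sd ** 2
            z = struct + rng_m.normal(0.0, spec.residual_sd, size=len(struct))
            if var <= 0:
                # loadings and residual all zero: marker is constant at its mean
                zeta = np.zeros_like(z)
            else:
                zeta = (z - struct.mean()) / np.sqrt(var)
            frame[spec.name] = _native_values(spec, zeta, cohort.name)

        panels.append(frame)
        truths.append(truth)

    panel = pd.concat(panels, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)

    outcome_seed = int(s_outcomes.generate_state(1)[0] % (2 ** 31))
    outcomes = simulate_outcomes(truth, config, seed=outcome_seed)
    panel = pd.concat([panel, outcomes.drop(columns=["true_death_age"])], axis=1)
    truth["true_death_age"] = outcomes["true_death_age"]

    # drop visits occurring after death so visit histories are self-consistent
    keep = ~(panel["death_age"].notna() & (panel["age"] >= panel["death_age"]))
    # never drop a subject's first visit (death is drawn from entry, so the
    # first visit always precedes it; this guards the degenerate hazard case)
    panel, truth = panel.loc[keep].reset_index(drop=True), truth.loc[keep].reset_index(drop=True)

    missing_seed = int(s_missing.generate_state(1)[0] % (2 ** 31))
    panel = apply_missingness(panel, config.missingness, seed=missing_seed,
                              markers=config.marker_names)
    truth.attrs["config"] = config
    panel.attrs["markers"] = config.marker_names
    return panel, truth


def simulate_outcomes(truth: pd.DataFrame, config: GeneratorConfig,
                      seed: int) -> pd.DataFrame:
    """Draw factor-linked outcomes for each truth row.

    Death times are exponential on the age timescale from study entry with
    rate ``h0 * exp(log_hr_f1 * F1_entry)``; frailty/comorbidity counts are
    truncated Poisson with log-rate linear in F1 at the visit; the
    diabetes-like flag is Bernoulli in F2 with a fixed probability of an
    "ambiguous" recorded code.
    """
    config.mortality.validate()
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=truth.index)

    # --- mortality: one draw per subject, from the first visit -------------
    first = truth.sort_values("visit").groupby("subject", sort=True).first()
    h0 = config.mortality.baseline_hazard
    rate = h0 * np.exp(config.mortality.log_hr_f1 * first["f1"].to_numpy())
    with np.errstate(divide="ignore"):
        t_death = first["age"].to_numpy() + np.where(
            rate > 0, rng.exponential(1.0, size=len(first)) / np.maximum(rate, 1e-300),
            np.inf,
        )
    per_cohort_window = {
        c.name: (config.mortality.follow_up_years
                 if config.mortality.follow_up_years is not None
                 else (c.visits - 1) * c.visit_gap * 1.2 + 2.0)
        for c in config.cohorts
    }
    window = first["cohort"].map(per_cohort_window).to_numpy()
    limit = first["age"].to_numpy() + window
    observed = t_death <= limit
    death_age = pd.Series(np.where(observed, t_death, np.nan), index=first.index)
    censor_age = pd.Series(np.where(observed, t_death, limit), index=first.index)

    subj = truth["subject"]
    out["death_age"] = subj.map(death_age).to_numpy()
    out["censor_age"] = subj.map(censor_age).to_numpy()
    out["death_observed"] = subj.map(pd.Series(observed, index=first.index)).to_numpy()
    out["true_death_age"] = subj.map(pd.Series(t_death, index=first.index)).to_numpy()

    # --- per-visit counts ---------------------------------------------------
    f1 = truth["f1"].to_numpy()
    for label, model in (("frailty", config.frailty),
                         ("comorbidities", config.comorbidity)):
        lam = np.exp(model.log_rate_intercept + model.log_rate_f1 * f1)
        out[label] = np.minimum(rng.poisson(lam), model.max_count)

    # --- disease flag -------------------------------------------------------
    f2 = truth["f2"].to_numpy()
    p = 1.0 / (1.0 + np.exp(-(config.disease.logit_intercept
                              + config.disease.logit_f2 * f2)))
    status = np.where(rng.random(len(f2)) < p, "positive", "negative")
    ambiguous = rng.random(len(f2)) < config.disease.ambiguous_prob
    out["diabetes"] = np.where(ambiguous, "ambiguous", status)
    return out


def apply_missingness(panel: pd.DataFrame, rates: float | dict, seed: int,
                      markers: list[str] | None = None) -> pd.DataFrame:
    """Independently blank marker cells at the configured per-(cohort, marker) rate."""
    if markers is None:
        markers = panel.attrs.get("markers")
        if markers is None:
            raise ValidationError("markers must be given when panel lacks marker metadata")

    def rate_for(cohort, marker):
        r = rates.get((cohort, marker), 0.0) if isinstance(rates, dict) else rates
        if not 0.0 <= r <= 1.0:
            raise ValidationError(
                f"missingness rate for ({cohort}, {marker}) outside [0, 1]: {r}"
            )
        return r

    out = panel.copy()
    rng = np.random.default_rng(seed)
    for cohort in out["cohort"].unique():
        mask_rows = out["cohort"] == cohort
        n = int(mask_rows.sum())
        for marker in markers:
            r = rate_for(cohort, marker)
            if r == 0.0:
                continue
            hit = rng.random(n) < r
            col = out.loc[mask_rows, marker].to_numpy(dtype=float)
            col[hit] = np.nan
            out.loc[mask_rows, marker] = col
    out.attrs["markers"] = list(markers)
    return out


def validate_panel(panel: pd.DataFrame, markers: list[str] | None = None) -> None:
    """Check the structural invariants of a visit panel; raise on violation."""
    for col in KEY_COLUMNS + ("age", "sex"):
        if col not in panel.columns:
            raise ValidationError(f"panel missing required column {col!r}")
    keys = panel[list(KEY_COLUMNS)]
    if keys.duplicated().any():
        dupes = keys[keys.duplicated()].head()
        raise ValidationError(f"duplicate (cohort, subject, visit) keys: {dupes.values.tolist()}")
    by_subj = panel.sort_values("visit").groupby("subject")["age"]
    if not (by_subj.apply(lambda a: bool(np.all(np.diff(a) > 0)))).all():
        raise ValidationError("within-subject visit ages must be strictly increasing")
    if "death_age" in panel.columns:
        last = panel.groupby("subject").agg(last_age=("age", "max"),
                                            death=("death_age", "first"))
        bad = last["death"].notna() & (last["death"] < last["last_age"])
        if bad.any():
            raise ValidationError(
                f"death age precedes a visit for subjects {list(last.index[bad][:5])}"
            )
    if markers:
        absent = [m for m in markers if m not in panel.columns]
        if absent:
            raise ValidationError(f"panel missing marker columns {absent}")
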