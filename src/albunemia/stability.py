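"""Axis stability across populations, demographic subsets and random partitions.

The central statistic: fit an axis separately within each subset of a
partition, orient each version, re-project every version onto the *full*
standardized matrix, and correlate the resulting score vectors pairwise.
Versions correlating above 0.9 are operationally "the same axis".  Repeating
the procedure over many random mutually exclusive partitions gives a null
distribution for how much correlation pure sampling variation produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .axes import AxisModel, AxisScores, ImportanceProfile, fit_axes, orient_axis, project
from .errors import ValidationError
from .preprocessing import StandardizedMatrix

DEFAULT_AGE_BANDS = ((-np.inf, 65.0), (65.0, 80.0), (80.0, np.inf))
DEFAULT_SAME_AXIS_THRESHOLD = 0.9


@dataclass
class SubsetScheme:
    """A labelled partition of the observations of one matrix."""

    name: str
    labels: np.ndarray  # one label per observation
    kind: str  # "demographic" | "random-exclusive"
    seed: int | None = None
    warnings: list = field(default_factory=list)

    @property
    def sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()

    def groups(self):
        s = pd.Series(self.labels)
        for label, idx in s.groupby(s, sort=True).groups.items():
            yield label, np.asarray(idx)


@dataclass
class StabilityReport:
    """Pairwise correlations among axis versions, with summary and verdict."""

    labels: list
    correlations: np.ndarray  # symmetric, unit diagonal
    subset_sizes: dict = field(default_factory=dict)
    threshold: float = DEFAULT_SAME_AXIS_THRESHOLD

    @property
    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.correlations[iu]

    @property
    def mean(self) -> float:
        return float(self.offdiagonal.mean())

    @property
    def minimum(self) -> float:
        return float(self.offdiagonal.min())

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.offdiagonal, [25, 75])
        return float(lo), float(hi)

    @property
    def same_axis(self) -> bool:
        return bool(np.all(self.offdiagonal > self.threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.correlations, index=self.labels,
                            columns=self.labels)


@dataclass
class NullDistributionSummary:
    """Per-replicate and grand summaries of the random-partition null."""

    per_replicate: pd.DataFrame  # columns: mean, min, q25, q75
    k: int
    seed: int

    @property
    def replicates(self) -> int:
        return len(self.per_replicate)

    @property
    def mean_of_means(self) -> float:
        return float(self.per_replicate["mean"].mean())

    @property
    def mean_of_minima(self) -> float:
        return float(self.per_replicate["min"].mean())

    @property
    def mean_iqr(self) -> tuple[float, float]:
        return (float(self.per_replicate["q25"].mean()),
                float(self.per_replicate["q75"].mean()))

    def to_dict(self) -> dict:
        lo, hi = self.mean_iqr
        return {
            "replicates": self.replicates, "k": self.k, "seed": self.seed,
            "mean_of_means": self.mean_of_means,
            "mean_of_minima": self.mean_of_minima,
            "mean_iqr_low": lo, "mean_iqr_high": hi,
        }


# --------------------------------------------------------------------------
# schemes
# --------------------------------------------------------------------------

def band_age(ages, bands=DEFAULT_AGE_BANDS) -> np.ndarray:
    """Default clinical age bands: <65, 65-80, 80+."""
    ages = np.asarray(ages, dtype=float)
    labels = np.empty(len(ages), dtype=object)
    names = ["<65", "65-80", "80+"] if bands is DEFAULT_AGE_BANDS else [
        f"{lo}-{hi}" for lo, hi in bands
    ]
    for (lo, hi), name in zip(bands, names):
        labels[(ages >= lo) & (ages < hi)] = name
    return labels


def demographic_subsets(meta: pd.DataFrame, variables,
                        n_markers: int | None = None) -> SubsetScheme:
    """Partition observations by the level combinations of demographic variables.

    ``age`` is banded at <65 / 65-80 / 80+.  Levels with fewer observations
    than markers (when ``n_markers`` is given) are flagged in the scheme's
    warnings; downstream PCA skips them.
    """
    variables = list(variables)
    parts = []
    for var in variables:
        if var == "age":
            parts.append(pd.Series(band_age(meta["age"]), index=meta.index,
                                   name="age"))
            continue
        if var not in meta.columns:
            raise ValidationError(f"demographic variable {var!r} absent from metadata")
        parts.append(meta[var].astype(str))
    combo = parts[0].astype(str)
    for p in parts[1:]:
        combo = combo + "/" + p.astype(str)
    labels = combo.to_numpy()
    scheme = SubsetScheme(name="+".join(variables), labels=labels,
                          kind="demographic")
    for var, p in zip(variables, parts):
        if p.nunique() < 2:
            raise ValidationError(
                f"demographic variable {var!r} has fewer than 2 non-empty levels"
            )
    if n_markers is not None:
        for label, count in scheme.sizes.items():
            if count <= n_markers:
                scheme.warnings.append(
                    f"subset {label!r} has {count} observations "
                    f"(<= {n_markers} markers); PCA may be skipped"
                )
    return scheme


def random_exclusive_subsets(n_obs: int, k: int, seed: int) -> SubsetScheme:
    """Uniformly random partition into k groups with sizes differing by <= 1."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n_obs:
        raise ValidationError(f"k = {k} exceeds n_obs = {n_obs}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_obs)
    base, rem = divmod(n_obs, k)
    sizes = [base + 1 if g < rem else base for g in range(k)]
    labels = np.empty(n_obs, dtype=object)
    start = 0
    for g, size in enumerate(sizes):
        labels[perm[start:start + size]] = f"subset-{g:02d}"
        start += size
    return SubsetScheme(name=f"random-{k}", labels=labels,
                        kind="random-exclusive", seed=seed)


# --------------------------------------------------------------------------
# replication
# --------------------------------------------------------------------------

def replicate_axes(matrix: StandardizedMatrix, scheme: SubsetScheme,
                   axis: int = 0):
    """Fit an axis in each subset, orient it, and re-project onto the full matrix.

    Subsets with no more rows than markers are skipped (reason logged on the
    scheme).  Returns ``(models, scores)`` with scores on the full matrix.
    """
    if len(scheme.labels) != matrix.n_obs:
        raise ValidationError(
            f"scheme covers {len(scheme.labels)} observations, matrix has {matrix.n_obs}"
        )
    p = len(matrix.markers)
    ages = (matrix.meta["age"].to_numpy()
            if "age" in matrix.meta.columns else None)
    models, scores = [], []
    for label, idx in scheme.groups():
        if len(idx) <= p:
            scheme.warnings.append(
                f"subset {label!r} skipped: {len(idx)} rows <= {p} markers"
            )
            continue
        sub = matrix.take(idx)
        model = fit_axes(sub, source=str(label))
        sub_scores = project(model, sub, axis=axis)
        sub_ages = ages[idx] if ages is not None else None
        model = orient_axis(model, sub_scores, sub_ages, axis=axis)
        models.append(model)
        scores.append(project(model, matrix, axis=axis))
    if not models:
        raise ValidationError("all subsets were unusable (too few rows)")
    return models, scores


def pairwise_axis_correlations(scores, labels=None,
                               threshold: float = DEFAULT_SAME_AXIS_THRESHOLD,
                               subset_sizes: dict | None = None) -> StabilityReport:
    """Pearson correlation matrix among axis-score versions on common rows."""
    arrays = [s.values if isinstance(s, AxisScores) else np.asarray(s, dtype=float)
              for s in scores]
    if len(arrays) < 2:
        raise ValidationError("need at least 2 score vectors")
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValidationError("score vectors cover different numbers of rows")
    if labels is None:
        labels = [
            s.source if isinstance(s, AxisScores) and s.source else f"v{i}"
            for i, s in enumerate(scores)
        ]
    corr = np.corrcoef(np.vstack(arrays))
    np.fill_diagonal(corr, 1.0)
    return StabilityReport(labels=list(labels), correlations=corr,
                           subset_sizes=subset_sizes or {}, threshold=threshold)


def same_axis(report: StabilityReport,
              threshold: float = DEFAULT_SAME_AXIS_THRESHOLD) -> bool:
    """True iff every off-diagonal correlation exceeds the threshold."""
    return bool(np.all(report.offdiagonal > threshold))


def null_distribution(matrix: StandardizedMatrix, k: int = 10,
                      reps: int = 100, seed: int = 0,
                      axis: int = 0) -> NullDistributionSummary:
    """Random-exclusive-subset stability null.

    Each replicate partitions the observations into ``k`` random exclusive
    groups, fits and orients an axis per group, re-projects all versions onto
    the full matrix, and summarizes the C(k,2) pairwise correlations.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2 ** 31)
    rows = []
    for rep, s in enumerate(child_seeds):
        try:
            scheme = random_exclusive_subsets(matrix.n_obs, k, int(s))
            _, scores = replicate_axes(matrix, scheme, axis=axis)
            report = pairwise_axis_correlations(scores)
        except ValidationError as err:
            raise ValidationError(f"replicate {rep}: {err}") from err
        lo, hi = report.iqr
        rows.append({"mean": report.mean, "min": report.minimum,
                     "q25": lo, "q75": hi})
    return NullDistributionSummary(per_replicate=pd.DataFrame(rows), k=k,
                                   seed=seed)


def importance_stability(profiles):
    """Agreement among importance profiles over a common marker set.

    Returns ``(mean absolute weight difference, mean Spearman rank correlation)``
    over all profile pairs.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValidationError("need at least 2 importance profiles")
    marker_sets = [frozenset(p.markers) for p in profiles]
    if len(set(marker_sets)) != 1:
        raise ValidationError("importance profiles cover different marker sets")
    series = [p.as_series().sort_index() for p in profiles]
    diffs, rhos = [], []
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            diffs.append(np.abs(series[i] - series[j]).mean())
            rho = stats.spearmanr(series[i], series[j]).statistic
            rhos.append(rho)
    return float(np.mean(diffs)), float(np.mean(rhos))
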