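"""Normality transforms and per-cohort standardization.

Protocol: for each (cohort, marker) independently, choose among identity,
log(x + shift) and sqrt(x + shift) the transform minimizing the absolute
sample skewness, then center/scale the transformed values to mean 0 / SD 1
within the cohort (within sex strata for flagged markers — estradiol by
default, so each individual is scored relative to members of their sex).
The fitted spec is serializable so stored axes can score new data exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateInputError, EmptyPanelError, ValidationError)

_SPEC_FORMAT_VERSION = 1

#: candidate transforms, least aggressive first (tie-break order)
_FAMILIES = ("identity", "sqrt", "log")

_POOLED = "__all__"  # stratum key when a marker is not sex-stratified


def _apply_family(family: str, values: np.ndarray, shift: float) -> np.ndarray:
    if family == "identity":
        return values
    shifted = values + shift
    if family == "log":
        if np.any(shifted <= 0):
            raise ValidationError(
                f"log transform domain error: value <= {-shift}"
            )
        return np.log(shifted)
    if family == "sqrt":
        if np.any(shifted < 0):
            raise ValidationError(
                f"sqrt transform domain error: value < {-shift}"
            )
        return np.sqrt(shifted)
    raise ValidationError(f"unknown transform family {family!r}")


def choose_transform(values) -> tuple[str, float]:
    """Pick the transform family minimizing |sample skewness|.

    Returns ``(family, shift)`` where ``shift = max(0, eps - min(values))``
    with ``eps = 1e-6 * SD`` guarantees strict positivity before log/sqrt.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise DegenerateInputError(
            f"need >= 10 non-missing values, got {v.size}"
        )
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant input: no transform is defined")
    shift = max(0.0, 1e-6 * sd - v.min())
    best_family, best_skew = None, np.inf
    for family in _FAMILIES:
        skew = abs(stats.skew(_apply_family(family, v, shift if family != "identity" else 0.0)))
        if skew < best_skew - 1e-15:
            best_family, best_skew = family, skew
    return best_family, (0.0 if best_family == "identity" else shift)


@dataclass
class MarkerTransform:
    """Fitted transform + per-stratum standardization for one (cohort, marker)."""

    family: str
    shift: float
    sex_stratified: bool
    params: dict  # stratum ("__all__", "female", "male") -> (center, scale)

    def standardize(self, values: np.ndarray, sex: np.ndarray | None) -> np.ndarray:
        out = np.full(values.shape, np.nan)
        ok = np.isfinite(values)
        if not self.sex_stratified:
            center, scale = self.params[_POOLED]
            out[ok] = (_apply_family(self.family, values[ok], self.shift) - center) / scale
            return out
        if sex is None:
            raise ValidationError("sex column required for a sex-stratified marker")
        for stratum, (center, scale) in self.params.items():
            sel = ok & (np.asarray(sex) == stratum)
            if sel.any():
                out[sel] = (_apply_family(self.family, values[sel], self.shift) - center) / scale
        return out


@dataclass
class TransformSpec:
    """Per-(cohort, marker) transforms; the full standardization recipe."""

    transforms: dict = field(default_factory=dict)  # (cohort, marker) -> MarkerTransform
    markers: list = field(default_factory=list)
    version: int = _SPEC_FORMAT_VERSION

    def get(self, cohort: str, marker: str) -> MarkerTransform:
        try:
            return self.transforms[(cohort, marker)]
        except KeyError:
            raise ValidationError(
                f"no fitted transform for cohort {cohort!r}, marker {marker!r}"
            ) from None

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": self.version,
            "markers": list(self.markers),
            "transforms": [
                {
                    "cohort": c, "marker": m, "family": t.family,
                    "shift": t.shift, "sex_stratified": t.sex_stratified,
                    "params": {k: [float(v[0]), float(v[1])] for k, v in t.params.items()},
                }
                for (c, m), t in self.transforms.items()
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        spec = cls(markers=list(d["markers"]), version=d.get("format_version", 1))
        for entry in d["transforms"]:
            spec.transforms[(entry["cohort"], entry["marker"])] = MarkerTransform(
                family=entry["family"], shift=entry["shift"],
                sex_stratified=entry["sex_stratified"],
                params={k: (v[0], v[1]) for k, v in entry["params"].items()},
            )
        return spec

    @classmethod
    def from_json(cls, text: str) -> "TransformSpec":
        return cls.from_dict(json.loads(text))


@dataclass
class StandardizedMatrix:
    """Observation x marker matrix on the standardized scale plus row metadata."""

    values: pd.DataFrame  # columns = markers; may contain NaN until complete_cases
    meta: pd.DataFrame  # cohort/subject/visit/age/sex/strata, index-aligned
    spec: TransformSpec

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_obs(self) -> int:
        return len(self.values)

    def subset_markers(self, markers) -> "StandardizedMatrix":
        absent = [m for m in markers if m not in self.values.columns]
        if absent:
            raise ValidationError(f"markers not in matrix: {absent}")
        return StandardizedMatrix(self.values[list(markers)].copy(), self.meta, self.spec)

    def take(self, positions) -> "StandardizedMatrix":
        return StandardizedMatrix(
            self.values.iloc[positions].reset_index(drop=True),
            self.meta.iloc[positions].reset_index(drop=True),
            self.spec,
        )


DEFAULT_SEX_STRATIFIED = ("estradiol",)


def fit_transform_spec(panel: pd.DataFrame, markers,
                       sex_stratified_markers=DEFAULT_SEX_STRATIFIED,
                       cohort_column: str | None = "cohort") -> TransformSpec:
    """Fit the full transformation recipe on a panel.

    Transform family/shift are chosen per (cohort, marker) on all non-missing
    values; centers and scales are computed on the transformed values, within
    sex strata for flagged markers.  Pass ``cohort_column=None`` to treat the
    whole panel as a single pooled cohort (used by the clinical calculator).
    """
    markers = list(markers)
    absent = [m for m in markers if m not in panel.columns]
    if absent:
        raise ValidationError(f"markers absent from panel: {absent}")
    spec = TransformSpec(markers=markers)
    if cohort_column is None:
        groups = [(_POOLED, panel)]
    else:
        groups = list(panel.groupby(cohort_column, sort=True))
    for cohort, sub in groups:
        for marker in markers:
            col = sub[marker].to_numpy(dtype=float)
            family, shift = choose_transform(col)
            stratified = marker in sex_stratified_markers
            params = {}
            if stratified:
                # strata are the sex levels present in this cohort (a
                # women-only cohort legitimately has a single stratum)
                for stratum in sorted(sub["sex"].dropna().unique()):
                    sel = (sub["sex"] == stratum).to_numpy()
                    vals = col[sel & np.isfinite(col)]
                    if vals.size < 2:
                        raise ValidationError(
                            f"sex stratum {stratum!r} empty or too small for "
                            f"stratified marker {marker!r} in cohort {cohort!r}"
                        )
                    t = _apply_family(family, vals, shift)
                    params[stratum] = (t.mean(), t.std(ddof=1))
            else:
                vals = col[np.isfinite(col)]
                t = _apply_family(family, vals, shift)
                params[_POOLED] = (t.mean(), t.std(ddof=1))
            for stratum, (center, scale) in params.items():
                if scale <= 0:
                    raise DegenerateInputError(
                        f"zero variance for marker {marker!r} in cohort "
                        f"{cohort!r} stratum {stratum!r}"
                    )
            spec.transforms[(cohort, marker)] = MarkerTransform(
                family, shift, stratified, params
            )
    return spec


def standardize(panel: pd.DataFrame, spec: TransformSpec,
                cohort_column: str | None = "cohort",
                meta_columns=None) -> StandardizedMatrix:
    """Apply a fitted spec; missing values stay missing."""
    values = pd.DataFrame(index=panel.index.copy())
    if cohort_column is None:
        cohort_of = pd.Series(_POOLED, index=panel.index)
    else:
        cohort_of = panel[cohort_column]
    sex = panel["sex"].to_numpy() if "sex" in panel.columns else None
    for marker in spec.markers:
        col = panel[marker].to_numpy(dtype=float)
        out = np.full(col.shape, np.nan)
        for cohort in cohort_of.unique():
            sel = (cohort_of == cohort).to_numpy()
            mt = spec.get(cohort, marker)
            out[sel] = mt.standardize(col[sel], sex[sel] if sex is not None else None)
        values[marker] = out
    meta_cols = meta_columns or [
        c for c in panel.columns if c not in spec.markers
    ]
    meta = panel[list(meta_cols)].copy()
    return StandardizedMatrix(values.reset_index(drop=True),
                              meta.reset_index(drop=True), spec)


def complete_cases(matrix: StandardizedMatrix, markers=None):
    """Keep rows with no missing value among the requested markers.

    Returns ``(filtered matrix, counts)`` where counts is a per-cohort table
    of retained individuals and visits.
    """
    markers = list(markers) if markers is not None else matrix.markers
    sub = matrix.subset_markers(markers)
    keep = np.flatnonzero(sub.values.notna().all(axis=1).to_numpy())
    if keep.size == 0:
        raise EmptyPanelError(
            f"no complete observations for the {len(markers)} requested markers"
        )
    out = sub.take(keep)
    if "cohort" in out.meta.columns:
        counts = out.meta.groupby("cohort").agg(
            individuals=("subject", "nunique"), visits=("subject", "size")
        )
    else:
        counts = pd.DataFrame(
            {"individuals": [out.meta["subject"].nunique() if "subject" in out.meta else out.n_obs],
             "visits": [out.n_obs]}, index=["all"]
        )
    return out, counts
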