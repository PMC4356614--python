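"""Principal-axis extraction and the reduced clinical score.

An axis is a unit-norm linear combination of standardized biomarkers
maximizing explained variance, orthogonal to preceding axes.  Axes are
extracted on the correlation scale (the sample correlation matrix of the
standardized matrix); a marker's *loading importance* on an axis is
|loading| / sum(|loadings|).  Because an eigenvector's sign is arbitrary,
axes are given a deterministic default sign (largest-|loading| marker
positive) and can be re-oriented to correlate positively with age, the
convention under which the first axis increases over adult life.

Cross-dataset replication works by *re-projection*: loadings estimated on
one dataset or subset are applied to another dataset standardized with its
own per-cohort recipe, and the resulting score vectors are compared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (DegenerateInputError, MarkerMismatchError,
                     ValidationError)
from .preprocessing import StandardizedMatrix, TransformSpec, complete_cases

_MODEL_FORMAT_VERSION = 1


@dataclass
class AxisModel:
    """Orthonormal loadings plus eigenvalues for a fitted marker panel."""

    markers: list  # ordered marker names
    loadings: np.ndarray  # p x k, orthonormal columns
    eigenvalues: np.ndarray  # length k, non-increasing
    source: str = ""
    orientation: list = field(default_factory=list)  # one record per axis
    spec: TransformSpec | None = None

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if not self.orientation:
            self.orientation = [{"rule": "default-sign", "flipped": False}
                                for _ in range(self.n_axes)]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    @property
    def variance_fractions(self) -> np.ndarray:
        """Eigenvalue over total standardized variance (= number of markers)."""
        return self.eigenvalues / self.n_markers

    def loading_series(self, axis: int = 0) -> pd.Series:
        return pd.Series(self.loadings[:, axis], index=self.markers)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": _MODEL_FORMAT_VERSION,
            "source": self.source,
            "markers": list(self.markers),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "orientation": self.orientation,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "AxisModel":
        return cls(markers=list(d["markers"]),
                   loadings=np.asarray(d["loadings"], dtype=float),
                   eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
                   source=d.get("source", ""),
                   orientation=list(d.get("orientation", [])))

    @classmethod
    def from_json(cls, text: str) -> "AxisModel":
        return cls.from_dict(json.loads(text))


@dataclass
class AxisScores:
    """Per-observation scores on one axis, with provenance."""

    values: np.ndarray
    axis: int
    source: str = ""
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("axis scores must be finite")

    def __len__(self):
        return len(self.values)


@dataclass
class ImportanceProfile:
    """Non-negative per-marker weights summing to 1, ordered descending."""

    markers: list
    weights: np.ndarray
    axis: int = 0
    source: str = ""

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.markers)


def _as_values(matrix) -> tuple[np.ndarray, list]:
    if isinstance(matrix, StandardizedMatrix):
        return matrix.values.to_numpy(dtype=float), matrix.markers
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.columns)
    arr = np.asarray(matrix, dtype=float)
    return arr, [f"m{i}" for i in range(arr.shape[1])]


def fit_axes(matrix, source: str = "") -> AxisModel:
    """Correlation-scale PCA of a standardized matrix.

    The decomposition is computed from the sample correlation matrix of the
    input (columns re-centered/re-scaled internally, which is a no-op on
    exactly standardized data).  Signs follow the deterministic default rule;
    use :func:`orient_axis` for the age convention.
    """
    X, markers = _as_values(matrix)
    n, p = X.shape
    if n < 3:
        raise DegenerateInputError(f"need at least 3 rows, got {n}")
    if np.isnan(X).any():
        raise ValidationError("matrix contains missing cells; run complete_cases first")
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateInputError(
            f"constant column(s): {[markers[i] for i in dead]}"
        )
    Z = (X - X.mean(axis=0)) / sd
    # SVD route; the explicit eigendecomposition of corrcoef is the test oracle
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = s ** 2 / (n - 1)
    loadings = vt.T
    if p > len(eig):  # n-1 < p: pad the null space with zero-variance axes
        pad = p - len(eig)
        eig = np.concatenate([eig, np.zeros(pad)])
        q, _ = np.linalg.qr(np.eye(p) - loadings @ loadings.T)
        loadings = np.hstack([loadings, q[:, :pad]])
    # deterministic sign: the largest-|loading| marker loads positively
    for k in range(loadings.shape[1]):
        top = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[top, k] < 0:
            loadings[:, k] = -loadings[:, k]
    spec = matrix.spec if isinstance(matrix, StandardizedMatrix) else None
    return AxisModel(markers=list(markers), loadings=loadings, eigenvalues=eig,
                     source=source, spec=spec)


def project(model: AxisModel, matrix, axis: int = 0) -> AxisScores:
    """Score observations: standardized row dot loading column."""
    X, markers = _as_values(matrix)
    if list(markers) != list(model.markers):
        missing = set(model.markers) - set(markers)
        extra = set(markers) - set(model.markers)
        if missing or extra:
            raise MarkerMismatchError(missing=missing, extra=extra)
        # same set, different order: align
        order = [list(markers).index(m) for m in model.markers]
        X = X[:, order]
    if np.isnan(X).any():
        raise ValidationError("matrix contains missing cells; run complete_cases first")
    meta = matrix.meta if isinstance(matrix, StandardizedMatrix) else None
    # row-local reduction: a row's score is bit-identical whether it is
    # scored alone or in a batch (a plain matmul is not)
    values = (X * model.loadings[:, axis]).sum(axis=1)
    return AxisScores(values=values, axis=axis, source=model.source, meta=meta)


def orient_axis(model: AxisModel, scores: AxisScores | np.ndarray | None = None,
                ages=None, axis: int = 0) -> AxisModel:
    """Flip an axis so its scores correlate positively with age.

    If ages are absent or the correlation is numerically zero, fall back to
    the deterministic rule (largest-|loading| marker positive).  Idempotent.
    """
    values = scores.values if isinstance(scores, AxisScores) else scores
    flip = None
    rule = "age-correlation"
    if values is not None and ages is not None:
        ages = np.asarray(ages, dtype=float)
        if len(ages) != len(values):
            raise ValidationError(
                f"length mismatch: {len(values)} scores vs {len(ages)} ages"
            )
        r = np.corrcoef(values, ages)[0, 1]
        if np.isfinite(r) and abs(r) >= 1e-6:
            flip = r < 0
    if flip is None:
        rule = "top-loading-positive"
        top = int(np.argmax(np.abs(model.loadings[:, axis])))
        flip = model.loadings[top, axis] < 0
    loadings = model.loadings.copy()
    if flip:
        loadings[:, axis] = -loadings[:, axis]
    orientation = [dict(rec) for rec in model.orientation]
    orientation[axis] = {"rule": rule, "flipped": bool(flip)}
    return replace(model, loadings=loadings, orientation=orientation)


def fit_oriented_axes(matrix: StandardizedMatrix, axis: int = 0,
                      source: str = "") -> tuple[AxisModel, AxisScores]:
    """Fit, orient axis ``axis`` by age (from row metadata), and score."""
    model = fit_axes(matrix, source=source)
    scores = project(model, matrix, axis=axis)
    ages = matrix.meta["age"].to_numpy() if "age" in matrix.meta.columns else None
    model = orient_axis(model, scores, ages, axis=axis)
    return model, project(model, matrix, axis=axis)


def importance(model: AxisModel, axis: int = 0) -> ImportanceProfile:
    """Loading importance: |loading| / sum(|loadings|), ordered descending."""
    if not 0 <= axis < model.n_axes:
        raise ValidationError(f"axis {axis} out of range (0..{model.n_axes - 1})")
    load = np.abs(model.loadings[:, axis])
    weights = load / load.sum()
    order = np.argsort(-weights, kind="stable")
    return ImportanceProfile(
        markers=[model.markers[i] for i in order], weights=weights[order],
        axis=axis, source=model.source,
    )


def anemia_subaxis(matrix: StandardizedMatrix, anemia_markers) -> AxisScores:
    """First-axis scores of a PCA restricted to the anemia marker cluster."""
    anemia_markers = list(anemia_markers)
    if not anemia_markers:
        raise ValidationError("anemia marker set is empty")
    sub, _ = complete_cases(matrix, anemia_markers)
    _, scores = fit_oriented_axes(sub, source="anemia-subaxis")
    return scores


def reduce_axis(model: AxisModel, matrix: StandardizedMatrix,
                required=(), forbidden=(), target_size: int = 14,
                axis: int = 0):
    """Greedy backward elimination toward a compact clinical axis.

    Repeatedly drops the non-required marker whose removal (after refitting
    the PCA on the remaining markers and orienting the refit axis to correlate
    positively with the full-axis scores) least reduces |r| with the full-axis
    scores.  Returns ``(reduced AxisModel, final r)``.
    """
    required, forbidden = set(required), set(forbidden)
    if required & forbidden:
        raise ValidationError(
            f"required and forbidden overlap: {sorted(required & forbidden)}"
        )
    if target_size < 2:
        raise ValidationError("target size must be >= 2")
    if target_size < len(required):
        raise ValidationError(
            f"target size {target_size} smaller than required set ({len(required)})"
        )
    full_scores = project(model, matrix, axis=axis).values
    current = [m for m in model.markers if m not in forbidden]
    if len(current) < target_size:
        raise ValidationError("forbidden set leaves fewer markers than target size")

    def refit_flip(markers):
        sub = matrix.subset_markers(markers)
        m = fit_axes(sub, source=f"reduced-{len(markers)}")
        s = project(m, sub, axis=axis).values
        r = float(np.corrcoef(s, full_scores)[0, 1])
        if r < 0:
            loadings = m.loadings.copy()
            loadings[:, axis] = -loadings[:, axis]
            orientation = [dict(rec) for rec in m.orientation]
            orientation[axis] = {"rule": "full-axis-correlation", "flipped": True}
            m = replace(m, loadings=loadings, orientation=orientation)
            r = -r
        return m, r

    best_model, best_r = refit_flip(current)
    while len(current) > target_size:
        candidates = [m for m in current if m not in required]
        if not candidates:
            break
        trials = []
        for drop in candidates:
            remaining = [m for m in current if m != drop]
            trials.append((refit_flip(remaining), drop))
        (best_model, best_r), dropped = max(trials, key=lambda t: t[0][1])
        current = [m for m in current if m != dropped]
    return best_model, float(best_r)


# --------------------------------------------------------------------------
# clinical score
# --------------------------------------------------------------------------

@dataclass
class ClinicalReference:
    """Everything needed to score a new patient on the reduced axis.

    Holds the reduced axis model and a flattened transform recipe (one
    family/shift/center/scale per marker, fitted on the pooled reference
    data) so scoring requires only raw native-unit measurements.
    """

    model: AxisModel
    transforms: dict  # marker -> {"family", "shift", "center", "scale"}
    training_scores: list = field(default_factory=list)  # reference histogram

    def to_json(self, **kw) -> str:
        return json.dumps({
            "format_version": _MODEL_FORMAT_VERSION,
            "model": self.model.to_dict(),
            "transforms": self.transforms,
            "training_scores": [float(x) for x in self.training_scores],
        }, **kw)

    @classmethod
    def from_json(cls, text: str) -> "ClinicalReference":
        d = json.loads(text)
        return cls(model=AxisModel.from_dict(d["model"]),
                   transforms=d["transforms"],
                   training_scores=d.get("training_scores", []))


def build_clinical_reference(model: AxisModel, spec: TransformSpec,
                             cohort: str, training_scores=()) -> ClinicalReference:
    """Flatten a per-cohort TransformSpec into a single-recipe reference."""
    from .preprocessing import _POOLED  # stratum key
    transforms = {}
    for marker in model.markers:
        mt = spec.get(cohort, marker)
        if mt.sex_stratified:
            raise ValidationError(
                f"marker {marker!r} is sex-stratified; the clinical reference "
                "requires unstratified transforms"
            )
        center, scale = mt.params[_POOLED]
        transforms[marker] = {"family": mt.family, "shift": mt.shift,
                              "center": float(center), "scale": float(scale)}
    return ClinicalReference(model=model, transforms=transforms,
                             training_scores=list(training_scores))


def clinical_score(measurements, reference: ClinicalReference,
                   axis: int = 0) -> np.ndarray:
    """Score one or many patients from raw native-unit measurements.

    ``measurements`` is a mapping (one patient) or DataFrame (batch) with all
    reference markers present and numeric; any missing marker raises an error
    listing the missing names — no partial scores are produced.
    """
    from .preprocessing import _apply_family
    if isinstance(measurements, dict):
        frame = pd.DataFrame([measurements])
    else:
        frame = pd.DataFrame(measurements)
    missing = [m for m in reference.model.markers if m not in frame.columns]
    present = [m for m in reference.model.markers if m in frame.columns]
    bad = [m for m in present if frame[m].isna().any()
           or not np.issubdtype(frame[m].dtype, np.number)]
    if missing or bad:
        raise ValidationError(
            f"cannot score: missing markers {sorted(set(missing) | set(bad))}"
        )
    cols = {}
    for marker in reference.model.markers:
        t = reference.transforms[marker]
        v = _apply_family(t["family"], frame[marker].to_numpy(dtype=float),
                          t["shift"])
        cols[marker] = (v - t["center"]) / t["scale"]
    Z = pd.DataFrame(cols)[reference.model.markers].to_numpy()
    return (Z * reference.model.loadings[:, axis]).sum(axis=1)
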