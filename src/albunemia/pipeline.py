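"""End-to-end analysis pipeline: panel in, report bundle out.

Stage order mirrors the study protocol: transform/standardize -> complete
cases on the chosen marker set -> visit selection -> axis extraction and
importance -> stability (demographic subsets + random-partition null) ->
age trajectories -> outcome associations -> reduced clinical reference.
Every source of randomness derives from the single configured seed, so a
(panel, config) pair fully determines the bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .axes import (AxisModel, build_clinical_reference, fit_oriented_axes,
                   importance, project, reduce_axis)
from .errors import ValidationError
from .markers import CLINICAL_14, marker_set
from .outcomes import (association_table, binary_association, build_intervals,
                       count_association, cox_axis)
from .preprocessing import (StandardizedMatrix, complete_cases,
                            fit_transform_spec, standardize)
from .stability import (demographic_subsets, null_distribution,
                        pairwise_axis_correlations, replicate_axes)
from .synthetic import (GeneratorConfig, KEY_COLUMNS, default_config,
                        generate_panel, validate_panel)
from .trajectories import fit_trajectory

VISIT_RULES = ("first", "all", "random-per-subject")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    panel_path: str | None = None  # CSV/TSV visit panel; or use generator
    generator: GeneratorConfig | None = None
    marker_set: str | list = "full-43"
    visit_rule: str = "first"
    stages: dict = field(default_factory=lambda: {
        "axes": True, "stability": True, "trajectories": True,
        "outcomes": True, "score": True,
    })
    stability_variables: list = field(default_factory=lambda: ["sex"])
    null_k: int = 10
    null_reps: int = 20
    trajectory_form: str = "quadratic"
    seed: int = 0
    outdir: str | None = None

    def validate(self):
        if (self.panel_path is None) == (self.generator is None):
            raise ValidationError(
                "exactly one input source required: panel_path or generator"
            )
        if self.visit_rule not in VISIT_RULES:
            raise ValidationError(f"visit_rule must be one of {VISIT_RULES}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.get("generator")
        if gen is not None and not isinstance(gen, GeneratorConfig):
            if gen == "default" or gen is True:
                d["generator"] = default_config(seed=d.get("seed", 0))
            elif isinstance(gen, dict):
                base = default_config(seed=gen.get("seed", d.get("seed", 0)),
                                      n_scale=gen.get("n_scale", 1.0))
                d["generator"] = base
            else:
                raise ValidationError("generator must be 'default' or a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ReportBundle:
    """All artifacts of one pipeline run."""

    panel: pd.DataFrame
    matrix: StandardizedMatrix | None = None
    complete_counts: pd.DataFrame | None = None
    axis_model: AxisModel | None = None
    importance_profiles: dict = field(default_factory=dict)
    stability_report: object = None
    null_summary: object = None
    trajectory_fits: list = field(default_factory=list)
    associations: list = field(default_factory=list)
    clinical_reference: object = None
    manifest: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)  # stage -> reason

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_panel(self.panel, out / "panel.csv")
        if self.matrix is not None:
            (out / "transform_spec.json").write_text(
                self.matrix.spec.to_json(indent=1))
        if self.complete_counts is not None:
            self.complete_counts.to_csv(out / "complete_case_counts.csv")
        if self.axis_model is not None:
            (out / "axis_model.json").write_text(self.axis_model.to_json(indent=1))
        for axis, prof in self.importance_profiles.items():
            prof.as_series().rename("importance").to_csv(
                out / f"importance_axis{axis + 1}.csv")
        if self.stability_report is not None:
            self.stability_report.to_frame().to_csv(out / "stability_matrix.csv")
        if self.null_summary is not None:
            (out / "null_summary.json").write_text(
                json.dumps(self.null_summary.to_dict(), indent=1))
        if self.trajectory_fits:
            pd.DataFrame([f.to_row() for f in self.trajectory_fits]).to_csv(
                out / "trajectory_fits.csv", index=False)
        if self.associations:
            association_table(self.associations).to_csv(
                out / "associations.csv", index=False)
        if self.clinical_reference is not None:
            (out / "clinical_reference.json").write_text(
                self.clinical_reference.to_json(indent=1))
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1,
                                                      default=str))


# --------------------------------------------------------------------------
# panel I/O
# --------------------------------------------------------------------------

REQUIRED_COLUMNS = ("cohort", "subject", "visit", "age", "sex")


def read_panel(path: str | Path, markers=None) -> pd.DataFrame:
    """Read and validate a long-format visit panel from CSV/TSV."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    panel = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in panel.columns]
    if missing:
        raise ValidationError(f"panel file missing required column(s) {missing}")
    validate_panel(panel, markers=list(markers) if markers else None)
    if markers:
        panel.attrs["markers"] = list(markers)
    return panel


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False, na_rep="")


def select_visits(panel: pd.DataFrame, rule: str, seed: int = 0) -> pd.DataFrame:
    """Apply the visit-selection rule: first / all / random-per-subject."""
    if rule == "all":
        return panel
    if rule == "first":
        idx = panel.sort_values("visit").groupby("subject", sort=False).head(1).index
        return panel.loc[idx].sort_index()
    if rule == "random-per-subject":
        rng = np.random.default_rng(seed)
        picks = panel.groupby("subject", sort=True).apply(
            lambda g: g.index[rng.integers(len(g))], include_groups=False)
        return panel.loc[sorted(picks)].copy()
    raise ValidationError(f"unknown visit rule {rule!r}")


# --------------------------------------------------------------------------
# the pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> ReportBundle:
    config.validate()
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2 ** 31)
    markers = list(marker_set(config.marker_set))

    if config.generator is not None:
        panel, truth = generate_panel(config.generator)
    else:
        panel = read_panel(config.panel_path, markers=markers)
    bundle = ReportBundle(panel=panel)
    bundle.manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "marker_set": (config.marker_set if isinstance(config.marker_set, str)
                       else list(config.marker_set)),
        "visit_rule": config.visit_rule,
        "stages": dict(config.stages),
        "input": (config.panel_path if config.panel_path
                  else {"generator": config.generator.to_dict()}),
    }

    # transform + standardize + complete cases (always required downstream)
    spec = fit_transform_spec(panel, markers)
    matrix = standardize(panel, spec)
    matrix, counts = complete_cases(matrix, markers)
    selected = select_visits(
        pd.concat([matrix.meta, matrix.values], axis=1), config.visit_rule,
        seed=int(seeds[0]))
    matrix = matrix.take(selected.index.to_numpy())
    bundle.matrix = matrix
    bundle.complete_counts = counts

    stages = config.stages
    if stages.get("axes", True):
        model, scores = fit_oriented_axes(matrix, source="full")
        bundle.axis_model = model
        for axis in range(min(3, model.n_axes)):
            bundle.importance_profiles[axis] = importance(model, axis)
    else:
        bundle.skipped["axes"] = "disabled"
        for dep in ("stability", "trajectories", "outcomes", "score"):
            if stages.get(dep, True):
                bundle.skipped[dep] = "requires axes stage"
        return bundle

    if stages.get("stability", True):
        try:
            scheme = demographic_subsets(matrix.meta, config.stability_variables,
                                         n_markers=len(markers))
            _, subset_scores = replicate_axes(matrix, scheme)
            bundle.stability_report = pairwise_axis_correlations(subset_scores)
        except ValidationError as err:
            bundle.skipped["stability-demographic"] = str(err)
        try:
            bundle.null_summary = null_distribution(
                matrix, k=config.null_k, reps=config.null_reps,
                seed=int(seeds[1]))
        except ValidationError as err:
            bundle.skipped["stability-null"] = str(err)

    if stages.get("trajectories", True):
        full = standardize(panel, spec)
        full, _ = complete_cases(full, markers)
        traj_scores = project(model, full)
        for cohort in full.meta["cohort"].unique():
            sel = np.flatnonzero((full.meta["cohort"] == cohort).to_numpy())
            try:
                fit = fit_trajectory(
                    traj_scores.values[sel], full.meta["age"].to_numpy()[sel],
                    full.meta["subject"].to_numpy()[sel],
                    form=config.trajectory_form)
                fit.dataset = cohort
                bundle.trajectory_fits.append(fit)
            except (ValidationError, Exception) as err:  # pragma: no cover
                bundle.skipped[f"trajectory-{cohort}"] = str(err)

    if stages.get("outcomes", True) and {"death_age", "censor_age"} <= set(panel.columns):
        full = standardize(panel, spec)
        full, _ = complete_cases(full, markers)
        sc = project(model, full)
        visits = full.meta[["subject", "age", "death_age", "censor_age"]].copy()
        visits["score"] = sc.values
        try:
            intervals = build_intervals(visits)
            bundle.associations.append(cox_axis(intervals, report_r2=True))
        except ValidationError as err:
            bundle.skipped["outcome-mortality"] = str(err)
        for outcome, family in (("frailty", "linear"), ("frailty", "poisson"),
                                ("comorbidities", "linear")):
            if outcome not in full.meta.columns:
                continue
            try:
                bundle.associations.append(count_association(
                    sc.values, full.meta[outcome].to_numpy(),
                    full.meta["age"].to_numpy(), family=family,
                    subjects=full.meta["subject"].to_numpy(), outcome=outcome))
            except ValidationError as err:
                bundle.skipped[f"outcome-{outcome}-{family}"] = str(err)
        if "diabetes" in full.meta.columns and model.n_axes > 1:
            sc2 = project(model, full, axis=1)
            try:
                bundle.associations.append(binary_association(
                    sc2.values, full.meta["diabetes"],
                    full.meta["age"].to_numpy(), outcome="diabetes"))
                bundle.associations[-1].axis = "pca2"
            except ValidationError as err:
                bundle.skipped["outcome-diabetes"] = str(err)

    if stages.get("score", True):
        try:
            clin_markers = [m for m in CLINICAL_14 if m in panel.columns]
            pooled_spec = fit_transform_spec(panel, clin_markers,
                                             cohort_column=None)
            pooled = standardize(panel, pooled_spec, cohort_column=None)
            pooled, _ = complete_cases(pooled, clin_markers)
            red_model, red_scores = fit_oriented_axes(pooled, source="clinical-14")
            bundle.clinical_reference = build_clinical_reference(
                red_model, pooled_spec, cohort="__all__",
                training_scores=project(red_model, pooled).values[:2000])
        except (ValidationError, Exception) as err:  # pragma: no cover
            bundle.skipped["score"] = str(err)

    if config.outdir:
        bundle.write(config.outdir)
    return bundle
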