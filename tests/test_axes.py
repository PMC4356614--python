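"""Axis extraction, orientation, importance, reduction and clinical scoring."""

import numpy as np
import pandas as pd
import pytest

import albunemia as ab
from albunemia.markers import ANEMIA_MARKERS, CLINICAL_14

from conftest import exactly_standardized


def _orthogonalize(x, against):
    r = x - against @ np.linalg.lstsq(against, x, rcond=None)[0]
    return r


def test_two_identical_markers_plus_independent_give_analytic_eigenvalues():
    rng = np.random.default_rng(0)
    z1 = rng.standard_normal(200)
    z2 = _orthogonalize(rng.standard_normal(200),
                        np.column_stack([np.ones(200), z1]))
    mat = exactly_standardized(np.column_stack([z1, z1, z2]))
    model = ab.fit_axes(mat)
    np.testing.assert_allclose(model.eigenvalues, [2.0, 1.0, 0.0], atol=1e-10)
    assert model.variance_fractions[0] == pytest.approx(2 / 3, abs=1e-12)


def test_loadings_match_brute_force_eigendecomposition():
    rng = np.random.default_rng(1)
    for _ in range(5):
        X = rng.standard_normal((200, 5)) @ rng.standard_normal((5, 5))
        mat = exactly_standardized(X)
        model = ab.fit_axes(mat)
        C = np.corrcoef(mat.values.to_numpy().T)
        w, v = np.linalg.eigh(C)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(model.eigenvalues, w, atol=1e-8)
        for k in range(5):
            dot = abs(v[:, k] @ model.loadings[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)


def test_axis_model_invariants(default_axis):
    model, _ = default_axis
    L = model.loadings
    np.testing.assert_allclose(L.T @ L, np.eye(model.n_axes), atol=1e-10)
    vf = model.variance_fractions
    assert np.all(np.diff(vf) <= 1e-12)
    assert vf.sum() == pytest.approx(1.0, abs=1e-10)


def test_constant_column_raises_named_error():
    vals = pd.DataFrame({"a": np.random.default_rng(0).standard_normal(50),
                         "flat": np.ones(50)})
    meta = pd.DataFrame(index=vals.index)
    mat = ab.StandardizedMatrix(vals, meta, ab.TransformSpec())
    with pytest.raises(ab.DegenerateInputError, match="flat"):
        ab.fit_axes(mat)


# -- projection -------------------------------------------------------------

def test_self_projection_reproduces_fit_scores_and_eigenvalue_variance():
    rng = np.random.default_rng(2)
    mat = exactly_standardized(rng.standard_normal((300, 4))
                               @ rng.standard_normal((4, 4)))
    model = ab.fit_axes(mat)
    s0 = ab.project(model, mat, axis=0)
    s0b = ab.project(model, mat, axis=0)
    np.testing.assert_array_equal(s0.values, s0b.values)
    assert np.var(s0.values, ddof=1) == pytest.approx(model.eigenvalues[0],
                                                      abs=1e-8)


def test_projection_onto_flipped_model_negates_scores():
    rng = np.random.default_rng(3)
    mat = exactly_standardized(rng.standard_normal((100, 3)))
    model = ab.fit_axes(mat)
    flipped = ab.AxisModel(model.markers, -model.loadings, model.eigenvalues)
    np.testing.assert_allclose(ab.project(flipped, mat).values,
                               -ab.project(model, mat).values, atol=1e-14)


def test_marker_mismatch_reports_symmetric_difference():
    rng = np.random.default_rng(4)
    mat = exactly_standardized(rng.standard_normal((50, 3)), ["a", "b", "c"])
    model = ab.fit_axes(mat)
    other = exactly_standardized(rng.standard_normal((50, 3)), ["a", "b", "d"])
    with pytest.raises(ab.MarkerMismatchError) as exc:
        ab.project(model, other)
    assert exc.value.missing == ["c"] and exc.value.extra == ["d"]


# -- orientation ------------------------------------------------------------

def test_orientation_flips_negative_age_correlation():
    rng = np.random.default_rng(5)
    ages = np.linspace(50, 90, 200)
    scores = -0.3 * (ages - 70) + rng.standard_normal(200) * 5
    mat = exactly_standardized(rng.standard_normal((200, 3)))
    model = ab.fit_axes(mat)
    oriented = ab.orient_axis(model, scores, ages)
    assert oriented.orientation[0]["flipped"] == (
        np.corrcoef(scores, ages)[0, 1] < 0)
    new_scores = ab.project(oriented, mat)
    assert np.corrcoef(
        new_scores.values,
        ages)[0, 1] * np.corrcoef(ab.project(model, mat).values, ages)[0, 1] <= 0 \
        or not oriented.orientation[0]["flipped"]


def test_orientation_is_idempotent():
    rng = np.random.default_rng(6)
    ages = np.linspace(50, 90, 100)
    mat = exactly_standardized(rng.standard_normal((100, 3)))
    model = ab.fit_axes(mat)
    scores = ab.project(model, mat)
    once = ab.orient_axis(model, scores, ages)
    twice = ab.orient_axis(once, ab.project(once, mat), ages)
    np.testing.assert_array_equal(once.loadings, twice.loadings)


def test_age_free_fallback_makes_top_loading_positive():
    rng = np.random.default_rng(7)
    mat = exactly_standardized(rng.standard_normal((100, 3)))
    model = ab.fit_axes(mat)
    negated = ab.AxisModel(model.markers, -model.loadings, model.eigenvalues)
    oriented = ab.orient_axis(negated)
    top = np.argmax(np.abs(oriented.loadings[:, 0]))
    assert oriented.loadings[top, 0] > 0


def test_oriented_first_axis_correlates_positively_with_age(default_axis,
                                                            default_matrix):
    _, cc, _, _ = default_matrix
    _, scores = default_axis
    assert np.corrcoef(scores.values, cc.meta["age"])[0, 1] > 0


# -- importance -------------------------------------------------------------

def test_importance_hand_computed_values():
    model = ab.AxisModel(["a", "b", "c"],
                         np.array([[0.8], [0.6], [0.0]]), np.array([1.5]))
    prof = ab.importance(model)
    assert prof.markers == ["a", "b", "c"]
    np.testing.assert_allclose(prof.weights, [0.8 / 1.4, 0.6 / 1.4, 0.0],
                               atol=1e-12)


def test_importance_equal_loadings_and_normalization(default_axis):
    p = 4
    model = ab.AxisModel([f"m{i}" for i in range(p)],
                         np.full((p, 1), 1 / np.sqrt(p)), np.array([2.0]))
    np.testing.assert_allclose(ab.importance(model).weights, np.full(p, 1 / p),
                               atol=1e-12)
    full_model, _ = default_axis
    for axis in (0, 1, 5):
        prof = ab.importance(full_model, axis)
        assert prof.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(prof.weights >= 0)
        assert np.all(np.diff(prof.weights) <= 1e-15)


def test_first_axis_importance_led_by_anemia_cluster(default_axis):
    model, _ = default_axis
    top8 = ab.importance(model, 0).markers[:8]
    assert len(set(top8) & set(ANEMIA_MARKERS) | {"albumin"} & set(top8)) >= 5


# -- anemia sub-axis --------------------------------------------------------

def test_single_marker_subaxis_equals_standardized_marker():
    rng = np.random.default_rng(8)
    mat = exactly_standardized(rng.standard_normal((100, 2)), ["hb", "x"])
    scores = ab.anemia_subaxis(mat, ["hb"])
    col = mat.values["hb"].to_numpy()
    assert (np.allclose(scores.values, col, atol=1e-10)
            or np.allclose(scores.values, -col, atol=1e-10))


def test_perfectly_correlated_pair_scores_proportional_to_mean():
    rng = np.random.default_rng(9)
    z = rng.standard_normal(100)
    mat = exactly_standardized(np.column_stack([z, z]), ["hb", "hct"])
    scores = ab.anemia_subaxis(mat, ["hb", "hct"])
    mean = mat.values.mean(axis=1).to_numpy()
    r = np.corrcoef(scores.values, mean)[0, 1]
    assert abs(r) == pytest.approx(1.0, abs=1e-10)


def test_anemia_subaxis_recovers_latent_factor(default_matrix):
    cfg, cc, truth, _ = default_matrix
    scores = ab.anemia_subaxis(cc, ANEMIA_MARKERS)
    f1c = (truth["f1"]
           - truth.groupby("cohort")["f1"].transform("mean")).to_numpy()
    assert abs(np.corrcoef(scores.values, f1c)[0, 1]) >= 0.8


# -- reduction and clinical score ------------------------------------------

def test_reduce_to_full_size_is_identity_correlation(default_matrix,
                                                     default_axis):
    _, cc, _, _ = default_matrix
    model, _ = default_axis
    _, r = ab.reduce_axis(model, cc, target_size=model.n_markers)
    assert r == pytest.approx(1.0, abs=1e-12)


def test_dropping_exactly_orthogonal_marker_leaves_r_unchanged():
    rng = np.random.default_rng(10)
    f = rng.standard_normal(300)
    block = np.column_stack([f + 0.3 * rng.standard_normal(300)
                             for _ in range(3)])
    extra = _orthogonalize(rng.standard_normal(300),
                           np.column_stack([np.ones(300), block]))
    mat = exactly_standardized(np.column_stack([block, extra]),
                               ["a", "b", "c", "orth"])
    model = ab.fit_axes(mat)
    assert abs(model.loadings[3, 0]) < 1e-8
    reduced, r = ab.reduce_axis(model, mat, target_size=3)
    assert "orth" not in reduced.markers
    assert r == pytest.approx(1.0, abs=1e-10)


def test_reduce_validation_errors(default_matrix, default_axis):
    _, cc, _, _ = default_matrix
    model, _ = default_axis
    with pytest.raises(ab.ValidationError):
        ab.reduce_axis(model, cc, required=["hemoglobin"],
                       forbidden=["hemoglobin"], target_size=14)
    with pytest.raises(ab.ValidationError):
        ab.reduce_axis(model, cc, required=list(CLINICAL_14), target_size=5)


def _clinical_reference(default_panel):
    cfg, panel, _ = default_panel
    spec = ab.fit_transform_spec(panel, list(CLINICAL_14), cohort_column=None)
    mat = ab.standardize(panel, spec, cohort_column=None)
    cc, _ = ab.complete_cases(mat, list(CLINICAL_14))
    model, _ = ab.fit_oriented_axes(cc, source="clinical-14")
    return ab.build_clinical_reference(model, spec, cohort="__all__"), cc


def test_clinical_score_at_centers_is_zero(default_panel):
    ref, _ = _clinical_reference(default_panel)
    centers = {}
    for m, t in ref.transforms.items():
        # native value whose transform equals the stored center
        if t["family"] == "identity":
            centers[m] = t["center"]
        elif t["family"] == "log":
            centers[m] = np.exp(t["center"]) - t["shift"]
        else:
            centers[m] = t["center"] ** 2 - t["shift"]
    assert ab.clinical_score(centers, ref)[0] == pytest.approx(0.0, abs=1e-10)


def test_clinical_score_one_sd_shift_equals_loading(default_panel):
    ref, _ = _clinical_reference(default_panel)
    marker = ref.model.markers[0]
    t = ref.transforms[marker]
    values = {}
    for m, tt in ref.transforms.items():
        target = tt["center"] + (tt["scale"] if m == marker else 0.0)
        if tt["family"] == "identity":
            values[m] = target
        elif tt["family"] == "log":
            values[m] = np.exp(target) - tt["shift"]
        else:
            values[m] = target ** 2 - tt["shift"]
    expected = ref.model.loadings[0, 0]
    assert ab.clinical_score(values, ref)[0] == pytest.approx(expected,
                                                              abs=1e-8)


def test_clinical_batch_equals_projection(default_panel):
    cfg, panel, _ = default_panel
    ref, cc = _clinical_reference(default_panel)
    rows = panel.dropna(subset=list(CLINICAL_14)).head(3)
    batch = ab.clinical_score(rows[list(CLINICAL_14)], ref)
    stacked = np.array([
        ab.clinical_score(rows.iloc[[i]][list(CLINICAL_14)], ref)[0]
        for i in range(3)
    ])
    np.testing.assert_allclose(batch, stacked, atol=1e-12)
    proj = ab.project(ref.model, cc)
    assert len(proj) == cc.n_obs


def test_clinical_score_missing_markers_error_names_them(default_panel):
    ref, _ = _clinical_reference(default_panel)
    with pytest.raises(ab.ValidationError) as exc:
        ab.clinical_score({"hemoglobin": 13.0}, ref)
    for m in ("hematocrit", "crp", "albumin"):
        assert m in str(exc.value)


def test_axis_model_json_roundtrip(default_axis):
    model, _ = default_axis
    again = ab.AxisModel.from_json(model.to_json())
    np.testing.assert_array_equal(again.loadings, model.loadings)
    np.testing.assert_array_equal(again.eigenvalues, model.eigenvalues)
    assert again.markers == model.markers


def test_scale_invariance_through_pipeline(default_panel):
    cfg, panel, _ = default_panel
    markers = cfg.marker_names[:8]
    spec1 = ab.fit_transform_spec(panel, markers)
    m1, _ = ab.complete_cases(ab.standardize(panel, spec1), markers)
    scaled = panel.copy()
    scaled["hemoglobin"] = scaled["hemoglobin"] * 10.0
    spec2 = ab.fit_transform_spec(scaled, markers)
    m2, _ = ab.complete_cases(ab.standardize(scaled, spec2), markers)
    a1 = ab.fit_axes(m1)
    a2 = ab.fit_axes(m2)
    np.testing.assert_allclose(a1.loadings[:, 0], a2.loadings[:, 0], atol=1e-8)
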