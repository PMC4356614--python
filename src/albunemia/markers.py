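"""The default 43-marker clinical panel.

Means and SDs are native-unit reference values for the three emulated cohorts
(WHAS: older US women; InCHIANTI: Tuscan adults of all ages; BLSA: US adults).
Units follow each cohort's own convention — notably albumin is recorded in
g/dL in WHAS and BLSA but as a percentage of total protein in InCHIANTI, so
per-cohort standardization is mandatory, never optional.

Two latent physiological factors drive the synthetic panels:

* F1 — the "integrated albunemia" axis: an anemia/inflammation gradient on
  which red-cell markers, iron, CRP and IL-6 load with one sign and albumin,
  the albumin–globulin ratio and calcium with the opposite sign.
* F2 — a metabolic-syndrome-like factor loading on lipids, glucose and the
  inflammatory markers.

The distribution family (gaussian vs lognormal) is a generator choice for
each marker based on whether clinical values of that analyte are typically
right-skewed; it is applied on the native scale with moments matched to the
reference mean/SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COHORTS = ("WHAS", "InCHIANTI", "BLSA")


@dataclass(frozen=True)
class MarkerDef:
    """Static description of one biomarker in the default panel."""

    name: str
    group: str
    units: str
    mean: dict  # cohort -> native-unit mean
    sd: dict  # cohort -> native-unit SD
    family: str = "gaussian"  # marginal family on the native scale
    loading_f1: float = 0.0  # standardized-scale loading on F1
    loading_f2: float = 0.0  # standardized-scale loading on F2
    in_34: bool = True  # available longitudinally (34-marker set)
    sex_stratified: bool = False


def _m(name, group, units, w, i, b, **kw):
    return MarkerDef(
        name,
        group,
        units,
        mean={"WHAS": w[0], "InCHIANTI": i[0], "BLSA": b[0]},
        sd={"WHAS": w[1], "InCHIANTI": i[1], "BLSA": b[1]},
        **kw,
    )


MARKER_DEFS: tuple[MarkerDef, ...] = (
    # -- basic blood measures -------------------------------------------------
    _m("hemoglobin", "basic_blood", "g/dL", (13.0, 1.2), (13.8, 1.5), (13.6, 1.4),
       loading_f1=0.70),
    _m("hematocrit", "basic_blood", "%", (39, 4), (41, 4), (41, 4),
       loading_f1=0.70),
    _m("iron", "basic_blood", "ug/dL", (80, 27), (85, 29), (89, 32),
       loading_f1=0.50),
    _m("rdw", "basic_blood", "%", (14.1, 1.4), (13.8, 1.2), (13.5, 1.5),
       loading_f1=0.40),
    _m("mch", "basic_blood", "pg", (30.5, 2.1), (30.5, 2.1), (30.4, 2.1),
       loading_f1=0.45),
    _m("mchc", "basic_blood", "g/dL", (33.1, 1.2), (33.7, 1.0), (33.5, 1.2),
       loading_f1=0.45),
    _m("platelets", "basic_blood", "K/uL", (242, 68), (236, 64), (231, 74)),
    _m("ferritin", "basic_blood", "ng/mL", (112, 124), (123, 127), (107, 99),
       family="lognormal"),
    _m("rbc", "basic_blood", "M/uL", (4.26, 0.43), (4.53, 0.47), (4.50, 0.48),
       loading_f1=0.60),
    _m("glucose", "basic_blood", "mg/dL", (114, 57), (94, 26), (93, 18),
       family="lognormal", loading_f2=0.60),
    # -- immune measures ------------------------------------------------------
    _m("wbc", "immune", "K/uL", (6.3, 2.4), (6.3, 1.7), (6.0, 3.5),
       family="lognormal"),
    _m("neutrophils", "immune", "%", (60, 10), (59, 9), (55, 10)),
    _m("monocytes", "immune", "%", (6.9, 2.4), (6.6, 2.2), (9.2, 4.3)),
    _m("lymphocytes", "immune", "%", (29, 9), (31, 8), (32, 10)),
    _m("eosinophils", "immune", "%", (3.0, 2.2), (3.2, 2.1), (3.5, 2.3),
       family="lognormal"),
    _m("basophils", "immune", "%", (0.74, 0.53), (0.52, 0.35), (0.55, 0.32),
       family="lognormal"),
    _m("il6", "immune", "pg/mL", (4.3, 9.7), (3.4, 2.4), (2.9, 2.3),
       family="lognormal", loading_f1=0.40, loading_f2=0.30, in_34=False),
    _m("crp", "immune", "ug/mL", (6.3, 8.5), (4.5, 9.0), (3.0, 5.9),
       family="lognormal", loading_f1=0.40, loading_f2=0.35, in_34=False),
    # -- electrolytes ---------------------------------------------------------
    _m("calcium", "electrolytes", "mg/dL", (9.5, 0.5), (9.4, 0.5), (9.3, 0.4),
       loading_f1=-0.50),
    _m("chloride", "electrolytes", "mEq/L", (103, 4), (106, 4), (104, 3)),
    _m("magnesium", "electrolytes", "mg/dL", (1.99, 0.20), (2.08, 0.36), (2.05, 0.20)),
    _m("sodium", "electrolytes", "mEq/L", (140.0, 2.9), (141.2, 2.9), (141.7, 2.8)),
    _m("potassium", "electrolytes", "mEq/L", (4.2, 0.43), (4.19, 0.40), (4.20, 0.34)),
    # -- vitamins -------------------------------------------------------------
    _m("vitamin_b12", "vitamins", "pg/mL", (494, 307), (471, 334), (640, 366),
       family="lognormal", in_34=False),
    _m("folate", "vitamins", "W,I: nmol/L; B: ng/mL", (12.4, 10.4), (10.1, 6.9),
       (24.6, 14.2), family="lognormal", in_34=False),
    # -- hormones -------------------------------------------------------------
    _m("igf1", "hormones", "ug/dL", (119, 54), (129, 65), (125, 47), in_34=False),
    _m("estradiol", "hormones", "pg/mL", (16.2, 17.8), (10.1, 14.8), (19.6, 30.7),
       family="lognormal", in_34=False, sex_stratified=True),
    _m("dheas", "hormones", "ug/dL", (43, 37), (104, 87), (64, 60),
       family="lognormal", in_34=False),
    _m("tsh", "hormones", "mIU/L", (2.3, 2.9), (1.9, 4.7), (2.6, 2.1),
       family="lognormal", in_34=False),
    # -- lipids ---------------------------------------------------------------
    _m("total_cholesterol", "lipids", "mg/dL", (224, 41), (212, 42), (191, 37),
       loading_f2=0.50),
    _m("triglycerides", "lipids", "mg/dL", (160, 98), (127, 77), (103, 58),
       family="lognormal", loading_f2=0.60),
    _m("hdl", "lipids", "mg/dL", (55, 16), (57, 15), (59, 17), loading_f2=-0.50),
    # -- proteins, liver, and kidney ------------------------------------------
    _m("albumin", "protein_liver_kidney", "W,B: g/dL; I: %", (4.1, 0.3),
       (58.9, 4.2), (4.1, 0.3), loading_f1=-0.55),
    _m("albumin_globulin_ratio", "protein_liver_kidney", "ratio", (1.46, 0.26),
       (1.46, 0.25), (1.36, 0.22), loading_f1=-0.45),
    _m("alkaline_phosphatase", "protein_liver_kidney", "U/L", (87, 35), (165, 110),
       (78, 23), family="lognormal"),
    _m("bun_creatinine_ratio", "protein_liver_kidney", "ratio", (19.1, 5.9),
       (37.8, 10.4), (16.9, 4.8), in_34=False),
    _m("total_proteins", "protein_liver_kidney", "g/dL", (7.0, 0.5), (7.3, 0.5),
       (7.1, 0.5)),
    _m("ggt", "protein_liver_kidney", "U/L", (31, 36), (27, 32), (30, 24),
       family="lognormal"),
    _m("ldh", "protein_liver_kidney", "U/L", (177, 35), (344, 75), (430, 163)),
    _m("creatinine", "protein_liver_kidney", "mg/dL", (1.01, 0.36), (0.92, 0.27),
       (1.02, 0.29), family="lognormal"),
    _m("uric_acid", "protein_liver_kidney", "mg/dL", (5.6, 1.7), (5.2, 1.4),
       (5.3, 1.4)),
    _m("alt", "protein_liver_kidney", "U/L", (19.6, 10.9), (20.8, 10.5),
       (32.0, 12.4), family="lognormal"),
    _m("ast", "protein_liver_kidney", "U/L", (16.2, 12.1), (19.4, 15.2),
       (28.1, 10.6), family="lognormal"),
)

MARKER_TABLE: dict[str, MarkerDef] = {m.name: m for m in MARKER_DEFS}

#: Cross-sectional set: every marker available in all three cohorts.
FULL_43: tuple[str, ...] = tuple(m.name for m in MARKER_DEFS)

#: Longitudinal set: markers re-measured at follow-up visits in every cohort.
LONGITUDINAL_34: tuple[str, ...] = tuple(m.name for m in MARKER_DEFS if m.in_34)

#: Reduced clinical set for the bedside calculator.
CLINICAL_14: tuple[str, ...] = (
    "hemoglobin", "hematocrit", "mch", "mchc", "rdw", "rbc", "platelets",
    "albumin", "albumin_globulin_ratio", "calcium", "crp", "alt", "iron",
    "alkaline_phosphatase",
)

#: Red-cell / iron markers used for the anemia sub-axis.
ANEMIA_MARKERS: tuple[str, ...] = (
    "hemoglobin", "hematocrit", "rbc", "iron", "mch", "mchc", "rdw",
)

#: Markers the first latent factor loads on in the default generator.
F1_MARKERS: tuple[str, ...] = tuple(
    m.name for m in MARKER_DEFS if m.loading_f1 != 0.0
)

_MARKER_SETS = {
    "full-43": FULL_43,
    "longitudinal-34": LONGITUDINAL_34,
    "clinical-14": CLINICAL_14,
    "anemia": ANEMIA_MARKERS,
}


def marker_set(name: str | list[str] | tuple[str, ...]) -> tuple[str, ...]:
    """Resolve a named preset or explicit list of marker names."""
    if isinstance(name, (list, tuple)):
        unknown = [m for m in name if m not in MARKER_TABLE]
        if unknown:
            raise KeyError(f"unknown markers: {unknown}")
        return tuple(name)
    try:
        return _MARKER_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown marker set {name!r}; available: {sorted(_MARKER_SETS)}"
        ) from None
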