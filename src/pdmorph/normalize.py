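"""Reference normalization and control-derived covariate correction.

Regional volumes are normalized to the study-mean intracranial volume,

    V_norm = V / V_icv_subject * mean(V_icv over the baseline cohort),

and regional cortical thickness is normalized the same way with the
subject's mean cortical thickness as the reference.  Normalized values
are then adjusted for age and years of education with per-region slopes
estimated by ordinary least squares on baseline healthy controls only,
centred at the whole-cohort baseline mean age and education:

    V_corrected = V_norm - g1 (age - mean_age) - g2 (edu - mean_edu).

The reference means (cohort-mean ICV, mean age, mean education) are
computed from the baseline visits of the whole study population; a
subject's reference (ICV, baseline mean thickness) is treated as
time-constant, so follow-up visits reuse it, and the control-fitted
slopes are never refitted on follow-up data.

Correction is linear, hence it commutes with hemisphere averaging; it is
not idempotent, so the table carries provenance flags and a second
application raises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import LongTable, PdmorphError

__all__ = [
    "NormalizationReference",
    "CovariateCorrectionModel",
    "normalize_to_reference",
    "fit_control_covariate_model",
    "apply_covariate_correction",
    "hemisphere_average",
    "percent_deviation",
    "normalize_table",
    "correct_table",
]

MEAN_THICKNESS_COLUMN = "mean_thickness"


class DomainError(PdmorphError):
    pass


class SingularityError(PdmorphError):
    pass


@dataclass(frozen=True)
class NormalizationReference:
    """Cohort-mean reference value (ICV in cm^3 or mean thickness in mm)."""

    kind: str  # "ICV" | "MEAN_THICKNESS"
    cohort_mean: float

    def __post_init__(self) -> None:
        if self.kind not in ("ICV", "MEAN_THICKNESS"):
            raise DomainError(f"unknown reference kind {self.kind!r}")
        if not self.cohort_mean > 0:
            raise DomainError("cohort mean reference must be positive")


@dataclass
class CovariateCorrectionModel:
    """Per-region OLS slopes from baseline controls plus reference means."""

    region: str
    gamma0: float
    gamma1: float  # per year of age
    gamma2: float  # per year of education
    ref_age: float
    ref_education: float
    n: int
    residual_sd: float
    gamma_sex: float = 0.0  # optional male-indicator term, 0 unless fitted
    with_sex: bool = False


def normalize_to_reference(
    value, subject_reference, reference: NormalizationReference
):
    """Scale a measurement by cohort_mean / subject_reference (units kept)."""
    subject_reference = np.asarray(subject_reference, dtype=float)
    if np.any(subject_reference <= 0):
        raise DomainError("subject reference must be positive")
    return np.asarray(value, dtype=float) * reference.cohort_mean / subject_reference


def fit_control_covariate_model(
    controls_baseline,
    region: str,
    ref_age: float,
    ref_education: float,
    with_sex: bool = False,
) -> CovariateCorrectionModel:
    """OLS fit of normalized baseline control values on age and education.

    ``controls_baseline`` is a DataFrame slice of baseline control rows
    whose ``region`` column already holds reference-normalized values.
    An optional male-indicator covariate is available for the
    mean-thickness model.  Deterministic; raises on a rank-deficient
    design (fewer than 3 usable records, or no variation in both age
    and education).
    """
    df = controls_baseline[controls_baseline[region].notna()]
    y = df[region].to_numpy(dtype=float)
    cols = [np.ones(len(df)), df["baseline_age"].to_numpy(dtype=float),
            df["education"].to_numpy(dtype=float)]
    if with_sex:
        cols.append((df["sex"] == "M").to_numpy(dtype=float))
    X = np.column_stack(cols)
    p = X.shape[1]
    if len(y) < p or np.linalg.matrix_rank(X) < p:
        raise SingularityError(
            f"{region}: covariate design is rank deficient "
            f"({len(y)} usable baseline control records)"
        )
    gamma, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ gamma
    dof = len(y) - p
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return CovariateCorrectionModel(
        region=region,
        gamma0=float(gamma[0]),
        gamma1=float(gamma[1]),
        gamma2=float(gamma[2]),
        ref_age=float(ref_age),
        ref_education=float(ref_education),
        n=len(y),
        residual_sd=residual_sd,
        gamma_sex=float(gamma[3]) if with_sex else 0.0,
        with_sex=with_sex,
    )


def apply_covariate_correction(value, age, education, model: CovariateCorrectionModel, male=None):
    """value - g1 (age - ref_age) - g2 (edu - ref_edu) [- g_sex * male]."""
    out = (
        np.asarray(value, dtype=float)
        - model.gamma1 * (np.asarray(age, dtype=float) - model.ref_age)
        - model.gamma2 * (np.asarray(education, dtype=float) - model.ref_education)
    )
    if model.with_sex:
        if male is None:
            raise DomainError("model was fitted with a sex term; pass male indicator")
        out = out - model.gamma_sex * np.asarray(male, dtype=float)
    return out


def hemisphere_average(values: dict) -> dict:
    """Arithmetic mean of left/right pairs keyed ``region_lh``/``region_rh``.

    Regions with one side missing yield a missing output and a warning.
    Unpaired keys (no _lh/_rh suffix) pass through unchanged.
    """
    out = {}
    sides = {}
    for key, v in values.items():
        if key.endswith("_lh") or key.endswith("_rh"):
            base, side = key[:-3], key[-2:]
            sides.setdefault(base, {})[side] = v
        else:
            out[key] = v
    for base, pair in sides.items():
        if "lh" in pair and "rh" in pair and np.isfinite(pair["lh"]) and np.isfinite(pair["rh"]):
            out[base] = 0.5 * (pair["lh"] + pair["rh"])
        else:
            warnings.warn(f"hemisphere pair incomplete for {base}; output missing")
            out[base] = float("nan")
    return out


def percent_deviation(group_mean, control_mean):
    """Signed deviation (group/control - 1) x 100; negative = loss."""
    control_mean = np.asarray(control_mean, dtype=float)
    if np.any(control_mean == 0):
        raise DomainError("control mean must be nonzero")
    return (np.asarray(group_mean, dtype=float) / control_mean - 1.0) * 100.0


# ---------------------------------------------------------------------
# Table-level pipeline steps
# ---------------------------------------------------------------------

def normalize_table(table: LongTable) -> tuple[LongTable, dict]:
    """Reference-normalize all region columns of a table (in a copy).

    Volumes and planar areas are normalized to the cohort-mean ICV;
    thickness regions to the cohort-mean of the subjects' baseline mean
    cortical thickness, each subject's own baseline value serving as the
    time-constant subject reference.  The ``mean_thickness`` column
    itself is left on its native scale (it cannot be normalized to
    itself) and is only covariate-corrected downstream.

    Returns the normalized table and the references used.
    """
    if table.normalized:
        raise DomainError("table is already normalized (provenance flag set)")
    out = table.copy()
    df = out.df
    base = df[df["visit_index"] == 0]
    refs: dict[str, NormalizationReference] = {}

    icv_ref = NormalizationReference("ICV", float(base["icv"].mean()))
    refs["ICV"] = icv_ref
    vol_regions = [n for n, r in out.regions.items() if r.kind in ("volume", "area")]
    if vol_regions:
        factor = icv_ref.cohort_mean / df["icv"].to_numpy(dtype=float)
        for name in vol_regions:
            df[name] = df[name].to_numpy(dtype=float) * factor

    thick_regions = [n for n, r in out.regions.items() if r.kind == "thickness"]
    if thick_regions:
        subj_ref = base.set_index("subject_id")[MEAN_THICKNESS_COLUMN]
        if subj_ref.isna().any() or (subj_ref <= 0).any():
            raise DomainError("baseline mean thickness missing or non-positive "
                              "for some subjects; cannot normalize thickness regions")
        mt_ref = NormalizationReference("MEAN_THICKNESS", float(subj_ref.mean()))
        refs["MEAN_THICKNESS"] = mt_ref
        factor = mt_ref.cohort_mean / df["subject_id"].map(subj_ref).to_numpy(dtype=float)
        for name in thick_regions:
            df[name] = df[name].to_numpy(dtype=float) * factor

    out.normalized = True
    return out, refs


def correct_table(
    table: LongTable,
    age_mode: str = "visit",
    with_sex_for_mean_thickness: bool = False,
) -> tuple[LongTable, dict]:
    """Covariate-correct all regions (and the mean-thickness column).

    Slopes come from baseline controls only; the reference age and
    education are baseline means of the whole study population.
    ``age_mode`` selects whether the visit-specific age ('visit',
    default) or the baseline age ('baseline') enters the correction.
    A sex term is fitted for mean thickness only when requested.
    """
    if not table.normalized:
        raise DomainError("normalize the table before covariate correction")
    if table.corrected:
        raise DomainError("table is already covariate-corrected (provenance flag set)")
    if age_mode not in ("visit", "baseline"):
        raise DomainError(f"unknown age_mode {age_mode!r}")
    out = table.copy()
    df = out.df
    base = df[df["visit_index"] == 0]
    ref_age = float(base["baseline_age"].mean())
    ref_edu = float(base["education"].mean())
    controls = base[base["group"] == "CTRL"]

    age = (df["age_at_visit"] if age_mode == "visit" else df["baseline_age"]).to_numpy(dtype=float)
    edu = df["education"].to_numpy(dtype=float)
    male = (df["sex"] == "M").to_numpy(dtype=float)

    models: dict[str, CovariateCorrectionModel] = {}
    targets = list(out.regions) + [MEAN_THICKNESS_COLUMN]
    for name in targets:
        if df[name].isna().all():
            continue
        with_sex = with_sex_for_mean_thickness and name == MEAN_THICKNESS_COLUMN
        model = fit_control_covariate_model(controls, name, ref_age, ref_edu, with_sex=with_sex)
        df[name] = apply_covariate_correction(
            df[name].to_numpy(dtype=float), age, edu, model,
            male=male if with_sex else None,
        )
        models[name] = model

    out.corrected = True
    return out, models
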