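"""Shared vocabulary: drug classes, table schemas, default code maps and weights.

Dates throughout the package are integer day offsets from a fixed study
epoch (nominally 1 January 2004, the start of the observation window).
``EPOCH_YEAR`` converts offsets to decimal calendar years so that ages can
be derived from ``birth_year``.
"""

from __future__ import annotations

EPOCH_YEAR: float = 2004.0
DAYS_PER_YEAR: float = 365.25

#: Oral glucose-lowering drug classes eligible to form a therapy line.
ORAL_CLASSES = ("MFN", "SU", "TZD", "DPP4", "SGLT2", "OTHER_ORAL")

#: Injectable glucose-lowering classes (never a valid therapy line here).
INJECTABLE_CLASSES = ("INSULIN", "OTHER_INJECTABLE")

#: Every glucose-lowering class the cohort logic recognises.
DIABETES_CLASSES = ORAL_CLASSES + INJECTABLE_CLASSES

FORMULATIONS = ("tablet", "solution", "injectable")

ETHNICITY_LEVELS = ("white", "black", "asian", "other", "missing")

#: Exclusion reasons in their fixed evaluation order. A patient is
#: attributed to the first rule that fires, so the audit log is
#: deterministic.
EXCLUSION_REASONS = (
    "no_diabetes_code",
    "pcos_metformin",
    "other_diabetes",
    "t1d_age_lt_35",
    "t1d_insulin_within_1yr",
    "lt_1yr_prescribing",
    "registration_gap",
    "dual_start_same_day",
    "start_within_91d_of_registration",
    "injectable_or_solution_line",
    "no_second_line",
)

MPR_STATUSES = (
    "valid",
    "too_few_prescriptions",
    "span_lt_90d",
    "gap_gt_6mo",
    "all_doses_missing",
    "out_of_range_lt20",
    "out_of_range_gt120",
    "stopped_changed_lt_90d",
)

#: Required columns per input table (the reader validates these).
TABLE_SCHEMAS = {
    "patients": (
        "patient_id",
        "regstart_date",
        "regend_date",
        "has_registration_gap",
        "sex",
        "birth_year",
        "ethnicity",
    ),
    "prescriptions": (
        "patient_id",
        "issue_date",
        "drug_class",
        "formulation",
        "quantity",
        "daily_dose",
    ),
    "clinical_events": ("patient_id", "event_date", "category"),
    "observations": ("patient_id", "obs_date", "kind", "value"),
}

#: Default map from non-diabetes drug codes to co-prescription categories.
#: Real code lists (BNF chapters) are licence-bound; deployments supply
#: their own map in the study config.
DEFAULT_CATEGORY_MAP = {
    "antihypertensive": "bp_lowering",
    "statin": "lipid_lowering",
    "ssri": "antidepressant",
    "tricyclic": "antidepressant",
    "analgesic": "other",
}

COPRESCRIPTION_CATEGORIES = ("bp_lowering", "lipid_lowering", "antidepressant", "other")

#: Standard Charlson comorbidity weights (original 17-condition scheme).
DEFAULT_CHARLSON_WEIGHTS = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "rheumatic_disease": 1,
    "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes_complications": 2,
    "hemiplegia": 2,
    "renal_disease": 2,
    "malignancy": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_tumour": 6,
    "aids": 6,
}

#: HbA1c threshold (mmol/mol) for "in the diabetes range" when dating
#: diagnosis. A config decision, not a literature constant.
DEFAULT_HBA1C_DIABETES_THRESHOLD = 48.0


def age_at(day: float, birth_year: float) -> float:
    """Age in years at an integer day offset, given a birth year."""
    return EPOCH_YEAR + day / DAYS_PER_YEAR - birth_year
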