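"""Baseline predictor derivation per patient per therapy line.

All features are strictly baseline: nothing after the episode start
date contributes. Windows follow routine-data convention — baseline
BMI/HbA1c are the closest value in the 183 days up to and including the
start date; co-prescriptions and pill burden use the 91 days before the
start ("3 months" taken as exactly 91 days, matching the divisor).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adherence import cap_mpr_for_modelling, classify_nonadherence
from .cohort import DrugEpisode, compute_diagnosis_date, _group_slices
from .definitions import (
    COPRESCRIPTION_CATEGORIES,
    DEFAULT_CATEGORY_MAP,
    DEFAULT_CHARLSON_WEIGHTS,
    DIABETES_CLASSES,
    age_at,
)
from .errors import ConfigurationError, ReferentialIntegrityError

__all__ = [
    "baseline_measurement",
    "mean_tablets_per_day",
    "coprescription_flags",
    "charlson_index",
    "assemble_features",
]

BASELINE_WINDOW_DAYS = 183
COPRESCRIPTION_WINDOW_DAYS = 91


def baseline_measurement(
    observations: pd.DataFrame,
    kind: str,
    start_date: int,
    window_days: int = BASELINE_WINDOW_DAYS,
) -> float:
    """Closest observation of ``kind`` at or before ``start_date``
    within ``window_days``; NaN when none qualifies."""
    m = (
        (observations["kind"] == kind)
        & (observations["obs_date"] <= start_date)
        & (start_date - observations["obs_date"] <= window_days)
    )
    if not m.any():
        return float("nan")
    sel = observations.loc[m]
    return float(sel.loc[sel["obs_date"].idxmax(), "value"])


def mean_tablets_per_day(prescriptions: pd.DataFrame, start_date: int) -> float:
    """Total tablet quantity of non-diabetes prescriptions issued in the
    91 days before the start date, divided by 91."""
    m = (
        (prescriptions["formulation"] == "tablet")
        & (~prescriptions["drug_class"].isin(DIABETES_CLASSES))
        & (prescriptions["issue_date"] >= start_date - COPRESCRIPTION_WINDOW_DAYS)
        & (prescriptions["issue_date"] < start_date)
    )
    return float(prescriptions.loc[m, "quantity"].sum()) / COPRESCRIPTION_WINDOW_DAYS


def coprescription_flags(
    prescriptions: pd.DataFrame,
    start_date: int,
    category_map: dict[str, str] | None = None,
) -> dict[str, bool]:
    """Blood-pressure-, lipid-lowering and antidepressant flags.

    ``category_map`` maps drug codes to categories; every mapped
    category must be one of the known co-prescription categories.
    """
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    for code, cat in cmap.items():
        if cat not in COPRESCRIPTION_CATEGORIES:
            raise ConfigurationError(
                f"category_map[{code!r}] = {cat!r} is not a known category"
            )
    m = (prescriptions["issue_date"] >= start_date - COPRESCRIPTION_WINDOW_DAYS) & (
        prescriptions["issue_date"] < start_date
    )
    cats = set(prescriptions.loc[m, "drug_class"].map(cmap).dropna())
    return {
        "on_bp_lowering": "bp_lowering" in cats,
        "on_lipid_lowering": "lipid_lowering" in cats,
        "on_antidepressant": "antidepressant" in cats,
    }


def charlson_index(
    clinical_events: pd.DataFrame,
    start_date: int,
    weight_table: dict[str, int] | None = None,
) -> int:
    """Sum of Charlson weights over distinct conditions recorded on or
    before the start date."""
    weights = DEFAULT_CHARLSON_WEIGHTS if weight_table is None else weight_table
    m = clinical_events["category"].str.startswith("charlson:") & (
        clinical_events["event_date"] <= start_date
    )
    total = 0
    for cond in set(clinical_events.loc[m, "category"].str.split(":", n=1).str[1]):
        if cond not in weights:
            raise ConfigurationError(f"no Charlson weight configured for {cond!r}")
        total += int(weights[cond])
    return total


def assemble_features(
    patients: pd.DataFrame,
    episodes: list[DrugEpisode],
    mpr: pd.DataFrame,
    clinical_events: pd.DataFrame,
    observations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    line: str,
    category_map: dict[str, str] | None = None,
    charlson_weights: dict[str, int] | None = None,
    hba1c_threshold: float | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """One feature row per episode of ``line`` with a valid MPR.

    For second-line rows the first drug's capped MPR and non-adherence
    flag are added; patients without a valid first-line MPR are dropped
    from the second-line modelling set. Returns the feature table and a
    per-field missingness report (models apply their own complete-case
    masks downstream; ethnicity stays a category with a ``missing``
    level).
    """
    from .definitions import DEFAULT_HBA1C_DIABETES_THRESHOLD

    thr = DEFAULT_HBA1C_DIABETES_THRESHOLD if hba1c_threshold is None else hba1c_threshold

    pat = patients.set_index("patient_id")
    mpr_valid = mpr[mpr["status"] == "valid"]
    own = mpr_valid[mpr_valid["line"] == line].set_index("patient_id")
    first = mpr_valid[mpr_valid["line"] == "first"].set_index("patient_id")

    # per-patient row slices for the event/obs/rx tables
    def slices(frame, date_col):
        f = frame.sort_values(["patient_id", date_col], kind="mergesort").reset_index(drop=True)
        idx = {p: (s, e) for p, s, e in _group_slices(f["patient_id"].to_numpy())}
        return f, idx

    ev, ev_idx = slices(clinical_events, "event_date")
    ob, ob_idx = slices(observations, "obs_date")
    rx, rx_idx = slices(prescriptions, "issue_date")

    def sub(frame, idx, p):
        s, e = idx.get(p, (0, 0))
        return frame.iloc[s:e]

    rows = []
    for ep in episodes:
        if ep.line != line:
            continue
        p = ep.patient_id
        if p not in own.index:
            continue
        if p not in pat.index:
            raise ReferentialIntegrityError(f"episode references unknown patient {p}")
        if line == "second" and p not in first.index:
            continue
        prow = pat.loc[p]
        ev_p = sub(ev, ev_idx, p)
        ob_p = sub(ob, ob_idx, p)
        rx_p = sub(rx, rx_idx, p)
        start = ep.start_date
        diag = compute_diagnosis_date(ev_p, rx_p, ob_p, hba1c_threshold=thr)
        by = float(prow["birth_year"])
        flags = coprescription_flags(rx_p, start, category_map)
        row = {
            "patient_id": p,
            "line": line,
            "age_at_diagnosis": age_at(diag, by),
            "age_at_start": age_at(start, by),
            "sex": prow["sex"],
            "ethnicity": prow["ethnicity"],
            "duration_years": (start - diag) / 365.25,
            "bmi": baseline_measurement(ob_p, "bmi", start),
            "hba1c": baseline_measurement(ob_p, "hba1c", start),
            "tablets_per_day": mean_tablets_per_day(rx_p, start),
            **flags,
            "charlson": charlson_index(ev_p, start, charlson_weights),
            "drug_class": ep.drug_class,
            "mpr_percent": float(own.loc[p, "mpr_raw"]),
            "nonadherent": classify_nonadherence(float(own.loc[p, "mpr_raw"])),
        }
        if line == "second":
            m1 = float(first.loc[p, "mpr_raw"])
            row["mpr_first_raw"] = m1
            row["mpr_first_capped"] = cap_mpr_for_modelling(m1)
            row["nonadh_first"] = classify_nonadherence(m1)
        rows.append(row)

    features = pd.DataFrame(rows)
    completeness: dict[str, float] = {}
    if len(features):
        for col in features.columns:
            if col in ("patient_id", "line"):
                continue
            if col == "ethnicity":
                missing = (features[col] == "missing").mean()
            else:
                missing = features[col].isna().mean()
            completeness[col] = float(missing)
    return features, completeness
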