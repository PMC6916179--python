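"""Cohort derivation: schema validation, eligibility cascade, therapy lines.

The eligibility rules mirror how type 2 diabetes cohorts are cleaned in
primary-care record studies: patients without a diabetes code, with
metformin-treated PCOS or another diabetes aetiology, with likely type 1
diabetes (diagnosis under 35 or insulin within a year of diagnosis),
with under a year of prescribing data, with registration gaps, with two
drugs started on the same day, with a first prescription within 91 days
of registration (possible continuation of prior therapy), with an
injectable or oral-solution first/second line, or with no second
therapy line are removed.

Rules are evaluated in a fixed order and each excluded patient is
attributed to the *first* rule that fires, so the audit log is
deterministic and its counts conserve the input count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .definitions import (
    DAYS_PER_YEAR,
    DEFAULT_HBA1C_DIABETES_THRESHOLD,
    DIABETES_CLASSES,
    EXCLUSION_REASONS,
    INJECTABLE_CLASSES,
    ORAL_CLASSES,
    TABLE_SCHEMAS,
    age_at,
)
from .errors import SchemaError, UndeterminedDiagnosisError

__all__ = [
    "validate_tables",
    "load_tables",
    "DrugEpisode",
    "LineDerivation",
    "ExclusionLog",
    "compute_diagnosis_date",
    "derive_therapy_lines",
    "apply_exclusions",
    "derive_all_episodes",
    "episodes_frame",
]


# ---------------------------------------------------------------------------
# schemas


def validate_tables(**tables: pd.DataFrame) -> None:
    """Check that each named table carries its required columns.

    Raises :class:`SchemaError` naming the first missing column.
    """
    for name, frame in tables.items():
        if name not in TABLE_SCHEMAS:
            raise SchemaError(f"unknown table {name!r}")
        for col in TABLE_SCHEMAS[name]:
            if col not in frame.columns:
                raise SchemaError(f"table {name!r} is missing required column {col!r}")


def load_tables(in_dir) -> dict[str, pd.DataFrame]:
    """Read and validate the four input CSVs from a directory."""
    import pathlib

    p = pathlib.Path(in_dir)
    tables = {name: pd.read_csv(p / f"{name}.csv") for name in TABLE_SCHEMAS}
    validate_tables(**tables)
    return tables


# ---------------------------------------------------------------------------
# domain types


@dataclass
class DrugEpisode:
    """One contiguous therapy line (first or second oral agent).

    ``dates``/``quantities``/``doses`` hold the episode's prescriptions
    sorted by issue date; ``start_date`` is the first prescription date.
    """

    patient_id: int
    line: str  # "first" | "second"
    drug_class: str
    start_date: int
    end_event: str  # switched | stopped_gap | records_end | ongoing_at_1yr
    end_event_date: int
    dates: np.ndarray
    quantities: np.ndarray
    doses: np.ndarray

    @property
    def prescriptions(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "issue_date": self.dates,
                "drug_class": self.drug_class,
                "quantity": self.quantities,
                "daily_dose": self.doses,
            }
        )


class LineDerivation(NamedTuple):
    episodes: list[DrugEpisode]
    dual_start: bool
    injectable_line: bool
    first_start: int | None  # earliest glucose-lowering prescription date


@dataclass
class ExclusionLog:
    """Per-reason exclusion counts; first-matching rule attributed."""

    n_input: int = 0
    n_retained: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in EXCLUSION_REASONS}
    )

    @property
    def conserved(self) -> bool:
        return self.n_input == self.n_retained + sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "excluded": dict(self.counts),
        }


# ---------------------------------------------------------------------------
# diagnosis date


def compute_diagnosis_date(
    clinical_events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    observations: pd.DataFrame | None = None,
    hba1c_threshold: float = DEFAULT_HBA1C_DIABETES_THRESHOLD,
) -> int:
    """Earliest of: diabetes code, glucose-lowering prescription, HbA1c
    in the diabetes range (``>= hba1c_threshold`` mmol/mol).

    All inputs are single-patient tables. Raises
    :class:`UndeterminedDiagnosisError` when no record qualifies.
    """
    candidates: list[int] = []
    if len(clinical_events):
        m = clinical_events["category"] == "diabetes_code"
        if m.any():
            candidates.append(int(clinical_events.loc[m, "event_date"].min()))
    if len(prescriptions):
        m = prescriptions["drug_class"].isin(DIABETES_CLASSES)
        if m.any():
            candidates.append(int(prescriptions.loc[m, "issue_date"].min()))
    if observations is not None and len(observations):
        m = (observations["kind"] == "hba1c") & (observations["value"] >= hba1c_threshold)
        if m.any():
            candidates.append(int(observations.loc[m, "obs_date"].min()))
    if not candidates:
        raise UndeterminedDiagnosisError("no qualifying record to date the diagnosis")
    return min(candidates)


# ---------------------------------------------------------------------------
# therapy lines


def _episode_end(
    start: int,
    own_last: int,
    later_start: int | None,
    records_end: int,
) -> tuple[str, int]:
    """Classify how a therapy line ended relative to its first year."""
    year_end = start + 365
    if own_last >= year_end:
        return "ongoing_at_1yr", year_end
    if later_start is not None and later_start <= year_end and later_start > own_last:
        return "switched", later_start
    if records_end <= year_end:
        return "records_end", records_end
    return "stopped_gap", own_last


def derive_therapy_lines(
    prescriptions: pd.DataFrame,
    records_end: int | None = None,
) -> LineDerivation:
    """Derive the ordered first/second therapy lines for one patient.

    The first line is the glucose-lowering class with the earliest
    issue; the second is the first distinct class started strictly
    later. Two distinct classes sharing the earliest date set the
    ``dual_start`` flag (no episodes are built). An injectable class or
    a non-tablet formulation occupying line 1 or 2 sets
    ``injectable_line``.
    """
    rx = prescriptions.sort_values("issue_date", kind="mergesort")
    dia = rx[rx["drug_class"].isin(DIABETES_CLASSES)]
    if not len(dia):
        return LineDerivation([], False, False, None)
    pid = int(dia["patient_id"].iloc[0])
    return _derive_from_arrays(
        pid,
        dia["issue_date"].to_numpy(),
        dia["drug_class"].to_numpy(),
        dia["formulation"].to_numpy() if "formulation" in dia else np.full(len(dia), "tablet"),
        dia["quantity"].to_numpy(float),
        dia["daily_dose"].to_numpy(float),
        int(records_end) if records_end is not None else int(dia["issue_date"].max()),
    )


def _derive_from_arrays(pid, dates, classes, forms, qty, dose, records_end) -> LineDerivation:
    """Core line derivation on presorted per-patient arrays."""
    order = np.argsort(dates, kind="stable")
    dates, classes, forms, qty, dose = (
        dates[order], classes[order], forms[order], qty[order], dose[order]
    )
    first_start = int(dates[0])
    # first issue date per class, in order of appearance
    class_first: dict[str, int] = {}
    class_form: dict[str, str] = {}
    for d, c, f in zip(dates, classes, forms):
        if c not in class_first:
            class_first[c] = int(d)
            class_form[c] = str(f)
    ordered = sorted(class_first.items(), key=lambda kv: (kv[1], kv[0]))
    t_first = ordered[0][1]
    starters = [c for c, d in ordered if d == t_first]
    if len(starters) > 1:
        return LineDerivation([], True, False, first_start)

    def is_injectable(cls: str) -> bool:
        return cls in INJECTABLE_CLASSES or class_form[cls] != "tablet"

    line_classes = [ordered[0][0]]
    if len(ordered) > 1:
        line_classes.append(ordered[1][0])
    if any(is_injectable(c) for c in line_classes):
        return LineDerivation([], False, True, first_start)

    episodes: list[DrugEpisode] = []
    for k, cls in enumerate(line_classes):
        sel = classes == cls
        own_dates = dates[sel]
        later = ordered[k + 1][1] if k + 1 < len(ordered) else None
        end_event, end_date = _episode_end(
            int(own_dates[0]), int(own_dates[-1]), later, records_end
        )
        episodes.append(
            DrugEpisode(
                patient_id=pid,
                line="first" if k == 0 else "second",
                drug_class=cls,
                start_date=int(own_dates[0]),
                end_event=end_event,
                end_event_date=int(end_date),
                dates=own_dates.astype(np.int64),
                quantities=qty[sel].astype(float),
                doses=dose[sel].astype(float),
            )
        )
    return LineDerivation(episodes, False, False, first_start)


# ---------------------------------------------------------------------------
# exclusion cascade


def _group_slices(ids: np.ndarray) -> Iterable[tuple[int, int, int]]:
    """Yield (id, start, stop) runs of a sorted id array."""
    if not len(ids):
        return
    bounds = np.flatnonzero(np.diff(ids)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [len(ids)]])
    for s, e in zip(starts, stops):
        yield int(ids[s]), int(s), int(e)


def apply_exclusions(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    clinical_events: pd.DataFrame,
    config: dict | None = None,
    observations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the eligibility cascade; return retained patients + audit log.

    ``observations`` (optional) lets the diagnosis date also consider
    HbA1c values in the diabetes range. ``config`` may override
    ``hba1c_diabetes_threshold``.
    """
    validate_tables(
        patients=patients, prescriptions=prescriptions, clinical_events=clinical_events
    )
    cfg = config or {}
    thr = float(cfg.get("hba1c_diabetes_threshold", DEFAULT_HBA1C_DIABETES_THRESHOLD))

    pids = patients["patient_id"].to_numpy()
    n = len(pids)
    pid_pos = {int(p): i for i, p in enumerate(pids)}
    regstart = patients["regstart_date"].to_numpy()
    regend = patients["regend_date"].to_numpy()
    birth_year = patients["birth_year"].to_numpy(float)
    has_gap = patients["has_registration_gap"].to_numpy().astype(bool)

    ev_cat = clinical_events["category"].to_numpy()
    ev_pid = clinical_events["patient_id"].to_numpy()
    ev_date = clinical_events["event_date"].to_numpy()

    def pid_mask_from(ids: np.ndarray) -> np.ndarray:
        out = np.zeros(n, dtype=bool)
        for p in ids:
            i = pid_pos.get(int(p))
            if i is not None:
                out[i] = True
        return out

    has_code = pid_mask_from(np.unique(ev_pid[ev_cat == "diabetes_code"]))
    has_pcos = pid_mask_from(np.unique(ev_pid[ev_cat == "pcos"]))
    has_other = pid_mask_from(np.unique(ev_pid[ev_cat == "other_diabetes"]))

    rx = prescriptions.sort_values(["patient_id", "issue_date"], kind="mergesort")
    rx_pid = rx["patient_id"].to_numpy()
    rx_date = rx["issue_date"].to_numpy()
    rx_class = rx["drug_class"].to_numpy()
    rx_form = rx["formulation"].to_numpy()
    rx_qty = rx["quantity"].to_numpy(float)
    rx_dose = rx["daily_dose"].to_numpy(float)

    has_mfn = pid_mask_from(np.unique(rx_pid[rx_class == "MFN"]))

    # earliest qualifying dates for the diagnosis
    diag = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    is_dia_rx = np.isin(rx_class, DIABETES_CLASSES)
    for p, s, e in _group_slices(rx_pid):
        i = pid_pos.get(p)
        if i is None:
            continue
        m = is_dia_rx[s:e]
        if m.any():
            diag[i] = min(diag[i], int(rx_date[s:e][m].min()))
    code_dates = ev_date[ev_cat == "diabetes_code"]
    code_pids = ev_pid[ev_cat == "diabetes_code"]
    for p, d in zip(code_pids, code_dates):
        i = pid_pos.get(int(p))
        if i is not None and d < diag[i]:
            diag[i] = int(d)
    if observations is not None and len(observations):
        m = (observations["kind"].to_numpy() == "hba1c") & (
            observations["value"].to_numpy(float) >= thr
        )
        for p, d in zip(observations["patient_id"].to_numpy()[m], observations["obs_date"].to_numpy()[m]):
            i = pid_pos.get(int(p))
            if i is not None and d < diag[i]:
                diag[i] = int(d)
    has_diag = diag < np.iinfo(np.int64).max

    age_diag = np.where(has_diag, age_at(diag.astype(float), birth_year), np.nan)

    # insulin within a year of diagnosis; last prescription per patient
    insulin_within_1yr = np.zeros(n, dtype=bool)
    last_rx = np.full(n, -np.inf)
    is_insulin = rx_class == "INSULIN"
    for p, s, e in _group_slices(rx_pid):
        i = pid_pos.get(p)
        if i is None:
            continue
        last_rx[i] = int(rx_date[e - 1])
        if has_diag[i]:
            m = is_insulin[s:e] & (rx_date[s:e] <= diag[i] + 365)
            if m.any():
                insulin_within_1yr[i] = True

    # therapy-line structure
    dual = np.zeros(n, dtype=bool)
    injectable = np.zeros(n, dtype=bool)
    no_second = np.zeros(n, dtype=bool)
    first_start = np.full(n, np.inf)
    derivations: dict[int, LineDerivation] = {}
    for p, s, e in _group_slices(rx_pid):
        i = pid_pos.get(p)
        if i is None:
            continue
        m = is_dia_rx[s:e]
        if not m.any():
            no_second[i] = True  # no therapy line at all
            continue
        der = _derive_from_arrays(
            p,
            rx_date[s:e][m],
            rx_class[s:e][m],
            rx_form[s:e][m],
            rx_qty[s:e][m],
            rx_dose[s:e][m],
            int(regend[i]),
        )
        derivations[p] = der
        first_start[i] = der.first_start
        dual[i] = der.dual_start
        injectable[i] = der.injectable_line
        no_second[i] = (not der.dual_start) and (not der.injectable_line) and len(der.episodes) < 2

    rules = [
        ("no_diabetes_code", ~has_code),
        ("pcos_metformin", has_pcos & has_mfn),
        ("other_diabetes", has_other),
        ("t1d_age_lt_35", has_diag & (age_diag < 35.0)),
        ("t1d_insulin_within_1yr", insulin_within_1yr),
        ("lt_1yr_prescribing", (last_rx - regstart) < 365),
        ("registration_gap", has_gap),
        ("dual_start_same_day", dual),
        ("start_within_91d_of_registration", (first_start - regstart) < 91),
        ("injectable_or_solution_line", injectable),
        ("no_second_line", no_second),
    ]
    reason = np.full(n, "", dtype=object)
    for name, mask in rules:
        fresh = mask & (reason == "")
        reason[fresh] = name

    log = ExclusionLog(n_input=n)
    for name, _ in rules:
        log.counts[name] = int((reason == name).sum())
    retained = reason == ""
    log.n_retained = int(retained.sum())
    eligible = patients.loc[retained].reset_index(drop=True)
    return eligible, log


def derive_all_episodes(
    eligible_patients: pd.DataFrame, prescriptions: pd.DataFrame
) -> list[DrugEpisode]:
    """Therapy-line episodes (both lines) for every eligible patient."""
    keep = set(eligible_patients["patient_id"].astype(int))
    regend = dict(
        zip(
            eligible_patients["patient_id"].astype(int),
            eligible_patients["regend_date"].astype(int),
        )
    )
    rx = prescriptions.sort_values(["patient_id", "issue_date"], kind="mergesort")
    rx_pid = rx["patient_id"].to_numpy()
    rx_date = rx["issue_date"].to_numpy()
    rx_class = rx["drug_class"].to_numpy()
    rx_form = rx["formulation"].to_numpy()
    rx_qty = rx["quantity"].to_numpy(float)
    rx_dose = rx["daily_dose"].to_numpy(float)
    is_dia = np.isin(rx_class, DIABETES_CLASSES)
    episodes: list[DrugEpisode] = []
    for p, s, e in _group_slices(rx_pid):
        if p not in keep:
            continue
        m = is_dia[s:e]
        if not m.any():
            continue
        der = _derive_from_arrays(
            p, rx_date[s:e][m], rx_class[s:e][m], rx_form[s:e][m],
            rx_qty[s:e][m], rx_dose[s:e][m], regend[p],
        )
        episodes.extend(der.episodes)
    return episodes


def episodes_frame(episodes: list[DrugEpisode]) -> pd.DataFrame:
    """Flat summary table of episodes (one row per episode)."""
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in episodes],
            "line": [e.line for e in episodes],
            "drug_class": [e.drug_class for e in episodes],
            "start_date": [e.start_date for e in episodes],
            "end_event": [e.end_event for e in episodes],
            "end_event_date": [e.end_event_date for e in episodes],
            "n_prescriptions": [len(e.dates) for e in episodes],
        }
    )
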