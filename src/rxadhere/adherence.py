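"""Medical possession ratio (MPR) per therapy-line episode.

MPR = 100 x (days of medication supplied) / (days from the first
prescription to the adherence-period end date). Supply per prescription
is quantity / daily dose. The end date is (i) 365 days after the first
prescription when the patient remains on the drug through the year,
otherwise (ii) the penultimate prescription date before the stop,
switch, or end of records (a following prescription is needed to know
the days covered between prescriptions).

Validity rules applied, in order:

* a break of more than 183 days between prescriptions counts as
  stopping the drug — the episode is truncated at the last prescription
  before the break and rule (ii) applies to the truncated series;
* at least three prescriptions with a recorded (non-zero) dose, issued
  on or before the end date, are required; none at all gives
  ``all_doses_missing``, one or two give ``too_few_prescriptions``;
* the adherence period must span at least 90 days
  (``stopped_changed_lt_90d`` when the episode ended by stop/switch,
  ``span_lt_90d`` when records simply ran out);
* prescriptions with a missing dose are dropped from the numerator and
  the interval from each to the next prescription is removed from the
  denominator;
* a computed MPR below 20% or above 120% is treated as a dose-recording
  error and voided (``out_of_range_lt20`` / ``out_of_range_gt120``).

Non-adherence is MPR <= 80%; for continuous modelling the MPR is capped
at 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DrugEpisode
from .errors import UndefinedOutcomeError

__all__ = [
    "MPRResult",
    "adherence_period_end",
    "compute_mpr",
    "classify_nonadherence",
    "cap_mpr_for_modelling",
    "mpr_table",
]

MAX_GAP_DAYS = 183  # ">6 months" between prescriptions = stopping
MIN_SPAN_DAYS = 90
MIN_VALID_PRESCRIPTIONS = 3
MPR_LOWER, MPR_UPPER = 20.0, 120.0
NONADHERENCE_THRESHOLD = 80.0
MODELLING_CAP = 100.0


@dataclass
class MPRResult:
    patient_id: int
    line: str
    mpr_percent: float  # NaN unless status == "valid"-class outcome
    status: str
    end_date: int
    supply_days: float
    denominator_days: float

    @property
    def is_valid(self) -> bool:
        return self.status == "valid"


def _truncate_at_gap(episode: DrugEpisode) -> tuple[np.ndarray, np.ndarray, np.ndarray, str, int, bool]:
    """Cut the series at the first >183-day break starting inside the
    first year; a qualifying break reclassifies the end event as
    stopping at the last prescription before the break."""
    dates, qty, dose = episode.dates, episode.quantities, episode.doses
    end_event, end_event_date = episode.end_event, episode.end_event_date
    truncated = False
    if len(dates) >= 2:
        gaps = np.diff(dates)
        big = np.flatnonzero(gaps > MAX_GAP_DAYS)
        for j in big:
            if dates[j] < episode.start_date + 365:
                dates, qty, dose = dates[: j + 1], qty[: j + 1], dose[: j + 1]
                end_event, end_event_date = "stopped_gap", int(dates[-1])
                truncated = True
                break
    return dates, qty, dose, end_event, end_event_date, truncated


def adherence_period_end(episode: DrugEpisode) -> tuple[int | None, str]:
    """Adherence-period end date and the rule that produced it.

    Returns ``(end_date, "rule_i")`` for episodes continuing through the
    first year, ``(end_date, "rule_ii")`` for stop/switch/records-end
    within the year (penultimate prescription before the event), or
    ``(None, "too_few_prescriptions")`` when no penultimate prescription
    exists.
    """
    dates, _, _, end_event, end_event_date, _ = _truncate_at_gap(episode)
    if end_event == "ongoing_at_1yr":
        return episode.start_date + 365, "rule_i"
    before = dates[dates <= end_event_date]
    if len(before) < 2:
        return None, "too_few_prescriptions"
    return int(before[-2]), "rule_ii"


def compute_mpr(episode: DrugEpisode) -> MPRResult:
    """Compute the episode's MPR and validity status.

    Supply sums quantity/dose over valid-dose prescriptions issued
    strictly before the end date; the denominator is the span from start
    to end minus, for each missing-dose prescription, the interval to
    the next prescription.
    """
    dates, qty, dose, end_event, end_event_date, truncated = _truncate_at_gap(episode)
    start = episode.start_date

    def result(status: str, mpr=np.nan, end=np.nan, supply=np.nan, denom=np.nan) -> MPRResult:
        return MPRResult(
            patient_id=episode.patient_id,
            line=episode.line,
            mpr_percent=float(mpr),
            status=status,
            end_date=int(end) if np.isfinite(end) else -1,
            supply_days=float(supply),
            denominator_days=float(denom),
        )

    if end_event == "ongoing_at_1yr":
        end = start + 365
    else:
        before = dates[dates <= end_event_date]
        if len(before) < 2:
            return result("gap_gt_6mo" if truncated else "too_few_prescriptions")
        end = int(before[-2])

    in_period = dates <= end
    d_in, q_in, dose_in = dates[in_period], qty[in_period], dose[in_period]
    n_valid = int((dose_in > 0).sum())
    if n_valid == 0:
        return result("all_doses_missing", end=end)
    if n_valid < MIN_VALID_PRESCRIPTIONS:
        return result("too_few_prescriptions", end=end)

    span = end - start
    if span < MIN_SPAN_DAYS:
        status = (
            "stopped_changed_lt_90d"
            if end_event in ("switched", "stopped_gap")
            else "span_lt_90d"
        )
        return result(status, end=end)

    before_end = d_in < end
    supply = float((q_in[before_end & (dose_in > 0)] / dose_in[before_end & (dose_in > 0)]).sum())

    denominator = float(span)
    all_dates = dates  # next prescription may be the end-date one
    for j in np.flatnonzero((dose_in == 0) & before_end):
        d = d_in[j]
        later = all_dates[all_dates > d]
        nxt = float(later[0]) if len(later) else float(end)
        denominator -= min(nxt, float(end)) - float(d)
    if denominator <= 0:
        return result("all_doses_missing", end=end)

    mpr = 100.0 * supply / denominator
    if mpr < MPR_LOWER:
        return result("out_of_range_lt20", end=end, supply=supply, denom=denominator)
    if mpr > MPR_UPPER:
        return result("out_of_range_gt120", end=end, supply=supply, denom=denominator)
    return result("valid", mpr=mpr, end=end, supply=supply, denom=denominator)


def classify_nonadherence(mpr_percent: float) -> bool:
    """True iff MPR <= 80% (valid MPRs only)."""
    if not np.isfinite(mpr_percent) or not (MPR_LOWER <= mpr_percent <= MPR_UPPER):
        raise UndefinedOutcomeError(
            f"non-adherence is undefined for MPR {mpr_percent!r}"
        )
    return bool(mpr_percent <= NONADHERENCE_THRESHOLD)


def cap_mpr_for_modelling(mpr_percent: float) -> float:
    """Cap MPR at 100% for continuous modelling (association flattens)."""
    return float(min(mpr_percent, MODELLING_CAP))


def mpr_table(episodes) -> pd.DataFrame:
    """Compute MPR for a list of episodes; one row per episode."""
    results = [compute_mpr(e) for e in episodes]
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "line": [r.line for r in results],
            "mpr_percent": [round(r.mpr_percent, 1) if np.isfinite(r.mpr_percent) else np.nan for r in results],
            "mpr_raw": [r.mpr_percent for r in results],
            "status": [r.status for r in results],
            "end_date": [r.end_date for r in results],
            "supply_days": [r.supply_days for r in results],
            "denominator_days": [r.denominator_days for r in results],
        }
    )
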