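"""Seeded generator of primary-care-style prescription tables with known truth.

The generator emulates the statistical structure of a UK primary-care
type 2 diabetes cohort: each patient carries a latent *adherence
propensity* on (0, 1] for each of their first two oral therapy lines.
The propensity drives the timing of prescription refills, so that the
medical possession ratio (MPR) computed downstream from the refill dates
recovers the propensity in expectation. First- and second-line
propensities share a Gaussian latent at correlation ``rho``, which is
what makes first-drug adherence predictive of second-drug adherence.

Observable imperfections of routine data are reproduced: a configurable
fraction of prescriptions has the daily dose recorded as zero (missing),
therapy lines stop or switch at a per-day hazard, and baseline
covariates (age, co-prescriptions, pill burden) shift the propensity
with configurable weak effects.

All randomness flows from a single integer seed; identical configuration
and seed give byte-identical CSV output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.special import ndtri

from .definitions import DAYS_PER_YEAR, EPOCH_YEAR
from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "SimTables",
    "generate_cohort_dataset",
    "simulate_refill_sequence",
    "inject_missingness",
]

#: Threshold on the latent propensity below which a patient is truly
#: non-adherent (the latent analogue of MPR <= 80%).
NONADHERENCE_PROPENSITY = 0.80

_DEFAULT_EFFECTS = {
    # log-odds slopes *on non-adherence*; signs follow the direction of
    # the reported associations (younger age below 70 and antidepressant
    # use increase non-adherence; higher pill burden decreases it for
    # the second line).
    "age_below_70_per_year": 0.015,
    "on_antidepressant": 0.30,
    "tablets_per_day_line2": -0.02,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Parameters
    ----------
    n_patients
        Number of simulated patients (before any eligibility exclusion).
    propensity_logit_sd
        Standard deviation of the latent logit of the adherence
        propensity (the propensity is logit-normal).
    propensity_logit_mean_line1, propensity_logit_mean_line2
        Latent logit means. ``None`` (default) auto-calibrates each mean
        so that the marginal probability of a propensity <= 0.80 matches
        ``target_nonadherent_line*``.
    target_nonadherent_line1, target_nonadherent_line2
        Calibration targets for the non-adherence prevalence on each
        line (defaults 19% and 14%).
    rho
        Correlation in [0, 1] of the Gaussian latents behind the two
        lines' propensities.
    missing_dose_frac
        Fraction of prescription rows whose daily dose is recorded as
        zero (default 0.21).
    switch_hazard
        Per-day hazard of intensification (start of the second drug)
        once the first line is at least 90 days old.
    covariate_effects
        Map predictor-name -> log-odds slope on non-adherence.
    supply_days
        Days of medication issued per prescription.
    refill_jitter_sd
        Log-scale SD of the multiplicative jitter on refill gaps.
    seed
        Default seed used when ``generate_cohort_dataset`` is called
        without an explicit one.
    """

    n_patients: int = 2000
    propensity_logit_sd: float = 1.0
    propensity_logit_mean_line1: float | None = None
    propensity_logit_mean_line2: float | None = None
    target_nonadherent_line1: float = 0.19
    target_nonadherent_line2: float = 0.14
    rho: float = 0.52
    missing_dose_frac: float = 0.21
    switch_hazard: float = 0.0015
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    supply_days: int = 28
    refill_jitter_sd: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients >= 1):
            raise ConfigurationError("n_patients must be a positive integer")
        for name in ("missing_dose_frac", "rho"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("target_nonadherent_line1", "target_nonadherent_line2"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v!r}")
        if self.propensity_logit_sd <= 0:
            raise ConfigurationError("propensity_logit_sd must be positive")
        if self.switch_hazard < 0:
            raise ConfigurationError("switch_hazard must be non-negative")
        if self.supply_days < 1:
            raise ConfigurationError("supply_days must be a positive integer")
        if self.refill_jitter_sd < 0:
            raise ConfigurationError("refill_jitter_sd must be non-negative")
        for k, v in self.covariate_effects.items():
            if not math.isfinite(v):
                raise ConfigurationError(f"covariate_effects[{k!r}] must be finite")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


class SimTables(NamedTuple):
    """The four input tables plus the per-patient ground truth."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    clinical_events: pd.DataFrame
    observations: pd.DataFrame
    ground_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# refill timing


YEAR_WINDOW = 365


def _gap_scale(propensity: float, supply_days: float) -> float:
    """Mean refill gap so the one-year-window MPR is unbiased.

    A patient who fills on day 0 and thereafter at gaps g accumulates,
    on average, ``0.5 + 365/g`` fills inside the year window, so the raw
    possession ratio ``supply * n_fills / 365`` overshoots the
    propensity by about ``supply / (2 * 365)``. The gap is widened by
    ``365*p / (365*p - supply/2)`` to cancel that edge effect; for
    typical propensities this keeps the mean gap within ~10% of
    ``supply / propensity``. Episodes that stop or switch within the
    year are measured up to a prescription date instead, where the
    plain gap ``supply / propensity`` is already unbiased, so the
    factor only applies when refills continue past a year.
    """
    target = YEAR_WINDOW * propensity
    return supply_days / propensity * (target / max(target - supply_days / 2.0, supply_days / 2.0))


def _refill_offsets(
    propensity: float,
    supply_days: int,
    horizon_days: int,
    rng: np.random.Generator,
    jitter_sd: float,
) -> np.ndarray:
    """Integer issue-day offsets in [0, horizon), first fill at day 0."""
    if propensity <= 0:
        raise ValueError("propensity must be strictly positive")
    if propensity > 1:
        raise ValueError("propensity must not exceed 1")
    if horizon_days < supply_days:
        raise ValueError("horizon_days must be at least supply_days")
    if horizon_days >= YEAR_WINDOW:
        gap_mean = _gap_scale(propensity, supply_days)
    else:
        gap_mean = supply_days / propensity
    n_max = int(horizon_days / gap_mean * 1.6) + 8
    if jitter_sd > 0:
        jitter = rng.lognormal(-0.5 * jitter_sd**2, jitter_sd, n_max)
    else:
        jitter = np.ones(n_max)
    gaps = np.maximum(1.0, np.rint(gap_mean * jitter))
    days = np.concatenate([[0.0], np.cumsum(gaps)])
    while days[-1] < horizon_days - 1:  # pragma: no cover - rare top-up
        extra = np.maximum(1.0, np.rint(gap_mean * rng.lognormal(-0.5 * jitter_sd**2, jitter_sd, 8)))
        days = np.concatenate([days, days[-1] + np.cumsum(extra)])
    return days[days < horizon_days].astype(np.int64)


def simulate_refill_sequence(
    propensity: float,
    supply_days: int,
    horizon_days: int,
    seed: int | np.random.Generator = 0,
    jitter_sd: float = 0.10,
) -> list[dict]:
    """Simulate one drug's refill record over an observation horizon.

    Returns a list of prescription records (``issue_date``, ``quantity``,
    ``daily_dose``) at daily dose 1, with the first record on day 0 and
    consecutive gaps close to ``supply_days / propensity`` with small
    multiplicative jitter. The possession ratio observable downstream
    equals the propensity in expectation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = _refill_offsets(propensity, supply_days, horizon_days, rng, jitter_sd)
    return [
        {"issue_date": int(d), "quantity": float(supply_days), "daily_dose": 1.0}
        for d in offsets
    ]


def inject_missingness(
    prescriptions: pd.DataFrame,
    frac: float,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Set ``daily_dose`` to zero on exactly ``round(frac * N)`` rows.

    Rows are chosen uniformly at random under the given seed; the input
    frame is not modified.
    """
    if not (0.0 <= frac <= 1.0):
        raise ConfigurationError(f"missing_dose_frac must lie in [0, 1], got {frac!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = prescriptions.copy()
    n = len(out)
    k = int(round(frac * n))
    if k > 0:
        rows = rng.choice(n, size=k, replace=False)
        out.iloc[rows, out.columns.get_loc("daily_dose")] = 0.0
    return out


# ---------------------------------------------------------------------------
# patient-level latent stage


def _draw_patient_frame(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw all patient-level variables, covariates and latent propensities.

    Kept separate from table construction so the dependence structure can
    be examined cheaply at large n.
    """
    n = config.n_patients
    eff = config.covariate_effects
    sd = config.propensity_logit_sd

    t0 = rng.integers(0, 1000, n)
    reg_offset = rng.integers(120, 2500, n)
    records_span = rng.integers(900, 2000, n)
    diag_lag = rng.integers(30, 700, n)

    female = rng.random(n) < 0.45
    age_start = np.clip(rng.normal(62.0, 12.0, n), 37.0, 92.0)

    u_eth = rng.random(n)
    eth_draw = rng.random(n)
    ethnicity = np.where(
        u_eth < 0.52,
        "missing",
        np.select(
            [eth_draw < 0.85, eth_draw < 0.93, eth_draw < 0.97],
            ["white", "asian", "black"],
            "other",
        ),
    )

    bmi = np.clip(rng.normal(31.0, 5.5, n), 17.0, 55.0)
    has_bmi = rng.random(n) < 0.85
    hba1c_line1 = np.clip(rng.normal(58.0, 12.0, n), 42.0, 110.0)
    has_h1 = rng.random(n) < 0.90
    hba1c_line2 = np.clip(rng.normal(68.0, 12.0, n), 42.0, 120.0)
    has_h2 = rng.random(n) < 0.90
    hba1c_diag = np.clip(rng.normal(64.0, 12.0, n), 48.0, 120.0)
    has_hdiag = rng.random(n) < 0.80

    on_antidep = rng.random(n) < 0.15
    on_bp = rng.random(n) < 0.60
    on_lipid = rng.random(n) < 0.55
    # co-medication: counts of distinct repeat medicines per category,
    # overdispersed (gamma-Poisson) for the unclassified remainder so
    # that pill burden has a realistic polypharmacy tail
    n_meds_bp = np.where(on_bp, 1 + rng.poisson(0.8, n), 0)
    n_meds_lip = on_lipid.astype(int)
    n_meds_dep = on_antidep.astype(int)
    n_meds_other = rng.poisson(rng.gamma(1.3, 3.0, n))
    n_meds = n_meds_bp + n_meds_lip + n_meds_dep + n_meds_other
    m_total = int(n_meds.sum())
    med_dose_flat = rng.choice([1.0, 2.0, 3.0], m_total, p=[0.45, 0.35, 0.2])
    med_issues_flat = rng.integers(1, 4, m_total)
    med_offsets = np.concatenate([[0], np.cumsum(n_meds)]).astype(int)
    med_qty = 28.0 * med_dose_flat * med_issues_flat
    qty_sum = np.zeros(n)
    if m_total:
        np.add.at(qty_sum, np.repeat(np.arange(n), n_meds), med_qty)
    n_charlson = rng.poisson(0.6, n)

    # exclusion-exercising subgroups (mutually exclusive, first match)
    u = rng.random(n)
    edges = [
        ("no_diabetes_code", 0.010),
        ("pcos_metformin", 0.010),
        ("other_diabetes", 0.010),
        ("t1d_age_lt_35", 0.015),
        ("t1d_insulin_within_1yr", 0.015),
        ("registration_gap", 0.020),
        ("start_within_91d", 0.020),
        ("lt_1yr_prescribing", 0.010),
        ("dual_start", 0.020),
        ("injectable_line", 0.010),
    ]
    trigger = np.full(n, "none", dtype=object)
    lo = 0.0
    for name, frac in edges:
        trigger[(u >= lo) & (u < lo + frac)] = name
        lo += frac

    # keep ordinary diagnoses comfortably above the type 1 age threshold
    diag_lag = np.minimum(diag_lag, ((age_start - 35.5) * DAYS_PER_YEAR).astype(int))
    diag_lag = np.minimum(diag_lag, reg_offset - 40)
    diag_lag = np.maximum(diag_lag, 1)

    m = trigger == "t1d_age_lt_35"
    if m.any():
        age_start[m] = rng.uniform(20.0, 34.0, m.sum()) + diag_lag[m] / DAYS_PER_YEAR
    m = trigger == "registration_gap"
    has_gap = m.copy()
    m = trigger == "start_within_91d"
    if m.any():
        reg_offset[m] = rng.integers(0, 91, m.sum())
    m = trigger == "lt_1yr_prescribing"
    if m.any():
        reg_offset[m] = rng.integers(95, 120, m.sum())
        records_span[m] = rng.integers(100, 240, m.sum())
    diag_lag = np.minimum(diag_lag, reg_offset - 40)
    diag_lag = np.maximum(diag_lag, 1)

    birth_year = np.rint(EPOCH_YEAR + t0 / DAYS_PER_YEAR - age_start).astype(int)

    # drug classes
    line1_class = np.where(rng.random(n) < 0.92, "MFN", "SU").astype(object)
    line1_class[trigger == "pcos_metformin"] = "MFN"
    line1_class[trigger == "injectable_line"] = "INSULIN"
    u2 = rng.random(n)
    line2_class = np.select(
        [u2 < 0.55, u2 < 0.85, u2 < 0.95], ["SU", "DPP4", "TZD"], "SGLT2"
    ).astype(object)
    # sulfonylurea starters usually intensify with metformin
    su_first = line1_class == "SU"
    line2_class[su_first] = np.where(u2[su_first] < 0.75, "MFN", "DPP4")
    line2_class[line2_class == line1_class] = "DPP4"

    # time to intensification
    if config.switch_hazard > 0:
        wait = rng.exponential(1.0 / config.switch_hazard, n)
    else:
        wait = np.full(n, np.inf)
    t2 = t0 + 90 + np.where(np.isfinite(wait), np.rint(wait), 10**9).astype(np.int64)
    t2[trigger == "dual_start"] = t0[trigger == "dual_start"]

    tablets_per_day = qty_sum / 91.0

    # covariate contributions on the non-adherence logit
    c1 = (
        eff.get("age_below_70_per_year", 0.0) * np.maximum(70.0 - age_start, 0.0)
        + eff.get("on_antidepressant", 0.0) * on_antidep
    )
    c2 = c1 + eff.get("tablets_per_day_line2", 0.0) * tablets_per_day
    c1 = c1 - c1.mean()
    c2 = c2 - c2.mean()

    thr = logit(NONADHERENCE_PROPENSITY)
    s1 = math.sqrt(sd**2 + float(np.var(c1)))
    s2 = math.sqrt(sd**2 + float(np.var(c2)))
    mu1 = (
        config.propensity_logit_mean_line1
        if config.propensity_logit_mean_line1 is not None
        else thr + s1 * float(ndtri(1.0 - config.target_nonadherent_line1))
    )
    mu2 = (
        config.propensity_logit_mean_line2
        if config.propensity_logit_mean_line2 is not None
        else thr + s2 * float(ndtri(1.0 - config.target_nonadherent_line2))
    )

    z1 = rng.standard_normal(n)
    z2 = config.rho * z1 + math.sqrt(1.0 - config.rho**2) * rng.standard_normal(n)
    p1 = expit(mu1 + sd * z1 - c1)
    p2 = expit(mu2 + sd * z2 - c2)

    return {
        "patient_id": np.arange(1, n + 1),
        "t0": t0,
        "t2": t2,
        "reg_offset": reg_offset,
        "records_span": records_span,
        "diag_lag": diag_lag,
        "female": female,
        "age_start": age_start,
        "birth_year": birth_year,
        "ethnicity": ethnicity,
        "bmi": bmi,
        "has_bmi": has_bmi,
        "hba1c_line1": hba1c_line1,
        "has_h1": has_h1,
        "hba1c_line2": hba1c_line2,
        "has_h2": has_h2,
        "hba1c_diag": hba1c_diag,
        "has_hdiag": has_hdiag,
        "on_antidep": on_antidep,
        "on_bp": on_bp,
        "on_lipid": on_lipid,
        "n_meds_bp": n_meds_bp,
        "n_meds_lip": n_meds_lip,
        "n_meds_dep": n_meds_dep,
        "n_meds_other": n_meds_other,
        "med_dose_flat": med_dose_flat,
        "med_issues_flat": med_issues_flat,
        "med_offsets": med_offsets,
        "tablets_per_day": tablets_per_day,
        "n_charlson": n_charlson,
        "trigger": trigger,
        "line1_class": line1_class,
        "line2_class": line2_class,
        "propensity_line1": p1,
        "propensity_line2": p2,
        "has_gap": has_gap,
    }


_CLASS_DOSE = {"MFN": 2.0, "SU": 1.0, "TZD": 1.0, "DPP4": 1.0, "SGLT2": 1.0, "INSULIN": 1.0}

_CHARLSON_POOL = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "chronic_pulmonary_disease",
    "rheumatic_disease",
    "peptic_ulcer_disease",
    "mild_liver_disease",
    "renal_disease",
    "malignancy",
)


def generate_cohort_dataset(config: SimConfig, seed: int | None = None) -> SimTables:
    """Generate the four input tables plus ground truth under one seed.

    The returned tables conform to the cohort reader's schemas; a
    ground-truth row is emitted for every patient, including those
    designed to fail an eligibility rule.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed if seed is None else int(seed)))
    pf = _draw_patient_frame(config, rng)
    n = config.n_patients
    supply = config.supply_days
    jit = config.refill_jitter_sd

    rx_rows: list[tuple] = []
    ev_rows: list[tuple] = []
    obs_rows: list[tuple] = []

    def add_refills(pid, start, cls, propensity, horizon, formulation="tablet"):
        dose = _CLASS_DOSE[cls]
        if horizon < supply:
            offs = np.array([0])
        else:
            offs = _refill_offsets(propensity, supply, horizon, rng, jit)
        for d in offs:
            rx_rows.append((pid, int(start + d), cls, formulation, supply * dose, dose))
        return offs

    def add_window_meds(pid, start, regstart, i):
        """Repeat co-medication issues in the 91 days before a start."""
        off = int(pf["med_offsets"][i])
        codes = (
            ["antihypertensive"] * int(pf["n_meds_bp"][i])
            + ["statin"] * int(pf["n_meds_lip"][i])
            + ["ssri"] * int(pf["n_meds_dep"][i])
            + ["analgesic"] * int(pf["n_meds_other"][i])
        )
        for j, code in enumerate(codes):
            dose = float(pf["med_dose_flat"][off + j])
            for _ in range(int(pf["med_issues_flat"][off + j])):
                d = start - int(rng.integers(1, 92))
                if d >= regstart:
                    rx_rows.append((pid, d, code, "tablet", 28.0 * dose, dose))

    for i in range(n):
        pid = int(pf["patient_id"][i])
        t0 = int(pf["t0"][i])
        t2 = int(pf["t2"][i])
        regstart = t0 - int(pf["reg_offset"][i])
        regend = t0 + int(pf["records_span"][i])
        diag = t0 - int(pf["diag_lag"][i])
        trig = pf["trigger"][i]
        p1 = float(pf["propensity_line1"][i])
        p2 = float(pf["propensity_line2"][i])
        cls1 = pf["line1_class"][i]
        cls2 = pf["line2_class"][i]

        # clinical events
        if trig != "no_diabetes_code":
            ev_rows.append((pid, diag, "diabetes_code"))
        if trig == "pcos_metformin":
            ev_rows.append((pid, max(regstart, diag - int(rng.integers(0, 200))), "pcos"))
        if trig == "other_diabetes":
            ev_rows.append((pid, diag, "other_diabetes"))
        if pf["on_antidep"][i]:
            ev_rows.append((pid, max(regstart, t0 - int(rng.integers(30, 400))), "depression"))
        for _ in range(int(pf["n_charlson"][i])):
            cond = _CHARLSON_POOL[int(rng.integers(0, len(_CHARLSON_POOL)))]
            ev_rows.append((pid, int(rng.integers(regstart, max(t0, regstart + 1))), f"charlson:{cond}"))

        # first-line refills
        form1 = "injectable" if trig == "injectable_line" else "tablet"
        horizon1 = min(t2, regend) - t0
        if trig == "dual_start":
            horizon1 = min(600, regend - t0)
        add_refills(pid, t0, cls1, p1, horizon1, form1)
        if trig == "t1d_insulin_within_1yr":
            rx_rows.append((pid, diag + int(rng.integers(30, 300)), "INSULIN", "injectable", supply, 1.0))

        # second-line refills
        start2 = None
        if trig == "dual_start":
            start2 = t0
            add_refills(pid, t0, cls2, p2, min(600, regend - t0))
        elif t2 + 90 <= regend:
            start2 = t2
            add_refills(pid, t2, cls2, p2, regend - t2)

        # co-medication around each therapy start
        add_window_meds(pid, t0, regstart, i)
        if start2 is not None and start2 != t0:
            add_window_meds(pid, start2, regstart, i)

        # observations
        if pf["has_hdiag"][i]:
            obs_rows.append((pid, diag, "hba1c", round(float(pf["hba1c_diag"][i]), 1)))
        if pf["has_h1"][i]:
            obs_rows.append((pid, t0 - int(rng.integers(1, 151)), "hba1c", round(float(pf["hba1c_line1"][i]), 1)))
        if pf["has_bmi"][i]:
            obs_rows.append((pid, t0 - int(rng.integers(1, 151)), "bmi", round(float(pf["bmi"][i]), 1)))
        if start2 is not None and pf["has_h2"][i]:
            obs_rows.append((pid, start2 - int(rng.integers(1, 151)), "hba1c", round(float(pf["hba1c_line2"][i]), 1)))
        if start2 is not None and pf["has_bmi"][i]:
            obs_rows.append((pid, start2 - int(rng.integers(1, 151)), "bmi", round(float(pf["bmi"][i]), 1)))

    patients = pd.DataFrame(
        {
            "patient_id": pf["patient_id"],
            "regstart_date": pf["t0"] - pf["reg_offset"],
            "regend_date": pf["t0"] + pf["records_span"],
            "has_registration_gap": pf["has_gap"].astype(int),
            "sex": np.where(pf["female"], "F", "M"),
            "birth_year": pf["birth_year"],
            "ethnicity": pf["ethnicity"],
        }
    )
    prescriptions = pd.DataFrame(
        rx_rows,
        columns=["patient_id", "issue_date", "drug_class", "formulation", "quantity", "daily_dose"],
    )
    prescriptions = prescriptions.sort_values(
        ["patient_id", "issue_date", "drug_class"], kind="mergesort"
    ).reset_index(drop=True)
    prescriptions = inject_missingness(prescriptions, config.missing_dose_frac, rng)

    clinical_events = pd.DataFrame(ev_rows, columns=["patient_id", "event_date", "category"])
    clinical_events = clinical_events.sort_values(
        ["patient_id", "event_date", "category"], kind="mergesort"
    ).reset_index(drop=True)
    observations = pd.DataFrame(obs_rows, columns=["patient_id", "obs_date", "kind", "value"])
    observations = observations.sort_values(
        ["patient_id", "obs_date", "kind"], kind="mergesort"
    ).reset_index(drop=True)

    ground_truth = pd.DataFrame(
        {
            "patient_id": pf["patient_id"],
            "propensity_line1": pf["propensity_line1"],
            "propensity_line2": pf["propensity_line2"],
            "true_nonadherent_line1": (pf["propensity_line1"] <= NONADHERENCE_PROPENSITY).astype(int),
            "true_nonadherent_line2": (pf["propensity_line2"] <= NONADHERENCE_PROPENSITY).astype(int),
        }
    )
    return SimTables(patients, prescriptions, clinical_events, observations, ground_truth)


def write_tables(tables: SimTables, out_dir) -> None:
    """Write the five tables as CSV; deterministic byte-for-byte."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = ["patients", "prescriptions", "clinical_events", "observations", "ground_truth"]
    for name, frame in zip(names, tables):
        frame.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
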