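"""Independent oracles used only by the test suite.

Each re-derives a quantity along a deliberately different code path
from the implementation it checks: the MPR oracle walks calendar days
one at a time with a medication-stock counter; the concordance oracle
enumerates all positive-negative pairs; the relative-risk oracle
bootstraps the 2x2 table.
"""

from __future__ import annotations

import math

import numpy as np


def mpr_day_walk(episode) -> tuple[str, float]:
    """Day-level stock-simulation MPR for one episode.

    Returns (status, mpr_percent); the MPR is NaN unless valid-range
    arithmetic applies. Possession is counted by walking every day from
    start to end, adding quantity/dose days of stock on each valid
    prescription day, consuming one day of stock per day, and crediting
    unconsumed stock at the end; missing-dose intervals are flagged day
    by day and dropped from the denominator.
    """
    ds = [int(d) for d in episode.dates]
    qs = [float(q) for q in episode.quantities]
    os_ = [float(o) for o in episode.doses]
    start = ds[0]
    end_event, end_event_date = episode.end_event, episode.end_event_date

    trunc = None
    for k in range(1, len(ds)):
        if ds[k] - ds[k - 1] > 183 and ds[k - 1] < start + 365:
            trunc = k
            break
    if trunc is not None:
        ds, qs, os_ = ds[:trunc], qs[:trunc], os_[:trunc]
        end_event, end_event_date = "stopped_gap", ds[-1]

    if end_event == "ongoing_at_1yr":
        end = start + 365
    else:
        before = [d for d in ds if d <= end_event_date]
        if len(before) < 2:
            return ("gap_gt_6mo" if trunc is not None else "too_few_prescriptions", math.nan)
        end = before[-2]

    in_period = [(d, q, o) for d, q, o in zip(ds, qs, os_) if d <= end]
    n_valid = sum(1 for _, _, o in in_period if o > 0)
    if n_valid == 0:
        return "all_doses_missing", math.nan
    if n_valid < 3:
        return "too_few_prescriptions", math.nan
    if end - start < 90:
        if end_event in ("switched", "stopped_gap"):
            return "stopped_changed_lt_90d", math.nan
        return "span_lt_90d", math.nan

    removed: set[int] = set()
    for d, q, o in in_period:
        if o == 0 and d < end:
            later = [x for x in ds if x > d]
            nxt = later[0] if later else end
            for day in range(d, min(nxt, end)):
                removed.add(day)

    additions: dict[int, float] = {}
    for d, q, o in in_period:
        if o > 0 and d < end:
            additions[d] = additions.get(d, 0.0) + q / o

    denom = 0
    stock = 0.0
    consumed = 0.0
    for day in range(start, end):
        stock += additions.get(day, 0.0)
        if day not in removed:
            denom += 1
        if stock > 0:
            take = min(1.0, stock)
            consumed += take
            stock -= take
    if denom <= 0:
        return "all_doses_missing", math.nan
    possession = consumed + stock  # unconsumed supply still counts
    mpr = 100.0 * possession / denom
    if mpr < 20.0:
        return "out_of_range_lt20", math.nan
    if mpr > 120.0:
        return "out_of_range_gt120", math.nan
    return "valid", mpr


def c_brute_force(scores, labels) -> float:
    """Concordance by enumerating every positive-negative pair."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def rr_bootstrap_log_se(a, n1, b, n2, n_boot=100_000, seed=0) -> float:
    """Bootstrap standard error of log(relative risk) for a 2x2 table."""
    rng = np.random.default_rng(seed)
    a_star = rng.binomial(n1, a / n1, n_boot)
    b_star = rng.binomial(n2, b / n2, n_boot)
    ok = (a_star > 0) & (b_star > 0)
    log_rr = np.log((a_star[ok] / n1) / (b_star[ok] / n2))
    return float(np.std(log_rr))
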