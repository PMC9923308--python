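"""Intensity classification, bout detection and daily/weekly PA summaries.

Epochs are classified against wrist-specific heart-failure cut-points
(inactive < inactivity_cut <= light < mvpa_cut <= MVPA).  Bouts are
sustained periods of at least 10 min in one category permitting up to 20%
of epochs outside it; bout selection is leftmost-first, then longest, with
in-category first and last epochs, and accepted bouts never overlap.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import constants
from .errors import IntegrityError
from .types import (
    BOUTING_MODES,
    CATEGORIES,
    STRATA,
    Bout,
    DailySummary,
    EpochSeries,
    SubjectVisitPA,
    ThresholdSet,
    ValidWeek,
)

log = logging.getLogger(__name__)

_CAT_CODE = {c: i for i, c in enumerate(CATEGORIES)}

# slack for the in-category fraction comparison: epoch counts are integers,
# so true margins are far larger than float rounding
_FRAC_EPS = 1e-9


def classify(enmo: np.ndarray, thresholds: ThresholdSet) -> np.ndarray:
    """Vectorised intensity codes (0 inactive, 1 light, 2 mvpa)."""
    enmo = np.asarray(enmo, dtype=float)
    return np.where(
        enmo < thresholds.inactivity_cut,
        0,
        np.where(enmo >= thresholds.mvpa_cut, 2, 1),
    ).astype(np.int8)


def classify_epoch(enmo: float, thresholds: ThresholdSet) -> str:
    """Category of a single epoch value (boundaries: < inactivity, >= mvpa)."""
    if enmo < 0:
        raise ValueError("enmo must be >= 0")
    return CATEGORIES[int(classify(np.array([enmo]), thresholds)[0])]


def impute_nonwear(week: ValidWeek) -> EpochSeries:
    """Fill non-wear/artifact epochs from same-clock-time epochs of other days.

    Each flagged epoch takes the mean ENMO of worn epochs at the same time
    of day across the other days of the week; if no day is worn at that
    time, the value falls back to 0 mg.  Worn epochs are unchanged and the
    flags are preserved (wear time is still computed from them).
    """
    ep = week.epochs
    per_day = int(round(86400.0 / ep.epoch_length))
    if ep.n != 7 * per_day:
        raise IntegrityError(f"valid week has {ep.n} epochs, expected {7 * per_day}")
    mat = ep.enmo.reshape(7, per_day)
    bad = ep.flagged.reshape(7, per_day)
    good = ~bad
    ngood = good.sum(axis=0)
    sums = np.where(good, mat, 0.0).sum(axis=0)
    col_mean = np.where(ngood > 0, sums / np.maximum(ngood, 1), 0.0)
    filled = np.where(bad, col_mean[None, :], mat)
    return replace(ep, enmo=filled.ravel())


def detect_bouts(
    epochs,
    category: str,
    thresholds: ThresholdSet,
    min_minutes: float = constants.BOUT_MIN_MINUTES,
    allowance: float = constants.BOUT_ALLOWANCE,
    epoch_length: Optional[float] = None,
) -> List[Bout]:
    """Detect intensity bouts of ``category`` in an epoch series.

    A bout is an interval whose first and last epoch are in-category, whose
    in-category fraction is at least ``1 - allowance`` and whose length is
    at least ``min_minutes``.  Scanning left to right, each bout takes the
    longest feasible end for the current leftmost feasible start; accepted
    bouts are disjoint and their epochs are not reused.

    ``epochs`` may be an :class:`EpochSeries` or a bare ENMO array (in which
    case ``epoch_length`` must be given).
    """
    if not 0.0 <= allowance < 0.5:
        raise ValueError("allowance must be in [0, 0.5)")
    if isinstance(epochs, EpochSeries):
        enmo = epochs.enmo
        el = epochs.epoch_length
    else:
        enmo = np.asarray(epochs, dtype=float)
        if epoch_length is None:
            raise ValueError("epoch_length required when passing a bare array")
        el = float(epoch_length)

    in_cat = classify(enmo, thresholds) == _CAT_CODE[category]
    n = in_cat.size
    min_len = int(round(min_minutes * 60.0 / el))
    q = 1.0 - allowance

    # prefix in-category counts; an interval [i, j] is fraction-feasible iff
    # f(j + 1) >= f(i) with f(k) = P[k] - q * k
    P = np.concatenate(([0], np.cumsum(in_cat)))
    f = P - q * np.arange(n + 1)
    g = np.where(in_cat, f[1:], -np.inf)  # candidate ends must be in-category
    suffix_max = np.maximum.accumulate(g[::-1])[::-1]
    neg_suffix = -suffix_max  # non-decreasing, for searchsorted

    starts = np.flatnonzero(in_cat)
    bouts: List[Bout] = []
    si = 0
    while si < starts.size:
        i = int(starts[si])
        lo = i + min_len - 1
        if lo >= n:
            break
        t = f[i] - _FRAC_EPS
        # largest j >= lo with g[j] >= t (positions with suffix_max >= t form
        # a prefix because suffix_max is non-increasing)
        k = int(np.searchsorted(neg_suffix[lo:], -t, side="right"))
        if k == 0:
            si += 1
            continue
        j = lo + k - 1
        bouts.append(
            Bout(
                category=category,
                start_epoch=i,
                end_epoch=j,
                n_in_category=int(P[j + 1] - P[i]),
            )
        )
        si = int(np.searchsorted(starts, j + 1))
    return bouts


def bout_mask(bouts: Sequence[Bout], n: int) -> np.ndarray:
    """Boolean mask of epochs covered by accepted bouts."""
    mask = np.zeros(n, dtype=bool)
    for b in bouts:
        mask[b.start_epoch : b.end_epoch + 1] = True
    return mask


def day_type_of(date: dt.date) -> str:
    """Saturday/Sunday of the local calendar are weekend days."""
    return "weekend" if date.weekday() >= 5 else "weekday"


def _unbouted_minutes(codes: np.ndarray, el: float) -> Dict[str, float]:
    """Category minutes over a full day.

    The epoch counts partition the 17,280-epoch day exactly; the minute
    values carry the usual binary representation error of count/12.
    """
    return {
        cat: float(np.sum(codes == _CAT_CODE[cat])) * el / 60.0 for cat in CATEGORIES
    }


def summarise_day(
    epochs_day: EpochSeries,
    bouts: Mapping[str, Sequence[Bout]],
    thresholds: ThresholdSet,
) -> DailySummary:
    """Daily bouted/unbouted minutes per category plus wear time.

    ``bouts`` maps category -> bouts with indices relative to the day's
    series (bouts crossing midnight are clipped by the caller).  Unbouted
    minutes partition the full 1440-min day exactly.
    """
    el = epochs_day.epoch_length
    per_day = int(round(86400.0 / el))
    if epochs_day.n != per_day:
        raise IntegrityError(f"day has {epochs_day.n} epochs, expected {per_day}")

    codes = classify(epochs_day.enmo, thresholds)
    unbouted = _unbouted_minutes(codes, el)
    bouted = {}
    for cat in CATEGORIES:
        mask = bout_mask(bouts.get(cat, ()), epochs_day.n)
        bouted[cat] = float(mask.sum()) * el / 60.0

    date = epochs_day.start.date()
    return DailySummary(
        date=date,
        day_type=day_type_of(date),
        wear_min=float(np.sum(~epochs_day.flagged)) * el / 60.0,
        unbouted_min=unbouted,
        bouted_min=bouted,
    )


def summarise_visit(
    daily: Sequence[DailySummary],
    guideline_weekly_min: float = constants.GUIDELINE_WEEKLY_MIN,
    subject_id: str = "",
    visit: str = "",
) -> SubjectVisitPA:
    """Weekly aggregates over a 5-weekday / 2-weekend-day valid week.

    The all-days mean is the (5 x weekday + 2 x weekend)/7 weighted mean;
    weekly MVPA is 7 x the all-days MVPA mean and sets the >=150 min/week
    guideline flag per bouting mode.
    """
    if len(daily) != 7:
        raise IntegrityError(f"expected 7 daily summaries, got {len(daily)}")
    wd = [d for d in daily if d.day_type == "weekday"]
    we = [d for d in daily if d.day_type == "weekend"]
    if len(wd) != 5 or len(we) != 2:
        raise IntegrityError(
            "expected 5 weekdays and 2 weekend days, got "
            + ", ".join(f"{d.date}({d.day_type})" for d in daily)
        )

    def _mean(days, cat, mode):
        vals = [
            (d.bouted_min if mode == "bouted" else d.unbouted_min)[cat] for d in days
        ]
        return float(np.mean(vals))

    means: Dict = {}
    for cat in CATEGORIES:
        for mode in BOUTING_MODES:
            wmean = _mean(wd, cat, mode)
            emean = _mean(we, cat, mode)
            means[("weekday", cat, mode)] = wmean
            means[("weekend", cat, mode)] = emean
            means[("all_days", cat, mode)] = (5.0 * wmean + 2.0 * emean) / 7.0

    weekly = {m: 7.0 * means[("all_days", "mvpa", m)] for m in BOUTING_MODES}
    meets = {m: weekly[m] >= guideline_weekly_min for m in BOUTING_MODES}
    return SubjectVisitPA(
        subject_id=subject_id,
        visit=visit,
        means=means,
        weekly_mvpa_min=weekly,
        meets_guideline=meets,
    )


def summarise_week(
    week: ValidWeek,
    thresholds: ThresholdSet,
    min_minutes: float = constants.BOUT_MIN_MINUTES,
    allowance: float = constants.BOUT_ALLOWANCE,
    guideline_weekly_min: float = constants.GUIDELINE_WEEKLY_MIN,
):
    """Impute non-wear, detect bouts over the full week, summarise days/visit.

    Bouts are detected on the imputed 7-day series so that bouts crossing
    midnight are kept; each day then counts the bout epochs falling inside
    it.  Returns ``(daily_summaries, subject_visit_pa)``.
    """
    imputed = impute_nonwear(week)
    el = imputed.epoch_length
    per_day = int(round(86400.0 / el))

    masks = {
        cat: bout_mask(
            detect_bouts(imputed, cat, thresholds, min_minutes, allowance), imputed.n
        )
        for cat in CATEGORIES
    }

    dailies: List[DailySummary] = []
    for d in range(7):
        i0, i1 = d * per_day, (d + 1) * per_day
        day_ep = imputed.slice(i0, i1)
        codes = classify(day_ep.enmo, thresholds)
        unbouted = _unbouted_minutes(codes, el)
        bouted = {
            cat: float(masks[cat][i0:i1].sum()) * el / 60.0 for cat in CATEGORIES
        }
        date = week.days[d]
        dailies.append(
            DailySummary(
                date=date,
                day_type=day_type_of(date),
                wear_min=float(np.sum(~day_ep.flagged)) * el / 60.0,
                unbouted_min=unbouted,
                bouted_min=bouted,
            )
        )
    visit = summarise_visit(
        dailies, guideline_weekly_min, subject_id=week.subject_id, visit=week.visit
    )
    return dailies, visit


# ---------------------------------------------------------------------------
# Tabular interfaces
# ---------------------------------------------------------------------------

def daily_table(dailies: Sequence[DailySummary], subject_id: str, visit: str) -> pd.DataFrame:
    rows = []
    for d in dailies:
        row = {
            "subject_id": subject_id,
            "visit": visit,
            "date": d.date.isoformat(),
            "day_type": d.day_type,
            "wear_min": d.wear_min,
        }
        for cat in CATEGORIES:
            row[f"{cat}_unbouted_min"] = d.unbouted_min[cat]
            row[f"{cat}_bouted_min"] = d.bouted_min[cat]
        rows.append(row)
    return pd.DataFrame(rows)


def visit_table(visits: Sequence[SubjectVisitPA]) -> pd.DataFrame:
    """Flatten SubjectVisitPA records into the per-visit CSV layout."""
    rows = []
    for v in visits:
        row = {"subject_id": v.subject_id, "visit": v.visit}
        for stratum in STRATA:
            for cat in CATEGORIES:
                for mode in BOUTING_MODES:
                    row[f"{stratum}_{cat}_{mode}"] = v.means[(stratum, cat, mode)]
        for mode in BOUTING_MODES:
            row[f"weekly_mvpa_{mode}"] = v.weekly_mvpa_min[mode]
            row[f"meets_guideline_{mode}"] = int(v.meets_guideline[mode])
        rows.append(row)
    return pd.DataFrame(rows)
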