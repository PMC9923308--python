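"""Classification, non-wear imputation, bout detection and PA summaries."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import helpers
from actihf import pa_metrics
from actihf.errors import IntegrityError
from actihf.types import EpochSeries, HF_LEFT, HF_RIGHT, ValidWeek

PER_DAY = 17280  # 5-s epochs per day


def _series(enmo, start="2015-06-01", nonwear=None, artifact=None):
    enmo = np.asarray(enmo, dtype=float)
    return EpochSeries(
        5.0,
        pd.Timestamp(start, tz="UTC"),
        enmo,
        np.zeros(enmo.size, bool) if artifact is None else artifact,
        np.zeros(enmo.size, bool) if nonwear is None else nonwear,
        "S0001",
        "baseline",
    )


def _week(enmo_by_day, start="2015-06-01", nonwear=None):
    enmo = np.concatenate(enmo_by_day)
    assert enmo.size == 7 * PER_DAY
    d0 = dt.date.fromisoformat(start)
    days = tuple(d0 + dt.timedelta(days=k) for k in range(7))
    return ValidWeek(
        "S0001", "baseline", days, _series(enmo, start=start, nonwear=nonwear)
    )


class TestClassify:
    @pytest.mark.parametrize(
        "enmo,thr,expected",
        [
            (10.0, "left", "inactive"),  # below the 16.7 mg left-wrist cut
            (43.6, "left", "mvpa"),  # MVPA boundary is inclusive (>= 3.0 METs)
            (30.0, "right", "light"),  # between the right-wrist cut-points
            (16.7, "left", "light"),  # inactivity boundary is exclusive
            (45.5, "right", "mvpa"),
            (18.59, "right", "inactive"),
        ],
    )
    def test_cut_point_boundaries(self, enmo, thr, expected):
        thresholds = HF_LEFT if thr == "left" else HF_RIGHT
        assert pa_metrics.classify_epoch(enmo, thresholds) == expected

    def test_wrist_relabel_changes_only_between_cut_values(self, rng):
        enmo = rng.uniform(0, 100, 5000)
        diff = pa_metrics.classify(enmo, HF_LEFT) != pa_metrics.classify(enmo, HF_RIGHT)
        between = ((enmo >= 16.7) & (enmo < 18.6)) | ((enmo >= 43.6) & (enmo < 45.5))
        assert np.array_equal(diff, between)


class TestImputeNonwear:
    def test_no_nonwear_is_identity(self, rng):
        week = _week([rng.uniform(0, 100, PER_DAY) for _ in range(7)])
        out = pa_metrics.impute_nonwear(week)
        assert np.array_equal(out.enmo, week.epochs.enmo)

    def test_block_imputed_from_other_days(self):
        days = [np.full(PER_DAY, 100.0) for _ in range(7)]
        nonwear = np.zeros(7 * PER_DAY, bool)
        # 30-min block on day 2 at 10:00
        lo = 2 * PER_DAY + 7200
        nonwear[lo : lo + 360] = True
        week = _week(days, nonwear=nonwear)
        week.epochs.enmo[lo : lo + 360] = 0.0
        out = pa_metrics.impute_nonwear(week)
        assert np.allclose(out.enmo[lo : lo + 360], 100.0)
        assert out.flagged[lo]  # flags preserved for wear-time accounting

    def test_fallback_to_zero_when_never_worn(self):
        days = [np.full(PER_DAY, 50.0) for _ in range(7)]
        nonwear = np.zeros(7 * PER_DAY, bool)
        for d in range(7):  # same clock time flagged every day
            nonwear[d * PER_DAY + 100 : d * PER_DAY + 200] = True
        week = _week(days, nonwear=nonwear)
        out = pa_metrics.impute_nonwear(week)
        assert np.allclose(out.enmo[100:200], 0.0)


def _mvpa_series(in_cat):
    """ENMO fixture: 100 mg where in-category, 5 mg elsewhere (left wrist)."""
    return np.where(np.asarray(in_cat, bool), 100.0, 5.0)


class TestDetectBouts:
    def test_strict_run_is_one_exact_bout(self):
        in_cat = np.zeros(400, bool)
        in_cat[100:220] = True  # 120 epochs = 10 min
        bouts = pa_metrics.detect_bouts(_mvpa_series(in_cat), "mvpa", HF_LEFT,
                                        epoch_length=5.0)
        assert [(b.start_epoch, b.end_epoch) for b in bouts] == [(100, 219)]
        assert bouts[0].n_in_category == 120

    def test_run_below_ten_minutes_is_no_bout(self):
        in_cat = np.zeros(400, bool)
        in_cat[100:219] = True  # 119 epochs
        assert pa_metrics.detect_bouts(_mvpa_series(in_cat), "mvpa", HF_LEFT,
                                       epoch_length=5.0) == []

    def test_four_in_one_out_pattern(self):
        pattern = np.tile([1, 1, 1, 1, 0], 30).astype(bool)  # 150 epochs
        bouts = pa_metrics.detect_bouts(_mvpa_series(pattern), "mvpa", HF_LEFT,
                                        epoch_length=5.0)
        expected = helpers.bout_oracle(pattern, 120, 0.2)
        assert [(b.start_epoch, b.end_epoch) for b in bouts] == expected
        assert len(bouts) == 1

    def test_boundary_fraction_exactly_allowed(self):
        # 96 in-category of 120 epochs is exactly the 20% allowance
        in_cat = np.ones(120, bool)
        in_cat[10:34] = False  # 24 out, interior
        bouts = pa_metrics.detect_bouts(_mvpa_series(in_cat), "mvpa", HF_LEFT,
                                        epoch_length=5.0)
        assert [(b.start_epoch, b.end_epoch) for b in bouts] == \
            helpers.bout_oracle(in_cat, 120, 0.2)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 600))
        enmo = helpers.random_intensity_fixture(rng, n, HF_LEFT)
        in_cat = pa_metrics.classify(enmo, HF_LEFT) == 2
        bouts = pa_metrics.detect_bouts(enmo, "mvpa", HF_LEFT, epoch_length=5.0)
        assert [(b.start_epoch, b.end_epoch) for b in bouts] == \
            helpers.bout_oracle(in_cat, 120, 0.2)

    def test_lowering_allowance_never_increases_bouted_minutes(self, rng):
        for _ in range(30):
            n = int(rng.integers(200, 1500))
            enmo = helpers.random_intensity_fixture(rng, n, HF_LEFT)
            totals = []
            for allowance in (0.3, 0.2, 0.1, 0.0):
                bouts = pa_metrics.detect_bouts(enmo, "mvpa", HF_LEFT,
                                                allowance=allowance,
                                                epoch_length=5.0)
                totals.append(sum(b.length for b in bouts))
            assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_raising_mvpa_cut_never_increases_unbouted_minutes(self, rng):
        from dataclasses import replace

        enmo = rng.uniform(0, 120, 5000)
        counts = []
        for cut in (40.0, 43.6, 50.0, 60.0):
            thr = replace(HF_LEFT, mvpa_cut=cut)
            counts.append(int(np.sum(pa_metrics.classify(enmo, thr) == 2)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSummariseDay:
    def _day(self, enmo):
        return _series(enmo)

    def _bouts(self, series):
        return {
            cat: pa_metrics.detect_bouts(series, cat, HF_LEFT)
            for cat in ("inactive", "light", "mvpa")
        }

    def test_uniform_inactive_day(self):
        day = self._day(np.full(PER_DAY, 5.0))
        s = pa_metrics.summarise_day(day, self._bouts(day), HF_LEFT)
        assert s.unbouted_min == {"inactive": 1440.0, "light": 0.0, "mvpa": 0.0}
        assert s.bouted_min["inactive"] == 1440.0

    def test_single_hour_mvpa_block(self):
        enmo = np.full(PER_DAY, 5.0)
        enmo[7200 : 7200 + 720] = 100.0  # 60 min at 100 mg
        day = self._day(enmo)
        s = pa_metrics.summarise_day(day, self._bouts(day), HF_LEFT)
        assert s.unbouted_min["mvpa"] == 60.0
        assert s.bouted_min["mvpa"] == 60.0

    def test_scattered_short_bursts_do_not_bout(self):
        enmo = np.full(PER_DAY, 5.0)
        for k in range(15):  # 15 x 3-min bursts = 45 min, separated by 30 min
            lo = 2000 + k * 400
            enmo[lo : lo + 36] = 100.0
        day = self._day(enmo)
        s = pa_metrics.summarise_day(day, self._bouts(day), HF_LEFT)
        assert s.unbouted_min["mvpa"] == 45.0
        assert s.bouted_min["mvpa"] == 0.0

    def test_conservation_of_unbouted_minutes(self, rng):
        day = self._day(rng.uniform(0, 120, PER_DAY))
        s = pa_metrics.summarise_day(day, self._bouts(day), HF_LEFT)
        assert sum(s.unbouted_min.values()) == pytest.approx(1440.0, abs=1e-9)

    def test_wrong_epoch_count_is_integrity_error(self):
        short = _series(np.zeros(PER_DAY - 1))
        with pytest.raises(IntegrityError, match="17280"):
            pa_metrics.summarise_day(short, {}, HF_LEFT)


def _daily(date, mvpa=0.0, light=0.0):
    inactive = 1440.0 - mvpa - light
    mins = {"inactive": inactive, "light": light, "mvpa": mvpa}
    return pa_metrics.DailySummary(
        date=date,
        day_type=pa_metrics.day_type_of(date),
        wear_min=1440.0,
        unbouted_min=dict(mins),
        bouted_min=dict(mins),
    )


class TestSummariseVisit:
    MONDAY = dt.date(2015, 6, 1)

    def _week_days(self, mvpa_by_day):
        return [
            _daily(self.MONDAY + dt.timedelta(days=k), mvpa=m)
            for k, m in enumerate(mvpa_by_day)
        ]

    def test_guideline_from_mean_mvpa(self):
        days = self._week_days([43.62] * 7)
        v = pa_metrics.summarise_visit(days)
        assert v.weekly_mvpa_min["bouted"] == pytest.approx(305.34)
        assert v.meets_guideline["bouted"]

    def test_zero_mvpa_fails_guideline(self):
        v = pa_metrics.summarise_visit(self._week_days([0.0] * 7))
        assert not v.meets_guideline["bouted"]

    def test_weekly_boundary_is_inclusive(self):
        v = pa_metrics.summarise_visit(self._week_days([150.0 / 7.0] * 7))
        assert v.weekly_mvpa_min["bouted"] == pytest.approx(150.0)
        assert v.meets_guideline["bouted"]

    def test_all_days_mean_is_weighted_day_type_mean(self):
        days = self._week_days([10, 20, 30, 40, 50, 60, 70])
        v = pa_metrics.summarise_visit(days)
        wd = v.means[("weekday", "mvpa", "bouted")]
        we = v.means[("weekend", "mvpa", "bouted")]
        assert v.means[("all_days", "mvpa", "bouted")] == pytest.approx(
            (5 * wd + 2 * we) / 7, abs=1e-9
        )

    def test_day_order_does_not_change_means(self, rng):
        mvpa = [10, 20, 30, 40, 50, 60, 70]
        days = self._week_days(mvpa)
        v1 = pa_metrics.summarise_visit(days)
        v2 = pa_metrics.summarise_visit(list(rng.permutation(days)))
        assert v1.means == v2.means

    def test_wrong_day_mix_is_integrity_error(self):
        days = [
            # six weekdays + one weekend day
            _daily(self.MONDAY + dt.timedelta(days=k)) for k in [0, 1, 2, 3, 4, 5, 7]
        ]
        with pytest.raises(IntegrityError, match="2015-06"):
            pa_metrics.summarise_visit(days)

    def test_wrong_day_count_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            pa_metrics.summarise_visit(self._week_days([0.0] * 6))


def test_summarise_week_end_to_end(rng):
    # one week: constant inactive days with a daily 30-min MVPA block
    days = []
    for _ in range(7):
        enmo = np.full(PER_DAY, 5.0)
        enmo[8000 : 8000 + 360] = 100.0
        days.append(enmo)
    week = _week(days)
    dailies, visit = pa_metrics.summarise_week(week, HF_LEFT)
    assert all(d.unbouted_min["mvpa"] == 30.0 for d in dailies)
    assert all(d.bouted_min["mvpa"] == 30.0 for d in dailies)
    assert visit.weekly_mvpa_min["bouted"] == pytest.approx(210.0)
    assert visit.meets_guideline["bouted"]
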