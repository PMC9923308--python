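"""Raw ingestion: CSV contract, autocalibration, ENMO epochs, non-wear,
valid-week selection."""

import numpy as np
import pandas as pd
import pytest

import helpers
from actihf import raw_ingest
from actihf.errors import ConfigError, FormatError, OrderingError
from actihf.types import AccelStream, EpochSeries


def _write_csv(path, rows, header_lines):
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        fh.write("timestamp,x,y,z\n")
        for row in rows:
            fh.write(",".join(str(v) for v in row) + "\n")


class TestReadRawCsv:
    def test_unit_conversion_g_to_mg(self, tmp_path):
        path = tmp_path / "s.csv"
        t0 = pd.Timestamp("2015-06-01 10:00:00")
        rows = [
            ((t0 + pd.Timedelta(seconds=k / 100)).isoformat(), 0.0, 0.0, 1.0)
            for k in range(4)
        ]
        _write_csv(path, rows, ["# units: g", "# sample_rate_hz: 100", "# wrist: left"])
        stream = raw_ingest.read_raw_csv(path, timezone="UTC")
        assert stream.n == 4
        assert np.allclose(stream.samples[:, 2], 1000.0)
        assert stream.sample_rate == 100.0

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        with open(path, "w") as fh:
            fh.write("# units: g\ntimestamp,x,y\n2015-06-01T00:00:00,0,0\n")
        with pytest.raises(FormatError, match="missing column z"):
            raw_ingest.read_raw_csv(path)

    def test_non_monotone_timestamps_rejected_with_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        rows = [
            ("2015-06-01T00:00:00", 0, 0, 1),
            ("2015-06-01T00:00:01", 0, 0, 1),
            ("2015-06-01T00:00:01", 0, 0, 1),
        ]
        _write_csv(path, rows, ["# units: g"])
        with pytest.raises(OrderingError, match="row 2"):
            raw_ingest.read_raw_csv(path)

    def test_unparseable_timestamp_rows_dropped(self, tmp_path):
        path = tmp_path / "s.csv"
        rows = [
            ("2015-06-01T00:00:00", 0, 0, 1),
            ("not-a-time", 0, 0, 1),
            ("2015-06-01T00:00:01", 0, 0, 1),
        ]
        _write_csv(path, rows, ["# units: g", "# sample_rate_hz: 1"])
        stream = raw_ingest.read_raw_csv(path, timezone="UTC")
        assert stream.n == 2

    def test_row_count_and_duration_at_20hz(self, tmp_path):
        # 86,400 samples at 20 Hz span 4,320 s = 72 min
        path = tmp_path / "long.csv"
        times = pd.date_range("2015-06-01", periods=86_400, freq="50ms")
        df = pd.DataFrame({"timestamp": times, "x": 0.0, "y": 0.0, "z": 1.0})
        with open(path, "w") as fh:
            fh.write("# units: g\n# sample_rate_hz: 20\n")
            df.to_csv(fh, index=False)
        stream = raw_ingest.read_raw_csv(path, timezone="UTC")
        assert stream.n == 86_400
        assert stream.duration_s == pytest.approx(4320.0)


class TestAutocalibrate:
    def test_identity_recovery_on_calibrated_postures(self):
        samples = helpers.stationary_postures()
        stream = AccelStream("s", "baseline", "left", 10.0,
                             pd.Timestamp("2015-06-01", tz="UTC"), samples)
        _, result = raw_ingest.autocalibrate(stream)
        assert result.applied
        assert np.allclose(result.gain, 1.0, atol=1e-6)
        assert np.allclose(result.offset, 0.0, atol=1e-6)

    def test_recovers_injected_gain_and_offset(self, rng):
        samples = helpers.stationary_postures(
            gain=(1.02, 1.0, 1.0), offset=(15.0, 0.0, 0.0), rng=rng
        )
        stream = AccelStream("s", "baseline", "left", 10.0,
                             pd.Timestamp("2015-06-01", tz="UTC"), samples)
        _, result = raw_ingest.autocalibrate(stream)
        assert result.applied
        assert result.gain[0] == pytest.approx(1.02, abs=0.005)
        assert result.offset[0] == pytest.approx(15.0, abs=3.0)
        assert result.residual_error < 5.0

    def test_white_noise_yields_no_calibration(self, rng):
        samples = rng.normal(0.0, 200.0, (6000, 3))
        stream = AccelStream("s", "baseline", "left", 10.0,
                             pd.Timestamp("2015-06-01", tz="UTC"), samples)
        out, result = raw_ingest.autocalibrate(stream)
        assert not result.applied
        assert result.n_stationary_epochs == 0
        assert out.samples is stream.samples

    def test_idempotent(self, rng):
        samples = helpers.stationary_postures(
            gain=(1.03, 0.98, 1.01), offset=(10.0, -20.0, 5.0), rng=rng
        )
        stream = AccelStream("s", "baseline", "left", 10.0,
                             pd.Timestamp("2015-06-01", tz="UTC"), samples)
        once, r1 = raw_ingest.autocalibrate(stream)
        twice, r2 = raw_ingest.autocalibrate(once)
        assert r1.applied
        assert np.allclose(r2.gain, 1.0, atol=1e-6)


class TestEnmoEpochs:
    @pytest.mark.parametrize(
        "vector,expected",
        [
            ((0.0, 0.0, 1000.0), 0.0),  # resting gravity
            ((1000.0, 1000.0, 1000.0), 1000.0 * (np.sqrt(3) - 1)),  # 732.05
            ((300.0, 400.0, 0.0), 0.0),  # norm 500, negative truncated
        ],
    )
    def test_constant_vectors(self, vector, expected):
        samples = np.tile(vector, (600, 1))
        stream = AccelStream("s", "baseline", "left", 10.0,
                             pd.Timestamp("2015-06-01", tz="UTC"), samples)
        epochs = raw_ingest.compute_enmo_epochs(stream)
        assert epochs.enmo == pytest.approx(expected, abs=1e-9)
        assert epochs.n == 12

    def test_rotation_invariance(self, rng):
        enmo = rng.uniform(0.0, 300.0, 1200)
        dirs = rng.normal(size=(1200, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        samples = dirs * (1000.0 + enmo)[:, None]
        # random rotation via QR
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        base = AccelStream("s", "baseline", "left", 10.0,
                           pd.Timestamp("2015-06-01", tz="UTC"), samples)
        rot = AccelStream("s", "baseline", "left", 10.0,
                          pd.Timestamp("2015-06-01", tz="UTC"), samples @ Q.T)
        e1 = raw_ingest.compute_enmo_epochs(base).enmo
        e2 = raw_ingest.compute_enmo_epochs(rot).enmo
        assert np.max(np.abs(e1 - e2)) < 1e-9

    def test_artifact_flag_above_norm_cut(self):
        enmo = np.zeros(240)
        enmo[130] = 7500.0  # norm 8500 > 8000
        stream = helpers.make_stream(enmo, sample_rate=10.0)
        epochs = raw_ingest.compute_enmo_epochs(stream)
        assert epochs.artifact[130 // 50]
        assert epochs.artifact.sum() == 1

    def test_epoch_alignment_to_midnight_grid(self):
        stream = helpers.make_stream(np.zeros(600), t0="2015-06-01 10:00:03")
        epochs = raw_ingest.compute_enmo_epochs(stream)
        assert epochs.start == pd.Timestamp("2015-06-01 10:00:00", tz="UTC")

    def test_bad_epoch_length_rejected(self):
        stream = helpers.make_stream(np.zeros(600))
        with pytest.raises(ConfigError):
            raw_ingest.compute_enmo_epochs(stream, epoch_length=7)


class TestNonwear:
    def test_device_on_table_flags_interior(self, rng):
        n = 3 * 3600 * 10  # 3 h at 10 Hz
        samples = np.tile((0.0, 0.0, 1000.0), (n, 1)) + rng.normal(0, 1.0, (n, 3))
        stream = AccelStream("s", "baseline", "left", 10.0,
                             pd.Timestamp("2015-06-01", tz="UTC"), samples)
        epochs = raw_ingest.compute_enmo_epochs(stream)
        flagged = raw_ingest.detect_nonwear(epochs, stream)
        # interior = [22.5 min, 180 min - 22.5 min)
        lo, hi = 270, 36 * 60 - 270
        assert flagged.nonwear[lo:hi].all()
        assert not flagged.nonwear[:lo].any()
        assert not flagged.nonwear[hi:].any()

    def test_worn_noise_never_flags(self, rng):
        n = 2 * 3600 * 10
        samples = np.tile((0.0, 0.0, 1000.0), (n, 1)) + rng.normal(0, 100.0, (n, 3))
        stream = AccelStream("s", "baseline", "left", 10.0,
                             pd.Timestamp("2015-06-01", tz="UTC"), samples)
        epochs = raw_ingest.compute_enmo_epochs(stream)
        flagged = raw_ingest.detect_nonwear(epochs, stream)
        assert flagged.nonwear.sum() == 0

    def test_single_flat_axis_is_not_nonwear(self, rng):
        # rule requires two of three axes below both cuts
        n = 2 * 3600 * 10
        samples = np.column_stack(
            [
                np.zeros(n),  # flat axis
                rng.normal(0, 40.0, n),
                1000.0 + rng.normal(0, 40.0, n),
            ]
        )
        stream = AccelStream("s", "baseline", "left", 10.0,
                             pd.Timestamp("2015-06-01", tz="UTC"), samples)
        epochs = raw_ingest.compute_enmo_epochs(stream)
        flagged = raw_ingest.detect_nonwear(epochs, stream)
        assert flagged.nonwear.sum() == 0

    def test_short_stream_produces_no_flags(self, rng, caplog):
        stream = helpers.make_stream(np.zeros(10 * 60 * 30))  # 30 min
        epochs = raw_ingest.compute_enmo_epochs(stream)
        flagged = raw_ingest.detect_nonwear(epochs, stream)
        assert flagged.nonwear.sum() == 0

    def test_matches_exhaustive_window_scan(self, rng):
        for _ in range(6):
            hours = rng.uniform(1.5, 4.0)
            n = int(hours * 3600 * 5)
            samples = np.tile((0.0, 0.0, 1000.0), (n, 1))
            t = 0
            while t < n:  # alternate still and worn segments
                seg = int(rng.uniform(10, 90) * 60 * 5)
                if rng.random() < 0.5:
                    samples[t : t + seg] += rng.normal(0, 1.0, (min(seg, n - t), 3))
                else:
                    samples[t : t + seg] += rng.normal(0, 80.0, (min(seg, n - t), 3))
                t += seg
            stream = AccelStream("s", "baseline", "left", 5.0,
                                 pd.Timestamp("2015-06-01", tz="UTC"), samples)
            epochs = raw_ingest.compute_enmo_epochs(stream)
            flagged = raw_ingest.detect_nonwear(epochs, stream)
            expected = helpers.nonwear_oracle(stream, n_epochs=epochs.n)
            assert np.array_equal(flagged.nonwear, expected)


def _week_epochs(day_nonwear_min, n_days=None, start="2015-06-01", el=5.0,
                 partial_tail_epochs=0):
    """Full-day epoch series with the given per-day non-wear minutes."""
    per_day = int(86400 / el)
    n_days = n_days or len(day_nonwear_min)
    enmo = np.full(per_day * n_days, 30.0)
    nonwear = np.zeros(per_day * n_days, dtype=bool)
    for d, minutes in enumerate(day_nonwear_min):
        k = int(minutes * 60 / el)
        nonwear[d * per_day : d * per_day + k] = True
    if partial_tail_epochs:
        enmo = np.concatenate([enmo, np.full(partial_tail_epochs, 30.0)])
        nonwear = np.concatenate([nonwear, np.zeros(partial_tail_epochs, bool)])
    return EpochSeries(el, pd.Timestamp(start, tz="UTC"), enmo,
                       np.zeros(enmo.size, bool), nonwear, "s", "baseline")


class TestValidWeek:
    def test_first_run_preferred(self):
        epochs = _week_epochs([0.0] * 8)
        week = raw_ingest.select_valid_week(epochs)
        assert week is not None
        assert week.days[0].isoformat() == "2015-06-01"
        assert week.days[-1].isoformat() == "2015-06-07"
        assert week.epochs.n == 7 * 17280

    def test_invalid_day_breaks_run(self):
        # 9 days, day 3 has 10 h non-wear (wear 14 h < 16 h) -> only 6 valid
        # days remain after it -> absent
        days = [0.0, 0.0, 600.0] + [0.0] * 6
        assert raw_ingest.select_valid_week(_week_epochs(days)) is None

    def test_wear_boundary_is_inclusive(self):
        # exactly 960 min wear per day (480 min non-wear) is still valid
        epochs = _week_epochs([480.0] * 7)
        week = raw_ingest.select_valid_week(epochs)
        assert week is not None
        # one more flagged epoch on a day drops below the boundary
        epochs.nonwear[17280 * 3 + 8000] = True
        assert raw_ingest.select_valid_week(epochs) is None

    def test_partial_days_never_valid(self):
        epochs = _week_epochs([0.0] * 7, partial_tail_epochs=500)
        week = raw_ingest.select_valid_week(epochs)
        assert week is not None and len(week.days) == 7
        # 6 full days + partial tail -> no week
        short = _week_epochs([0.0] * 6, partial_tail_epochs=500)
        assert raw_ingest.select_valid_week(short) is None

    def test_day_shift_equivariance(self):
        days = [0.0, 600.0] + [0.0] * 7
        base = _week_epochs(days, start="2015-06-01")
        shifted = _week_epochs(days, start="2015-06-04")
        w1 = raw_ingest.select_valid_week(base)
        w2 = raw_ingest.select_valid_week(shifted)
        assert (w2.days[0] - w1.days[0]).days == 3
        assert np.array_equal(w1.epochs.enmo, w2.epochs.enmo)


def test_epoch_csv_round_trip(tmp_path, rng):
    enmo = np.round(rng.uniform(0, 200, 1000), 4)
    series = EpochSeries(5.0, pd.Timestamp("2015-06-01", tz="UTC"), enmo,
                         rng.random(1000) < 0.01, rng.random(1000) < 0.05,
                         "S0001", "baseline")
    path = tmp_path / "epochs.csv"
    raw_ingest.write_epoch_csv(series, path)
    back = raw_ingest.read_epoch_csv(path)
    assert back.epoch_length == 5.0
    assert np.allclose(back.enmo, series.enmo, atol=1e-4)
    assert np.array_equal(back.nonwear, series.nonwear)
    assert back.subject_id == "S0001"
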