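"""Raw triaxial ingestion: CSV reading, autocalibration, ENMO epochs,
non-wear detection and valid-week selection.

The processing chain mirrors standard open-source raw-accelerometry
practice (GGIR-style): autocalibrate against the 1 g gravity sphere using
stationary windows, average sample-level ENMO over short epochs aligned to
the local-midnight grid, detect non-wear from per-axis range/SD over
sliding 60-min windows, then keep the first run of 7 consecutive calendar
days with at least 16 h of wear each.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import constants
from .errors import ConfigError, FormatError, OrderingError
from .types import AccelStream, CalibrationResult, EpochSeries, ValidWeek

log = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("timestamp", "x", "y", "z")


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

def _parse_header(path) -> Tuple[dict, int]:
    """Read leading ``# key: value`` metadata lines; return (meta, n_lines)."""
    meta = {}
    n = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip().lower()] = value.strip()
    return meta, n


def read_raw_csv(
    path,
    wrist: Optional[str] = None,
    timezone: Optional[str] = None,
) -> AccelStream:
    """Read a raw triaxial CSV into an :class:`AccelStream` (mg units).

    The file carries ``# key: value`` metadata lines (units, sample_rate_hz,
    wrist, timezone, subject_id, visit) followed by columns
    ``timestamp,x,y,z``.  Explicit ``wrist`` / ``timezone`` arguments
    override the header.  Rows with unparseable timestamps are rejected and
    counted; non-monotone timestamps are an error.
    """
    meta, n_meta = _parse_header(path)
    units = meta.get("units", "g").lower()
    if units not in ("g", "mg"):
        raise FormatError(f"unknown units declaration {units!r} (expected g or mg)")
    tz = timezone or meta.get("timezone", constants.TIMEZONE)
    wrist = wrist or meta.get("wrist", "left")

    df = pd.read_csv(path, skiprows=n_meta)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        log.warning("%s: rejected %d rows with unparseable timestamps", path, int(bad.sum()))
        df = df.loc[~bad]
        ts = ts.loc[~bad]
    if len(df) == 0:
        raise FormatError("no valid rows after timestamp parsing")
    if getattr(ts.dt, "tz", None) is None:
        ts = ts.dt.tz_localize(tz)
    else:
        ts = ts.dt.tz_convert(tz)

    tvals = ts.astype("int64").to_numpy()
    nonmono = np.flatnonzero(np.diff(tvals) <= 0)
    if nonmono.size:
        raise OrderingError(
            f"timestamps not strictly increasing at row {int(nonmono[0]) + 1}"
        )

    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if units == "g":
        xyz = xyz * 1000.0

    if "sample_rate_hz" in meta:
        fs = float(meta["sample_rate_hz"])
    else:
        fs = 1.0 / float(np.median(np.diff(tvals)) / 1e9)

    return AccelStream(
        subject_id=meta.get("subject_id", "unknown"),
        visit=meta.get("visit", "baseline"),
        wrist=wrist,
        sample_rate=fs,
        t0=ts.iloc[0],
        samples=xyz,
    )


def write_raw_csv(stream: AccelStream, path, units: str = "mg") -> None:
    """Write an :class:`AccelStream` in the dialect :func:`read_raw_csv` reads."""
    scale = 1.0 if units == "mg" else 1e-3
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units: {units}\n")
        fh.write(f"# sample_rate_hz: {stream.sample_rate:g}\n")
        fh.write(f"# wrist: {stream.wrist}\n")
        fh.write(f"# timezone: {stream.t0.tz}\n")
        fh.write(f"# subject_id: {stream.subject_id}\n")
        fh.write(f"# visit: {stream.visit}\n")
        fh.write("timestamp,x,y,z\n")
        times = stream.timestamps()
        vals = stream.samples * scale
        for t, (x, y, z) in zip(times, vals):
            fh.write(f"{t.isoformat()},{x:.6f},{y:.6f},{z:.6f}\n")


def write_epoch_csv(series: EpochSeries, path) -> None:
    """Write the epoch-level CSV (enmo to 4 decimal places, 0/1 flags).

    Timestamps are ISO-8601 local wall-clock with the UTC offset of the
    first epoch (fixed-offset zones assumed for epoch data).
    """
    times = series.times()
    naive = times.tz_localize(None).values.astype("datetime64[s]").astype(str)
    offset = times[0].strftime("%z")
    offset = offset[:3] + ":" + offset[3:] if offset else ""
    df = pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "visit": series.visit,
            "epoch_start": np.char.add(naive, offset),
            "enmo_mg": np.round(series.enmo, 4),
            "artifact": series.artifact.astype(int),
            "nonwear": series.nonwear.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.4f")


def read_epoch_csv(path) -> EpochSeries:
    df = pd.read_csv(path)
    for col in ("epoch_start", "enmo_mg", "artifact", "nonwear"):
        if col not in df.columns:
            raise FormatError(f"missing column {col}")
    times = pd.to_datetime(df["epoch_start"], format="ISO8601")
    if len(times) < 2:
        raise FormatError("epoch CSV must contain at least two epochs")
    el = (times.iloc[1] - times.iloc[0]).total_seconds()
    return EpochSeries(
        epoch_length=el,
        start=times.iloc[0],
        enmo=df["enmo_mg"].to_numpy(dtype=float),
        artifact=df["artifact"].to_numpy(dtype=bool),
        nonwear=df["nonwear"].to_numpy(dtype=bool),
        subject_id=str(df["subject_id"].iloc[0]) if "subject_id" in df else "",
        visit=str(df["visit"].iloc[0]) if "visit" in df else "",
    )


# ---------------------------------------------------------------------------
# Autocalibration
# ---------------------------------------------------------------------------

def autocalibrate(
    stream: AccelStream,
    stationary_sd_cut: float = constants.CALIBRATION_SD_CUT_MG,
    window_seconds: float = constants.CALIBRATION_WINDOW_SECONDS,
    min_windows: int = constants.CALIBRATION_MIN_WINDOWS,
    min_octants: int = constants.CALIBRATION_MIN_OCTANTS,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> Tuple[AccelStream, CalibrationResult]:
    """Fit per-axis gain/offset so stationary vectors sit on the 1 g sphere.

    Stationary 10-s windows (all three axis SDs below ``stationary_sd_cut``)
    provide calibration points; if at least ``min_windows`` of them span at
    least ``min_octants`` orientation octants, gains and offsets are fitted
    by iterative per-axis least squares toward the closest point on the
    1000 mg sphere.  Otherwise the stream is returned unmodified with
    ``applied=False``.
    """
    w = max(1, int(round(window_seconds * stream.sample_rate)))
    nwin = stream.n // w
    identity = CalibrationResult(
        gain=np.ones(3), offset=np.zeros(3), n_stationary_epochs=0,
        residual_error=float("nan"), applied=False,
    )
    if nwin == 0:
        log.warning("stream too short for calibration windows; calibration skipped")
        return stream, identity

    blocks = stream.samples[: nwin * w].reshape(nwin, w, 3)
    sds = blocks.std(axis=1, ddof=0)
    means = blocks.mean(axis=1)
    stationary = np.all(sds < stationary_sd_cut, axis=1)
    pts = means[stationary]
    identity.n_stationary_epochs = int(stationary.sum())

    if len(pts) < min_windows:
        log.warning(
            "only %d stationary windows (< %d); calibration not applied",
            len(pts), min_windows,
        )
        return stream, identity
    octants = np.unique((pts >= 0).astype(int), axis=0).shape[0]
    if octants < min_octants:
        log.warning(
            "stationary windows span %d octants (< %d); calibration not applied",
            octants, min_octants,
        )
        return stream, identity

    gain = np.ones(3)
    offset = np.zeros(3)
    for _ in range(max_iter):
        cal = pts * gain + offset
        norms = np.linalg.norm(cal, axis=1)
        norms[norms == 0] = 1.0
        target = cal / norms[:, None] * 1000.0
        step_gain = np.empty(3)
        step_off = np.empty(3)
        for a in range(3):
            A = np.column_stack([np.ones(len(cal)), cal[:, a]])
            (c0, c1), *_ = np.linalg.lstsq(A, target[:, a], rcond=None)
            step_off[a], step_gain[a] = c0, c1
        gain = gain * step_gain
        offset = offset * step_gain + step_off
        if np.max(np.abs(step_gain - 1.0)) < tol and np.max(np.abs(step_off)) < tol * 1000:
            break

    cal = pts * gain + offset
    residual = float(np.mean(np.abs(np.linalg.norm(cal, axis=1) - 1000.0)))

    g_lo, g_hi = constants.CALIBRATION_GAIN_RANGE
    o_lo, o_hi = constants.CALIBRATION_OFFSET_RANGE_MG
    if np.any(gain < g_lo) or np.any(gain > g_hi) or np.any(offset < o_lo) or np.any(offset > o_hi):
        log.warning(
            "calibration outside plausible range (gain %s, offset %s mg); not applied",
            np.round(gain, 4), np.round(offset, 2),
        )
        identity.residual_error = residual
        return stream, identity

    result = CalibrationResult(
        gain=gain,
        offset=offset,
        n_stationary_epochs=int(stationary.sum()),
        residual_error=residual,
        applied=True,
    )
    calibrated = replace(stream, samples=stream.samples * gain + offset)
    return calibrated, result


# ---------------------------------------------------------------------------
# ENMO epochs
# ---------------------------------------------------------------------------

def compute_enmo_epochs(
    stream: AccelStream,
    epoch_length: float = constants.EPOCH_SECONDS,
    artifact_norm_cut: float = constants.ARTIFACT_NORM_CUT_MG,
) -> EpochSeries:
    """Average sample-level ENMO over epochs aligned to local midnight.

    Per sample, ENMO = max(0, sqrt(x^2 + y^2 + z^2) - 1000) mg; the epoch
    value is the mean over its samples.  Any sample with vector norm above
    ``artifact_norm_cut`` flags its epoch as artifact, as do epochs with no
    samples at all.
    """
    if 60 % epoch_length != 0:
        raise ConfigError(f"epoch_length {epoch_length} s must divide 60 s")

    offs = stream.sample_offsets()
    idx = np.floor(offs / epoch_length).astype(np.int64)
    i0 = int(idx[0])
    rel = idx - i0
    nep = int(rel[-1]) + 1

    norm = np.linalg.norm(stream.samples, axis=1)
    enmo_s = np.clip(norm - 1000.0, 0.0, None)

    counts = np.bincount(rel, minlength=nep)
    sums = np.bincount(rel, weights=enmo_s, minlength=nep)
    artifact = np.bincount(rel, weights=(norm > artifact_norm_cut).astype(float),
                           minlength=nep) > 0
    empty = counts == 0
    enmo = np.where(empty, 0.0, sums / np.maximum(counts, 1))
    artifact = artifact | empty

    start = stream.t0.normalize() + pd.Timedelta(seconds=i0 * epoch_length)
    return EpochSeries(
        epoch_length=float(epoch_length),
        start=start,
        enmo=enmo,
        artifact=artifact,
        nonwear=np.zeros(nep, dtype=bool),
        subject_id=stream.subject_id,
        visit=stream.visit,
    )


# ---------------------------------------------------------------------------
# Non-wear detection
# ---------------------------------------------------------------------------

def detect_nonwear(
    epochs: EpochSeries,
    raw: AccelStream,
    window_min: float = constants.NONWEAR_WINDOW_MIN,
    step_min: float = constants.NONWEAR_STEP_MIN,
    range_cut_mg: float = constants.NONWEAR_RANGE_CUT_MG,
    sd_cut_mg: float = constants.NONWEAR_SD_CUT_MG,
    axes_required: int = constants.NONWEAR_AXES_REQUIRED,
) -> EpochSeries:
    """Flag non-wear epochs from per-axis range and SD of the raw signal.

    A 60-min window slides in 15-min steps on the midnight-anchored grid;
    whenever at least ``axes_required`` of the three axes have range below
    ``range_cut_mg`` *and* SD below ``sd_cut_mg`` within the window, the
    central 15 min of that window are marked non-wear.  The union of marked
    blocks sets ``nonwear_flag``.  Streams shorter than one window produce
    no flags.
    """
    nonwear = epochs.nonwear.copy()
    out = replace(epochs, nonwear=nonwear)

    step_s = step_min * 60.0
    win_s = window_min * 60.0
    if raw.duration_s < win_s:
        log.warning("stream shorter than %g min; no non-wear windows evaluated", window_min)
        return out

    offs = raw.sample_offsets()
    block = np.floor(offs / step_s).astype(np.int64)
    b0 = int(block[0])
    rel = block - b0
    nb = int(rel[-1]) + 1

    counts = np.bincount(rel, minlength=nb)
    sums = np.stack(
        [np.bincount(rel, weights=raw.samples[:, a], minlength=nb) for a in range(3)],
        axis=1,
    )
    sqs = np.stack(
        [np.bincount(rel, weights=raw.samples[:, a] ** 2, minlength=nb) for a in range(3)],
        axis=1,
    )
    # contiguous sampling: every interior block is non-empty, so reduceat
    # segments line up with block boundaries
    first_idx = np.searchsorted(rel, np.arange(nb))
    mins = np.minimum.reduceat(raw.samples, first_idx, axis=0)
    maxs = np.maximum.reduceat(raw.samples, first_idx, axis=0)

    expected = int(np.floor(step_s * raw.sample_rate))
    complete = counts >= expected
    bpw = int(round(win_s / step_s))

    el = epochs.epoch_length
    ep_start_off = epochs.start_offset_s()
    centre_lead = (win_s - step_s) / 2.0  # 22.5 min for the 60/15 rule

    for j in range(nb - bpw + 1):
        if not complete[j : j + bpw].all():
            continue
        n = counts[j : j + bpw].sum()
        s = sums[j : j + bpw].sum(axis=0)
        ss = sqs[j : j + bpw].sum(axis=0)
        var = (ss - s * s / n) / (n - 1)
        sd = np.sqrt(np.clip(var, 0.0, None))
        rng = maxs[j : j + bpw].max(axis=0) - mins[j : j + bpw].min(axis=0)
        if int(np.sum((rng < range_cut_mg) & (sd < sd_cut_mg))) >= axes_required:
            wstart = (b0 + j) * step_s
            c0 = wstart + centre_lead
            c1 = c0 + step_s
            e0 = int(np.ceil((c0 - ep_start_off) / el - 1e-9))
            e1 = int(np.ceil((c1 - ep_start_off) / el - 1e-9))
            nonwear[max(e0, 0) : max(min(e1, epochs.n), 0)] = True

    return out


# ---------------------------------------------------------------------------
# Valid-week selection
# ---------------------------------------------------------------------------

def select_valid_week(
    epochs: EpochSeries,
    valid_day_hours: float = constants.VALID_DAY_HOURS,
) -> Optional[ValidWeek]:
    """Return the earliest run of 7 consecutive valid calendar days, if any.

    A day is valid iff it is fully covered by epochs and its wear time
    (epochs neither non-wear nor artifact) is at least ``valid_day_hours``.
    Partial first/last days are never valid.  ``None`` is a normal outcome;
    the caller excludes the subject-visit.
    """
    el = epochs.epoch_length
    per_day = int(round(86400.0 / el))
    abs_idx = int(round(epochs.start_offset_s() / el)) + np.arange(epochs.n)
    day = abs_idx // per_day
    d0 = int(day[0])
    rel_day = day - d0
    ndays = int(rel_day[-1]) + 1

    counts = np.bincount(rel_day, minlength=ndays)
    wear = np.bincount(rel_day, weights=(~epochs.flagged).astype(float), minlength=ndays)
    need = valid_day_hours * 3600.0 / el
    valid = (counts == per_day) & (wear >= need - 1e-9)

    run = 0
    start_day = None
    for d in range(ndays):
        run = run + 1 if valid[d] else 0
        if run == 7:
            start_day = d - 6
            break
    if start_day is None:
        return None

    i0 = int(np.searchsorted(rel_day, start_day))
    i1 = int(np.searchsorted(rel_day, start_day + 7))
    # day indices count from the first day's midnight, so day k's date is
    # first_midnight + (d0 + start_day + k) days
    first_midnight = epochs.start.normalize()
    dates = tuple(
        (first_midnight + pd.Timedelta(days=d0 + start_day + k)).date() for k in range(7)
    )
    return ValidWeek(
        subject_id=epochs.subject_id,
        visit=epochs.visit,
        days=dates,
        epochs=epochs.slice(i0, i1),
    )


def process_stream(
    stream: AccelStream,
    epoch_length: float = constants.EPOCH_SECONDS,
    calibrate: bool = True,
    **nonwear_kwargs,
) -> Tuple[EpochSeries, Optional[CalibrationResult]]:
    """Convenience chain: autocalibrate -> ENMO epochs -> non-wear flags."""
    cal_result = None
    if calibrate:
        stream, cal_result = autocalibrate(stream)
    epochs = compute_enmo_epochs(stream, epoch_length=epoch_length)
    epochs = detect_nonwear(epochs, stream, **nonwear_kwargs)
    return epochs, cal_result
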