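"""Shared fixtures-by-construction and independent brute-force oracles.

The oracles deliberately re-derive each quantity by direct enumeration over
the raw definitions (all index pairs, every sliding window, the closed-form
two-group ANCOVA estimator) so they share no code path with the package.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd

from actihf.types import AccelStream, ThresholdSet


def make_stream(
    enmo_mg: np.ndarray,
    sample_rate: float = 10.0,
    t0: str = "2015-06-01 00:00:00",
    tz: str = "UTC",
    direction=(0.0, 0.0, 1.0),
    subject_id: str = "T001",
    visit: str = "baseline",
    wrist: str = "left",
) -> AccelStream:
    """Stream whose per-sample vector norm is 1000 + the given ENMO values."""
    enmo_mg = np.asarray(enmo_mg, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    samples = np.outer(1000.0 + enmo_mg, d)
    return AccelStream(
        subject_id=subject_id,
        visit=visit,
        wrist=wrist,
        sample_rate=sample_rate,
        t0=pd.Timestamp(t0, tz=tz),
        samples=samples,
    )


def stationary_postures(
    n_postures: int = 40,
    window_samples: int = 100,
    gain=(1.0, 1.0, 1.0),
    offset=(0.0, 0.0, 0.0),
    rng=None,
) -> np.ndarray:
    """Still postures spanning all 8 octants, optionally mis-calibrated.

    Orientations are the 8 octant diagonals plus random unit vectors (from a
    fixed internal seed), giving enough orientation diversity to identify
    per-axis gains.  Returns raw (measured) samples such that
    measured * gain + offset lies on the 1000 mg sphere:
    measured = (true - offset) / gain.
    """
    dirs = []
    for sx in (1, -1):
        for sy in (1, -1):
            for sz in (1, -1):
                v = np.array([sx, sy, sz], dtype=float)
                dirs.append(v / np.linalg.norm(v))
    extra = np.random.default_rng(1234).normal(size=(max(n_postures - 8, 0), 3))
    extra /= np.linalg.norm(extra, axis=1, keepdims=True)
    dirs = np.concatenate([np.array(dirs), extra], axis=0)
    parts = []
    for d in dirs:
        true = np.tile(d * 1000.0, (window_samples, 1))
        if rng is not None:
            true = true + rng.normal(0, 0.5, true.shape)
        measured = (true - np.asarray(offset)) / np.asarray(gain)
        parts.append(measured)
    return np.concatenate(parts, axis=0)


# ---------------------------------------------------------------------------
# bout oracle: full pairwise enumeration + greedy leftmost-longest selection
# ---------------------------------------------------------------------------

def bout_oracle(in_cat: np.ndarray, min_len: int, allowance: float) -> List[Tuple[int, int]]:
    """Enumerate all candidate intervals (i, j) with both endpoints
    in-category, length >= min_len and in-category fraction >= 1 - allowance;
    greedily accept the leftmost candidate (longest end on ties), never
    reusing epochs."""
    in_cat = np.asarray(in_cat, dtype=bool)
    n = in_cat.size
    q = 1.0 - allowance
    P = np.concatenate(([0], np.cumsum(in_cat)))
    idx = np.arange(n)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    length = jj - ii + 1
    counts = P[jj + 1] - P[ii]
    valid = (
        in_cat[:, None]
        & in_cat[None, :]
        & (length >= min_len)
        & (counts >= q * length - 1e-9)
    )
    accepted = []
    lo = 0
    while True:
        rows = np.flatnonzero(valid[lo:, :].any(axis=1))
        if rows.size == 0:
            break
        i = lo + int(rows[0])
        j = int(np.flatnonzero(valid[i])[-1])
        accepted.append((i, j))
        lo = j + 1
        valid[:, : j + 1] = False
        valid[: j + 1, :] = False
    return accepted


# ---------------------------------------------------------------------------
# non-wear oracle: direct evaluation of every sliding window
# ---------------------------------------------------------------------------

def nonwear_oracle(
    stream: AccelStream,
    epoch_length: float = 5.0,
    n_epochs: int | None = None,
    window_min: float = 60.0,
    step_min: float = 15.0,
    range_cut: float = 50.0,
    sd_cut: float = 13.0,
    axes_required: int = 2,
) -> np.ndarray:
    """Exhaustive window scan: per 15-min grid start, slice the raw samples,
    compute per-axis range/SD directly, mark the central 15 min."""
    offs = stream.sample_offsets()
    if n_epochs is None:
        ep_idx = np.floor(offs / epoch_length).astype(int)
        e0 = int(ep_idx[0])
        n_epochs = int(ep_idx[-1]) - e0 + 1
    else:
        e0 = int(np.floor(offs[0] / epoch_length))
    flags = np.zeros(n_epochs, dtype=bool)
    step_s, win_s = step_min * 60.0, window_min * 60.0
    first_block = int(np.ceil(offs[0] / step_s - 1e-9))
    wstart = first_block * step_s
    while wstart + win_s <= offs[-1] + 1.0 / stream.sample_rate + 1e-9:
        sel = (offs >= wstart) & (offs < wstart + win_s)
        if sel.sum() >= int(np.floor(win_s * stream.sample_rate)):
            seg = stream.samples[sel]
            ok = 0
            for a in range(3):
                rng_a = seg[:, a].max() - seg[:, a].min()
                sd_a = seg[:, a].std(ddof=1)
                if rng_a < range_cut and sd_a < sd_cut:
                    ok += 1
            if ok >= axes_required:
                c0 = wstart + (win_s - step_s) / 2.0
                lo = int(np.ceil((c0 - e0 * epoch_length) / epoch_length - 1e-9))
                hi = int(np.ceil((c0 + step_s - e0 * epoch_length) / epoch_length - 1e-9))
                flags[max(lo, 0) : max(min(hi, n_epochs), 0)] = True
        wstart += step_s
    return flags


# ---------------------------------------------------------------------------
# closed-form two-group ANCOVA estimator
# ---------------------------------------------------------------------------

def ancova_closed_form(base: np.ndarray, follow: np.ndarray, group: np.ndarray) -> float:
    """Difference in follow-up means minus pooled within-group slope times
    difference in baseline means (intervention minus control)."""
    group = np.asarray(group, dtype=bool)
    num = 0.0
    den = 0.0
    for sel in (group, ~group):
        xb, yb = base[sel], follow[sel]
        num += np.sum((xb - xb.mean()) * (yb - yb.mean()))
        den += np.sum((xb - xb.mean()) ** 2)
    slope = num / den
    return (follow[group].mean() - follow[~group].mean()) - slope * (
        base[group].mean() - base[~group].mean()
    )


def random_intensity_fixture(rng: np.random.Generator, n: int,
                             thresholds: ThresholdSet) -> np.ndarray:
    """Markov-persistent ENMO series mixing the three intensity bands."""
    levels = np.array(
        [
            thresholds.inactivity_cut * 0.4,
            (thresholds.inactivity_cut + thresholds.mvpa_cut) / 2.0,
            thresholds.mvpa_cut * 1.8,
        ]
    )
    stay = rng.uniform(0.7, 0.97)
    draws = rng.integers(0, 3, n)
    switch = rng.random(n) > stay
    switch[0] = True
    # forward-fill the state drawn at the most recent switch point
    anchor = np.where(switch, np.arange(n), 0)
    anchor = np.maximum.accumulate(anchor)
    state = draws[anchor]
    return levels[state] * rng.uniform(0.8, 1.2, n)
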