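"""Synthetic two-arm accelerometer trial generator.

Three generation fidelities share one ground-truth ledger:

* ``plan`` — per-day intended minutes in each behaviour state, vectorised;
  fast enough for replicate-based statistical studies.
* ``epoch`` — 5-s ENMO epoch series built from per-day behaviour schedules
  (sleep window, sedentary filler, light blocks, MVPA sessions and short
  bursts, optional non-wear blocks); exercises the metrics pipeline.
* ``raw`` — triaxial samples at a configurable rate whose vector norm is
  1000 mg + the scheduled ENMO level, with a slow orientation random walk
  during wear and a frozen orientation during non-wear; exercises
  calibration, ENMO epoching and non-wear detection.

Activity volumes are right-skewed (lognormal), matched in mean and SD to
the reference arm-level summaries; baseline and follow-up share a subject
latent with correlation ``rho``.  Outcome-level simulators
(:func:`simulate_ancova_cohort` and friends) support large replicate
studies of the estimators without signal-level generation.
"""

from __future__ import annotations

import copy
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import presets
from .errors import ScenarioError
from .types import AccelStream, EpochSeries, ThresholdSet, HF_LEFT, HF_RIGHT

STATE_CATEGORY = {
    "sleep": "inactive",
    "sedentary": "inactive",
    "light": "light",
    "mvpa": "mvpa",
}

#: Default ENMO level (mean, SD) in mg per behaviour state.  Means sit
#: safely inside their intensity band for both wrists' cut-points.
DEFAULT_STATE_LEVELS = {
    "sleep": (3.0, 1.5),
    "sedentary": (8.0, 4.0),
    "light": (28.0, 5.0),
    "mvpa": (85.0, 18.0),
}

_VISIT_START = {
    # Mondays, so the first 7 generated days are Mon..Sun (5 + 2)
    "baseline": dt.date(2015, 6, 1),
    "post_intervention": dt.date(2015, 9, 28),
    "final_followup": dt.date(2016, 5, 30),
}


def validate_state_levels(levels: Dict[str, Tuple[float, float]],
                          thresholds: ThresholdSet) -> None:
    """Each state's mean ENMO must lie inside its intensity band."""
    for state, (mean, sd) in levels.items():
        cat = STATE_CATEGORY[state]
        if sd < 0:
            raise ScenarioError(f"state {state}: negative SD")
        if cat == "inactive" and not mean < thresholds.inactivity_cut:
            raise ScenarioError(
                f"state {state}: level {mean} mg not below the "
                f"inactivity cut {thresholds.inactivity_cut} mg"
            )
        if cat == "light" and not (
            thresholds.inactivity_cut <= mean < thresholds.mvpa_cut
        ):
            raise ScenarioError(
                f"state {state}: level {mean} mg not between the cut-points"
            )
        if cat == "mvpa" and not mean >= thresholds.mvpa_cut:
            raise ScenarioError(
                f"state {state}: level {mean} mg below the MVPA cut "
                f"{thresholds.mvpa_cut} mg"
            )


def _lognormal(rng_or_z, mean: float, sd: float, size=None) -> np.ndarray:
    """Lognormal draws matched to a target mean and SD.

    ``rng_or_z`` is either a Generator (fresh draws) or an array of standard
    normal latents (for correlated draws).  ``sd = 0`` degenerates to the
    constant mean.
    """
    if sd == 0:
        z = 0.0 if not isinstance(rng_or_z, np.ndarray) else np.zeros_like(rng_or_z)
        return np.full(size, mean) if size is not None else mean + z
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    if isinstance(rng_or_z, np.ndarray):
        z = rng_or_z
    else:
        z = rng_or_z.standard_normal(size)
    return np.exp(mu + np.sqrt(sigma2) * z)


# ---------------------------------------------------------------------------
# day-level signal generation
# ---------------------------------------------------------------------------

def generate_day_signal(
    plan: Sequence[Tuple[str, float]],
    thresholds: ThresholdSet,
    rng: np.random.Generator,
    state_levels: Optional[Dict[str, Tuple[float, float]]] = None,
    epoch_length: float = 5.0,
    mode: str = "epoch",
    sample_rate: float = 10.0,
    start: Optional[pd.Timestamp] = None,
    subject_id: str = "",
    visit: str = "baseline",
):
    """Generate one day of signal from a behaviour plan.

    ``plan`` is an ordered list of ``(state, minutes)`` blocks with state in
    {sleep, sedentary, light, mvpa, nonwear}; durations must be whole
    minutes summing to at most 1440 (the remainder is padded with
    sedentary).  Returns ``(signal, ledger)`` where the signal is an
    :class:`EpochSeries` (epoch mode) or :class:`AccelStream` (raw mode) and
    the ledger records the intended minutes per category plus the minutes
    scheduled in MVPA blocks of at least 10 min.
    """
    levels = dict(DEFAULT_STATE_LEVELS)
    if state_levels:
        levels.update(state_levels)
    validate_state_levels(levels, thresholds)

    total = sum(m for _, m in plan)
    if total > 1440 + 1e-9:
        raise ScenarioError(f"plan durations sum to {total} min > 1440")
    plan = list(plan)
    if total < 1440:
        plan.append(("sedentary", 1440 - total))

    ledger = {"inactive": 0.0, "light": 0.0, "mvpa": 0.0, "nonwear": 0.0,
              "mvpa_bouted": 0.0}
    for state, minutes in plan:
        if minutes < 0 or abs(minutes - round(minutes)) > 1e-9:
            raise ScenarioError(f"block ({state}, {minutes}): whole minutes required")
        if state == "nonwear":
            ledger["nonwear"] += minutes
        else:
            ledger[STATE_CATEGORY[state]] += minutes
            if state == "mvpa" and minutes >= 10:
                ledger["mvpa_bouted"] += minutes

    eppm = int(round(60.0 / epoch_length))
    enmo_parts: List[np.ndarray] = []
    nonwear_parts: List[np.ndarray] = []
    for state, minutes in plan:
        n_ep = int(round(minutes)) * eppm
        if state == "nonwear":
            enmo_parts.append(np.zeros(n_ep))
            nonwear_parts.append(np.ones(n_ep, dtype=bool))
        else:
            mean, sd = levels[state]
            enmo_parts.append(np.asarray(_lognormal(rng, mean, sd, n_ep), dtype=float))
            nonwear_parts.append(np.zeros(n_ep, dtype=bool))
    enmo = np.concatenate(enmo_parts)
    nonwear = np.concatenate(nonwear_parts)

    if start is None:
        start = pd.Timestamp("2015-06-01", tz="UTC")
    start = start.normalize()

    if mode == "epoch":
        series = EpochSeries(
            epoch_length=epoch_length,
            start=start,
            enmo=enmo,
            artifact=np.zeros(enmo.size, dtype=bool),
            nonwear=nonwear,
            subject_id=subject_id,
            visit=visit,
        )
        return series, ledger

    if mode != "raw":
        raise ScenarioError(f"unknown generation mode {mode!r}")

    spe = int(round(epoch_length * sample_rate))  # samples per epoch
    n = enmo.size * spe
    norm = 1000.0 + np.repeat(enmo, spe)
    # slow orientation random walk while worn; frozen while off-body
    worn = ~np.repeat(nonwear, spe)
    dth = np.where(worn, rng.normal(0.0, 0.004, n), 0.0)
    dph = np.where(worn, rng.normal(0.0, 0.004, n), 0.0)
    theta = 1.0 + np.cumsum(dth)
    phi = 0.5 + np.cumsum(dph)
    dirs = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    stream = AccelStream(
        subject_id=subject_id,
        visit=visit,
        wrist=thresholds.wrist,
        sample_rate=sample_rate,
        t0=start,
        samples=dirs * norm[:, None],
    )
    return stream, ledger


def build_day_schedule(
    mvpa_bouted: float,
    mvpa_extra: float,
    light_bouted: float,
    light_extra: float,
    rng: np.random.Generator,
    sleep_min: int = 480,
    nonwear_min: int = 0,
) -> List[Tuple[str, int]]:
    """Turn daily minute targets into an ordered behaviour plan.

    MVPA is scheduled in 10-30-min sessions (bouted) plus 3-min bursts
    (too short to count as bouts); light activity in 15-40-min blocks plus
    5-min bursts.  Sleep wraps the day (midnight block plus late-evening
    block) and sedentary time fills the gaps.  Sub-10-min bouted residue is
    promoted to a 10-min session or dropped with probability matching its
    size, keeping the expected total unbiased.
    """
    def _chunks(total: float, lo: int, hi: int) -> List[int]:
        total = max(0.0, float(total))
        out = []
        whole = int(total)
        frac = total - whole
        if rng.random() < frac:
            whole += 1
        while whole >= lo:
            size = int(rng.integers(lo, min(hi, whole) + 1))
            if whole - size < lo and whole <= hi:
                size = whole
            out.append(size)
            whole -= size
        if whole > 0:
            # residue below the minimum block size: promote or drop
            if rng.random() < whole / lo:
                out.append(lo)
        return out

    blocks: List[Tuple[str, int]] = []
    blocks += [("mvpa", c) for c in _chunks(mvpa_bouted, 10, 30)]
    blocks += [("mvpa", 3) for _ in range(int(round(mvpa_extra / 3.0)))]
    blocks += [("light", c) for c in _chunks(light_bouted, 15, 40)]
    blocks += [("light", 5) for _ in range(int(round(light_extra / 5.0)))]
    if nonwear_min > 0:
        blocks.append(("nonwear", int(nonwear_min)))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    sleep_late = 60
    sleep_early = int(sleep_min) - sleep_late
    wake = 1440 - int(sleep_min)
    activity = sum(m for _, m in blocks)
    if activity > wake - len(blocks):  # need at least 1-min gaps
        raise ScenarioError(
            f"daily plan infeasible: {activity} active min exceed the "
            f"{wake}-min wake window"
        )
    filler = wake - activity
    gaps = len(blocks) + 1
    base_gap, rem = divmod(filler, gaps)
    plan: List[Tuple[str, int]] = [("sleep", sleep_early)]
    for k, blk in enumerate(blocks):
        gap = base_gap + (1 if k < rem else 0)
        if gap:
            plan.append(("sedentary", gap))
        plan.append(blk)
    last_gap = base_gap + (1 if len(blocks) < rem else 0)
    if len(blocks) == 0:
        last_gap = filler
    if last_gap:
        plan.append(("sedentary", last_gap))
    plan.append(("sleep", sleep_late))
    return [(s, m) for s, m in plan if m > 0]


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Everything the trial generator needs; presets freeze the defaults."""

    name: str = "custom"
    seed: int = 0
    n_per_arm: Tuple[int, int] = (
        presets.ARM_N_ENROLLED["intervention"],
        presets.ARM_N_ENROLLED["control"],
    )
    wrist_left_prob: float = 0.5
    days_per_visit: int = 9
    visits: Tuple[str, ...] = ("baseline", "post_intervention", "final_followup")
    #: retention probability per visit (participant flow 247 -> 198 -> 173)
    retention: Tuple[float, ...] = (
        1.0,
        presets.TRIAL_FLOW["post_intervention"] / presets.TRIAL_FLOW["baseline"],
        presets.TRIAL_FLOW["final_followup"] / presets.TRIAL_FLOW["baseline"],
    )
    rho: float = 0.5  # baseline-follow-up latent correlation
    sleep_min: int = 480
    state_levels: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STATE_LEVELS)
    )
    pa_summary: Dict = field(default_factory=lambda: copy.deepcopy(presets.PA_SUMMARY))
    equal_arms: bool = False  # both arms drawn from the control rows
    mvpa_day_cv: float = 0.35  # day-to-day lognormal CV around the subject target
    light_day_cv: float = 0.20
    mvpa_extra_frac: float = 0.35  # short-burst MVPA relative to bouted target
    light_extra_frac: float = 0.20
    nonwear_per_day: float = 0.0  # probability of one non-wear block per day
    nonwear_duration_min: Tuple[int, int] = (30, 120)
    covariate_effects: Dict[str, float] = field(default_factory=dict)
    covariate_resid_sd: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.wrist_left_prob, self.nonwear_per_day, *self.retention):
            if not 0.0 <= p <= 1.0:
                raise ScenarioError(f"probability {p} outside [0, 1]")
        if not 0.0 <= self.rho <= 1.0:
            raise ScenarioError("rho must be in [0, 1]")
        if self.days_per_visit < 7:
            raise ScenarioError("need at least 7 days per visit")
        if len(self.retention) != len(self.visits):
            raise ScenarioError("retention must match visits")
        if not 0 < self.sleep_min < 1440:
            raise ScenarioError("sleep_min must be in (0, 1440)")


def scenario_preset(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named frozen scenarios.

    ``table2`` — arms parameterised from the reference arm-level PA
    summaries (the default scenario).  ``table3`` — equal arms whose MVPA
    change is driven by the reference combined predictor-model
    coefficients.
    """
    if name == "table2":
        cfg = ScenarioConfig(name=name, seed=seed)
    elif name == "table3":
        cfg = ScenarioConfig(
            name=name,
            seed=seed,
            equal_arms=True,
            covariate_effects=dict(presets.PREDICTOR_MODEL3),
            covariate_resid_sd=54.0,
        )
    else:
        raise ScenarioError(f"unknown scenario preset {name!r}")
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ScenarioError(f"unknown scenario field {key!r}")
        setattr(cfg, key, value)
    cfg.__post_init__()
    return cfg


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

_CENTRE_SORTED = tuple(sorted(presets.CENTRES))


def _generate_subjects(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_i, n_c = cfg.n_per_arm
    n = n_i + n_c
    group = np.array(["intervention"] * n_i + ["control"] * n_c)
    cov = presets.COVARIATE_SUMMARY
    prev = presets.COVARIATE_PREVALENCE
    age = np.clip(rng.normal(*cov["age"], n), 20, 100)
    iswt = np.clip(rng.normal(*cov["iswt"], n), 0, None)
    hads_anx = np.clip(rng.normal(*cov["hads_anxiety"], n), 0, 21)
    hads_dep = np.clip(rng.normal(*cov["hads_depression"], n), 0, 21)
    schfi = np.clip(rng.normal(*cov["schfi_maintenance"], n), 0, 100)
    ntprobnp = _lognormal(rng, 1300.0, 1700.0, n)
    return pd.DataFrame(
        {
            "subject_id": [f"S{k:04d}" for k in range(1, n + 1)],
            "group": group,
            "centre": rng.choice(_CENTRE_SORTED, n),
            "bnp2000": ntprobnp > 2000.0,
            "wrist": np.where(rng.random(n) < cfg.wrist_left_prob, "left", "right"),
            "age": age,
            "female": rng.random(n) < prev["female"],
            "iswt": iswt,
            "hads_anxiety": hads_anx,
            "hads_depression": hads_dep,
            "schfi_maintenance": schfi,
            "diabetes": rng.random(n) < prev["diabetes"],
            "live_with_parent": rng.random(n) < prev["live_with_parent"],
            "live_with_child_over_18": rng.random(n) < prev["live_with_child_over_18"],
        }
    )


def _covariate_delta(cfg: ScenarioConfig, subjects: pd.DataFrame,
                     baseline_allday_mvpa: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-subject MVPA change (min/day) implied by the covariate model."""
    eff = cfg.covariate_effects
    n = len(subjects)
    delta = np.full(n, float(eff.get("const", 0.0)))
    for name, coef in eff.items():
        if name == "const":
            continue
        if name == "baseline_mvpa":
            x = baseline_allday_mvpa
        elif name == "group":
            x = (subjects["group"] == "intervention").to_numpy(float)
        elif name == "centre":
            x = np.array([_CENTRE_SORTED.index(c) for c in subjects["centre"]], float)
        else:
            x = pd.to_numeric(subjects[name]).to_numpy(float)
        delta = delta + coef * x
    if cfg.covariate_resid_sd > 0:
        delta = delta + rng.normal(0.0, cfg.covariate_resid_sd, n)
    return delta


@dataclass
class TrialDataset:
    """Generated trial: covariate table, per-day minute ledger, ground truth."""

    scenario: ScenarioConfig
    subjects: pd.DataFrame
    day_minutes: pd.DataFrame
    truth: Dict

    def visit_summaries(self) -> pd.DataFrame:
        """Per subject-visit 7-day PA aggregates (plan-mode fast path).

        Uses the first 7 generated days (Mon..Sun) of each visit and the
        same weighting as the epoch pipeline: all-days mean =
        (5 x weekday + 2 x weekend) / 7.
        """
        dm = self.day_minutes[self.day_minutes["day"] < 7]
        rows = []
        for (sid, visit), g in dm.groupby(["subject_id", "visit"], sort=False):
            row = {"subject_id": sid, "visit": visit}
            parts = {}
            for day_type in ("weekday", "weekend"):
                sel = g[g["day_type"] == day_type]
                mv_b = sel["mvpa_bouted"].mean()
                mv_u = (sel["mvpa_bouted"] + sel["mvpa_extra"]).mean()
                li_b = sel["light_bouted"].mean()
                li_u = (sel["light_bouted"] + sel["light_extra"]).mean()
                parts[day_type] = {
                    ("mvpa", "bouted"): mv_b,
                    ("mvpa", "unbouted"): mv_u,
                    ("light", "bouted"): li_b,
                    ("light", "unbouted"): li_u,
                    ("inactive", "bouted"): 1440.0 - mv_b - li_b,
                    ("inactive", "unbouted"): 1440.0 - mv_u - li_u,
                }
            for key in parts["weekday"]:
                cat, mode = key
                wd, we = parts["weekday"][key], parts["weekend"][key]
                row[f"weekday_{cat}_{mode}"] = wd
                row[f"weekend_{cat}_{mode}"] = we
                row[f"all_days_{cat}_{mode}"] = (5.0 * wd + 2.0 * we) / 7.0
            for mode in ("bouted", "unbouted"):
                weekly = 7.0 * row[f"all_days_mvpa_{mode}"]
                row[f"weekly_mvpa_{mode}"] = weekly
                row[f"meets_guideline_{mode}"] = int(weekly >= 150.0)
            rows.append(row)
        return pd.DataFrame(rows)

    def thresholds_for(self, subject_id: str) -> ThresholdSet:
        wrist = self.subjects.set_index("subject_id").loc[subject_id, "wrist"]
        return HF_LEFT if wrist == "left" else HF_RIGHT

    def _day_rows(self, subject_id: str, visit: str) -> pd.DataFrame:
        dm = self.day_minutes
        sel = dm[(dm["subject_id"] == subject_id) & (dm["visit"] == visit)]
        if sel.empty:
            raise ScenarioError(f"no generated days for {subject_id}/{visit}")
        return sel.sort_values("day")

    def _signal(self, subject_id: str, visit: str, mode: str,
                sample_rate: float = 10.0):
        cfg = self.scenario
        rows = self._day_rows(subject_id, visit)
        thresholds = self.thresholds_for(subject_id)
        sidx = int(self.subjects.index[self.subjects["subject_id"] == subject_id][0])
        vidx = cfg.visits.index(visit)
        rng = np.random.default_rng([cfg.seed % (2**31), sidx, vidx, 99])
        parts = []
        ledgers = []
        start0 = pd.Timestamp(rows.iloc[0]["date"], tz="UTC")
        for _, r in rows.iterrows():
            plan = build_day_schedule(
                r["mvpa_bouted"], r["mvpa_extra"], r["light_bouted"],
                r["light_extra"], rng, sleep_min=cfg.sleep_min,
                nonwear_min=int(r["nonwear_min"]),
            )
            sig, ledger = generate_day_signal(
                plan, thresholds, rng, state_levels=cfg.state_levels,
                mode=mode, sample_rate=sample_rate,
                start=pd.Timestamp(r["date"], tz="UTC"),
                subject_id=subject_id, visit=visit,
            )
            parts.append(sig)
            ledgers.append(ledger)
        if mode == "epoch":
            series = EpochSeries(
                epoch_length=parts[0].epoch_length,
                start=start0,
                enmo=np.concatenate([p.enmo for p in parts]),
                artifact=np.concatenate([p.artifact for p in parts]),
                nonwear=np.concatenate([p.nonwear for p in parts]),
                subject_id=subject_id,
                visit=visit,
            )
            return series, ledgers
        stream = AccelStream(
            subject_id=subject_id,
            visit=visit,
            wrist=thresholds.wrist,
            sample_rate=sample_rate,
            t0=start0,
            samples=np.concatenate([p.samples for p in parts], axis=0),
        )
        return stream, ledgers

    def epoch_series(self, subject_id: str, visit: str = "baseline"):
        """Deterministic epoch-mode signal for one subject-visit."""
        return self._signal(subject_id, visit, "epoch")

    def accel_stream(self, subject_id: str, visit: str = "baseline",
                     sample_rate: float = 10.0):
        """Deterministic raw-mode signal for one subject-visit."""
        return self._signal(subject_id, visit, "raw", sample_rate=sample_rate)

    def write(self, out_dir, mode: str = "plan") -> None:
        from .raw_ingest import write_epoch_csv, write_raw_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "covariates.csv", index=False, float_format="%.6f")
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True, default=float)
        if mode == "plan":
            self.visit_summaries().to_csv(
                out / "visits.csv", index=False, float_format="%.6f"
            )
            self.day_minutes.to_csv(
                out / "day_minutes.csv", index=False, float_format="%.6f"
            )
            return
        sub = out / ("epochs" if mode == "epoch" else "raw")
        sub.mkdir(exist_ok=True)
        for (sid, visit), _ in self.day_minutes.groupby(["subject_id", "visit"]):
            sig, _ledgers = self._signal(sid, visit, mode)
            path = sub / f"{sid}_{visit}.csv"
            if mode == "epoch":
                write_epoch_csv(sig, path)
            else:
                write_raw_csv(sig, path)


def generate_trial(scenario: ScenarioConfig,
                   rng: Optional[np.random.Generator] = None) -> TrialDataset:
    """Generate a full two-arm trial under a scenario (plan-level ledger).

    Reproducible under a fixed seed.  Subject activity volumes are drawn
    per arm/visit/day-type from the scenario's PA summaries with latent
    correlation ``rho`` between baseline and follow-up; a covariate model,
    when configured, replaces the follow-up MVPA draw with baseline +
    covariate-implied change.  Attrition removes subject-visits at the
    configured retention rates.
    """
    cfg = scenario
    rng = rng or np.random.default_rng(cfg.seed)
    subjects = _generate_subjects(cfg, rng)
    n = len(subjects)
    arm_of = subjects["group"].to_numpy()

    retained = {}
    for v, (visit, r) in enumerate(zip(cfg.visits, cfg.retention)):
        retained[visit] = np.ones(n, bool) if r >= 1.0 else rng.random(n) < r

    # subject latents per intensity, correlated baseline -> follow-up
    z_mvpa_b = rng.standard_normal(n)
    z_light_b = rng.standard_normal(n)
    z_follow = {}
    for visit in cfg.visits[1:]:
        z_follow[visit] = (
            cfg.rho * z_mvpa_b + np.sqrt(1 - cfg.rho**2) * rng.standard_normal(n),
            cfg.rho * z_light_b + np.sqrt(1 - cfg.rho**2) * rng.standard_normal(n),
        )

    def _stats(day_type: str, intensity: str, arm: str, visit: str):
        key_arm = "control" if cfg.equal_arms else arm
        row = cfg.pa_summary[(day_type, intensity)][key_arm]
        if visit == "baseline":
            return row.baseline_mean, row.baseline_sd
        return row.followup_mean, row.followup_sd

    def _targets(intensity: str, z: np.ndarray, visit: str) -> Dict[str, np.ndarray]:
        out = {}
        for day_type in ("weekday", "weekend"):
            vals = np.empty(n)
            for arm in ("intervention", "control"):
                sel = arm_of == arm
                mean, sd = _stats(day_type, intensity, arm, visit)
                vals[sel] = _lognormal(z[sel], mean, sd)
            out[day_type] = vals
        return out

    mvpa_targets = {"baseline": _targets("mvpa", z_mvpa_b, "baseline")}
    light_targets = {"baseline": _targets("light", z_light_b, "baseline")}
    for visit in cfg.visits[1:]:
        zm, zl = z_follow[visit]
        mvpa_targets[visit] = _targets("mvpa", zm, visit)
        light_targets[visit] = _targets("light", zl, visit)

    if cfg.covariate_effects:
        base_allday = (
            5.0 * mvpa_targets["baseline"]["weekday"]
            + 2.0 * mvpa_targets["baseline"]["weekend"]
        ) / 7.0
        for visit in cfg.visits[1:]:
            delta = _covariate_delta(cfg, subjects, base_allday, rng)
            for day_type in ("weekday", "weekend"):
                mvpa_targets[visit][day_type] = np.clip(
                    mvpa_targets["baseline"][day_type] + delta, 0.0, None
                )

    # cap extreme lognormal tails below the hard wake budget, keeping
    # headroom for scheduling gaps and injected effect shifts
    wake_cap = 1440.0 - cfg.sleep_min - 60.0 - 45.0
    frames = []
    for visit in cfg.visits:
        keep = retained[visit]
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        start = _VISIT_START.get(visit, dt.date(2015, 6, 1))
        for d in range(cfg.days_per_visit):
            day_type = "weekday" if d % 7 < 5 else "weekend"
            mult_m = _lognormal(rng, 1.0, cfg.mvpa_day_cv, idx.size)
            mult_l = _lognormal(rng, 1.0, cfg.light_day_cv, idx.size)
            mvpa = mvpa_targets[visit][day_type][idx] * mult_m
            light = light_targets[visit][day_type][idx] * mult_l
            mvpa_extra = mvpa * cfg.mvpa_extra_frac
            light_extra = light * cfg.light_extra_frac
            total = mvpa + mvpa_extra + light + light_extra
            over = total > wake_cap
            if np.any(over):
                scale = wake_cap / total[over]
                for arr in (mvpa, mvpa_extra, light, light_extra):
                    arr[over] *= scale
            nw = np.where(
                rng.random(idx.size) < cfg.nonwear_per_day,
                rng.integers(cfg.nonwear_duration_min[0],
                             cfg.nonwear_duration_min[1] + 1, idx.size),
                0,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subjects["subject_id"].to_numpy()[idx],
                        "visit": visit,
                        "day": d,
                        "date": (start + dt.timedelta(days=d)).isoformat(),
                        "day_type": day_type,
                        "mvpa_bouted": mvpa,
                        "mvpa_extra": mvpa_extra,
                        "light_bouted": light,
                        "light_extra": light_extra,
                        "nonwear_min": nw,
                    }
                )
            )
    day_minutes = pd.concat(frames, ignore_index=True)
    day_minutes = day_minutes.sort_values(["subject_id", "visit", "day"],
                                          kind="stable").reset_index(drop=True)

    truth = _ground_truth(cfg, subjects, day_minutes)
    return TrialDataset(scenario=cfg, subjects=subjects,
                        day_minutes=day_minutes, truth=truth)


def _ground_truth(cfg: ScenarioConfig, subjects: pd.DataFrame,
                  day_minutes: pd.DataFrame) -> Dict:
    dm = day_minutes[day_minutes["day"] < 7].merge(
        subjects[["subject_id", "group"]], on="subject_id"
    )
    truth: Dict = {"visit_counts": {}, "arm_day_type_means": {}, "injected": {}}
    for visit, g in dm.groupby("visit"):
        truth["visit_counts"][visit] = int(g["subject_id"].nunique())
        for (arm, day_type), gg in g.groupby(["group", "day_type"]):
            per_subject = gg.groupby("subject_id")[
                ["mvpa_bouted", "mvpa_extra", "light_bouted", "light_extra"]
            ].mean()
            truth["arm_day_type_means"][f"{visit}/{arm}/{day_type}"] = {
                "mvpa_bouted": float(per_subject["mvpa_bouted"].mean()),
                "mvpa_unbouted": float(
                    (per_subject["mvpa_bouted"] + per_subject["mvpa_extra"]).mean()
                ),
                "light_bouted": float(per_subject["light_bouted"].mean()),
                "n": int(len(per_subject)),
            }
    return truth


def inject_compensation(
    dataset: TrialDataset,
    weekday_delta: float,
    weekend_delta: float,
    arm: str = "intervention",
    intensity: str = "mvpa",
) -> TrialDataset:
    """Shift an arm's follow-up weekday/weekend activity by fixed deltas.

    Adds ``weekday_delta`` min/day to each follow-up weekday and
    ``weekend_delta`` to each follow-up weekend day of the named arm
    (bouted minutes of the chosen intensity), modelling a weekday gain
    compensated at the weekend.  Raises :class:`ScenarioError` if any day
    would go below zero or above the wake budget.  Ground truth is updated.
    """
    if intensity not in ("mvpa", "light"):
        raise ScenarioError(f"cannot inject into intensity {intensity!r}")
    col = f"{intensity}_bouted"
    dm = dataset.day_minutes.copy()
    arm_subjects = set(dataset.subjects.loc[dataset.subjects["group"] == arm,
                                            "subject_id"])
    follow = ~dm["visit"].eq("baseline")
    sel = follow & dm["subject_id"].isin(arm_subjects)
    delta = np.where(dm.loc[sel, "day_type"] == "weekday",
                     weekday_delta, weekend_delta)
    newvals = dm.loc[sel, col].to_numpy() + delta
    if np.any(newvals < 0):
        raise ScenarioError("infeasible compensation delta: negative minutes")
    wake_cap = 1440.0 - dataset.scenario.sleep_min - 60.0
    active = (
        dm.loc[sel, ["mvpa_bouted", "mvpa_extra", "light_bouted", "light_extra"]]
        .sum(axis=1).to_numpy() + delta
    )
    if np.any(active > wake_cap + 1e-6):
        raise ScenarioError("infeasible compensation delta: exceeds wake budget")
    dm.loc[sel, col] = newvals
    truth = copy.deepcopy(dataset.truth)
    truth["injected"] = {
        "arm": arm, "intensity": intensity,
        "weekday_delta": float(weekday_delta),
        "weekend_delta": float(weekend_delta),
        "all_days_delta": float((5.0 * weekday_delta + 2.0 * weekend_delta) / 7.0),
    }
    return TrialDataset(scenario=dataset.scenario, subjects=dataset.subjects,
                        day_minutes=dm, truth=truth)


# ---------------------------------------------------------------------------
# outcome-level simulators for replicate studies
# ---------------------------------------------------------------------------

def simulate_ancova_cohort(
    rng: np.random.Generator,
    n_per_arm: Tuple[int, int],
    baseline_means: Tuple[float, float],
    baseline_sds: Tuple[float, float],
    followup_sds: Tuple[float, float],
    rho: float = 0.5,
    effect: float = 0.0,
    drift: float = 0.0,
    n_centres: int = 5,
    p_bnp: float = 0.25,
) -> pd.DataFrame:
    """One simulated trial at the outcome level for the ANCOVA estimator.

    Baselines are normal per arm (intervention first); follow-up is
    ``gamma + b * baseline + effect * group + e`` with the common slope
    ``b = rho * sd_f / sd_b`` and residual SD ``sd_f * sqrt(1 - rho^2)``,
    so the generating group effect is exactly ``effect`` and the
    baseline-follow-up correlation is ``rho``.
    """
    n_i, n_c = n_per_arm
    n = n_i + n_c
    group = np.array(["intervention"] * n_i + ["control"] * n_c)
    g = (group == "intervention").astype(float)
    base = np.empty(n)
    base[:n_i] = rng.normal(baseline_means[0], baseline_sds[0], n_i)
    base[n_i:] = rng.normal(baseline_means[1], baseline_sds[1], n_c)
    sd_b = float(np.mean(baseline_sds))
    sd_f = float(np.mean(followup_sds))
    b = rho * sd_f / sd_b
    resid = sd_f * np.sqrt(1.0 - rho**2)
    pooled_mean = (n_i * baseline_means[0] + n_c * baseline_means[1]) / n
    gamma = (1.0 - b) * pooled_mean + drift
    follow = gamma + b * base + effect * g + rng.normal(0.0, resid, n)
    return pd.DataFrame(
        {
            "group": group,
            "baseline": base,
            "followup": follow,
            "bnp2000": rng.random(n) < p_bnp,
            "centre": rng.integers(0, n_centres, n).astype(str),
        }
    )


def simulate_predictor_cohort(
    rng: np.random.Generator,
    n: int = 170,
    coefs: Optional[Dict[str, float]] = None,
    resid_sd: float = 54.0,
) -> pd.DataFrame:
    """A cohort whose MVPA change follows a linear covariate model.

    Covariates are drawn from the reference baseline distributions; the
    change score is the linear predictor (ordinal centre coding,
    intervention = 1) plus normal residuals of SD ``resid_sd``.
    """
    coefs = dict(presets.PREDICTOR_MODEL3) if coefs is None else dict(coefs)
    cov = presets.COVARIATE_SUMMARY
    prev = presets.COVARIATE_PREVALENCE
    df = pd.DataFrame(
        {
            "group": np.where(rng.random(n) < 0.5, "intervention", "control"),
            "baseline_mvpa": _lognormal(rng, 46.0, 55.0, n),
            "centre": rng.choice(_CENTRE_SORTED, n),
            "bnp2000": rng.random(n) < 0.25,
            "iswt": np.clip(rng.normal(*cov["iswt"], n), 0, None),
            "hads_anxiety": np.clip(rng.normal(*cov["hads_anxiety"], n), 0, 21),
            "live_with_parent": rng.random(n) < prev["live_with_parent"],
            "live_with_child_over_18": rng.random(n)
            < prev["live_with_child_over_18"],
        }
    )
    lin = np.full(n, float(coefs.pop("const", 0.0)))
    for name, coef in coefs.items():
        if name == "group":
            x = (df["group"] == "intervention").to_numpy(float)
        elif name == "centre":
            x = np.array([_CENTRE_SORTED.index(c) for c in df["centre"]], float)
        else:
            x = pd.to_numeric(df[name]).to_numpy(float)
        lin = lin + coef * x
    df["delta_mvpa"] = lin + rng.normal(0.0, resid_sd, n)
    return df


def simulate_guideline_cohort(
    rng: np.random.Generator,
    n_per_arm: Tuple[int, int] = (200, 200),
    log_or: float = 0.0,
    intercept: float = -0.5,
    baseline_coef: float = 1.0,
    n_centres: int = 5,
    p_bnp: float = 0.25,
) -> pd.DataFrame:
    """Binary guideline attainment under a logistic model with group log-OR."""
    n_i, n_c = n_per_arm
    n = n_i + n_c
    group = np.array(["intervention"] * n_i + ["control"] * n_c)
    g = (group == "intervention").astype(float)
    base = (rng.random(n) < 0.5).astype(float)
    eta = intercept + baseline_coef * base + log_or * g
    p = 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame(
        {
            "group": group,
            "baseline_meets": base.astype(int),
            "followup_meets": (rng.random(n) < p).astype(int),
            "bnp2000": rng.random(n) < p_bnp,
            "centre": rng.integers(0, n_centres, n).astype(str),
        }
    )
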