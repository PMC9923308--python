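"""End-to-end orchestration: process -> summarise -> analyze, with a
run manifest recording versions, config and input hashes, and per-stage
row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__, pa_metrics, raw_ingest, trial_analysis
from .config import RunConfig
from .errors import DataError, FormatError
from .types import threshold_profile

log = logging.getLogger(__name__)


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def process_raw_file(path, config: RunConfig):
    """Raw CSV -> calibrated, non-wear-flagged epoch series."""
    stream = raw_ingest.read_raw_csv(path, timezone=config.timezone)
    stream, cal = raw_ingest.autocalibrate(stream)
    epochs = raw_ingest.compute_enmo_epochs(stream, epoch_length=config.epoch_seconds)
    epochs = raw_ingest.detect_nonwear(
        epochs,
        stream,
        window_min=config.nonwear.window_min,
        step_min=config.nonwear.step_min,
        range_cut_mg=config.nonwear.range_cut_mg,
        sd_cut_mg=config.nonwear.sd_cut_mg,
        axes_required=config.nonwear.axes_required,
    )
    log.info(
        "processed %s: %d epochs, %.1f%% non-wear, calibration %s",
        path, epochs.n, 100.0 * epochs.nonwear.mean(),
        "applied" if cal and cal.applied else "skipped",
    )
    return epochs


def summarise_epochs(epochs, config: RunConfig, wrist: Optional[str] = None):
    """Epoch series -> (daily table, visit summary) or None if no valid week."""
    week = raw_ingest.select_valid_week(epochs, valid_day_hours=config.valid_day_hours)
    if week is None:
        log.warning("%s/%s: no run of 7 valid days; excluded",
                    epochs.subject_id, epochs.visit)
        return None
    profile = config.thresholds_profile
    if wrist is not None:
        profile = "hf_left" if wrist == "left" else "hf_right"
    thresholds = threshold_profile(profile)
    dailies, visit = pa_metrics.summarise_week(
        week,
        thresholds,
        min_minutes=config.bout.min_minutes,
        allowance=config.bout.allowance,
        guideline_weekly_min=config.guideline_weekly_min,
    )
    return dailies, visit


def analyze_trial(visits_df: pd.DataFrame, covariates: pd.DataFrame,
                  config: RunConfig) -> Dict:
    """Visit-level PA table + covariates -> effects and report tables."""
    followup = config.analysis.visit
    numeric, formatted, effects = trial_analysis.report_table2(
        visits_df,
        covariates,
        followup_visit=followup,
        bouting=config.analysis.bouting,
        centre_coding=config.analysis.centre_coding,
    )
    artifacts: Dict = {
        "table2": numeric,
        "table2_formatted": formatted,
        "effects": [e.to_dict() for e in effects],
    }

    merged = visits_df.merge(
        covariates[["subject_id", "group", "bnp2000", "centre"]], on="subject_id"
    )
    base = merged[merged["visit"] == "baseline"].set_index("subject_id")
    post = merged[merged["visit"] == followup].set_index("subject_id")
    paired = base.index.intersection(post.index)
    gcol = f"meets_guideline_{config.analysis.bouting}"
    guide = pd.DataFrame(
        {
            "baseline_meets": base.loc[paired, gcol].astype(int),
            "followup_meets": post.loc[paired, gcol].astype(int),
            "group": base.loc[paired, "group"],
            "bnp2000": base.loc[paired, "bnp2000"],
            "centre": base.loc[paired, "centre"],
        }
    )
    try:
        guideline = trial_analysis.guideline_logistic(
            guide, centre_coding=config.analysis.centre_coding, visit=followup
        )
        artifacts["guideline_effect"] = guideline.to_dict()
    except DataError as exc:
        log.warning("guideline logistic model skipped: %s", exc)
        artifacts["guideline_effect"] = None
    return artifacts


def run_pipeline(config: RunConfig, input_dir, out_dir) -> Dict:
    """Execute all stages on a directory of inputs; write artifacts + manifest.

    ``input_dir`` holds either ``raw/*.csv`` or ``epochs/*.csv`` plus
    ``covariates.csv``.  Outputs: ``epochs/`` (when starting from raw),
    ``days.csv``, ``visits.csv``, ``table2.csv``, ``effects.json`` and
    ``manifest.json``.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: Dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "inputs": {},
        "stages": {},
    }

    cov_path = input_dir / "covariates.csv"
    if not cov_path.exists():
        raise FormatError(f"missing covariates table {cov_path}")
    covariates = pd.read_csv(cov_path)
    manifest["inputs"][str(cov_path)] = _file_hash(cov_path)

    raw_files = sorted((input_dir / "raw").glob("*.csv")) if (input_dir / "raw").is_dir() else []
    epoch_files = sorted((input_dir / "epochs").glob("*.csv")) if (input_dir / "epochs").is_dir() else []

    epoch_series = []
    if raw_files:
        epoch_out = out_dir / "epochs"
        epoch_out.mkdir(exist_ok=True)
        for path in raw_files:
            manifest["inputs"][str(path)] = _file_hash(path)
            epochs = process_raw_file(path, config)
            raw_ingest.write_epoch_csv(epochs, epoch_out / path.name)
            epoch_series.append(epochs)
        manifest["stages"]["process"] = {"files": len(raw_files)}
    elif epoch_files:
        for path in epoch_files:
            manifest["inputs"][str(path)] = _file_hash(path)
            epoch_series.append(raw_ingest.read_epoch_csv(path))
    else:
        raise FormatError(f"no raw/ or epochs/ inputs under {input_dir}")

    wrist_by_subject = (
        covariates.set_index("subject_id")["wrist"].to_dict()
        if "wrist" in covariates.columns else {}
    )
    daily_frames: List[pd.DataFrame] = []
    visit_records = []
    excluded = 0
    for epochs in epoch_series:
        result = summarise_epochs(
            epochs, config, wrist=wrist_by_subject.get(epochs.subject_id)
        )
        if result is None:
            excluded += 1
            continue
        dailies, visit = result
        daily_frames.append(pa_metrics.daily_table(dailies, epochs.subject_id, epochs.visit))
        visit_records.append(visit)
    if not visit_records:
        raise DataError("no subject-visit produced a valid week")
    days_df = pd.concat(daily_frames, ignore_index=True)
    visits_df = pa_metrics.visit_table(visit_records)
    days_df.to_csv(out_dir / "days.csv", index=False, float_format="%.4f")
    visits_df.to_csv(out_dir / "visits.csv", index=False, float_format="%.6f")
    visit_counts = visits_df.groupby("visit")["subject_id"].nunique().to_dict()
    manifest["stages"]["summarise"] = {
        "subject_visits": len(visit_records),
        "excluded_no_valid_week": excluded,
        "subjects_by_visit": {k: int(v) for k, v in visit_counts.items()},
    }

    artifacts = analyze_trial(visits_df, covariates, config)
    artifacts["table2"].to_csv(out_dir / "table2.csv", index=False, float_format="%.4f")
    artifacts["table2_formatted"].to_csv(out_dir / "table2_formatted.csv", index=False)
    with open(out_dir / "effects.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"effects": artifacts["effects"],
             "guideline_effect": artifacts["guideline_effect"]},
            fh, indent=1,
        )
    manifest["stages"]["analyze"] = {"n_effects": len(artifacts["effects"])}

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
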