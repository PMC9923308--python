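"""Single definition site for every processing and analysis constant.

All defaults can be overridden through :class:`actihf.config.RunConfig`;
overrides are echoed to the run log so a run never silently drifts from the
reference values.
"""

#: Epoch length over which sample-level ENMO is averaged (seconds).
EPOCH_SECONDS = 5

#: Non-wear detection: window length / step (minutes), per-axis range and
#: SD cuts (mg), and the number of axes that must satisfy both cuts.
NONWEAR_WINDOW_MIN = 60
NONWEAR_STEP_MIN = 15
NONWEAR_RANGE_CUT_MG = 50.0
NONWEAR_SD_CUT_MG = 13.0
NONWEAR_AXES_REQUIRED = 2

#: Minimum daily wear time for a valid day (hours).
VALID_DAY_HOURS = 16.0

#: Heart-failure-specific intensity cut-points (mg), by wrist.
#: inactivity: < 1.5 METs; MVPA: >= 3.0 METs.
THRESHOLD_PROFILES = {
    "hf_left": ("left", 16.7, 43.6),
    "hf_right": ("right", 18.6, 45.5),
}

#: Bout rule: minimum duration (minutes) and fractional allowance for
#: epochs outside the intensity category.
BOUT_MIN_MINUTES = 10.0
BOUT_ALLOWANCE = 0.2

#: Weekly MVPA guideline (minutes per week).
GUIDELINE_WEEKLY_MIN = 150.0

#: Samples with vector norm above this value (mg) flag their epoch as an
#: artifact (abnormally high value for a wrist device).
ARTIFACT_NORM_CUT_MG = 8000.0

#: Autocalibration: per-axis SD cut for a stationary 10-s window (mg),
#: minimum number of stationary windows and distinct orientation octants
#: required before a calibration is fitted.
CALIBRATION_SD_CUT_MG = 13.0
CALIBRATION_WINDOW_SECONDS = 10
CALIBRATION_MIN_WINDOWS = 20
CALIBRATION_MIN_OCTANTS = 6
CALIBRATION_GAIN_RANGE = (0.9, 1.1)
CALIBRATION_OFFSET_RANGE_MG = (-150.0, 150.0)

#: Screening / significance thresholds for the predictor models.
ALPHA_ENTRY = 0.15
ALPHA_SIGNIFICANT = 0.05

#: Default timezone.  A fixed-offset zone keeps every civil day exactly
#: 86 400 s long, which the daily integrity checks rely on.
TIMEZONE = "UTC"
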