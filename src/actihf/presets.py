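"""Frozen reference summaries used to parameterise the default scenarios.

These are published arm-level summary statistics from a two-arm randomised
evaluation of a home-based cardiac-rehabilitation programme in heart
failure, measured with wrist accelerometry under the heart-failure-specific
cut-points.  They define the study conditions the synthetic generator
emulates; they are generator inputs, never analysis outputs.
"""

from collections import namedtuple

ArmSummary = namedtuple(
    "ArmSummary", "baseline_mean baseline_sd followup_mean followup_sd"
)

#: Bouted minutes/day by (stratum, intensity): per-arm mean (SD) at baseline
#: and final follow-up, plus the adjusted between-group estimate (95% CI, p).
PA_SUMMARY = {
    ("all_days", "mvpa"): {
        "intervention": ArmSummary(43.62, 51.15, 47.61, 67.78),
        "control": ArmSummary(49.66, 73.98, 44.56, 72.10),
        "effect": 7.61, "ci": (-5.11, 20.33), "p": 0.24,
    },
    ("all_days", "light"): {
        "intervention": ArmSummary(213.80, 110.94, 221.92, 129.57),
        "control": ArmSummary(219.93, 114.73, 209.50, 120.90),
        "effect": 16.87, "ci": (-8.79, 42.54), "p": 0.20,
    },
    ("all_days", "inactive"): {
        "intervention": ArmSummary(1182.58, 144.43, 1170.47, 170.47),
        "control": ArmSummary(1170.41, 164.42, 1185.78, 167.52),
        "effect": -24.77, "ci": (-56.69, 7.16), "p": 0.13,
    },
    ("weekend", "mvpa"): {
        "intervention": ArmSummary(43.72, 56.62, 38.67, 61.04),
        "control": ArmSummary(41.0, 69.84, 36.43, 62.10),
        "effect": 0.14, "ci": (-12.92, 13.21), "p": 0.98,
    },
    ("weekend", "light"): {
        "intervention": ArmSummary(208.10, 123.23, 201.36, 128.36),
        "control": ArmSummary(202.18, 118.25, 206.22, 123.41),
        "effect": -8.38, "ci": (-37.96, 21.20), "p": 0.58,
    },
    ("weekend", "inactive"): {
        "intervention": ArmSummary(1188.18, 161.84, 1199.98, 162.57),
        "control": ArmSummary(1196.82, 160.52, 1197.35, 158.21),
        "effect": 8.27, "ci": (-27.01, 43.55), "p": 0.64,
    },
    ("weekday", "mvpa"): {
        "intervention": ArmSummary(43.58, 50.71, 51.19, 71.70),
        "control": ArmSummary(53.12, 79.66, 47.82, 78.90),
        "effect": 10.87, "ci": (-2.94, 24.69), "p": 0.12,
    },
    ("weekday", "light"): {
        "intervention": ArmSummary(216.08, 112.68, 230.15, 135.37),
        "control": ArmSummary(227.03, 120.85, 210.81, 125.37),
        "effect": 26.87, "ci": (-0.05, 53.78), "p": 0.05,
    },
    ("weekday", "inactive"): {
        "intervention": ArmSummary(1180.34, 143.59, 1158.66, 178.56),
        "control": ArmSummary(1159.85, 174.23, 1181.37, 178.59),
        "effect": -38.31, "ci": (-72.13, -4.50), "p": 0.03,
    },
}

#: Analysed sample sizes at final follow-up, by arm.
ARM_N_FINAL = {"intervention": 80, "control": 93}

#: Enrolled sample sizes, by arm.
ARM_N_ENROLLED = {"intervention": 122, "control": 125}

#: Participant flow: complete accelerometer data at each visit.
TRIAL_FLOW = {"baseline": 247, "post_intervention": 198, "final_followup": 173}

#: Combined predictor model for change in MVPA (min/day) at final follow-up:
#: unstandardised coefficients (ordinal centre coding, NT-proBNP stratum as
#: a binary indicator).  Used as generating truth in recovery simulations.
PREDICTOR_MODEL3 = {
    "const": -14.51,
    "group": -8.37,
    "baseline_mvpa": -0.21,
    "centre": -0.11,
    "bnp2000": -6.21,
    "iswt": 0.08,
    "live_with_child_over_18": 30.48,
    "hads_anxiety": 1.89,
    "live_with_parent": -52.60,
}

#: Baseline covariate summaries (means/SDs pooled over arms) used only for
#: realism of the generated covariate table.
COVARIATE_SUMMARY = {
    "age": (70.9, 10.3),
    "iswt": (230.0, 150.0),
    "hads_anxiety": (5.6, 4.4),
    "hads_depression": (4.8, 3.5),
    "schfi_maintenance": (54.5, 15.8),
}

#: Prevalences for binary covariates in the generated cohort.
COVARIATE_PREVALENCE = {
    "female": 0.28,
    "diabetes": 0.30,
    "live_with_parent": 0.05,
    "live_with_child_over_18": 0.10,
}

CENTRES = ("truro", "gwent", "birmingham", "york", "dundee")
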