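"""Run configuration: YAML schema, validation and the constants registry.

Defaults come from :mod:`actihf.constants` (the single definition site);
unknown keys are errors, not warnings, so a config file cannot silently
drift from the reference processing constants, and every override is
echoed to the run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from . import constants
from .errors import ConfigError
from .types import VISITS, threshold_profile

log = logging.getLogger(__name__)


@dataclass
class NonwearConfig:
    window_min: float = constants.NONWEAR_WINDOW_MIN
    step_min: float = constants.NONWEAR_STEP_MIN
    range_cut_mg: float = constants.NONWEAR_RANGE_CUT_MG
    sd_cut_mg: float = constants.NONWEAR_SD_CUT_MG
    axes_required: int = constants.NONWEAR_AXES_REQUIRED


@dataclass
class BoutConfig:
    min_minutes: float = constants.BOUT_MIN_MINUTES
    allowance: float = constants.BOUT_ALLOWANCE


@dataclass
class AnalysisConfig:
    visit: str = "final_followup"
    bouting: str = "bouted"
    centre_coding: str = "indicator"
    cooks_flag: Optional[float] = None  # None -> 4/n
    alpha_entry: float = constants.ALPHA_ENTRY
    alpha_significant: float = constants.ALPHA_SIGNIFICANT


@dataclass
class RunConfig:
    timezone: str = constants.TIMEZONE
    epoch_seconds: float = constants.EPOCH_SECONDS
    nonwear: NonwearConfig = field(default_factory=NonwearConfig)
    valid_day_hours: float = constants.VALID_DAY_HOURS
    thresholds_profile: str = "hf_left"
    bout: BoutConfig = field(default_factory=BoutConfig)
    guideline_weekly_min: float = constants.GUIDELINE_WEEKLY_MIN
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        if 60 % self.epoch_seconds != 0:
            raise ConfigError(f"epoch_seconds {self.epoch_seconds} must divide 60")
        if not 0.0 <= self.bout.allowance < 0.5:
            raise ConfigError(f"bout.allowance {self.bout.allowance} outside [0, 0.5)")
        if self.bout.min_minutes <= 0:
            raise ConfigError("bout.min_minutes must be positive")
        if not 0 < self.valid_day_hours <= 24:
            raise ConfigError("valid_day_hours must be in (0, 24]")
        if self.thresholds_profile not in constants.THRESHOLD_PROFILES:
            raise ConfigError(
                f"unknown thresholds profile {self.thresholds_profile!r}; "
                f"known: {sorted(constants.THRESHOLD_PROFILES)}"
            )
        if self.analysis.visit not in VISITS:
            raise ConfigError(f"analysis.visit must be one of {VISITS}")
        if self.analysis.bouting not in ("bouted", "unbouted"):
            raise ConfigError("analysis.bouting must be bouted or unbouted")
        if self.analysis.centre_coding not in ("indicator", "ordinal"):
            raise ConfigError("analysis.centre_coding must be indicator or ordinal")
        for name in ("alpha_entry", "alpha_significant"):
            a = getattr(self.analysis, name)
            if not 0.0 < a < 1.0:
                raise ConfigError(f"analysis.{name} must be in (0, 1)")
        if self.nonwear.window_min <= 0 or self.nonwear.step_min <= 0:
            raise ConfigError("nonwear window/step must be positive")
        if self.nonwear.window_min % self.nonwear.step_min != 0:
            raise ConfigError("nonwear.window_min must be a multiple of step_min")
        if self.nonwear.axes_required not in (1, 2, 3):
            raise ConfigError("nonwear.axes_required must be 1, 2 or 3")
        return self

    @property
    def thresholds(self):
        return threshold_profile(self.thresholds_profile)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SECTIONS = {"nonwear": NonwearConfig, "bout": BoutConfig, "analysis": AnalysisConfig}


def config_from_dict(data: dict) -> RunConfig:
    """Build a validated RunConfig, rejecting unknown keys at every level."""
    data = dict(data or {})
    cfg = RunConfig()
    defaults = cfg.to_dict()
    unknown = [k for k in data if k not in defaults]
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            section = getattr(cfg, key)
            sub_defaults = asdict(section)
            bad = [k for k in value if k not in sub_defaults]
            if bad:
                raise ConfigError(f"unknown config keys in {key!r}: {sorted(bad)}")
            for k, v in value.items():
                if v != sub_defaults[k]:
                    log.info("config override: %s.%s = %r (default %r)",
                             key, k, v, sub_defaults[k])
                setattr(section, k, v)
        else:
            if value != defaults[key]:
                log.info("config override: %s = %r (default %r)",
                         key, value, defaults[key])
            setattr(cfg, key, value)
    return cfg.validate()


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(data)
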