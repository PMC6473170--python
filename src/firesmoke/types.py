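"""Domain types for the firefighter smoke-exposure pipeline.

All calendar arithmetic is in whole days (``datetime.date``), intervals
inclusive of both endpoints, matching the day-level granularity of the
deployment questionnaire.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "Device",
    "SmokingStatus",
    "RPEUsage",
    "HygieneAccess",
    "UrineSample",
    "DeploymentRecord",
    "FirefighterRecord",
    "MonitoringGrid",
    "ExposureSummary",
    "ProcessedSample",
    "ValidationError",
    "MissingDataError",
    "ConfigurationError",
]

FRACTION_TOL = 1e-6


class ValidationError(ValueError):
    """An input record violates a structural invariant."""


class MissingDataError(KeyError):
    """A required datum (grid cell, questionnaire answer) is absent."""

    def __str__(self) -> str:  # KeyError quotes its payload; we want plain text
        return self.args[0] if self.args else ""


class ConfigurationError(ValueError):
    """A configuration value is unusable."""


class Device(str, Enum):
    """Respiratory protective equipment classes, in order of protection."""

    NONE = "none"
    DUST_MASK = "dust_mask"
    HALF_FACE = "half_face"
    FULL_FACE = "full_face"
    SCBA = "scba"


class SmokingStatus(str, Enum):
    CURRENT = "current"
    EX = "ex"
    NEVER = "never"


@dataclass(frozen=True)
class RPEUsage:
    """Respirator use within one task.

    ``fraction_worn`` is the proportion of task time the device was worn;
    ``change_adequacy`` is 1 when the mask/filter was changed as often as
    recommended, scaled down towards 0 for less frequent changes.
    """

    device: Device
    fraction_worn: float
    change_adequacy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_worn <= 1.0):
            raise ValidationError(
                f"fraction_worn must be in [0,1], got {self.fraction_worn}"
            )
        if not (0.0 <= self.change_adequacy <= 1.0):
            raise ValidationError(
                f"change_adequacy must be in [0,1], got {self.change_adequacy}"
            )
        if self.device == Device.NONE and self.fraction_worn > 0:
            raise ValidationError("device=none forces fraction_worn=0")


@dataclass(frozen=True)
class HygieneAccess:
    """Yes/no answers to the three skin-hygiene opportunity questions."""

    wash_in_breaks: Optional[bool]
    shower_between_shifts: Optional[bool]
    clean_clothes: Optional[bool]


@dataclass(frozen=True)
class UrineSample:
    """A spot urine sample: 1-HP concentration, creatinine, censoring flags."""

    hp_ug_per_L: float
    below_lod: bool
    below_loq: bool
    creatinine_mg_per_dL: float
    collection_date: dt.date

    def __post_init__(self) -> None:
        if self.hp_ug_per_L < 0 or math.isnan(self.hp_ug_per_L):
            raise ValidationError(f"hp_ug_per_L must be >= 0, got {self.hp_ug_per_L}")
        if self.below_lod and not self.below_loq:
            raise ValidationError("below_lod implies below_loq")


@dataclass(frozen=True)
class DeploymentRecord:
    """One continuous period of firefighting duty.

    ``shift_hours`` maps each calendar day of the deployment to the hours
    actively fighting the fire within that 24 h; ``area_fractions`` and
    ``task_fractions`` each sum to 1 (tasks each >= 0.05, the questionnaire's
    reporting threshold).
    """

    start_date: dt.date
    end_date: dt.date
    shift_hours: dict[dt.date, float]
    area_fractions: dict[str, float]
    task_fractions: dict[str, float]
    rpe_usage: dict[str, RPEUsage]

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValidationError("end_date before start_date")
        for day, hours in self.shift_hours.items():
            if not (0.0 <= hours <= 24.0):
                raise ValidationError(f"hours on {day} outside [0, 24]: {hours}")
            if not (self.start_date <= day <= self.end_date):
                raise ValidationError(f"shift day {day} outside deployment interval")
        for name, fracs in (("area", self.area_fractions), ("task", self.task_fractions)):
            if fracs and abs(sum(fracs.values()) - 1.0) > FRACTION_TOL:
                raise ValidationError(
                    f"{name}_fractions sum to {sum(fracs.values())}, expected 1"
                )
            for key, f in fracs.items():
                if f < 0:
                    raise ValidationError(f"negative {name} fraction for {key!r}")

    @property
    def days(self) -> list[dt.date]:
        n = (self.end_date - self.start_date).days + 1
        return [self.start_date + dt.timedelta(days=i) for i in range(n)]

    @property
    def total_hours(self) -> float:
        return sum(self.shift_hours.values())


@dataclass
class FirefighterRecord:
    """One subject: deployments, protection behaviour, confounders, sample."""

    subject_id: str
    sex: str
    age: float
    bmi: float
    smoking_status: SmokingStatus
    bbq_last_48h: bool
    role_firefighter: bool
    other_fire_14d: bool
    other_fire_3d: bool
    fire_service: str
    deployments: list[DeploymentRecord]
    hygiene: HygieneAccess
    sample: Optional[UrineSample] = None

    def __post_init__(self) -> None:
        if not self.deployments:
            raise ValidationError(f"{self.subject_id}: deployments must be non-empty")
        deps = self.deployments
        for a, b in zip(deps, deps[1:]):
            if b.start_date <= a.end_date:
                raise ValidationError(
                    f"{self.subject_id}: deployments overlap or are out of order"
                )
        if self.sample is not None:
            if self.sample.collection_date < deps[-1].end_date:
                raise ValidationError(
                    f"{self.subject_id}: sample collected before last deployment ended"
                )

    @property
    def last_deployment_end(self) -> dt.date:
        return self.deployments[-1].end_date

    def collection_delay_days(self) -> int:
        """Whole days between end of last deployment and sample collection."""
        if self.sample is None:
            raise MissingDataError(f"{self.subject_id}: no urine sample")
        return (self.sample.collection_date - self.last_deployment_end).days


@dataclass
class MonitoringGrid:
    """Mean 24-h PM2.5 (ug/m3) indexed by (area, calendar day).

    Missing cells are explicit: lookups raise :class:`MissingDataError`
    naming the area and date rather than returning a silent zero.
    """

    values: dict[tuple[str, dt.date], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (area, day), v in self.values.items():
            if v < 0:
                raise ValidationError(f"negative PM2.5 at ({area}, {day}): {v}")

    def pm25(self, area: str, day: dt.date) -> float:
        try:
            return self.values[(area, day)]
        except KeyError:
            raise MissingDataError(
                f"no PM2.5 value for area {area!r} on {day.isoformat()}"
            ) from None

    @property
    def areas(self) -> list[str]:
        return sorted({a for a, _ in self.values})

    @property
    def days(self) -> list[dt.date]:
        return sorted({d for _, d in self.values})


@dataclass(frozen=True)
class ExposureSummary:
    """Per-subject exposure reconstruction for the regression models.

    ``env_first``/``env_total`` are in ug/m3-day-equivalents (PM2.5 weighted
    by hours/24 and area time-shares); ``exposure_index`` is
    env_first x task_factor / 1000, dimensionless.
    """

    subject_id: str
    env_first: float
    env_total: float
    task_factor: float
    exposure_index: float
    rpe_index: float
    semi: int

    def __post_init__(self) -> None:
        if self.exposure_index < 0:
            raise ValidationError("exposure_index must be >= 0")
        if not (0.0 <= self.rpe_index <= 1.0):
            raise ValidationError(f"rpe_index outside [0,1]: {self.rpe_index}")
        if self.semi not in (0, 1, 2, 3):
            raise ValidationError(f"semi must be in 0..3, got {self.semi}")


@dataclass(frozen=True)
class ProcessedSample:
    """A urine sample after censoring substitution, creatinine correction
    and creatinine-range exclusion."""

    subject_id: str
    hp_ng_per_g_creat: float
    excluded: bool
    exclusion_reason: str  # creatinine_low | creatinine_high | none
    substituted: str  # none | loq | lod

    def __post_init__(self) -> None:
        if self.hp_ng_per_g_creat < 0:
            raise ValidationError("hp_ng_per_g_creat must be >= 0")
        if self.exclusion_reason not in ("creatinine_low", "creatinine_high", "none"):
            raise ValidationError(f"bad exclusion_reason {self.exclusion_reason!r}")
        if self.excluded != (self.exclusion_reason != "none"):
            raise ValidationError("excluded flag inconsistent with exclusion_reason")
        if self.substituted not in ("none", "loq", "lod"):
            raise ValidationError(f"bad substituted flag {self.substituted!r}")
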