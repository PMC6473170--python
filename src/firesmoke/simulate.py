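"""Synthetic cohort generator with a two-compartment 1-HP excretion model.

The generator emulates the three inputs the analysis pipeline consumes — a
questionnaire-style firefighter cohort, an area-by-day PM2.5 grid, and spot
urine samples — with the statistical structure the analysis assumes, so that
every downstream stage has a parameter-recovery test surface.

The exposure-to-excretion link is a two-compartment first-order elimination
model. Urinary 1-HP excretion after PAH exposure shows a fast phase
(half-life on the order of 1-2 days) and a slow phase (half-life around
16 days); dermal absorption peaks later than inhalation, so the dermal dose
is given a smaller fast-phase fraction. At delay ``t`` days after the last
exposure the concentration is

    C(t) = D_inh * [a_inh * 2^(-t/T_fast) + (1 - a_inh) * 2^(-t/T_slow)]
         + D_skin * [a_skin * 2^(-t/T_fast) + (1 - a_skin) * 2^(-t/T_slow)]
         + baseline + beta_smoke*I(current smoker) + beta_bbq*I(recent BBQ)
         + beta_otherfire*I(other fire within 14 d),

all multiplied by mean-one lognormal noise, where the route doses are

    D_inh  = w_inh  * E * (1 - R)                 (respirator-mitigated)
    D_skin = w_skin * E * (1 - m_skin * SEMI/3)   (hygiene-mitigated)

with E the composite exposure index, R the RPE quotient in [0,1] and SEMI
the 0-3 skin-hygiene index. This link function is a test harness, not a
calibrated toxicokinetic model for pyrene.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import biomarker
from .exposure import (
    DEFAULT_TASK_WEIGHTS,
    cumulative_env_exposure,
    exposure_index,
    task_smoke_factor,
    total_exposure_all_deployments,
)
from .protection import rpe_quotient, semi_score
from .types import (
    ConfigurationError,
    DeploymentRecord,
    Device,
    ExposureSummary,
    FirefighterRecord,
    HygieneAccess,
    MonitoringGrid,
    RPEUsage,
    SmokingStatus,
    UrineSample,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "generate_grid",
    "generate_cohort",
    "simulate_hp",
    "concentration_at",
    "route_doses",
    "compute_exposure_summary",
]

_DEVICES = [Device.NONE, Device.DUST_MASK, Device.HALF_FACE, Device.FULL_FACE, Device.SCBA]
_DEVICE_P = [0.45, 0.20, 0.20, 0.10, 0.05]
_SMOKING = [SmokingStatus.CURRENT, SmokingStatus.EX, SmokingStatus.NEVER]
_SMOKING_P = [0.03, 0.18, 0.79]
_SERVICES = ["A", "B", "C"]
_SERVICE_P = [0.47, 0.10, 0.43]
_CHANGE_LEVELS = [0.0, 0.25, 0.5, 0.75, 1.0]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a severe urban-interface wildfire: very high PM2.5 in
    the first days decaying over the two-month window, week-scale deployments
    with long shifts, spot urine samples collected 0-16 days after the last
    shift, and confounder effects (smoking, barbeque, other fires) of the
    relative size seen in occupational 1-HP work.
    """

    n_subjects: int = 200
    date_start: dt.date = dt.date(2016, 5, 2)
    date_end: dt.date = dt.date(2016, 6, 30)
    areas: tuple[str, ...] = ("downtown", "north", "south")
    task_weight_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TASK_WEIGHTS)
    )
    pm25_base: float = 300.0  # ug/m3 at the fire's outbreak
    pm25_decay: float = 0.03  # exponential decline per day
    pm25_sigma: float = 0.3  # lognormal scatter of grid cells (mean-one)
    # two-compartment elimination
    T_fast: float = 1.5  # days, fast-phase half-life
    T_slow: float = 16.0  # days, slow-phase half-life
    a_inh: float = 0.8  # fast-phase fraction of the inhaled dose
    a_skin: float = 0.3  # fast-phase fraction of the dermal dose (later peak)
    w_inh: float = 0.5  # route weights, sum to 1
    w_skin: float = 0.5
    m_skin: float = 0.8  # maximal fractional dermal dose reduction at SEMI=3
    # concentration-scale effects, ug/L
    baseline: float = 0.05
    beta_smoke: float = 0.15
    beta_bbq: float = 0.02
    beta_otherfire: float = 0.05
    sigma_noise: float = 0.4  # lognormal scale of the multiplicative noise
    # creatinine lognormal (natural-log parameters of mg/dL)
    creat_mu: float = math.log(120.0)
    creat_sigma: float = 0.5
    # assay censoring thresholds, ug/L
    lod: float = biomarker.DEFAULT_LOD_UG_L
    loq: float = biomarker.DEFAULT_LOQ_UG_L
    # cohort structure
    p_multi_deployment: float = 0.45
    delay_min_days: int = 0
    delay_max_days: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.T_fast < self.T_slow):
            raise ConfigurationError(
                f"need 0 < T_fast < T_slow, got {self.T_fast}, {self.T_slow}"
            )
        for name in ("a_inh", "a_skin", "m_skin"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.a_skin >= self.a_inh:
            raise ConfigurationError(
                "a_skin must be < a_inh (dermal uptake peaks later in urine)"
            )
        if abs(self.w_inh + self.w_skin - 1.0) > 1e-9:
            raise ConfigurationError("w_inh + w_skin must equal 1")
        if self.sigma_noise < 0 or self.pm25_sigma < 0:
            raise ConfigurationError("noise scales must be >= 0")
        if self.delay_min_days < 0 or self.delay_max_days < self.delay_min_days:
            raise ConfigurationError("invalid sample-delay range")


def _days(start: dt.date, end: dt.date) -> list[dt.date]:
    return [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]


def generate_grid(config: SimConfig, rng: np.random.Generator | None = None) -> MonitoringGrid:
    """Area-by-day PM2.5 grid declining exponentially from the outbreak.

    Cell values are pm25_base * exp(-pm25_decay * day_index) times mean-one
    lognormal scatter, so with zero decay the grand mean equals pm25_base.
    """
    if not config.areas:
        raise ConfigurationError("no areas configured")
    if config.date_end < config.date_start:
        raise ConfigurationError("empty date range")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    days = _days(config.date_start, config.date_end)
    sig = config.pm25_sigma
    noise = np.exp(
        rng.normal(-0.5 * sig * sig, sig, size=(len(config.areas), len(days)))
    ) if sig > 0 else np.ones((len(config.areas), len(days)))
    values: dict[tuple[str, dt.date], float] = {}
    for i, area in enumerate(config.areas):
        for j, day in enumerate(days):
            trend = config.pm25_base * math.exp(-config.pm25_decay * j)
            values[(area, day)] = trend * float(noise[i, j])
    return MonitoringGrid(values=values)


def _dirichlet_with_floor(rng: np.random.Generator, k: int, floor: float) -> np.ndarray:
    """k fractions summing to 1, each >= floor."""
    raw = rng.dirichlet(np.full(k, 2.0))
    return floor + raw * (1.0 - floor * k)


def _random_deployment(
    rng: np.random.Generator, config: SimConfig, start: dt.date, severe: bool
) -> DeploymentRecord:
    duration = int(rng.integers(2, 8))
    end = min(start + dt.timedelta(days=duration - 1), config.date_end)
    days = _days(start, end)
    lo, hi = (10.0, 24.0) if severe else (6.0, 16.0)
    hours = {d: float(rng.uniform(lo, hi)) for d in days}

    n_areas = int(rng.integers(1, len(config.areas) + 1))
    chosen_areas = [str(a) for a in rng.choice(config.areas, size=n_areas, replace=False)]
    area_fracs = dict(zip(chosen_areas, _dirichlet_with_floor(rng, n_areas, 0.0)))

    tasks = list(config.task_weight_table)
    n_tasks = int(rng.integers(2, min(4, len(tasks)) + 1))
    chosen_tasks = [str(t) for t in rng.choice(tasks, size=n_tasks, replace=False)]
    task_fracs = dict(zip(chosen_tasks, _dirichlet_with_floor(rng, n_tasks, 0.05)))

    rpe = {}
    for task in chosen_tasks:
        device = _DEVICES[rng.choice(len(_DEVICES), p=_DEVICE_P)]
        if device == Device.NONE:
            usage = RPEUsage(device, 0.0, 0.0)
        else:
            usage = RPEUsage(
                device,
                float(rng.beta(2.0, 2.0)),
                float(rng.choice(_CHANGE_LEVELS)),
            )
        rpe[task] = usage
    return DeploymentRecord(
        start_date=start,
        end_date=end,
        shift_hours=hours,
        area_fractions={k: float(v) for k, v in area_fracs.items()},
        task_fractions={k: float(v) for k, v in task_fracs.items()},
        rpe_usage=rpe,
    )


def compute_exposure_summary(
    record: FirefighterRecord, grid: MonitoringGrid, config: SimConfig
) -> ExposureSummary:
    """Exposure reconstruction for one record, via the exposure model proper."""
    first = record.deployments[0]
    env_first = cumulative_env_exposure(first, grid)
    env_total = total_exposure_all_deployments(record, grid)
    tf = task_smoke_factor(first.task_fractions, config.task_weight_table)
    return ExposureSummary(
        subject_id=record.subject_id,
        env_first=env_first,
        env_total=env_total,
        task_factor=tf,
        exposure_index=exposure_index(env_first, tf),
        rpe_index=rpe_quotient(first),
        semi=semi_score(record.hygiene),
    )


def _phase_mix(t: float, a_fast: float, config: SimConfig) -> float:
    return a_fast * 2.0 ** (-t / config.T_fast) + (1.0 - a_fast) * 2.0 ** (
        -t / config.T_slow
    )


def route_doses(exposure: ExposureSummary, config: SimConfig) -> tuple[float, float]:
    """Mitigated route doses (D_inh, D_skin) on the concentration scale."""
    E = exposure.exposure_index
    if E < 0:
        raise ValidationError(f"negative exposure index: {E}")
    d_inh = config.w_inh * E * (1.0 - exposure.rpe_index)
    d_skin = config.w_skin * E * (1.0 - config.m_skin * exposure.semi / 3.0)
    return d_inh, d_skin


def concentration_at(
    t: float,
    exposure: ExposureSummary,
    config: SimConfig,
    *,
    current_smoker: bool = False,
    bbq: bool = False,
    other_fire_14d: bool = False,
) -> float:
    """Noise-free urinary 1-HP concentration (ug/L) at delay t days."""
    if t < 0:
        raise ValidationError(f"negative delay: {t}")
    d_inh, d_skin = route_doses(exposure, config)
    conc = (
        d_inh * _phase_mix(t, config.a_inh, config)
        + d_skin * _phase_mix(t, config.a_skin, config)
        + config.baseline
        + config.beta_smoke * current_smoker
        + config.beta_bbq * bbq
        + config.beta_otherfire * other_fire_14d
    )
    return conc


def simulate_hp(
    record: FirefighterRecord,
    exposure: ExposureSummary,
    config: SimConfig,
    *,
    collection_date: dt.date | None = None,
    rng: np.random.Generator | None = None,
) -> UrineSample:
    """Draw a urine sample from the two-compartment excretion model.

    The multiplicative lognormal noise has mean one, so the noise-free
    :func:`concentration_at` value is also the conditional expectation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if collection_date is None:
        delay = int(rng.integers(config.delay_min_days, config.delay_max_days + 1))
        collection_date = record.last_deployment_end + dt.timedelta(days=delay)
    t = (collection_date - record.last_deployment_end).days
    if t < 0:
        raise ValidationError("collection before end of last deployment")
    conc = concentration_at(
        float(t),
        exposure,
        config,
        current_smoker=record.smoking_status == SmokingStatus.CURRENT,
        bbq=record.bbq_last_48h,
        other_fire_14d=record.other_fire_14d,
    )
    if config.sigma_noise > 0:
        s = config.sigma_noise
        conc *= math.exp(rng.normal(-0.5 * s * s, s))
    creat = float(np.exp(rng.normal(config.creat_mu, config.creat_sigma)))
    return UrineSample(
        hp_ug_per_L=conc,
        below_lod=conc < config.lod,
        below_loq=conc < config.loq,
        creatinine_mg_per_dL=creat,
        collection_date=collection_date,
    )


def generate_cohort(
    config: SimConfig, grid: MonitoringGrid
) -> list[FirefighterRecord]:
    """Generate a full cohort with samples, deterministic under config.seed."""
    if config.n_subjects < 0:
        raise ConfigurationError(f"n_subjects must be >= 0, got {config.n_subjects}")
    rng = np.random.default_rng(config.seed)
    window_days = (config.date_end - config.date_start).days + 1
    cohort: list[FirefighterRecord] = []
    for i in range(config.n_subjects):
        service = _SERVICES[rng.choice(3, p=_SERVICE_P)]
        # services differ in deployment timing: B and C were engaged from the
        # first days; only some of A saw the severe early phase
        if service == "A":
            start_off = int(rng.integers(0, min(21, window_days)))
        else:
            start_off = int(rng.integers(0, min(6, window_days)))
        start = config.date_start + dt.timedelta(days=start_off)
        severe = start_off < 6
        deployments = [_random_deployment(rng, config, start, severe)]
        if rng.random() < config.p_multi_deployment:
            n_extra = int(rng.integers(1, 3))
            for _ in range(n_extra):
                gap = int(rng.integers(2, 11))
                nxt = deployments[-1].end_date + dt.timedelta(days=gap)
                if nxt > config.date_end:
                    break
                deployments.append(_random_deployment(rng, config, nxt, False))
        hygiene = HygieneAccess(
            wash_in_breaks=bool(rng.random() < 0.55),
            shower_between_shifts=bool(rng.random() < 0.6),
            clean_clothes=bool(rng.random() < 0.6),
        )
        other_14 = bool(rng.random() < 0.15)
        record = FirefighterRecord(
            subject_id=f"FF{i:04d}",
            sex="male" if rng.random() < 0.94 else "female",
            age=float(np.clip(rng.normal(36.0, 9.0), 20.0, 65.0)),
            bmi=float(np.clip(rng.normal(29.0, 3.5), 20.0, 47.0)),
            smoking_status=_SMOKING[rng.choice(3, p=_SMOKING_P)],
            bbq_last_48h=bool(rng.random() < 0.38),
            role_firefighter=bool(rng.random() < 0.88),
            other_fire_14d=other_14,
            other_fire_3d=bool(other_14 and rng.random() < 0.3),
            fire_service=service,
            deployments=deployments,
            hygiene=hygiene,
        )
        summary = compute_exposure_summary(record, grid, config)
        record.sample = simulate_hp(record, summary, config, rng=rng)
        cohort.append(record)
    return cohort


def regenerate(config: SimConfig, seed: int | None = None):
    """Convenience: (grid, cohort) for a config, optionally re-seeded."""
    cfg = config if seed is None else replace(config, seed=seed)
    grid = generate_grid(cfg)
    return grid, generate_cohort(cfg, grid)
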