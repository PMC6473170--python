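"""Environmental and task-weighted exposure reconstruction.

The exposure model turns a firefighter's self-reported deployment diary and
an area-by-day PM2.5 grid into three quantities used downstream:

* cumulative environmental exposure over the first deployment, in
  ug/m3-day-equivalents: each day contributes (hours worked / 24) times the
  time-share-weighted mean PM2.5 over the areas worked that day;
* a dimensionless task smoke factor on the 1-5 visible-smoke scale, the
  time-weighted mean of per-task smoke weightings (patrolling 2.7 up to
  actively attacking the fire 4.1);
* the composite exposure index, the product of the two divided by 1000.

A total over all deployments (environmental only, no task weighting) is also
provided for subjects with repeat rotations.
"""
from __future__ import annotations

from .types import (
    FRACTION_TOL,
    DeploymentRecord,
    FirefighterRecord,
    MissingDataError,
    MonitoringGrid,
    ValidationError,
)

__all__ = [
    "DEFAULT_TASK_WEIGHTS",
    "cumulative_env_exposure",
    "task_smoke_factor",
    "exposure_index",
    "total_exposure_all_deployments",
]

# Smoke-intensity weightings on the five-point visible-smoke scale. The two
# endpoints (patrol 2.7, attack 4.1) are the published cohort means; the four
# intermediate tasks are documented interpolations on that range (see
# docs/methods.md) and are configurable.
DEFAULT_TASK_WEIGHTS: dict[str, float] = {
    "actively_attacking": 4.1,
    "overhauling_hotspots": 3.8,
    "backburn": 3.6,
    "protection_unburnt": 3.1,
    "driving_operating": 2.9,
    "patrolling": 2.7,
}


def cumulative_env_exposure(
    deployment: DeploymentRecord, grid: MonitoringGrid
) -> float:
    """Cumulative PM2.5 exposure over one deployment, ug/m3-day-equivalents.

    Sum over days of (hours/24) x sum over areas of fraction x PM2.5(area, day).
    Missing grid cells raise :class:`MissingDataError` naming the cell; they
    are never imputed to zero.
    """
    total = 0.0
    for day in deployment.days:
        hours = deployment.shift_hours.get(day, 0.0)
        if hours == 0.0:
            continue
        day_pm = sum(
            frac * grid.pm25(area, day)
            for area, frac in deployment.area_fractions.items()
        )
        total += (hours / 24.0) * day_pm
    return total


def task_smoke_factor(
    task_fractions: dict[str, float],
    weight_table: dict[str, float] | None = None,
) -> float:
    """Time-weighted task smoke factor, sum of fraction x weight over tasks.

    Lies within [min weight, max weight] of the table because the fractions
    form a convex combination.
    """
    weights = DEFAULT_TASK_WEIGHTS if weight_table is None else weight_table
    unknown = sorted(set(task_fractions) - set(weights))
    if unknown:
        raise MissingDataError(
            f"unknown task(s) {unknown}; permitted tasks: {sorted(weights)}"
        )
    s = sum(task_fractions.values())
    if abs(s - 1.0) > FRACTION_TOL:
        raise ValidationError(f"task fractions sum to {s}, expected 1")
    return sum(frac * weights[task] for task, frac in task_fractions.items())


def exposure_index(env: float, task_factor: float) -> float:
    """Composite exposure index: env x task_factor / 1000."""
    if env < 0 or task_factor < 0:
        raise ValidationError("exposure inputs must be non-negative")
    return env * task_factor / 1000.0


def total_exposure_all_deployments(
    record: FirefighterRecord, grid: MonitoringGrid
) -> float:
    """Environmental exposure summed over every deployment, task-unweighted."""
    return sum(cumulative_env_exposure(d, grid) for d in record.deployments)
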