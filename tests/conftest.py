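import datetime as dt

import numpy as np
import pytest

from firesmoke.types import (
    DeploymentRecord,
    Device,
    FirefighterRecord,
    HygieneAccess,
    MonitoringGrid,
    RPEUsage,
    SmokingStatus,
)

MAY = dt.date(2016, 5, 1)


def day(offset: int) -> dt.date:
    return MAY + dt.timedelta(days=offset)


def make_deployment(
    start=day(1),
    n_days=3,
    hours=12.0,
    areas=None,
    tasks=None,
    rpe=None,
):
    days = [start + dt.timedelta(days=i) for i in range(n_days)]
    end = days[-1]
    areas = {"downtown": 1.0} if areas is None else areas
    tasks = {"patrolling": 1.0} if tasks is None else tasks
    if rpe is None:
        rpe = {t: RPEUsage(Device.NONE, 0.0, 0.0) for t in tasks}
    shift_hours = hours if isinstance(hours, dict) else {d: hours for d in days}
    return DeploymentRecord(
        start_date=start,
        end_date=end,
        shift_hours=shift_hours,
        area_fractions=areas,
        task_fractions=tasks,
        rpe_usage=rpe,
    )


def make_record(
    subject_id="FF0000",
    deployments=None,
    hygiene=None,
    smoking=SmokingStatus.NEVER,
    sample=None,
    **kwargs,
):
    fields = dict(
        sex="male",
        age=35.0,
        bmi=27.0,
        bbq_last_48h=False,
        role_firefighter=True,
        other_fire_14d=False,
        other_fire_3d=False,
        fire_service="A",
    )
    fields.update(kwargs)
    return FirefighterRecord(
        subject_id=subject_id,
        smoking_status=smoking,
        deployments=deployments or [make_deployment()],
        hygiene=hygiene or HygieneAccess(True, True, True),
        sample=sample,
        **fields,
    )


def constant_grid(value=100.0, areas=("downtown", "north", "south"), n_days=60):
    return MonitoringGrid(
        values={(a, day(i)): value for a in areas for i in range(n_days)}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
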