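"""Respiratory-protection quotient and skin-hygiene mitigation index.

The RPE use quotient scores how much respiratory protection a firefighter
actually obtained over the first deployment, anchored at 0 (never used any
device) and 1 (self-contained breathing apparatus worn correctly throughout).
Within each task the per-task protection is

    p_task = fraction_worn x change_adequacy x (1 - 1/PF(device))

with PF the assigned protection factor of the device class, and the quotient
is the task-time-weighted sum of p_task. SCBA supplies its own air, so its
(1 - 1/PF) term is treated as exactly 1, which makes the score-1 anchor
attainable. This per-task form is a documented reconstruction chosen to
satisfy both anchors and monotonicity in wear time, change frequency and PF.

The Skin Exposure Mitigation Index (SEMI) counts, 0-3, the hygiene
opportunities available: washing during breaks, showering between shifts,
clean clothes.
"""
from __future__ import annotations

import math

from .types import (
    FRACTION_TOL,
    DeploymentRecord,
    Device,
    HygieneAccess,
    MissingDataError,
    ValidationError,
)

__all__ = [
    "DEFAULT_PF_TABLE",
    "DEFAULT_CHANGE_FREQUENCY_MAP",
    "rpe_quotient",
    "semi_score",
]

# Conventional assigned protection factors by device class (configurable).
# none -> PF 1 so (1 - 1/PF) = 0; SCBA uses the supplied-air convention
# (1 - 1/PF) = 1, represented by PF = +inf.
DEFAULT_PF_TABLE: dict[Device, float] = {
    Device.NONE: 1.0,
    Device.DUST_MASK: 3.0,
    Device.HALF_FACE: 10.0,
    Device.FULL_FACE: 50.0,
    Device.SCBA: math.inf,
}

# Lookup mapping the questionnaire's categorical mask/filter change-frequency
# answer onto the [0,1] change_adequacy scale (1 = changed as recommended).
DEFAULT_CHANGE_FREQUENCY_MAP: dict[str, float] = {
    "never": 0.0,
    "rarely": 0.25,
    "sometimes": 0.5,
    "often": 0.75,
    "as_recommended": 1.0,
}


def _validate_pf_table(pf_table: dict[Device, float]) -> None:
    for device, pf in pf_table.items():
        if pf < 1.0:
            raise ValidationError(f"protection factor for {device} below 1: {pf}")
    if Device.SCBA in pf_table:
        if pf_table[Device.SCBA] < max(pf_table.values()):
            raise ValidationError("SCBA must carry the maximal protection factor")


def rpe_quotient(
    deployment: DeploymentRecord,
    pf_table: dict[Device, float] | None = None,
) -> float:
    """Respiratory-protection use quotient over one deployment, in [0, 1].

    0 when no device was ever used; 1 when SCBA was worn for the whole of
    every task with fully adequate change frequency.
    """
    table = DEFAULT_PF_TABLE if pf_table is None else pf_table
    _validate_pf_table(table)
    fracs = deployment.task_fractions
    s = sum(fracs.values())
    if abs(s - 1.0) > FRACTION_TOL:
        raise ValidationError(f"task fractions sum to {s}, expected 1")
    total = 0.0
    for task, frac in fracs.items():
        usage = deployment.rpe_usage.get(task)
        if usage is None:
            raise MissingDataError(f"no RPE usage recorded for task {task!r}")
        if usage.device not in table:
            raise MissingDataError(
                f"device {usage.device!r} not in protection factor table; "
                f"known devices: {sorted(d.value for d in table)}"
            )
        pf = table[usage.device]
        efficiency = 1.0 - 1.0 / pf  # == 1 exactly for PF = inf (SCBA)
        total += frac * usage.fraction_worn * usage.change_adequacy * efficiency
    # guard against float drift at the anchors
    return min(max(total, 0.0), 1.0)


def semi_score(h: HygieneAccess) -> int:
    """Skin Exposure Mitigation Index: count of available hygiene opportunities."""
    answers = {
        "wash_in_breaks": h.wash_in_breaks,
        "shower_between_shifts": h.shower_between_shifts,
        "clean_clothes": h.clean_clothes,
    }
    missing = [k for k, v in answers.items() if v is None]
    if missing:
        raise MissingDataError(f"missing hygiene answer(s): {missing}")
    return sum(bool(v) for v in answers.values())
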