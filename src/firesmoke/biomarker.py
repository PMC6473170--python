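"""Urinary 1-hydroxypyrene handling rules.

Order is fixed: censoring substitution happens on the ug/L concentration
scale *before* creatinine correction, and the creatinine-range exclusion is
applied last. :func:`process_samples` is the single composite entry point so
the order cannot be permuted by callers.

Censored values are replaced by threshold/sqrt(2): below-LoD measurements by
LoD/sqrt(2) and below-LOQ (but detected) measurements by LOQ/sqrt(2), the
standard substitution for left-censored environmental data. With the default
LoD/LOQ of 0.0099/0.0198 ug/L the substituted values are 0.0070 and
0.0140 ug/L.

Creatinine correction reports ng of 1-HP per g creatinine:
(hp ug/L x 1000 ng/ug) / (creatinine mg/dL x 0.01 g/L per mg/dL).
Samples with creatinine < 30 or > 300 mg/dL (strict inequalities; the
boundaries are retained) are flagged excluded.
"""
from __future__ import annotations

import math
from typing import Iterable, Sequence

from .types import (
    ConfigurationError,
    ProcessedSample,
    UrineSample,
    ValidationError,
)

__all__ = [
    "DEFAULT_LOD_UG_L",
    "DEFAULT_LOQ_UG_L",
    "CREATININE_MIN_MG_DL",
    "CREATININE_MAX_MG_DL",
    "substitute_censored",
    "creatinine_correct",
    "apply_exclusions",
    "process_samples",
]

DEFAULT_LOD_UG_L = 0.0099
DEFAULT_LOQ_UG_L = 0.0198
CREATININE_MIN_MG_DL = 30.0
CREATININE_MAX_MG_DL = 300.0

_SQRT2 = math.sqrt(2.0)


def substitute_censored(
    sample: UrineSample,
    lod: float = DEFAULT_LOD_UG_L,
    loq: float = DEFAULT_LOQ_UG_L,
) -> float:
    """Concentration in ug/L after left-censoring substitution.

    below_lod -> lod/sqrt(2); below_loq only -> loq/sqrt(2); otherwise the
    measured value unchanged.
    """
    if lod <= 0:
        raise ConfigurationError(f"lod must be > 0, got {lod}")
    if loq < lod:
        raise ConfigurationError(f"loq ({loq}) must be >= lod ({lod})")
    if sample.below_lod:
        return lod / _SQRT2
    if sample.below_loq:
        return loq / _SQRT2
    return sample.hp_ug_per_L


def creatinine_correct(hp_ug_per_L: float, creatinine_mg_per_dL: float) -> float:
    """1-HP normalized to urinary creatinine, ng/g creatinine."""
    if creatinine_mg_per_dL <= 0:
        raise ValidationError(
            f"creatinine must be > 0 mg/dL, got {creatinine_mg_per_dL}"
        )
    if hp_ug_per_L < 0:
        raise ValidationError(f"hp concentration must be >= 0, got {hp_ug_per_L}")
    ng_per_L = hp_ug_per_L * 1000.0
    g_creat_per_L = creatinine_mg_per_dL * 0.01
    return ng_per_L / g_creat_per_L


def _exclusion_reason(creatinine: float) -> str:
    if creatinine < CREATININE_MIN_MG_DL:
        return "creatinine_low"
    if creatinine > CREATININE_MAX_MG_DL:
        return "creatinine_high"
    return "none"


def apply_exclusions(
    samples: Sequence[tuple[str, float, float, str]],
) -> list[ProcessedSample]:
    """Flag creatinine-range exclusions on already-substituted, corrected rows.

    Each row is (subject_id, hp_ng_per_g_creat, creatinine_mg_per_dL,
    substituted_flag). Exclusion is strict: creatinine < 30 or > 300 mg/dL;
    30 and 300 exactly are retained.
    """
    out = []
    for subject_id, hp_ng_g, creat, substituted in samples:
        reason = _exclusion_reason(creat)
        out.append(
            ProcessedSample(
                subject_id=subject_id,
                hp_ng_per_g_creat=hp_ng_g,
                excluded=reason != "none",
                exclusion_reason=reason,
                substituted=substituted,
            )
        )
    return out


def process_samples(
    samples: Iterable[tuple[str, UrineSample]],
    lod: float = DEFAULT_LOD_UG_L,
    loq: float = DEFAULT_LOQ_UG_L,
) -> list[ProcessedSample]:
    """Full handling pipeline: substitution -> creatinine correction -> exclusion."""
    rows = []
    for subject_id, sample in samples:
        conc = substitute_censored(sample, lod=lod, loq=loq)
        substituted = "lod" if sample.below_lod else ("loq" if sample.below_loq else "none")
        hp_ng_g = creatinine_correct(conc, sample.creatinine_mg_per_dL)
        rows.append((subject_id, hp_ng_g, sample.creatinine_mg_per_dL, substituted))
    return apply_exclusions(rows)
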