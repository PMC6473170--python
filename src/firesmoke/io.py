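"""Schema-validated delimited-text I/O for every pipeline table.

All file access in the package flows through this module. Tables are plain
CSV (comma, UTF-8, "." decimal, ISO-8601 dates) with an explicit header;
floats are written with ``repr`` so a write/read round trip is exact. Schema
violations raise with file, line and column so questionnaire-scale data can
be fixed by hand.

Column dictionary (long formats):

* ``cohort.csv`` — subject_id, fire_service, sex, age (years), bmi (kg/m2),
  smoking_status (current|ex|never), bbq_last_48h, role_firefighter,
  other_fire_14d, other_fire_3d, wash_in_breaks, shower_between_shifts,
  clean_clothes (booleans: true|false, hygiene answers may be the empty
  string for a missing answer)
* ``deployments.csv`` — subject_id, deployment_index, start_date, end_date
* ``shifts.csv`` — subject_id, deployment_index, date, hours (0-24, hours
  actively fighting within that 24 h)
* ``areas.csv`` — subject_id, deployment_index, area, fraction (time share)
* ``rpe.csv`` — subject_id, deployment_index, task, task_fraction, device
  (none|dust_mask|half_face|full_face|scba), fraction_worn, change_adequacy
* ``samples.csv`` — subject_id, hp_ug_per_L, below_lod, below_loq,
  creatinine_mg_per_dL, collection_date
* ``pm25_grid.csv`` — area, date, pm25 (ug/m3, mean 24-h)
* ``config.json`` — machine-readable echo of the generating configuration
"""
from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import json
import math
from pathlib import Path
from typing import Any, Callable, Sequence

from .types import (
    DeploymentRecord,
    Device,
    FirefighterRecord,
    HygieneAccess,
    MonitoringGrid,
    ProcessedSample,
    RPEUsage,
    SmokingStatus,
    UrineSample,
    ValidationError,
)

__all__ = [
    "Column",
    "read_table",
    "write_table",
    "write_cohort",
    "read_cohort",
    "write_processed_samples",
    "COHORT_SCHEMA",
    "GRID_SCHEMA",
]


def _parse_bool(s: str) -> bool:
    if s == "true":
        return True
    if s == "false":
        return False
    raise ValueError(f"expected 'true' or 'false', got {s!r}")


def _parse_opt_bool(s: str) -> bool | None:
    return None if s == "" else _parse_bool(s)


def _parse_date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def _fmt(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, dt.date):
        return value.isoformat()
    return str(value)


@dataclasses.dataclass(frozen=True)
class Column:
    name: str
    parse: Callable[[str], Any]
    check: Callable[[Any], bool] | None = None
    description: str = ""


def _nonneg(x: float) -> bool:
    return x >= 0 and not math.isnan(x)


COHORT_SCHEMA = [
    Column("subject_id", str),
    Column("fire_service", str),
    Column("sex", str, lambda v: v in ("male", "female")),
    Column("age", float, lambda v: 0 < v < 120),
    Column("bmi", float, lambda v: 5 < v < 100),
    Column("smoking_status", SmokingStatus),
    Column("bbq_last_48h", _parse_bool),
    Column("role_firefighter", _parse_bool),
    Column("other_fire_14d", _parse_bool),
    Column("other_fire_3d", _parse_bool),
    Column("wash_in_breaks", _parse_opt_bool),
    Column("shower_between_shifts", _parse_opt_bool),
    Column("clean_clothes", _parse_opt_bool),
]

DEPLOYMENTS_SCHEMA = [
    Column("subject_id", str),
    Column("deployment_index", int, lambda v: v >= 0),
    Column("start_date", _parse_date),
    Column("end_date", _parse_date),
]

SHIFTS_SCHEMA = [
    Column("subject_id", str),
    Column("deployment_index", int, lambda v: v >= 0),
    Column("date", _parse_date),
    Column("hours", float, lambda v: 0 <= v <= 24),
]

AREAS_SCHEMA = [
    Column("subject_id", str),
    Column("deployment_index", int, lambda v: v >= 0),
    Column("area", str),
    Column("fraction", float, lambda v: 0 <= v <= 1),
]

RPE_SCHEMA = [
    Column("subject_id", str),
    Column("deployment_index", int, lambda v: v >= 0),
    Column("task", str),
    Column("task_fraction", float, lambda v: 0 <= v <= 1),
    Column("device", Device),
    Column("fraction_worn", float, lambda v: 0 <= v <= 1),
    Column("change_adequacy", float, lambda v: 0 <= v <= 1),
]

SAMPLES_SCHEMA = [
    Column("subject_id", str),
    Column("hp_ug_per_L", float, _nonneg),
    Column("below_lod", _parse_bool),
    Column("below_loq", _parse_bool),
    Column("creatinine_mg_per_dL", float, _nonneg),
    Column("collection_date", _parse_date),
]

GRID_SCHEMA = [
    Column("area", str),
    Column("date", _parse_date),
    Column("pm25", float, _nonneg),
]


def read_table(path: str | Path, schema: Sequence[Column]) -> list[dict[str, Any]]:
    """Read and validate one CSV table; errors carry file, line and column."""
    path = Path(path)
    expected = [c.name for c in schema]
    rows: list[dict[str, Any]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file, expected header {expected}")
        if header != expected:
            raise ValidationError(
                f"{path}: header mismatch; expected {expected}, got {header}"
            )
        for lineno, raw in enumerate(reader, start=2):
            if len(raw) != len(schema):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(schema)} fields, got {len(raw)}"
                )
            row: dict[str, Any] = {}
            for col, cell in zip(schema, raw):
                try:
                    value = col.parse(cell)
                except (ValueError, KeyError):
                    raise ValidationError(
                        f"{path}:{lineno}: column {col.name!r}: "
                        f"cannot parse {cell!r}"
                    ) from None
                if col.check is not None and value is not None and not col.check(value):
                    raise ValidationError(
                        f"{path}:{lineno}: column {col.name!r}: "
                        f"value {cell!r} out of range"
                    )
                row[col.name] = value
            rows.append(row)
    return rows


def write_table(
    path: str | Path, schema: Sequence[Column], rows: Sequence[dict[str, Any]]
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([c.name for c in schema])
        for row in rows:
            writer.writerow([_fmt(row[c.name]) for c in schema])


# ---------------------------------------------------------------------------
# cohort-level round trip

_FILES = {
    "cohort": ("cohort.csv", COHORT_SCHEMA),
    "deployments": ("deployments.csv", DEPLOYMENTS_SCHEMA),
    "shifts": ("shifts.csv", SHIFTS_SCHEMA),
    "areas": ("areas.csv", AREAS_SCHEMA),
    "rpe": ("rpe.csv", RPE_SCHEMA),
    "samples": ("samples.csv", SAMPLES_SCHEMA),
    "grid": ("pm25_grid.csv", GRID_SCHEMA),
}


def write_cohort(
    cohort: Sequence[FirefighterRecord],
    grid: MonitoringGrid,
    path: str | Path,
    config: Any | None = None,
) -> None:
    """Write a cohort and grid as the documented set of CSV tables.

    If ``config`` (a dataclass) is given, a machine-readable echo is written
    to ``config.json`` alongside the tables.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, list[dict[str, Any]]] = {k: [] for k in _FILES}
    for rec in cohort:
        h = rec.hygiene
        tables["cohort"].append(
            {
                "subject_id": rec.subject_id,
                "fire_service": rec.fire_service,
                "sex": rec.sex,
                "age": rec.age,
                "bmi": rec.bmi,
                "smoking_status": rec.smoking_status.value,
                "bbq_last_48h": rec.bbq_last_48h,
                "role_firefighter": rec.role_firefighter,
                "other_fire_14d": rec.other_fire_14d,
                "other_fire_3d": rec.other_fire_3d,
                "wash_in_breaks": h.wash_in_breaks,
                "shower_between_shifts": h.shower_between_shifts,
                "clean_clothes": h.clean_clothes,
            }
        )
        for di, dep in enumerate(rec.deployments):
            tables["deployments"].append(
                {
                    "subject_id": rec.subject_id,
                    "deployment_index": di,
                    "start_date": dep.start_date,
                    "end_date": dep.end_date,
                }
            )
            for day in sorted(dep.shift_hours):
                tables["shifts"].append(
                    {
                        "subject_id": rec.subject_id,
                        "deployment_index": di,
                        "date": day,
                        "hours": dep.shift_hours[day],
                    }
                )
            for area in sorted(dep.area_fractions):
                tables["areas"].append(
                    {
                        "subject_id": rec.subject_id,
                        "deployment_index": di,
                        "area": area,
                        "fraction": dep.area_fractions[area],
                    }
                )
            for task in sorted(dep.task_fractions):
                usage = dep.rpe_usage[task]
                tables["rpe"].append(
                    {
                        "subject_id": rec.subject_id,
                        "deployment_index": di,
                        "task": task,
                        "task_fraction": dep.task_fractions[task],
                        "device": usage.device.value,
                        "fraction_worn": usage.fraction_worn,
                        "change_adequacy": usage.change_adequacy,
                    }
                )
        if rec.sample is not None:
            s = rec.sample
            tables["samples"].append(
                {
                    "subject_id": rec.subject_id,
                    "hp_ug_per_L": s.hp_ug_per_L,
                    "below_lod": s.below_lod,
                    "below_loq": s.below_loq,
                    "creatinine_mg_per_dL": s.creatinine_mg_per_dL,
                    "collection_date": s.collection_date,
                }
            )
    for (area, day) in sorted(grid.values):
        tables["grid"].append(
            {"area": area, "date": day, "pm25": grid.values[(area, day)]}
        )
    for key, (fname, schema) in _FILES.items():
        write_table(outdir / fname, schema, tables[key])
    if config is not None:
        echo = dataclasses.asdict(config)
        with (outdir / "config.json").open("w", encoding="utf-8") as fh:
            json.dump(echo, fh, indent=2, sort_keys=True, default=_fmt)
            fh.write("\n")


def read_cohort(path: str | Path) -> tuple[list[FirefighterRecord], MonitoringGrid]:
    """Read the table set written by :func:`write_cohort` back into records."""
    indir = Path(path)
    raw = {
        key: read_table(indir / fname, schema)
        for key, (fname, schema) in _FILES.items()
    }
    deps: dict[str, dict[int, dict[str, Any]]] = {}
    for row in raw["deployments"]:
        deps.setdefault(row["subject_id"], {})[row["deployment_index"]] = {
            "start_date": row["start_date"],
            "end_date": row["end_date"],
            "shift_hours": {},
            "area_fractions": {},
            "task_fractions": {},
            "rpe_usage": {},
        }

    def _dep(sid: str, di: int, path_name: str) -> dict[str, Any]:
        try:
            return deps[sid][di]
        except KeyError:
            raise ValidationError(
                f"{path_name}: deployment ({sid!r}, {di}) not in deployments.csv"
            ) from None

    for row in raw["shifts"]:
        _dep(row["subject_id"], row["deployment_index"], "shifts.csv")[
            "shift_hours"
        ][row["date"]] = row["hours"]
    for row in raw["areas"]:
        _dep(row["subject_id"], row["deployment_index"], "areas.csv")[
            "area_fractions"
        ][row["area"]] = row["fraction"]
    for row in raw["rpe"]:
        d = _dep(row["subject_id"], row["deployment_index"], "rpe.csv")
        d["task_fractions"][row["task"]] = row["task_fraction"]
        d["rpe_usage"][row["task"]] = RPEUsage(
            device=row["device"],
            fraction_worn=row["fraction_worn"],
            change_adequacy=row["change_adequacy"],
        )
    samples = {
        row["subject_id"]: UrineSample(
            hp_ug_per_L=row["hp_ug_per_L"],
            below_lod=row["below_lod"],
            below_loq=row["below_loq"],
            creatinine_mg_per_dL=row["creatinine_mg_per_dL"],
            collection_date=row["collection_date"],
        )
        for row in raw["samples"]
    }
    cohort = []
    for row in raw["cohort"]:
        sid = row["subject_id"]
        dep_records = [
            DeploymentRecord(**deps[sid][di]) for di in sorted(deps.get(sid, {}))
        ]
        cohort.append(
            FirefighterRecord(
                subject_id=sid,
                sex=row["sex"],
                age=row["age"],
                bmi=row["bmi"],
                smoking_status=row["smoking_status"],
                bbq_last_48h=row["bbq_last_48h"],
                role_firefighter=row["role_firefighter"],
                other_fire_14d=row["other_fire_14d"],
                other_fire_3d=row["other_fire_3d"],
                fire_service=row["fire_service"],
                deployments=dep_records,
                hygiene=HygieneAccess(
                    wash_in_breaks=row["wash_in_breaks"],
                    shower_between_shifts=row["shower_between_shifts"],
                    clean_clothes=row["clean_clothes"],
                ),
                sample=samples.get(sid),
            )
        )
    grid = MonitoringGrid(
        values={(row["area"], row["date"]): row["pm25"] for row in raw["grid"]}
    )
    return cohort, grid


PROCESSED_SCHEMA = [
    Column("subject_id", str),
    Column("hp_ng_per_g_creat", float, _nonneg),
    Column("excluded", _parse_bool),
    Column("exclusion_reason", str),
    Column("substituted", str),
]


def write_report(report: Any, out: str | Path) -> None:
    """Write an :class:`~firesmoke.analysis.AnalysisReport` as CSV tables
    plus a plain-text rendering under ``out``."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.txt").write_text(report.render(), encoding="utf-8")
    if report.confounder_model is not None:
        report.confounder_model.table.to_csv(out / "confounder_model.csv")
    for name, model in report.subgroup_models.items():
        if model is not None:
            model.table.to_csv(out / f"model_{name}.csv")
    for name, att in report.attrition.items():
        att.to_csv(out / f"attrition_{name}.csv", index=False)
    if report.hygiene_table is not None:
        report.hygiene_table.to_csv(out / "hygiene_table.csv", index=False)


def write_processed_samples(
    path: str | Path, processed: Sequence[ProcessedSample]
) -> None:
    write_table(
        path,
        PROCESSED_SCHEMA,
        [dataclasses.asdict(p) for p in processed],
    )
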