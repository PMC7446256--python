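"""File formats: fraction tables, patients, resections, reports, PK configs.

Conventions: UTF-8, comma-separated CSV with a mandatory header row and dot
decimals; machine outputs key regions by slug id, human-readable tables use
the display names; JSON outputs carry full precision plus the tool version
and the registry checksum so any report is traceable to the fraction table
it was computed against. Format is dispatched on file extension
(.csv / .json / .yaml / .yml).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .anthropometry import PatientRecord
from .cohort import CohortMatrix, CohortSummary, ComparisonResult
from .pk import UNIT_CONVENTIONS, PKScenario, PKTrajectory, SensitivityRow
from .regions import RegionRegistry, build_registry
from .resection import ResectionRecord, SurfaceReport

__all__ = [
    "IOError_",
    "RunConfig",
    "read_fraction_table",
    "write_fraction_table",
    "read_registry",
    "write_registry",
    "read_patients",
    "write_patients",
    "read_resections",
    "write_resections",
    "write_report",
    "render_report_table",
    "write_cohort_matrix",
    "write_cohort_summary",
    "read_scenario",
    "write_trajectory",
    "write_sensitivity",
]


class IOError_(ValueError):
    """Raised for malformed or wrongly-keyed input files."""


def _load_structured(path: Path) -> Any:
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix.lower() == ".json":
        return json.loads(text)
    raise IOError_(f"unsupported structured format {path.suffix!r} for {path}")


# --- region-fraction tables -------------------------------------------------

def read_fraction_table(path: str | Path) -> dict[str, float]:
    """Read a region→fraction-percent table from CSV or YAML.

    CSV needs columns ``region`` and ``fraction_percent`` (a ``group``
    column, as in the bundled template, is accepted and ignored — group
    membership is fixed by the canonical listing). YAML is a flat
    name→percent mapping.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        missing = {"region", "fraction_percent"} - set(df.columns)
        if missing:
            raise IOError_(f"{path}: missing column(s) {sorted(missing)}")
        return dict(zip(df["region"].astype(str), df["fraction_percent"].astype(float)))
    data = _load_structured(path)
    if not isinstance(data, Mapping):
        raise IOError_(f"{path}: expected a mapping of region name to percent")
    return {str(k): float(v) for k, v in data.items()}


def write_fraction_table(table: Mapping[str, float], path: str | Path) -> None:
    path = Path(path)
    reg = build_registry(table)
    rows = [
        {"region": r.display_name, "group": r.group, "fraction_percent": reg.fractions[r.id]}
        for r in reg.regions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_registry(path: str | Path) -> RegionRegistry:
    """Load a registry either from its JSON serialization or a fraction table."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = _load_structured(path)
        if isinstance(data, Mapping) and "schema_version" in data:
            return RegionRegistry.from_dict(data)
        if isinstance(data, Mapping):
            return build_registry({str(k): float(v) for k, v in data.items()})
        raise IOError_(f"{path}: unrecognized registry JSON")
    return build_registry(read_fraction_table(path))


def write_registry(reg: RegionRegistry, path: str | Path) -> None:
    Path(path).write_text(reg.to_json(indent=2), encoding="utf-8")


# --- patients ---------------------------------------------------------------

_PATIENT_CORE = ("patient_id", "height_cm", "weight_kg")


def read_patients(path: str | Path, check_bounds: bool = True) -> list[PatientRecord]:
    """Read patient records from JSON (list of objects) or CSV.

    Columns beyond patient_id/height_cm/weight_kg become metadata.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = pd.read_csv(path).to_dict(orient="records")
    else:
        data = _load_structured(path)
        rows = data if isinstance(data, list) else data.get("patients")
        if not isinstance(rows, list):
            raise IOError_(f"{path}: expected a list of patient objects")
    out = []
    for row in rows:
        missing = [k for k in _PATIENT_CORE if k not in row or pd.isna(row[k])]
        if missing:
            raise IOError_(f"{path}: patient row missing field(s) {missing}: {row}")
        meta = {k: v for k, v in row.items() if k not in _PATIENT_CORE and not pd.isna(v)}
        out.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                height_cm=float(row["height_cm"]),
                weight_kg=float(row["weight_kg"]),
                metadata=meta,
                check_bounds=check_bounds,
            )
        )
    return out


def write_patients(patients: Sequence[PatientRecord], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {"patient_id": p.patient_id, "height_cm": p.height_cm, "weight_kg": p.weight_kg,
         **dict(p.metadata)}
        for p in patients
    ]
    if path.suffix.lower() == ".csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(rows, indent=2, default=str), encoding="utf-8")


# --- resections -------------------------------------------------------------

def read_resections(path: str | Path) -> list[ResectionRecord]:
    """Read resection records: JSON objects or long-format CSV.

    JSON: ``{"patient_id": ..., "resections": {region_id: percent}}`` or a
    list of such objects. CSV: columns patient_id, region, resected_percent.
    Absent regions mean 0%.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        missing = {"patient_id", "region", "resected_percent"} - set(df.columns)
        if missing:
            raise IOError_(f"{path}: missing column(s) {sorted(missing)}")
        out = []
        for pid, grp in df.groupby("patient_id", sort=False):
            entries = dict(zip(grp["region"].astype(str), grp["resected_percent"].astype(float)))
            out.append(ResectionRecord(patient_id=str(pid), entries=entries))
        return out
    data = _load_structured(path)
    items = data if isinstance(data, list) else [data]
    out = []
    for item in items:
        if not isinstance(item, Mapping) or "patient_id" not in item:
            raise IOError_(f"{path}: resection object needs 'patient_id': {item}")
        entries = {str(k): float(v) for k, v in (item.get("resections") or {}).items()}
        out.append(ResectionRecord(patient_id=str(item["patient_id"]), entries=entries))
    return out


def write_resections(records: Sequence[ResectionRecord], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = [
            {"patient_id": r.patient_id, "region": rid, "resected_percent": y}
            for r in records
            for rid, y in r.entries.items()
        ]
        pd.DataFrame(rows, columns=["patient_id", "region", "resected_percent"]).to_csv(
            path, index=False
        )
    else:
        payload = [
            {"patient_id": r.patient_id, "resections": dict(r.entries)} for r in records
        ]
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")


# --- surface reports --------------------------------------------------------

def write_report(report: SurfaceReport, path: str | Path) -> None:
    """Full-precision JSON report, stamped with tool version."""
    payload = {"tool_version": __version__, **report.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def render_report_table(report: SurfaceReport) -> str:
    """Human-readable per-region table, areas rounded to whole cm²."""
    lines = [
        f"Patient {report.patient_id}   (registry {report.registry_checksum}, "
        f"tool {__version__})",
        f"PSA before CRS: {report.psa_before_cm2:,.0f} cm2   "
        f"after: {report.psa_after_cm2:,.0f} cm2   "
        f"resected: {report.psa_resected_cm2:,.0f} cm2",
        f"Surface ratio before: {report.ratio_before_percent:.1f}%   "
        f"after: {report.ratio_after_percent:.1f}%",
        "",
        f"{'#':>2}  {'Region':<42}{'Group':<7}{'Before':>9}{'Resected':>9}{'After':>9}",
    ]
    for r in report.rows:
        lines.append(
            f"{r.index:>2}  {r.display_name:<42}{r.group:<7}"
            f"{r.area_before_cm2:>9,.0f}{r.area_resected_cm2:>9,.0f}{r.area_after_cm2:>9,.0f}"
        )
    lines.append("")
    for g in report.groups:
        lines.append(
            f"    {g.group:<49}{g.area_before_cm2:>9,.0f}"
            f"{g.area_resected_cm2:>9,.0f}{g.area_after_cm2:>9,.0f}"
        )
    return "\n".join(lines) + "\n"


# --- cohort -----------------------------------------------------------------

def write_cohort_matrix(
    matrix: CohortMatrix, path: str | Path, rounded: bool = False
) -> None:
    """CSV heatmap export: rows = region ids in registry order, cols = patients."""
    df = matrix.values.round(0).astype(int) if rounded else matrix.values
    df.to_csv(Path(path))


def write_cohort_summary(
    summary: CohortSummary,
    path: str | Path,
    comparison: ComparisonResult | None = None,
) -> None:
    payload: dict[str, Any] = {"tool_version": __version__, **summary.to_dict()}
    if comparison is not None:
        payload["before_after_comparison"] = comparison.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


# --- PK ---------------------------------------------------------------------

_SCENARIO_KEYS = {f.name for f in dataclasses.fields(PKScenario)}


def read_scenario(path: str | Path, area_cm2: float | None = None) -> PKScenario:
    """Load a PK scenario from YAML/JSON with explicit unit-bearing keys.

    Unknown keys are rejected; missing keys are named. ``area_cm2`` given
    here (e.g. sourced from a surface report's psa_after) overrides the file.
    """
    path = Path(path)
    data = _load_structured(path)
    if not isinstance(data, Mapping):
        raise IOError_(f"{path}: expected a mapping of scenario parameters")
    data = dict(data)
    if area_cm2 is not None:
        data["area_cm2"] = float(area_cm2)
    unknown = sorted(set(data) - _SCENARIO_KEYS)
    if unknown:
        raise IOError_(f"{path}: unknown scenario key(s): {', '.join(unknown)}")
    required = {"permeability_cm_per_min", "area_cm2", "volume_peritoneal_L",
                "volume_body_L", "dose_mg", "duration_min"}
    missing = sorted(required - set(data))
    if missing:
        raise IOError_(f"{path}: missing scenario key(s): {', '.join(missing)}")
    return PKScenario(**{k: float(v) for k, v in data.items()})


def write_trajectory(traj: PKTrajectory, path: str | Path) -> None:
    """CSV time course with unit-labeled columns."""
    df = pd.DataFrame(
        {
            "time_min": traj.time_min,
            "c_peritoneal_mg_per_L": traj.c_peritoneal_mg_per_L,
            "c_blood_mg_per_L": traj.c_blood_mg_per_L,
            "eliminated_mg": traj.eliminated_mg,
        }
    )
    df.to_csv(Path(path), index=False)


def write_sensitivity(rows: Sequence[SensitivityRow], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    df.to_csv(Path(path), index=False)


# --- run configuration ------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Optional config file backing the CLI flags; unknown keys rejected."""

    registry: str | None = None
    patients: str | None = None
    resections: str | None = None
    out_dir: str = "."
    as_printed_ratio: bool = False
    welch: bool = False
    paired: bool = False
    strict_registry_tolerance: bool = False
    log_level: str = "INFO"
    schema_version: int = 1

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = _load_structured(Path(path))
        if not isinstance(data, Mapping):
            raise IOError_(f"{path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise IOError_(f"{path}: unknown config key(s): {', '.join(unknown)}")
        return cls(**data)
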