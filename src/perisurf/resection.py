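"""Per-region resection arithmetic: from intraoperative percentages to areas.

Each region i contributes X_i percent of the total PSA; the surgeon enters
the resected share y_i ∈ [0, 100] of that region ("0% means no peritoneal
resection, 100% means complete peritoneal resection"). Then

    area_before_i  = PSA_total · X_i / 100
    area_after_i   = area_before_i · (1 − y_i / 100)
    area_resected_i = area_before_i − area_after_i

and the patient-level totals are the sums; PSA_resected = PSA_before −
PSA_after by construction. Conservation (before = resected + after) holds
per region and in aggregate, at full double precision; rounding happens
only at report rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .anthropometry import SurfaceBasis
from .regions import GROUPS, RegionError, RegionRegistry

__all__ = [
    "ResectionRecord",
    "RegionRow",
    "GroupSubtotal",
    "SurfaceReport",
    "region_area_before",
    "apply_resection",
    "surface_ratio",
    "group_summaries",
]


class ResectionError(ValueError):
    """Raised for resection percentages outside [0, 100] or unknown regions."""


@dataclass(frozen=True)
class ResectionRecord:
    """Intraoperative entry: region id → resected percent of that region.

    Unlisted regions default to 0% (no resection). Validity against a
    specific registry (region ids exist) is checked in
    :func:`apply_resection`; the value range is checked here.
    """

    patient_id: str
    entries: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region_id, y in self.entries.items():
            if not isinstance(y, (int, float)) or not math.isfinite(y) or not 0 <= y <= 100:
                raise ResectionError(
                    f"patient {self.patient_id!r}: resected percent for region "
                    f"{region_id!r} must be in [0, 100], got {y!r}"
                )

    def percent(self, region_id: str) -> float:
        return float(self.entries.get(region_id, 0.0))


@dataclass(frozen=True)
class RegionRow:
    region_id: str
    display_name: str
    group: str
    index: int
    fraction_percent: float
    resected_percent: float
    area_before_cm2: float
    area_resected_cm2: float
    area_after_cm2: float


@dataclass(frozen=True)
class GroupSubtotal:
    group: str
    area_before_cm2: float
    area_resected_cm2: float
    area_after_cm2: float


@dataclass(frozen=True)
class SurfaceReport:
    """One patient's per-region and total surface accounting."""

    patient_id: str
    rows: tuple[RegionRow, ...]
    groups: tuple[GroupSubtotal, ...]
    psa_before_cm2: float
    psa_after_cm2: float
    psa_resected_cm2: float
    ratio_before_percent: float
    ratio_after_percent: float
    bsa_cm2: float
    registry_checksum: str

    def group(self, group: str) -> GroupSubtotal:
        for g in self.groups:
            if g.group == group:
                return g
        raise RegionError(f"unknown group {group!r}")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "bsa_cm2": self.bsa_cm2,
            "psa_before_cm2": self.psa_before_cm2,
            "psa_after_cm2": self.psa_after_cm2,
            "psa_resected_cm2": self.psa_resected_cm2,
            "ratio_before_percent": self.ratio_before_percent,
            "ratio_after_percent": self.ratio_after_percent,
            "registry_checksum": self.registry_checksum,
            "groups": [vars(g) for g in self.groups],
            "regions": [vars(r) for r in self.rows],
        }


def region_area_before(reg: RegionRegistry, basis: SurfaceBasis, region_id: str) -> float:
    """Pre-surgery area of one region: PSA_total · X_i / 100 (cm²)."""
    return basis.psa_total_cm2 * reg.fraction(region_id) / 100.0


def surface_ratio(psa_cm2: float, bsa_cm2: float, as_printed: bool = False) -> float:
    """Peritoneal surface ratio, percent: 100 · PSA / BSA.

    ``as_printed=True`` reproduces the literal published arithmetic
    ([PSA/BSA]/100), retained only for auditability — it yields 0.01 for an
    intact peritoneum, not a percentage.
    """
    if not math.isfinite(bsa_cm2) or bsa_cm2 <= 0:
        raise ResectionError(f"bsa_cm2 must be > 0, got {bsa_cm2!r}")
    if psa_cm2 < 0:
        raise ResectionError(f"psa_cm2 must be >= 0, got {psa_cm2!r}")
    ratio = psa_cm2 / bsa_cm2
    return ratio / 100.0 if as_printed else ratio * 100.0


def apply_resection(
    reg: RegionRegistry,
    basis: SurfaceBasis,
    rec: ResectionRecord,
    as_printed_ratio: bool = False,
) -> SurfaceReport:
    """Compute the full surface report for one patient.

    Pure and deterministic; recomputed from scratch on every call so the
    conservation invariants hold after any entry-edit sequence.
    """
    known = set(reg.region_ids)
    unknown = sorted(set(rec.entries) - known)
    if unknown:
        raise ResectionError(
            f"patient {rec.patient_id!r}: unknown region id(s): {', '.join(unknown)}"
        )

    rows = []
    for r in reg.regions:
        before = region_area_before(reg, basis, r.id)
        y = rec.percent(r.id)
        after = before * (1.0 - y / 100.0)
        rows.append(
            RegionRow(
                region_id=r.id,
                display_name=r.display_name,
                group=r.group,
                index=r.index,
                fraction_percent=reg.fractions[r.id],
                resected_percent=y,
                area_before_cm2=before,
                area_resected_cm2=before - after,
                area_after_cm2=after,
            )
        )

    groups = tuple(
        GroupSubtotal(
            group=g,
            area_before_cm2=sum(r.area_before_cm2 for r in rows if r.group == g),
            area_resected_cm2=sum(r.area_resected_cm2 for r in rows if r.group == g),
            area_after_cm2=sum(r.area_after_cm2 for r in rows if r.group == g),
        )
        for g in GROUPS
    )
    psa_before = sum(r.area_before_cm2 for r in rows)
    psa_after = sum(r.area_after_cm2 for r in rows)
    return SurfaceReport(
        patient_id=rec.patient_id,
        rows=tuple(rows),
        groups=groups,
        psa_before_cm2=psa_before,
        psa_after_cm2=psa_after,
        psa_resected_cm2=psa_before - psa_after,
        ratio_before_percent=surface_ratio(psa_before, basis.bsa_cm2, as_printed_ratio),
        ratio_after_percent=surface_ratio(psa_after, basis.bsa_cm2, as_printed_ratio),
        bsa_cm2=basis.bsa_cm2,
        registry_checksum=reg.checksum(),
    )


def group_summaries(report: SurfaceReport, reg: RegionRegistry) -> tuple[GroupSubtotal, ...]:
    """Per-group before/resected/after subtotals, recomputed from the rows.

    Rejects a report whose regions do not match the registry.
    """
    if tuple(r.region_id for r in report.rows) != reg.region_ids:
        raise ResectionError("report regions do not match registry")
    return tuple(
        GroupSubtotal(
            group=g,
            area_before_cm2=sum(r.area_before_cm2 for r in report.rows if r.group == g),
            area_resected_cm2=sum(r.area_resected_cm2 for r in report.rows if r.group == g),
            area_after_cm2=sum(r.area_after_cm2 for r in report.rows if r.group == g),
        )
        for g in GROUPS
    )
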