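"""Canonical 40-region anatomical decomposition of the peritoneum.

The peritoneal surface is partitioned into four groups — supramesocolic
visceral (SMCVP, 16 regions), supramesocolic parietal (SMCPP, 6),
inframesocolic visceral (IMCVP, 12) and inframesocolic parietal (IMCPP, 6) —
for a total of 40 named regions. Each region carries a fractional
contribution ``X_i`` (percent of total peritoneal surface area, PSA); the
fractions must partition 100%.

The numeric fractions are *not* shipped as clinical defaults: published
per-region values exist in the anatomical literature but are a required
user input here. A uniform 2.5% placeholder table (clearly non-clinical)
is bundled for tests and demos.
"""

from __future__ import annotations

import json
import math
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "GROUPS",
    "GROUP_SIZES",
    "CANONICAL_REGIONS",
    "Region",
    "RegionRegistry",
    "ValidationReport",
    "canonicalize",
    "build_registry",
    "validate_registry",
    "group_fraction",
    "uniform_fraction_table",
]

GROUPS = ("SMCVP", "SMCPP", "IMCVP", "IMCPP")
GROUP_SIZES = {"SMCVP": 16, "SMCPP": 6, "IMCVP": 12, "IMCPP": 6}

SCHEMA_VERSION = 1

# Canonical listing in reading order (column by column), giving the stable
# region index 1..40 used by heatmap exports.
CANONICAL_REGIONS: tuple[tuple[str, str], ...] = (
    # Supramesocolic visceral peritoneum (16)
    ("Liver", "SMCVP"),
    ("Gastrocolic ligament", "SMCVP"),
    ("Stomach", "SMCVP"),
    ("Spleen", "SMCVP"),
    ("Transverse mesocolon: superior layer", "SMCVP"),
    ("Lesser omentum", "SMCVP"),
    ("Falciform ligament", "SMCVP"),
    ("Pancreas", "SMCVP"),
    ("Gastrosplenic ligament", "SMCVP"),
    ("Teres ligament", "SMCVP"),
    ("Duodenum", "SMCVP"),
    ("Left triangular ligament", "SMCVP"),
    ("Gall bladder", "SMCVP"),
    ("Lienorenal ligament", "SMCVP"),
    ("Right triangular ligament", "SMCVP"),
    ("Abdominal esophagus", "SMCVP"),
    # Supramesocolic parietal peritoneum (6)
    ("Right diaphragmatic wall", "SMCPP"),
    ("Left diaphragmatic wall", "SMCPP"),
    ("Right antero-lateral supraumbilical wall", "SMCPP"),
    ("Left antero-lateral supraumbilical wall", "SMCPP"),
    ("Right dorsal supracolic parietal wall", "SMCPP"),
    ("Left dorsal supracolic parietal wall", "SMCPP"),
    # Inframesocolic visceral peritoneum (12)
    ("Mesentery", "IMCVP"),
    ("Jejunum-ileum", "IMCVP"),
    ("Greater omentum", "IMCVP"),
    ("Sigmoid colon", "IMCVP"),
    ("Transverse colon", "IMCVP"),
    ("Transverse mesocolon: inferior layer", "IMCVP"),
    ("Caecum v. appendix ascending colon", "IMCVP"),
    ("Sigmoid mesocolon", "IMCVP"),
    ("Uterus and broad ligaments", "IMCVP"),
    ("Rectum", "IMCVP"),
    ("Descending colon", "IMCVP"),
    ("Urinary bladder", "IMCVP"),
    # Inframesocolic parietal peritoneum (6)
    ("Right antero-lateral infraumbilical wall", "IMCPP"),
    ("Left antero-lateral infraumbilical wall", "IMCPP"),
    ("Left dorsal infracolic parietal wall", "IMCPP"),
    ("Right dorsal infracolic parietal wall", "IMCPP"),
    ("Left lateral pelvic wall", "IMCPP"),
    ("Right lateral pelvic wall", "IMCPP"),
)

# Sum-to-100 tolerances, percentage points.
STRICT_TOLERANCE = 1e-6
LENIENT_TOLERANCE = 0.5


class RegionError(ValueError):
    """Raised when a region name, fraction table or registry is invalid."""


def canonicalize(name: str) -> str:
    """Slugify an anatomical region name into a stable machine-safe id.

    Lowercases, strips diacritics and punctuation, and collapses runs of
    whitespace/punctuation into single hyphens. Idempotent.

    >>> canonicalize("Caecum v. appendix ascending colon")
    'caecum-v-appendix-ascending-colon'
    """
    s = unicodedata.normalize("NFKD", name)
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = s.lower()
    s = re.sub(r"[^a-z0-9]+", "-", s)
    return s.strip("-")


@dataclass(frozen=True)
class Region:
    """A single named peritoneal region."""

    id: str
    display_name: str
    group: str
    index: int  # 1-based stable index in canonical order

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise RegionError(f"unknown group {self.group!r}; expected one of {GROUPS}")


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of registry validation: issues with severities, ok iff no error."""

    issues: tuple[tuple[str, str, str], ...] = ()  # (severity, region id or "global", message)

    @property
    def ok(self) -> bool:
        return not any(sev == "error" for sev, _, _ in self.issues)


@dataclass(frozen=True)
class RegionRegistry:
    """The 40 regions in canonical order with their fractional PSA contributions.

    ``fractions[region.id]`` is X_i, the region's percent of total PSA.
    """

    regions: tuple[Region, ...]
    fractions: Mapping[str, float] = field(hash=False)

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.regions)

    def fraction(self, region_id: str) -> float:
        try:
            return self.fractions[region_id]
        except KeyError:
            raise RegionError(f"unknown region id {region_id!r}") from None

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.id == region_id:
                return r
        raise RegionError(f"unknown region id {region_id!r}")

    def by_group(self, group: str) -> tuple[Region, ...]:
        if group not in GROUPS:
            raise RegionError(f"unknown group {group!r}; expected one of {GROUPS}")
        return tuple(r for r in self.regions if r.group == group)

    def total_fraction(self) -> float:
        return float(sum(self.fractions[r.id] for r in self.regions))

    def checksum(self) -> str:
        """Short stable digest of ids+fractions, embedded in outputs for traceability."""
        import hashlib

        payload = ";".join(f"{r.id}={self.fractions[r.id]!r}" for r in self.regions)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "regions": [
                {
                    "id": r.id,
                    "display_name": r.display_name,
                    "group": r.group,
                    "index": r.index,
                    "fraction_percent": self.fractions[r.id],
                }
                for r in self.regions
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegionRegistry":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise RegionError(
                f"unsupported registry schema version {d.get('schema_version')!r}"
            )
        table = {row["display_name"]: row["fraction_percent"] for row in d["regions"]}
        return build_registry(table)

    @classmethod
    def from_json(cls, s: str) -> "RegionRegistry":
        return cls.from_dict(json.loads(s))


def uniform_fraction_table() -> dict[str, float]:
    """Uniform 2.5% placeholder table over the 40 canonical names.

    Non-clinical: real per-region fractions must be transcribed from the
    anatomical literature by the user.
    """
    return {name: 2.5 for name, _ in CANONICAL_REGIONS}


def build_registry(
    fraction_table: Mapping[str, float],
    names_source: Iterable[tuple[str, str]] = CANONICAL_REGIONS,
) -> RegionRegistry:
    """Build a registry from a name→percent fraction table.

    Keys are matched against the canonical listing after slug
    canonicalization, so punctuation/case variants of the printed names are
    accepted. The table must cover exactly the 40 regions.

    Raises :class:`RegionError` naming unknown, missing or duplicate regions
    and negative fractions.
    """
    canonical = tuple(names_source)
    slug_to_region: dict[str, tuple[int, str, str]] = {}
    for idx, (display, group) in enumerate(canonical, start=1):
        slug_to_region[canonicalize(display)] = (idx, display, group)

    resolved: dict[str, float] = {}
    unknown: list[str] = []
    duplicates: list[str] = []
    for name, value in fraction_table.items():
        slug = canonicalize(str(name))
        if slug not in slug_to_region:
            unknown.append(str(name))
            continue
        if slug in resolved:
            duplicates.append(str(name))
            continue
        resolved[slug] = float(value)
    if unknown:
        raise RegionError(f"unknown region name(s): {', '.join(sorted(unknown))}")
    if duplicates:
        raise RegionError(
            f"duplicate region name(s) after canonicalization: {', '.join(sorted(duplicates))}"
        )
    missing = [d for s, (_, d, _) in slug_to_region.items() if s not in resolved]
    if missing:
        raise RegionError(f"missing region(s): {', '.join(sorted(missing))}")

    negative = sorted(s for s, v in resolved.items() if v < 0 or not math.isfinite(v))
    if negative:
        raise RegionError(f"negative or non-finite fraction for region(s): {', '.join(negative)}")

    regions = tuple(
        Region(id=slug, display_name=display, group=group, index=idx)
        for slug, (idx, display, group) in sorted(slug_to_region.items(), key=lambda kv: kv[1][0])
    )
    return RegionRegistry(regions=regions, fractions=dict(resolved))


def validate_registry(
    reg: RegionRegistry, tolerance: float = LENIENT_TOLERANCE
) -> ValidationReport:
    """Check registry invariants; report (never raise) every problem found.

    Flags: Σ X_i deviating from 100 by more than ``tolerance`` percentage
    points, negative fractions, wrong total or per-group region counts.
    """
    issues: list[tuple[str, str, str]] = []
    n = len(reg.regions)
    if n != 40:
        issues.append(("error", "global", f"expected 40 regions, found {n}"))
    counts = {g: 0 for g in GROUPS}
    for r in reg.regions:
        counts[r.group] += 1
    for g, expected in GROUP_SIZES.items():
        if counts[g] != expected:
            issues.append(
                ("error", "global", f"group {g} has {counts[g]} regions, expected {expected}")
            )
    for r in reg.regions:
        x = reg.fractions.get(r.id)
        if x is None:
            issues.append(("error", r.id, "no fraction assigned"))
        elif x < 0:
            issues.append(("error", r.id, f"negative fraction {x}"))
    total = reg.total_fraction()
    if abs(total - 100.0) > tolerance:
        issues.append(
            (
                "error",
                "global",
                f"fractions sum to {total:.6f}%, deviating from 100% by more than {tolerance}",
            )
        )
    return ValidationReport(issues=tuple(issues))


def group_fraction(reg: RegionRegistry, group: str) -> float:
    """Σ X_i over the regions of one group (percent of total PSA)."""
    return float(sum(reg.fractions[r.id] for r in reg.by_group(group)))
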