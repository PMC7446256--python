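"""Seeded synthetic patients, resection records and region-fraction tables.

The generator emulates the statistical shape of an adult CRS/HIPEC cohort:
heights and weights from truncated normal distributions sized to give body
surface areas in the ~1.5–2.5 m² range, and a sparse, zero-inflated
resection pattern — per region, a Bernoulli draw (with a per-group
probability) decides whether any peritoneum was resected there, and a
scaled Beta distribution draws the resected share given resection. Real
intraoperative heatmaps are dominated by zero cells with sparse large
values; the two-part model reproduces that sparsity.

Determinism contract: all draws come from a single
``numpy.random.default_rng(seed)`` (integer-state PCG64), so a fixed seed
reproduces the cohort bit-for-bit across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .anthropometry import PLAUSIBLE_HEIGHT_CM, PLAUSIBLE_WEIGHT_KG, PatientRecord
from .regions import CANONICAL_REGIONS, GROUPS, RegionRegistry, build_registry
from .resection import ResectionRecord

__all__ = [
    "DEFAULT_GROUP_RESECTION_PROB",
    "CohortSpec",
    "generate_cohort",
    "generate_region_table",
]

# Any-resection probability per group. Ordering mirrors the clinical
# pattern that inframesocolic parietal peritonectomy is the most extensive
# relative to group size and supramesocolic visceral the least.
DEFAULT_GROUP_RESECTION_PROB = {"SMCVP": 0.2, "SMCPP": 0.4, "IMCVP": 0.3, "IMCPP": 0.6}


class SpecError(ValueError):
    """Raised for invalid cohort-specification fields."""


@dataclass(frozen=True)
class CohortSpec:
    """Statistical specification of a synthetic cohort.

    Defaults: height ~ N(170, 10) cm and weight ~ N(78, 15) kg, truncated
    to the anthropometric plausibility bounds; resection extent given
    resection ~ 100 · Beta(2, 2).
    """

    n: int = 36
    seed: int = 0
    height_mean_cm: float = 170.0
    height_sd_cm: float = 10.0
    weight_mean_kg: float = 78.0
    weight_sd_kg: float = 15.0
    group_resection_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_RESECTION_PROB)
    )
    extent_beta_a: float = 2.0
    extent_beta_b: float = 2.0
    registry: RegionRegistry | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SpecError(f"n must be >= 1, got {self.n}")
        if self.height_sd_cm < 0 or self.weight_sd_kg < 0:
            raise SpecError("distribution SDs must be >= 0")
        if self.extent_beta_a <= 0 or self.extent_beta_b <= 0:
            raise SpecError("Beta shape parameters must be > 0")
        if set(self.group_resection_prob) != set(GROUPS):
            raise SpecError(
                f"group_resection_prob must cover exactly {GROUPS}, "
                f"got {sorted(self.group_resection_prob)}"
            )
        for g, p in self.group_resection_prob.items():
            if not 0 <= p <= 1:
                raise SpecError(f"resection probability for {g} must be in [0, 1], got {p}")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Rejection-sampled truncated normal; exact and deterministic per rng state."""
    if sd == 0:
        if not lo <= mean <= hi:
            raise SpecError(f"degenerate distribution at {mean} outside [{lo}, {hi}]")
        return np.full(size, float(mean))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: size - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def generate_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], list[ResectionRecord]]:
    """Draw a deterministic synthetic cohort of patients and resection records.

    Heights/weights respect the plausibility bounds by truncation; every
    resected percent lies in [0, 100]; regions with no resection are simply
    absent from the record (default-zero semantics).
    """
    rng = np.random.default_rng(spec.seed)
    reg = spec.registry if spec.registry is not None else build_registry(
        {name: 2.5 for name, _ in CANONICAL_REGIONS}
    )

    heights = _truncated_normal(
        rng, spec.height_mean_cm, spec.height_sd_cm, *PLAUSIBLE_HEIGHT_CM, size=spec.n
    )
    weights = _truncated_normal(
        rng, spec.weight_mean_kg, spec.weight_sd_kg, *PLAUSIBLE_WEIGHT_KG, size=spec.n
    )

    patients = [
        PatientRecord(
            patient_id=f"SYN-{i + 1:04d}",
            height_cm=float(heights[i]),
            weight_kg=float(weights[i]),
            metadata={"synthetic": True},
        )
        for i in range(spec.n)
    ]

    records = []
    probs = np.array([spec.group_resection_prob[r.group] for r in reg.regions])
    for i in range(spec.n):
        resected = rng.random(len(reg.regions)) < probs
        extents = 100.0 * rng.beta(spec.extent_beta_a, spec.extent_beta_b, size=len(reg.regions))
        entries = {
            r.id: float(extents[j])
            for j, r in enumerate(reg.regions)
            if resected[j]
        }
        records.append(ResectionRecord(patient_id=patients[i].patient_id, entries=entries))
    return patients, records


def generate_region_table(mode: str = "uniform", seed: int = 0) -> dict[str, float]:
    """Generate a region-fraction table over the 40 canonical names.

    ``uniform`` gives 2.5% each; ``random-dirichlet`` draws a Dirichlet(3)
    vector scaled to percent, with the final region absorbing float
    rounding so the fractions sum to exactly 100.
    """
    names = [name for name, _ in CANONICAL_REGIONS]
    if mode == "uniform":
        return {name: 2.5 for name in names}
    if mode == "random-dirichlet":
        rng = np.random.default_rng(seed)
        frac = 100.0 * rng.dirichlet(np.full(len(names), 3.0))
        frac[-1] = 100.0 - float(np.sum(frac[:-1]))
        return {name: float(f) for name, f in zip(names, frac)}
    raise SpecError(f"unknown mode {mode!r}; expected 'uniform' or 'random-dirichlet'")
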