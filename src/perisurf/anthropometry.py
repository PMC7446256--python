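"""Body surface area and its mapping to total peritoneal surface area.

BSA follows the DuBois–DuBois formula

    BSA (m²) = 0.20247 · height(m)^0.725 · weight(kg)^0.425

with height accepted in centimetres (the clinical entry unit) and converted
internally. The total peritoneal surface area (PSA) is taken equal to the
BSA expressed in cm²; that value is the 100% denominator for all region
arithmetic downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = [
    "DUBOIS_COEFFICIENT",
    "HEIGHT_EXPONENT",
    "WEIGHT_EXPONENT",
    "PLAUSIBLE_HEIGHT_CM",
    "PLAUSIBLE_WEIGHT_KG",
    "PatientRecord",
    "SurfaceBasis",
    "compute_bsa",
    "surface_basis",
]

DUBOIS_COEFFICIENT = 0.20247
HEIGHT_EXPONENT = 0.725
WEIGHT_EXPONENT = 0.425

# Plausibility gate for intraoperative data entry: a transposed
# height/weight must fail loudly. Overridable for edge research use.
PLAUSIBLE_HEIGHT_CM = (100.0, 250.0)
PLAUSIBLE_WEIGHT_KG = (20.0, 300.0)


class AnthropometryError(ValueError):
    """Raised for non-positive or implausible height/weight input."""


def compute_bsa(height_cm: float, weight_kg: float) -> float:
    """DuBois–DuBois body surface area in m² from height (cm) and weight (kg).

    Strictly increasing in both arguments. Requires strictly positive,
    finite inputs; plausibility bounds are enforced at the
    :class:`PatientRecord` level, not here.

    >>> compute_bsa(100.0, 1.0)  # unit inputs expose the bare coefficient
    0.20247
    """
    for name, value in (("height_cm", height_cm), ("weight_kg", weight_kg)):
        if not math.isfinite(value) or value <= 0:
            raise AnthropometryError(f"{name} must be finite and > 0, got {value!r}")
    height_m = height_cm / 100.0
    return DUBOIS_COEFFICIENT * height_m**HEIGHT_EXPONENT * weight_kg**WEIGHT_EXPONENT


@dataclass(frozen=True)
class PatientRecord:
    """Patient anthropometry: the source of the BSA/PSA denominator.

    ``check_bounds=False`` disables the plausibility gate (positivity is
    always enforced). Optional metadata (age, sex, tumor origin, ...) is
    carried through to reports untouched.
    """

    patient_id: str
    height_cm: float
    weight_kg: float
    metadata: Mapping[str, Any] = field(default_factory=dict)
    check_bounds: bool = True

    def __post_init__(self) -> None:
        for name, value in (("height_cm", self.height_cm), ("weight_kg", self.weight_kg)):
            if not isinstance(value, (int, float)) or not math.isfinite(value) or value <= 0:
                raise AnthropometryError(
                    f"patient {self.patient_id!r}: {name} must be finite and > 0, got {value!r}"
                )
        if self.check_bounds:
            lo, hi = PLAUSIBLE_HEIGHT_CM
            if not lo <= self.height_cm <= hi:
                raise AnthropometryError(
                    f"patient {self.patient_id!r}: height_cm {self.height_cm} outside "
                    f"plausibility bounds [{lo}, {hi}] (pass check_bounds=False to override)"
                )
            lo, hi = PLAUSIBLE_WEIGHT_KG
            if not lo <= self.weight_kg <= hi:
                raise AnthropometryError(
                    f"patient {self.patient_id!r}: weight_kg {self.weight_kg} outside "
                    f"plausibility bounds [{lo}, {hi}] (pass check_bounds=False to override)"
                )


@dataclass(frozen=True)
class SurfaceBasis:
    """BSA in m² and cm², and the PSA total it defines (PSA ≡ BSA in cm²)."""

    bsa_m2: float
    bsa_cm2: float
    psa_total_cm2: float

    def __post_init__(self) -> None:
        if self.bsa_cm2 != self.bsa_m2 * 10_000.0:
            raise AnthropometryError("bsa_cm2 must equal bsa_m2 × 10,000 exactly")
        if self.psa_total_cm2 != self.bsa_cm2:
            raise AnthropometryError("psa_total_cm2 must equal bsa_cm2")


def surface_basis(p: PatientRecord) -> SurfaceBasis:
    """Compute the patient's surface basis: BSA (m², cm²) and PSA total (cm²).

    The returned ``psa_total_cm2`` is thereafter the 100% denominator for
    every region-level area.
    """
    bsa_m2 = compute_bsa(p.height_cm, p.weight_kg)
    bsa_cm2 = bsa_m2 * 10_000.0
    return SurfaceBasis(bsa_m2=bsa_m2, bsa_cm2=bsa_cm2, psa_total_cm2=bsa_cm2)
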