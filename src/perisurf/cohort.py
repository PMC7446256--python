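"""Cohort aggregation: region×patient resection matrices, summaries, tests.

The heatmap matrix has one row per region (stable index 1–40, registry
order) and one column per patient; cells are resected areas in cm², so each
column sums to that patient's PSA_resected. Summaries report sample mean
and sample SD (n−1 denominator) — SEM is computed alongside and labeled,
since "mean ± SD" and "mean ± SEM" are easily conflated in clinical
reporting. The before/after comparison defaults to the unpaired
pooled-variance Student's t-test; Welch and paired variants are available
by flag. Note the before/after design is intrinsically paired — the
unpaired default mirrors common practice in this literature, and a warning
is logged when it is used on paired-shaped data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import GROUPS, RegionRegistry
from .resection import SurfaceReport

__all__ = [
    "CohortMatrix",
    "CohortSummary",
    "ComparisonResult",
    "build_cohort_matrix",
    "summarize_cohort",
    "compare_groups",
]

logger = logging.getLogger(__name__)


class CohortError(ValueError):
    """Raised for empty cohorts, registry mismatches or insufficient n."""


@dataclass(frozen=True)
class CohortMatrix:
    """Region × patient matrix of resected areas (cm²)."""

    values: pd.DataFrame  # index: region ids in registry order; columns: patient ids
    registry_checksum: str

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def column_sums(self) -> pd.Series:
        return self.values.sum(axis=0)


@dataclass(frozen=True)
class QuantitySummary:
    mean: float
    sd: float | None  # None at n=1: sample SD undefined
    sem: float | None
    minimum: float
    maximum: float


@dataclass(frozen=True)
class CohortSummary:
    """Mean/SD/SEM of the patient-level totals plus the resection extremes."""

    n: int
    psa_before_cm2: QuantitySummary
    psa_after_cm2: QuantitySummary
    psa_resected_cm2: QuantitySummary
    groups: dict[str, dict[str, QuantitySummary]]  # group → {before,resected,after}
    min_resected_patient: tuple[str, float]
    max_resected_patient: tuple[str, float]

    def to_dict(self) -> dict:
        def qs(q: QuantitySummary) -> dict:
            return {"mean": q.mean, "sd": q.sd, "sem": q.sem, "min": q.minimum, "max": q.maximum}

        return {
            "n": self.n,
            "psa_before_cm2": qs(self.psa_before_cm2),
            "psa_after_cm2": qs(self.psa_after_cm2),
            "psa_resected_cm2": qs(self.psa_resected_cm2),
            "groups": {
                g: {k: qs(v) for k, v in d.items()} for g, d in self.groups.items()
            },
            "min_resected_patient": {
                "patient_id": self.min_resected_patient[0],
                "psa_resected_cm2": self.min_resected_patient[1],
            },
            "max_resected_patient": {
                "patient_id": self.max_resected_patient[0],
                "psa_resected_cm2": self.max_resected_patient[1],
            },
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample t-test result (variant recorded for traceability)."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    variant: str  # "student" | "welch" | "paired"

    def to_dict(self) -> dict:
        return vars(self).copy()


def build_cohort_matrix(reports: Sequence[SurfaceReport], reg: RegionRegistry) -> CohortMatrix:
    """Assemble the region×patient resected-area matrix from patient reports.

    All reports must have been computed against the same registry (checked
    via the embedded registry checksum).
    """
    if not reports:
        raise CohortError("empty cohort")
    checksum = reg.checksum()
    mismatched = [r.patient_id for r in reports if r.registry_checksum != checksum]
    if mismatched:
        raise CohortError(
            f"reports computed against a different registry: {', '.join(mismatched)}"
        )
    data = {
        rep.patient_id: [row.area_resected_cm2 for row in rep.rows] for rep in reports
    }
    df = pd.DataFrame(data, index=list(reg.region_ids))
    df.index.name = "region"
    return CohortMatrix(values=df, registry_checksum=checksum)


def _summarize(values: np.ndarray) -> QuantitySummary:
    n = len(values)
    mean = float(np.mean(values))
    if n >= 2:
        sd = float(np.std(values, ddof=1))
        sem = sd / math.sqrt(n)
    else:
        sd = sem = None
    return QuantitySummary(
        mean=mean, sd=sd, sem=sem, minimum=float(np.min(values)), maximum=float(np.max(values))
    )


def summarize_cohort(reports: Sequence[SurfaceReport]) -> CohortSummary:
    """Cohort summary statistics of the patient-level surface totals."""
    if not reports:
        raise CohortError("empty cohort")
    n = len(reports)
    if n == 1:
        logger.warning("cohort of one patient: sample SD is undefined and reported as absent")

    before = np.array([r.psa_before_cm2 for r in reports])
    after = np.array([r.psa_after_cm2 for r in reports])
    resected = np.array([r.psa_resected_cm2 for r in reports])

    groups: dict[str, dict[str, QuantitySummary]] = {}
    for g in GROUPS:
        groups[g] = {
            "before": _summarize(np.array([r.group(g).area_before_cm2 for r in reports])),
            "resected": _summarize(np.array([r.group(g).area_resected_cm2 for r in reports])),
            "after": _summarize(np.array([r.group(g).area_after_cm2 for r in reports])),
        }

    i_min = int(np.argmin(resected))
    i_max = int(np.argmax(resected))
    return CohortSummary(
        n=n,
        psa_before_cm2=_summarize(before),
        psa_after_cm2=_summarize(after),
        psa_resected_cm2=_summarize(resected),
        groups=groups,
        min_resected_patient=(reports[i_min].patient_id, float(resected[i_min])),
        max_resected_patient=(reports[i_max].patient_id, float(resected[i_max])),
    )


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided two-sample t-test between groups of areas.

    Default is the unpaired pooled-variance Student's t-test. ``welch=True``
    drops the equal-variance assumption; ``paired=True`` runs the paired
    test (requires equal lengths). Before/after surface measurements on the
    same patients are paired by design; a warning is logged when the
    unpaired default is applied to equal-length groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CohortError("each group needs n >= 2 for a t-test")
    if paired:
        if welch:
            raise CohortError("welch and paired are mutually exclusive")
        if len(a) != len(b):
            raise CohortError(f"paired test requires equal lengths, got {len(a)} vs {len(b)}")
        res = stats.ttest_rel(a, b)
        df = float(len(a) - 1)
        variant = "paired"
    else:
        if len(a) == len(b):
            logger.warning(
                "unpaired t-test on equal-length groups: if these are before/after "
                "measurements on the same patients, consider paired=True"
            )
        res = stats.ttest_ind(a, b, equal_var=not welch)
        df = float(res.df)
        variant = "welch" if welch else "student"
    return ComparisonResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        sd_a=float(np.std(a, ddof=1)),
        sd_b=float(np.std(b, ddof=1)),
        n_a=len(a),
        n_b=len(b),
        variant=variant,
    )
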