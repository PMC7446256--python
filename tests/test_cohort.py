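"""Cohort matrices, summaries and the before/after t-test vs hand oracles."""

import math

import numpy as np
import pytest

from perisurf import apply_resection, surface_basis
from perisurf.cohort import (
    CohortError,
    build_cohort_matrix,
    compare_groups,
    summarize_cohort,
)
from perisurf.resection import ResectionRecord

# --- independent textbook oracles ------------------------------------------


def student_t_oracle(a, b):
    """Pooled-variance two-sample t, coded directly from the textbook formula."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    sa2 = sum((x - ma) ** 2 for x in a) / (na - 1)
    sb2 = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, na + nb - 2


def welford_oracle(values):
    """Streaming mean/SD (Welford), independent of the two-pass numpy path."""
    n = 0
    mean = 0.0
    m2 = 0.0
    for x in values:
        n += 1
        d = x - mean
        mean += d / n
        m2 += d * (x - mean)
    sd = math.sqrt(m2 / (n - 1)) if n > 1 else None
    return mean, sd


def _reports(uniform_registry, patients, records):
    recs = {r.patient_id: r for r in records}
    return [
        apply_resection(uniform_registry, surface_basis(p), recs[p.patient_id])
        for p in patients
    ]


class TestCohortMatrix:
    def test_zero_resection_gives_zero_matrix(self, uniform_registry):
        from perisurf import PatientRecord

        patients = [PatientRecord(f"p{i}", 170.0, 70.0) for i in range(3)]
        reports = [
            apply_resection(uniform_registry, surface_basis(p), ResectionRecord(p.patient_id))
            for p in patients
        ]
        m = build_cohort_matrix(reports, uniform_registry)
        assert m.values.shape == (40, 3)
        assert (m.values.to_numpy() == 0).all()

    def test_single_resected_region_is_single_cell(self, uniform_registry, reference_basis):
        rep = apply_resection(
            uniform_registry, reference_basis, ResectionRecord("p1", {"liver": 50.0})
        )
        m = build_cohort_matrix([rep], uniform_registry)
        nz = m.values.to_numpy().nonzero()
        assert len(nz[0]) == 1
        assert m.values.loc["liver", "p1"] == pytest.approx(rep.psa_resected_cm2)

    def test_column_sums_match_reports(self, uniform_registry, small_cohort):
        patients, records = small_cohort
        reports = _reports(uniform_registry, patients, records)
        m = build_cohort_matrix(reports, uniform_registry)
        for rep in reports:
            assert m.column_sums()[rep.patient_id] == pytest.approx(
                rep.psa_resected_cm2, rel=1e-9
            )

    def test_registry_mismatch_rejected(self, uniform_registry, reference_basis):
        from perisurf import build_registry
        from perisurf.regions import uniform_fraction_table

        other_table = uniform_fraction_table()
        other_table["Liver"] = 2.6
        other = build_registry(other_table)
        rep = apply_resection(uniform_registry, reference_basis, ResectionRecord("p1"))
        with pytest.raises(CohortError, match="different registry"):
            build_cohort_matrix([rep], other)


class TestSummarizeCohort:
    def test_single_patient_sd_absent(self, uniform_registry, reference_basis):
        rep = apply_resection(uniform_registry, reference_basis, ResectionRecord("p1"))
        s = summarize_cohort([rep])
        assert s.n == 1
        assert s.psa_before_cm2.sd is None
        assert s.psa_before_cm2.sem is None

    def test_identical_patients_sd_zero(self, uniform_registry, reference_basis):
        reps = [
            apply_resection(uniform_registry, reference_basis,
                            ResectionRecord(f"p{i}", {"liver": 20.0}))
            for i in range(2)
        ]
        s = summarize_cohort(reps)
        assert s.psa_resected_cm2.sd == pytest.approx(0.0, abs=1e-12)
        assert s.min_resected_patient[1] == s.max_resected_patient[1]

    def test_matches_welford_oracle(self, uniform_registry, small_cohort):
        patients, records = small_cohort
        reports = _reports(uniform_registry, patients, records)
        s = summarize_cohort(reports)
        mean, sd = welford_oracle([r.psa_resected_cm2 for r in reports])
        assert s.psa_resected_cm2.mean == pytest.approx(mean, rel=1e-12)
        assert s.psa_resected_cm2.sd == pytest.approx(sd, rel=1e-10)
        assert s.psa_resected_cm2.sem == pytest.approx(sd / math.sqrt(len(reports)), rel=1e-10)

    def test_extremes_identified(self, uniform_registry, small_cohort):
        patients, records = small_cohort
        reports = _reports(uniform_registry, patients, records)
        s = summarize_cohort(reports)
        resected = {r.patient_id: r.psa_resected_cm2 for r in reports}
        assert s.min_resected_patient[0] == min(resected, key=resected.get)
        assert s.max_resected_patient[0] == max(resected, key=resected.get)

    def test_permutation_invariant(self, uniform_registry, small_cohort):
        patients, records = small_cohort
        reports = _reports(uniform_registry, patients, records)
        s1 = summarize_cohort(reports)
        s2 = summarize_cohort(list(reversed(reports)))
        for attr in ("psa_before_cm2", "psa_after_cm2", "psa_resected_cm2"):
            a, b = getattr(s1, attr), getattr(s2, attr)
            assert a.mean == pytest.approx(b.mean, rel=1e-12)
            assert a.sd == pytest.approx(b.sd, rel=1e-12)
            assert (a.minimum, a.maximum) == (b.minimum, b.maximum)
        assert s1.max_resected_patient == s2.max_resected_patient


class TestCompareGroups:
    def test_identical_groups_t_zero_p_one(self):
        r = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_within_group_order_irrelevant(self):
        r1 = compare_groups([1.0, 2.0, 3.0], [4.0, 6.0, 5.0])
        r2 = compare_groups([3.0, 1.0, 2.0], [6.0, 5.0, 4.0])
        assert (r1.t, r1.p) == (r2.t, r2.p)

    def test_antisymmetric_in_group_swap(self):
        a, b = [1.0, 2.0, 3.0, 7.0], [2.0, 4.0, 8.0]
        assert compare_groups(a, b).t == -compare_groups(b, a).t

    def test_matches_textbook_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.normal(10, 3, size=int(rng.integers(3, 12))).tolist()
            b = rng.normal(11, 2, size=int(rng.integers(3, 12))).tolist()
            res = compare_groups(a, b)
            t, df = student_t_oracle(a, b)
            assert res.t == pytest.approx(t, rel=1e-10)
            assert res.df == df
            assert res.variant == "student"

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10).tolist()
        b = rng.normal(0, 20, 25).tolist()
        student = compare_groups(a, b)
        welch = compare_groups(a, b, welch=True)
        assert welch.variant == "welch"
        assert welch.df != student.df

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(CohortError, match="equal lengths"):
            compare_groups([1.0, 2.0, 3.0], [1.0, 2.0], paired=True)

    def test_insufficient_n_rejected(self):
        with pytest.raises(CohortError, match="n >= 2"):
            compare_groups([1.0], [1.0, 2.0])
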