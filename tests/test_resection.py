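"""Resection arithmetic: per-region areas, conservation, ratios, subtotals."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perisurf.anthropometry import SurfaceBasis
from perisurf.regions import CANONICAL_REGIONS, build_registry, uniform_fraction_table
from perisurf.resection import (
    ResectionError,
    ResectionRecord,
    apply_resection,
    group_summaries,
    region_area_before,
    surface_ratio,
)

BASIS_20K = SurfaceBasis(bsa_m2=2.0, bsa_cm2=20_000.0, psa_total_cm2=20_000.0)


def _random_record(pid, percents):
    ids = [r_id for r_id in percents]
    return ResectionRecord(patient_id=pid, entries=dict(zip(ids, percents.values())))


class TestRegionAreaBefore:
    def test_uniform_share_of_20k(self, uniform_registry):
        assert region_area_before(uniform_registry, BASIS_20K, "liver") == pytest.approx(500.0)

    def test_zero_fraction_zero_area(self):
        table = {name: 0.0 for name, _ in CANONICAL_REGIONS}
        table["Liver"] = 100.0
        reg = build_registry(table)
        assert region_area_before(reg, BASIS_20K, "spleen") == 0.0

    def test_sum_over_regions_recovers_total(self, uniform_registry):
        total = sum(
            region_area_before(uniform_registry, BASIS_20K, rid)
            for rid in uniform_registry.region_ids
        )
        assert total == pytest.approx(BASIS_20K.psa_total_cm2, rel=1e-12)


class TestApplyResection:
    def test_no_resection_is_identity(self, uniform_registry):
        rep = apply_resection(uniform_registry, BASIS_20K, ResectionRecord("p"))
        assert rep.psa_after_cm2 == pytest.approx(rep.psa_before_cm2)
        assert rep.psa_resected_cm2 == pytest.approx(0.0, abs=1e-9)
        assert rep.ratio_after_percent == pytest.approx(100.0)

    def test_total_peritonectomy_empties_surface(self, uniform_registry):
        rec = ResectionRecord("p", {rid: 100.0 for rid in uniform_registry.region_ids})
        rep = apply_resection(uniform_registry, BASIS_20K, rec)
        assert rep.psa_after_cm2 == pytest.approx(0.0, abs=1e-9)
        assert rep.psa_resected_cm2 == pytest.approx(rep.psa_before_cm2)
        assert rep.ratio_after_percent == pytest.approx(0.0, abs=1e-9)

    def test_single_region_partial_resection(self, uniform_registry):
        rep = apply_resection(uniform_registry, BASIS_20K, ResectionRecord("p", {"liver": 40.0}))
        liver = next(r for r in rep.rows if r.region_id == "liver")
        assert liver.area_before_cm2 == pytest.approx(500.0)
        assert liver.area_resected_cm2 == pytest.approx(200.0)
        assert liver.area_after_cm2 == pytest.approx(300.0)
        assert rep.psa_resected_cm2 == pytest.approx(200.0)

    def test_unknown_region_named(self, uniform_registry):
        with pytest.raises(ResectionError, match="splene"):
            apply_resection(uniform_registry, BASIS_20K, ResectionRecord("p", {"splene": 10.0}))

    @pytest.mark.parametrize("bad", [-0.5, 100.5, float("nan")])
    def test_out_of_range_percent_named(self, bad):
        with pytest.raises(ResectionError, match="liver"):
            ResectionRecord("p", {"liver": bad})

    def test_monotone_in_resection_extent(self, uniform_registry):
        lo = apply_resection(uniform_registry, BASIS_20K, ResectionRecord("p", {"liver": 10.0}))
        hi = apply_resection(uniform_registry, BASIS_20K, ResectionRecord("p", {"liver": 60.0}))
        assert hi.psa_after_cm2 < lo.psa_after_cm2
        assert hi.psa_resected_cm2 > lo.psa_resected_cm2

    def test_entry_order_invariance(self, uniform_registry):
        entries = {"liver": 30.0, "spleen": 70.0, "rectum": 15.0}
        fwd = apply_resection(uniform_registry, BASIS_20K, ResectionRecord("p", entries))
        rev = apply_resection(
            uniform_registry, BASIS_20K,
            ResectionRecord("p", dict(reversed(list(entries.items())))),
        )
        assert fwd == rev

    @given(
        fractions=st.lists(
            st.floats(min_value=0.0, max_value=10.0, allow_nan=False), min_size=40, max_size=40
        ),
        percents=st.lists(
            st.floats(min_value=0.0, max_value=100.0, allow_nan=False), min_size=40, max_size=40
        ),
        psa_total=st.floats(min_value=10_000.0, max_value=25_000.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_conservation_under_random_inputs(self, fractions, percents, psa_total):
        reg = build_registry({n: f for (n, _), f in zip(CANONICAL_REGIONS, fractions)})
        bsa_m2 = psa_total / 10_000.0
        basis = SurfaceBasis(bsa_m2, bsa_m2 * 10_000.0, bsa_m2 * 10_000.0)
        rec = ResectionRecord("p", dict(zip(reg.region_ids, percents)))
        rep = apply_resection(reg, basis, rec)
        for row in rep.rows:
            assert row.area_before_cm2 >= 0
            assert math.isclose(
                row.area_before_cm2,
                row.area_resected_cm2 + row.area_after_cm2,
                rel_tol=1e-12,
                abs_tol=1e-9,
            )
        assert math.isclose(
            rep.psa_before_cm2, rep.psa_resected_cm2 + rep.psa_after_cm2,
            rel_tol=1e-12, abs_tol=1e-9,
        )

    def test_resected_total_linear_in_each_entry(self, uniform_registry):
        # brute-force oracle: enumerate regions and sum the per-region products
        entries = {"liver": 25.0, "mesentery": 80.0, "urinary-bladder": 5.0}
        rep = apply_resection(uniform_registry, BASIS_20K, ResectionRecord("p", entries))
        oracle = sum(
            BASIS_20K.psa_total_cm2
            * uniform_registry.fractions[rid]
            / 100.0
            * (y / 100.0)
            for rid, y in entries.items()
        )
        assert rep.psa_resected_cm2 == pytest.approx(oracle, rel=1e-12)
        # slope of psa_resected in y_liver is psa_total·X_liver/10,000
        bumped = dict(entries, liver=26.0)
        rep2 = apply_resection(uniform_registry, BASIS_20K, ResectionRecord("p", bumped))
        slope = rep2.psa_resected_cm2 - rep.psa_resected_cm2
        assert slope == pytest.approx(
            BASIS_20K.psa_total_cm2 * uniform_registry.fractions["liver"] / 10_000.0,
            rel=1e-9,
        )


class TestSurfaceRatio:
    @pytest.mark.parametrize(
        "psa, bsa, expected", [(2.0, 2.0, 100.0), (1.0, 2.0, 50.0), (0.0, 2.0, 0.0)]
    )
    def test_percent_convention(self, psa, bsa, expected):
        assert surface_ratio(psa, bsa) == pytest.approx(expected)

    def test_as_printed_flag_reproduces_literal_arithmetic(self):
        # the published formula divides by 100 instead; kept for audit only
        assert surface_ratio(2.0, 2.0, as_printed=True) == pytest.approx(0.01)

    def test_nonpositive_bsa_rejected(self):
        with pytest.raises(ResectionError):
            surface_ratio(1.0, 0.0)


class TestGroupSummaries:
    def test_uniform_group_totals_before(self, uniform_registry):
        rep = apply_resection(uniform_registry, BASIS_20K, ResectionRecord("p"))
        groups = {g.group: g for g in group_summaries(rep, uniform_registry)}
        assert groups["IMCVP"].area_before_cm2 == pytest.approx(6_000.0)  # 12 × 500
        assert groups["SMCVP"].area_before_cm2 == pytest.approx(8_000.0)
        assert all(g.area_resected_cm2 == pytest.approx(0.0, abs=1e-9) for g in groups.values())

    def test_groups_partition_totals(self, uniform_registry):
        rec = ResectionRecord("p", {"liver": 50.0, "rectum": 25.0})
        rep = apply_resection(uniform_registry, BASIS_20K, rec)
        groups = group_summaries(rep, uniform_registry)
        assert sum(g.area_after_cm2 for g in groups) == pytest.approx(rep.psa_after_cm2)
        assert sum(g.area_before_cm2 for g in groups) == pytest.approx(rep.psa_before_cm2)
        assert groups == rep.groups
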