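"""The excess statistic (OR − 1) × rate, its CI convention, and bookkeeping."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from telburden.burden_attribution import ExcessBurden, attribute, excess, total_excess
from telburden.definition_mapping import allocate, case_fraction
from telburden.harmonization import normalize_direction
from telburden.tables_io import (
    DALY,
    INCIDENCE,
    PER_SD_LONGER,
    PER_SD_SHORTER,
    BurdenEstimate,
    DiseaseAssociation,
    ValidationError,
)


def assoc(name, or_, lo=None, hi=None, direction=PER_SD_LONGER):
    return DiseaseAssociation(name, or_, lo, hi, direction, "s", True)


def burden(name, value, lo=None, hi=None, measure=INCIDENCE):
    return BurdenEstimate(name, measure, value, lo, hi)


class TestExcess:
    @pytest.mark.parametrize(
        "or_, rate, expected",
        [
            (5.27, 8.39, 35.83),     # glioma incidence
            (1.28, 190.81, 53.43),   # coronary heart disease incidence
            (5.27, 134.46, 574.14),  # glioma DALYs
            (1.28, 2106.22, 589.74), # coronary heart disease DALYs
        ],
    )
    def test_per_disease_statistic_matches_hand_value(self, or_, rate, expected):
        row = excess(assoc("d", or_, or_ * 0.8, or_ * 1.2), burden("d", rate))
        assert round(row.value, 2) == expected

    def test_or_ci_times_burden_point(self):
        row = excess(
            assoc("chd", 1.28, 1.11, 1.49, direction=PER_SD_SHORTER),
            burden("chd", 190.81, 171.96, 211.00),
        )
        assert round(row.value, 2) == 53.43
        assert round(row.ci_lower, 2) == 20.99
        assert round(row.ci_upper, 2) == 93.50  # burden CI unused

    def test_null_effect_keeps_ci_from_or_bounds(self):
        row = excess(assoc("d", 1.0, 0.9, 1.2), burden("d", 50.0))
        assert row.value == 0.0
        assert row.ci_lower == pytest.approx((0.9 - 1) * 50.0)
        assert row.ci_upper == pytest.approx((1.2 - 1) * 50.0)

    def test_burden_ci_fallback_when_or_ci_missing(self):
        row = excess(assoc("d", 1.81), burden("d", 32.57, 31.62, 33.41),
                     ci_source="auto")
        assert row.value == pytest.approx(0.81 * 32.57)
        assert row.ci_lower == pytest.approx(0.81 * 31.62)
        assert row.ci_upper == pytest.approx(0.81 * 33.41)

    def test_missing_burden_value_raises_for_exclusion_routing(self):
        with pytest.raises(ValidationError, match="MISSING"):
            excess(assoc("d", 2.0, 1.5, 2.5), burden("d", None))

    @settings(deadline=None)
    @given(
        or_=st.floats(min_value=0.2, max_value=10),
        rate=st.floats(min_value=0.01, max_value=1e4),
        frac_num=st.integers(0, 100),
    )
    def test_linearity_under_allocation(self, or_, rate, frac_num):
        a = assoc("d", or_, or_ * 0.8, or_ * 1.2)
        v = burden("Broad", rate, rate * 0.9, rate * 1.1)
        frac = case_fraction(frac_num, 100, narrow_name="d", broad_name="Broad")
        direct = excess(a, allocate(v, frac))
        scaled = excess(a, v)
        f = frac.fraction
        assert direct.value == pytest.approx(f * scaled.value, abs=1e-9)
        assert direct.ci_lower == pytest.approx(f * scaled.ci_lower, abs=1e-9)
        assert direct.ci_upper == pytest.approx(f * scaled.ci_upper, abs=1e-9)

    @settings(deadline=None)
    @given(
        or_=st.floats(min_value=0.2, max_value=10),
        spread=st.floats(min_value=1.0, max_value=2.0),
        rate=st.floats(min_value=0.01, max_value=1e4),
    )
    def test_ci_contains_value_when_or_ci_valid(self, or_, spread, rate):
        row = excess(assoc("d", or_, or_ / spread, or_ * spread), burden("d", rate))
        assert row.ci_lower - 1e-12 <= row.value <= row.ci_upper + 1e-12
        # sign of the excess matches sign of OR - 1
        assert math.copysign(1, row.value) == math.copysign(1, or_ - 1) or row.value == 0


class TestTotalExcess:
    def test_singleton_sum_is_itself(self):
        row = ExcessBurden("a", INCIDENCE, PER_SD_LONGER, 3.0, 1.0, 5.0)
        tot = total_excess([row])
        assert (tot.value, tot.ci_lower, tot.ci_upper) == (3.0, 1.0, 5.0)

    def test_sums_values_and_like_bounds_without_reround(self):
        rows = [
            ExcessBurden("a", INCIDENCE, PER_SD_LONGER, 1.004, 0.4, 2.0),
            ExcessBurden("b", INCIDENCE, PER_SD_LONGER, 2.004, 0.6, 3.0),
        ]
        tot = total_excess(rows)
        assert tot.value == pytest.approx(3.008, abs=1e-15)
        assert (tot.ci_lower, tot.ci_upper) == (1.0, 5.0)
        assert tot.components == ("a", "b")

    def test_rss_alternative_is_narrower_than_bound_sum(self):
        rows = [
            ExcessBurden("a", INCIDENCE, PER_SD_LONGER, 10.0, 5.0, 15.0),
            ExcessBurden("b", INCIDENCE, PER_SD_LONGER, 10.0, 5.0, 15.0),
        ]
        summed = total_excess(rows, bounds="sum")
        rss = total_excess(rows, bounds="rss")
        assert rss.ci_lower > summed.ci_lower
        assert rss.ci_upper < summed.ci_upper

    def test_mixed_measure_or_direction_rejected(self):
        rows = [
            ExcessBurden("a", INCIDENCE, PER_SD_LONGER, 1.0, 0.5, 1.5),
            ExcessBurden("b", DALY, PER_SD_LONGER, 1.0, 0.5, 1.5),
        ]
        with pytest.raises(ValidationError, match="mixed"):
            total_excess(rows)


class TestAttribute:
    def test_partial_burden_availability_per_measure(self):
        # burden present for DALYs only -> excluded from incidence, kept for DALYs
        assocs = normalize_direction(
            [assoc("Aortic aneurysm", 1.59, 1.23, 2.04, direction=PER_SD_SHORTER)],
            PER_SD_SHORTER,
        )
        burdens = [
            burden("Aortic aneurysm", None),
            burden("Aortic aneurysm", 57.09, 55.47, 58.72, measure=DALY),
        ]
        report = attribute(assocs, burdens)
        assert [(e.disease_name, e.measure) for e in report.excluded] == [
            ("Aortic aneurysm", INCIDENCE)
        ]
        (daly_row,) = report.rows
        assert round(daly_row.value, 2) == 33.68
        assert round(daly_row.ci_lower, 2) == 13.13
        assert round(daly_row.ci_upper, 2) == 59.37
        assert (INCIDENCE, PER_SD_SHORTER) not in report.totals

    def test_empty_association_list(self):
        report = attribute([], [burden("x", 1.0)])
        assert report.rows == [] and report.totals == {}

    def test_name_mismatch_routed_to_exclusions_with_reason(self):
        assocs = normalize_direction([assoc("Glioma", 5.27, 3.15, 8.81)], PER_SD_LONGER)
        report = attribute(assocs, [burden("Brain cancer", 8.39)])
        reasons = {(e.disease_name, e.measure): e.reason for e in report.excluded}
        assert reasons[("Glioma", INCIDENCE)] == "no burden record"
        assert reasons[("Glioma", DALY)] == "no burden record"

    def test_alias_table_bridges_names(self):
        assocs = normalize_direction([assoc("Glioma", 5.27, 3.15, 8.81)], PER_SD_LONGER)
        report = attribute(
            assocs,
            [burden("Brain cancer", 8.39)],
            aliases={"Glioma": "Brain cancer"},
        )
        (row,) = report.rows
        assert round(row.value, 2) == 35.83

    def test_duplicate_disease_rejected(self):
        a = normalize_direction([assoc("d", 2.0, 1.5, 2.5)], PER_SD_LONGER)
        with pytest.raises(ValidationError, match="duplicate"):
            attribute(a + a, [burden("d", 1.0)])

    def test_every_association_accounted_per_measure(self):
        assocs = normalize_direction(
            [assoc("a", 2.0, 1.5, 2.5), assoc("b", 3.0, 2.0, 4.0)], PER_SD_LONGER
        )
        report = attribute(assocs, [burden("a", 5.0)])
        accounted = {(r.cause_name, r.measure) for r in report.rows}
        accounted |= {(e.disease_name, e.measure) for e in report.excluded}
        assert accounted == {("a", INCIDENCE), ("a", DALY),
                             ("b", INCIDENCE), ("b", DALY)}
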