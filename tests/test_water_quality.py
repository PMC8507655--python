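"""Mean-concentration rules, HAA supersession, and the hazard sum."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_records
from waterdisparity.benchmarks import BenchmarkTable, Contaminant
from waterdisparity.units import UnitError, convert
from waterdisparity.water_quality import (
    ConcentrationProfile,
    build_profiles,
    cumulative_risk,
    mean_concentration,
    occurrence_summary,
    resolve_haa,
    risk_table,
)


class TestUnits:
    @pytest.mark.parametrize(
        "value,frm,to,expected",
        [
            (500.0, "ng/L", "µg/L", 0.5),
            (1.0, "mg/L", "µg/L", 1000.0),
            (1.0, "µg/L", "ng/L", 1000.0),
            (2.0, "ug/L", "µg/L", 2.0),
            (3.0, "pCi/L", "pCi/L", 3.0),
        ],
    )
    def test_conversion(self, value, frm, to, expected):
        assert convert(value, frm, to) == pytest.approx(expected)

    def test_mass_activity_mixing_is_error(self):
        with pytest.raises(UnitError):
            convert(1.0, "pCi/L", "µg/L")

    def test_unknown_unit_is_error(self):
        with pytest.raises(UnitError):
            convert(1.0, "ppm", "µg/L")


class TestMeanConcentration:
    def test_nondetects_count_as_zero(self):
        recs = make_records(
            [("S", "A", "2015-01-01", 1.0, "µg/L"),
             ("S", "A", "2015-02-01", None, "µg/L"),
             ("S", "A", "2015-03-01", 2.0, "µg/L")]
        )
        mean, n, detected = mean_concentration(recs, "µg/L")
        assert mean == pytest.approx(1.0)
        assert n == 3 and detected

    def test_all_nondetect_gives_zero_and_no_detection(self):
        recs = make_records([("S", "A", "2015-01-01", None, "µg/L")] * 3)
        mean, n, detected = mean_concentration(recs, "µg/L")
        assert mean == 0.0 and not detected

    def test_unit_conversion_to_benchmark_unit(self):
        recs = make_records([("S", "A", "2015-01-01", 500.0, "ng/L")])
        mean, _, _ = mean_concentration(recs, "µg/L")
        assert mean == pytest.approx(0.5)

    def test_out_of_window_records_yield_absent(self):
        recs = make_records([("S", "A", "2010-01-01", 1.0, "µg/L")])
        assert mean_concentration(recs, "µg/L") is None

    def test_window_is_inclusive_on_both_ends(self):
        recs = make_records(
            [("S", "A", "2014-01-01", 2.0, "µg/L"),
             ("S", "A", "2019-12-31", 4.0, "µg/L")]
        )
        mean, n, _ = mean_concentration(recs, "µg/L")
        assert n == 2 and mean == pytest.approx(3.0)

    def test_negative_value_rejected(self):
        recs = make_records([("S", "A", "2015-01-01", -1.0, "µg/L")])
        with pytest.raises(ValueError, match="negative"):
            mean_concentration(recs, "µg/L")

    def test_value_xor_nondetect_enforced(self):
        recs = make_records([("S", "A", "2015-01-01", 1.0, "µg/L")])
        recs.loc[0, "nondetect"] = 1  # value present AND flagged: invalid
        with pytest.raises(ValueError, match="nondetect"):
            mean_concentration(recs, "µg/L")

    def test_duplicate_records_are_retained(self):
        recs = make_records([("S", "A", "2015-01-01", 3.0, "µg/L")] * 2
                            + [("S", "A", "2015-02-01", 0.0, "µg/L")])
        mean, n, _ = mean_concentration(recs, "µg/L")
        assert n == 3 and mean == pytest.approx(2.0)


class TestHaaRule:
    def test_haa9_supersedes_haa5(self, simple_benchmarks):
        prof = ConcentrationProfile("S", {"HAA5": 8.0, "HAA9": 20.0})
        prof = resolve_haa(prof, simple_benchmarks)
        assert prof.risk_eligible == {"HAA9": 20.0}
        assert "HAA5" in prof.concentrations  # retained for occurrence stats
        assert prof.haa_rule == "HAA9 supersedes HAA5"

    def test_haa5_alone_remains(self, simple_benchmarks):
        prof = resolve_haa(ConcentrationProfile("S", {"HAA5": 8.0}), simple_benchmarks)
        assert prof.risk_eligible == {"HAA5": 8.0}

    def test_profile_without_either_group_unchanged(self, simple_benchmarks):
        prof = resolve_haa(ConcentrationProfile("S", {"A": 1.0}), simple_benchmarks)
        assert prof.risk_eligible == {"A": 1.0} and prof.haa_rule is None


class TestCumulativeRisk:
    def test_benchmark_definition(self, simple_benchmarks):
        res = cumulative_risk(ConcentrationProfile("S", {"A": 1.0}), simple_benchmarks)
        assert res.rho == pytest.approx(1.0)
        assert res.lifetime_risk == pytest.approx(1e-6)

    def test_hand_arithmetic(self, simple_benchmarks):
        res = cumulative_risk(
            ConcentrationProfile("S", {"A": 2.0, "B": 5.0}), simple_benchmarks
        )
        assert res.rho == pytest.approx(2.5)  # 2/1 + 5/10

    def test_empty_profile_zero_risk(self, simple_benchmarks):
        res = cumulative_risk(ConcentrationProfile("S", {}), simple_benchmarks)
        assert res.rho == 0.0 and res.lifetime_risk == 0.0

    def test_missing_benchmark_skipped_not_zeroed(self, simple_benchmarks, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            res = cumulative_risk(
                ConcentrationProfile("S", {"A": 1.0, "UNKNOWN": 9.0}), simple_benchmarks
            )
        assert res.rho == pytest.approx(1.0)
        assert res.skipped == ["UNKNOWN"]
        assert "UNKNOWN" in caplog.text

    def test_contributions_sum_to_rho(self, simple_benchmarks):
        res = cumulative_risk(
            ConcentrationProfile("S", {"A": 3.0, "B": 7.0}), simple_benchmarks
        )
        assert sum(res.contributions.values()) == pytest.approx(res.rho)

    @given(
        concs=st.dictionaries(
            st.sampled_from(["A", "B"]),
            st.floats(0, 1e3, allow_nan=False),
            min_size=1,
        ),
        k=st.floats(0.1, 10),
    )
    @settings(deadline=None)
    def test_linearity_in_concentration(self, simple_benchmarks, concs, k):
        base = cumulative_risk(ConcentrationProfile("S", dict(concs)), simple_benchmarks)
        scaled = cumulative_risk(
            ConcentrationProfile("S", {c: v * k for c, v in concs.items()}),
            simple_benchmarks,
        )
        assert scaled.rho == pytest.approx(k * base.rho, rel=1e-9, abs=1e-12)

    @given(
        concs=st.dictionaries(
            st.sampled_from(["A", "B", "HAA5"]),
            st.floats(0, 1e3, allow_nan=False),
            min_size=2,
        )
    )
    @settings(deadline=None)
    def test_removing_a_contaminant_never_increases_rho(self, simple_benchmarks, concs):
        full = cumulative_risk(ConcentrationProfile("S", dict(concs)), simple_benchmarks)
        dropped = dict(concs)
        dropped.pop(next(iter(dropped)))
        less = cumulative_risk(ConcentrationProfile("S", dropped), simple_benchmarks)
        assert less.rho <= full.rho + 1e-12

    def test_rho_invariant_to_record_units(self, simple_benchmarks):
        recs_ug = make_records([("S", "A", "2015-01-01", 2.0, "µg/L")])
        recs_ng = make_records([("S", "A", "2015-01-01", 2000.0, "ng/L")])
        r_ug = risk_table(recs_ug, simple_benchmarks)
        r_ng = risk_table(recs_ng, simple_benchmarks)
        assert r_ug["rho"].iloc[0] == pytest.approx(r_ng["rho"].iloc[0])

    def test_haa_exclusivity_in_contributions(self, simple_benchmarks):
        recs = make_records(
            [("S", "HAA5", "2015-01-01", 8.0, "µg/L"),
             ("S", "HAA9", "2015-01-01", 20.0, "µg/L")]
        )
        prof = build_profiles(recs, simple_benchmarks)[0]
        res = cumulative_risk(resolve_haa(prof, simple_benchmarks), simple_benchmarks)
        assert "HAA9" in res.contributions and "HAA5" not in res.contributions


class TestAliases:
    def test_combined_nitrate_nitrite_feeds_nitrate_stream(self):
        bm = BenchmarkTable(
            contaminants={"NITRATE": Contaminant("NITRATE", 0.14, "mg/L")},
            aliases={"NITRATE_NITRITE": "NITRATE"},
        )
        recs = make_records(
            [("S", "NITRATE", "2015-01-01", 1.0, "mg/L"),
             ("S", "NITRATE_NITRITE", "2015-02-01", 3.0, "mg/L")]
        )
        prof = build_profiles(recs, bm)[0]
        assert prof.concentrations == {"NITRATE": pytest.approx(2.0)}
        assert prof.n_tests["NITRATE"] == 2


class TestOccurrenceSummary:
    def test_weighted_and_simple_averages(self):
        profiles = [
            ConcentrationProfile("S1", {"A": 10.0}, {"A": 1}, {"A": True}),
            ConcentrationProfile("S2", {"A": 20.0}, {"A": 1}, {"A": True}),
        ]
        out = occurrence_summary(profiles, {"S1": 100, "S2": 300})
        row = out.iloc[0]
        assert row["simple_average"] == pytest.approx(15.0)
        assert row["population_weighted_average"] == pytest.approx(17.5)

    def test_equal_populations_weighted_equals_simple(self):
        profiles = [
            ConcentrationProfile("S1", {"A": 4.0}, {"A": 1}, {"A": True}),
            ConcentrationProfile("S2", {"A": 8.0}, {"A": 1}, {"A": True}),
        ]
        out = occurrence_summary(profiles, {"S1": 500, "S2": 500})
        row = out.iloc[0]
        assert row["population_weighted_average"] == pytest.approx(row["simple_average"])

    def test_all_nd_system_has_data_but_no_detection(self, simple_benchmarks):
        recs = make_records(
            [("S1", "A", "2015-01-01", None, "µg/L"),
             ("S1", "A", "2015-02-01", None, "µg/L"),
             ("S2", "A", "2015-01-01", 5.0, "µg/L")]
        )
        profiles = build_profiles(recs, simple_benchmarks)
        out = occurrence_summary(profiles, {"S1": 100, "S2": 200})
        row = out.iloc[0]
        assert row["n_systems_with_data"] == 2
        assert row["n_systems_with_detections"] == 1
        assert row["population_with_detections"] == pytest.approx(200)
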