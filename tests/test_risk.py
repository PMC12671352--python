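"""Deterministic risk indices against the published report tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foodrisk import (
    ConcentrationTable,
    ExposureScenario,
    compute_risk_table,
    estimated_daily_intake,
    exceedance_report,
    hazard_index,
    site_summary,
    target_hazard_quotient,
)
from foodrisk.errors import DomainError, UnknownMetalError, UnknownSiteError
from reference_values import (
    HI_ORDER,
    PRINTED_FOLDS,
    PRINTED_RISK_TABLE,
    printed_tolerance,
)

positive = st.floats(min_value=1e-3, max_value=1e4,
                     allow_nan=False, allow_infinity=False)


class TestEstimatedDailyIntake:
    def test_published_iron_cell(self):
        # CS1A Fe: 519.24 mg/kg at 60 g/day over 58 kg
        assert round(estimated_daily_intake(519.24), 2) == 537.14

    def test_published_zinc_cell(self):
        assert estimated_daily_intake(844.94) == pytest.approx(874.08,
                                                               abs=0.005)

    def test_zero_and_negative(self):
        assert estimated_daily_intake(0.0) == 0.0
        with pytest.raises(DomainError):
            estimated_daily_intake(-1.0)

    @settings(derandomize=True, max_examples=50)
    @given(c=positive, k=positive)
    def test_homogeneity_in_concentration_and_rates(self, c, k):
        s = ExposureScenario()
        base = estimated_daily_intake(c, s)
        assert estimated_daily_intake(k * c, s) == pytest.approx(
            k * base, rel=1e-9)
        scaled_dir = ExposureScenario(dir=s.dir * k)
        assert estimated_daily_intake(c, scaled_dir) == pytest.approx(
            k * base, rel=1e-9)
        scaled_bw = ExposureScenario(bw=s.bw * k)
        assert estimated_daily_intake(c, scaled_bw) == pytest.approx(
            base / k, rel=1e-9)


class TestTargetHazardQuotient:
    def test_published_copper_cell(self):
        assert target_hazard_quotient(88.36, 0.04) == pytest.approx(
            2.209, abs=5e-4)

    def test_zero_intake(self):
        assert target_hazard_quotient(0.0, 0.04) == 0.0

    def test_averaging_time_scaling(self):
        half = ExposureScenario(ef=365, ed=35, at=25550)
        assert target_hazard_quotient(1.0, 0.001, half) == pytest.approx(0.5)

    def test_missing_reference_dose_names_metal(self):
        with pytest.raises(DomainError, match="Hg"):
            target_hazard_quotient(1.0, None, metal="Hg")

    @settings(derandomize=True, max_examples=50)
    @given(edi=positive, rfd=positive)
    def test_scenario_identity_when_ef_ed_equals_at(self, edi, rfd):
        # with EF*ED = AT, THQ * RfD * 1e3 recovers the EDI exactly
        s = ExposureScenario(ef=365, ed=70, at=25550)
        thq = target_hazard_quotient(edi, rfd, s)
        assert thq * rfd * 1e3 == pytest.approx(edi, rel=1e-12)


class TestHazardIndex:
    def test_sum_and_threshold_flag(self):
        hi = hazard_index({"Cd": 0.4, "Pb": 0.3})
        assert hi.value == pytest.approx(0.7) and not hi.exceeds
        assert hazard_index({"Cd": 0.6, "Pb": 0.6}).exceeds

    def test_all_zero_and_single_metal(self):
        assert hazard_index({"Cd": 0.0, "Pb": 0.0}) == (0.0, False)
        assert hazard_index({"Cd": 2.2}).value == 2.2

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            hazard_index({})

    @settings(derandomize=True, max_examples=30)
    @given(st.dictionaries(st.sampled_from(list(HI_ORDER)), positive,
                           min_size=2, max_size=7))
    def test_permutation_invariant_and_additive(self, thqs):
        value = hazard_index(thqs).value
        reversed_ = dict(reversed(list(thqs.items())))
        assert hazard_index(reversed_).value == pytest.approx(value)
        keys = list(thqs)
        left = {k: thqs[k] for k in keys[:1]}
        right = {k: thqs[k] for k in keys[1:]}
        assert (hazard_index(left).value + hazard_index(right).value
                == pytest.approx(value, rel=1e-12))


class TestRiskTableAgainstPublished:
    def test_every_cell_within_printed_precision(self, risk_table):
        for sample, (edis, thqs, hi) in PRINTED_RISK_TABLE.items():
            for metal, printed in zip(HI_ORDER, edis):
                assert risk_table.edi.at[sample, metal] == pytest.approx(
                    float(printed), abs=printed_tolerance(printed)), (
                    f"EDI {sample}/{metal}")
            for metal, printed in zip(HI_ORDER, thqs):
                assert risk_table.thq.at[sample, metal] == pytest.approx(
                    float(printed), abs=printed_tolerance(printed)), (
                    f"THQ {sample}/{metal}")
            assert risk_table.hi.at[sample] == pytest.approx(
                float(hi), abs=printed_tolerance(hi)), f"HI {sample}"

    def test_hazard_index_extrema_by_site(self, risk_table):
        cec = site_summary(risk_table, "Cecomaf")
        lut = site_summary(risk_table, "Lutendele")
        assert cec.hi_max == pytest.approx(16.11, abs=0.02)
        assert cec.hi_min == pytest.approx(2.98, abs=0.02)
        assert lut.hi_max == pytest.approx(12.15, abs=0.02)
        assert lut.hi_min == pytest.approx(4.85, abs=0.02)
        assert (cec.n, lut.n) == (11, 8)

    def test_full_precision_hazard_indices(self, risk_table):
        # independently recomputed from the concentration table
        assert round(risk_table.hi.at["CS4M"], 2) == 2.99
        assert round(risk_table.hi.at["LS4A"], 2) == 12.15

    def test_hi_equals_sum_of_thq(self, risk_table):
        np.testing.assert_allclose(risk_table.hi.to_numpy(),
                                   risk_table.thq.sum(axis=1).to_numpy(),
                                   rtol=1e-12)

    def test_all_zero_table_gives_zero_indices(self, brassica):
        zeros = ConcentrationTable(brassica.data * 0.0, brassica.sites)
        rt = compute_risk_table(zeros)
        assert (rt.edi.to_numpy() == 0).all()
        assert (rt.hi.to_numpy() == 0).all()

    def test_missing_metal_named_in_error(self, brassica):
        dropped = ConcentrationTable(brassica.data.drop(columns=["Pb"]),
                                     brassica.sites)
        with pytest.raises(UnknownMetalError, match="Pb"):
            compute_risk_table(dropped)

    def test_single_sample_site_summary(self, brassica):
        one = ConcentrationTable(brassica.data.iloc[:1],
                                 brassica.sites.iloc[:1])
        rt = compute_risk_table(one)
        s = site_summary(rt, "Cecomaf")
        assert s.hi_min == s.hi_max == s.hi_mean

    def test_unknown_site_rejected(self, risk_table):
        with pytest.raises(UnknownSiteError):
            site_summary(risk_table, "Atlantis")


class TestExceedanceScreening:
    def test_published_fold_ratios(self, brassica):
        report = exceedance_report(brassica)
        folds = report.frame.set_index("metal")["fold"]
        for metal, fold in PRINTED_FOLDS.items():
            assert folds[metal] == pytest.approx(fold)

    def test_lead_fold_follows_the_table_not_the_narrative(self, brassica):
        # 30.94 / 0.3 = 103.1; the published narrative prints 103.3
        report = exceedance_report(brassica)
        folds = report.frame.set_index("metal")["fold"]
        assert round(folds["Pb"], 1) == 103.1

    def test_exceeding_set(self, brassica):
        report = exceedance_report(brassica)
        assert set(report.exceeding_metals) == {"Cr", "Cu", "Cd", "Pb", "Hg"}

    def test_boundary_fold_of_one_does_not_exceed(self, brassica, registry):
        data = brassica.data.copy()
        data["Cd"] = registry["Cd"].food_limit  # max equals the limit
        table = ConcentrationTable(data, brassica.sites)
        report = exceedance_report(table)
        row = report.frame.set_index("metal").loc["Cd"]
        assert row["fold"] == pytest.approx(1.0) and not row["exceeds"]

    def test_monotone_in_concentration(self, brassica):
        base = exceedance_report(brassica).frame.set_index("metal")
        scaled = ConcentrationTable(brassica.data * 3.0, brassica.sites)
        more = exceedance_report(scaled).frame.set_index("metal")
        assert (more["fold"] >= base["fold"]).all()
        assert (more["exceeds"] | ~base["exceeds"]).all()

    def test_site_filter(self, brassica):
        lut = exceedance_report(brassica, site="Lutendele")
        folds = lut.frame.set_index("metal")["fold"]
        assert folds["Cd"] == pytest.approx(0.57 / 0.1)
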