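import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietpaf as dp
from dietpaf.errors import ContractError, InvalidInputError


def rr_cont(value, increment, factor=None):
    return dp.RelativeRisk(value, value, value, increment=increment,
                           exposure_form="continuous", factor_id=factor)


class TestDeviation:
    def test_excess_over_threshold(self):
        cf = dp.Counterfactual("at_most", 50.0)
        assert dp.deviation_from_counterfactual(58.37, cf, "harmful") == pytest.approx(8.37)

    def test_recommendation_met_contributes_zero(self):
        cf = dp.Counterfactual("at_least", 30.0)
        assert dp.deviation_from_counterfactual(34.9, cf, "protective") == 0.0

    def test_non_consumer_carries_full_deficit(self):
        cf = dp.Counterfactual("at_least", 300.0)
        assert dp.deviation_from_counterfactual(0.0, cf, "protective") == 300.0

    def test_any_intake_routed_to_dichotomous_path(self):
        with pytest.raises(ContractError):
            dp.deviation_from_counterfactual(10.0, dp.Counterfactual("any_intake"), "harmful")

    def test_undefined_direction_scenario_combinations(self):
        with pytest.raises(ContractError):
            dp.deviation_from_counterfactual(
                10.0, dp.Counterfactual("at_least", 30.0), "harmful"
            )

    @given(
        intake=st.floats(min_value=0, max_value=1000),
        threshold=st.floats(min_value=1, max_value=500),
    )
    @settings(max_examples=50, derandomize=True)
    def test_deviations_never_negative(self, intake, threshold):
        for kind, direction in [
            ("zero_intake", "harmful"),
            ("at_most", "harmful"),
            ("at_least", "protective"),
        ]:
            cf = dp.Counterfactual(kind, threshold if kind != "zero_intake" else None)
            assert dp.deviation_from_counterfactual(intake, cf, direction) >= 0.0


class TestExcessRR:
    def test_one_full_increment(self):
        assert dp.excess_rr(rr_cont(1.16, 50), 50.0) == pytest.approx(0.16)

    def test_zero_deviation(self):
        assert dp.excess_rr(rr_cont(1.16, 50), 0.0) == 0.0

    def test_protective_uses_reciprocal(self):
        # one full 10 g deficit of a protective factor: ERR = 1/0.93 - 1
        assert dp.excess_rr(rr_cont(0.93, 10), 10.0) == pytest.approx(1 / 0.93 - 1)

    def test_negative_deviation_rejected(self):
        with pytest.raises(InvalidInputError):
            dp.excess_rr(rr_cont(1.16, 50), -1.0)


class TestContinuousPAF:
    def test_hand_computed_three_category_distribution(self):
        # explicit arithmetic oracle: probs (0.2, 0.4, 0.4), intakes
        # (0, 10, 60), RR 1.5 per 50 g/day, zero-intake counterfactual
        dist = dp.ExposureDistribution(
            probabilities=[0.2, 0.4, 0.4],
            representative_values=[0.0, 10.0, 60.0],
            boundaries=[0.0, 30.0, 100.0],
        )
        rr = rr_cont(1.5, 50)
        s = 0.4 * (1.5 ** (10 / 50) - 1) + 0.4 * (1.5 ** (60 / 50) - 1)
        est = dp.paf_continuous(dist, rr, dp.Counterfactual("zero_intake"))
        assert est.paf == pytest.approx(s / (1 + s), rel=1e-12)

    def test_processed_meat_reproduces_published_value(self, config):
        pair = next(p for p in config.pairs if p.factor_id == "processed_meat")
        dist = dp.build_exposure_distribution(config.summaries[("processed_meat", "male")])
        est = dp.paf_continuous(dist, pair.rr, pair.counterfactual)
        assert est.paf == pytest.approx(0.105, abs=0.003)

    def test_all_mass_meeting_counterfactual_gives_zero(self):
        dist = dp.ExposureDistribution(
            probabilities=[0.0, 0.5, 0.5],
            representative_values=[0.0, 40.0, 45.0],
            boundaries=[0.0, 42.0, 50.0],
        )
        est = dp.paf_continuous(
            dist, rr_cont(0.9, 10), dp.Counterfactual("at_least", 35.0)
        )
        assert est.paf == 0.0

    def test_factor_mismatch_is_contract_error(self, config):
        dist = dp.build_exposure_distribution(config.summaries[("fiber", "male")])
        with pytest.raises(ContractError):
            dp.paf_continuous(dist, rr_cont(1.16, 50, factor="processed_meat"),
                              dp.Counterfactual("zero_intake"))

    def test_dichotomous_rr_rejected(self):
        rr = dp.RelativeRisk(0.66, 0.55, 0.78, exposure_form="any_vs_none")
        dist = dp.ExposureDistribution([1.0], [0.0], [0.0])
        with pytest.raises(ContractError):
            dp.paf_continuous(dist, rr, dp.Counterfactual("zero_intake"))

    def test_monotone_in_rr_for_harmful_factor(self, config):
        summary = config.summaries[("processed_meat", "male")]
        dist = dp.build_exposure_distribution(summary)
        cf = dp.Counterfactual("zero_intake")
        pafs = [dp.paf_continuous(dist, rr_cont(v, 50), cf).paf
                for v in (1.05, 1.16, 1.30, 1.50)]
        assert all(a < b for a, b in zip(pafs, pafs[1:]))

    def test_monotone_in_mean_intake(self):
        # harmful: more intake, more attributable; protective factor
        # (deficit counterfactual): more intake, less attributable
        cf_h, cf_p = dp.Counterfactual("zero_intake"), dp.Counterfactual("at_least", 30.0)
        h, p = [], []
        for mean in (10.0, 20.0, 40.0):
            summary = dp.IntakeSummary("x", "male", 0.9, mean, 8.0, 1000)
            dist = dp.build_exposure_distribution(summary)
            h.append(dp.paf_continuous(dist, rr_cont(1.2, 50), cf_h).paf)
            p.append(dp.paf_continuous(dist, rr_cont(0.9, 10), cf_p).paf)
        assert h == sorted(h) and p == sorted(p, reverse=True)

    def test_invariant_to_splitting_categories(self):
        rr = rr_cont(1.3, 50)
        cf = dp.Counterfactual("zero_intake")
        whole = dp.ExposureDistribution([0.2, 0.3, 0.5], [0.0, 20.0, 70.0], [0, 40, 100])
        split = dp.ExposureDistribution(
            [0.2, 0.15, 0.15, 0.5], [0.0, 20.0, 20.0 + 1e-12, 70.0], [0, 40, 40, 100]
        )
        a = dp.paf_continuous(whole, rr, cf).paf
        b = dp.paf_continuous(split, rr, cf).paf
        assert a == pytest.approx(b, rel=1e-9)


class TestDichotomousPAF:
    @pytest.mark.parametrize(
        "rr,prev,expected",
        [
            (0.66, 0.91, 0.319),  # coffee and liver cancer, men
            (0.87, 0.51, 0.071),  # citrus fruit and cardia stomach cancer, women
        ],
    )
    def test_levin_formula_protective(self, rr, prev, expected):
        est = dp.paf_dichotomous(
            dp.RelativeRisk(rr, rr, rr, exposure_form="any_vs_none"), prev
        )
        assert round(est.paf, 3) == expected

    def test_null_rr_gives_zero(self):
        est = dp.paf_dichotomous(
            dp.RelativeRisk(1.0, 1.0, 1.0, exposure_form="any_vs_none"), 0.5
        )
        assert est.paf == 0.0

    def test_continuous_rr_rejected(self):
        with pytest.raises(ContractError):
            dp.paf_dichotomous(rr_cont(1.16, 50), 0.5)

    def test_levin_collapse_of_continuous_formula(self):
        # a two-point exposure distribution (0 with prob 1-Pr, x with
        # prob Pr) must give the same PAF as Levin's formula with
        # RR = exp(ln(r)/increment * x)
        x, prev = 37.0, 0.7
        rr = rr_cont(1.25, 50)
        dist = dp.ExposureDistribution([1 - prev, prev], [0.0, x], [0.0, x])
        cont = dp.paf_continuous(dist, rr, dp.Counterfactual("zero_intake")).paf
        rr_eff = math.exp(math.log(1.25) / 50 * x)
        lev = dp.paf_dichotomous(
            dp.RelativeRisk(rr_eff, rr_eff, rr_eff, exposure_form="any_vs_none"), prev
        ).paf
        assert cont == pytest.approx(lev, rel=1e-12)


def test_mgf_closed_form_oracle(config):
    # for a zero-intake counterfactual the PAF has a closed form via the
    # gamma moment generating function: S = prev * (M(t) - 1),
    # M(t) = (1 - scale*t)^(-shape), t = ln(RR)/increment
    summary = config.summaries[("processed_meat", "male")]
    params = dp.fit_gamma_moments(summary.mean_intake, summary.sd_intake)
    t = math.log(1.16) / 50.0
    m = (1.0 - params.scale * t) ** (-params.shape)
    s = summary.prevalence * (m - 1.0)
    expected = s / (1.0 + s)
    dist = dp.build_exposure_distribution(summary, n_consumer_categories=10_000)
    pair = next(p for p in config.pairs if p.factor_id == "processed_meat")
    got = dp.paf_continuous(dist, pair.rr, pair.counterfactual).paf
    assert got == pytest.approx(expected, abs=1e-3)


def test_relative_risk_validation():
    with pytest.raises(InvalidInputError):
        dp.RelativeRisk(1.16, 1.20, 1.28, increment=50)  # low > value
    with pytest.raises(InvalidInputError):
        dp.RelativeRisk(1.16, 1.10, 1.28)  # continuous without increment
    with pytest.raises(InvalidInputError):
        dp.Counterfactual("at_most")  # threshold required
    with pytest.raises(InvalidInputError):
        dp.Counterfactual("banana")
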