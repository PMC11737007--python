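import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gamma as scipy_gamma

import dietpaf as dp
from dietpaf.errors import InvalidInputError


@pytest.mark.parametrize(
    "mean,sd,shape,scale",
    [
        # closed-form moment equations: shape=(mean/sd)^2, scale=sd^2/mean
        (40.7, 31.0, (40.7 / 31.0) ** 2, 31.0**2 / 40.7),
        (10.0, 10.0, 1.0, 10.0),  # mean == sd forces the exponential case
        (19.6, 7.3, (19.6 / 7.3) ** 2, 7.3**2 / 19.6),
    ],
)
def test_fit_gamma_moments_closed_form(mean, sd, shape, scale):
    params = dp.fit_gamma_moments(mean, sd)
    assert params.shape == pytest.approx(shape, rel=1e-12)
    assert params.scale == pytest.approx(scale, rel=1e-12)
    # the fit must reproduce the moments it was given
    assert params.mean == pytest.approx(mean, rel=1e-12)
    assert params.sd == pytest.approx(sd, rel=1e-12)


@pytest.mark.parametrize("mean,sd", [(0.0, 10.0), (-5.0, 10.0), (10.0, 0.0), (10.0, -1.0)])
def test_fit_gamma_moments_rejects_nonpositive(mean, sd):
    with pytest.raises(InvalidInputError, match="fiber"):
        dp.fit_gamma_moments(mean, sd, factor="fiber")


@given(
    mean=st.floats(min_value=0.5, max_value=500.0),
    sd=st.floats(min_value=0.5, max_value=300.0),
)
@settings(max_examples=50, derandomize=True)
def test_fit_gamma_moments_round_trip(mean, sd):
    params = dp.fit_gamma_moments(mean, sd)
    assert params.mean == pytest.approx(mean, rel=1e-9)
    assert params.sd == pytest.approx(sd, rel=1e-9)


def test_exposure_categories_prevalence_arithmetic(processed_meat_men):
    dist = dp.build_exposure_distribution(processed_meat_men)
    assert dist.n_categories == 11
    assert dist.probabilities[0] == pytest.approx(0.13)
    np.testing.assert_allclose(dist.probabilities[1:], 0.087)
    assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
    assert dist.representative_values[0] == 0.0
    assert (np.diff(dist.representative_values[1:]) > 0).all()


def test_full_prevalence_splits_consumers_evenly(config):
    dist = dp.build_exposure_distribution(config.summaries[("fiber", "male")])
    assert dist.probabilities[0] == pytest.approx(0.0)
    np.testing.assert_allclose(dist.probabilities[1:], 0.1)


def test_lowest_category_midpoint_is_half_first_decile(config):
    # independent oracle: representative value of consumer category 1 is
    # q_{0.1}/2 of the fitted gamma, since the lower boundary is 0
    summary = config.summaries[("fiber", "male")]
    dist = dp.build_exposure_distribution(summary)
    q10 = scipy_gamma.ppf(0.1, a=(19.6 / 7.3) ** 2, scale=7.3**2 / 19.6)
    assert dist.representative_values[1] == pytest.approx(q10 / 2.0, rel=1e-12)


def test_top_category_capped_at_quantile(processed_meat_men):
    dist = dp.build_exposure_distribution(processed_meat_men, cap_quantile=0.99)
    params = dp.fit_gamma_moments(40.7, 31.0)
    assert dist.boundaries[-1] == pytest.approx(params.ppf(0.99), rel=1e-12)
    top_mid = (params.ppf(0.9) + params.ppf(0.99)) / 2.0
    assert dist.representative_values[-1] == pytest.approx(top_mid, rel=1e-12)


def test_discretized_mean_close_to_population_mean(config):
    # probability-weighted representative intake should track
    # prevalence * mean for every survey row with a continuous intake
    for (factor, sex), summary in config.summaries.items():
        if summary.mean_intake is None:
            continue
        dist = dp.build_exposure_distribution(summary)
        target = summary.prevalence * summary.mean_intake
        assert dist.mean == pytest.approx(target, rel=0.05), (factor, sex)


def test_zero_prevalence_degenerates_to_point_mass():
    summary = dp.IntakeSummary("salt_fish", "male", 0.0, n_subjects=100)
    dist = dp.build_exposure_distribution(summary)
    assert dist.probabilities.tolist() == [1.0]
    assert dist.representative_values.tolist() == [0.0]


def test_missing_moments_with_positive_prevalence_is_an_error():
    summary = dp.IntakeSummary("citrus", "male", 0.45, n_subjects=1068)
    with pytest.raises(InvalidInputError, match="citrus"):
        dp.build_exposure_distribution(summary)


def test_discretization_convergence(config):
    # the operational 10-category grid sits within 1 pp of the converged
    # PAF for every pair (within 0.5 pp for all but the strongest
    # dose-response), and the scheme converges: K=100 vs K=1000 differ
    # by < 0.1 pp everywhere
    for pair in config.pairs:
        if pair.rr.exposure_form != "continuous":
            continue
        summary = config.summaries[(pair.factor_id, "male")]
        paf = {
            k: dp.paf_continuous(
                dp.build_exposure_distribution(summary, k), pair.rr, pair.counterfactual
            ).paf
            for k in (10, 100, 1000)
        }
        assert abs(paf[10] - paf[1000]) < 0.010, (pair.factor_id, pair.cancer_id)
        assert abs(paf[100] - paf[1000]) < 0.001, (pair.factor_id, pair.cancer_id)


def test_invalid_summary_fields_rejected():
    with pytest.raises(InvalidInputError):
        dp.IntakeSummary("x", "male", 1.2)
    with pytest.raises(InvalidInputError):
        dp.IntakeSummary("x", "male", 0.5, mean_intake=-1.0, sd_intake=1.0)
    with pytest.raises(InvalidInputError):
        dp.IntakeSummary("x", "other", 0.5)
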