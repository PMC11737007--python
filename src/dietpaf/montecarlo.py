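"""Monte Carlo propagation of sampling uncertainty into PAF confidence intervals.

Each simulation draws the quantities the point estimate treats as
fixed, from their asymptotic sampling distributions:

* ``ln RR ~ Normal(ln value, sd)`` with ``sd`` derived from the
  published 95% CI;
* for continuous factors, the consumer mean intake
  ``~ Normal(mean, sd_intake / sqrt(n_consumers))``; the gamma is
  refitted with the simulated mean and the observed SD and the exposure
  distribution rebuilt;
* for dichotomous factors, the consumer prevalence from the normal
  approximation of the binomial, truncated to [0, 1].

The PAF is recomputed per draw and the empirical 2.5th/97.5th
percentiles form the 95% CI, with a negative lower bound clipped to
zero. Draws where the simulated RR crosses 1 are kept: the direction of
the contrast stays that of the published RR, so such draws contribute
negative PAFs and widen the interval honestly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma
from scipy.stats import norm

from .errors import InvalidInputError
from .intake import IntakeSummary
from .paf import Counterfactual, RelativeRisk

__all__ = [
    "SimulationSettings",
    "PAFSampleSet",
    "rr_sampling_sd",
    "simulate_paf_distribution",
    "percentile_ci",
]

# two-sided 97.5% normal quantile used to back out the SE from a 95% CI
_Z975 = norm.ppf(0.975)


@dataclass(frozen=True)
class SimulationSettings:
    """Number of Monte Carlo draws, RNG seed and CI level."""

    n_sims: int = 10_000
    seed: int = 0
    ci_level: float = 0.95
    n_consumer_categories: int = 10
    cap_quantile: float | None = None

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise InvalidInputError("n_sims must be at least 1")
        if not 0.0 < self.ci_level < 1.0:
            raise InvalidInputError("ci_level must be in (0, 1)")


@dataclass
class PAFSampleSet:
    """Monte Carlo PAF draws for one factor-cancer-sex pair."""

    samples: np.ndarray
    factor_id: str | None = None
    cancer_id: str | None = None
    sex: str | None = None
    seed: int | None = None
    n_redraws: int = 0  # simulated means <= 0 that were redrawn

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) == 0:
            raise InvalidInputError("samples must be a non-empty 1-d array")


def rr_sampling_sd(rr: RelativeRisk) -> float:
    """Standard deviation of ln RR implied by its 95% CI.

    ``(ln ci_high - ln ci_low) / (2 * z_0.975)``; 0 for a degenerate CI.
    """
    if rr.ci_high < rr.ci_low:
        raise InvalidInputError("RR CI has ci_high < ci_low")
    return float(np.log(rr.ci_high / rr.ci_low) / (2.0 * _Z975))


def _signed_log_rr_per_gram(log_rr_draws: np.ndarray, rr: RelativeRisk) -> np.ndarray:
    # direction is fixed by the published RR; protective factors use the
    # reciprocal of the simulated RR, so a draw crossing 1 flips sign.
    sign = 1.0 if rr.direction == "harmful" else -1.0
    return sign * log_rr_draws / rr.increment


def simulate_paf_distribution(
    rr: RelativeRisk,
    counterfactual: Counterfactual,
    summary: IntakeSummary,
    settings: SimulationSettings,
    cancer_id: str | None = None,
) -> PAFSampleSet:
    """Draw a Monte Carlo sample of PAFs for one factor-cancer-sex pair.

    Identical settings (including seed) give bit-identical sample sets.
    """
    rng = np.random.default_rng(settings.seed)
    n = settings.n_sims
    log_rr = rng.normal(np.log(rr.value), rr_sampling_sd(rr), size=n)

    if rr.exposure_form == "any_vs_none":
        p = summary.prevalence
        if summary.n_subjects <= 0:
            raise InvalidInputError(f"{summary.factor_id}: n_subjects required for simulation")
        se = np.sqrt(p * (1.0 - p) / summary.n_subjects)
        prev = np.clip(rng.normal(p, se, size=n), 0.0, 1.0)
        r = np.exp(log_rr) if rr.direction == "harmful" else np.exp(-log_rr)
        s = (r - 1.0) * prev
        samples = s / (1.0 + s)
        n_redraws = 0
    else:
        if summary.mean_intake is None or summary.sd_intake is None:
            raise InvalidInputError(f"{summary.factor_id}: mean/SD required for simulation")
        n_consumers = summary.n_consumers
        if n_consumers <= 0:
            raise InvalidInputError(f"{summary.factor_id}: no consumers in stratum")
        se_mean = summary.sd_intake / np.sqrt(n_consumers)
        mean = rng.normal(summary.mean_intake, se_mean, size=n)
        n_redraws = 0
        while (bad := mean <= 0).any():  # keep the gamma defined
            n_redraws += int(bad.sum())
            mean[bad] = rng.normal(summary.mean_intake, se_mean, size=int(bad.sum()))
        samples = _continuous_paf_draws(
            mean, summary.sd_intake, summary.prevalence, log_rr, rr, counterfactual,
            settings.n_consumer_categories, settings.cap_quantile,
        )

    return PAFSampleSet(
        samples=samples,
        factor_id=summary.factor_id,
        cancer_id=cancer_id,
        sex=summary.sex,
        seed=settings.seed,
        n_redraws=n_redraws,
    )


def _continuous_paf_draws(
    mean: np.ndarray,
    sd: float,
    prevalence: float,
    log_rr: np.ndarray,
    rr: RelativeRisk,
    counterfactual: Counterfactual,
    K: int,
    cap_quantile: float | None,
) -> np.ndarray:
    """Vectorized rebuild of the exposure distribution per draw."""
    if cap_quantile is None:
        cap_quantile = 1.0 - 0.1 / K
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    probs_q = np.concatenate([np.arange(1, K) / K, [cap_quantile]])
    q = _gamma.ppf(probs_q[None, :], a=shape[:, None], scale=scale[:, None])
    bounds = np.concatenate([np.zeros((len(mean), 1)), q], axis=1)
    mids = (bounds[:, :-1] + bounds[:, 1:]) / 2.0
    values = np.concatenate([np.zeros((len(mean), 1)), mids], axis=1)

    kind = counterfactual.kind
    direction = rr.direction
    if direction == "harmful" and kind == "zero_intake":
        dev = values
    elif direction == "harmful" and kind == "at_most":
        dev = np.maximum(0.0, values - counterfactual.threshold)
    elif direction == "protective" and kind == "at_least":
        dev = np.maximum(0.0, counterfactual.threshold - values)
    else:
        raise InvalidInputError(
            f"counterfactual {kind!r} undefined for a {direction} factor"
        )

    weights = np.concatenate([[1.0 - prevalence], np.full(K, prevalence / K)])
    err = np.exp(_signed_log_rr_per_gram(log_rr, rr)[:, None] * dev) - 1.0
    s = err @ weights
    return s / (1.0 + s)


def percentile_ci(samples: PAFSampleSet | np.ndarray, ci_level: float = 0.95):
    """Empirical percentile CI of a PAF sample, lower bound clipped at 0."""
    x = samples.samples if isinstance(samples, PAFSampleSet) else np.asarray(samples, float)
    if len(x) == 0:
        raise InvalidInputError("empty sample set")
    alpha = 1.0 - ci_level
    low, high = np.quantile(x, [alpha / 2.0, 1.0 - alpha / 2.0])
    return max(0.0, float(low)), float(high)
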