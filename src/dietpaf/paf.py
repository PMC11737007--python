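"""Population attributable fraction (PAF) point estimation.

Two exposure contrasts are supported:

* **Continuous factors** — the population's discretized intake
  distribution is compared to a counterfactual (recommended-intake)
  scenario. For each category ``k`` the deviation ``Dev_k`` from the
  recommendation is converted into an excess relative risk
  ``ERR_k = exp(lnRR_1g * Dev_k) - 1`` using the log-linear
  dose-response implied by a published RR per intake increment, and

      PAF = sum_k Pr_k * ERR_k / (1 + sum_k Pr_k * ERR_k).

  For protective factors the reciprocal of the RR is used, so that
  ``lnRR_1g`` measures the risk increase per gram of *deficit*.

* **Dichotomous (any-vs-none) factors** — Levin's formula
  ``PAF = Pr (RR - 1) / (1 + Pr (RR - 1))`` with ``Pr`` the proportion
  of consumers and, for protective factors, the reciprocal RR.

Deviations are floored at zero: a category already meeting the
recommendation contributes no excess risk, rather than a negative one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, InvalidInputError
from .intake import ExposureDistribution

__all__ = [
    "RelativeRisk",
    "Counterfactual",
    "PAFEstimate",
    "deviation_from_counterfactual",
    "excess_rr",
    "paf_continuous",
    "paf_dichotomous",
]

EXPOSURE_FORMS = ("continuous", "any_vs_none")
COUNTERFACTUAL_KINDS = ("zero_intake", "at_most", "at_least", "any_intake")


@dataclass(frozen=True)
class RelativeRisk:
    """A published relative risk with its 95% CI.

    For continuous factors the RR refers to an intake ``increment`` in
    g/day (e.g. 1.16 per 50 g/day of processed meat). For any-vs-none
    factors the increment is absent. A factor is *protective* when its
    RR is below 1.
    """

    value: float
    ci_low: float
    ci_high: float
    increment: float | None = None
    exposure_form: str = "continuous"
    factor_id: str | None = None

    def __post_init__(self) -> None:
        if self.exposure_form not in EXPOSURE_FORMS:
            raise InvalidInputError(f"unknown exposure form {self.exposure_form!r}")
        if not 0 < self.ci_low <= self.value <= self.ci_high:
            raise InvalidInputError(
                f"RR CI must satisfy 0 < low <= value <= high, got "
                f"{self.value} ({self.ci_low}-{self.ci_high})"
            )
        if self.exposure_form == "continuous":
            if self.increment is None or self.increment <= 0:
                raise InvalidInputError("continuous RR requires a positive increment")

    @property
    def direction(self) -> str:
        return "protective" if self.value < 1.0 else "harmful"

    @property
    def log_rr_per_gram(self) -> float:
        """ln RR per 1 g/day of deviation; positive for both directions.

        Harmful factors use ln(RR)/increment; protective factors the
        reciprocal, ln(1/RR)/increment, the risk increase per gram of
        deficit relative to the recommendation.
        """
        if self.exposure_form != "continuous":
            raise ContractError("log_rr_per_gram is defined for continuous RRs only")
        r = self.value if self.direction == "harmful" else 1.0 / self.value
        return math.log(r) / self.increment


@dataclass(frozen=True)
class Counterfactual:
    """Recommended-intake scenario the population is compared against.

    ``zero_intake``: no consumption at all (harmful factors, e.g.
    processed meat); ``at_most``/``at_least``: a g/day threshold;
    ``any_intake``: the dichotomous any-vs-none contrast.
    """

    kind: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in COUNTERFACTUAL_KINDS:
            raise InvalidInputError(f"unknown counterfactual kind {self.kind!r}")
        if self.kind in ("at_most", "at_least"):
            if self.threshold is None or self.threshold <= 0:
                raise InvalidInputError(f"counterfactual {self.kind} requires threshold > 0")
        elif self.threshold is not None:
            raise InvalidInputError(f"counterfactual {self.kind} takes no threshold")


@dataclass
class PAFEstimate:
    """A PAF point estimate, optionally with a percentile CI attached."""

    paf: float
    ci_low: float | None = None
    ci_high: float | None = None
    factor_id: str | None = None
    cancer_id: str | None = None
    sex: str | None = None


def deviation_from_counterfactual(intake, counterfactual: Counterfactual, direction: str):
    """Deviation (g/day) of an intake from the counterfactual scenario.

    The deviation is the excess (harmful factors) or deficit
    (protective factors) relative to the recommendation, floored at
    zero so intakes already meeting it contribute nothing. Accepts a
    scalar or an array of intakes.
    """
    intake = np.asarray(intake, dtype=float)
    if (intake < 0).any():
        raise InvalidInputError("intake must be non-negative")
    kind = counterfactual.kind
    if kind == "any_intake":
        raise ContractError(
            "any-vs-none counterfactuals use the dichotomous path (paf_dichotomous)"
        )
    if direction == "harmful" and kind == "zero_intake":
        dev = intake.copy()
    elif direction == "harmful" and kind == "at_most":
        dev = np.maximum(0.0, intake - counterfactual.threshold)
    elif direction == "protective" and kind == "at_least":
        dev = np.maximum(0.0, counterfactual.threshold - intake)
    else:
        raise ContractError(
            f"counterfactual {kind!r} is not defined for a {direction} factor"
        )
    return float(dev) if dev.ndim == 0 else dev


def excess_rr(rr: RelativeRisk, deviation):
    """Excess relative risk for a deviation from the counterfactual.

    ``ERR = exp(lnRR_1g * Dev) - 1`` with the reciprocal RR for
    protective factors, so ERR is non-negative whenever the deviation
    is. Accepts a scalar or array deviation.
    """
    deviation = np.asarray(deviation, dtype=float)
    if (deviation < 0).any():
        raise InvalidInputError("deviation must be non-negative")
    err = np.exp(rr.log_rr_per_gram * deviation) - 1.0
    return float(err) if err.ndim == 0 else err


def paf_continuous(
    dist: ExposureDistribution,
    rr: RelativeRisk,
    counterfactual: Counterfactual,
    cancer_id: str | None = None,
) -> PAFEstimate:
    """PAF of a continuous factor from its discretized exposure distribution.

    ``PAF = S / (1 + S)`` with ``S = sum_k Pr_k * ERR_k`` over all
    categories, including the non-consumers.
    """
    if rr.exposure_form != "continuous":
        raise ContractError("paf_continuous requires a continuous-exposure RR")
    if (
        rr.factor_id is not None
        and dist.factor_id is not None
        and rr.factor_id != dist.factor_id
    ):
        raise ContractError(
            f"RR is for factor {rr.factor_id!r} but distribution is {dist.factor_id!r}"
        )
    dev = deviation_from_counterfactual(dist.representative_values, counterfactual, rr.direction)
    s = float(dist.probabilities @ excess_rr(rr, dev))
    return PAFEstimate(
        paf=s / (1.0 + s),
        factor_id=dist.factor_id or rr.factor_id,
        cancer_id=cancer_id,
        sex=dist.sex,
    )


def paf_dichotomous(
    rr: RelativeRisk,
    prevalence_consumers: float,
    factor_id: str | None = None,
    cancer_id: str | None = None,
    sex: str | None = None,
) -> PAFEstimate:
    """Levin's formula for an any-vs-none exposure contrast.

    Uses the prevalence of consumers and, for protective factors, the
    reciprocal of the RR, so the PAF measures the burden attributable
    to *not* consuming a protective food (e.g. coffee and liver
    cancer).
    """
    if rr.exposure_form != "any_vs_none":
        raise ContractError("paf_dichotomous requires an any-vs-none RR")
    if not 0.0 <= prevalence_consumers <= 1.0:
        raise InvalidInputError(f"prevalence {prevalence_consumers} outside [0, 1]")
    r = rr.value if rr.direction == "harmful" else 1.0 / rr.value
    s = (r - 1.0) * prevalence_consumers
    return PAFEstimate(
        paf=s / (1.0 + s),
        factor_id=factor_id or rr.factor_id,
        cancer_id=cancer_id,
        sex=sex,
    )
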