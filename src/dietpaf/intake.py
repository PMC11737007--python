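"""Exposure modelling for dietary intakes.

Food-consumption surveys are usually published as summary statistics:
the share of the population that consumes a food at all, and the mean
and standard deviation of intake among consumers. PAF formulas, on the
other hand, need a full exposure distribution. This module bridges the
two: a gamma distribution is fitted to the consumer mean/SD by the
method of moments and then discretized into a fixed number of
equal-probability intake categories, with the non-consumers kept as a
separate point mass at zero.

The resulting :class:`ExposureDistribution` carries, for each category,
its population share ``Pr_k`` and a representative intake in g/day (the
arithmetic midpoint of the category's quantile boundaries), which is all
downstream PAF computations consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma

from .errors import InvalidInputError

__all__ = [
    "IntakeSummary",
    "GammaParams",
    "ExposureDistribution",
    "fit_gamma_moments",
    "build_exposure_distribution",
]

SEXES = ("male", "female")


@dataclass(frozen=True)
class IntakeSummary:
    """Published summary of one dietary factor for one sex stratum.

    ``mean_intake`` and ``sd_intake`` are statistics *among consumers*
    (g/day); ``prevalence`` is the proportion of consumers in the
    stratum. Factors analysed as any-vs-none (e.g. coffee) carry only a
    prevalence; mean/SD are then ``None``.
    """

    factor_id: str
    sex: str
    prevalence: float
    mean_intake: float | None = None
    sd_intake: float | None = None
    n_subjects: int = 0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise InvalidInputError(f"{self.factor_id}: unknown sex {self.sex!r}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise InvalidInputError(
                f"{self.factor_id}: prevalence {self.prevalence} outside [0, 1]"
            )
        if self.mean_intake is not None and self.mean_intake <= 0:
            raise InvalidInputError(
                f"{self.factor_id}: mean intake must be positive, got {self.mean_intake}"
            )
        if self.sd_intake is not None and self.sd_intake <= 0:
            raise InvalidInputError(
                f"{self.factor_id}: SD of intake must be positive, got {self.sd_intake}"
            )
        if self.n_subjects < 0:
            raise InvalidInputError(f"{self.factor_id}: negative n_subjects")

    @property
    def n_consumers(self) -> int:
        """Survey consumers in the stratum, ``round(prevalence * n_subjects)``."""
        return int(round(self.prevalence * self.n_subjects))


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale parametrization of a gamma intake distribution."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise InvalidInputError(
                f"gamma parameters must be positive (shape={self.shape}, scale={self.scale})"
            )

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.shape) * self.scale)

    def ppf(self, q):
        """Gamma quantile function (inverse CDF)."""
        return _gamma.ppf(q, a=self.shape, scale=self.scale)


def fit_gamma_moments(
    mean_intake: float, sd_intake: float, factor: str | None = None
) -> GammaParams:
    """Fit a gamma distribution to a mean and SD by the method of moments.

    Equating the first two moments gives ``shape = (mean/sd)^2`` and
    ``scale = sd^2/mean``. The survey mean and SD are treated as
    population values; no small-sample correction is applied.
    """
    label = f"{factor}: " if factor else ""
    if mean_intake is None or sd_intake is None:
        raise InvalidInputError(f"{label}mean and SD of intake are required")
    if mean_intake <= 0:
        raise InvalidInputError(f"{label}mean intake must be positive, got {mean_intake}")
    if sd_intake <= 0:
        raise InvalidInputError(f"{label}SD of intake must be positive, got {sd_intake}")
    return GammaParams(
        shape=(mean_intake / sd_intake) ** 2,
        scale=sd_intake**2 / mean_intake,
    )


@dataclass(frozen=True)
class ExposureDistribution:
    """Discretized population distribution of intake for one factor/sex.

    Category 0 is the non-consumers (representative value 0 g/day); the
    remaining categories partition the consumers into equal-probability
    slices of the fitted gamma. ``boundaries`` holds the quantile cut
    points of the consumer categories (starting at 0, ending at the cap
    quantile).
    """

    probabilities: np.ndarray
    representative_values: np.ndarray
    boundaries: np.ndarray
    factor_id: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "probabilities", np.asarray(self.probabilities, float))
        object.__setattr__(
            self, "representative_values", np.asarray(self.representative_values, float)
        )
        object.__setattr__(self, "boundaries", np.asarray(self.boundaries, float))
        p, v = self.probabilities, self.representative_values
        if p.shape != v.shape:
            raise InvalidInputError("probabilities and representative values differ in length")
        if abs(p.sum() - 1.0) > 1e-9:
            raise InvalidInputError(f"category probabilities sum to {p.sum()!r}, not 1")
        if (v < 0).any():
            raise InvalidInputError("representative intakes must be non-negative")
        if len(v) > 1 and not (np.diff(v[1:]) > 0).all():
            raise InvalidInputError("consumer representative intakes must be increasing")

    @property
    def n_categories(self) -> int:
        return len(self.probabilities)

    @property
    def mean(self) -> float:
        """Probability-weighted mean intake of the discretized distribution."""
        return float(self.probabilities @ self.representative_values)


def build_exposure_distribution(
    summary: IntakeSummary,
    n_consumer_categories: int = 10,
    cap_quantile: float | None = None,
) -> ExposureDistribution:
    """Discretize a factor's intake into non-consumers plus gamma slices.

    Consumers are split into ``n_consumer_categories`` categories of
    equal probability, bounded by the fitted gamma's quantiles at
    k/K (k = 0..K). Each category is represented by the arithmetic
    midpoint of its boundaries; the lowest boundary is 0 and the
    unbounded top category is closed at ``cap_quantile`` so that its
    midpoint is finite. By default the cap sits at ``1 - 0.1/K``
    (0.99 for the standard 10 categories), scaling with the
    discretization so the top category stays well represented.

    A factor with prevalence 0 degenerates to a point mass at 0 g/day.
    """
    K = int(n_consumer_categories)
    if K < 2:
        raise InvalidInputError("need at least 2 consumer categories")
    if cap_quantile is None:
        cap_quantile = 1.0 - 0.1 / K
    if not (1.0 - 1.0 / K) < cap_quantile < 1.0:
        raise InvalidInputError(
            f"cap_quantile {cap_quantile} must lie strictly between 1-1/K and 1"
        )

    if summary.prevalence == 0.0:
        return ExposureDistribution(
            probabilities=np.array([1.0]),
            representative_values=np.array([0.0]),
            boundaries=np.array([0.0]),
            factor_id=summary.factor_id,
            sex=summary.sex,
        )

    if summary.mean_intake is None or summary.sd_intake is None:
        raise InvalidInputError(
            f"{summary.factor_id}: mean/SD of intake required when prevalence > 0"
        )

    params = fit_gamma_moments(summary.mean_intake, summary.sd_intake, summary.factor_id)
    inner = params.ppf(np.arange(1, K) / K)
    boundaries = np.concatenate([[0.0], inner, [params.ppf(cap_quantile)]])
    midpoints = (boundaries[:-1] + boundaries[1:]) / 2.0

    probabilities = np.concatenate(
        [[1.0 - summary.prevalence], np.full(K, summary.prevalence / K)]
    )
    values = np.concatenate([[0.0], midpoints])
    return ExposureDistribution(
        probabilities=probabilities,
        representative_values=values,
        boundaries=boundaries,
        factor_id=summary.factor_id,
        sex=summary.sex,
    )
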