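"""Attributable cases and deaths.

PAFs become absolute burden by multiplication with the observed case
(or death) counts of the matching cancer, sex and year. Registries do
not report every subtype separately, so some counts are derived from a
parent site by a fixed splitting fraction (e.g. nasopharyngeal cancers
as a share of all oral and pharyngeal cancers). Per-pair burdens are
summed into diet-related and all-cancer totals; overlapping factor
effects on the same site are summed as-is, which is why the aggregate
can exceed any single-factor PAF and should be read as an upper-end
figure.

Reported PAFs carry one decimal in percent, so PAFs are rounded to
0.001 before multiplying by counts; attributable counts are rounded to
the nearest integer (half away from zero). CI bounds of counts apply
the same arithmetic to the PAF CI bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigError, InvalidInputError

__all__ = [
    "CancerCounts",
    "SubtypeRule",
    "AttributableBurden",
    "split_subtypes",
    "attributable_count",
    "round_paf",
    "make_burden",
    "aggregate_burden",
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CancerCounts:
    """Observed cases (and optionally deaths) of one cancer for one sex/year."""

    cancer_id: str
    sex: str
    year: int
    cases: int
    deaths: int | None = None
    icd10: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cases < 0 or (self.deaths is not None and self.deaths < 0):
            raise InvalidInputError(f"{self.cancer_id}: counts must be non-negative")


@dataclass(frozen=True)
class SubtypeRule:
    """Derive a subtype's counts as a fixed fraction of a parent site.

    ``fraction`` is either a single proportion or a per-sex mapping
    (e.g. nasopharynx: 8.7% of oral/pharyngeal cancers in men, 6.9% in
    women).
    """

    parent_cancer_id: str
    subtype_id: str
    fraction: float | Mapping[str, float]

    def fraction_for(self, sex: str) -> float:
        if isinstance(self.fraction, Mapping):
            if sex not in self.fraction:
                raise ConfigError(
                    f"subtype rule {self.subtype_id}: no fraction for sex {sex!r}"
                )
            f = self.fraction[sex]
        else:
            f = self.fraction
        if not 0.0 < f <= 1.0:
            raise ConfigError(f"subtype rule {self.subtype_id}: fraction {f} outside (0, 1]")
        return float(f)


@dataclass
class AttributableBurden:
    """Attributable burden of one factor-cancer-sex pair (or an aggregate).

    ``paf`` is the full-precision estimate; ``paf_rounded`` the 0.001
    resolution used in count arithmetic, matching the one-decimal
    percent reporting convention.
    """

    factor_id: str
    cancer_id: str
    sex: str
    paf: float
    paf_rounded: float
    observed_cases: int
    attributable_cases: int
    paf_ci: tuple[float, float] | None = None
    cases_ci: tuple[int, int] | None = None
    observed_deaths: int | None = None
    attributable_deaths: int | None = None
    deaths_ci: tuple[int, int] | None = None
    exposure_year: int | None = None
    outcome_year: int | None = None


def split_subtypes(counts: CancerCounts, rule: SubtypeRule) -> CancerCounts:
    """Apply a splitting fraction to a parent site's counts."""
    if counts.cancer_id != rule.parent_cancer_id:
        raise ConfigError(
            f"subtype rule for {rule.parent_cancer_id!r} applied to {counts.cancer_id!r}"
        )
    f = rule.fraction_for(counts.sex)
    return CancerCounts(
        cancer_id=rule.subtype_id,
        sex=counts.sex,
        year=counts.year,
        cases=_round_half_away(f * counts.cases),
        deaths=None if counts.deaths is None else _round_half_away(f * counts.deaths),
        icd10=counts.icd10,
    )


def round_paf(paf: float) -> float:
    """Round a PAF to 0.001 (the 0.1 percentage-point reporting resolution)."""
    return _round_half_away(paf * 1000.0) / 1000.0


def attributable_count(paf: float, count: int) -> int:
    """Attributable cases/deaths: rounded PAF times observed count.

    The PAF is first rounded to 0.001 — the resolution at which PAFs
    are reported — and the product rounded to the nearest whole case.
    """
    if not 0.0 <= paf < 1.0:
        raise InvalidInputError(f"PAF {paf} outside [0, 1)")
    return _round_half_away(round_paf(paf) * count)


def make_burden(
    factor_id: str,
    cancer_id: str,
    sex: str,
    paf: float,
    counts: CancerCounts,
    paf_ci: tuple[float, float] | None = None,
    exposure_year: int | None = None,
) -> AttributableBurden:
    """Assemble the attributable burden of one pair from its PAF and counts."""
    paf_for_counts = max(0.0, paf)
    burden = AttributableBurden(
        factor_id=factor_id,
        cancer_id=cancer_id,
        sex=sex,
        paf=paf,
        paf_rounded=round_paf(paf),
        observed_cases=counts.cases,
        attributable_cases=attributable_count(paf_for_counts, counts.cases),
        exposure_year=exposure_year,
        outcome_year=counts.year,
    )
    if counts.deaths is not None:
        burden.observed_deaths = counts.deaths
        burden.attributable_deaths = attributable_count(paf_for_counts, counts.deaths)
    if paf_ci is not None:
        low, high = max(0.0, paf_ci[0]), paf_ci[1]
        burden.paf_ci = (low, high)
        burden.cases_ci = (
            attributable_count(low, counts.cases),
            attributable_count(high, counts.cases),
        )
        if counts.deaths is not None:
            burden.deaths_ci = (
                attributable_count(low, counts.deaths),
                attributable_count(high, counts.deaths),
            )
    return burden


def aggregate_burden(
    burdens: Sequence[AttributableBurden],
    totals: CancerCounts,
    label: str = "aggregate",
) -> AttributableBurden:
    """Sum per-pair burdens for one sex against an observed total.

    Attributable counts (and their CI bounds) are summed across pairs;
    the aggregate PAF is total attributable over total observed.
    Factors acting on the same site are summed without overlap
    correction, so the aggregate is an upper-end estimate.
    """
    if not burdens:
        raise InvalidInputError("no burdens to aggregate")
    sexes = {b.sex for b in burdens}
    if len(sexes) != 1:
        raise InvalidInputError(f"aggregation mixes sexes {sorted(sexes)}")
    if totals is None:
        raise ConfigError(f"missing totals row for aggregate {label!r}")
    total_cases = sum(b.attributable_cases for b in burdens)
    agg = AttributableBurden(
        factor_id=label,
        cancer_id=totals.cancer_id,
        sex=burdens[0].sex,
        paf=total_cases / totals.cases if totals.cases else 0.0,
        paf_rounded=round_paf(total_cases / totals.cases) if totals.cases else 0.0,
        observed_cases=totals.cases,
        attributable_cases=total_cases,
        outcome_year=totals.year,
        exposure_year=burdens[0].exposure_year,
    )
    if all(b.cases_ci is not None for b in burdens):
        agg.cases_ci = (
            sum(b.cases_ci[0] for b in burdens),
            sum(b.cases_ci[1] for b in burdens),
        )
        if totals.cases:
            agg.paf_ci = (agg.cases_ci[0] / totals.cases, agg.cases_ci[1] / totals.cases)
    if totals.deaths is not None and all(b.attributable_deaths is not None for b in burdens):
        agg.observed_deaths = totals.deaths
        agg.attributable_deaths = sum(b.attributable_deaths for b in burdens)
        if all(b.deaths_ci is not None for b in burdens):
            agg.deaths_ci = (
                sum(b.deaths_ci[0] for b in burdens),
                sum(b.deaths_ci[1] for b in burdens),
            )
    return agg
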