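"""Synthetic dietary-survey microdata.

The analysis consumes only summary statistics of a food-consumption
survey (prevalence of consumers; mean and SD of intake among
consumers). This module generates individual-level records with exactly
the statistical structure those summaries assume — consumption is
Bernoulli with the factor's prevalence, and intake among consumers is
gamma — then summarizes them back, closing the loop for parameter- and
PAF-recovery experiments with no external data.

Factors are generated independently across subjects and factors; the
real survey's within-subject correlation is irrelevant here because the
analysis never uses joint intakes. Intakes are continuous g/day with no
multi-day averaging structure, since only the summary moments feed the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .intake import IntakeSummary, build_exposure_distribution
from .paf import Counterfactual, RelativeRisk, paf_continuous

__all__ = [
    "SurveyFactorTruth",
    "generate_survey",
    "summarize_survey",
    "recovery_experiment",
    "RecoveryReport",
]


@dataclass(frozen=True)
class SurveyFactorTruth:
    """True generating parameters of one factor: Bernoulli x gamma."""

    factor_id: str
    prevalence: float
    shape: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise InvalidInputError(f"{self.factor_id}: prevalence outside [0, 1]")
        if self.prevalence > 0 and (self.shape is None or self.scale is None):
            raise InvalidInputError(f"{self.factor_id}: gamma shape/scale required")
        if self.shape is not None and self.shape <= 0:
            raise InvalidInputError(f"{self.factor_id}: shape must be positive")
        if self.scale is not None and self.scale <= 0:
            raise InvalidInputError(f"{self.factor_id}: scale must be positive")

    @property
    def mean(self) -> float:
        return 0.0 if self.prevalence == 0 else self.shape * self.scale

    @property
    def sd(self) -> float:
        return 0.0 if self.prevalence == 0 else float(np.sqrt(self.shape) * self.scale)


def generate_survey(
    truths: Sequence[SurveyFactorTruth],
    n_subjects: int,
    seed: int,
    sex: str = "male",
) -> pd.DataFrame:
    """Simulate survey microdata: one row per subject, one column per factor.

    Each subject consumes each factor with its prevalence; consumer
    intakes are gamma draws. Non-consumers have intake 0, which is also
    how consumer status is encoded.
    """
    if n_subjects < 1:
        raise InvalidInputError("n_subjects must be at least 1")
    rng = np.random.default_rng(seed)
    data = {"subject_id": np.arange(1, n_subjects + 1), "sex": sex}
    for t in truths:
        consumes = rng.random(n_subjects) < t.prevalence
        intake = np.zeros(n_subjects)
        n_cons = int(consumes.sum())
        if n_cons and t.prevalence > 0:
            intake[consumes] = rng.gamma(shape=t.shape, scale=t.scale, size=n_cons)
        data[t.factor_id] = intake
    return pd.DataFrame(data)


def summarize_survey(records: pd.DataFrame, factor_id: str, sex: str) -> IntakeSummary:
    """Summarize microdata back to the statistics the pipeline consumes.

    Prevalence is the share of subjects with positive intake; mean and
    SD are computed among consumers only (ddof=1).
    """
    sub = records[records["sex"] == sex]
    if len(sub) == 0:
        raise InvalidInputError(f"no records for sex {sex!r}")
    intake = sub[factor_id].to_numpy(dtype=float)
    consumers = intake[intake > 0]
    prevalence = len(consumers) / len(intake)
    if len(consumers) == 0:
        return IntakeSummary(factor_id=factor_id, sex=sex, prevalence=0.0,
                             n_subjects=len(intake))
    mean = float(consumers.mean())
    sd = float(consumers.std(ddof=1)) if len(consumers) > 1 else None
    return IntakeSummary(
        factor_id=factor_id,
        sex=sex,
        prevalence=prevalence,
        mean_intake=mean,
        sd_intake=sd if sd and sd > 0 else None,
        n_subjects=len(intake),
    )


@dataclass
class RecoveryReport:
    """Bias/RMSE of PAFs recomputed from synthetic survey summaries."""

    true_paf: float
    replicate_pafs: np.ndarray
    n_subjects: int
    n_replicates: int

    @property
    def bias(self) -> float:
        return float(self.replicate_pafs.mean() - self.true_paf)

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean((self.replicate_pafs - self.true_paf) ** 2)))


def paf_from_truth(
    truth: SurveyFactorTruth,
    rr: RelativeRisk,
    counterfactual: Counterfactual,
    n_consumer_categories: int = 10,
) -> float:
    """PAF implied by the true generating parameters (no sampling noise)."""
    if truth.prevalence == 0:
        summary = IntakeSummary(truth.factor_id, "male", 0.0, n_subjects=1)
    else:
        summary = IntakeSummary(
            truth.factor_id, "male", truth.prevalence,
            mean_intake=truth.mean, sd_intake=truth.sd, n_subjects=1,
        )
    dist = build_exposure_distribution(summary, n_consumer_categories)
    return paf_continuous(dist, rr, counterfactual).paf


def recovery_experiment(
    truth: SurveyFactorTruth,
    rr: RelativeRisk,
    counterfactual: Counterfactual,
    n_subjects: int,
    n_replicates: int,
    seed: int,
    n_consumer_categories: int = 10,
) -> RecoveryReport:
    """Generate -> summarize -> PAF, replicated; report bias and RMSE.

    Each replicate simulates a survey from the true parameters,
    summarizes it and runs the PAF pipeline on the summaries; the
    report compares the replicate PAFs against the PAF computed
    directly from the truth.
    """
    true_paf = paf_from_truth(truth, rr, counterfactual, n_consumer_categories)
    rng = np.random.default_rng(seed)
    pafs = np.empty(n_replicates)
    for i in range(n_replicates):
        records = generate_survey(
            [truth], n_subjects, seed=int(rng.integers(0, 2**31 - 1))
        )
        summary = summarize_survey(records, truth.factor_id, "male")
        if summary.prevalence == 0 or summary.mean_intake is None or summary.sd_intake is None:
            pafs[i] = 0.0
            continue
        dist = build_exposure_distribution(summary, n_consumer_categories)
        pafs[i] = paf_continuous(dist, rr, counterfactual).paf
    return RecoveryReport(
        true_paf=true_paf,
        replicate_pafs=pafs,
        n_subjects=n_subjects,
        n_replicates=n_replicates,
    )
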