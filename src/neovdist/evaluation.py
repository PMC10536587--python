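"""Study-level comparison of predicted and observed Vss, plus covariate tests.

``evaluate_predictions`` turns matched (study, prediction) pairs into fold
errors and aggregates them into AFE / AAFE / two-fold summaries overall,
per drug and per neonatal population.  Covariate analyses test whether the
prediction error depends on drug lipophilicity (ordinary least squares of
log10 FE on LogP) or on categorical covariates such as ionization type or
population composition (Kruskal-Wallis on log fold errors).  Fold errors
are log-transformed before analysis and group summaries are
back-transformed to geometric means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .scaling_metrics import AccuracySummary, fold_error, summarize_accuracy
from .trials import StudyRecord, TrialPrediction

__all__ = [
    "CovariateTestResult",
    "EvaluationReport",
    "evaluate_predictions",
    "covariate_linear",
    "covariate_kruskal",
]


@dataclass(frozen=True)
class CovariateTestResult:
    """Outcome of one covariate analysis on fold errors."""

    covariate: str
    test: str  # "linear_model" or "kruskal_wallis"
    statistic: float
    p_value: float
    group_summaries: Mapping[str, float]  # per-group geometric-mean FE
    slope: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy summaries at every scope plus the per-study fold errors."""

    overall: AccuracySummary
    per_drug: Mapping[str, AccuracySummary]
    per_population: Mapping[str, AccuracySummary]
    fold_errors: Mapping[str, float]  # study_id -> FE


def evaluate_predictions(
    studies: Sequence[StudyRecord],
    predictions: Sequence[TrialPrediction],
) -> EvaluationReport:
    """Fold errors and accuracy summaries for one prediction method.

    Every study must have exactly one prediction (matched on
    ``study_id``) and vice versa; order of the inputs is irrelevant.
    """
    by_id = {p.study_id: p for p in predictions}
    if len(by_id) != len(predictions):
        raise ValueError("duplicate study_id in predictions")
    study_ids = {s.study_id for s in studies}
    unmatched = study_ids.symmetric_difference(by_id)
    if unmatched:
        raise ValueError(f"unmatched study/prediction ids: {sorted(unmatched)}")

    ordered = sorted(studies, key=lambda s: s.study_id)
    fes = {
        s.study_id: fold_error(by_id[s.study_id].vss_pred_l_per_kg, s.vss_obs_l_per_kg)
        for s in ordered
    }
    fe_arr = np.array([fes[s.study_id] for s in ordered])

    per_drug: dict[str, AccuracySummary] = {}
    for drug in sorted({s.drug for s in ordered}):
        sel = [fes[s.study_id] for s in ordered if s.drug == drug]
        per_drug[drug] = summarize_accuracy(sel, scope="per_drug")

    per_pop: dict[str, AccuracySummary] = {}
    for label in ("term", "preterm", "mixed"):
        sel = [fes[s.study_id] for s in ordered if s.population_label == label]
        if sel:
            per_pop[label] = summarize_accuracy(sel, scope="per_population")

    return EvaluationReport(
        overall=summarize_accuracy(fe_arr, scope="overall"),
        per_drug=per_drug,
        per_population=per_pop,
        fold_errors=fes,
    )


def covariate_linear(
    fes: Sequence[float], logps: Sequence[float], covariate: str = "logp"
) -> CovariateTestResult:
    """OLS of log10 fold error on a continuous covariate (LogP).

    Reports the slope and the two-sided t-test p-value for a zero slope.
    """
    fes = np.asarray(fes, dtype=float)
    logps = np.asarray(logps, dtype=float)
    if fes.size != logps.size:
        raise ValueError("fes and covariate must have equal length")
    if fes.size < 3:
        raise ValueError("at least 3 points required")
    if np.any(fes <= 0):
        raise ValueError("fold errors must be > 0")
    if np.ptp(logps) == 0:
        raise ValueError("covariate is constant; slope not identifiable")
    result = stats.linregress(logps, np.log10(fes))
    # geometric-mean FE below/above the median covariate, for orientation
    median = float(np.median(logps))
    lo, hi = logps <= median, logps > median
    groups = {}
    for name, mask in (("low", lo), ("high", hi)):
        if np.any(mask):
            groups[name] = float(10.0 ** np.mean(np.log10(fes[mask])))
    return CovariateTestResult(
        covariate=covariate,
        test="linear_model",
        statistic=float(result.slope / result.stderr)
        if result.stderr > 0
        else float(np.inf),
        p_value=float(result.pvalue),
        group_summaries=groups,
        slope=float(result.slope),
    )


def covariate_kruskal(
    fes: Sequence[float], groups: Sequence[str], covariate: str = "group"
) -> CovariateTestResult:
    """Kruskal-Wallis H test of log fold errors across categorical groups.

    Uses the tie-corrected H statistic with a chi-square approximation on
    ``k - 1`` degrees of freedom.  When every observation is identical the
    statistic is reported as 0 with p = 1.
    """
    fes = np.asarray(fes, dtype=float)
    labels = np.asarray(groups)
    if fes.size != labels.size:
        raise ValueError("fes and groups must have equal length")
    if np.any(fes <= 0):
        raise ValueError("fold errors must be > 0")
    unique = sorted(set(labels.tolist()))
    if len(unique) < 2:
        raise ValueError("at least two groups required")
    samples = [np.log10(fes[labels == g]) for g in unique]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least two members")
    if np.ptp(fes) == 0:
        statistic, p_value = 0.0, 1.0
    else:
        statistic, p_value = stats.kruskal(*samples)
    summaries = {
        g: float(10.0 ** np.mean(s)) for g, s in zip(unique, samples)
    }
    return CovariateTestResult(
        covariate=covariate,
        test="kruskal_wallis",
        statistic=float(statistic),
        p_value=float(p_value),
        group_summaries=summaries,
    )
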