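"""Theoretical and trial-mimicking virtual simulations.

Theoretical simulations characterize the models at fixed covariates:
cohorts of 50 male + 50 female virtual subjects at gestational age 30
weeks (preterm population) and postnatal age 7 days (term population),
with the neonatal predictions expressed as fold changes relative to an
adult (20-25 y) cohort.

Trial-mimicking simulations reproduce the design of a clinical study:
subjects are sampled matching the study's size, proportion of females,
postnatal-age range and (for preterms) gestational-age range; mixed
term/preterm studies are simulated in both populations and combined as a
weighted average.  Each virtual trial is repeated (ten times by default)
and the per-repetition mean per-kg Vss values are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import NEONATE_PNA_MAX_DAYS, PRETERM_GA_THRESHOLD_WEEKS
from .drug_data import DrugRecord
from .kp_vss import predict_vss
from .physiology import (
    PhysiologyConfig,
    build_reference_subject,
    default_physiology,
    sample_subject,
)

__all__ = [
    "StudyRecord",
    "StudyValidationError",
    "TrialPrediction",
    "run_theoretical",
    "run_trial_mimicking",
    "load_study_table",
    "write_study_table",
]

logger = logging.getLogger(__name__)

POPULATION_LABELS = ("term", "preterm", "mixed")


class StudyValidationError(ValueError):
    """A clinical study record failed validation."""


@dataclass(frozen=True)
class StudyRecord:
    """One clinical (sub)study: design covariates and observed Vss.

    Optional fields reflect the missing-data patterns of real neonatal
    literature: unreported mean body weight, unreported gestational ages
    and unknown preterm proportion in mixed populations.
    """

    study_id: str
    drug: str
    n: int
    prop_female: float
    pna_min_days: float
    pna_max_days: float
    vss_obs_l_per_kg: float
    population_label: str
    ga_min_weeks: float | None = None
    ga_max_weeks: float | None = None
    preterm_proportion: float | None = None
    mean_bw_kg: float | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise StudyValidationError(
                f"{self.study_id}: at least three neonates required, got {self.n}"
            )
        if not 0.0 <= self.prop_female <= 1.0:
            raise StudyValidationError(f"{self.study_id}: prop_female outside [0, 1]")
        if self.pna_max_days > NEONATE_PNA_MAX_DAYS:
            raise StudyValidationError(
                f"{self.study_id}: PNA max {self.pna_max_days} exceeds "
                f"{NEONATE_PNA_MAX_DAYS} days"
            )
        if self.pna_min_days < 0 or self.pna_min_days > self.pna_max_days:
            raise StudyValidationError(f"{self.study_id}: invalid PNA range")
        if self.population_label not in POPULATION_LABELS:
            raise StudyValidationError(
                f"{self.study_id}: unknown population label "
                f"{self.population_label!r}"
            )
        if self.vss_obs_l_per_kg <= 0:
            raise StudyValidationError(f"{self.study_id}: observed Vss must be > 0")
        if (self.ga_min_weeks is None) != (self.ga_max_weeks is None):
            raise StudyValidationError(
                f"{self.study_id}: GA min/max must both be given or both absent"
            )
        if self.ga_max_weeks is not None:
            if self.ga_min_weeks > self.ga_max_weeks:
                raise StudyValidationError(f"{self.study_id}: inverted GA range")
            # label consistency with reported gestational ages
            if (
                self.ga_max_weeks < PRETERM_GA_THRESHOLD_WEEKS
                and self.population_label != "preterm"
            ):
                raise StudyValidationError(
                    f"{self.study_id}: all GA < {PRETERM_GA_THRESHOLD_WEEKS} weeks "
                    "but label is not 'preterm'"
                )
            if (
                self.ga_min_weeks >= PRETERM_GA_THRESHOLD_WEEKS
                and self.population_label == "preterm"
            ):
                raise StudyValidationError(
                    f"{self.study_id}: labelled preterm but all GA >= "
                    f"{PRETERM_GA_THRESHOLD_WEEKS} weeks"
                )
        if self.preterm_proportion is not None and not (
            0.0 <= self.preterm_proportion <= 1.0
        ):
            raise StudyValidationError(
                f"{self.study_id}: preterm_proportion outside [0, 1]"
            )
        if self.mean_bw_kg is not None and self.mean_bw_kg <= 0:
            raise StudyValidationError(f"{self.study_id}: mean_bw_kg must be > 0")


@dataclass(frozen=True)
class TrialPrediction:
    """Averaged prediction of one virtual trial."""

    study_id: str
    method: str
    vss_pred_l_per_kg: float
    rep_values: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if abs(self.vss_pred_l_per_kg - float(np.mean(self.rep_values))) > 1e-9:
            raise ValueError("vss_pred must equal the mean of rep_values")


# -- theoretical simulations ------------------------------------------------


def run_theoretical(
    drugs: Sequence[DrugRecord],
    method: str,
    config: PhysiologyConfig | None = None,
    *,
    n_per_sex: int = 50,
    preterm_ga_weeks: float = 30.0,
    term_pna_days: float = 7.0,
    iiv_cv: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fold change in predicted Vss of neonates relative to adults.

    For each drug, cohorts of ``n_per_sex`` males plus ``n_per_sex``
    females are simulated in three populations — preterm at a fixed
    gestational age, term neonates at a fixed postnatal age, and adults
    (age range from the configuration) — and the cohort-mean per-kg Vss
    of each neonatal population is divided by the adult cohort mean.

    Returns a DataFrame with columns ``drug, population, method,
    vss_l_per_kg, adult_vss_l_per_kg, fold_change``.
    """
    config = config or default_physiology()
    rng = np.random.default_rng(seed)

    cohorts: dict[str, list] = {}
    for label, cov in (
        ("adult", {}),
        ("preterm", {"ga": (preterm_ga_weeks, preterm_ga_weeks), "pna": (0.0, 0.0)}),
        ("term", {"pna": (term_pna_days, term_pna_days)}),
    ):
        spec = config.default_spec(label)
        subjects = []
        for sex_prop in (1.0, 0.0):  # 50 female, then 50 male
            for _ in range(n_per_sex):
                subjects.append(
                    sample_subject(
                        spec,
                        {**cov, "prop_female": sex_prop},
                        rng,
                        config,
                        iiv_cv=iiv_cv,
                    )
                )
        cohorts[label] = subjects

    rows = []
    for drug in drugs:
        means = {
            label: float(
                np.mean(
                    [predict_vss(drug, s, method).vss_l_per_kg for s in subjects]
                )
            )
            for label, subjects in cohorts.items()
        }
        for label in ("preterm", "term"):
            rows.append(
                {
                    "drug": drug.name,
                    "population": label,
                    "method": method,
                    "vss_l_per_kg": means[label],
                    "adult_vss_l_per_kg": means["adult"],
                    "fold_change": means[label] / means["adult"],
                }
            )
    return pd.DataFrame(rows)


# -- trial-mimicking simulations --------------------------------------------


def _study_covariates(study: StudyRecord, label: str) -> dict:
    cov: dict = {
        "prop_female": study.prop_female,
        "pna": (study.pna_min_days, study.pna_max_days),
    }
    if label == "preterm":
        if study.ga_min_weeks is not None:
            lo = study.ga_min_weeks
            hi = min(study.ga_max_weeks, PRETERM_GA_THRESHOLD_WEEKS - 1e-3)
            if lo >= hi:
                lo = hi = min(lo, PRETERM_GA_THRESHOLD_WEEKS - 1e-3)
            cov["ga"] = (lo, hi)
    elif study.ga_min_weeks is not None and study.ga_max_weeks is not None:
        lo = max(study.ga_min_weeks, PRETERM_GA_THRESHOLD_WEEKS)
        hi = max(study.ga_max_weeks, lo)
        cov["ga"] = (lo, hi)
    return cov


def _midpoint_subject(
    study: StudyRecord, label: str, config: PhysiologyConfig
):
    """Deterministic subject at the covariate midpoints of a study."""
    spec = config.default_spec(label)
    pna = 0.5 * (study.pna_min_days + study.pna_max_days)
    kwargs: dict = {"pna_days": pna}
    if label == "preterm":
        if study.ga_min_weeks is not None:
            ga = 0.5 * (
                study.ga_min_weeks
                + min(study.ga_max_weeks, PRETERM_GA_THRESHOLD_WEEKS - 1e-3)
            )
            ga = min(ga, PRETERM_GA_THRESHOLD_WEEKS - 1e-3)
        else:
            ga = 0.5 * sum(spec.ga_range)
        kwargs["ga_weeks"] = ga
    return build_reference_subject(spec, config, **kwargs)


def _populations_for(study: StudyRecord) -> list[tuple[str, float]]:
    """(population, weight) pairs for the study's composition.

    Mixed studies combine both populations weighted by the preterm
    proportion; when that proportion is unknown an equal split is
    assumed.  Studies without reported gestational ages are assumed to be
    at term.
    """
    if study.population_label == "term":
        return [("term", 1.0)]
    if study.population_label == "preterm":
        return [("preterm", 1.0)]
    prop = study.preterm_proportion
    if prop is None:
        prop = 0.5
    pairs = []
    if prop > 0.0:
        pairs.append(("preterm", prop))
    if prop < 1.0:
        pairs.append(("term", 1.0 - prop))
    return pairs


def run_trial_mimicking(
    study: StudyRecord,
    drug: DrugRecord,
    method: str,
    *,
    reps: int = 10,
    seed: int = 0,
    config: PhysiologyConfig | None = None,
    iiv_cv: float | None = None,
    geometric: bool = False,
) -> TrialPrediction:
    """Simulate one clinical study design and average over repetitions.

    Each repetition samples ``study.n`` subjects matched to the study's
    covariates (split across populations for mixed studies) and averages
    their per-kg Vss (arithmetically by default, geometrically with
    ``geometric=True``); the trial output is the mean over repetitions.

    With ``iiv_cv = 0`` the simulation is fully deterministic: each
    population contributes the reference-subject prediction at the
    study's covariate midpoints, weighted by population share.
    """
    config = config or default_physiology()
    if iiv_cv is None:
        iiv_cv = config.cv_bw
    pairs = _populations_for(study)

    if iiv_cv == 0.0:
        value = 0.0
        for label, weight in pairs:
            subject = _midpoint_subject(study, label, config)
            value += weight * predict_vss(drug, subject, method).vss_l_per_kg
        return TrialPrediction(
            study_id=study.study_id,
            method=method,
            vss_pred_l_per_kg=value,
            rep_values=tuple([value] * reps),
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    rep_values = []
    for _ in range(reps):
        rep_total = 0.0
        for label, weight in pairs:
            n_pop = max(1, int(round(study.n * weight)))
            spec = config.default_spec(label)
            cov = _study_covariates(study, label)
            values = []
            for _ in range(n_pop):
                subject = sample_subject(
                    spec,
                    cov,
                    rng,
                    config,
                    iiv_cv=iiv_cv,
                    bw_mean_target=study.mean_bw_kg,
                )
                values.append(predict_vss(drug, subject, method).vss_l_per_kg)
            values = np.asarray(values)
            pop_mean = (
                float(np.exp(np.mean(np.log(values))))
                if geometric
                else float(np.mean(values))
            )
            rep_total += weight * pop_mean
        rep_values.append(rep_total)
    return TrialPrediction(
        study_id=study.study_id,
        method=method,
        vss_pred_l_per_kg=float(np.mean(rep_values)),
        rep_values=tuple(rep_values),
        seed=seed,
    )


# -- study-table I/O --------------------------------------------------------

_STUDY_COLUMNS = [
    "study_id",
    "drug",
    "n",
    "prop_female",
    "pna_min_days",
    "pna_max_days",
    "ga_min_weeks",
    "ga_max_weeks",
    "preterm_proportion",
    "mean_bw_kg",
    "population_label",
    "vss_obs_l_per_kg",
]


def load_study_table(path) -> list[StudyRecord]:
    """Load a clinical-study CSV into validated records."""
    frame = pd.read_csv(path, comment="#")
    missing = set(_STUDY_COLUMNS) - set(frame.columns)
    if missing:
        raise StudyValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        def _opt(key):
            value = row[key]
            return None if pd.isna(value) else float(value)

        records.append(
            StudyRecord(
                study_id=str(row["study_id"]),
                drug=str(row["drug"]),
                n=int(row["n"]),
                prop_female=float(row["prop_female"]),
                pna_min_days=float(row["pna_min_days"]),
                pna_max_days=float(row["pna_max_days"]),
                ga_min_weeks=_opt("ga_min_weeks"),
                ga_max_weeks=_opt("ga_max_weeks"),
                preterm_proportion=_opt("preterm_proportion"),
                mean_bw_kg=_opt("mean_bw_kg"),
                population_label=str(row["population_label"]),
                vss_obs_l_per_kg=float(row["vss_obs_l_per_kg"]),
            )
        )
    return records


def write_study_table(studies: Sequence[StudyRecord], path) -> None:
    """Write study records to the documented CSV schema."""
    rows = []
    for s in studies:
        rows.append(
            {
                "study_id": s.study_id,
                "drug": s.drug,
                "n": s.n,
                "prop_female": s.prop_female,
                "pna_min_days": s.pna_min_days,
                "pna_max_days": s.pna_max_days,
                "ga_min_weeks": s.ga_min_weeks,
                "ga_max_weeks": s.ga_max_weeks,
                "preterm_proportion": s.preterm_proportion,
                "mean_bw_kg": s.mean_bw_kg,
                "population_label": s.population_label,
                "vss_obs_l_per_kg": s.vss_obs_l_per_kg,
            }
        )
    pd.DataFrame(rows, columns=_STUDY_COLUMNS).to_csv(path, index=False)
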