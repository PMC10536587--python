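"""Model / Results front-end tying the prediction pipeline together.

:class:`NeonatalVssModel` is constructed from a clinical-study table and a
drug-parameter table (plus a physiology configuration) and, on
:meth:`~NeonatalVssModel.fit`, produces per-study Vss predictions with the
requested methods — isometric scaling, allometric scaling with a chosen
exponent, and the two mechanistic tissue-composition methods — evaluated
against the observed values.  The returned
:class:`NeonatalVssResults` carries the per-study fold errors, accuracy
summaries at every scope, covariate tests, the allometric-exponent sweep
and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import ADULT_BW_KG
from .drug_data import DrugRecord, load_drug_table, packaged_drug_table
from .evaluation import (
    CovariateTestResult,
    EvaluationReport,
    covariate_kruskal,
    covariate_linear,
    evaluate_predictions,
)
from .kp_vss import predict_vss
from .physiology import PhysiologyConfig, build_reference_subject, default_physiology
from .scaling_metrics import (
    DEFAULT_ALPHA_GRID,
    SweepResult,
    allometric_vss,
    study_bw,
    sweep_alpha,
)
from .trials import StudyRecord, TrialPrediction, run_trial_mimicking

__all__ = ["NeonatalVssModel", "NeonatalVssResults", "adult_reference_vss"]

SCALING_METHODS = ("isometric", "allometric")
PBPK_METHODS = ("PT_plus", "RR")
ALL_METHODS = SCALING_METHODS + PBPK_METHODS


def adult_reference_vss(
    drugs: Sequence[DrugRecord],
    method: str = "PT_plus",
    config: PhysiologyConfig | None = None,
) -> dict[str, float]:
    """Mechanistic adult per-kg Vss per drug (reference-subject cohort).

    Used as the adult anchor of the scaling comparators when no observed
    adult values are supplied.
    """
    config = config or default_physiology()
    spec = config.default_spec("adult")
    subject = build_reference_subject(spec, config)
    return {
        d.name: predict_vss(d, subject, method).vss_l_per_kg for d in drugs
    }


class NeonatalVssModel:
    """Neonatal Vss prediction model over a set of clinical studies.

    Parameters
    ----------
    studies : sequence of StudyRecord
        The clinical (sub)studies to predict, each carrying its design
        covariates and observed per-kg Vss.
    drugs : sequence of DrugRecord
        Drug parameters covering every drug referenced by the studies.
    physiology : PhysiologyConfig, optional
        Body-composition configuration (packaged default when omitted).
    methods : sequence of str
        Any of ``isometric``, ``allometric``, ``PT_plus``, ``RR``.
    alpha : float
        Exponent for the ``allometric`` method (default 0.85).
    adult_vss : mapping, optional
        Observed adult per-kg Vss per drug for the scaling comparators;
        computed mechanistically from the adult reference subject when
        omitted.
    reps : int
        Virtual-trial repetitions per study (default 10).
    iiv_cv : float, optional
        Inter-individual variability CV; config default when None, 0 for
        fully deterministic midpoint predictions.
    """

    def __init__(
        self,
        studies: Sequence[StudyRecord],
        drugs: Sequence[DrugRecord],
        physiology: PhysiologyConfig | None = None,
        methods: Sequence[str] = ALL_METHODS,
        alpha: float = 0.85,
        adult_vss: Mapping[str, float] | None = None,
        reps: int = 10,
        iiv_cv: float | None = None,
    ) -> None:
        if not studies:
            raise ValueError("study list must be nonempty")
        unknown = [m for m in methods if m not in ALL_METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; expected {ALL_METHODS}")
        if not methods:
            raise ValueError("at least one method required")
        if reps < 1:
            raise ValueError("reps must be >= 1")
        self.studies = list(studies)
        self.drugs = {d.name: d for d in drugs}
        missing = sorted({s.drug for s in studies} - set(self.drugs))
        if missing:
            raise ValueError(f"no drug parameters for: {missing}")
        self.physiology = physiology or default_physiology()
        self.methods = tuple(methods)
        self.alpha = alpha
        self.reps = reps
        self.iiv_cv = iiv_cv
        self.adult_vss = dict(
            adult_vss
            if adult_vss is not None
            else adult_reference_vss(drugs, "PT_plus", self.physiology)
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        drugs: Sequence[DrugRecord] | None = None,
        **kwargs,
    ) -> "NeonatalVssModel":
        """Build from a study table DataFrame (schema of ``studies.csv``)."""
        from .trials import _STUDY_COLUMNS  # same schema as the CSV loader

        def _opt(row, key):
            value = row.get(key)
            return None if value is None or pd.isna(value) else float(value)

        records = [
            StudyRecord(
                study_id=str(row["study_id"]),
                drug=str(row["drug"]),
                n=int(row["n"]),
                prop_female=float(row["prop_female"]),
                pna_min_days=float(row["pna_min_days"]),
                pna_max_days=float(row["pna_max_days"]),
                ga_min_weeks=_opt(row, "ga_min_weeks"),
                ga_max_weeks=_opt(row, "ga_max_weeks"),
                preterm_proportion=_opt(row, "preterm_proportion"),
                mean_bw_kg=_opt(row, "mean_bw_kg"),
                population_label=str(row["population_label"]),
                vss_obs_l_per_kg=float(row["vss_obs_l_per_kg"]),
            )
            for row in frame.to_dict("records")
        ]
        return cls(records, drugs if drugs is not None else packaged_drug_table(), **kwargs)

    # -- fitting ------------------------------------------------------------

    def _predict_method(self, method: str, seed: int) -> list[TrialPrediction]:
        predictions = []
        seed_rng = np.random.default_rng(seed)
        study_seeds = seed_rng.integers(0, 2**31 - 1, size=len(self.studies))
        for study, study_seed in zip(self.studies, study_seeds):
            drug = self.drugs[study.drug]
            if method in SCALING_METHODS:
                alpha = 1.0 if method == "isometric" else self.alpha
                value = allometric_vss(
                    self.adult_vss[study.drug], study_bw(study), ADULT_BW_KG, alpha
                )
                predictions.append(
                    TrialPrediction(
                        study_id=study.study_id,
                        method=method,
                        vss_pred_l_per_kg=value,
                        rep_values=(value,),
                        seed=int(study_seed),
                    )
                )
            else:
                predictions.append(
                    run_trial_mimicking(
                        study,
                        drug,
                        method,
                        reps=self.reps,
                        seed=int(study_seed),
                        config=self.physiology,
                        iiv_cv=self.iiv_cv,
                    )
                )
        return predictions

    def fit(self, seed: int = 0) -> "NeonatalVssResults":
        """Run every configured method and evaluate against observations."""
        predictions = {m: self._predict_method(m, seed) for m in self.methods}
        reports = {
            m: evaluate_predictions(self.studies, predictions[m])
            for m in self.methods
        }
        return NeonatalVssResults(
            model=self, predictions=predictions, reports=reports, seed=seed
        )


@dataclass
class NeonatalVssResults:
    """Fitted results: predictions, fold errors, accuracy and diagnostics."""

    model: NeonatalVssModel
    predictions: Mapping[str, Sequence[TrialPrediction]]
    reports: Mapping[str, EvaluationReport]
    seed: int

    # -- tabular views -------------------------------------------------------

    def predictions_frame(self) -> pd.DataFrame:
        """Long table: study_id, method, predicted / observed Vss, FE."""
        obs = {s.study_id: s.vss_obs_l_per_kg for s in self.model.studies}
        rows = []
        for method, preds in self.predictions.items():
            fes = self.reports[method].fold_errors
            for p in preds:
                rows.append(
                    {
                        "study_id": p.study_id,
                        "method": method,
                        "vss_pred_l_per_kg": p.vss_pred_l_per_kg,
                        "vss_obs_l_per_kg": obs[p.study_id],
                        "fold_error": fes[p.study_id],
                        "seed": p.seed,
                    }
                )
        return pd.DataFrame(rows)

    def accuracy_frame(self) -> pd.DataFrame:
        """Accuracy metrics per method and scope."""
        rows = []
        for method, report in self.reports.items():
            entries = [("overall", "overall", report.overall)]
            entries += [
                ("per_population", label, summary)
                for label, summary in report.per_population.items()
            ]
            entries += [
                ("per_drug", drug, summary)
                for drug, summary in report.per_drug.items()
            ]
            for scope, label, summary in entries:
                rows.append(
                    {
                        "method": method,
                        "scope": scope,
                        "group": label,
                        "n_studies": summary.n_studies,
                        "afe": summary.afe,
                        "aafe": summary.aafe,
                        "pct_within_twofold": summary.pct_within_twofold,
                    }
                )
        return pd.DataFrame(rows)

    # -- diagnostics ---------------------------------------------------------

    def sweep(self, alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID) -> SweepResult:
        """Allometric-exponent sweep over the model's studies."""
        return sweep_alpha(self.model.studies, self.model.adult_vss, alpha_grid)

    def covariate_tests(self, method: str) -> dict[str, CovariateTestResult]:
        """LogP (linear), ionization type and population (Kruskal-Wallis)."""
        report = self.reports[method]
        studies = sorted(self.model.studies, key=lambda s: s.study_id)
        fes = np.array([report.fold_errors[s.study_id] for s in studies])
        logps = np.array([self.model.drugs[s.drug].logp for s in studies])
        ion = [self.model.drugs[s.drug].ionization_type for s in studies]
        pops = [s.population_label for s in studies]
        out = {
            "logp": covariate_linear(fes, logps, covariate="logp"),
        }
        if len(set(ion)) >= 2:
            out["ionization_type"] = covariate_kruskal(
                fes, ion, covariate="ionization_type"
            )
        if len(set(pops)) >= 2:
            out["population_label"] = covariate_kruskal(
                fes, pops, covariate="population_label"
            )
        return out

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        """Printable accuracy table in the style of a fitted-model summary."""
        lines = [
            "Neonatal Vss prediction accuracy",
            "=" * 64,
            f"studies: {len(self.model.studies)}   drugs: "
            f"{len({s.drug for s in self.model.studies})}   seed: {self.seed}",
            f"allometric exponent: {self.model.alpha}   trial reps: "
            f"{self.model.reps}",
            "-" * 64,
            f"{'method':<12}{'n':>5}{'AFE':>10}{'AAFE':>10}{'within 2-fold':>16}",
        ]
        for method, report in self.reports.items():
            s = report.overall
            lines.append(
                f"{method:<12}{s.n_studies:>5}{s.afe:>10.3f}{s.aafe:>10.3f}"
                f"{s.pct_within_twofold:>15.1f}%"
            )
        lines.append("-" * 64)
        lines.append(
            "AFE: geometric-mean fold error (bias; <1 = underprediction). "
        )
        lines.append("AAFE: geometric mean of |log fold error| scale (>= 1).")
        return "\n".join(lines)

    def plot_fold_errors(self, method: str, ax=None):
        """Per-drug fold-error strip plot with drug-level AFE bars."""
        import matplotlib.pyplot as plt

        report = self.reports[method]
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        drugs = sorted({s.drug for s in self.model.studies})
        positions = {d: i for i, d in enumerate(drugs)}
        for s in self.model.studies:
            ax.plot(
                positions[s.drug],
                report.fold_errors[s.study_id],
                marker="^",
                linestyle="none",
                color="0.3",
                markersize=4,
            )
        afes = [report.per_drug[d].afe for d in drugs]
        ax.bar(range(len(drugs)), afes, color="0.8", zorder=0)
        ax.axhline(1.0, color="k", linewidth=0.8)
        ax.axhline(2.0, color="k", linewidth=0.6, linestyle=":")
        ax.axhline(0.5, color="k", linewidth=0.6, linestyle=":")
        ax.set_yscale("log")
        ax.set_xticks(range(len(drugs)))
        ax.set_xticklabels(drugs, rotation=90, fontsize=7)
        ax.set_ylabel("fold error (pred/obs)")
        ax.set_title(f"{method}: per-study fold errors")
        return ax
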