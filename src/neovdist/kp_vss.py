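"""Tissue-composition partition coefficients and whole-body Vss.

Implements the two mechanistic tissue:plasma partition (Kp) methods used
for steady-state volume of distribution prediction:

* ``PT_plus`` — Poulin & Theil with the Berezhkovskiy tissue-binding
  correction.  Kp is driven by the octanol:water partition coefficient of
  the drug acting on tissue neutral lipid (with phospholipid treated as
  30% lipid / 70% water), scaled by the plasma:tissue unbound-fraction
  ratio.  Adipose uses the vegetable-oil:water coefficient of the neutral
  species at plasma pH and unit tissue binding.

* ``RR`` — Rodgers & Rowland.  Tissues are split into extra- and
  intracellular water with pH-dependent (Henderson-Hasselbalch)
  partitioning.  Moderate-to-strong bases (basic pKa >= 7) bind acidic
  phospholipids with an association constant back-calculated from the
  blood-to-plasma ratio via the erythrocyte:unbound-plasma partition;
  acids, weak bases and neutrals bind extracellular protein with an
  association constant back-calculated from 1/fu.

Whole-body Vss sums Kp-weighted tissue volumes plus plasma and an
erythrocyte term derived from the blood-to-plasma ratio and hematocrit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .constants import (
    PHOSPHOLIPID_LIPID_FRACTION,
    PHOSPHOLIPID_WATER_FRACTION,
    STRONG_BASE_PKA_THRESHOLD,
)
from .drug_data import DrugRecord, neutral_fraction, oil_water_partition
from .physiology import BloodParams, Subject, TissueComposition, scale_fu

__all__ = [
    "KpSet",
    "VssResult",
    "BloodPlasmaError",
    "berezhkovskiy_fu_tissue",
    "kp_poulin_theil_plus",
    "kp_rodgers_rowland",
    "vss_from_kps",
    "predict_vss",
    "erythrocyte_plasma_ratio",
]

logger = logging.getLogger(__name__)

METHODS = ("PT_plus", "RR")


class BloodPlasmaError(ValueError):
    """Blood-to-plasma ratio inconsistent with hematocrit."""


@dataclass(frozen=True)
class KpSet:
    """Tissue:plasma partition coefficients from one method for one drug."""

    method: str
    kp: Mapping[str, float]
    fu_used: float
    intermediate: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        for tissue, value in self.kp.items():
            if not value > 0:
                raise ValueError(f"{tissue}: Kp must be > 0, got {value}")


@dataclass(frozen=True)
class VssResult:
    """Whole-body steady-state volume of distribution for one subject."""

    vss_l: float
    vss_l_per_kg: float
    kps: KpSet
    subject_bw_kg: float

    def __post_init__(self) -> None:
        if abs(self.vss_l_per_kg - self.vss_l / self.subject_bw_kg) > 1e-9:
            raise ValueError("vss_l_per_kg inconsistent with vss_l / bw")


# -- shared helpers ---------------------------------------------------------


def _lipid_term(p: float, comp: TissueComposition) -> float:
    """Neutral-lipid equivalent solvent term P*f_NL + (0.3 P + 0.7) f_NP."""
    return p * comp.f_neutral_lipid + (
        PHOSPHOLIPID_LIPID_FRACTION * p + PHOSPHOLIPID_WATER_FRACTION
    ) * comp.f_neutral_phospholipid


def berezhkovskiy_fu_tissue(fu_p: float) -> float:
    """Berezhkovskiy tissue unbound fraction from the plasma fu.

    Assumes interstitial binding-protein concentration half of plasma:
    ``fu_t = 1 / (1 + (1 - fu_p) / (2 fu_p))``.
    """
    if not 0.0 < fu_p <= 1.0:
        raise ValueError(f"fu_p must be in (0, 1], got {fu_p}")
    return 1.0 / (1.0 + (1.0 - fu_p) / (2.0 * fu_p))


def _ionization_factor(drug: DrugRecord, ph: float) -> float:
    """X = 1 / neutral fraction — the Henderson-Hasselbalch denominator."""
    return 1.0 / neutral_fraction(drug.ionization_type, drug.pkas, ph)


def _cationic_term(drug: DrugRecord, ph: float) -> float:
    """10^(pKa_base - pH): the protonated-base term at the given pH."""
    pka = drug.basic_pka
    if pka is None:
        return 0.0
    return 10.0 ** (pka - ph)


def _is_strong_base(drug: DrugRecord, threshold: float) -> bool:
    pka = drug.basic_pka
    return pka is not None and pka >= threshold


# -- Poulin & Theil with Berezhkovskiy correction ---------------------------


def kp_poulin_theil_plus(
    drug: DrugRecord,
    comps: Mapping[str, TissueComposition],
    fu_p: float,
) -> KpSet:
    """Kp per tissue by the Poulin & Theil method (Berezhkovskiy fu_t).

    ``comps`` must contain a ``plasma`` entry plus one entry per tissue.
    Non-adipose tissues use the octanol:water partition coefficient
    ``P = 10^logP``; adipose uses the vegetable-oil:water coefficient of
    the neutral species at plasma pH with unit tissue binding (no binding
    protein in adipose interstitium).
    """
    if not 0.0 < fu_p <= 1.0:
        raise ValueError(f"fu_p must be in (0, 1], got {fu_p}")
    if "plasma" not in comps:
        raise ValueError("comps must include a 'plasma' composition")
    plasma = comps["plasma"]
    p = 10.0**drug.logp
    fn_plasma = drug.neutral_fraction(plasma.ph_intracellular)
    d_vow = oil_water_partition(drug.logp, fn_plasma)
    fu_t = berezhkovskiy_fu_tissue(fu_p)

    kp: dict[str, float] = {}
    for tissue, comp in comps.items():
        if tissue in ("plasma", "erythrocyte"):
            continue
        if tissue == "adipose":
            coeff, fu_tissue = d_vow, 1.0
        else:
            coeff, fu_tissue = p, fu_t
        numer = coeff * (
            comp.f_neutral_lipid
            + PHOSPHOLIPID_LIPID_FRACTION * comp.f_neutral_phospholipid
        ) + (
            comp.f_water_total
            + PHOSPHOLIPID_WATER_FRACTION * comp.f_neutral_phospholipid
        )
        denom = coeff * (
            plasma.f_neutral_lipid
            + PHOSPHOLIPID_LIPID_FRACTION * plasma.f_neutral_phospholipid
        ) + (
            plasma.f_water_total
            + PHOSPHOLIPID_WATER_FRACTION * plasma.f_neutral_phospholipid
        )
        kp[tissue] = (numer / denom) * (fu_p / fu_tissue)

    return KpSet(
        method="PT_plus",
        kp=kp,
        fu_used=fu_p,
        intermediate={"fu_tissue": fu_t, "d_vow": d_vow, "p_ow": p},
    )


# -- Rodgers & Rowland ------------------------------------------------------


def erythrocyte_plasma_ratio(bp: float, hematocrit: float) -> float:
    """Erythrocyte:plasma concentration ratio E:P from BP and hematocrit."""
    return (bp - (1.0 - hematocrit)) / hematocrit


def _ka_ap_from_blood(
    drug: DrugRecord,
    blood: BloodParams,
    ery: TissueComposition,
    fu_p: float,
    bp: float,
    x_plasma: float,
    p: float,
) -> float:
    """Acidic-phospholipid association constant from the erythrocyte ratio.

    Back-calculates Ka_AP from the erythrocyte:unbound-plasma partition
    ``Kpu_BC = (Hct - 1 + BP) / (Hct * fu_p)`` after removing the
    erythrocyte water and neutral-lipid/phospholipid contributions.
    """
    hct = blood.hematocrit
    kpu_bc = (hct - 1.0 + bp) / (hct * fu_p)
    if kpu_bc <= 0.0:
        raise BloodPlasmaError(
            f"{drug.name}: BP ({bp}) inconsistent with hematocrit ({hct}): "
            "BP must exceed 1 - Hct for the erythrocyte-derived "
            "acidic-phospholipid association constant to be defined"
        )
    x_rbc = _ionization_factor(drug, blood.ph_erythrocyte)
    y_rbc = _cationic_term(drug, blood.ph_erythrocyte)
    water_term = (x_rbc / x_plasma) * ery.f_water_intracellular
    lipid_term = _lipid_term(p, ery) / x_plasma
    ka_ap = (kpu_bc - water_term - lipid_term) * x_plasma / (
        ery.acidic_phospholipid * y_rbc
    )
    if ka_ap < 0.0:
        logger.warning(
            "%s: erythrocyte-derived Ka_AP negative (%.3g); clamped to 0",
            drug.name,
            ka_ap,
        )
        ka_ap = 0.0
    return ka_ap


def kp_rodgers_rowland(
    drug: DrugRecord,
    comps: Mapping[str, TissueComposition],
    blood: BloodParams,
    fu_p: float,
    bp: float | None = None,
    *,
    strong_base_threshold: float = STRONG_BASE_PKA_THRESHOLD,
) -> KpSet:
    """Kp per tissue by the Rodgers & Rowland method.

    Compounds whose (most) basic pKa is at or above
    ``strong_base_threshold`` use the acidic-phospholipid (base) branch;
    all others use the extracellular-protein branch.  Ampholytes with a
    strong basic centre use the base branch when the blood-to-plasma
    ratio permits back-calculation of the association constant, and fall
    back to the protein branch (with a logged warning) otherwise.

    Raises
    ------
    BloodPlasmaError
        For a monoprotic/diprotic base with ``bp <= 1 - hematocrit``.
    """
    if not 0.0 < fu_p <= 1.0:
        raise ValueError(f"fu_p must be in (0, 1], got {fu_p}")
    if "plasma" not in comps:
        raise ValueError("comps must include a 'plasma' composition")
    if bp is None:
        bp = drug.bp
    plasma = comps["plasma"]
    ery = comps.get("erythrocyte")
    ph_p = blood.ph_plasma
    p = 10.0**drug.logp
    d_vow = oil_water_partition(drug.logp, drug.neutral_fraction(ph_p))
    x_plasma = _ionization_factor(drug, ph_p)

    use_base_branch = _is_strong_base(drug, strong_base_threshold)
    ka_ap = 0.0
    ka_pr = 0.0
    if use_base_branch:
        if ery is None:
            raise ValueError("base branch requires an 'erythrocyte' composition")
        try:
            ka_ap = _ka_ap_from_blood(drug, blood, ery, fu_p, bp, x_plasma, p)
        except BloodPlasmaError:
            if drug.ionization_type == "ampholyte":
                logger.warning(
                    "%s: ampholyte with BP <= 1 - Hct; falling back to the "
                    "extracellular-protein branch",
                    drug.name,
                )
                use_base_branch = False
            else:
                raise
    if not use_base_branch:
        # association constant x protein concentration, from plasma binding
        ka_pr = 1.0 / fu_p - 1.0 - _lipid_term(p, plasma) / x_plasma
        if ka_pr < 0.0:
            logger.warning(
                "%s: plasma-derived protein association constant negative "
                "(%.3g); clamped to 0",
                drug.name,
                ka_pr,
            )
            ka_pr = 0.0

    neutral_drug = drug.ionization_type == "neutral"

    kp: dict[str, float] = {}
    for tissue, comp in comps.items():
        if tissue in ("plasma", "erythrocyte"):
            continue
        x_iw = _ionization_factor(drug, comp.ph_intracellular)
        coeff = d_vow if tissue == "adipose" else p
        kpu = (
            comp.f_water_extracellular
            + (x_iw / x_plasma) * comp.f_water_intracellular
            + _lipid_term(coeff, comp) / x_plasma
        )
        if use_base_branch:
            y_iw = _cationic_term(drug, comp.ph_intracellular)
            kpu += ka_ap * comp.acidic_phospholipid * y_iw / x_plasma
        else:
            ratio = (
                comp.protein_ratio_lipoprotein
                if neutral_drug
                else comp.protein_ratio_albumin
            )
            kpu += ka_pr * ratio
        kp[tissue] = kpu * fu_p

    return KpSet(
        method="RR",
        kp=kp,
        fu_used=fu_p,
        intermediate={
            "x_plasma": x_plasma,
            "ka_ap": ka_ap,
            "ka_protein": ka_pr,
            "base_branch": float(use_base_branch),
            "kpu_bc": (blood.hematocrit - 1.0 + bp) / (blood.hematocrit * fu_p),
        },
    )


# -- whole-body assembly ----------------------------------------------------


def vss_from_kps(kps: KpSet, subject: Subject, bp: float) -> VssResult:
    """Assemble whole-body Vss from a Kp set and a subject's volumes.

    ``Vss = V_plasma + V_ery * E:P + sum_t Kp_t * V_t`` with the
    erythrocyte:plasma ratio ``E:P = (BP - (1 - Hct)) / Hct``, floored at
    zero (with a warning) when BP is below the plasma-only bound.
    """
    missing = [t for t in kps.kp if t not in subject.tissue_volumes]
    if missing:
        raise ValueError(f"subject lacks volumes for tissues: {missing}")
    ep = erythrocyte_plasma_ratio(bp, subject.blood.hematocrit)
    if ep < 0.0:
        logger.warning(
            "E:P ratio negative (BP %.3g < 1 - Hct %.3g); floored at 0",
            bp,
            1.0 - subject.blood.hematocrit,
        )
        ep = 0.0
    vss = (
        subject.plasma_volume_l
        + subject.erythrocyte_volume_l * ep
        + sum(kps.kp[t] * subject.tissue_volumes[t] for t in kps.kp)
    )
    return VssResult(
        vss_l=vss,
        vss_l_per_kg=vss / subject.bw_kg,
        kps=kps,
        subject_bw_kg=subject.bw_kg,
    )


def predict_vss(drug: DrugRecord, subject: Subject, method: str) -> VssResult:
    """Predict Vss for one drug in one subject with the selected method.

    Neonatal subjects have the adult fraction unbound rescaled to their
    plasma-protein level before the Kp computation; adults use the drug's
    fu as given.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if subject.population == "adult":
        fu = drug.fu
    else:
        fu = scale_fu(drug.fu, drug.binding_protein, subject.blood)
    if method == "PT_plus":
        kps = kp_poulin_theil_plus(drug, subject.compositions, fu)
    else:
        kps = kp_rodgers_rowland(
            drug, subject.compositions, subject.blood, fu, drug.bp
        )
    return vss_from_kps(kps, subject, drug.bp)
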