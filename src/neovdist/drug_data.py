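"""Drug parameter records, ionization chemistry and drug-table I/O.

A :class:`DrugRecord` holds the physicochemical and binding parameters that
the tissue-composition partition methods consume: molecular weight, LogP,
acid-base character with pKa values, fraction unbound in plasma (fu), the
main plasma binding protein (albumin or alpha-1-acid glycoprotein) and the
blood-to-plasma concentration ratio (BP).

The module also implements the Henderson-Hasselbalch neutral-fraction
arithmetic shared by both Kp methods, and the vegetable-oil:water partition
coefficient used for adipose tissue.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .constants import VOW_INTERCEPT, VOW_SLOPE

__all__ = [
    "DrugRecord",
    "DrugValidationError",
    "IONIZATION_TYPES",
    "load_drug_table",
    "write_drug_table",
    "packaged_drug_table",
    "neutral_fraction",
    "oil_water_partition",
]

logger = logging.getLogger(__name__)

IONIZATION_TYPES = (
    "neutral",
    "monoprotic_acid",
    "diprotic_acid",
    "monoprotic_base",
    "diprotic_base",
    "ampholyte",
)

#: Number of pKa values each ionization type must carry.
_N_PKAS = {
    "neutral": 0,
    "monoprotic_acid": 1,
    "monoprotic_base": 1,
    "diprotic_acid": 2,
    "diprotic_base": 2,
    "ampholyte": 2,  # (acidic pKa, basic pKa)
}

_BINDING_PROTEINS = ("HSA", "AGP")
_BP_SOURCES = ("measured", "assumed", "predicted")


class DrugValidationError(ValueError):
    """A drug record or drug-table row failed validation."""


@dataclass(frozen=True)
class DrugRecord:
    """Physicochemical and binding parameters for one drug.

    Parameters
    ----------
    name : str
        Drug identifier.
    mwt : float
        Molecular weight (g/mol).
    logp : float
        Log10 octanol:water partition coefficient.
    ionization_type : str
        One of ``neutral``, ``monoprotic_acid``, ``diprotic_acid``,
        ``monoprotic_base``, ``diprotic_base``, ``ampholyte``.
    pkas : tuple of float
        0-2 pKa values; ampholytes store ``(acidic, basic)``.
    fu : float
        Fraction unbound in plasma, in (0, 1].
    binding_protein : str
        Main plasma binding protein, ``HSA`` or ``AGP``.
    bp : float
        Blood-to-plasma concentration ratio (> 0).
    bp_source : str
        ``measured``, ``assumed`` or ``predicted``.
    """

    name: str
    mwt: float
    logp: float
    ionization_type: str
    pkas: tuple[float, ...]
    fu: float
    binding_protein: str
    bp: float
    bp_source: str = "measured"

    def __post_init__(self) -> None:
        if self.ionization_type not in IONIZATION_TYPES:
            raise DrugValidationError(
                f"{self.name}: unknown ionization_type {self.ionization_type!r}"
            )
        object.__setattr__(self, "pkas", tuple(float(p) for p in self.pkas))
        expected = _N_PKAS[self.ionization_type]
        if len(self.pkas) != expected:
            raise DrugValidationError(
                f"{self.name}: {self.ionization_type} requires {expected} pKa "
                f"value(s), got {len(self.pkas)}"
            )
        if not 0.0 < self.fu <= 1.0:
            raise DrugValidationError(
                f"{self.name}: fu must be in (0, 1], got {self.fu}"
            )
        if self.bp <= 0:
            raise DrugValidationError(f"{self.name}: bp must be > 0, got {self.bp}")
        if self.mwt <= 0:
            raise DrugValidationError(f"{self.name}: mwt must be > 0, got {self.mwt}")
        if self.binding_protein not in _BINDING_PROTEINS:
            raise DrugValidationError(
                f"{self.name}: binding_protein must be one of {_BINDING_PROTEINS}"
            )
        if self.bp_source not in _BP_SOURCES:
            raise DrugValidationError(
                f"{self.name}: bp_source must be one of {_BP_SOURCES}"
            )

    # -- ionization helpers -------------------------------------------------

    @property
    def basic_pka(self) -> float | None:
        """The (most) basic pKa, or None for compounds without a basic centre."""
        if self.ionization_type in ("monoprotic_base",):
            return self.pkas[0]
        if self.ionization_type == "diprotic_base":
            return max(self.pkas)
        if self.ionization_type == "ampholyte":
            return self.pkas[1]
        return None

    def neutral_fraction(self, ph: float) -> float:
        """Fraction of this drug in the neutral form at the given pH."""
        return neutral_fraction(self.ionization_type, self.pkas, ph)


# -- ionization chemistry ---------------------------------------------------


def neutral_fraction(
    ionization_type: str, pkas: Sequence[float], ph: float
) -> float:
    """Henderson-Hasselbalch fraction of drug in the neutral form at ``ph``.

    For a monoprotic acid the neutral fraction is ``1/(1 + 10^(pH - pKa))``,
    for a monoprotic base ``1/(1 + 10^(pKa - pH))``; diprotic species and
    ampholytes accumulate both ionization terms in the denominator.

    Parameters
    ----------
    ionization_type : str
        One of :data:`IONIZATION_TYPES`.
    pkas : sequence of float
        The pKa values matching the ionization type; ampholytes pass
        ``(acidic, basic)``; diprotic acids/bases pass both pKas.
    ph : float
        pH of the medium, in [0, 14].

    Returns
    -------
    float
        Neutral fraction in (0, 1].
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"ph must be in [0, 14], got {ph}")
    if ionization_type not in IONIZATION_TYPES:
        raise ValueError(f"unknown ionization_type {ionization_type!r}")
    if len(pkas) != _N_PKAS[ionization_type]:
        raise ValueError(
            f"{ionization_type} requires {_N_PKAS[ionization_type]} pKa value(s)"
        )
    if ionization_type == "neutral":
        return 1.0
    if ionization_type == "monoprotic_acid":
        denom = 1.0 + 10.0 ** (ph - pkas[0])
    elif ionization_type == "monoprotic_base":
        denom = 1.0 + 10.0 ** (pkas[0] - ph)
    elif ionization_type == "diprotic_acid":
        p1, p2 = sorted(pkas)
        denom = 1.0 + 10.0 ** (ph - p1) + 10.0 ** (2.0 * ph - p1 - p2)
    elif ionization_type == "diprotic_base":
        p1, p2 = sorted(pkas, reverse=True)
        denom = 1.0 + 10.0 ** (p1 - ph) + 10.0 ** (p1 + p2 - 2.0 * ph)
    else:  # ampholyte: (acidic pKa, basic pKa)
        pka_acid, pka_base = pkas
        denom = 1.0 + 10.0 ** (ph - pka_acid) + 10.0 ** (pka_base - ph)
    return 1.0 / denom


def oil_water_partition(logp: float, neutral_fraction_at_plasma_ph: float) -> float:
    """Vegetable-oil:water distribution coefficient of the neutral species.

    Uses the Leo-type correlation ``log P_vo:w = 1.115 logP - 1.35`` and
    multiplies by the neutral fraction at plasma pH, since only the neutral
    species partitions into oil.  This is the adipose-tissue partition
    driver of the Poulin & Theil method.
    """
    if not 0.0 <= neutral_fraction_at_plasma_ph <= 1.0:
        raise ValueError("neutral fraction must be in [0, 1]")
    p_vow = 10.0 ** (VOW_SLOPE * logp + VOW_INTERCEPT)
    return p_vow * neutral_fraction_at_plasma_ph


# -- table I/O --------------------------------------------------------------

_CSV_COLUMNS = [
    "name",
    "mwt_g_mol",
    "logp",
    "ionization_type",
    "pka1",
    "pka2",
    "fu",
    "binding_protein",
    "bp",
    "bp_source",
]


def _parse_row(row: dict[str, str], lineno: int) -> DrugRecord:
    name = (row.get("name") or "").strip()
    if not name:
        raise DrugValidationError(f"row {lineno}: missing drug name")

    def _num(field_name: str, required: bool = True) -> float | None:
        raw = (row.get(field_name) or "").strip()
        if raw == "":
            if required:
                raise DrugValidationError(
                    f"row {lineno} ({name}): missing field {field_name!r}"
                )
            return None
        try:
            return float(raw)
        except ValueError as exc:
            raise DrugValidationError(
                f"row {lineno} ({name}): field {field_name!r} is not numeric: {raw!r}"
            ) from exc

    ionization_type = (row.get("ionization_type") or "").strip()
    pkas = [v for v in (_num("pka1", False), _num("pka2", False)) if v is not None]
    bp = _num("bp", required=False)
    bp_source = (row.get("bp_source") or "").strip()
    if bp is None:
        # No measured/predicted BP available: default to unity (the
        # least-assumptive value; exact for a drug that does not enter or
        # bind red cells beyond plasma water).
        bp = 1.0
        bp_source = "assumed"
        logger.warning("%s: no blood-to-plasma ratio given; assuming BP = 1.0", name)
    if not bp_source:
        bp_source = "measured"
    try:
        return DrugRecord(
            name=name,
            mwt=_num("mwt_g_mol"),
            logp=_num("logp"),
            ionization_type=ionization_type,
            pkas=tuple(pkas),
            fu=_num("fu"),
            binding_protein=(row.get("binding_protein") or "").strip(),
            bp=bp,
            bp_source=bp_source,
        )
    except DrugValidationError as exc:
        raise DrugValidationError(f"row {lineno}: {exc}") from exc


def load_drug_table(path: str | Path) -> list[DrugRecord]:
    """Load and validate a drug-parameter CSV.

    The file must be UTF-8, comma-separated, with a header row containing
    the columns ``name, mwt_g_mol, logp, ionization_type, pka1, pka2, fu,
    binding_protein, bp, bp_source``.  Rows with a blank ``bp`` receive a
    default of 1.0 with ``bp_source = assumed``.  Row order is preserved.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise DrugValidationError(f"{path}: empty file")
        missing = set(_CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise DrugValidationError(f"{path}: missing columns {sorted(missing)}")
        return [_parse_row(row, i) for i, row in enumerate(reader, start=2)]


def write_drug_table(records: Iterable[DrugRecord], path: str | Path) -> None:
    """Write validated records back to the documented CSV schema."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_CSV_COLUMNS)
        for rec in records:
            pka1 = rec.pkas[0] if len(rec.pkas) >= 1 else ""
            pka2 = rec.pkas[1] if len(rec.pkas) >= 2 else ""
            writer.writerow(
                [
                    rec.name,
                    rec.mwt,
                    rec.logp,
                    rec.ionization_type,
                    pka1,
                    pka2,
                    rec.fu,
                    rec.binding_protein,
                    rec.bp,
                    rec.bp_source,
                ]
            )


def packaged_drug_table() -> list[DrugRecord]:
    """Load the packaged 24-drug reference table."""
    with resources.as_file(
        resources.files("neovdist.data").joinpath("reference_drugs.csv")
    ) as path:
        return load_drug_table(path)
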