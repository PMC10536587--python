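"""Age- and gestational-age-parameterized body composition.

Builds virtual subjects (adult, term neonate, preterm neonate) from a
transparent YAML physiology configuration: per-tissue volume fractions of
body weight, tissue compositions (water / lipid / phospholipid fractions,
acidic phospholipid, protein concentration ratios), blood parameters, and
plasma-protein ontogeny scalars.

The neonatal tables are documented approximations built from published
body-composition ontogeny; they are not intended to be bit-compatible with
any commercial simulator's virtual populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .constants import NEONATE_PNA_MAX_DAYS, PRETERM_GA_THRESHOLD_WEEKS

__all__ = [
    "TISSUES",
    "TissueComposition",
    "BloodParams",
    "Subject",
    "PopulationSpec",
    "PhysiologyConfig",
    "load_physiology",
    "default_physiology",
    "build_reference_subject",
    "sample_subject",
    "scale_fu",
]

#: The twelve perfused tissues modelled as explicit compartments.
TISSUES = (
    "adipose",
    "bone",
    "brain",
    "gut",
    "pancreas",
    "heart",
    "kidney",
    "liver",
    "lung",
    "muscle",
    "skin",
    "spleen",
)

POPULATION_LABELS = ("adult", "term", "preterm")


@dataclass(frozen=True)
class TissueComposition:
    """Fractional composition of one tissue (or plasma / erythrocyte).

    Water fractions are volumes of water per volume of tissue, split into
    extra- and intracellular; neutral lipid and neutral phospholipid are
    volume fractions; acidic phospholipid is mg per g of tissue; protein
    ratios are tissue:plasma concentration ratios for albumin and
    lipoprotein.
    """

    tissue: str
    f_water_total: float
    f_water_extracellular: float
    f_water_intracellular: float
    f_neutral_lipid: float
    f_neutral_phospholipid: float
    acidic_phospholipid: float
    protein_ratio_albumin: float
    protein_ratio_lipoprotein: float
    ph_intracellular: float

    def __post_init__(self) -> None:
        for name in (
            "f_water_total",
            "f_water_extracellular",
            "f_water_intracellular",
            "f_neutral_lipid",
            "f_neutral_phospholipid",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.tissue}: {name} = {v} outside [0, 1]")
        if (
            self.f_water_extracellular + self.f_water_intracellular
            > self.f_water_total + 1e-9
        ):
            raise ValueError(
                f"{self.tissue}: extracellular + intracellular water exceeds total"
            )
        if self.acidic_phospholipid < 0:
            raise ValueError(f"{self.tissue}: acidic_phospholipid < 0")


@dataclass(frozen=True)
class BloodParams:
    """Blood-side parameters of one subject."""

    hematocrit: float
    ph_plasma: float = 7.4
    ph_erythrocyte: float = 7.22
    albumin_relative: float = 1.0  # neonate:adult plasma albumin ratio
    agp_relative: float = 1.0  # neonate:adult AGP ratio

    def __post_init__(self) -> None:
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError(f"hematocrit must be in (0, 1), got {self.hematocrit}")
        if self.albumin_relative <= 0 or self.agp_relative <= 0:
            raise ValueError("relative protein levels must be > 0")


@dataclass(frozen=True)
class Subject:
    """One virtual individual: covariates plus a physiology snapshot."""

    sex: str
    ga_weeks: float
    pna_days: float
    bw_kg: float
    tissue_volumes: Mapping[str, float]
    plasma_volume_l: float
    erythrocyte_volume_l: float
    compositions: Mapping[str, TissueComposition]
    blood: BloodParams
    population: str = "adult"

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.bw_kg <= 0:
            raise ValueError("bw_kg must be > 0")
        for tissue, vol in self.tissue_volumes.items():
            if vol <= 0:
                raise ValueError(f"{tissue}: volume must be > 0")
        if self.plasma_volume_l <= 0 or self.erythrocyte_volume_l <= 0:
            raise ValueError("blood compartment volumes must be > 0")
        total = (
            sum(self.tissue_volumes.values())
            + self.plasma_volume_l
            + self.erythrocyte_volume_l
        )
        # density sanity: modelled compartments cannot exceed body volume
        if total > self.bw_kg / 0.9:
            raise ValueError(
                f"modelled volumes ({total:.2f} L) exceed plausible body volume "
                f"for {self.bw_kg:.2f} kg"
            )

    @property
    def total_modeled_volume_l(self) -> float:
        return (
            sum(self.tissue_volumes.values())
            + self.plasma_volume_l
            + self.erythrocyte_volume_l
        )


@dataclass(frozen=True)
class PopulationSpec:
    """A virtual population and its admissible covariate ranges."""

    label: str
    ga_range: tuple[float, float] | None = None
    pna_range: tuple[float, float] | None = None
    age_range: tuple[float, float] | None = None
    preterm_threshold: float = PRETERM_GA_THRESHOLD_WEEKS
    neonate_pna_max: float = NEONATE_PNA_MAX_DAYS

    def __post_init__(self) -> None:
        if self.label not in POPULATION_LABELS:
            raise ValueError(f"unknown population label {self.label!r}")
        if self.label == "preterm":
            if self.ga_range is None:
                raise ValueError("preterm population requires a ga_range")
            lo, hi = self.ga_range
            if not (22.0 <= lo <= hi < self.preterm_threshold):
                raise ValueError(
                    f"preterm ga_range must lie within [22, {self.preterm_threshold})"
                )
        if self.label == "term" and self.ga_range is not None:
            if self.ga_range[0] < self.preterm_threshold:
                raise ValueError("term population requires GA >= 37 weeks")
        if self.label in ("term", "preterm"):
            pna = self.pna_range or (0.0, self.neonate_pna_max)
            if pna[1] > self.neonate_pna_max:
                raise ValueError(
                    f"neonatal PNA must be <= {self.neonate_pna_max} days"
                )
        if self.label == "adult" and self.age_range is None:
            raise ValueError("adult population requires an age_range")


# -- configuration ----------------------------------------------------------


@dataclass(frozen=True)
class PhysiologyConfig:
    """Parsed physiology configuration (see ``data/physiology.yaml``)."""

    raw: dict = field(repr=False)

    @property
    def ph_plasma(self) -> float:
        return float(self.raw["ph"]["plasma"])

    @property
    def ph_intracellular(self) -> float:
        return float(self.raw["ph"]["intracellular"])

    @property
    def ph_erythrocyte(self) -> float:
        return float(self.raw["ph"]["erythrocyte"])

    @property
    def cv_bw(self) -> float:
        return float(self.raw["variability"]["cv_bw"])

    @property
    def cv_tissue(self) -> float:
        return float(self.raw["variability"]["cv_tissue"])

    def population(self, label: str) -> dict:
        try:
            return self.raw["populations"][label]
        except KeyError as exc:
            raise ValueError(f"unknown population {label!r}") from exc

    def default_spec(self, label: str) -> PopulationSpec:
        pop = self.population(label)
        if label == "adult":
            return PopulationSpec(label, age_range=tuple(pop["age_range_years"]))
        return PopulationSpec(
            label,
            ga_range=tuple(pop["ga_range_weeks"]) if label == "preterm" else None,
            pna_range=tuple(pop["pna_range_days"]),
        )


def load_physiology(path: str | Path) -> PhysiologyConfig:
    """Load a physiology YAML configuration."""
    with Path(path).open(encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    for key in ("ph", "plasma_composition", "adult_tissue_composition", "populations"):
        if key not in raw:
            raise ValueError(f"physiology config missing section {key!r}")
    return PhysiologyConfig(raw=raw)


def default_physiology() -> PhysiologyConfig:
    """Load the packaged physiology configuration."""
    with resources.as_file(
        resources.files("neovdist.data").joinpath("physiology.yaml")
    ) as path:
        return load_physiology(path)


# -- composition assembly ---------------------------------------------------


def _scaled_water(f_ew: float, f_iw: float, ew_scale: float, iw_scale: float):
    """Scale water fractions, renormalizing if total water exceeds 0.94."""
    ew, iw = f_ew * ew_scale, f_iw * iw_scale
    total = ew + iw
    cap = 0.94
    if total > cap:
        ew, iw = ew * cap / total, iw * cap / total
        total = cap
    return ew, iw, total


def _tissue_composition(
    config: PhysiologyConfig, label: str, tissue: str
) -> TissueComposition:
    row = config.raw["adult_tissue_composition"][tissue]
    f_ew, f_iw, f_nl, f_np, ap, alb, lipo = (float(v) for v in row)
    pop = config.population(label)
    ws = pop["water_scale"]
    ls = pop["lipid_scale"]
    ew, iw, total = _scaled_water(
        f_ew, f_iw, float(ws["extracellular"]), float(ws["intracellular"])
    )
    return TissueComposition(
        tissue=tissue,
        f_water_total=total,
        f_water_extracellular=ew,
        f_water_intracellular=iw,
        f_neutral_lipid=min(f_nl * float(ls["neutral_lipid"]), 1.0),
        f_neutral_phospholipid=min(f_np * float(ls["phospholipid"]), 1.0),
        acidic_phospholipid=ap,
        protein_ratio_albumin=alb,
        protein_ratio_lipoprotein=lipo,
        ph_intracellular=config.ph_intracellular,
    )


def _plasma_composition(config: PhysiologyConfig) -> TissueComposition:
    pc = config.raw["plasma_composition"]
    fw = float(pc["f_water"])
    return TissueComposition(
        tissue="plasma",
        f_water_total=fw,
        f_water_extracellular=fw,
        f_water_intracellular=0.0,
        f_neutral_lipid=float(pc["f_neutral_lipid"]),
        f_neutral_phospholipid=float(pc["f_neutral_phospholipid"]),
        acidic_phospholipid=0.0,
        protein_ratio_albumin=1.0,
        protein_ratio_lipoprotein=1.0,
        ph_intracellular=config.ph_plasma,
    )


def _erythrocyte_composition(config: PhysiologyConfig) -> TissueComposition:
    ec = config.raw["erythrocyte_composition"]
    fiw = float(ec["f_water_intracellular"])
    return TissueComposition(
        tissue="erythrocyte",
        f_water_total=fiw,
        f_water_extracellular=0.0,
        f_water_intracellular=fiw,
        f_neutral_lipid=float(ec["f_neutral_lipid"]),
        f_neutral_phospholipid=float(ec["f_neutral_phospholipid"]),
        acidic_phospholipid=float(ec["acidic_phospholipid"]),
        protein_ratio_albumin=0.0,
        protein_ratio_lipoprotein=0.0,
        ph_intracellular=config.ph_erythrocyte,
    )


def _interp_fraction(pop: dict, tissue: str, x: float) -> float:
    table = pop["volume_fractions"]
    return float(np.interp(x, table["breakpoints"], table[tissue]))


def _interp_bw(pop: dict, x: float) -> float:
    g = pop["growth"]
    return float(np.interp(x, g["breakpoints"], g["bw_kg"]))


def _covariate_coordinate(label: str, ga_weeks: float, pna_days: float,
                          age_years: float | None) -> float:
    """The abscissa used for table interpolation per population."""
    if label == "adult":
        return float(age_years if age_years is not None else 22.5)
    if label == "preterm":
        return float(ga_weeks)
    return float(pna_days)


def build_reference_subject(
    spec: PopulationSpec,
    config: PhysiologyConfig | None = None,
    *,
    ga_weeks: float | None = None,
    pna_days: float | None = None,
    age_years: float | None = None,
    sex: str = "F",
    bw_kg: float | None = None,
) -> Subject:
    """Deterministic subject at the given covariates.

    Tissue volumes and body weight are interpolated from the configured
    tables at the given gestational age (preterm), postnatal age (term) or
    age (adult).  No inter-individual variability is applied.
    """
    config = config or default_physiology()
    label = spec.label
    pop = config.population(label)

    if label == "adult":
        age = age_years if age_years is not None else sum(spec.age_range) / 2.0
        lo, hi = spec.age_range
        if not lo <= age <= hi:
            raise ValueError(f"age {age} outside adult range [{lo}, {hi}]")
        ga = 40.0
        pna = 0.0
    else:
        pna_range = spec.pna_range or (0.0, NEONATE_PNA_MAX_DAYS)
        pna = pna_days if pna_days is not None else sum(pna_range) / 2.0
        if not pna_range[0] <= pna <= pna_range[1]:
            raise ValueError(f"PNA {pna} outside range {pna_range}")
        if label == "preterm":
            ga_range = spec.ga_range
            ga = ga_weeks if ga_weeks is not None else sum(ga_range) / 2.0
            if not ga_range[0] <= ga <= ga_range[1]:
                raise ValueError(f"GA {ga} outside range {ga_range}")
        else:
            ga = ga_weeks if ga_weeks is not None else 40.0
            if ga < spec.preterm_threshold:
                raise ValueError(
                    f"term subject requires GA >= {spec.preterm_threshold} weeks"
                )
        age = None

    x = _covariate_coordinate(label, ga, pna, age)
    if bw_kg is None:
        bw_kg = _interp_bw(pop, x)
        if label == "preterm" and pna > 7.0:
            # postnatal growth on top of GA-determined birth weight
            rate = float(config.raw.get("postnatal_growth_per_day", 0.0))
            bw_kg *= 1.0 + rate * (pna - 7.0)

    volumes = {t: _interp_fraction(pop, t, x) * bw_kg for t in TISSUES}
    plasma_l = _interp_fraction(pop, "plasma", x) * bw_kg
    ery_l = _interp_fraction(pop, "erythrocyte", x) * bw_kg

    comps = {t: _tissue_composition(config, label, t) for t in TISSUES}
    comps["plasma"] = _plasma_composition(config)
    comps["erythrocyte"] = _erythrocyte_composition(config)

    blood = BloodParams(
        hematocrit=float(pop["hematocrit"]),
        ph_plasma=config.ph_plasma,
        ph_erythrocyte=config.ph_erythrocyte,
        albumin_relative=float(pop["albumin_relative"]),
        agp_relative=float(pop["agp_relative"]),
    )
    return Subject(
        sex=sex,
        ga_weeks=ga,
        pna_days=pna,
        bw_kg=bw_kg,
        tissue_volumes=volumes,
        plasma_volume_l=plasma_l,
        erythrocyte_volume_l=ery_l,
        compositions=comps,
        blood=blood,
        population=label,
    )


def sample_subject(
    spec: PopulationSpec,
    covariate_ranges: dict,
    rng: np.random.Generator,
    config: PhysiologyConfig | None = None,
    *,
    iiv_cv: float | None = None,
    bw_mean_target: float | None = None,
) -> Subject:
    """Sample one virtual subject.

    GA and PNA are drawn uniformly within ``covariate_ranges`` (keys
    ``ga`` and/or ``pna``, each a (min, max) pair), sex is Bernoulli with
    ``covariate_ranges['prop_female']``, and body weight / tissue volume
    fractions receive lognormal inter-individual variability with
    coefficient of variation ``iiv_cv`` (config default when None).

    ``bw_mean_target`` rescales the sampled body weight towards a study's
    reported mean body weight (multiplicative shift of the growth-table
    median).
    """
    config = config or default_physiology()
    if iiv_cv is None:
        iiv_cv = config.cv_bw

    def _draw_range(key: str, default: tuple[float, float] | None):
        rng_pair = covariate_ranges.get(key, default)
        if rng_pair is None:
            return None
        lo, hi = float(rng_pair[0]), float(rng_pair[1])
        if hi < lo:
            raise ValueError(f"inverted {key} range ({lo}, {hi})")
        return rng.uniform(lo, hi) if hi > lo else lo

    prop_female = float(covariate_ranges.get("prop_female", 0.5))
    sex = "F" if rng.random() < prop_female else "M"

    kwargs: dict = {"sex": sex}
    if spec.label == "adult":
        kwargs["age_years"] = _draw_range("age", spec.age_range)
    else:
        kwargs["pna_days"] = _draw_range(
            "pna", spec.pna_range or (0.0, NEONATE_PNA_MAX_DAYS)
        )
        if spec.label == "preterm":
            kwargs["ga_weeks"] = _draw_range("ga", spec.ga_range)
        else:
            ga_pair = covariate_ranges.get("ga")
            kwargs["ga_weeks"] = _draw_range("ga", None) if ga_pair else 40.0

    base = build_reference_subject(spec, config, **kwargs)

    sigma_bw = math.sqrt(math.log(1.0 + iiv_cv**2))
    bw_factor = math.exp(rng.normal(0.0, sigma_bw)) if sigma_bw > 0 else 1.0
    median_bw = base.bw_kg
    bw = median_bw * bw_factor
    if bw_mean_target is not None:
        bw *= bw_mean_target / median_bw

    sigma_t = math.sqrt(math.log(1.0 + (iiv_cv if iiv_cv else 0.0) ** 2))
    scale = bw / base.bw_kg

    def _jitter() -> float:
        return math.exp(rng.normal(0.0, sigma_t)) if sigma_t > 0 else 1.0

    jittered = {t: v * scale * _jitter() for t, v in base.tissue_volumes.items()}
    # jitter perturbs relative tissue proportions; renormalize so the
    # total modelled volume keeps its fraction of body weight
    target = sum(base.tissue_volumes.values()) * scale
    norm = target / sum(jittered.values())
    volumes = {t: v * norm for t, v in jittered.items()}
    return replace(
        base,
        bw_kg=bw,
        tissue_volumes=volumes,
        plasma_volume_l=base.plasma_volume_l * scale,
        erythrocyte_volume_l=base.erythrocyte_volume_l * scale,
    )


# -- protein-binding ontogeny ----------------------------------------------


def scale_fu(fu_adult: float, binding_protein: str, blood: BloodParams) -> float:
    """Scale the adult fraction unbound to a subject's plasma-protein level.

    Uses the standard protein-ratio relationship
    ``fu = 1 / (1 + ((1 - fu_adult) / fu_adult) * R)`` where ``R`` is the
    subject:adult concentration ratio of the drug's main binding protein
    (albumin or alpha-1-acid glycoprotein).  Lower neonatal protein levels
    (R < 1) increase the free fraction.
    """
    if not 0.0 < fu_adult <= 1.0:
        raise ValueError(f"fu_adult must be in (0, 1], got {fu_adult}")
    r = blood.albumin_relative if binding_protein == "HSA" else blood.agp_relative
    if r <= 0:
        raise ValueError("relative protein level must be > 0")
    return 1.0 / (1.0 + ((1.0 - fu_adult) / fu_adult) * r)
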