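"""Partition-coefficient methods and whole-body Vss assembly."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import neovdist as nv
from neovdist.kp_vss import (
    BloodPlasmaError,
    KpSet,
    berezhkovskiy_fu_tissue,
    erythrocyte_plasma_ratio,
    kp_poulin_theil_plus,
    kp_rodgers_rowland,
    predict_vss,
    vss_from_kps,
)
from neovdist.physiology import BloodParams, TissueComposition


def _comp(tissue, f_ew, f_iw, f_nl=0.0, f_np=0.0, ap=0.0, alb=1.0, lipo=1.0,
          ph=7.0):
    return TissueComposition(
        tissue=tissue,
        f_water_total=f_ew + f_iw,
        f_water_extracellular=f_ew,
        f_water_intracellular=f_iw,
        f_neutral_lipid=f_nl,
        f_neutral_phospholipid=f_np,
        acidic_phospholipid=ap,
        protein_ratio_albumin=alb,
        protein_ratio_lipoprotein=lipo,
        ph_intracellular=ph,
    )


def _water_plasma():
    # degenerate plasma: pure water, no lipids, at plasma pH
    return _comp("plasma", 1.0, 0.0, ph=7.4)


def _drug(**overrides):
    base = dict(
        name="probe",
        mwt=300.0,
        logp=2.0,
        ionization_type="neutral",
        pkas=(),
        fu=0.5,
        binding_protein="HSA",
        bp=1.0,
    )
    base.update(overrides)
    return nv.DrugRecord(**base)


class TestPoulinTheil:
    def test_symmetric_media_gives_unit_kp(self):
        # tissue composition identical to plasma and fu_t == fu_p (fu = 1)
        comps = {
            "plasma": _water_plasma(),
            "muscle": _comp("muscle", 0.5, 0.5, ph=7.4),
        }
        kps = kp_poulin_theil_plus(_drug(), comps, fu_p=1.0)
        assert kps.kp["muscle"] == pytest.approx(1.0, rel=1e-12)

    def test_hydrophilic_limit_is_water_ratio(self):
        comps = {
            "plasma": _comp("plasma", 0.9, 0.0, ph=7.4),
            "muscle": _comp("muscle", 0.2, 0.5),
        }
        kps = kp_poulin_theil_plus(_drug(logp=-12.0), comps, fu_p=1.0)
        assert kps.kp["muscle"] == pytest.approx(0.7 / 0.9, rel=1e-6)

    def test_cefazolin_muscle_golden_value(self, drugs_by_name, adult_subject):
        # hand evaluation of the closed form with the shipped adult
        # composition: P = 10^-1.2, muscle (fw .748, fnl .010, fnp .0072),
        # plasma (fw .945, fnl .0035, fnp .00225), fu 0.18
        p = 10.0**-1.2
        numer = p * (0.010 + 0.3 * 0.0072) + (0.748 + 0.7 * 0.0072)
        denom = p * (0.0035 + 0.3 * 0.00225) + (0.945 + 0.7 * 0.00225)
        fu_t = 1.0 / (1.0 + (1.0 - 0.18) / (2.0 * 0.18))
        expected = numer / denom * 0.18 / fu_t
        kps = kp_poulin_theil_plus(
            drugs_by_name["Cefazolin"], adult_subject.compositions, fu_p=0.18
        )
        assert kps.kp["muscle"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.4699, abs=2e-4)  # frozen magnitude

    def test_adipose_uses_oil_water_and_unit_tissue_binding(self, adult_subject):
        # a fully ionized acid partitions into adipose only via water
        drug = _drug(ionization_type="monoprotic_acid", pkas=(1.0,), logp=3.0)
        kps = kp_poulin_theil_plus(drug, adult_subject.compositions, fu_p=0.5)
        adipose_comp = adult_subject.compositions["adipose"]
        plasma = adult_subject.compositions["plasma"]
        water_only = (
            adipose_comp.f_water_total + 0.7 * adipose_comp.f_neutral_phospholipid
        ) / (plasma.f_water_total + 0.7 * plasma.f_neutral_phospholipid)
        # D_vo:w is ~0 at neutral fraction 10^-6.4, so Kp -> water ratio * fu
        assert kps.kp["adipose"] == pytest.approx(water_only * 0.5, rel=1e-3)

    def test_fu_out_of_range_rejected(self, adult_subject):
        with pytest.raises(ValueError):
            kp_poulin_theil_plus(_drug(), adult_subject.compositions, fu_p=0.0)

    def test_berezhkovskiy_fu_tissue_closed_form(self):
        assert berezhkovskiy_fu_tissue(1.0) == 1.0
        assert berezhkovskiy_fu_tissue(0.5) == pytest.approx(2 * 0.5 / 1.5)


class TestRodgersRowland:
    def test_symmetric_media_neutral_drug_gives_unit_kp(self):
        comps = {
            "plasma": _water_plasma(),
            "muscle": _comp("muscle", 0.4, 0.6, ph=7.4),
            "erythrocyte": _comp("erythrocyte", 0.0, 0.6, ap=0.5, ph=7.22),
        }
        blood = BloodParams(hematocrit=0.45)
        kps = kp_rodgers_rowland(_drug(fu=0.3), comps, blood, fu_p=0.3, bp=1.0)
        assert kps.kp["muscle"] == pytest.approx(1.0, rel=1e-12)

    def test_fentanyl_erythrocyte_ratio_golden_value(self, drugs_by_name):
        # Kpu_BC = (Hct - 1 + BP) / (Hct * fu) = (0.45 - 1 + 0.99)/(0.45*0.16)
        fentanyl = drugs_by_name["Fentanyl"]
        blood = BloodParams(hematocrit=0.45)
        comps = {
            "plasma": _water_plasma(),
            "muscle": _comp("muscle", 0.4, 0.5, ap=1.5),
            "erythrocyte": _comp("erythrocyte", 0.0, 0.603, ap=0.5, ph=7.22),
        }
        kps = kp_rodgers_rowland(fentanyl, comps, blood, fu_p=0.16, bp=0.99)
        assert kps.intermediate["kpu_bc"] == pytest.approx(
            (0.45 - 1 + 0.99) / (0.45 * 0.16), rel=1e-12
        )
        assert kps.intermediate["kpu_bc"] == pytest.approx(6.1111, abs=1e-4)
        assert kps.intermediate["base_branch"] == 1.0

    def test_strong_base_with_bp_at_boundary_raises(self, drugs_by_name):
        fentanyl = drugs_by_name["Fentanyl"]
        blood = BloodParams(hematocrit=0.45)
        comps = {
            "plasma": _water_plasma(),
            "muscle": _comp("muscle", 0.4, 0.5, ap=1.5),
            "erythrocyte": _comp("erythrocyte", 0.0, 0.603, ap=0.5, ph=7.22),
        }
        with pytest.raises(BloodPlasmaError, match="inconsistent with hematocrit"):
            kp_rodgers_rowland(fentanyl, comps, blood, fu_p=0.16, bp=0.55)

    def test_ampholyte_low_bp_falls_back_to_protein_branch(self, drugs_by_name,
                                                           adult_subject):
        meropenem = drugs_by_name["Meropenem"]  # basic pKa 9.4, BP 0.507
        kps = kp_rodgers_rowland(
            meropenem,
            adult_subject.compositions,
            adult_subject.blood,
            fu_p=meropenem.fu,
            bp=meropenem.bp,
        )
        assert kps.intermediate["base_branch"] == 0.0
        assert all(v > 0 for v in kps.kp.values())

    def test_neutral_drug_insensitive_to_intracellular_ph(self, adult_subject):
        drug = _drug(logp=1.5)
        comps = dict(adult_subject.compositions)
        shifted = {
            t: dataclasses.replace(c, ph_intracellular=6.0)
            if t not in ("plasma", "erythrocyte")
            else c
            for t, c in comps.items()
        }
        a = kp_rodgers_rowland(drug, comps, adult_subject.blood, 0.4, 1.0)
        b = kp_rodgers_rowland(drug, shifted, adult_subject.blood, 0.4, 1.0)
        for tissue in a.kp:
            assert a.kp[tissue] == pytest.approx(b.kp[tissue], rel=1e-12)

    def test_base_kp_increases_with_acidic_phospholipid(self, drugs_by_name):
        fentanyl = drugs_by_name["Fentanyl"]
        blood = BloodParams(hematocrit=0.45)

        def kp_with_ap(ap):
            comps = {
                "plasma": _water_plasma(),
                "muscle": _comp("muscle", 0.4, 0.5, ap=ap),
                "erythrocyte": _comp("erythrocyte", 0.0, 0.603, ap=0.5, ph=7.22),
            }
            return kp_rodgers_rowland(
                fentanyl, comps, blood, fu_p=0.16, bp=0.99
            ).kp["muscle"]

        assert kp_with_ap(3.0) > kp_with_ap(1.0) > kp_with_ap(0.0)


class TestVssAssembly:
    def test_conservation_with_unit_kps(self, adult_subject):
        kps = KpSet(
            method="PT_plus",
            kp={t: 1.0 for t in adult_subject.tissue_volumes},
            fu_used=0.5,
        )
        result = vss_from_kps(kps, adult_subject, bp=1.0)
        # BP = 1, Hct 0.45 -> E:P = 1: Vss is the total modelled volume
        assert result.vss_l == pytest.approx(
            adult_subject.total_modeled_volume_l, rel=1e-12
        )

    def test_plasma_confined_drug(self, adult_subject):
        kps = KpSet(
            method="PT_plus",
            kp={t: 1e-12 for t in adult_subject.tissue_volumes},
            fu_used=0.5,
        )
        bp = 1.0 - adult_subject.blood.hematocrit  # E:P floored at 0
        result = vss_from_kps(kps, adult_subject, bp=bp)
        assert result.vss_l == pytest.approx(adult_subject.plasma_volume_l, rel=1e-6)

    def test_matches_naive_summation_oracle(self, adult_subject):
        rng = np.random.default_rng(123)
        for _ in range(50):
            kp_map = {
                t: float(rng.uniform(0.01, 30.0))
                for t in adult_subject.tissue_volumes
            }
            kps = KpSet(method="RR", kp=kp_map, fu_used=0.3)
            bp = float(rng.uniform(0.6, 2.0))
            expected = adult_subject.plasma_volume_l
            expected += adult_subject.erythrocyte_volume_l * max(
                erythrocyte_plasma_ratio(bp, adult_subject.blood.hematocrit), 0.0
            )
            for tissue, kp in kp_map.items():
                expected += kp * adult_subject.tissue_volumes[tissue]
            result = vss_from_kps(kps, adult_subject, bp)
            assert result.vss_l == pytest.approx(expected, rel=1e-12)
            assert result.vss_l_per_kg == pytest.approx(
                expected / adult_subject.bw_kg, rel=1e-9
            )

    def test_missing_tissue_volume_rejected(self, adult_subject):
        kps = KpSet(method="RR", kp={"tail": 2.0}, fu_used=0.5)
        with pytest.raises(ValueError, match="tail"):
            vss_from_kps(kps, adult_subject, bp=1.0)

    def test_increasing_any_kp_increases_vss(self, adult_subject):
        base = {t: 1.0 for t in adult_subject.tissue_volumes}
        v0 = vss_from_kps(
            KpSet(method="RR", kp=base, fu_used=0.5), adult_subject, 1.0
        ).vss_l
        for tissue in base:
            bumped = dict(base, **{tissue: 1.5})
            v1 = vss_from_kps(
                KpSet(method="RR", kp=bumped, fu_used=0.5), adult_subject, 1.0
            ).vss_l
            assert v1 > v0


class TestPredictVss:
    def test_every_drug_both_methods_in_sanity_envelope(self, drugs, adult_subject):
        for drug in drugs:
            for method in ("PT_plus", "RR"):
                value = predict_vss(drug, adult_subject, method).vss_l_per_kg
                assert math.isfinite(value)
                assert 0.01 <= value <= 100.0

    def test_propofol_preterm_below_adult(self, drugs_by_name, adult_subject,
                                          preterm_subject):
        propofol = drugs_by_name["Propofol"]
        for method in ("PT_plus", "RR"):
            preterm = predict_vss(propofol, preterm_subject, method).vss_l_per_kg
            adult = predict_vss(propofol, adult_subject, method).vss_l_per_kg
            assert preterm < adult

    def test_hydrophilic_acid_term_at_least_adult(self, drugs_by_name,
                                                  adult_subject, term_subject):
        cefazolin = drugs_by_name["Cefazolin"]  # logp -1.2 acid
        for method in ("PT_plus", "RR"):
            term = predict_vss(cefazolin, term_subject, method).vss_l_per_kg
            adult = predict_vss(cefazolin, adult_subject, method).vss_l_per_kg
            assert term >= adult

    @given(logp=st.floats(-2.0, 4.0))
    def test_kp_continuity_in_logp(self, logp, adult_subject):
        drug_lo = _drug(logp=logp)
        drug_hi = _drug(logp=logp + 1e-7)
        a = kp_poulin_theil_plus(drug_lo, adult_subject.compositions, 0.5)
        b = kp_poulin_theil_plus(drug_hi, adult_subject.compositions, 0.5)
        for tissue in a.kp:
            assert b.kp[tissue] == pytest.approx(a.kp[tissue], rel=1e-5)
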