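"""Fold-error metrics, allometric scaling and the exponent sweep."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neovdist.scaling_metrics import (
    AccuracySummary,
    aafe,
    afe,
    allometric_vss,
    fold_error,
    pct_within_twofold,
    summarize_accuracy,
    sweep_alpha,
)
from neovdist.trials import StudyRecord


def _brute_afe(fes):
    return 10.0 ** (sum(np.log10(f) for f in fes) / len(fes))


def _brute_aafe(fes):
    return 10.0 ** (sum(abs(np.log10(f)) for f in fes) / len(fes))


fe_lists = st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=50)


class TestAllometric:
    def test_isometric_is_identity(self):
        # body-weight terms cancel at alpha = 1
        assert allometric_vss(0.12, 3.23, 70.0, 1.0) == 0.12
        assert allometric_vss(5.0, 1.19, 70.0, 1.0) == 5.0

    def test_cefazolin_like_example(self):
        # 0.12 L/kg scaled to a 3.23 kg term neonate at alpha 0.85
        expected = 0.12 * (3.23 / 70.0) ** (-0.15)
        assert allometric_vss(0.12, 3.23, 70.0, 0.85) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.190, abs=5e-4)

    def test_equal_weights_identity_for_any_alpha(self):
        for alpha in (0.75, 0.85, 1.0):
            assert allometric_vss(0.7, 70.0, 70.0, alpha) == pytest.approx(0.7)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            allometric_vss(0.5, 0.0, 70.0, 0.85)


class TestFoldErrorMetrics:
    def test_fold_error_basics(self):
        assert fold_error(0.5, 1.0) == 0.5
        assert fold_error(0.3, 0.3) == 1.0
        assert fold_error(0.3, 0.12) == pytest.approx(2.5)
        with pytest.raises(ValueError):
            fold_error(-1.0, 1.0)

    def test_symmetric_pair(self):
        assert afe([2.0, 0.5]) == pytest.approx(1.0, rel=1e-12)
        assert aafe([2.0, 0.5]) == pytest.approx(2.0, rel=1e-12)

    def test_constant_vectors(self):
        assert afe([10.0, 10.0]) == pytest.approx(10.0, rel=1e-12)
        assert aafe([1.0, 1.0, 1.0]) == pytest.approx(1.0)
        assert pct_within_twofold([1.0, 1.0, 1.0]) == 100.0

    def test_twofold_boundaries_inclusive(self):
        assert pct_within_twofold([0.5, 2.0]) == 100.0
        assert pct_within_twofold([0.4, 0.6, 1.5, 2.5]) == 50.0

    def test_empty_rejected(self):
        for fn in (afe, aafe, pct_within_twofold):
            with pytest.raises(ValueError):
                fn([])

    @given(fe_lists)
    def test_agrees_with_brute_force(self, fes):
        assert afe(fes) == pytest.approx(_brute_afe(fes), rel=1e-12)
        assert aafe(fes) == pytest.approx(_brute_aafe(fes), rel=1e-12)

    @given(fe_lists, st.floats(1e-3, 1e3))
    def test_afe_scale_equivariance(self, fes, c):
        assert afe([c * f for f in fes]) == pytest.approx(c * afe(fes), rel=1e-9)

    @given(fe_lists)
    def test_reciprocal_symmetries(self, fes):
        recip = [1.0 / f for f in fes]
        assert afe(recip) == pytest.approx(1.0 / afe(fes), rel=1e-9)
        assert aafe(recip) == pytest.approx(aafe(fes), rel=1e-9)
        assert aafe(fes) + 1e-9 >= max(afe(fes), 1.0 / afe(fes))
        assert aafe(fes) >= 1.0 - 1e-12

    def test_summary_invariants_enforced(self):
        with pytest.raises(ValueError):
            AccuracySummary(n_studies=2, afe=2.0, aafe=1.5, pct_within_twofold=50.0)


def _study(study_id, drug, label, bw, obs, **kwargs):
    defaults = dict(
        n=10,
        prop_female=0.5,
        pna_min_days=0.0,
        pna_max_days=28.0,
        mean_bw_kg=bw,
        vss_obs_l_per_kg=obs,
        population_label=label,
    )
    if label == "preterm":
        defaults.update(ga_min_weeks=28.0, ga_max_weeks=34.0)
    defaults.update(kwargs)
    return StudyRecord(study_id=study_id, drug=drug, **defaults)


class TestSweepAlpha:
    def _noise_free_studies(self, alpha_true, adult_vss, labels_bws):
        studies = []
        for i, (label, bw) in enumerate(labels_bws):
            obs = adult_vss["drugA"] * (bw / 70.0) ** (alpha_true - 1.0)
            studies.append(_study(f"S{i}", "drugA", label, bw, obs))
        return studies

    def test_recovers_generating_exponent_exactly(self):
        adult = {"drugA": 0.8}
        studies = self._noise_free_studies(
            0.85, adult, [("term", 3.2), ("preterm", 1.2), ("mixed", 2.4)] * 5
        )
        result = sweep_alpha(studies, adult)
        assert result.optimal_alpha == 0.85
        idx = result.alphas.index(0.85)
        assert result.curves["overall"][idx].afe == pytest.approx(1.0, rel=1e-12)

    def test_preterm_only_recovery_at_090(self):
        adult = {"drugA": 0.8}
        studies = self._noise_free_studies(
            0.90, adult, [("preterm", bw) for bw in (0.8, 1.0, 1.5, 2.0)]
        )
        result = sweep_alpha(studies, adult, alpha_grid=np.arange(0.75, 1.01, 0.05))
        assert result.optimal_alpha == pytest.approx(0.90)
        assert result.optimal_alpha_by_subgroup["preterm"] == pytest.approx(0.90)

    def test_degenerate_grid_equals_isometric_metrics(self):
        adult = {"drugA": 0.8}
        studies = self._noise_free_studies(0.85, adult, [("term", 3.2)] * 4)
        result = sweep_alpha(studies, adult, alpha_grid=[1.0])
        fes = [0.8 / s.vss_obs_l_per_kg for s in studies]
        assert result.curves["overall"][0].afe == pytest.approx(afe(fes), rel=1e-12)

    def test_missing_adult_value_rejected(self):
        studies = [_study("S0", "mystery", "term", 3.2, 0.5)]
        with pytest.raises(ValueError, match="mystery"):
            sweep_alpha(studies, {"drugA": 0.8})

    def test_imputed_bw_used_when_unreported(self):
        adult = {"drugA": 1.0}
        obs = 1.0 * (3.23 / 70.0) ** (0.85 - 1.0)  # truth at the term constant
        studies = [_study("S0", "drugA", "term", None, obs)]
        result = sweep_alpha(studies, adult)
        idx = result.alphas.index(0.85)
        assert result.curves["overall"][idx].afe == pytest.approx(1.0, rel=1e-12)

    def test_afe_monotone_in_alpha_at_fixed_bw(self):
        adult = {"drugA": 1.0}
        studies = [_study(f"S{i}", "drugA", "term", 3.2, 0.6) for i in range(3)]
        result = sweep_alpha(studies, adult)
        afes = [s.afe for s in result.curves["overall"]]
        # neonatal BW < adult BW: larger alpha lowers the prediction
        assert all(a >= b for a, b in zip(afes, afes[1:]))
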