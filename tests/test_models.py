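"""Forward-model correctness: closed forms against quadrature, degenerate
limits, convergence of the GPD eigenmode sum, and mixture identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import verdictmri as v
from verdictmri.models import (
    B_UNIT,
    D_VASC,
    sphere_attenuation,
)


class TestSphereGPD:
    def test_no_weighting_gives_unit_signal(self):
        assert v.signal_sphere_gpd(7.0, 2.0, 0.0, 4.8, 27.0) == 1.0

    def test_vanishing_sphere_gives_unit_signal(self, kidney_scheme):
        for c in kidney_scheme.combos:
            s = v.signal_sphere_gpd(1e-3, 2.0, c.b, c.delta, c.Delta)
            assert s == pytest.approx(1.0, abs=1e-6)

    def test_frozen_spins_give_unit_signal(self):
        assert v.signal_sphere_gpd(7.0, 0.0, 2000.0, 16.8, 37.5) == 1.0

    def test_large_sphere_approaches_free_diffusion(self):
        # diffusion length ~10 um << R: restricted signal -> exp(-b d)
        s = v.signal_sphere_gpd(1000.0, 2.0, 70.0, 4.8, 27.0, n_roots=3000)
        assert s == pytest.approx(np.exp(-70 * B_UNIT * 2.0), rel=1e-2)

    def test_monotone_in_b_and_radius(self, kidney_scheme):
        radii = np.linspace(0.5, 15.0, 30)
        # group combos with shared timing so b is the only variable
        for dl, DL in [(4.8, 27.0), (16.8, 37.5)]:
            bs = [c.b for c in kidney_scheme.combos if c.delta == dl]
            sig = sphere_attenuation(radii, 2.0, bs, dl, DL)
            assert np.all(np.diff(sig, axis=1) <= 1e-12)  # decreasing in b
            assert np.all(np.diff(sig, axis=0) <= 1e-12)  # decreasing in R

    def test_diffusivity_limits_and_motional_narrowing(self):
        # restricted signal is non-monotone in d: attenuation vanishes both
        # for frozen spins (d -> 0) and for fast exchange across the sphere
        # (motional narrowing, large d); the Monte-Carlo oracle confirms the
        # rising branch at the tissue diffusivity scale
        s_frozen = v.signal_sphere_gpd(7.0, 1e-4, 2000.0, 16.8, 37.5)
        s_tissue = v.signal_sphere_gpd(7.0, 2.0, 2000.0, 16.8, 37.5)
        s_fast = v.signal_sphere_gpd(7.0, 50.0, 2000.0, 16.8, 37.5)
        assert s_frozen == pytest.approx(1.0, abs=1e-3)
        assert s_fast > s_tissue
        assert s_fast == pytest.approx(1.0, abs=0.05)
        assert s_tissue < 0.9  # genuine attenuation in between

    def test_eigenmode_truncation_converged(self, kidney_scheme):
        radii = np.linspace(0.5, 15.0, 12)
        s20 = sphere_attenuation(
            radii, 2.0, kidney_scheme.b_values, kidney_scheme.deltas,
            kidney_scheme.Deltas, n_roots=20,
        )
        s60 = sphere_attenuation(
            radii, 2.0, kidney_scheme.b_values, kidney_scheme.deltas,
            kidney_scheme.Deltas, n_roots=60,
        )
        np.testing.assert_allclose(s20, s60, atol=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            v.signal_sphere_gpd(-1.0, 2.0, 70.0, 4.8, 27.0)
        with pytest.raises(ValueError):
            v.signal_sphere_gpd(7.0, 2.0, 70.0, 30.0, 27.0)


class TestAstrosticks:
    def test_zero_b_exact(self):
        assert v.signal_astrosticks(0.0, 50.0) == 1.0

    @pytest.mark.parametrize("b", [70, 90, 150, 500, 1000, 1500, 2000, 2200, 2500])
    def test_matches_orientation_average_quadrature(self, b):
        expected = quad(lambda t: np.exp(-b * B_UNIT * D_VASC * t**2), 0.0, 1.0)[0]
        assert v.signal_astrosticks(b, D_VASC) == pytest.approx(expected, abs=1e-6)

    @given(b=st.floats(0.0, 5000.0), d=st.floats(0.1, 60.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_in_unit_interval_and_decreasing(self, b, d):
        s = v.signal_astrosticks(b, d)
        assert 0.0 < s <= 1.0
        assert v.signal_astrosticks(b + 100.0, d) <= s + 1e-12

    def test_rejects_nonpositive_diffusivity(self):
        with pytest.raises(ValueError):
            v.signal_astrosticks(70.0, 0.0)


class TestBallAndComposites:
    def test_ball_value_and_doubling_identity(self):
        assert v.signal_ball(0, 2.0) == 1.0
        assert v.signal_ball(1000, 2.0) == pytest.approx(np.exp(-2.0), rel=1e-12)
        s1, s2 = v.signal_ball(700, 1.3), v.signal_ball(1400, 1.3)
        assert s2 == pytest.approx(s1**2, rel=1e-12)

    def test_verdict_degenerates_to_ball(self, kidney_scheme):
        p = v.TissueParams(f_ic=0.0, f_ees=1.0, radius=5.0)
        np.testing.assert_allclose(
            v.model_signal("verdict", p, kidney_scheme),
            v.signal_ball(kidney_scheme.b_values, 2.0),
            rtol=1e-12,
        )

    def test_ivim_degenerates_to_adc(self, kidney_scheme):
        ivim = v.model_signal(
            "ivim", v.IvimParams(f=0.0, d_star=20.0, d=1.5), kidney_scheme
        )
        adc = v.model_signal("adc", v.AdcParams(adc=1.5), kidney_scheme)
        np.testing.assert_allclose(ivim, adc, rtol=1e-12)

    def test_verdict_equals_sum_of_compartments(self, kidney_scheme):
        p = v.TissueParams(f_ic=0.3, f_ees=0.5, radius=7.0)
        sig = v.model_signal("verdict", p, kidney_scheme)
        assert sig.shape == (9,)
        manual = np.array(
            [
                0.2 * v.signal_astrosticks(c.b, 50.0)
                + 0.3 * v.signal_sphere_gpd(7.0, 2.0, c.b, c.delta, c.Delta)
                + 0.5 * v.signal_ball(c.b, 2.0)
                for c in kidney_scheme.combos
            ]
        )
        np.testing.assert_allclose(sig, manual, rtol=1e-10)
        assert np.all((sig > 0) & (sig <= 1))

    def test_mixture_affine_in_fractions(self, kidney_scheme):
        # at fixed R the signal is affine in (f_ic, f_ees)
        r = 7.0
        s00 = v.model_signal("verdict", v.TissueParams(0.0, 0.0, r), kidney_scheme)
        s10 = v.model_signal("verdict", v.TissueParams(0.6, 0.0, r), kidney_scheme)
        s01 = v.model_signal("verdict", v.TissueParams(0.0, 0.6, r), kidney_scheme)
        mix = v.model_signal("verdict", v.TissueParams(0.3, 0.3, r), kidney_scheme)
        np.testing.assert_allclose(
            mix, s00 + 0.5 * (s10 - s00) + 0.5 * (s01 - s00), rtol=1e-10
        )

    def test_invalid_params_rejected(self, kidney_scheme):
        with pytest.raises(ValueError):
            v.TissueParams(f_ic=0.7, f_ees=0.7, radius=5.0)
        with pytest.raises(ValueError):
            v.TissueParams(f_ic=0.2, f_ees=0.2, radius=20.0)
        with pytest.raises(ValueError):
            v.IvimParams(f=0.3, d_star=1.0, d=2.0)
        with pytest.raises(TypeError):
            v.model_signal("verdict", v.AdcParams(adc=1.0), kidney_scheme)
        with pytest.raises(ValueError):
            v.model_signal("kurtosis", v.AdcParams(adc=1.0), kidney_scheme)

    def test_constants_validation(self):
        with pytest.raises(ValueError):
            v.ModelConstants(n_gpd_roots=10)
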