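"""Phantom generator: class contrasts, seeding, the Rician noise channel and
its analytic limits, T2 cancellation, and cohort construction."""

import numpy as np
import pytest
from scipy import stats as sps

import verdictmri as v
from verdictmri.datasets import volume_layout
from verdictmri.synthetic import CLASS_TABLE


def test_default_class_means_follow_reported_contrasts():
    assert CLASS_TABLE["normal_kidney"].f_ic == pytest.approx(0.12)
    assert CLASS_TABLE["cancer"].f_ic == pytest.approx(0.32)
    assert CLASS_TABLE["oncocytoma"].f_ic == pytest.approx(0.17)
    for name in ("ccRCC", "chRCC", "oncocytoma"):
        assert CLASS_TABLE[name].f_vasc == pytest.approx(0.29)
        assert CLASS_TABLE[name].vascular
    for name in ("pRCC", "uRCC"):
        assert CLASS_TABLE[name].f_vasc == pytest.approx(0.13)
        assert not CLASS_TABLE[name].vascular
    assert CLASS_TABLE["normal_kidney"].f_ic_sd == pytest.approx(0.03)


def test_zero_sd_puts_every_voxel_at_class_mean():
    classes = tuple(
        v.TissueClassSpec(c.name, c.f_ic, 0.0, c.f_vasc, 0.0, c.radius, 0.0, c.vascular)
        for c in (CLASS_TABLE["normal_kidney"], CLASS_TABLE["cancer"])
    )
    spec = v.PhantomSpec(shape=(6, 6, 1), classes=classes, snr=None, seed=0)
    ph = v.make_phantom(spec)
    for cid, cls in enumerate(classes):
        sel = ph.class_ids == cid
        assert np.allclose(ph.maps["f_ic"][sel], cls.f_ic)
        assert np.allclose(ph.maps["radius"][sel], cls.radius)


def test_same_seed_reproduces_phantom_and_signals(kidney_scheme):
    spec = v.PhantomSpec(shape=(6, 6, 1), seed=4)
    d1 = v.simulate_signals(v.make_phantom(spec), kidney_scheme)
    d2 = v.simulate_signals(v.make_phantom(spec), kidney_scheme)
    np.testing.assert_array_equal(d1.signals, d2.signals)


def test_overlapping_regions_rejected():
    m = np.ones((4, 4, 1), dtype=bool)
    with pytest.raises(ValueError, match="overlap"):
        v.PhantomSpec(
            shape=(4, 4, 1),
            classes=(CLASS_TABLE["normal_kidney"], CLASS_TABLE["cancer"]),
            regions=(m, m),
        ).region_masks()


def test_noise_free_signals_equal_forward_model(noiseless_dataset, kidney_scheme):
    ph, ds = noiseless_dataset
    _, dw_idx = volume_layout(kidney_scheme)
    i = 7
    c = ds.coords[i]
    p = v.TissueParams(
        f_ic=ph.maps["f_ic"][tuple(c)],
        f_ees=ph.maps["f_ees"][tuple(c)],
        radius=ph.maps["radius"][tuple(c)],
    )
    np.testing.assert_allclose(
        ds.signals[i, dw_idx], v.model_signal("verdict", p, kidney_scheme), rtol=1e-10
    )
    b0_idx, _ = volume_layout(kidney_scheme)
    assert np.all(ds.signals[:, b0_idx] == 1.0)


def test_t2_channel_cancels_under_matched_b0_division(kidney_scheme):
    base = dict(shape=(6, 6, 1), snr=40.0, seed=12)
    ds_plain = v.simulate_signals(
        v.make_phantom(v.PhantomSpec(**base, with_t2=False)), kidney_scheme
    )
    ds_t2 = v.simulate_signals(
        v.make_phantom(v.PhantomSpec(**base, with_t2=True)), kidney_scheme
    )
    np.testing.assert_allclose(ds_plain.signals, ds_t2.signals, rtol=1e-12)
    np.testing.assert_allclose(ds_plain.dw_directions, ds_t2.dw_directions, rtol=1e-12)


class TestRicianChannel:
    def _b0_samples(self, snr, n=20_000, seed=0):
        rng = np.random.default_rng(seed)
        s = 1.0 / snr
        return np.sqrt(
            (1.0 + s * rng.normal(size=n)) ** 2 + (s * rng.normal(size=n)) ** 2
        )

    def test_b0_mean_matches_rice_closed_form(self):
        # Rice mean via the Laguerre closed form with exponentially scaled
        # Bessels (overflow-safe at high SNR, where scipy's moment formula
        # loses precision): E = sigma sqrt(pi/2) L_{1/2}(-nu^2 / 2 sigma^2)
        from scipy.special import ive

        snr = 50.0
        nu, sigma = 1.0, 1.0 / snr
        z = -(nu**2) / (2 * sigma**2)
        expected = (
            sigma
            * np.sqrt(np.pi / 2)
            * ((1 - z) * ive(0, -z / 2) - z * ive(1, -z / 2))
        )
        # cross-check the scaled form against scipy where scipy is stable
        z3 = -(3.0**2) / 2.0
        lag3 = np.sqrt(np.pi / 2) * ((1 - z3) * ive(0, -z3 / 2) - z3 * ive(1, -z3 / 2))
        assert lag3 == pytest.approx(sps.rice.mean(b=3.0, scale=1.0), rel=1e-10)
        samples = self._b0_samples(snr)
        assert samples.mean() == pytest.approx(
            expected, abs=4 * samples.std() / np.sqrt(len(samples))
        )

    def test_high_snr_noise_is_gaussian(self):
        samples = self._b0_samples(100.0)
        assert abs(sps.skew(samples)) < 0.05

    def test_zero_signal_magnitude_is_rayleigh(self):
        rng = np.random.default_rng(1)
        s = 0.05
        mags = np.hypot(rng.normal(0, s, 20_000), rng.normal(0, s, 20_000))
        assert mags.mean() / s == pytest.approx(np.sqrt(np.pi / 2), rel=0.02)


def test_pipeline_closure_noiseless_recovery(noiseless_dataset, kidney_scheme):
    """Classical fit on noise-free phantom signals recovers the ground truth
    within 1e-2 — the master regression check tying generator and fitter."""
    ph, ds = noiseless_dataset
    _, dw_idx = volume_layout(kidney_scheme)
    rng = np.random.default_rng(2)
    for i in rng.choice(ds.n_voxels, 5, replace=False):
        c = tuple(ds.coords[i])
        res = v.fit_nlls("verdict", ds.signals[i, dw_idx], kidney_scheme)
        assert res.params.f_ic == pytest.approx(ph.maps["f_ic"][c], abs=1e-2)
        assert res.params.f_ees == pytest.approx(ph.maps["f_ees"][c], abs=1e-2)


class TestCohort:
    def test_default_cohort_size_matches_study(self):
        cohort = v.make_cohort(v.PhantomSpec(shape=(4, 4, 1)), seed=0)
        assert len(cohort) == 14

    def test_single_subject_equals_direct_simulation(self, kidney_scheme):
        spec = v.PhantomSpec(shape=(5, 5, 1), seed=0)
        cohort = v.make_cohort(
            spec, n_subjects=1, seed=3, scheme=kidney_scheme,
            jitter_f_ic=0.0, jitter_f_vasc=0.0, jitter_radius=0.0,
        )
        s_seed = int(
            np.random.SeedSequence(3).spawn(1)[0].generate_state(1)[0] % (2**31)
        )
        from dataclasses import replace

        direct = v.simulate_signals(
            v.make_phantom(replace(spec, seed=s_seed)), kidney_scheme, seed=s_seed + 1
        )
        np.testing.assert_array_equal(cohort[0].signals, direct.signals)

    def test_distinct_seeds_differ(self):
        spec = v.PhantomSpec(shape=(4, 4, 1))
        c1 = v.make_cohort(spec, n_subjects=2, seed=0)
        c2 = v.make_cohort(spec, n_subjects=2, seed=1)
        assert not np.array_equal(c1[0].signals, c2[0].signals)

    def test_rejects_empty_cohort_request(self):
        with pytest.raises(ValueError):
            v.make_cohort(v.PhantomSpec(shape=(4, 4, 1)), n_subjects=0)
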