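"""Reconstruction: preprocessing, phase-difference velocity, wrap correction,
background polynomial fitting and TKE mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from refless4dflow.phantom import PhantomConfig, generate_phantom, simulate_encodings
from refless4dflow.recon import (EncodingSet, compute_tke, fit_background,
                                 normalize_and_centralize, n_poly_terms,
                                 polynomial_basis, reconstruct_velocity,
                                 static_tissue_mask, unwrap_velocity,
                                 VelocityField, wrap_phase)


def _es_from_phase(dphi, venc=1.2, mag=1.0):
    """EncodingSet with reference phase 0 and all motion phases = dphi."""
    shape = (1, 4, 4, 4)
    real = np.empty((4,) + shape)
    imag = np.empty_like(real)
    real[0], imag[0] = mag, 0.0
    for e in range(1, 4):
        real[e] = mag * np.cos(dphi)
        imag[e] = mag * np.sin(dphi)
    return EncodingSet(real=real, imag=imag, venc_m_s=venc,
                       voxel_size_mm=(1, 1, 1), dt_s=0.05)


class TestWrapPhase:
    @given(st.floats(-50, 50), st.integers(-3, 3))
    @settings(max_examples=50, derandomize=True)
    def test_periodic_and_bounded(self, x, k):
        w = wrap_phase(x)
        assert -np.pi < w <= np.pi + 1e-12
        assert abs(wrap_phase(x + 2 * np.pi * k) - w) < 1e-9

    def test_venc_maps_to_plus_pi(self):
        assert wrap_phase(np.pi) == pytest.approx(np.pi)
        assert wrap_phase(-np.pi) == pytest.approx(np.pi)


class TestNormalizeAndCentralize:
    def test_constant_magnitude_zero_phase(self):
        es = _es_from_phase(0.0, mag=5.0)
        pre = normalize_and_centralize(es)
        assert pre.preprocessed
        # magnitude becomes 1 everywhere, then the real channel centres to 0
        assert np.allclose(pre.real, 0.0, atol=1e-12)
        assert np.allclose(pre.norm_scale, 5.0)

    def test_postconditions_on_random_phantom(self, noisy_encodings):
        pre = normalize_and_centralize(noisy_encodings)
        mags = pre.magnitude().reshape(4, -1).max(axis=1)
        # centering can only move the max magnitude by the (subtracted) mean
        assert np.all(mags <= 1.0 + np.abs(pre.channel_means).max() + 1e-9)
        means = (pre.real + 1j * pre.imag).reshape(4, pre.n_timeframes, -1).mean(axis=2)
        assert np.abs(means).max() < 1e-9

    def test_noop_when_already_preprocessed(self, noisy_encodings):
        pre = normalize_and_centralize(noisy_encodings)
        again = normalize_and_centralize(pre)
        assert again is pre

    def test_all_zero_magnitude_errors(self):
        es = _es_from_phase(0.0, mag=0.0)
        with pytest.raises(ValueError, match="all-zero"):
            normalize_and_centralize(es)


class TestReconstructVelocity:
    @pytest.mark.parametrize("dphi,expected", [(np.pi / 2, 0.6), (0.0, 0.0)])
    def test_linear_phase_map(self, dphi, expected):
        vf = reconstruct_velocity(_es_from_phase(dphi, venc=1.2))
        assert np.allclose(vf.v, expected, atol=1e-12)

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 0.9])
    def test_velocity_linearity_in_phase(self, alpha):
        base = np.pi / 2
        v1 = reconstruct_velocity(_es_from_phase(base)).v
        v2 = reconstruct_velocity(_es_from_phase(alpha * base)).v
        assert np.allclose(v2, alpha * v1, atol=1e-12)

    def test_zero_magnitude_voxels_flagged(self):
        es = _es_from_phase(np.pi / 2)
        es.real[1, 0, 0, 0, 0] = 0.0
        es.imag[1, 0, 0, 0, 0] = 0.0
        vf = reconstruct_velocity(es)
        assert vf.v[0, 0, 0, 0, 0] == 0.0
        assert vf.unreliable[0, 0, 0, 0, 0]


class TestUnwrapVelocity:
    def _smooth_field(self, value, shape=(8, 8, 8)):
        v = np.full((3, 1) + shape, 0.0)
        v[2] = value
        return VelocityField(v=v, venc_m_s=1.2, voxel_size_mm=(1, 1, 1), dt_s=0.05)

    def test_wrap_free_identity(self):
        vf = self._smooth_field(0.9)
        mask = np.ones((8, 8, 8), bool)
        out = unwrap_velocity(vf, mask)
        assert np.array_equal(out.v, vf.v)

    def test_single_wrapped_voxel_restored(self):
        venc = 1.2
        vf = self._smooth_field(1.25)
        vf.v[2, 0, 4, 4, 4] = 1.3 - 2 * venc        # aliased copy of 1.3
        out = unwrap_velocity(vf, np.ones((8, 8, 8), bool))
        assert out.v[2, 0, 4, 4, 4] == pytest.approx(1.3, abs=1e-12)

    def test_two_adjacent_wrapped_voxels_restored(self):
        venc = 1.2
        vf = self._smooth_field(1.25)
        for vox in [(4, 4, 4), (4, 4, 5)]:
            vf.v[(2, 0) + vox] = 1.3 - 2 * venc
        out = unwrap_velocity(vf, np.ones((8, 8, 8), bool))
        for vox in [(4, 4, 4), (4, 4, 5)]:
            assert out.v[(2, 0) + vox] == pytest.approx(1.3, abs=1e-12)

    def test_changes_are_multiples_of_two_venc(self):
        rng = np.random.default_rng(0)
        vf = self._smooth_field(1.0)
        vf.v[2, 0] += rng.normal(0, 0.6, (8, 8, 8))
        out = unwrap_velocity(vf, np.ones((8, 8, 8), bool))
        k = (out.v - vf.v) / (2 * vf.venc_m_s)
        assert np.allclose(k, np.round(k), atol=1e-12)


class TestStaticTissueMask:
    def test_phantom_recovery_dice(self, noisy_gt, noisy_encodings):
        vf = reconstruct_velocity(noisy_encodings)
        mask = static_tissue_mask(vf, noisy_encodings.magnitude(0).mean(axis=0))
        truth = noisy_gt.masks["static_tissue"]
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.9

    def test_zero_noise_superset_of_static(self, noiseless_gt, noiseless_encodings):
        vf = reconstruct_velocity(noiseless_encodings)
        mask = static_tissue_mask(vf, noiseless_encodings.magnitude(0).mean(axis=0))
        truth = noiseless_gt.masks["static_tissue"]
        # noiseless: every bright, truly static voxel is detected
        missed = truth & ~mask & (noiseless_gt.magnitude > 0.5)
        assert missed.sum() == 0

    def test_all_moving_volume_errors(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 0.5, (3, 4, 8, 8, 8))
        vf = VelocityField(v=v, venc_m_s=1.2, voxel_size_mm=(1, 1, 1), dt_s=0.05)
        with pytest.raises(ValueError, match="static-tissue mask is empty"):
            static_tissue_mask(vf, np.ones((8, 8, 8)))


class TestFitBackground:
    @staticmethod
    def _poly_offset(shape, order, seed):
        rng = np.random.default_rng(seed)
        basis = polynomial_basis(shape, order)
        c = rng.normal(0, 0.02, (3, basis.shape[1]))
        off = np.stack([(basis @ ci).reshape(shape) for ci in c])
        return c, off

    def test_degree4_offset_recovered(self):
        shape = (20, 20, 20)
        c_true, off = self._poly_offset(shape, 4, seed=2)
        v = np.broadcast_to(off[:, None], (3, 2) + shape).copy()
        vf = VelocityField(v=v, venc_m_s=1.2, voxel_size_mm=(2, 2, 2), dt_s=0.05)
        static = np.ones(shape, bool)
        pf, corrected = fit_background(vf, static, order=4)
        assert np.abs(pf.coefficients - c_true[None]).max() < 1e-8
        assert np.abs(corrected.v[:, :, static]).max() < 1e-8

    def test_zero_offset_identity(self, noiseless_gt, noiseless_encodings):
        vf = reconstruct_velocity(noiseless_encodings)
        # remove the shared background first so the remaining offset is zero
        vf0 = VelocityField(v=noiseless_gt.velocity.copy(), venc_m_s=1.2,
                            voxel_size_mm=(2.8,) * 3, dt_s=0.05)
        static = noiseless_gt.masks["static_tissue"]
        _, corrected = fit_background(vf0, static, order=4)
        assert np.abs(corrected.v - vf0.v).max() < 1e-10

    def test_projection_property(self):
        shape = (20, 20, 20)
        _, off = self._poly_offset(shape, 4, seed=3)
        rng = np.random.default_rng(4)
        v = np.broadcast_to(off[:, None], (3, 1) + shape).copy()
        v += rng.normal(0, 0.01, v.shape)
        vf = VelocityField(v=v, venc_m_s=1.2, voxel_size_mm=(2, 2, 2), dt_s=0.05)
        static = np.zeros(shape, bool)
        static.ravel()[rng.choice(v[0, 0].size, 2000, replace=False)] = True
        _, once = fit_background(vf, static, order=4)
        pf2, twice = fit_background(once, static, order=4)
        assert np.abs(twice.v - once.v).max() < 1e-9

    def test_noisy_static_residual(self):
        """Degree-4 offset + N(0, 0.01) noise on ~10^4 static voxels: the
        corrected static-tissue residual mean stays below 1e-3 m/s."""
        shape = (22, 22, 22)
        _, off = self._poly_offset(shape, 4, seed=5)
        rng = np.random.default_rng(6)
        v = np.broadcast_to(off[:, None], (3, 1) + shape).copy()
        v += rng.normal(0, 0.01, v.shape)
        vf = VelocityField(v=v, venc_m_s=1.2, voxel_size_mm=(2, 2, 2), dt_s=0.05)
        static = np.ones(shape, bool)
        _, corrected = fit_background(vf, static, order=4)
        assert abs(corrected.v[:, :, static].mean()) < 1e-3

    def test_small_static_mask_errors(self):
        v = np.zeros((3, 1, 16, 16, 16))
        vf = VelocityField(v=v, venc_m_s=1.2, voxel_size_mm=(2, 2, 2), dt_s=0.05)
        static = np.zeros((16, 16, 16), bool)
        static[:4, :4, :4] = True       # 64 voxels << 10 * 35
        with pytest.raises(ValueError, match="static mask"):
            fit_background(vf, static, order=4)

    def test_coefficient_count(self):
        assert n_poly_terms(4) == 35


class TestComputeTke:
    def test_equal_magnitudes_zero_tke(self):
        # identical encodings -> exactly zero
        tm = compute_tke(_es_from_phase(0.0))
        assert np.all(tm.tke == 0.0)
        # same magnitude, different phase -> zero up to float rounding in |S|
        tm2 = compute_tke(_es_from_phase(0.3))
        assert np.abs(tm2.tke).max() < 1e-10

    def test_closed_form_e_minus_one(self):
        es = _es_from_phase(0.0)
        for e in range(1, 4):
            es.real[e] *= np.exp(-1.0)
            es.imag[e] *= np.exp(-1.0)
        tm = compute_tke(es)
        sigma2_expected = (1.2 / np.pi) ** 2                    # ~0.14590 m^2/s^2
        assert np.allclose(tm.sigma2, sigma2_expected, atol=1e-10)
        assert np.allclose(tm.tke, 0.5 * 1060 * 3 * sigma2_expected, atol=1e-6)
        assert tm.tke.flat[0] == pytest.approx(232.0, abs=0.1)

    def test_phantom_round_trip(self, noiseless_gt, noiseless_encodings):
        tm = compute_tke(noiseless_encodings)
        tke_true = 0.5 * 1060 * (noiseless_gt.sigma ** 2).sum(axis=0)
        assert np.abs(tm.tke - tke_true[None]).max() < 1e-8

    def test_rho_proportionality_and_nonnegativity(self, noisy_encodings):
        t1 = compute_tke(noisy_encodings, rho=1060.0)
        t2 = compute_tke(noisy_encodings, rho=530.0)
        assert np.allclose(t1.tke, 2.0 * t2.tke)
        assert np.all(t1.tke >= 0.0)
        assert np.all(t1.sigma2 >= 0.0)

    def test_classical_factor_doubles_sigma2(self, noiseless_encodings):
        tp = compute_tke(noiseless_encodings, sigma_factor="direct")
        tl = compute_tke(noiseless_encodings, sigma_factor="classical")
        assert np.allclose(tl.sigma2, 2.0 * tp.sigma2)

    def test_zero_motion_magnitude_capped(self):
        es = _es_from_phase(0.0)
        es.real[1, 0, 0, 0, 0] = 0.0
        es.imag[1, 0, 0, 0, 0] = 0.0
        tm = compute_tke(es)
        assert tm.sigma2[0, 0, 0, 0, 0] == 20.0 * (1.2 / np.pi) ** 2
        assert tm.capped[0, 0, 0, 0]
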