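"""ESPIRiT maps, receive combination, transmit profiles, coil compression."""

import numpy as np
import pytest

from ptxb1map.core import fft_centered, crop_kspace_center
from ptxb1map.sensitivity import (combine_receive, espirit_maps,
                                  svd_coil_compress, tx_relative_maps)

from conftest import bandlimited_channels


def _object_image(n):
    ax = np.linspace(-1, 1, n)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    obj = (X**2 / 0.7**2 + Y**2 / 0.8**2) <= 1
    return np.where(obj, 1.0 + 0.3 * np.cos(4 * X) + 0.2 * Y, 0.0), obj


class TestEspiritMaps:
    def test_single_uniform_channel(self):
        n = 24
        img, obj = _object_image(n)
        ksp = fft_centered(img[..., None].astype(complex), axes=(0, 1))
        sm = espirit_maps(ksp, kernel=(5, 5), crop=0.9)
        assert sm.eigval[obj].min() > 0.98
        np.testing.assert_allclose(np.abs(sm.maps[obj, 0]), 1.0, atol=1e-6)

    def test_smooth_sensitivities_recovered(self):
        n = 32
        sens = bandlimited_channels(8, n, 3, seed=7)
        img, obj = _object_image(n)
        ksp = fft_centered(sens * img[..., None], axes=(0, 1))
        sm = espirit_maps(ksp, kernel=(5, 5), sv_threshold=0.02, crop=0.9)
        truth = sens / np.linalg.norm(sens, axis=-1, keepdims=True)
        corr = np.abs(np.sum(np.conj(sm.maps) * truth, axis=-1))
        assert sm.support[obj].all()
        assert corr[obj].min() > 0.99

    def test_pure_noise_calibration_has_empty_support(self):
        rng = np.random.default_rng(0)
        calib = rng.standard_normal((12, 12, 8)) + 1j * rng.standard_normal((12, 12, 8))
        sm = espirit_maps(calib, kernel=(5, 5), crop=0.9)
        assert sm.support.mean() < 0.05

    def test_scaling_invariance_up_to_reference_phase(self):
        n = 24
        sens = bandlimited_channels(4, n, 3, seed=8)
        img, obj = _object_image(n)
        ksp = fft_centered(sens * img[..., None], axes=(0, 1))
        a = espirit_maps(ksp, crop=0.9)
        b = espirit_maps(ksp * (3.0 - 4.0j), crop=0.9)
        np.testing.assert_allclose(a.maps[obj], b.maps[obj], atol=1e-6)

    def test_too_small_calibration_rejected(self):
        with pytest.raises(ValueError):
            espirit_maps(np.ones((4, 4, 2), complex), kernel=(5, 5))

    def test_multi_frame_calibration_accepted(self):
        n = 24
        sens = bandlimited_channels(4, n, 3, seed=9)
        img, obj = _object_image(n)
        frames = np.stack([sens * img[..., None],
                           sens * (img * (1 + 0.1))[..., None]], axis=-1)
        ksp = fft_centered(frames, axes=(0, 1))
        sm = espirit_maps(crop_kspace_center(ksp, (12, 12), axes=(0, 1)),
                          out_shape=(n, n), crop=0.9)
        truth = sens / np.linalg.norm(sens, axis=-1, keepdims=True)
        corr = np.abs(np.sum(np.conj(sm.maps) * truth, axis=-1))
        assert np.median(corr[obj]) > 0.99


class TestCombineReceive:
    def test_matched_filter_recovers_common_image(self):
        n = 24
        sens = bandlimited_channels(6, n, 3, seed=10)
        img, obj = _object_image(n)
        data = sens * img[..., None]
        ksp = fft_centered(data, axes=(0, 1))
        sm = espirit_maps(ksp, crop=0.9)
        out = combine_receive(data, sm)
        # output equals the image times the per-voxel sensitivity norm (and a
        # unit phase from referencing), so compare magnitudes
        expect = img * np.linalg.norm(sens, axis=-1)
        sel = obj & sm.support
        np.testing.assert_allclose(np.abs(out[sel]), expect[sel], rtol=1e-2)

    def test_single_unit_channel_is_identity(self):
        from ptxb1map.sensitivity import SensitivityMaps
        rng = np.random.default_rng(1)
        img = rng.standard_normal((8, 8, 1)) + 1j * rng.standard_normal((8, 8, 1))
        sm = SensitivityMaps(maps=np.ones((8, 8, 1), complex),
                             eigval=np.ones((8, 8)),
                             support=np.ones((8, 8), bool))
        np.testing.assert_allclose(combine_receive(img, sm), img[..., 0])

    def test_combination_improves_snr_over_best_channel(self):
        """Matched-filter SNR (coherent signal / noise std) beats every single
        channel, because the combined signal scales with the sensitivity norm."""
        n = 24
        rng = np.random.default_rng(2)
        sens = bandlimited_channels(8, n, 3, seed=11)
        img, obj = _object_image(n)
        clean = sens * img[..., None]
        sm = espirit_maps(fft_centered(clean, axes=(0, 1)), crop=0.9)
        sigma = 1e-3 * np.abs(clean).max()
        sel = obj & sm.support
        ref = combine_receive(clean, sm)
        noise_stds = []
        for trial in range(10):
            noisy = clean + sigma * (rng.standard_normal(clean.shape)
                                     + 1j * rng.standard_normal(clean.shape))
            noise_stds.append(np.std(combine_receive(noisy, sm)[sel] - ref[sel]))
        snr_comb = np.mean(np.abs(ref[sel])) / np.mean(noise_stds)
        snr_single = max(np.mean(np.abs(clean[..., c][sel])) / sigma
                         for c in range(8))
        assert snr_comb > snr_single


class TestTxRelativeMaps:
    def test_noiseless_recovery_both_methods(self, fieldset_small):
        fs = fieldset_small
        imgs = fs.proton_density[..., None] * fs.b1plus
        truth = fs.b1plus / np.linalg.norm(fs.b1plus, axis=-1, keepdims=True)
        truth = truth * np.exp(-1j * np.angle(truth[..., 0]))[..., None]
        body = fs.roi_masks["body"]
        eig = tx_relative_maps(imgs, method="eigen")
        np.testing.assert_allclose(eig[body], truth[body], atol=1e-10)
        esp = tx_relative_maps(imgs, method="espirit", calib_size=12)
        corr = np.abs(np.sum(np.conj(esp) * truth, axis=-1))
        assert np.median(corr[body]) > 0.99

    def test_single_channel_gives_unit_map(self):
        img = (np.random.default_rng(3).standard_normal((8, 8, 1))
               + 1j * np.random.default_rng(4).standard_normal((8, 8, 1)))
        out = tx_relative_maps(img, method="eigen")
        np.testing.assert_allclose(np.abs(out[..., 0]), 1.0, atol=1e-12)

    def test_channel_permutation_equivariance(self, fieldset_small):
        fs = fieldset_small
        imgs = fs.proton_density[..., None] * fs.b1plus
        perm = [3, 1, 0, 2, 7, 6, 5, 4]
        a = tx_relative_maps(imgs, method="eigen")[..., perm]
        b = tx_relative_maps(imgs[..., perm], method="eigen")
        # re-reference a to the permuted channel 0
        ref = a[..., 0]
        a = a * np.exp(-1j * np.angle(np.where(ref == 0, 1.0, ref)))[..., None]
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            tx_relative_maps(np.ones((4, 4, 2), complex), method="magic")


class TestCoilCompression:
    def test_full_virtual_set_preserves_energy(self):
        rng = np.random.default_rng(5)
        ksp = rng.standard_normal((12, 12, 6, 2)) + 1j * rng.standard_normal((12, 12, 6, 2))
        out, energy = svd_coil_compress(ksp, 6)
        assert energy == pytest.approx(1.0, abs=1e-10)
        assert np.sum(np.abs(out) ** 2) == pytest.approx(np.sum(np.abs(ksp) ** 2),
                                                         rel=1e-10)

    def test_low_dimensional_data_compresses_losslessly(self):
        rng = np.random.default_rng(6)
        basis = rng.standard_normal((3, 8)) + 1j * rng.standard_normal((3, 8))
        coeffs = rng.standard_normal((12, 12, 2, 3)) + 1j * rng.standard_normal((12, 12, 2, 3))
        ksp = np.moveaxis(coeffs @ basis, -1, -2)  # (12, 12, 8rx, 2modes)
        out, energy = svd_coil_compress(ksp, 3)
        assert energy == pytest.approx(1.0, abs=1e-8)
        back, _ = svd_coil_compress(ksp, 8)
        assert np.sum(np.abs(out) ** 2) == pytest.approx(np.sum(np.abs(ksp) ** 2),
                                                         rel=1e-8)

    def test_retained_energy_monotone_in_virtual_coils(self):
        rng = np.random.default_rng(7)
        ksp = rng.standard_normal((10, 10, 8, 2)) + 1j * rng.standard_normal((10, 10, 8, 2))
        energies = [svd_coil_compress(ksp, v)[1] for v in range(1, 9)]
        assert np.all(np.diff(energies) >= -1e-12)

    def test_invalid_virtual_counts_rejected(self):
        ksp = np.ones((4, 4, 4, 1), complex)
        with pytest.raises(ValueError):
            svd_coil_compress(ksp, 0)
        with pytest.raises(ValueError):
            svd_coil_compress(ksp, 5)
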