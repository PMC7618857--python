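"""Structured low-rank completion: operator identities, exact recovery, and
the hybrid-space 3D path."""

import numpy as np
import pytest

from ptxb1map.core import fft_centered, ifft_centered
from ptxb1map.sampling import full_sampling_pattern, mask_bank
from ptxb1map.txlr import (HankelConfig, build_block_hankel, hankel_adjoint,
                           hankel_average, low_rank_project,
                           reconstruct_3d_hybrid, txlr_reconstruct)

from conftest import lowrank_multichannel_kspace


class TestBlockHankel:
    def test_matrix_dimensions(self):
        ksp = np.ones((24, 24, 96), complex)
        h = build_block_hankel(ksp, (5, 5))
        assert h.shape == (400, 2400)

    def test_zero_input_gives_zero_matrix(self):
        h = build_block_hankel(np.zeros((10, 10, 2), complex), (3, 3))
        assert np.count_nonzero(h) == 0

    def test_kernel_larger_than_grid_rejected(self):
        with pytest.raises(ValueError):
            build_block_hankel(np.ones((4, 4, 1), complex), (5, 5))

    def test_adjoint_identity(self):
        rng = np.random.default_rng(0)
        shape = (10, 9, 3)
        x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        hx = build_block_hankel(x, (3, 4))
        y = rng.standard_normal(hx.shape) + 1j * rng.standard_normal(hx.shape)
        lhs = np.vdot(y, hx)
        rhs = np.vdot(hankel_adjoint(y, (3, 4), shape), x)
        assert abs(lhs - rhs) < 1e-10 * abs(lhs)

    def test_average_of_consistent_matrix_is_identity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 8, 4)) + 1j * rng.standard_normal((8, 8, 4))
        h = build_block_hankel(x, (3, 3))
        np.testing.assert_allclose(hankel_average(h, (3, 3), x.shape), x,
                                   atol=1e-12)

    def test_average_is_linear(self):
        rng = np.random.default_rng(2)
        shape = (6, 6, 2)
        a = rng.standard_normal((16, 18)) + 1j * rng.standard_normal((16, 18))
        b = rng.standard_normal((16, 18)) + 1j * rng.standard_normal((16, 18))
        np.testing.assert_allclose(
            hankel_average(a + b, (3, 3), shape),
            hankel_average(a, (3, 3), shape) + hankel_average(b, (3, 3), shape),
            atol=1e-12)

    def test_average_is_least_squares_structure_projection(self):
        """On a 6x6 toy grid the averaged k-space minimizes the Frobenius
        distance between its consistent matrix and the input matrix."""
        rng = np.random.default_rng(3)
        shape = (6, 6, 1)
        m = rng.standard_normal((16, 9)) + 1j * rng.standard_normal((16, 9))
        x_avg = hankel_average(m, (3, 3), shape)
        base = np.linalg.norm(build_block_hankel(x_avg, (3, 3)) - m)
        for trial in range(5):
            dx = 1e-3 * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
            perturbed = np.linalg.norm(build_block_hankel(x_avg + dx, (3, 3)) - m)
            assert perturbed >= base - 1e-12


class TestLowRankProject:
    def test_matches_truncated_svd_on_both_orientations(self):
        rng = np.random.default_rng(4)
        for shape in [(20, 50), (50, 20)]:
            m = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
            u, s, vh = np.linalg.svd(m, full_matrices=False)
            expect = (u[:, :5] * s[:5]) @ vh[:5]
            np.testing.assert_allclose(low_rank_project(m, 5), expect, atol=1e-8)


class TestReconstruct:
    def test_fully_sampled_input_returned_exactly(self):
        ksp = lowrank_multichannel_kspace()
        pattern = np.ones(ksp.shape, bool)
        out = txlr_reconstruct(ksp, pattern, HankelConfig(iters=3))
        np.testing.assert_array_equal(out, ksp)

    def test_exact_recovery_from_undersampled_data(self):
        """Exactly structured data at R=3 with a 4x4 calibration block is
        completed to below 1% unmeasured-entry error in 50 iterations, with
        measured entries untouched."""
        ksp = lowrank_multichannel_kspace()
        masks = mask_bank((24, 24), 3.0, 8, calib_size=4, seed=0)
        pattern = np.stack([m.mask for m in masks], axis=-1)
        under = ksp * pattern
        out = txlr_reconstruct(under, pattern, HankelConfig())
        un = ~pattern
        nrmse = np.linalg.norm((out - ksp)[un]) / np.linalg.norm(ksp[un])
        assert nrmse < 0.01
        np.testing.assert_array_equal(out[pattern], under[pattern])

    def test_plain_iteration_residual_is_monotone(self):
        """Without inertia, the energy beyond the kept rank never grows."""
        ksp = lowrank_multichannel_kspace()
        masks = mask_bank((24, 24), 3.0, 8, calib_size=4, seed=0)
        pattern = np.stack([m.mask for m in masks], axis=-1)
        x = ksp * pattern
        meas = x[pattern]
        residuals = []
        for _ in range(15):
            x = txlr_reconstruct(x, pattern, HankelConfig(iters=1, momentum=0.0))
            s = np.linalg.svd(build_block_hankel(x, (5, 5)), compute_uv=False)
            residuals.append(np.linalg.norm(s[50:]))
            x[pattern] = meas
        diffs = np.diff(residuals)
        assert np.all(diffs <= 1e-8 * residuals[0])

    def test_idempotent_on_consistent_low_rank_data(self):
        """Already-consistent exactly-low-rank data is a fixed point: marking
        entries unmeasured without corrupting them changes nothing."""
        ksp = lowrank_multichannel_kspace()
        pattern = np.random.default_rng(9).random(ksp.shape) > 0.3
        out = txlr_reconstruct(ksp, pattern, HankelConfig(iters=5))
        assert np.abs(out - ksp).max() < 1e-8 * np.abs(ksp).max()

    def test_oversized_rank_clamped_with_warning(self, caplog):
        rng = np.random.default_rng(5)
        ksp = rng.standard_normal((8, 8, 2)) + 0j
        pattern = np.ones(ksp.shape, bool)
        pattern[0, 0, 0] = False
        with caplog.at_level("WARNING", logger="ptxb1map.txlr"):
            txlr_reconstruct(ksp * pattern, pattern,
                             HankelConfig(kernel=(3, 3), rank=1000, iters=1))
        assert any("clamped" in r.message for r in caplog.records)

    def test_early_stop_tolerance(self):
        ksp = lowrank_multichannel_kspace()
        masks = mask_bank((24, 24), 3.0, 8, calib_size=4, seed=0)
        pattern = np.stack([m.mask for m in masks], axis=-1)
        out = txlr_reconstruct(ksp * pattern, pattern,
                               HankelConfig(iters=500, tol=1e-3))
        np.testing.assert_array_equal(out[pattern], (ksp * pattern)[pattern])


class TestHybrid3D:
    def _ksp3d(self, nx=4, n=16, nc=3):
        rng = np.random.default_rng(6)
        sens = ifft_centered(
            np.pad(rng.standard_normal((3, 3, nc)) + 1j * rng.standard_normal((3, 3, nc)),
                   ((6, 7), (6, 7), (0, 0))), axes=(0, 1))
        img = np.exp(-np.linspace(-1, 1, n)[:, None] ** 2
                     - np.linspace(-1, 1, n)[None, :] ** 2)
        sl = sens * img[..., None]
        vol = np.stack([sl * (1 + 0.1 * i) for i in range(nx)], axis=0)
        vol = vol[..., None, :]  # (x, ky', kz', rx=1, mode=nc) image domain
        return fft_centered(vol, axes=(0, 1, 2))

    def test_separable_volume_gives_identical_slices(self):
        """Same 2D pattern on every x-slice: slices reconstruct identically
        up to their known scale factors (slice independence)."""
        ksp = self._ksp3d()
        masks = mask_bank((16, 16), 2.0, 3, calib_size=4, seed=1)
        from ptxb1map.sampling import apply_mask
        under = apply_mask(ksp, masks)
        out = reconstruct_3d_hybrid(under, masks, HankelConfig(iters=5, rank=20))
        hyb = ifft_centered(out, axes=(0,))
        ref = hyb[0]
        for i in range(1, 4):
            np.testing.assert_allclose(hyb[i], ref * (1 + 0.1 * i) / 1.0,
                                       atol=1e-8 * np.abs(ref).max())

    def test_fully_sampled_is_identity(self):
        ksp = self._ksp3d()
        masks = [np.ones((16, 16), bool)] * 3
        out = reconstruct_3d_hybrid(ksp, masks, HankelConfig(iters=2, rank=20))
        np.testing.assert_allclose(out, ksp, atol=1e-10)

    def test_masks_covering_kx_rejected(self):
        ksp = self._ksp3d()
        with pytest.raises(ValueError):
            reconstruct_3d_hybrid(ksp, [np.ones((4, 16, 16), bool)] * 3)

    def test_reconstruction_beats_zero_filling(self, fieldset_small):
        """Extruded surrogate volume at R=4: hybrid-space completion gets
        closer to the fully sampled data than the zero-filled input."""
        from ptxb1map.fields import (acquisition_stack, extrude_fieldset,
                                     simulate_acquisition)
        from ptxb1map.sampling import apply_mask

        fs3 = extrude_fieldset(fieldset_small, 6, 24.0)
        acq = simulate_acquisition(fs3)
        stack = acquisition_stack(acq)[:, :, :, :4, :]  # 4 rx for speed
        ksp = fft_centered(stack, axes=(0, 1, 2))
        masks = mask_bank((24, 6), 4.0, 12, calib_size=2, seed=2)
        under = apply_mask(ksp, masks)
        out = reconstruct_3d_hybrid(under, masks,
                                    HankelConfig(kernel=(5, 3), rank=30, iters=20))
        err_rec = np.linalg.norm(out - ksp)
        err_zf = np.linalg.norm(under - ksp)
        assert err_rec < err_zf
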