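"""Calibrationless joint structured low-rank k-space completion.

All receive channels and transmit modes of the concatenated relative /
reference / prepared acquisition are stacked as columns of a multi-channel
block-Hankel matrix built from sliding kernel windows of the phase-encode
plane.  Undersampled k-space is completed by alternating projection: hard
rank truncation of the block-Hankel matrix, projection back onto the set of
structured (consistent) matrices by anti-diagonal averaging, and exact
replacement of the measured samples.  3D data with a fully sampled
frequency-encode axis are reconstructed slice-by-slice in hybrid
x–k_y–k_z space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import fft_centered, ifft_centered

__all__ = [
    "HankelConfig",
    "build_block_hankel",
    "hankel_adjoint",
    "hankel_average",
    "low_rank_project",
    "txlr_reconstruct",
    "reconstruct_3d_hybrid",
]

logger = logging.getLogger(__name__)


@dataclass
class HankelConfig:
    """Kernel size, rank truncation level and iteration budget."""

    kernel: tuple[int, int] = (5, 5)
    rank: int = 50
    iters: int = 50
    tol: float | None = None  # optional early stop on relative k-space change
    #: inertial (heavy-ball) extrapolation weight; 0 recovers the plain
    #: alternating-projection iteration, the default markedly speeds up
    #: convergence to the same fixed point
    momentum: float = 0.85

    def __post_init__(self) -> None:
        self.kernel = tuple(int(k) for k in self.kernel)
        if any(k < 1 for k in self.kernel):
            raise ValueError("kernel sizes must be >= 1")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.iters < 0:
            raise ValueError("iters must be >= 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


def _as_grid_channels(ksp: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    """Reshape ``(n1, n2, *channel_axes)`` to ``(n1, n2, C)``."""
    if ksp.ndim < 3:
        raise ValueError("expected (n1, n2, channels...) k-space")
    chan_shape = ksp.shape[2:]
    return ksp.reshape(ksp.shape[0], ksp.shape[1], -1), chan_shape


def build_block_hankel(ksp: np.ndarray, kernel=(5, 5)) -> np.ndarray:
    """Multi-channel block-Hankel matrix from sliding kernel windows.

    ``ksp`` is ``(n1, n2, C)`` (channels = flattened receive × transmit-mode).
    Rows are the valid kernel positions, columns the kernel elements of every
    channel: shape ``((n1-k1+1)(n2-k2+1), k1 k2 C)``.
    """
    k1, k2 = kernel
    n1, n2, nc = ksp.shape
    if k1 > n1 or k2 > n2:
        raise ValueError(f"kernel {kernel} larger than grid ({n1}, {n2})")
    win = sliding_window_view(ksp, (k1, k2), axis=(0, 1))  # (w1, w2, C, k1, k2)
    w1, w2 = win.shape[0], win.shape[1]
    win = np.moveaxis(win, 2, -1)                          # (w1, w2, k1, k2, C)
    return win.reshape(w1 * w2, k1 * k2 * nc)


def hankel_adjoint(mat: np.ndarray, kernel, shape) -> np.ndarray:
    """Adjoint of :func:`build_block_hankel`: scatter-add matrix entries."""
    k1, k2 = kernel
    n1, n2, nc = shape
    w1, w2 = n1 - k1 + 1, n2 - k2 + 1
    m = mat.reshape(w1, w2, k1, k2, nc)
    out = np.zeros(shape, dtype=mat.dtype)
    for i in range(k1):
        for j in range(k2):
            out[i:i + w1, j:j + w2, :] += m[:, :, i, j, :]
    return out


def hankel_counts(kernel, shape) -> np.ndarray:
    """Number of block-Hankel entries referencing each k-space sample."""
    k1, k2 = kernel
    ones = np.ones((shape[0], shape[1], 1))
    return hankel_adjoint(build_block_hankel(ones, kernel), kernel, (shape[0], shape[1], 1))


def hankel_average(mat: np.ndarray, kernel, shape) -> np.ndarray:
    """Project a matrix onto the block-Hankel-structured set.

    Every k-space entry becomes the mean of all matrix entries that reference
    it — the Frobenius-nearest structured (consistent) matrix.
    """
    counts = hankel_counts(kernel, shape)
    return hankel_adjoint(mat, kernel, shape) / counts


def low_rank_project(mat: np.ndarray, rank: int) -> np.ndarray:
    """Hard truncation to the top ``rank`` singular values.

    Computed through the eigendecomposition of the Gram matrix on the smaller
    side, which is numerically equivalent to a truncated SVD and much cheaper
    for wide matrices.
    """
    r = min(rank, *mat.shape)
    tall = mat.shape[0] <= mat.shape[1]
    g = mat @ mat.conj().T if tall else mat.conj().T @ mat
    vals, vecs = np.linalg.eigh(g)
    u = vecs[:, ::-1][:, :r]  # descending eigenvalues
    if tall:
        return u @ (u.conj().T @ mat)
    return (mat @ u) @ u.conj().T


def txlr_reconstruct(ksp_under: np.ndarray, sample_mask: np.ndarray,
                     cfg: HankelConfig | None = None) -> np.ndarray:
    """Joint structured low-rank completion of a 2-D multi-channel k-space.

    ``ksp_under`` is zero-filled at unsampled points, shape
    ``(n1, n2, *channel_axes)``; ``sample_mask`` is boolean of the same shape
    marking measured entries.  Measured samples are re-imposed exactly after
    every iteration (and after the last), so data consistency is bit-exact.
    """
    cfg = cfg or HankelConfig()
    x, chan_shape = _as_grid_channels(np.array(ksp_under))
    mask, _ = _as_grid_channels(np.asarray(sample_mask, bool))
    if mask.shape != x.shape:
        raise ValueError("sample_mask shape must match k-space shape")
    meas = x[mask]

    n1, n2, nc = x.shape
    w = (n1 - cfg.kernel[0] + 1) * (n2 - cfg.kernel[1] + 1)
    cols = cfg.kernel[0] * cfg.kernel[1] * nc
    rank = cfg.rank
    if rank > min(w, cols):
        logger.warning("rank %d exceeds block-Hankel min dimension %d; clamped",
                       rank, min(w, cols))
        rank = min(w, cols)

    counts = hankel_counts(cfg.kernel, x.shape)
    x_prev = x.copy()
    for it in range(cfg.iters):
        v = x + cfg.momentum * (x - x_prev) if it > 0 else x
        h = build_block_hankel(v, cfg.kernel)
        h = low_rank_project(h, rank)
        x_new = hankel_adjoint(h, cfg.kernel, x.shape) / counts
        x_new[mask] = meas
        if cfg.tol is not None:
            num = np.linalg.norm(x_new - x)
            den = np.linalg.norm(x) or 1.0
            x_prev, x = x, x_new
            if num / den < cfg.tol:
                break
        else:
            x_prev, x = x, x_new
    x[mask] = meas
    return x.reshape(ksp_under.shape)


def reconstruct_3d_hybrid(ksp_3d: np.ndarray, masks, cfg: HankelConfig | None = None,
                          ) -> np.ndarray:
    """Slice-by-slice reconstruction of 3D k-space in hybrid x–k_y–k_z space.

    ``ksp_3d`` is ``(kx, ky, kz, rx, mode)`` with the frequency-encode axis
    ``kx`` fully sampled; ``masks`` is one phase-encode-plane mask per mode
    over ``(ky, kz)``.  The data are inverse-transformed along ``kx`` and each
    x-slice is completed independently (slices commute, so execution order is
    irrelevant), then transformed back.
    """
    from .sampling import SamplingMask  # local import to avoid cycle

    if ksp_3d.ndim != 5:
        raise ValueError("expected (kx, ky, kz, rx, mode) k-space")
    arrs = [m.mask if isinstance(m, SamplingMask) else np.asarray(m, bool) for m in masks]
    stacked = np.stack(arrs)  # (mode, ky, kz)
    if stacked.shape[1:] != ksp_3d.shape[1:3]:
        if stacked.ndim - 1 == 3:
            raise ValueError("masks cover all spatial axes: kx must be fully sampled")
        raise ValueError("mask extent does not match (ky, kz)")
    pattern = np.moveaxis(stacked, 0, -1)[None, :, :, None, :]
    pattern2d = np.broadcast_to(pattern[0], ksp_3d.shape[1:])

    hybrid = ifft_centered(ksp_3d, axes=(0,))
    out = np.empty_like(hybrid)
    for ix in range(hybrid.shape[0]):
        out[ix] = txlr_reconstruct(hybrid[ix], pattern2d, cfg)
        logger.info("hybrid-space slice %d/%d reconstructed", ix + 1, hybrid.shape[0])
    return fft_centered(out, axes=(0,))
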