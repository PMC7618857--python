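"""Eigenvalue-based autocalibrated sensitivity estimation (ESPIRiT), receive
coil combination, transmit relative maps, and SVD coil compression.

ESPIRiT estimates per-channel sensitivity maps from a centered k-space
calibration block: a calibration (Casorati) matrix of sliding kernel windows
is decomposed, the right singular vectors above a singular-value threshold
span the local signal subspace, and a per-voxel eigendecomposition of the
image-transformed kernels yields the sensitivities (top eigenvector) together
with an eigenvalue map in [0, 1] that is ≈1 wherever the signal model holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ifft_centered, zero_pad
from .txlr import build_block_hankel

__all__ = [
    "SensitivityMaps",
    "espirit_maps",
    "combine_receive",
    "tx_relative_maps",
    "svd_coil_compress",
]


@dataclass
class SensitivityMaps:
    """Per-channel complex maps, eigenvalue map, and support mask.

    Inside the support the maps have unit per-voxel L2 norm and are
    phase-referenced to channel 0; outside they are zero.
    """

    maps: np.ndarray     # (x, y, n_ch)
    eigval: np.ndarray   # (x, y), in [0, 1]
    support: np.ndarray  # (x, y) boolean


def espirit_maps(ksp_calib: np.ndarray, kernel=(5, 5), sv_threshold: float = 0.02,
                 crop: float = 0.9, out_shape=None) -> SensitivityMaps:
    """ESPIRiT sensitivity estimation from a centered calibration block.

    ``ksp_calib`` is ``(cx, cy, n_ch)`` or ``(cx, cy, n_ch, n_frames)``; extra
    frames (e.g. several transmit modes sharing the same receive
    sensitivities) contribute additional calibration-matrix rows.
    ``out_shape`` is the spatial shape of the returned maps (defaults to the
    calibration block's own shape).
    """
    calib = np.asarray(ksp_calib, complex)
    if calib.ndim == 3:
        calib = calib[..., None]
    if calib.ndim != 4:
        raise ValueError("expected (cx, cy, n_ch[, n_frames]) calibration data")
    cx, cy, nc, nframes = calib.shape
    k1, k2 = kernel
    if k1 > cx or k2 > cy:
        raise ValueError(f"calibration block ({cx}, {cy}) smaller than kernel {kernel}")
    out_shape = tuple(out_shape) if out_shape is not None else (cx, cy)

    rows = [build_block_hankel(calib[..., f], (k1, k2)) for f in range(nframes)]
    a = np.concatenate(rows, axis=0)
    _, s, vh = np.linalg.svd(a, full_matrices=False)
    n_sub = int(np.sum(s >= sv_threshold * s[0]))
    n_sub = max(n_sub, 1)
    kernels = vh[:n_sub].conj().T.reshape(k1, k2, nc, n_sub)

    # transform the conjugated kernels to image space (the per-voxel signal
    # vector is an eigenvector of the conjugate of the kernel Gram operator);
    # the scale makes eigenvalues land in [0, 1], 1 where the subspace holds
    nx, ny = out_shape
    padded = zero_pad(np.conj(kernels), (nx, ny), axes=(0, 1))
    g = ifft_centered(padded, axes=(0, 1)) * np.sqrt(nx * ny / (k1 * k2))

    # per-voxel nc×nc operator G G^H and its top eigenpair
    w = np.einsum("...cq,...dq->...cd", g, g.conj())
    vals, vecs = np.linalg.eigh(w)
    eigval = np.clip(vals[..., -1].real, 0.0, 1.0)
    maps = vecs[..., -1]

    support = eigval >= crop
    ref = maps[..., 0]
    phase = np.exp(-1j * np.angle(np.where(ref == 0, 1.0, ref)))
    maps = maps * phase[..., None]
    maps = np.where(support[..., None], maps, 0.0)
    return SensitivityMaps(maps=maps, eigval=eigval, support=support)


def combine_receive(img: np.ndarray, sens: SensitivityMaps) -> np.ndarray:
    """Matched-filter receive combination; removes the receive axis.

    ``img`` is ``(x, y, rx)`` or ``(x, y, rx, mode)``.  Inside the support the
    output is ``Σ_r conj(S_r) I_r / Σ_r |S_r|²``; outside it is zero.
    """
    if img.ndim == sens.maps.ndim + 1:   # trailing transmit-mode axis
        s, ax = sens.maps[..., None], -2
    elif img.ndim == sens.maps.ndim:
        s, ax = sens.maps, -1
    else:
        raise ValueError("image and sensitivity shapes are incompatible")
    num = np.sum(np.conj(s) * img, axis=ax)
    den = np.sum(np.abs(s) ** 2, axis=ax)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def tx_relative_maps(relative: np.ndarray, method: str = "eigen",
                     kernel=(5, 5), sv_threshold: float = 0.02,
                     crop: float = 0.9, calib_size: int | None = None) -> np.ndarray:
    """Relative per-channel transmit profiles from receive-combined images.

    ``relative`` is ``(x, y, n_tx)``.  The output has unit per-voxel L2 norm
    and is phase-referenced to transmit channel 0.

    ``method="eigen"`` (default) performs the per-voxel image-domain
    eigen-analysis directly — the top eigenvector of the rank-one per-voxel
    channel matrix, i.e. the normalized channel vector — which is exact on
    noiseless model data.  ``method="espirit"`` runs the transmit-channel axis
    through the same k-space ESPIRiT machinery as the receive axis, using a
    centered ``calib_size`` block of the images' k-space.
    """
    if relative.ndim != 3:
        raise ValueError("expected (x, y, n_tx) combined relative images")
    if method == "eigen":
        norm = np.linalg.norm(relative, axis=-1, keepdims=True)
        maps = np.divide(relative, norm, out=np.zeros_like(relative), where=norm > 0)
        ref = maps[..., 0]
        phase = np.exp(-1j * np.angle(np.where(ref == 0, 1.0, ref)))
        return maps * phase[..., None]
    if method == "espirit":
        from .core import crop_kspace_center, fft_centered

        ksp = fft_centered(relative, axes=(0, 1))
        if calib_size is not None:
            c = min(calib_size, *relative.shape[:2])
            ksp = crop_kspace_center(ksp, (c, c), axes=(0, 1))
        sm = espirit_maps(ksp, kernel=kernel, sv_threshold=sv_threshold, crop=crop,
                          out_shape=relative.shape[:2])
        return sm.maps
    raise ValueError(f"unknown method {method!r}")


def svd_coil_compress(ksp: np.ndarray, n_virtual: int, rx_axis: int = -2
                      ) -> tuple[np.ndarray, float]:
    """Project the receive axis onto its top singular subspace.

    Returns the compressed k-space (receive axis length ``n_virtual``) and
    the fraction of total signal energy retained.
    """
    nc = ksp.shape[rx_axis]
    if n_virtual < 1:
        raise ValueError("n_virtual must be >= 1")
    if n_virtual > nc:
        raise ValueError(f"n_virtual={n_virtual} exceeds {nc} receive channels")
    x = np.moveaxis(ksp, rx_axis, -1).reshape(-1, nc)
    gram = x.conj().T @ x
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1]
    u = vecs[:, order[:n_virtual]]
    compressed = x @ u
    energy = float(np.sum(vals[order[:n_virtual]].real) / np.sum(vals.real))
    out_shape = list(np.moveaxis(ksp, rx_axis, -1).shape)
    out_shape[-1] = n_virtual
    out = compressed.reshape(out_shape)
    return np.moveaxis(out, -1, rx_axis), energy
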