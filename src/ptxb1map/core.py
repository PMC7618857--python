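"""Shared numerical substrate: centered unitary FFTs, k-space cropping,
apodization windows, and zero-padding.

Array convention
----------------
Image- and k-space stacks are plain complex ndarrays with spatial axes first,
followed by the receive-channel and transmit-mode axes, e.g. ``(x, y, rx, mode)``
or ``(x, y, z, rx, mode)``.  All k-space arrays use the *centered-DC* convention:
the DC sample of an axis of length ``N`` sits at index ``N // 2`` (for both odd
and even ``N``).  FFTs are unitary, so Parseval holds exactly and noise
variances are identical in the two domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "dc_index",
    "fft_centered",
    "ifft_centered",
    "crop_kspace_center",
    "zero_pad",
    "tukey_window_1d",
    "hann_window_1d",
    "apply_window",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform Cartesian grid: matrix size and field of view per spatial axis.

    ``voxel_mm`` is derived as ``fov_mm / matrix_size``; all entries must be
    positive.
    """

    matrix_size: tuple[int, ...]
    fov_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix_size", tuple(int(n) for n in self.matrix_size))
        object.__setattr__(self, "fov_mm", tuple(float(f) for f in self.fov_mm))
        if len(self.matrix_size) != len(self.fov_mm):
            raise ValueError("matrix_size and fov_mm must have the same length")
        if any(n <= 0 for n in self.matrix_size) or any(f <= 0 for f in self.fov_mm):
            raise ValueError("matrix_size and fov_mm entries must be positive")

    @property
    def ndim(self) -> int:
        return len(self.matrix_size)

    @property
    def voxel_mm(self) -> tuple[float, ...]:
        return tuple(f / n for f, n in zip(self.fov_mm, self.matrix_size))


def dc_index(n: int) -> int:
    """Index of the DC sample on a centered axis of length ``n``."""
    return n // 2


def _check_axes(data: np.ndarray, axes) -> tuple[int, ...]:
    axes = tuple(int(a) % data.ndim for a in axes)
    if len(set(axes)) != len(axes):
        raise ValueError("duplicate axes")
    return axes


def fft_centered(img: np.ndarray, axes=(0, 1)) -> np.ndarray:
    """Unitary image→k-space transform with DC at ``N // 2`` on every axis."""
    axes = _check_axes(img, axes)
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(img, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft_centered(ksp: np.ndarray, axes=(0, 1)) -> np.ndarray:
    """Unitary k-space→image transform, inverse of :func:`fft_centered`."""
    axes = _check_axes(ksp, axes)
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(ksp, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def _center_slices(src_shape, target, axes):
    """Per-axis slices that carve a DC-aligned centered block of size ``target``."""
    slices = [slice(None)] * len(src_shape)
    for ax, t in zip(axes, target):
        n = src_shape[ax]
        start = dc_index(n) - dc_index(t)
        slices[ax] = slice(start, start + t)
    return tuple(slices)


def crop_kspace_center(ksp: np.ndarray, target, axes=(0, 1)) -> np.ndarray:
    """Crop a centered k-space to ``target`` samples on the given axes.

    The retained window is chosen so the source DC index maps onto the target
    DC index; non-spatial axes are untouched.
    """
    axes = _check_axes(ksp, axes)
    target = tuple(int(t) for t in target)
    if len(target) != len(axes):
        raise ValueError("target must give one size per axis")
    for ax, t in zip(axes, target):
        if t > ksp.shape[ax]:
            raise ValueError(
                f"crop target {t} exceeds source size {ksp.shape[ax]} on axis {ax}"
            )
        if t < 1:
            raise ValueError("crop target must be >= 1")
    return np.ascontiguousarray(ksp[_center_slices(ksp.shape, target, axes)])


def zero_pad(ksp: np.ndarray, target, axes=(0, 1)) -> np.ndarray:
    """Zero-pad a centered k-space out to ``target`` samples, DC-aligned.

    In image space this is sinc interpolation onto a finer grid.
    """
    axes = _check_axes(ksp, axes)
    target = tuple(int(t) for t in target)
    if len(target) != len(axes):
        raise ValueError("target must give one size per axis")
    for ax, t in zip(axes, target):
        if t < ksp.shape[ax]:
            raise ValueError(
                f"pad target {t} smaller than source size {ksp.shape[ax]} on axis {ax}"
            )
    out_shape = list(ksp.shape)
    for ax, t in zip(axes, target):
        out_shape[ax] = t
    out = np.zeros(out_shape, dtype=ksp.dtype)
    # placing the source block centered in the target grid is the adjoint of crop
    src_sizes = tuple(ksp.shape[ax] for ax in axes)
    out[_center_slices(out_shape, src_sizes, axes)] = ksp
    return out


def tukey_window_1d(n: int, cosine_fraction: float) -> np.ndarray:
    """DC-centered tapered-cosine window of length ``n``.

    Coordinates run over ``x = (i - n//2) / (n/2)`` so the gain at the DC
    sample is exactly 1; the window is flat for ``|x| <= 1 - cosine_fraction``
    and rolls off as a raised cosine outside.  ``cosine_fraction=0`` is the
    rectangular window, ``cosine_fraction=1`` the Hann window.
    """
    if not 0.0 <= cosine_fraction <= 1.0:
        raise ValueError("cosine_fraction must lie in [0, 1]")
    i = np.arange(n)
    x = np.abs((i - dc_index(n)) / (n / 2.0))
    x = np.minimum(x, 1.0)
    w = np.ones(n)
    if cosine_fraction > 0.0:
        taper = x > (1.0 - cosine_fraction)
        w[taper] = 0.5 * (
            1.0 + np.cos(np.pi * (x[taper] - (1.0 - cosine_fraction)) / cosine_fraction)
        )
    return w


def hann_window_1d(n: int) -> np.ndarray:
    """DC-centered Hann window (the ``cosine_fraction = 1`` tapered cosine)."""
    return tukey_window_1d(n, 1.0)


def apply_window(ksp: np.ndarray, kind: str = "hann", cosine_fraction: float = 0.7,
                 axes=(0, 1)) -> np.ndarray:
    """Apodize a centered k-space with a separable per-axis window.

    ``kind`` is ``"hann"``, ``"tukey"`` (with ``cosine_fraction``) or ``"none"``.
    The window gain at DC is 1 on every axis.
    """
    if kind == "none":
        return ksp.copy()
    if kind not in ("hann", "tukey"):
        raise ValueError(f"unknown window kind {kind!r}")
    axes = _check_axes(ksp, axes)
    out = ksp.copy()
    for ax in axes:
        n = ksp.shape[ax]
        w = hann_window_1d(n) if kind == "hann" else tukey_window_1d(n, cosine_fraction)
        shape = [1] * ksp.ndim
        shape[ax] = n
        out = out * w.reshape(shape)
    return out
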