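"""Poisson-disc (blue-noise) undersampling masks for phase-encode planes.

Masks are generated at uniform target density with a minimum-distance
constraint, one mask per transmit mode; the reference and prepared images of
an absolute-map mode share a single mask.  An optional centered calibration
block is always fully sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import dc_index

__all__ = ["SamplingMask", "poisson_disc_mask", "mask_bank", "apply_mask"]

#: minimum-distance floor, as a fraction of the density-matched radius
_RADIUS_FLOOR = 0.7
#: radii tried for dart throwing, descending, as fractions of r_target
_RADIUS_LADDER = (1.0, 0.93, 0.86, 0.79, 0.73, _RADIUS_FLOOR)


@dataclass
class SamplingMask:
    """Binary phase-encode sampling pattern for one transmit mode."""

    mask: np.ndarray            # boolean, shape = phase-encode extent
    requested_R: float
    calib_size: int | None = None

    @property
    def n_sampled(self) -> int:
        return int(self.mask.sum())

    @property
    def effective_R(self) -> float:
        return self.mask.size / self.n_sampled

    def calib_slices(self) -> tuple[slice, ...] | None:
        if self.calib_size is None:
            return None
        return _calib_slices(self.mask.shape, self.calib_size)


def _calib_slices(shape, calib_size: int) -> tuple[slice, ...]:
    out = []
    for n in shape:
        c = min(calib_size, n)
        start = dc_index(n) - dc_index(c)
        out.append(slice(start, start + c))
    return tuple(out)


def density_matched_radius(shape, n_points: int) -> float:
    """Mean nearest-sample spacing for ``n_points`` uniformly spread over ``shape``."""
    total = math.prod(shape)
    d = len(shape)
    return (total / n_points) ** (1.0 / d)


def poisson_disc_mask(shape, R: float, calib_size: int | None = None,
                      seed: int = 0) -> SamplingMask:
    """Generate one uniform-density Poisson-disc mask.

    Dart throwing accepts grid points in a seeded random order subject to a
    minimum Euclidean distance among accepted (non-calibration) points; the
    radius is lowered down a short ladder (never below ``0.7`` of the
    density-matched radius) until the requested count is reachable, then a
    random excess is pruned so the effective undersampling factor lands within
    10% of the request.  The centered ``calib_size`` block is always on.
    """
    shape = tuple(int(n) for n in shape)
    total = math.prod(shape)
    if R < 1:
        raise ValueError("undersampling factor R must be >= 1")
    n_target = int(round(total / R))
    if n_target < 1:
        raise ValueError(f"R={R} leaves no sampled points on shape {shape}")

    mask = np.zeros(shape, dtype=bool)
    if calib_size is not None:
        mask[_calib_slices(shape, calib_size)] = True
    n_calib = int(mask.sum())

    if R == 1 or n_target >= total:
        return SamplingMask(np.ones(shape, dtype=bool), float(R), calib_size)

    rng = np.random.default_rng(seed)
    coords = np.argwhere(~mask).astype(float)
    order = rng.permutation(len(coords))
    candidates = coords[order]

    n_extra = max(n_target - n_calib, 0)
    r_target = density_matched_radius(shape, n_target)

    accepted = np.empty((0, len(shape)))
    for frac in _RADIUS_LADDER:
        r = frac * r_target
        accepted = _dart_throw(candidates, r)
        if len(accepted) >= n_extra:
            break
    if len(accepted) > n_extra:
        keep = rng.choice(len(accepted), size=n_extra, replace=False)
        accepted = accepted[keep]
    idx = tuple(accepted.astype(int).T)
    mask[idx] = True
    return SamplingMask(mask, float(R), calib_size)


def _dart_throw(candidates: np.ndarray, r: float) -> np.ndarray:
    """Greedy sequential acceptance with minimum pairwise distance ``r``."""
    if r <= 1.0:
        # every pair of distinct grid points already satisfies the constraint
        return candidates
    accepted: list[np.ndarray] = []
    acc = np.empty((0, candidates.shape[1]))
    r2 = r * r
    for p in candidates:
        if len(accepted) == 0:
            accepted.append(p)
            continue
        acc = np.asarray(accepted)
        d2 = np.sum((acc - p) ** 2, axis=1)
        if d2.min() >= r2:
            accepted.append(p)
    return np.asarray(accepted)


def mask_bank(shape, R: float, n_modes: int, calib_size: int | None = None,
              seed: int = 0) -> list[SamplingMask]:
    """One mask per transmit mode, seeds derived as ``seed + mode_index``."""
    return [poisson_disc_mask(shape, R, calib_size, seed=seed + i) for i in range(n_modes)]


def apply_mask(ksp: np.ndarray, masks) -> np.ndarray:
    """Zero out unsampled k-space entries.

    ``ksp`` has shape ``(*spatial, rx, mode)``; ``masks`` is a sequence of
    :class:`SamplingMask` (or boolean arrays), one per mode, each covering the
    *trailing* spatial axes (the leading frequency-encode axis of a 3D hybrid
    acquisition is fully sampled and broadcast over).
    """
    arrs = [m.mask if isinstance(m, SamplingMask) else np.asarray(m, bool) for m in masks]
    stacked = np.stack(arrs)               # (mode, *pe)
    n_modes = stacked.shape[0]
    if ksp.shape[-1] != n_modes:
        raise ValueError(f"{n_modes} masks for {ksp.shape[-1]} transmit modes")
    pe_shape = stacked.shape[1:]
    n_spatial = ksp.ndim - 2
    if pe_shape != ksp.shape[:n_spatial][n_spatial - len(pe_shape):]:
        raise ValueError(
            f"mask extent {pe_shape} does not match trailing spatial axes of {ksp.shape}"
        )
    full = np.moveaxis(stacked, 0, -1)     # (*pe, mode)
    full = full[..., None, :]              # broadcast over rx
    return ksp * full


def full_sampling_pattern(ksp_shape, masks) -> np.ndarray:
    """Boolean array of ``ksp_shape`` marking measured entries for each mode."""
    arrs = [m.mask if isinstance(m, SamplingMask) else np.asarray(m, bool) for m in masks]
    stacked = np.stack(arrs)
    full = np.moveaxis(stacked, 0, -1)[..., None, :]
    return np.broadcast_to(full, ksp_shape).copy()
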