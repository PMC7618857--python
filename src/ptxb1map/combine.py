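"""Per-channel absolute B1+ maps from relative maps plus two absolute
shim-mode flip-angle maps (the B1TIAMO-style combination), shim efficiency,
and validity masking.

The relative per-channel profiles are known only up to a common per-voxel
scale; each absolute mode map pins that scale where its own shim has enough
B1+.  The two per-mode corrections are blended with weights proportional to
the m-th power of the mode's reference-image intensity, so the brighter
(higher-B1+) mode dominates voxelwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import ShimVector
from .flipangle import FlipAngleMap

__all__ = [
    "MultiChannelB1Map",
    "shim_combine",
    "shim_efficiency",
    "b1tiamo_combine",
    "build_valid_mask",
]


@dataclass
class MultiChannelB1Map:
    """Complex per-transmit-channel B1+ map.

    Magnitude is the flip angle in degrees at the reference condition; phase
    is relative to transmit channel 0.
    """

    maps: np.ndarray   # (x, y, n_tx) complex
    valid: np.ndarray  # (x, y) boolean

    @property
    def n_tx(self) -> int:
        return self.maps.shape[-1]


def shim_combine(rel: np.ndarray, shim: ShimVector) -> np.ndarray:
    """Complex channel combination ``Σ_c w_c map_c`` per voxel."""
    maps = rel.maps if isinstance(rel, MultiChannelB1Map) else np.asarray(rel)
    if maps.shape[-1] != len(shim.weights):
        raise ValueError("channel count mismatch between maps and shim")
    return maps @ shim.weights


def shim_efficiency(rel: np.ndarray, shim: ShimVector) -> np.ndarray:
    """Constructiveness of a shim: |Σ w_c rel_c| / Σ |w_c||rel_c| in [0, 1].

    1 means fully constructive interference; voxels where the denominator
    vanishes get efficiency 0.
    """
    maps = rel.maps if isinstance(rel, MultiChannelB1Map) else np.asarray(rel)
    num = np.abs(maps @ shim.weights)
    den = np.abs(maps) @ np.abs(shim.weights)
    eff = np.zeros(num.shape)
    np.divide(num, den, out=eff, where=den > 0)
    return eff


def b1tiamo_combine(rel: np.ndarray, fa_maps, ref_mags, shims, m: float = 4.0,
                    ) -> MultiChannelB1Map:
    """Scale relative per-channel profiles to absolute degrees.

    Per voxel, each absolute mode ``j`` proposes the common scale
    ``fa_j / R_j`` with ``R_j = |Σ_c w_jc rel_c|``; the proposals are blended
    with weights ``λ_j = I_j^m / Σ_k I_k^m`` built from the reference-image
    magnitudes ``I_j`` (total scaling exponent ``m``), and the output is
    ``rel_c`` times the blended correction.  Modes with vanishing ``R_j`` are
    dropped from the blend; a voxel with no usable mode is invalid.

    Parameters: ``rel`` — (x, y, n_tx) relative (unitless) maps;
    ``fa_maps`` — two :class:`~ptxb1map.flipangle.FlipAngleMap` in degrees;
    ``ref_mags`` — two reference-image magnitude maps; ``shims`` — the two
    matching shim vectors.
    """
    if len(fa_maps) != 2 or len(ref_mags) != 2 or len(shims) != 2:
        raise ValueError("exactly two absolute modes are required")
    rel = np.asarray(rel)

    fa = np.stack([f.fa_deg if isinstance(f, FlipAngleMap) else np.asarray(f)
                   for f in fa_maps], axis=-1)
    fa_valid = np.stack(
        [f.valid if isinstance(f, FlipAngleMap) else np.ones(f.shape, bool)
         for f in fa_maps], axis=-1)
    intensity = np.stack([np.abs(np.asarray(i)) for i in ref_mags], axis=-1)
    big_r = np.stack([np.abs(shim_combine(rel, s)) for s in shims], axis=-1)

    usable = (big_r > 0) & fa_valid
    lam_raw = np.where(usable, intensity**m, 0.0)
    lam_sum = lam_raw.sum(axis=-1)
    valid = lam_sum > 0
    lam = np.divide(lam_raw, lam_sum[..., None],
                    out=np.zeros_like(lam_raw), where=valid[..., None])

    per_mode = np.divide(fa, big_r, out=np.zeros_like(fa), where=usable)
    correction = np.sum(lam * per_mode, axis=-1)
    maps = rel * correction[..., None]
    maps[~valid] = 0.0
    return MultiChannelB1Map(maps=maps, valid=valid)


def build_valid_mask(relative_images: np.ndarray, rel_maps: np.ndarray, shims,
                     value_frac: float = 0.1, efficiency_min: float = 0.30,
                     ) -> np.ndarray:
    """Binary output mask from image intensity and shim efficiency.

    A voxel is kept when the root-sum-of-squares of the (fully sampled)
    relative images over all channel axes reaches ``value_frac`` of its 95th
    percentile *and* the best shim mode reaches ``efficiency_min`` efficiency
    (low maximum efficiency means too little B1+ in every mode for a reliable
    absolute measurement).
    """
    if not 0.0 < value_frac < 1.0:
        raise ValueError("value_frac must lie in (0, 1)")
    imgs = np.asarray(relative_images)
    spatial_ndim = rel_maps.ndim - 1
    chan_axes = tuple(range(spatial_ndim, imgs.ndim))
    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=chan_axes))
    if rss.max() == 0:
        return np.zeros(rss.shape, bool)
    value_mask = rss >= value_frac * np.percentile(rss, 95)

    eff = np.stack([shim_efficiency(rel_maps, s) for s in shims], axis=-1)
    eff_mask = eff.max(axis=-1) >= efficiency_min
    return value_mask & eff_mask
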