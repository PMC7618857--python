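"""Shared fixtures: surrogate field sets and band-limited test objects."""

import numpy as np
import pytest

from ptxb1map.core import GridSpec, fft_centered, ifft_centered, zero_pad
from ptxb1map.fields import make_surrogate_fields
from ptxb1map.pipeline import RunConfig


@pytest.fixture(scope="session")
def fieldset_native():
    """Default-geometry surrogate (64x64 native grid, 8Tx/8Rx)."""
    return make_surrogate_fields(8, 8, GridSpec((64, 64), (256.0, 256.0)), seed=0)


@pytest.fixture(scope="session")
def fieldset_small():
    """Small surrogate directly at the 24x24 scan matrix (no crop loss)."""
    return make_surrogate_fields(8, 8, GridSpec((24, 24), (96.0, 96.0)), seed=3)


@pytest.fixture
def identity_config():
    """Noiseless, fully sampled, crop-free configuration: the pipeline should
    be an exact identity on model data under it."""
    return RunConfig(grid_matrix=(24, 24), grid_fov_mm=(96.0, 96.0),
                     crop_matrix=(24, 24), R=1.0, psnr_db=None,
                     window_kind="none", iters=0)


def bandlimited_channels(n_ch: int, n: int, support: int, seed: int,
                         ) -> np.ndarray:
    """Smooth per-channel complex fields with exact k-space support."""
    rng = np.random.default_rng(seed)
    kb = rng.standard_normal((support, support, n_ch)) \
        + 1j * rng.standard_normal((support, support, n_ch))
    return ifft_centered(zero_pad(kb, (n, n), axes=(0, 1)), axes=(0, 1))


def lowrank_multichannel_kspace(n: int = 24, n_ch: int = 8, seed: int = 1,
                                ) -> np.ndarray:
    """Exactly structured test k-space: band-limited (3x3-kernel) channel
    sensitivities times one common image with sharp support."""
    sens = bandlimited_channels(n_ch, n, 3, seed)
    ax = np.linspace(-1, 1, n)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    img = np.where(X**2 + Y**2 <= 0.8, 1 + 0.4 * np.cos(3 * X) + 0.3 * Y, 0.0)
    return fft_centered(sens * img[..., None], axes=(0, 1))
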