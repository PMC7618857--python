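"""Synthetic multi-channel acquisition: transmit/receive field sets, the
proton-density phantom, shim modes, the relative / reference / prepared
(sandwich) image model, and k-space noise.

A :class:`FieldSet` holds per-channel complex transmit fields whose magnitude
is the saturation flip angle in degrees achieved at the reference drive,
per-channel complex receive sensitivities (arbitrary units), a nonnegative
proton-density map, grid metadata, and named ROI masks.  The built-in
surrogate generator produces fields with the qualitative structure of a
body-sized dipole array at 7 T — smooth magnitude decay away from each
element, phase advancing with distance at roughly the in-tissue RF
wavelength, and constructive interference of the first-order circularly
polarized (CP+) mode near the centre — so the full pipeline can run without
any electromagnetic simulation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GridSpec, fft_centered, ifft_centered

__all__ = [
    "FieldSet",
    "ShimVector",
    "AcquisitionSet",
    "cp_shim",
    "synthesize_proton_density",
    "make_surrogate_fields",
    "extrude_fieldset",
    "simulate_acquisition",
    "acquisition_stack",
    "add_kspace_noise",
]


@dataclass
class FieldSet:
    """Per-channel transmit/receive fields plus phantom and ROI masks."""

    b1plus: np.ndarray          # (x, y, n_tx) complex, magnitude in degrees
    b1minus: np.ndarray         # (x, y, n_rx) complex, arbitrary units
    proton_density: np.ndarray  # (x, y) real, >= 0
    grid: GridSpec
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sp = self.proton_density.shape
        if self.b1plus.shape[:-1] != sp or self.b1minus.shape[:-1] != sp:
            raise ValueError("b1plus/b1minus spatial shape must match proton_density")
        if tuple(self.grid.matrix_size) != sp:
            raise ValueError("grid matrix_size must match map shape")
        if np.any(self.proton_density < 0):
            raise ValueError("proton_density must be nonnegative")
        if not np.all(np.isfinite(self.b1plus)):
            raise ValueError("b1plus must be finite")
        for name, m in self.roi_masks.items():
            if m.shape != sp:
                raise ValueError(f"ROI mask {name!r} shape mismatch")

    @property
    def n_tx(self) -> int:
        return self.b1plus.shape[-1]

    @property
    def n_rx(self) -> int:
        return self.b1minus.shape[-1]


@dataclass(frozen=True)
class ShimVector:
    """Complex per-channel drive weights with unit L2 norm."""

    weights: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, complex)
        object.__setattr__(self, "weights", w)
        if not np.isclose(np.linalg.norm(w), 1.0):
            raise ValueError("shim weights must have unit L2 norm")


def cp_shim(order: int, n_tx: int) -> ShimVector:
    """Circularly polarized shim of the given order.

    Channel ``c`` (indexed 0..n_tx-1 in azimuthal order) gets weight
    ``exp(-i 2π order c / n_tx) / sqrt(n_tx)``; order 1 is CP+, order 2 CP2+.
    """
    c = np.arange(n_tx)
    w = np.exp(-2j * np.pi * order * c / n_tx) / np.sqrt(n_tx)
    name = {1: "CP+", 2: "CP2+"}.get(order, f"CP{order}+")
    return ShimVector(w, name)


def synthesize_proton_density(tissue_density: np.ndarray) -> np.ndarray:
    """Proton-density phantom from a tissue-density map (kg/m^3).

    Densities greater than 1200 (bone) or below 400 (lung/air) are replaced
    by 80 so the phantom resembles an MR magnitude image; everything else
    passes through unchanged.
    """
    td = np.asarray(tissue_density, float)
    if np.any(td < 0):
        raise ValueError("tissue densities must be nonnegative")
    pd = td.copy()
    pd[(td > 1200) | (td < 400)] = 80.0
    return pd


def _ellipse_mask(grid: GridSpec, center_frac, semi_frac) -> np.ndarray:
    nx, ny = grid.matrix_size
    x = (np.arange(nx)[:, None] - center_frac[0] * nx) / (semi_frac[0] * nx)
    y = (np.arange(ny)[None, :] - center_frac[1] * ny) / (semi_frac[1] * ny)
    return x**2 + y**2 <= 1.0


def make_surrogate_fields(
    n_tx: int = 8,
    n_rx: int = 8,
    grid: GridSpec | None = None,
    seed: int = 0,
    *,
    source_radius_frac: float = 0.62,
    decay_exponent: float = 1.0,
    phase_wavelength_mm: float = 300.0,
    target_cp_mean_deg: float = 66.0,
) -> FieldSet:
    """Surrogate multi-channel field set for a body transmit/receive array.

    Transmit elements sit evenly spaced on an ellipse around the FOV; each
    channel's magnitude decays with distance from its element and its phase
    advances with distance (wavenumber ``2π / phase_wavelength_mm``) plus the
    element's azimuthal angle, so the CP+ combination interferes
    constructively near the centre.  The default phase-advance wavelength is
    deliberately long compared with the in-tissue RF wavelength: it keeps the
    per-channel fields dominated by low-order spatial modes, the property of
    body transmit arrays that makes small-matrix acquisition and joint
    low-rank completion viable in the first place.  The per-channel
    magnitudes are scaled so the CP+ mode's mean flip angle over the heart
    ROI equals ``target_cp_mean_deg``.  Receive elements use the same
    geometry with independent random perturbations.  Deterministic for a
    given seed.
    """
    if n_tx < 2:
        raise ValueError("n_tx must be >= 2")
    grid = grid or GridSpec((64, 64), (256.0, 256.0))
    rng = np.random.default_rng(seed)
    nx, ny = grid.matrix_size
    dx, dy = grid.voxel_mm
    xs = (np.arange(nx) - nx / 2) * dx
    ys = (np.arange(ny) - ny / 2) * dy
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    ax = source_radius_frac * grid.fov_mm[0]
    ay = source_radius_frac * grid.fov_mm[1]
    k = 2 * np.pi / phase_wavelength_mm

    def channel_fields(n_ch: int, jitter: float) -> np.ndarray:
        angles = 2 * np.pi * np.arange(n_ch) / n_ch + jitter * rng.standard_normal(n_ch)
        amp_jit = 1.0 + 0.05 * rng.standard_normal(n_ch)
        maps = np.empty((nx, ny, n_ch), complex)
        for c in range(n_ch):
            px, py = ax * np.cos(angles[c]), ay * np.sin(angles[c])
            d = np.hypot(X - px, Y - py)
            d0 = 0.35 * min(grid.fov_mm)
            mag = amp_jit[c] * (d0 / (d0 + d)) ** decay_exponent
            # phase advances with distance from the element and with the
            # element's azimuthal position; the latter makes CP modes
            # constructive at the centre under w_c ∝ exp(-i 2π c / N)
            phase = -k * d + 2 * np.pi * c / n_ch
            maps[..., c] = mag * np.exp(1j * phase)
        return maps

    b1plus = channel_fields(n_tx, jitter=0.02)
    b1minus = channel_fields(n_rx, jitter=0.05)
    b1minus *= np.exp(1j * 2 * np.pi * rng.random(n_rx))  # independent rx phases

    body = _ellipse_mask(grid, (0.5, 0.5), (0.42, 0.46))
    heart = _ellipse_mask(grid, (0.42, 0.44), (0.12, 0.14))

    # tissue-density-style phantom: soft tissue with a low-density "lung"
    # pocket and a high-density "bone" rim, run through the MR-resemblance rule
    td = np.zeros((nx, ny))
    td[body] = 1020.0 + 60.0 * np.cos(2 * np.pi * X[body] / grid.fov_mm[0])
    lung = _ellipse_mask(grid, (0.58, 0.58), (0.10, 0.10)) & body
    td[lung] = 300.0
    rim = body & ~_ellipse_mask(grid, (0.5, 0.5), (0.39, 0.43))
    td[rim] = 1400.0
    pd = synthesize_proton_density(td)
    pd[~body] = 0.0

    # scale transmit magnitudes so the CP+ mean flip angle in the heart ROI
    # matches the requested study condition
    w = cp_shim(1, n_tx).weights
    cp_mag = np.abs(b1plus @ w)
    scale = target_cp_mean_deg / cp_mag[heart].mean()
    b1plus = b1plus * scale

    return FieldSet(
        b1plus=b1plus,
        b1minus=b1minus,
        proton_density=pd,
        grid=grid,
        roi_masks={"body": body, "heart": heart},
    )


def extrude_fieldset(fs: FieldSet, nz: int, fov_z_mm: float,
                     modulation: float = 0.2) -> FieldSet:
    """Extend a 2D field set to 3D by smooth through-slab modulation.

    Fields get a gentle cosine amplitude profile and a mild through-slab
    phase roll along z; the phantom is tapered with a raised-cosine slab
    profile so the object ends inside the FOV.  Intended for exercising the
    hybrid-space (fully sampled frequency-encode) 3D reconstruction path.
    """
    if fs.proton_density.ndim != 2:
        raise ValueError("extrude_fieldset expects a 2D field set")
    z = (np.arange(nz) - nz / 2) / nz  # -0.5 .. 0.5
    prof_tx = (1.0 + modulation * np.cos(2 * np.pi * 0.4 * z)) * np.exp(1j * 0.6 * np.pi * z)
    prof_rx = (1.0 + modulation * np.cos(2 * np.pi * 0.4 * z + 0.5)) * np.exp(-1j * 0.4 * np.pi * z)
    slab = 0.5 * (1 + np.cos(np.pi * np.clip(np.abs(z) / 0.45, 0, 1)))

    b1p = fs.b1plus[:, :, None, :] * prof_tx[None, None, :, None]
    b1m = fs.b1minus[:, :, None, :] * prof_rx[None, None, :, None]
    pd3 = fs.proton_density[:, :, None] * slab[None, None, :]
    grid3 = GridSpec(fs.grid.matrix_size + (nz,), fs.grid.fov_mm + (float(fov_z_mm),))
    rois = {name: m[:, :, None] & (slab > 0.1)[None, None, :]
            for name, m in fs.roi_masks.items()}
    return FieldSet(b1plus=b1p, b1minus=b1m, proton_density=pd3, grid=grid3,
                    roi_masks=rois)


@dataclass
class AcquisitionSet:
    """Relative, reference and prepared receive-channel image stacks."""

    relative: np.ndarray   # (x, y, rx, n_tx)
    reference: np.ndarray  # (x, y, rx, 2)
    prepared: np.ndarray   # (x, y, rx, 2)
    shims: tuple[ShimVector, ShimVector]
    mode_flip_deg: np.ndarray  # (x, y, 2) noiseless mode flip-angle maps


def simulate_acquisition(fs: FieldSet, shims=None,
                         nominal_saturation_deg: float = 90.0) -> AcquisitionSet:
    """Noiseless ideal-model acquisition from a field set.

    Relative image of channel ``c``: ``pd · b1plus_c``.  Reference image of
    shim mode ``j``: ``pd · Σ_c w_jc b1plus_c``.  Prepared image of mode
    ``j``: the reference image times ``cos`` of the mode flip angle
    ``|Σ_c w_jc b1plus_c| · nominal_saturation_deg / 90``.  Each is then
    multiplied by every receive sensitivity.  Pure function of its inputs.
    """
    if shims is None:
        shims = (cp_shim(1, fs.n_tx), cp_shim(2, fs.n_tx))
    if len(shims) != 2:
        raise ValueError("exactly two absolute-map shim modes are required")

    pd = fs.proton_density
    rel_combined = pd[..., None] * fs.b1plus                       # (x, y, n_tx)

    mode_fields = np.stack([fs.b1plus @ s.weights for s in shims], axis=-1)
    fa_deg = np.abs(mode_fields) * (nominal_saturation_deg / 90.0)  # (x, y, 2)
    ref_combined = pd[..., None] * mode_fields
    prep_combined = ref_combined * np.cos(np.deg2rad(fa_deg))

    rx = fs.b1minus[..., :, None]  # (x, y, rx, 1)
    return AcquisitionSet(
        relative=rel_combined[..., None, :] * rx,
        reference=ref_combined[..., None, :] * rx,
        prepared=prep_combined[..., None, :] * rx,
        shims=tuple(shims),
        mode_flip_deg=fa_deg,
    )


def acquisition_stack(acq: AcquisitionSet) -> np.ndarray:
    """Concatenate relative, reference and prepared images along the mode axis.

    Mode ordering: ``n_tx`` relative channels, then the two reference modes,
    then the two prepared modes (``n_tx + 4`` modes total).
    """
    return np.concatenate([acq.relative, acq.reference, acq.prepared], axis=-1)


def add_kspace_noise(ksp: np.ndarray, psnr_db: float, seed: int = 0,
                     spatial_axes=(0, 1)) -> np.ndarray:
    """Add channel-independent complex Gaussian noise at a given peak SNR.

    The per-component standard deviation σ satisfies
    ``20 log10(peak image magnitude / σ) = psnr_db``; with the unitary FFT
    convention the same σ applies in either domain.  ``psnr_db = inf`` returns
    the data unchanged.
    """
    if not psnr_db > 0:
        raise ValueError("psnr_db must be positive")
    if np.isinf(psnr_db):
        return ksp.copy()
    peak = np.abs(ifft_centered(ksp, axes=spatial_axes)).max()
    sigma = peak * 10.0 ** (-psnr_db / 20.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0, sigma, ksp.shape) + 1j * rng.normal(0, sigma, ksp.shape)
    return ksp + noise
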