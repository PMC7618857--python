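"""Absolute flip-angle maps from sandwich reference/prepared image pairs.

Two inversion paths are provided.  The ideal path takes the arccosine of the
reference/prepared ratio, which is exact when the saturation pulse behaves as
an ideal rotation (the cosine model).  The lookup path corrects the
saturation nonlinearity of a shaped pulse (by default a nonadiabatic
hyperbolic-secant pulse of order 8, HS8) using a Bloch-simulated table
mapping the residual longitudinal fraction Mz/M0 to the effective flip
angle; out-of-domain voxels are masked and filled by spatial interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import griddata

__all__ = [
    "FlipAngleMap",
    "RFPulse",
    "rect_pulse",
    "hs_pulse",
    "fa_from_ratio_arccos",
    "bloch_simulate_saturation",
    "LookupTable",
    "build_lookup",
    "fa_from_ratio_lookup",
    "fill_holes",
]


@dataclass
class FlipAngleMap:
    """Saturation flip angle in degrees plus a validity mask."""

    fa_deg: np.ndarray
    valid: np.ndarray
    method: str = "arccos"


@dataclass
class RFPulse:
    """Complex RF waveform.

    ``samples`` are complex amplitudes in rad/s (rotation rate at unit B1
    scale); ``duration_s`` is the total pulse duration.  At B1 scale ``s`` the
    on-resonance rotation of sample ``k`` is ``|samples_k| · s · dt`` about a
    transverse axis at angle ``arg(samples_k)``.
    """

    samples: np.ndarray
    duration_s: float
    family: str = "custom"

    @property
    def dt(self) -> float:
        return self.duration_s / len(self.samples)

    @property
    def nominal_flip_deg(self) -> float:
        """On-resonance flip of the amplitude integral at unit scale."""
        return float(np.degrees(np.sum(np.abs(self.samples)) * self.dt))


def rect_pulse(flip_deg: float = 90.0, duration_s: float = 5e-3,
               n_samples: int = 128) -> RFPulse:
    """Constant-amplitude pulse calibrated to ``flip_deg`` at unit B1 scale."""
    amp = np.deg2rad(flip_deg) / duration_s
    return RFPulse(np.full(n_samples, amp, complex), duration_s, "rect")


def hs_pulse(order: int = 8, beta: float = 5.3, bandwidth_hz: float = 1000.0,
             flip_deg: float = 90.0, duration_s: float = 5e-3,
             n_samples: int = 256) -> RFPulse:
    """Hyperbolic-secant pulse of the given order (HSn).

    Amplitude ``A(t) = A0 sech(β τ^n)`` with ``τ = 2t/T − 1``; the frequency
    sweeps over ``bandwidth_hz`` following the normalized integral of
    ``sech²(β τ^n)``.  ``A0`` is calibrated so the amplitude integral equals
    ``flip_deg`` at unit B1 scale (the nonlinearity of the achieved rotation
    is exactly what the lookup table corrects).
    """
    t = (np.arange(n_samples) + 0.5) * duration_s / n_samples
    tau = 2 * t / duration_s - 1
    am = 1.0 / np.cosh(beta * tau**order)
    dt = duration_s / n_samples
    a0 = np.deg2rad(flip_deg) / (am.sum() * dt)

    fm_shape = am**2
    cum = np.cumsum(fm_shape)
    cum = cum - cum[-1] / 2  # sweep symmetric about pulse centre
    freq = (bandwidth_hz / 2) * cum / np.abs(cum).max()
    phase = 2 * np.pi * np.cumsum(freq) * dt
    return RFPulse(a0 * am * np.exp(1j * phase), duration_s, f"hs{order}")


def bloch_simulate_saturation(pulse: RFPulse, b1_scale):
    """Residual longitudinal fraction Mz/M0 after the saturation pulse.

    Hard-pulse-train integration of the Bloch equations starting from
    equilibrium; relaxation is neglected during the pulse (ms durations are
    much shorter than tissue T1).  ``b1_scale`` may be a scalar or an array;
    the return value (in [-1, 1]) matches its shape.
    """
    scales = np.atleast_1d(np.asarray(b1_scale, float))
    m = np.zeros((scales.size, 3))
    m[:, 2] = 1.0
    dt = pulse.dt
    for a in pulse.samples:
        theta = np.abs(a) * scales * dt
        ux, uy = np.cos(np.angle(a)), np.sin(np.angle(a))
        u = np.array([ux, uy, 0.0])
        c, s = np.cos(theta)[:, None], np.sin(theta)[:, None]
        # Rodrigues rotation about the transverse axis u
        m = m * c + np.cross(u, m) * s + u * (m @ u)[:, None] * (1 - c)
    mz = m[:, 2]
    if np.isscalar(b1_scale) or np.ndim(b1_scale) == 0:
        return float(mz[0])
    return mz.reshape(np.shape(b1_scale))


@dataclass
class LookupTable:
    """Invertible map from the saturation ratio Mz/M0 to flip angle (degrees).

    ``ratio_grid`` is strictly decreasing over the monotone domain;
    ``fa_grid`` ascends.  Out-of-domain ratios are flagged invalid.
    """

    ratio_grid: np.ndarray
    fa_grid: np.ndarray
    pulse_family: str = "custom"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ratio_grid) >= 0):
            raise ValueError("ratio_grid must be strictly decreasing")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.ratio_grid[-1]), float(self.ratio_grid[0])

    def invert(self, ratio: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear-interpolated table inversion; returns (fa_deg, in_domain)."""
        r = np.asarray(ratio, float)
        lo, hi = self.domain
        in_domain = (r >= lo) & (r <= hi)
        # np.interp needs ascending abscissae
        fa = np.interp(r, self.ratio_grid[::-1], self.fa_grid[::-1])
        return fa, in_domain

    def save_csv(self, path) -> None:
        header = f"lookup table: {self.pulse_family}\nratio,fa_deg"
        np.savetxt(path, np.column_stack([self.ratio_grid, self.fa_grid]),
                   delimiter=",", header=header)

    @classmethod
    def load_csv(cls, path) -> "LookupTable":
        data = np.loadtxt(path, delimiter=",")
        return cls(data[:, 0], data[:, 1])


def build_lookup(pulse: RFPulse, scale_grid: np.ndarray | None = None) -> LookupTable:
    """Bloch-simulated lookup table over a grid of B1 scales.

    The flip-angle axis is the cosine-equivalent angle of the nominal pulse
    (``scale × nominal flip``); the table is restricted to the maximal prefix
    over which the simulated ratio is strictly decreasing, so it stays
    invertible.  For a rectangular pulse it reduces to the arccosine.
    """
    if scale_grid is None:
        scale_grid = np.linspace(0.0, 2.0, 401)
    scale_grid = np.asarray(scale_grid, float)
    ratios = bloch_simulate_saturation(pulse, scale_grid)
    fa = scale_grid * pulse.nominal_flip_deg

    dec = np.diff(ratios) < 0
    n_mono = 1 + int(np.argmin(dec)) if not dec.all() else len(ratios)
    if n_mono < len(ratios):
        import warnings

        warnings.warn(
            f"lookup domain truncated to flip angles <= {fa[n_mono - 1]:.1f} deg "
            "(ratio no longer monotone beyond)", stacklevel=2)
    return LookupTable(ratios[:n_mono], fa[:n_mono], pulse.family)


def _projected_ratio(ref: np.ndarray, prep: np.ndarray,
                     noise_floor_frac: float = 1e-6):
    """Real projection of prep onto ref, normalized: Re(prep ref*) / |ref|²."""
    den = np.abs(ref) ** 2
    ratio = np.zeros(ref.shape, float)
    np.divide((prep * np.conj(ref)).real, den, out=ratio, where=den > 0)
    floor = noise_floor_frac * np.abs(ref).max()
    signal = np.abs(ref) > floor
    return ratio, signal


def fa_from_ratio_arccos(ref: np.ndarray, prep: np.ndarray,
                         noise_floor_frac: float = 1e-6) -> FlipAngleMap:
    """Ideal cosine-model flip angle: arccos of the reference/prepared ratio.

    The ratio uses the real projection ``Re(prep·conj(ref)) / |ref|²`` so the
    common (receive and background) phase drops out without the noise-floor
    bias of a magnitude ratio.  Voxels with |ratio| > 1 or reference
    magnitude below the noise floor are flagged invalid, not raised.
    """
    ratio, signal = _projected_ratio(ref, prep, noise_floor_frac)
    valid = signal & (np.abs(ratio) <= 1.0)
    fa = np.degrees(np.arccos(np.clip(ratio, -1.0, 1.0)))
    fa[~valid] = 0.0
    return FlipAngleMap(fa_deg=fa, valid=valid, method="arccos")


def fill_holes(fa: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid voxels by linear interpolation from valid neighbours.

    Voxels outside the convex hull of valid points fall back to the nearest
    valid value.
    """
    if valid.all():
        return fa.copy()
    if not valid.any():
        raise ValueError("no valid voxels to interpolate from")
    pts = np.argwhere(valid)
    vals = fa[valid]
    holes = np.argwhere(~valid)
    out = fa.copy()
    filled = griddata(pts, vals, holes, method="linear")
    nan = np.isnan(filled)
    if nan.any():
        filled[nan] = griddata(pts, vals, holes[nan], method="nearest")
    out[tuple(holes.T)] = filled
    return out


def fa_from_ratio_lookup(ref: np.ndarray, prep: np.ndarray, lut: LookupTable,
                         noise_floor_frac: float = 1e-6,
                         fill: bool = True) -> FlipAngleMap:
    """Table-inverted flip angle with hole filling.

    Per-voxel linear interpolation of the lookup table; voxels whose ratio
    falls outside the table's monotone domain (or below the reference noise
    floor) are masked out and, when ``fill`` is set, filled by linear spatial
    interpolation from their valid neighbours.
    """
    ratio, signal = _projected_ratio(ref, prep, noise_floor_frac)
    fa, in_domain = lut.invert(ratio)
    valid = signal & in_domain
    if not valid.any():
        raise ValueError("all voxels fall outside the lookup domain")
    fa = np.where(valid, fa, 0.0)
    if fill:
        fa = fill_holes(fa, valid)
    return FlipAngleMap(fa_deg=fa, valid=valid, method="lookup")
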