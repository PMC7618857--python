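"""Error metrics and ROI summary statistics.

All metrics are pure functions of their inputs; complex flip-angle maps are
compared voxelwise (magnitude in degrees, phase referenced to transmit
channel 0), so the reported RMSE is in degrees on the complex values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RoiStats", "complex_rmse", "normalized_rmse_relative", "roi_stats"]


@dataclass
class RoiStats:
    """Mean / min / max flip angle and coefficient of variation over an ROI."""

    mean_deg: float
    min_deg: float
    max_deg: float
    cv_percent: float
    n_voxels: int


def _roi_values(arr: np.ndarray, roi: np.ndarray | None) -> np.ndarray:
    if roi is None:
        return arr.reshape(-1)
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    return arr[roi]


def complex_rmse(est: np.ndarray, ref: np.ndarray, roi: np.ndarray | None = None,
                 ) -> float:
    """RMS of the complex voxelwise difference over the ROI (degrees)."""
    if est.shape != ref.shape:
        raise ValueError("shape mismatch")
    d = _roi_values(est - ref, roi)
    return float(np.sqrt(np.mean(np.abs(d) ** 2)))


def normalized_rmse_relative(est: np.ndarray, ref: np.ndarray,
                             roi: np.ndarray | None = None) -> float:
    """Complex RMSE of relative maps as a percentage of the total available B1+.

    The normalizer is the ROI mean of ``Σ_c |ref_c|`` (the B1+ magnitude all
    channels could contribute if fully constructive); the result is scale
    invariant.  ``est``/``ref`` are ``(..., n_ch)`` relative maps.
    """
    if est.shape != ref.shape:
        raise ValueError("shape mismatch")
    diff = _roi_values(est - ref, roi)
    total = _roi_values(np.sum(np.abs(ref), axis=-1), roi)
    denom = float(np.mean(total))
    if denom == 0:
        raise ValueError("zero total reference B1+ over the ROI")
    rmse = float(np.sqrt(np.mean(np.abs(diff) ** 2)))
    return 100.0 * rmse / denom


def roi_stats(fa_map: np.ndarray, roi: np.ndarray | None = None) -> RoiStats:
    """Mean, min, max and coefficient of variation (SD/mean × 100) over an ROI."""
    vals = _roi_values(np.asarray(fa_map, float), roi)
    if vals.size == 0:
        raise ValueError("empty ROI")
    mean = float(vals.mean())
    cv = float(100.0 * vals.std() / mean) if mean != 0 else float("inf")
    return RoiStats(mean_deg=mean, min_deg=float(vals.min()),
                    max_deg=float(vals.max()), cv_percent=cv, n_voxels=vals.size)
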