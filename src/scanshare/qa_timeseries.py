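"""Time-series (fMRI) QA: per-timepoint summary traces and scalar
temporal-SNR measures.

Two kinds of output are produced for a 4D series:

* traces — the mean volume intensity at each timepoint and the intensity
  center of mass (x, y, z) at each timepoint, in voxel coordinates.  A spike
  shows up as a transient in the mean trace; subject motion as a step in the
  center-of-mass trace.
* scalars — mean tSNR (temporal mean / raw temporal SD per voxel, averaged
  over a mask) and mean SFNR (temporal mean / SD of the residuals after a
  2nd-order polynomial detrend, averaged over the same mask).  The detrend
  absorbs slow scanner drift, so SFNR is never below tSNR voxelwise.

A 3D input does not meet the prerequisites of any of these measures and
raises :class:`NotApplicableError`, which QA dispatch converts to a
``not_applicable`` status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dicom_io import VolumeStack
from .errors import NotApplicableError

__all__ = [
    "TimeseriesQaResult",
    "volume_mean_trace",
    "com_trace",
    "auto_mask",
    "tsnr_sfnr",
    "run_timeseries_qa",
]

DETREND_ORDER = 2
AUTO_MASK_FRACTION = 0.2  # of the robust max of the temporal-mean image


@dataclass
class TimeseriesQaResult:
    mean_intensity: list[float]
    com: list[tuple[float, float, float]]
    mean_snr: float
    mean_sfnr: float
    n_timepoints: int
    n_excluded_voxels: int = 0
    n_mask_voxels: int = 0

    def as_dict(self) -> dict:
        return {
            "mean_intensity": self.mean_intensity,
            "com": [list(c) for c in self.com],
            "mean_snr": self.mean_snr,
            "mean_sfnr": self.mean_sfnr,
            "n_timepoints": self.n_timepoints,
            "n_excluded_voxels": self.n_excluded_voxels,
            "n_mask_voxels": self.n_mask_voxels,
        }


def _require_4d(volume: VolumeStack, min_timepoints: int = 2) -> np.ndarray:
    data = np.asarray(volume.data, dtype=float)
    if data.ndim != 4 or data.shape[3] < min_timepoints:
        raise NotApplicableError(
            "time-series QA requires a 4D series with at least "
            f"{min_timepoints} timepoints")
    return data


def volume_mean_trace(volume: VolumeStack) -> list[float]:
    """Mean intensity over all voxels, per timepoint."""
    data = _require_4d(volume)
    return [float(v) for v in data.mean(axis=(0, 1, 2))]


def com_trace(volume: VolumeStack) -> list[tuple[float, float, float]]:
    """Intensity-weighted centroid (voxel coordinates) per timepoint.

    A timepoint with zero total intensity yields a (nan, nan, nan) entry.
    """
    data = _require_4d(volume)
    grids = np.meshgrid(*[np.arange(n) for n in data.shape[:3]], indexing="ij")
    out = []
    for t in range(data.shape[3]):
        frame = data[..., t]
        total = frame.sum()
        if total <= 0:
            out.append((float("nan"),) * 3)
            continue
        out.append(tuple(float((g * frame).sum() / total) for g in grids))
    return out


def auto_mask(volume: VolumeStack,
              fraction: float = AUTO_MASK_FRACTION) -> np.ndarray:
    """Voxels whose temporal mean exceeds ``fraction`` of the robust
    (98th-percentile) maximum of the temporal-mean image."""
    from .qa_struct import nearest_rank_percentile

    data = _require_4d(volume)
    mean_image = data.mean(axis=3)
    robust_max = nearest_rank_percentile(mean_image, 98)
    return mean_image > fraction * robust_max


def tsnr_sfnr(volume: VolumeStack,
              mask: np.ndarray | str = "auto",
              detrend_order: int = DETREND_ORDER,
              ) -> tuple[float, float, int, int]:
    """Mean tSNR and mean SFNR over a mask.

    Per voxel, tSNR = temporal mean / temporal SD and SFNR = temporal mean /
    SD of the residuals after a polynomial detrend of order
    ``detrend_order`` (population SD in both cases).  Voxels with zero raw
    temporal SD carry no noise information and are excluded; their count is
    returned.

    Returns (mean_snr, mean_sfnr, n_excluded, n_mask_voxels); the scalars
    are NaN when every mask voxel is excluded.
    """
    data = _require_4d(volume, min_timepoints=max(5, detrend_order + 2))
    if isinstance(mask, str):
        if mask != "auto":
            raise ValueError(f"unknown mask mode {mask!r}")
        mask = auto_mask(volume)
    series = data[mask]                          # (n_voxels, T)
    n_mask = series.shape[0]
    if n_mask == 0:
        return float("nan"), float("nan"), 0, 0

    t = np.linspace(-1.0, 1.0, data.shape[3])
    design = np.vander(t, detrend_order + 1, increasing=True)
    coefficients, *_ = np.linalg.lstsq(design, series.T, rcond=None)
    residuals = series.T - design @ coefficients  # (T, n_voxels)

    temporal_mean = series.mean(axis=1)
    raw_sd = series.std(axis=1, ddof=0)
    residual_sd = residuals.std(axis=0, ddof=0)

    keep = raw_sd > 0
    n_excluded = int(n_mask - keep.sum())
    if not np.any(keep):
        return float("nan"), float("nan"), n_excluded, n_mask
    mean_snr = float(np.mean(temporal_mean[keep] / raw_sd[keep]))
    mean_sfnr = float(np.mean(temporal_mean[keep] / residual_sd[keep]))
    return mean_snr, mean_sfnr, n_excluded, n_mask


def run_timeseries_qa(volume: VolumeStack,
                      mask: np.ndarray | str = "auto") -> TimeseriesQaResult:
    """Full time-series QA bundle for a 4D volume."""
    trace = volume_mean_trace(volume)
    com = com_trace(volume)
    mean_snr, mean_sfnr, n_excluded, n_mask = tsnr_sfnr(volume, mask=mask)
    return TimeseriesQaResult(
        mean_intensity=trace, com=com, mean_snr=mean_snr,
        mean_sfnr=mean_sfnr, n_timepoints=len(trace),
        n_excluded_voxels=n_excluded, n_mask_voxels=n_mask)
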