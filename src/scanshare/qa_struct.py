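"""Structural image QA: region masks, per-region intensity statistics, and
the structural signal-to-noise ratio.

SNR here is the mean intensity inside the brain divided by the standard
deviation of the intensity in the region exterior to the head, i.e. the
air/background, where the only signal is noise.  Statistics per region are
the min/max, a robust (2nd–98th percentile) range, mean, standard deviation,
voxel count and volume, for white matter, gray matter, CSF, whole brain and
the exterior.

Segmentation is a native, deliberately simple pipeline tuned for phantoms
and quick triage rather than anatomical fidelity: the head is the largest
connected component above an Otsu threshold after morphological closing; the
brain is the head eroded by a margin; tissue classes are a three-class 1D
k-means over brain intensities (ascending means -> CSF, gray matter, white
matter); the exterior is the complement of the dilated head.  Externally
produced masks can be substituted wholesale via :func:`region_stats` /
:func:`structural_snr`, which only consume the mask container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .dicom_io import VolumeStack
from .errors import EmptyImageError

__all__ = [
    "RegionMasks",
    "RegionStats",
    "StructuralQaResult",
    "segment",
    "region_stats",
    "structural_snr",
    "run_structural_qa",
    "nearest_rank_percentile",
]

REGIONS = ("white", "gray", "csf", "brain", "head", "exterior")


@dataclass
class RegionMasks:
    """Binary masks over the volume grid.

    white, gray and csf are pairwise disjoint subsets of brain; brain is a
    subset of head; exterior is disjoint from head (a buffer ring between
    head and exterior is allowed to belong to neither).
    """

    head: np.ndarray
    brain: np.ndarray
    white: np.ndarray
    gray: np.ndarray
    csf: np.ndarray
    exterior: np.ndarray

    def __getitem__(self, region: str) -> np.ndarray:
        return getattr(self, region)

    def check(self) -> None:
        assert not np.any(self.white & self.gray)
        assert not np.any(self.white & self.csf)
        assert not np.any(self.gray & self.csf)
        for tissue in (self.white, self.gray, self.csf):
            assert not np.any(tissue & ~self.brain)
        assert not np.any(self.brain & ~self.head)
        assert not np.any(self.exterior & self.head)


@dataclass
class RegionStats:
    minimum: float
    maximum: float
    robust_min: float
    robust_max: float
    mean: float
    sd: float
    n_voxels: int
    volume_mm3: float
    defined: bool = True

    @classmethod
    def undefined(cls) -> "RegionStats":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, 0, 0.0, defined=False)

    def as_dict(self) -> dict:
        return {
            "min": self.minimum, "max": self.maximum,
            "robust_min": self.robust_min, "robust_max": self.robust_max,
            "mean": self.mean, "sd": self.sd,
            "n_voxels": self.n_voxels, "volume_mm3": self.volume_mm3,
            "defined": self.defined,
        }


@dataclass
class StructuralQaResult:
    stats: dict[str, RegionStats]
    snr: float

    @property
    def snr_defined(self) -> bool:
        return math.isfinite(self.snr)

    def as_dict(self) -> dict:
        return {"snr": self.snr if self.snr_defined else None,
                "snr_defined": self.snr_defined,
                "regions": {name: s.as_dict() for name, s in self.stats.items()}}


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _kmeans_1d(values: np.ndarray, k: int = 3, max_iter: int = 100) -> np.ndarray:
    """Deterministic 1D k-means.  Centers start evenly spaced across the
    robust (2nd-98th percentile) intensity range rather than at data
    quantiles, so a dominant class cannot swallow two initial centers.
    Returns labels 0..k-1 sorted by ascending center."""
    lo, hi = np.percentile(values, [2, 98])
    centers = lo + (np.arange(k) + 0.5) / k * (hi - lo)
    for _ in range(max_iter):
        labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new_centers = np.array([
            values[labels == j].mean() if np.any(labels == j) else centers[j]
            for j in range(k)])
        if np.allclose(new_centers, centers):
            break
        centers = new_centers
    order = np.argsort(centers)
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[labels]


def segment(volume: VolumeStack, erosion_margin: int = 2,
            exterior_gap: int = 3) -> RegionMasks:
    """Compute head/brain/tissue/exterior masks for a 3D volume.

    erosion_margin: voxels eroded off the head to approximate the brain.
    exterior_gap: dilation of the head before taking its complement as the
    exterior, leaving a buffer so partial-volume rim voxels contaminate
    neither side.
    """
    if volume.data.ndim != 3:
        raise ValueError("segment expects a 3D volume")
    data = np.asarray(volume.data, dtype=float)
    if not np.any(data):
        raise EmptyImageError("all-zero volume")

    threshold = threshold_otsu(data)
    foreground = data > threshold
    # Morphology on an edge-replicated pad: a head truncated by the field
    # of view is treated as continuing beyond it, so closing/erosion do not
    # strip voxels at the volume boundary.
    pad = erosion_margin + exterior_gap + 2
    padded = np.pad(foreground, pad, mode="edge")
    padded = ndimage.binary_closing(padded, iterations=2)
    labels, n_components = ndimage.label(padded)
    if n_components == 0:
        raise EmptyImageError("no foreground above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n_components + 1))
    head_p = labels == (1 + int(np.argmax(sizes)))
    head_p = ndimage.binary_fill_holes(head_p)

    brain_p = ndimage.binary_erosion(head_p, iterations=erosion_margin)
    exterior_p = ~ndimage.binary_dilation(head_p, iterations=exterior_gap)
    crop = tuple(slice(pad, pad + n) for n in data.shape)
    head = head_p[crop]
    brain = brain_p[crop]
    exterior = exterior_p[crop]

    white = np.zeros_like(brain)
    gray = np.zeros_like(brain)
    csf = np.zeros_like(brain)
    brain_values = data[brain]
    if brain_values.size >= 3:
        tissue_labels = _kmeans_1d(brain_values, k=3)
        full = np.zeros(data.shape, dtype=int) - 1
        full[brain] = tissue_labels
        csf = full == 0
        gray = full == 1
        white = full == 2
    return RegionMasks(head=head, brain=brain, white=white, gray=gray,
                       csf=csf, exterior=exterior)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def nearest_rank_percentile(values: np.ndarray, percent: float) -> float:
    """Nearest-rank percentile: the smallest value whose rank is at least
    ceil(p/100 * n)."""
    ordered = np.sort(np.asarray(values).ravel())
    if ordered.size == 0:
        raise ValueError("empty input")
    rank = max(1, math.ceil(percent / 100.0 * ordered.size))
    return float(ordered[rank - 1])


def region_stats(volume: VolumeStack,
                 masks: RegionMasks | Mapping[str, np.ndarray],
                 regions: tuple[str, ...] = REGIONS) -> dict[str, RegionStats]:
    """Per-region intensity statistics over masked voxels.

    sd uses the population formula (divide by N).  The robust range is the
    2nd/98th nearest-rank percentile.  An empty region yields undefined
    stats rather than an error.
    """
    data = np.asarray(volume.data, dtype=float)
    out: dict[str, RegionStats] = {}
    for region in regions:
        mask = masks[region]
        if mask.shape != data.shape:
            raise ValueError(f"mask {region!r} does not match the volume grid")
        values = data[mask]
        if values.size == 0:
            out[region] = RegionStats.undefined()
            continue
        out[region] = RegionStats(
            minimum=float(values.min()),
            maximum=float(values.max()),
            robust_min=nearest_rank_percentile(values, 2),
            robust_max=nearest_rank_percentile(values, 98),
            mean=float(values.mean()),
            sd=float(values.std(ddof=0)),
            n_voxels=int(values.size),
            volume_mm3=float(values.size * volume.voxel_volume),
        )
    return out


def structural_snr(volume: VolumeStack,
                   masks: RegionMasks | Mapping[str, np.ndarray]) -> float:
    """Mean brain intensity over the standard deviation of the exterior.

    Returns NaN (undefined) when the exterior noise estimate is zero, e.g.
    on a noiseless phantom.
    """
    data = np.asarray(volume.data, dtype=float)
    brain_values = data[masks["brain"]]
    exterior_values = data[masks["exterior"]]
    if brain_values.size == 0 or exterior_values.size == 0:
        raise ValueError("brain and exterior masks must be non-empty")
    noise = float(exterior_values.std(ddof=0))
    if noise == 0.0:
        return float("nan")
    return float(brain_values.mean()) / noise


def run_structural_qa(volume: VolumeStack,
                      masks: RegionMasks | None = None) -> StructuralQaResult:
    """Segment (unless masks are supplied), then compute stats and SNR."""
    if masks is None:
        masks = segment(volume)
    stats = region_stats(volume, masks)
    snr = structural_snr(volume, masks)
    return StructuralQaResult(stats=stats, snr=snr)
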