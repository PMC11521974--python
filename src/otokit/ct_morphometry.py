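"""μCT otolith quantification.

The chain mirrors how otoconial masses are measured on micro-CT: summarize
the CT numbers of a manually placed otolith ROI (alpha) and a surrounding
tissue ROI (beta), segment the otolith at the midpoint threshold
T = (alpha + beta)/2, report volume and mean CT number, and quantify the
striola boundary with the dual-threshold edge band [0.9 T, T): a sharp
boundary contributes almost nothing to the band, a blurred (collapsed)
boundary contributes a large shell.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import (
    CTVolume,
    DegenerateInputError,
    EdgeVolumeResult,
    MorphometryResult,
    RoiPair,
    ThresholdResult,
    VolumeMeta,
)

#: 26-neighbourhood, the standard connectivity for bright 3D objects
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

_AXES = {"z": 0, "y": 1, "x": 2}


def roi_histogram(vol: CTVolume, roi: np.ndarray, n_bins: int = 64):
    """Histogram of CT numbers inside a ROI.

    Returns (bin_edges, counts); counts sum to the ROI voxel count and the
    bin range spans the observed values (a constant ROI occupies one bin).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise DegenerateInputError("cannot histogram an empty ROI")
    values = vol.voxels[roi]
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:  # degenerate range: a single occupied bin
        hi = lo + 1.0
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return edges, counts


def _summarize(values: np.ndarray, summary: str, n_bins: int) -> float:
    if summary == "mean":
        return float(values.mean())
    if summary == "mode":
        counts, edges = np.histogram(values, bins=n_bins)
        k = int(np.argmax(counts))
        return float((edges[k] + edges[k + 1]) / 2.0)
    raise ValueError(f"summary must be 'mean' or 'mode', got {summary!r}")


def compute_threshold(
    vol: CTVolume, rois: RoiPair, summary: str = "mean", n_bins: int = 64
) -> ThresholdResult:
    """Per-specimen midpoint threshold from ROI contrast.

    alpha summarizes the otolith ROI and beta the tissue ROI (arithmetic mean
    by default, histogram mode optionally); the segmentation threshold is
    (alpha + beta)/2 and the edge band lower bound is 0.9 of it. Raises if
    the contrast is absent or inverted.
    """
    alpha = _summarize(vol.voxels[rois.otolith_roi], summary, n_bins)
    beta = _summarize(vol.voxels[rois.tissue_roi], summary, n_bins)
    return ThresholdResult(alpha=alpha, beta=beta)


def segment_otolith(
    vol: CTVolume, roi: np.ndarray, threshold: float, keep_largest: bool = False
) -> np.ndarray:
    """Supra-threshold segmentation within a ROI.

    mask = {v in roi : CT(v) >= threshold}; with ``keep_largest`` the mask is
    reduced to its largest 26-connected component. An empty result is
    returned with a warning, not an error.
    """
    roi = np.asarray(roi, dtype=bool)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask = roi & (vol.voxels >= threshold)
    if not mask.any():
        warnings.warn(f"segmentation at threshold {threshold} is empty", stacklevel=2)
        return mask
    if keep_largest:
        labels, n = ndimage.label(mask, structure=_STRUCT_26)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def quantify(vol: CTVolume, seg: np.ndarray, meta: VolumeMeta | None = None) -> MorphometryResult:
    """Volume (μm³) and mean CT number of a segmented otolith.

    The mean is taken over the raw CT values of the segmented voxels, so for
    a segmentation produced at threshold T it is >= T by construction. An
    empty mask yields volume 0 and a missing (NaN) mean.
    """
    meta = meta or vol.meta
    seg = np.asarray(seg, dtype=bool)
    if seg.shape != vol.voxels.shape:
        raise ValueError("segmentation mask must be on the volume's grid")
    n = int(seg.sum())
    mean_ct = float(vol.voxels[seg].mean()) if n else float("nan")
    return MorphometryResult(
        volume_voxels=n,
        volume_um3=n * meta.voxel_volume_um3,
        mean_ct=mean_ct,
        segmented_mask=seg,
    )


def striola_edge_volume(
    vol: CTVolume, roi: np.ndarray, thr: ThresholdResult, keep_largest: bool = False
) -> EdgeVolumeResult:
    """Volume of the striola edge band.

    The edge set is the region newly detected when the threshold is lowered
    to 90%: segment_otolith at 0.9 T minus segment_otolith at T, with the
    same keep_largest policy in both segmentations.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty sub-segmentations are fine here
        wide = segment_otolith(vol, roi, thr.edge_lower, keep_largest)
        core = segment_otolith(vol, roi, thr.threshold, keep_largest)
    edge = wide & ~core
    n = int(edge.sum())
    return EdgeVolumeResult(
        edge_voxels=n,
        edge_volume_um3=n * vol.meta.voxel_volume_um3,
        edge_mask=edge,
    )


def slice_areas(seg: np.ndarray, meta: VolumeMeta, axis: str = "z") -> pd.DataFrame:
    """Per-slice cross-sectional areas (μm²) of a segmentation.

    Useful for cross-validating μCT segmentations against serial tissue
    sections cut at the same thickness. The table has one row per slice
    along ``axis`` (z, y or x), area = in-slice voxel count x in-plane pixel
    area; summing area x slice thickness recovers the total volume.
    """
    seg = np.asarray(seg, dtype=bool)
    ax = _AXES[axis]
    other = [i for i in range(3) if i != ax]
    pixel_area = meta.spacing_um[other[0]] * meta.spacing_um[other[1]]
    counts = seg.sum(axis=tuple(other))
    return pd.DataFrame(
        {
            "slice": np.arange(seg.shape[ax]),
            "area_um2": counts * pixel_area,
        }
    )
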