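"""Core containers shared across the otolith analysis pipeline.

Conventions: volumes are (z, y, x) arrays of CT numbers; voxel spacing is in
micrometres; physical coordinate = index * spacing + origin; traces are
uniformly sampled with times in seconds; angles are in degrees.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class OtokitError(Exception):
    """Base class for all otokit errors."""


class FormatError(OtokitError):
    """Malformed external input (file contents, table layout, time base)."""


class ParameterError(OtokitError, ValueError):
    """Invalid parameter combination."""


class DegenerateInputError(OtokitError, ValueError):
    """Input that makes the requested quantity undefined."""


class ConfigurationError(OtokitError):
    """Invalid or incomplete pipeline configuration."""


@dataclass(frozen=True)
class VolumeMeta:
    """Voxel-grid metadata for a CT volume.

    spacing_um is (z, y, x) voxel size in micrometres; CT numbers themselves
    are unitless attenuation values.
    """

    spacing_um: tuple[float, float, float] = (10.0, 10.0, 10.0)
    ct_units: str = "CT number"
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ParameterError(f"spacing_um must be 3 positive values, got {self.spacing_um}")
        object.__setattr__(self, "spacing_um", tuple(float(s) for s in self.spacing_um))
        object.__setattr__(self, "origin_um", tuple(float(s) for s in self.origin_um))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))


@dataclass
class CTVolume:
    """A 3D scalar field of CT numbers on a regular grid."""

    voxels: np.ndarray
    meta: VolumeMeta = field(default_factory=VolumeMeta)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"CT volume must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("CT volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class RoiPair:
    """Otolith ROI and surrounding-tissue ROI on the same voxel grid.

    The otolith ROI encloses the high-attenuation otoconial mass; the tissue
    ROI samples endolymph/perilymph background. They must be disjoint and
    non-empty so that the contrast summaries alpha and beta are well defined.
    """

    otolith_roi: np.ndarray
    tissue_roi: np.ndarray

    def __post_init__(self) -> None:
        self.otolith_roi = np.asarray(self.otolith_roi).astype(bool)
        self.tissue_roi = np.asarray(self.tissue_roi).astype(bool)
        if self.otolith_roi.shape != self.tissue_roi.shape:
            raise FormatError("ROI masks must share one voxel grid")
        if not self.otolith_roi.any():
            raise DegenerateInputError("otolith ROI is empty")
        if not self.tissue_roi.any():
            raise DegenerateInputError("tissue ROI is empty")
        if np.any(self.otolith_roi & self.tissue_roi):
            raise FormatError("otolith and tissue ROIs overlap")


@dataclass(frozen=True)
class ThresholdResult:
    """Midpoint segmentation threshold derived from ROI contrast.

    alpha summarizes CT numbers inside the otolith ROI, beta inside the
    tissue ROI; the otolith is segmented at T = (alpha + beta) / 2 and the
    striola edge band is [0.9 T, T).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.beta < self.alpha:
            raise DegenerateInputError(
                f"no ROI contrast: alpha={self.alpha} must exceed beta={self.beta} "
                "(ROIs swapped or degenerate?)"
            )

    @property
    def threshold(self) -> float:
        return (self.alpha + self.beta) / 2.0

    @property
    def edge_lower(self) -> float:
        return 0.9 * self.threshold


@dataclass
class MorphometryResult:
    """Volume and density of a segmented otolith."""

    volume_voxels: int
    volume_um3: float
    mean_ct: float  # NaN when the segmentation is empty
    segmented_mask: np.ndarray


@dataclass
class EdgeVolumeResult:
    """Volume of the striola edge band (CT in [0.9 T, T))."""

    edge_voxels: int
    edge_volume_um3: float
    edge_mask: np.ndarray


@dataclass
class SledTrace:
    """Uniformly sampled sled kinematics.

    position_mm is along the rail (positive toward the far end); velocity and
    acceleration are either analytic (generator) or derived from position
    (``derive_kinematics``).
    """

    t: np.ndarray
    position_mm: np.ndarray
    velocity_mm_s: np.ndarray
    acceleration_mm_s2: np.ndarray
    rate_hz: float
    orientation: str = "lateral"

    def __post_init__(self) -> None:
        n = len(self.position_mm)
        if not (len(self.t) == len(self.velocity_mm_s) == len(self.acceleration_mm_s2) == n):
            raise FormatError("sled trace channels must have equal length")


@dataclass
class EyeTrace:
    """Axis-angle eye position (degrees) relative to rest.

    X/Y/Z components reflect mainly the torsional, vertical and horizontal
    rotations; only the vertical (Y) component enters the function index.
    """

    t: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    z_deg: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.x_deg) == len(self.y_deg) == len(self.z_deg) == n):
            raise FormatError("eye trace channels must have equal length")


@dataclass
class CycleSet:
    """Stimulation cycles (one round trip each) and end-dwell intervals.

    Each entry is a half-open (start, stop) sample-index window; cycles are
    ordered and non-overlapping.
    """

    cycles: list[tuple[int, int]]
    dwells: list[tuple[int, int]]


@dataclass
class IndexResult:
    """Otolith function index: per-cycle half peak-to-peak vertical
    excursions and the mean of the three largest."""

    per_cycle: list[float]
    index: float
    baseline_deg: float


@dataclass
class LayerTrace:
    """Traced 2D point sets (μm) for the otoconial layer angle."""

    les_points: np.ndarray  # (n, 2)
    base_points: np.ndarray  # (m, 2)

    def __post_init__(self) -> None:
        self.les_points = np.atleast_2d(np.asarray(self.les_points, dtype=float))
        self.base_points = np.atleast_2d(np.asarray(self.base_points, dtype=float))
        for name, pts in (("les", self.les_points), ("base", self.base_points)):
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
                raise DegenerateInputError(f"{name} point set must be (n>=2, 2), got {pts.shape}")


@dataclass(frozen=True)
class AngleResult:
    """Otoconial layer angle in [0, 90] degrees with per-line fit residuals."""

    angle_deg: float
    les_rms_um: float
    base_rms_um: float
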