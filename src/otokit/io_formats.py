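"""Readers and writers for the pipeline's external representations.

Volumes travel as NIfTI (.nii/.nii.gz) or multipage TIFF with voxel arrays
in (z, y, x) order; masks are 0/1 volumes on the same grid. Traces, traced
point sets and cohort tables are one-header-row UTF-8 CSV with '.' decimals.
Voxel spacing is carried in the NIfTI header (zooms, interpreted as μm) or a
JSON sidecar for TIFF; when absent it defaults to 10 μm isotropic with a
warning.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import CTVolume, EyeTrace, FormatError, LayerTrace, VolumeMeta

DEFAULT_SPACING_UM = (10.0, 10.0, 10.0)

#: tolerance (s) for declaring a trace's time base uniform
TIME_UNIFORMITY_TOL_S = 1e-6


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_volume(path: str | Path) -> tuple[CTVolume, VolumeMeta]:
    """Read a CT volume (NIfTI file, multipage TIFF, or directory of TIFFs).

    Returns the volume with (z, y, x) voxel order and its grid metadata.
    NIfTI zooms are interpreted as μm; TIFFs look for a ``<file>.meta.json``
    sidecar with ``spacing_um``. Missing spacing falls back to 10 μm
    isotropic with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        pages = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
        if not pages:
            raise FileNotFoundError(f"no TIFF slices in directory {path}")
        data = np.stack([tifffile.imread(p) for p in pages], axis=0)
        meta = _tiff_meta(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        meta = _tiff_meta(path)
    elif path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        # stored (x, y, z); internal convention is (z, y, x)
        data = np.asarray(img.dataobj).transpose(2, 1, 0)
        zooms = img.header.get_zooms()[:3]
        if all(abs(z - 1.0) < 1e-12 for z in zooms):
            warnings.warn(
                f"{path}: no voxel spacing in header; defaulting to 10 μm isotropic",
                stacklevel=2,
            )
            spacing = DEFAULT_SPACING_UM
        else:
            spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        meta = VolumeMeta(spacing_um=spacing)
    else:
        raise FormatError(f"unsupported volume format: {path}")
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D data, got shape {data.shape}")
    vol = CTVolume(np.asarray(data, dtype=float), meta)
    return vol, meta


def _tiff_meta(path: Path) -> VolumeMeta:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        return VolumeMeta(
            spacing_um=tuple(info["spacing_um"]),
            origin_um=tuple(info.get("origin_um", (0.0, 0.0, 0.0))),
        )
    warnings.warn(
        f"{path}: no spacing sidecar ({sidecar.name}); defaulting to 10 μm isotropic",
        stacklevel=2,
    )
    return VolumeMeta(spacing_um=DEFAULT_SPACING_UM)


def write_volume(path: str | Path, vol: CTVolume) -> Path:
    """Write a volume (and its spacing) as NIfTI or multipage TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith((".nii", ".nii.gz")):
        sz, sy, sx = vol.meta.spacing_um
        affine = np.diag([sx, sy, sz, 1.0])
        img = nib.Nifti1Image(vol.voxels.transpose(2, 1, 0), affine)
        img.header.set_zooms((sx, sy, sz))
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, vol.voxels.astype(np.float32))
        _sidecar_path(path).write_text(
            json.dumps(
                {"spacing_um": list(vol.meta.spacing_um), "origin_um": list(vol.meta.origin_um)}
            )
        )
    else:
        raise FormatError(f"unsupported volume format: {path}")
    return path


def write_mask(path: str | Path, mask: np.ndarray, meta: VolumeMeta) -> Path:
    """Write a binary mask as a 0/1 volume."""
    return write_volume(path, CTVolume(np.asarray(mask, dtype=np.uint8).astype(float), meta))


def read_mask(path: str | Path) -> np.ndarray:
    vol, _ = read_volume(path)
    return vol.voxels > 0.5


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def read_trace(path: str | Path, time_column: str = "t_s") -> pd.DataFrame:
    """Read a uniformly sampled trace table from CSV.

    Requires a header row with a time column plus at least one channel;
    validates time uniformity to within 1 μs and attaches the inferred
    sampling rate as ``df.attrs['rate_hz']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trace: {path}")
    df = pd.read_csv(path)
    if time_column not in df.columns:
        raise FormatError(f"{path}: missing time column {time_column!r}")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least one channel beside {time_column!r}")
    if len(df) < 2:
        raise FormatError(f"{path}: sampling rate undefined with {len(df)} row(s)")
    t = df[time_column].to_numpy(dtype=float)
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    step = float(np.median(dts))
    if np.max(np.abs(dts - step)) > TIME_UNIFORMITY_TOL_S:
        raise FormatError(
            f"{path}: non-uniform time base (max deviation "
            f"{np.max(np.abs(dts - step)):.3g} s exceeds {TIME_UNIFORMITY_TOL_S} s)"
        )
    df.attrs["rate_hz"] = 1.0 / step
    return df


def write_trace(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def sled_trace_frame(sled) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_s": sled.t,
            "position_mm": sled.position_mm,
            "velocity_mm_s": sled.velocity_mm_s,
            "acceleration_mm_s2": sled.acceleration_mm_s2,
        }
    )


def eye_trace_frame(eye: EyeTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_s": eye.t,
            "eye_x_deg": eye.x_deg,
            "eye_y_deg": eye.y_deg,
            "eye_z_deg": eye.z_deg,
        }
    )


def read_eye_trace(path: str | Path) -> EyeTrace:
    df = read_trace(path)
    for col in ("eye_x_deg", "eye_y_deg", "eye_z_deg"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing eye channel {col!r}")
    return EyeTrace(
        t=df["t_s"].to_numpy(float),
        x_deg=df["eye_x_deg"].to_numpy(float),
        y_deg=df["eye_y_deg"].to_numpy(float),
        z_deg=df["eye_z_deg"].to_numpy(float),
        rate_hz=df.attrs["rate_hz"],
    )


# ---------------------------------------------------------------------------
# Point sets and cohort tables
# ---------------------------------------------------------------------------

def read_layer_points(path: str | Path) -> LayerTrace:
    """Read a traced layer point set: CSV columns set_label, x_um, y_um."""
    df = pd.read_csv(path)
    for col in ("set_label", "x_um", "y_um"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    sets = {}
    for label in ("les", "base"):
        pts = df[df["set_label"] == label][["x_um", "y_um"]].to_numpy(float)
        if len(pts) < 2:
            raise FormatError(f"{path}: point set {label!r} needs >= 2 points")
        sets[label] = pts
    return LayerTrace(les_points=sets["les"], base_points=sets["base"])


def write_layer_points(path: str | Path, les: np.ndarray, base: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame({"set_label": label, "x_um": pts[:, 0], "y_um": pts[:, 1]})
        for label, pts in (("les", np.asarray(les)), ("base", np.asarray(base)))
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


COHORT_COLUMNS = ["mouse_id", "ear", "age_group", "sex", "measurement", "value"]


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cohort table missing columns {missing}")
    return df


def write_cohort(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Read a pipeline config (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
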