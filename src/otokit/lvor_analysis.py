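"""Linear vestibulo-ocular reflex (LVOR) analysis.

From sled marker positions and left-eye axis-angle traces recorded during
reciprocating linear translation, this module derives sled kinematics,
segments the recording into stimulation cycles (one round trip each) using
the end dwells, and computes the otolith function index: per cycle, half the
peak-to-peak excursion of the vertical (Y) eye component relative to rest,
aggregated as the mean of the three largest of the five cycles. The index
drops when the otoconial mass or its central pathway is impaired.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import CycleSet, EyeTrace, IndexResult, ParameterError, SledTrace


class SegmentationError(ParameterError):
    """The sled trace does not contain the expected dwell/cycle structure."""


def derive_kinematics(
    position_mm: np.ndarray,
    rate_hz: float,
    smooth_window: int = 5,
    orientation: str = "lateral",
) -> SledTrace:
    """Velocity and acceleration from a sampled sled position.

    The position is smoothed with a zero-phase moving average of odd length
    ``smooth_window`` (1 = none), then differentiated twice with centered
    finite differences (one-sided at the endpoints). Centered differences
    are exact for locally quadratic motion, i.e. within the constant-
    acceleration phases of a trapezoidal profile.
    """
    position_mm = np.asarray(position_mm, dtype=float)
    if position_mm.ndim != 1 or len(position_mm) < 3:
        raise ParameterError("need a 1D position series with at least 3 samples")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ParameterError("smooth_window must be a positive odd integer")
    smoothed = position_mm
    if smooth_window > 1:
        smoothed = ndimage.uniform_filter1d(position_mm, smooth_window, mode="nearest")
    dt = 1.0 / rate_hz
    velocity = np.gradient(smoothed, dt)
    acceleration = np.gradient(velocity, dt)
    t = np.arange(len(position_mm)) * dt
    return SledTrace(t, position_mm, velocity, acceleration, rate_hz, orientation)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index windows of maximal True runs."""
    labels, n = ndimage.label(mask)
    out = []
    for sl in ndimage.find_objects(labels):
        out.append((sl[0].start, sl[0].stop))
    return out


def segment_cycles(
    sled: SledTrace, v_dwell_mm_s: float = 20.0, min_dwell_s: float = 0.25
) -> CycleSet:
    """Detect end dwells and carve the trace into round-trip cycles.

    Dwells are maximal runs with |v| <= v_dwell_mm_s lasting at least
    ``min_dwell_s``. Dwells at even positions (0, 2, 4, ...) are visits to
    the home end, so one cycle runs from the start of motion after dwell 2k
    up to the start of motion after dwell 2k+2, covering one full round trip
    including the far-end dwell. Only complete cycles are returned.
    """
    min_len = int(round(min_dwell_s * sled.rate_hz))
    runs = _runs(np.abs(sled.velocity_mm_s) <= v_dwell_mm_s)
    dwells = [(a, b) for a, b in runs if (b - a) >= min_len]
    cycles = []
    for k in range(0, len(dwells) - 2, 2):
        cycles.append((dwells[k][1], dwells[k + 2][1]))
    if not cycles:
        raise SegmentationError(
            f"found {len(dwells)} qualifying dwells; need at least 3 for one "
            "complete round-trip cycle"
        )
    return CycleSet(cycles=cycles, dwells=dwells)


def cycle_index(eye: EyeTrace, window: tuple[int, int], baseline_deg: float = 0.0) -> float:
    """Half the peak-to-peak vertical excursion within one cycle window.

    (max(y - baseline) - min(y - baseline)) / 2 over the half-open window;
    invariant to additive offsets and always >= 0.
    """
    start, stop = window
    y = eye.y_deg[start:stop]
    if y.size == 0:
        raise ParameterError(f"empty cycle window {window}")
    y = y - baseline_deg
    return float((y.max() - y.min()) / 2.0)


def otolith_function_index(
    eye: EyeTrace,
    cycles: CycleSet,
    exclude_dwells: bool = False,
    smooth_window: int = 41,
) -> IndexResult:
    """Otolith function index over a set of stimulation cycles.

    The vertical component is first smoothed with a zero-phase moving
    average of odd length ``smooth_window`` (1 = none; default ~0.17 s at
    240 Hz). Peak-picking on a noisy sampled trace otherwise inflates the
    half peak-to-peak range by the expected extreme of the noise; the
    acceleration plateaus of the trapezoidal stimulus are much longer than
    the window, so the true excursion is preserved. The resting baseline is
    the mean vertical component over all dwell samples; the index is the
    mean of the three largest per-cycle values. With ``exclude_dwells`` the
    max/min search within each cycle skips the detected dwell samples.
    """
    if len(cycles.cycles) < 3:
        raise ParameterError(
            f"need at least 3 cycles to average the top three, got {len(cycles.cycles)}"
        )
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ParameterError("smooth_window must be a positive odd integer")
    y_all = eye.y_deg
    if smooth_window > 1:
        y_all = ndimage.uniform_filter1d(y_all, smooth_window, mode="nearest")
    dwell_mask = np.zeros(len(y_all), dtype=bool)
    for a, b in cycles.dwells:
        dwell_mask[a:b] = True
    if not dwell_mask.any():
        raise ParameterError("cycle set contains no dwell samples for the baseline")
    baseline = float(y_all[dwell_mask].mean())

    per_cycle = []
    for start, stop in cycles.cycles:
        y = y_all[start:stop]
        if exclude_dwells:
            y = y[~dwell_mask[start:stop]]
            if y.size == 0:
                raise ParameterError(f"cycle {start, stop} has no non-dwell samples")
        if y.size == 0:
            raise ParameterError(f"empty cycle window {(start, stop)}")
        y = y - baseline
        per_cycle.append(float((y.max() - y.min()) / 2.0))
    top3 = sorted(per_cycle, reverse=True)[:3]
    return IndexResult(per_cycle=per_cycle, index=float(np.mean(top3)), baseline_deg=baseline)


#: sled orientation -> the otolith organ its acceleration direction stimulates
ORGAN_BY_ORIENTATION = {"lateral": "utricle", "longitudinal": "saccule"}

_ACCEL_LEVELS = {"1.3G": "1.3G", "0.7G": "0.7G", "1.3": "1.3G", "0.7": "0.7G"}


def orient_run(orientation: str, accel_level: str | float) -> dict:
    """Label an index measurement with the organ and stimulus it probes.

    Lateral (interaural) acceleration stimulates mainly the utricle,
    longitudinal (cephalonasal) acceleration mainly the saccule.
    """
    organ = ORGAN_BY_ORIENTATION.get(orientation)
    if organ is None:
        raise ParameterError(f"unknown orientation {orientation!r}")
    key = f"{accel_level:.1f}" if isinstance(accel_level, float) else str(accel_level)
    level = _ACCEL_LEVELS.get(key)
    if level is None:
        raise ParameterError(f"unknown acceleration level {accel_level!r}")
    return {
        "orientation": orientation,
        "accel_level": level,
        "organ": organ,
        "tag": f"{organ}_{level}",
    }
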