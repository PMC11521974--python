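"""Otoconial layer angle from traced electron-micrograph point sets.

The layer angle — between the lateral-extrastriola (LES) otoconial surface
and the basal plane of the striola — is a morphological marker of striola
integrity: 90° means the two layers are sharply distinguishable, 0° means
the boundary has collapsed. Each traced point set is reduced to a line by
total least squares (orthogonal regression), so the result does not depend
on the axis orientation of the tracing; the angle between the two fitted
directions is folded into [0, 90] via the absolute cosine.
"""
from __future__ import annotations

import math

import numpy as np

from .types import AngleResult, DegenerateInputError, LayerTrace


def fit_direction(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Total-least-squares line direction of a 2D point set.

    Returns a unit direction (sign-normalized so its first nonzero component
    is positive) and the rms orthogonal residual in the input units. Raises
    on fewer than two distinct points, for which no direction exists.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DegenerateInputError(f"need an (n>=2, 2) point set, got shape {pts.shape}")
    centered = pts - pts.mean(axis=0)
    if not centered.any():
        raise DegenerateInputError("all points coincide; direction undefined")
    # principal axis of the scatter = TLS direction
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    nz = np.flatnonzero(np.abs(direction) > 1e-12)
    if direction[nz[0]] < 0:
        direction = -direction
    residuals = centered @ vt[1]
    rms = float(np.sqrt(np.mean(residuals**2)))
    return direction, rms


def layer_angle(trace: LayerTrace) -> AngleResult:
    """Angle (degrees, in [0, 90]) between the LES and basal-plane lines."""
    d_les, rms_les = fit_direction(trace.les_points)
    d_base, rms_base = fit_direction(trace.base_points)
    # atan2 of |cross| and |dot| stays well-conditioned for near-parallel and
    # near-perpendicular lines, unlike arccos of the dot product
    dot = abs(float(d_les @ d_base))
    cross = abs(float(d_les[0] * d_base[1] - d_les[1] * d_base[0]))
    return AngleResult(
        angle_deg=math.degrees(math.atan2(cross, dot)),
        les_rms_um=rms_les,
        base_rms_um=rms_base,
    )
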