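"""Synthetic data generators for every stage of the otolith pipeline.

The generators emulate the statistical structure of the real measurements:

* μCT phantoms — an ellipsoidal otoconial mass of high CT number over a low
  background, optionally carved by a planar low-density striola channel, with
  Gaussian boundary blur (the aging knob for the edge statistic) and additive
  voxel noise;
* sled motion — trapezoidal-velocity round trips with end dwells, at the two
  stimulus levels used for linear-VOR testing (1.3 G / 3.25 m/s and
  0.7 G / 3.06 m/s over 1.8 m, five reciprocations, 240 Hz);
* eye traces — a linear, lag-free vertical response proportional to sled
  acceleration, plus drift and noise;
* otoconial-layer tracings — two jittered 2D point sets meeting at a known
  angle;
* cohorts — additive age x sex effects with homoscedastic Gaussian residuals,
  the design assumed by the downstream two-way ANOVA.

Every generator is deterministic under a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import CTVolume, ParameterError, RoiPair, SledTrace, EyeTrace, VolumeMeta

#: standard gravity used to convert between G and m/s² throughout the package
G_M_S2 = 9.81


# ---------------------------------------------------------------------------
# CT phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the ellipsoidal otolith phantom.

    The otoconial mass is an ellipsoid of CT number ``mu_otolith`` centred in
    a background of ``mu_background``. A striola is modelled as a planar
    channel of width ``striola_width_um`` through the ellipsoid centre,
    normal to the longest semi-axis, in which the density is reduced by
    ``striola_depth`` of the otolith/background contrast. The noiseless field
    is smoothed with a Gaussian of physical scale ``edge_blur_um`` (0 = sharp
    boundary) before i.i.d. Gaussian noise of sd ``noise_sd`` is added.

    ROIs mimic manual placement: the otolith ROI is the ellipsoid dilated by
    ``roi_margin_um``; the tissue ROI is a background shell between
    ``tissue_shell_um`` distances from the ellipsoid surface.
    """

    grid: tuple[int, int, int] = (72, 72, 72)
    spacing_um: tuple[float, float, float] = (5.0, 5.0, 5.0)
    semi_axes_um: tuple[float, float, float] = (100.0, 60.0, 40.0)
    mu_otolith: float = 200.0
    mu_background: float = 50.0
    striola_width_um: float = 0.0
    striola_depth: float = 0.0
    edge_blur_um: float = 0.0
    noise_sd: float = 5.0
    roi_margin_um: float = 5.0
    tissue_shell_um: tuple[float, float] = (30.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_otolith <= self.mu_background:
            raise ParameterError("mu_otolith must exceed mu_background")
        if not 0.0 <= self.striola_depth <= 1.0:
            raise ParameterError("striola_depth must lie in [0, 1]")
        if self.striola_width_um < 0 or self.edge_blur_um < 0 or self.noise_sd < 0:
            raise ParameterError("widths, blur scale and noise sd must be >= 0")
        for n, sp, ax in zip(self.grid, self.spacing_um, self.semi_axes_um):
            if ax >= (n - 1) * sp / 2.0:
                raise ParameterError(
                    f"ellipsoid semi-axis {ax} μm does not fit inside a grid of "
                    f"{n} voxels at {sp} μm spacing"
                )


def striola_preset(**overrides) -> PhantomParams:
    """Phantom preset with a visible low-density striola channel.

    Depth 0.9 leaves only a thin residue of otoconial density in the
    channel, well below the edge band: the channel shows up as a central gap
    in the supra-threshold model, and the edge band [0.9 T, T) is populated
    only by the blurred striola/extrastriola and outer boundaries — the
    mechanism the edge-volume statistic measures.
    """
    defaults = dict(striola_width_um=30.0, striola_depth=0.9)
    defaults.update(overrides)
    return PhantomParams(**defaults)


def edge_study_preset(**overrides) -> PhantomParams:
    """Finer-grid striola phantom for dual-threshold edge-volume studies.

    2.5 μm voxels resolve boundary blur scales down to 2 μm, and the larger
    otoconial mass keeps its plateau intact up to 16 μm blur, so the edge
    band volume responds monotonically over the whole blur range of
    interest. The 60 μm channel is a striola-scale gap in the mass.
    """
    defaults = dict(
        grid=(176, 136, 104),
        spacing_um=(2.5, 2.5, 2.5),
        semi_axes_um=(150.0, 100.0, 60.0),
        striola_width_um=60.0,
        striola_depth=0.9,
    )
    defaults.update(overrides)
    return PhantomParams(**defaults)


@dataclass
class GroundTruth:
    """Pre-blur, pre-noise truth recorded by :func:`gen_ct_phantom`."""

    otolith_mask: np.ndarray
    striola_mask: np.ndarray
    volume_um3: float
    mean_ct: float


def _physical_grids(grid, spacing):
    return np.meshgrid(
        *(np.arange(n) * sp for n, sp in zip(grid, spacing)), indexing="ij"
    )


def gen_ct_phantom(p: PhantomParams) -> tuple[CTVolume, RoiPair, GroundTruth]:
    """Generate a μCT otolith phantom with ROI pair and ground truth."""
    spacing = tuple(float(s) for s in p.spacing_um)
    center = tuple((n - 1) * sp / 2.0 for n, sp in zip(p.grid, spacing))
    zz, yy, xx = _physical_grids(p.grid, spacing)
    coords = (zz, yy, xx)

    r2 = sum(((c - c0) / ax) ** 2 for c, c0, ax in zip(coords, center, p.semi_axes_um))
    ellipsoid = r2 <= 1.0

    contrast = p.mu_otolith - p.mu_background
    striola = np.zeros_like(ellipsoid)
    if p.striola_width_um > 0 and p.striola_depth > 0:
        axis = int(np.argmax(p.semi_axes_um))
        channel = np.abs(coords[axis] - center[axis]) <= p.striola_width_um / 2.0
        striola = ellipsoid & channel

    field = np.full(p.grid, p.mu_background, dtype=float)
    field[ellipsoid] = p.mu_otolith
    field[striola] -= p.striola_depth * contrast

    truth = GroundTruth(
        otolith_mask=ellipsoid.copy(),
        striola_mask=striola.copy(),
        volume_um3=float(ellipsoid.sum()) * float(np.prod(spacing)),
        mean_ct=float(field[ellipsoid].mean()),
    )

    if p.edge_blur_um > 0:
        field = ndimage.gaussian_filter(field, sigma=[p.edge_blur_um / s for s in spacing])
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        field = field + rng.normal(0.0, p.noise_sd, size=field.shape)

    # distance (μm) from the ellipsoid surface, 0 inside
    dist = ndimage.distance_transform_edt(~ellipsoid, sampling=spacing)
    otolith_roi = dist <= p.roi_margin_um
    inner, outer = p.tissue_shell_um
    if not inner < outer:
        raise ParameterError("tissue_shell_um must be (inner, outer) with inner < outer")
    if inner <= p.roi_margin_um:
        raise ParameterError("tissue shell must start beyond the otolith ROI margin")
    tissue_roi = (dist >= inner) & (dist <= outer)

    vol = CTVolume(field, VolumeMeta(spacing_um=spacing))
    return vol, RoiPair(otolith_roi, tissue_roi), truth


# ---------------------------------------------------------------------------
# Sled motion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SledParams:
    """Trapezoidal sled motion profile.

    Each one-way leg covers ``distance_m`` with |a| <= a_max and |v| <= v_max,
    both bounds attained (accelerate at a_max, cruise at v_max, decelerate at
    a_max); the sled dwells for ``dwell_s`` at each end and reciprocates
    ``n_round_trips`` times.
    """

    a_max: float
    v_max: float
    distance_m: float = 1.8
    dwell_s: float = 0.3
    n_round_trips: int = 5
    rate_hz: float = 240.0
    orientation: str = "lateral"

    def __post_init__(self) -> None:
        for name in ("a_max", "v_max", "distance_m", "dwell_s", "rate_hz"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.n_round_trips < 1:
            raise ParameterError("n_round_trips must be >= 1")
        if self.orientation not in ("lateral", "longitudinal"):
            raise ParameterError(f"unknown orientation {self.orientation!r}")
        if self.v_max**2 / self.a_max > self.distance_m * (1 + 1e-12):
            raise ParameterError(
                f"infeasible trapezoid: v_max²/a_max = {self.v_max**2 / self.a_max:.4f} m "
                f"exceeds travel distance {self.distance_m} m (v_max never attained)"
            )

    @classmethod
    def level_1_3g(cls, **kw) -> "SledParams":
        """High stimulus level: 1.3 G peak acceleration, 3.25 m/s peak speed."""
        return cls(a_max=1.3 * G_M_S2, v_max=3.25, **kw)

    @classmethod
    def level_0_7g(cls, **kw) -> "SledParams":
        """Low stimulus level: 0.7 G peak acceleration, 3.06 m/s peak speed."""
        return cls(a_max=0.7 * G_M_S2, v_max=3.06, **kw)


def _leg_kinematics(t: np.ndarray, a: float, v: float, d: float):
    """Closed-form trapezoidal leg: position/velocity/acceleration at times t."""
    ta = v / a
    tc = max((d - v * v / a) / v, 0.0)
    total = 2 * ta + tc
    t = np.clip(t, 0.0, total)
    s = np.empty_like(t)
    vel = np.empty_like(t)
    acc = np.empty_like(t)

    accel = t < ta
    cruise = (t >= ta) & (t < ta + tc)
    decel = t >= ta + tc

    s[accel] = 0.5 * a * t[accel] ** 2
    vel[accel] = a * t[accel]
    acc[accel] = a

    s[cruise] = 0.5 * a * ta**2 + v * (t[cruise] - ta)
    vel[cruise] = v
    acc[cruise] = 0.0

    tau = t[decel] - (ta + tc)
    s[decel] = 0.5 * a * ta**2 + v * tc + v * tau - 0.5 * a * tau**2
    vel[decel] = v - a * tau
    acc[decel] = -a
    return s, vel, acc, total


def gen_sled_trace(p: SledParams) -> SledTrace:
    """Sample the reciprocating sled motion at ``rate_hz``.

    Dwells contribute exactly round(dwell_s * rate_hz) zero-velocity samples;
    legs are sampled on the 1/rate grid strictly inside the motion interval,
    so the sub-sample remainder of each leg (< one sample's travel) is
    absorbed at the leg/dwell junction.
    """
    dt = 1.0 / p.rate_hz
    n_dwell = int(round(p.dwell_s * p.rate_hz))
    leg_t = None  # filled below once total leg duration is known

    pos_parts: list[np.ndarray] = []
    vel_parts: list[np.ndarray] = []
    acc_parts: list[np.ndarray] = []

    def dwell(position_m: float) -> None:
        pos_parts.append(np.full(n_dwell, position_m))
        vel_parts.append(np.zeros(n_dwell))
        acc_parts.append(np.zeros(n_dwell))

    def leg(start_m: float, direction: float) -> None:
        s, v, a, _ = _leg_kinematics(leg_t, p.a_max, p.v_max, p.distance_m)
        pos_parts.append(start_m + direction * s)
        vel_parts.append(direction * v)
        acc_parts.append(direction * a)

    _, _, _, total = _leg_kinematics(np.zeros(1), p.a_max, p.v_max, p.distance_m)
    n_leg = int(math.floor(total * p.rate_hz + 1e-9))
    leg_t = np.arange(1, n_leg + 1) * dt

    dwell(0.0)
    for _ in range(p.n_round_trips):
        leg(0.0, +1.0)
        dwell(p.distance_m)
        leg(p.distance_m, -1.0)
        dwell(0.0)

    pos = np.concatenate(pos_parts) * 1000.0
    vel = np.concatenate(vel_parts) * 1000.0
    acc = np.concatenate(acc_parts) * 1000.0
    t = np.arange(len(pos)) * dt
    return SledTrace(t, pos, vel, acc, p.rate_hz, orientation=p.orientation)


# ---------------------------------------------------------------------------
# Eye response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeModelParams:
    """Linear vertical eye response to linear acceleration.

    The vertical (Y) axis-angle component follows
    ``gain_deg_per_g * a(t)/g + drift_deg_per_s * t + noise``; torsional (X)
    and horizontal (Z) components are noise-only. ``lag_s`` optionally delays
    the response by an integer number of samples.
    """

    gain_deg_per_g: float = 2.0
    noise_sd_deg: float = 0.05
    drift_deg_per_s: float = 0.0
    lag_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_deg < 0:
            raise ParameterError("noise_sd_deg must be >= 0")
        if self.lag_s < 0:
            raise ParameterError("lag_s must be >= 0")


def gen_eye_trace(sled: SledTrace, p: EyeModelParams) -> EyeTrace:
    """Simulate a left-eye axis-angle trace driven by sled acceleration.

    Sign convention: positive sled acceleration produces a positive vertical
    shift of the left eye.
    """
    a_g = sled.acceleration_mm_s2 / (1000.0 * G_M_S2)
    lag_n = int(round(p.lag_s * sled.rate_hz))
    if lag_n:
        a_g = np.concatenate([np.zeros(lag_n), a_g[:-lag_n]])
    rng = np.random.default_rng(p.seed)
    n = len(a_g)
    y = p.gain_deg_per_g * a_g + p.drift_deg_per_s * sled.t
    if p.noise_sd_deg > 0:
        y = y + rng.normal(0.0, p.noise_sd_deg, n)
        x = rng.normal(0.0, p.noise_sd_deg, n)
        z = rng.normal(0.0, p.noise_sd_deg, n)
    else:
        x = np.zeros(n)
        z = np.zeros(n)
    return EyeTrace(sled.t.copy(), x, y, z, sled.rate_hz)


# ---------------------------------------------------------------------------
# Layer tracings
# ---------------------------------------------------------------------------

def gen_layer_points(
    angle_deg: float,
    n_points: int,
    noise_um: float,
    seed: int,
    length_um: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two 2D point sets along lines meeting at ``angle_deg``.

    The basal-plane line runs along +x from the origin; the lateral
    extrastriola line leaves the origin at ``angle_deg``. Both are sampled at
    ``n_points`` evenly spaced positions over ``length_um`` with isotropic
    Gaussian jitter of sd ``noise_um``.
    """
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    if not 0.0 <= angle_deg <= 90.0:
        raise ParameterError("angle_deg must lie in [0, 90]")
    if noise_um < 0:
        raise ParameterError("noise_um must be >= 0")
    rng = np.random.default_rng(seed)
    ts = np.linspace(0.0, length_um, n_points)
    theta = math.radians(angle_deg)
    les_dir = np.array([math.cos(theta), math.sin(theta)])
    base_dir = np.array([1.0, 0.0])
    les = ts[:, None] * les_dir
    base = ts[:, None] * base_dir
    if noise_um > 0:
        les = les + rng.normal(0.0, noise_um, les.shape)
        base = base + rng.normal(0.0, noise_um, base.shape)
    return les, base


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

AGE_GROUPS = ("young", "old")
SEXES = ("female", "male")


@dataclass(frozen=True)
class MeasurementEffects:
    """Additive cell effects for one measurement in a 2x2 age x sex design.

    value = baseline + age_effect·1[old] + sex_effect·1[male]
            + interaction_effect·1[old & male] + N(0, residual_sd).
    """

    baseline: float
    age_effect: float = 0.0
    sex_effect: float = 0.0
    interaction_effect: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ParameterError("residual_sd must be > 0")

    def cell_mean(self, age_group: str, sex: str) -> float:
        old = age_group == "old"
        male = sex == "male"
        return (
            self.baseline
            + self.age_effect * old
            + self.sex_effect * male
            + self.interaction_effect * (old and male)
        )


@dataclass(frozen=True)
class CohortEffects:
    """Cohort design: per-cell sample size and per-measurement effects."""

    n_per_cell: int
    measurements: dict[str, MeasurementEffects] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ParameterError("n_per_cell must be >= 2")
        if not self.measurements:
            raise ParameterError("at least one measurement must be specified")


def default_cohort_effects(n_per_cell: int = 10, seed: int = 0) -> CohortEffects:
    """Cohort with the direction of effects seen in aging mice.

    Old ears show lower otolith density (CT number) and function index, a
    larger striola edge volume, and a smaller otoconial layer angle; males
    trend slightly below females on density and function.
    """
    return CohortEffects(
        n_per_cell=n_per_cell,
        measurements={
            "ct_number": MeasurementEffects(
                baseline=200.0, age_effect=-15.0, sex_effect=-5.0, residual_sd=10.0
            ),
            "edge_volume_um3": MeasurementEffects(
                baseline=2.0e4, age_effect=8.0e3, residual_sd=5.0e3
            ),
            "layer_angle_deg": MeasurementEffects(
                baseline=60.0, age_effect=-15.0, residual_sd=8.0
            ),
            "lvor_index_deg": MeasurementEffects(
                baseline=2.6, age_effect=-0.6, sex_effect=-0.3, residual_sd=0.5
            ),
        },
        seed=seed,
    )


def gen_cohort(e: CohortEffects) -> pd.DataFrame:
    """Per-ear cohort table with additive age x sex effects.

    Records are ears; consecutive ears within a cell pair up into mice
    (left/right), mirroring a design where both ears of each animal are
    measured and treated as independent observations.
    """
    rng = np.random.default_rng(e.seed)
    rows = []
    for name in sorted(e.measurements):
        eff = e.measurements[name]
        for age in AGE_GROUPS:
            for sex in SEXES:
                mean = eff.cell_mean(age, sex)
                values = mean + rng.normal(0.0, eff.residual_sd, e.n_per_cell)
                for i, v in enumerate(values):
                    rows.append(
                        {
                            "mouse_id": f"{age[0]}{sex[0]}{i // 2:02d}",
                            "ear": "left" if i % 2 == 0 else "right",
                            "age_group": age,
                            "sex": sex,
                            "measurement": name,
                            "value": float(v),
                        }
                    )
    return pd.DataFrame(rows)
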