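"""Synthetic study generator: every input the analysis pipeline consumes.

The stated world is a 4-temperature (23, 37, 60, 90 °C) × 18-replicate design
of ~11 μl sheep-blood drops on glass, evaporating in CCR mode with an initial
contact angle of 50°. Per drop the generator emulates:

* a side-view trajectory — at 23 °C volume, height and contact angle fall
  linearly to zero over ~20 min; at 37 °C the height rebounds into a dome
  after ~900 s; at 60/90 °C the dome grows from the start with shorter
  lifetimes, and the volume slope steepens with temperature;
* a thermal frame stack whose edge–center difference ΔT(t) is obtained by
  *inverting* a prescribed Ma(t) through the Marangoni formula (the 37 °C
  default is piecewise linear with rates 1.66 and 55 Ma-units/s and a break
  at 900 s, so the full IR → Ma pipeline reproduces those rates as a round
  trip — a deliberate calibration of the stated world);
* a deposit height map with a peripheral rim, central cavity/dome and
  radial + ortho-radial crack grooves, whose amplitudes and crack counts vary
  monotonically with the substrate temperature so every texture parameter
  carries a programmed temperature effect.

Everything is deterministic under the design's master seed; per-record child
seeds are spawned through :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import DropletTimeSeries, cap_profile, spherical_cap_height
from .properties import BloodProperties, blood_viscosity, dsigma_dT_mean
from .thermography import ThermalFrameSeries, disc_annulus_masks
from .topography import HeightMap

__all__ = [
    "StudyDesign",
    "StudyRecord",
    "ScenarioConfig",
    "default_scenario",
    "generate_study",
    "generate_droplet_series",
    "initial_cap_profile",
    "base_diameter_from_volume",
    "ma_target_function",
    "invert_marangoni_to_deltaT",
    "generate_thermal_frames",
    "generate_deposit",
]


@dataclass(frozen=True)
class StudyDesign:
    """Study layout: temperatures × replicates with a jittered dose volume."""

    temperatures: tuple[float, ...] = (23.0, 37.0, 60.0, 90.0)
    replicates: int = 18
    base_volume_ul: float = 11.0
    volume_jitter_ul: float = 0.2  # automatic doser reproducibility
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.base_volume_ul <= 0:
            raise ValueError("invalid study design")

    @property
    def n_records(self) -> int:
        return len(self.temperatures) * self.replicates


@dataclass(frozen=True)
class StudyRecord:
    """One drop of the study: metadata plus its private random seed."""

    record_id: str
    Ts: float
    V0_ul: float
    replicate: int
    seed: int


@dataclass(frozen=True)
class ScenarioConfig:
    """Per-temperature trajectory, thermal and deposit morphology settings.

    Trajectory: ``lifetime_s`` is the full evaporation time of an 11 μl drop
    (scaled linearly with the actual dose); ``dome_onset_s`` the programmed
    height-rebound time (None = monotone decay); ``dome_amp`` the rebound
    amplitude as a fraction of the initial height. Thermal: the prescribed
    Ma(t) is either piecewise linear (``ma_break_s`` with early/late rates)
    or plain linear (``ma_rate``); frames are rendered with a radial
    (r/R)^``gamma`` field on a ``grid_size``² grid. Deposit: overall relief
    ``amp_um``, rim/dome/cavity weights and crack counts set the morphology;
    all amplitudes and the crack count rise monotonically with Ts.
    """

    Ts: float
    lifetime_s: float
    dome_onset_s: float | None
    dome_amp: float = 0.25
    dome_rise_s: float = 150.0
    theta0_deg: float = 50.0
    noise_frac: float = 0.01
    # thermal / Marangoni
    ma_break_s: float | None = None
    ma_early_rate: float = 1.66
    ma_late_rate: float = 55.0
    ma_rate: float = 0.02
    thermal_span_s: float | None = None
    thermal_dt_s: float = 10.0
    grid_size: int = 128
    drop_radius_px: int = 40
    gamma: float = 2.0
    thermal_noise_degC: float = 0.02
    T_center_offset_degC: float = -2.0
    ring_width_px: float = 2.0
    alpha_mode: str = "si"
    # deposit morphology
    deposit_grid: int = 128
    deposit_radius_px: int = 56
    amp_um: float = 3.0
    rim_w: float = 1.0
    dome_w: float = 0.0
    cavity_w: float = 0.45
    n_radial_cracks: int = 10
    ring_radii: tuple[float, ...] = (0.45, 0.7)
    crack_width_px: float = 2.5
    crack_depth_frac: float = 1.0
    texture_amp_frac: float = 0.10
    sector_mod: float = 0.15
    amp_jitter: float = 0.08
    deposit_noise_um: float = 0.05


_DEFAULTS: dict[float, ScenarioConfig] = {
    23.0: ScenarioConfig(
        Ts=23.0, lifetime_s=1200.0, dome_onset_s=None, ma_rate=0.02,
        amp_um=3.0, rim_w=1.0, dome_w=0.0, cavity_w=0.45, n_radial_cracks=10,
    ),
    37.0: ScenarioConfig(
        Ts=37.0, lifetime_s=1100.0, dome_onset_s=900.0,
        ma_break_s=900.0, ma_early_rate=1.66, ma_late_rate=55.0,
        thermal_span_s=1050.0,
        amp_um=4.5, rim_w=0.9, dome_w=0.25, cavity_w=0.35, n_radial_cracks=13,
    ),
    60.0: ScenarioConfig(
        Ts=60.0, lifetime_s=600.0, dome_onset_s=0.0, ma_rate=8.0,
        dome_amp=0.5, dome_rise_s=120.0,
        amp_um=6.5, rim_w=0.6, dome_w=0.9, cavity_w=0.15, n_radial_cracks=17,
    ),
    90.0: ScenarioConfig(
        Ts=90.0, lifetime_s=400.0, dome_onset_s=0.0, ma_rate=20.0,
        dome_amp=0.5, dome_rise_s=80.0,
        amp_um=9.0, rim_w=0.4, dome_w=1.2, cavity_w=0.0, n_radial_cracks=22,
    ),
}


def default_scenario(Ts: float) -> ScenarioConfig:
    """Default scenario for one of the study temperatures (interpolated for
    other temperatures by nearest neighbor, rescaled lifetime)."""
    Ts = float(Ts)
    if Ts in _DEFAULTS:
        return _DEFAULTS[Ts]
    nearest = min(_DEFAULTS, key=lambda k: abs(k - Ts))
    return replace(_DEFAULTS[nearest], Ts=Ts)


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

def generate_study(design: StudyDesign) -> list[StudyRecord]:
    """Materialize the study records with per-drop child seeds.

    Deterministic given the master seed; dose volumes are jittered around the
    design's base volume. Default design: 72 records, 18 per temperature.
    """
    ss = np.random.SeedSequence(design.master_seed)
    children = ss.spawn(design.n_records + 1)
    vol_rng = np.random.default_rng(children[0])
    records = []
    i = 0
    for Ts in design.temperatures:
        for rep in range(design.replicates):
            child_seed = int(children[i + 1].generate_state(1)[0])
            v0 = float(design.base_volume_ul
                       + design.volume_jitter_ul * vol_rng.standard_normal())
            v0 = max(v0, 0.2 * design.base_volume_ul)
            records.append(
                StudyRecord(
                    record_id=f"T{Ts:g}_r{rep:02d}",
                    Ts=float(Ts),
                    V0_ul=v0,
                    replicate=rep,
                    seed=child_seed,
                )
            )
            i += 1
    return records


def _record_rng(record: StudyRecord, stage: int) -> np.random.Generator:
    """Independent per-record, per-stage random stream."""
    return np.random.default_rng([record.seed, stage])


# ---------------------------------------------------------------------------
# Droplet trajectories
# ---------------------------------------------------------------------------

def base_diameter_from_volume(V0_ul: float, theta_deg: float = 50.0) -> float:
    """Base diameter (mm) of a spherical cap of volume V0 at contact angle θ.

    Closed form from V = (π/6)·r³·tan(θ/2)·(3 + tan²(θ/2)) with r = D/2.
    """
    tau = math.tan(math.radians(theta_deg) / 2.0)
    r3 = 6.0 * V0_ul / (math.pi * tau * (3.0 + tau * tau))
    return 2.0 * r3 ** (1.0 / 3.0)


def initial_cap_profile(record: StudyRecord, cfg: ScenarioConfig | None = None,
                        n: int = 201) -> np.ndarray:
    """Noiseless t = 0 side-view contour of a drop, as an (n, 2) polyline (mm)."""
    cfg = cfg or default_scenario(record.Ts)
    D = base_diameter_from_volume(record.V0_ul, cfg.theta0_deg)
    return cap_profile(D, cfg.theta0_deg, n=n)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_droplet_series(
    record: StudyRecord,
    cfg: ScenarioConfig | None = None,
    n_samples: int = 240,
    noise_frac: float | None = None,
) -> DropletTimeSeries:
    """Synthetic CCR-mode trajectory for one drop.

    Volume decays linearly to zero over the (dose-scaled) lifetime at every
    temperature; height and contact angle decay linearly too, plus — in the
    heated regimes — a dome rebound of amplitude ``dome_amp``·H₀ starting at
    the programmed onset. Additive Gaussian noise, σ = ``noise_frac`` of each
    channel's initial value (0.2 % of D for the pinned base line).
    """
    cfg = cfg or default_scenario(record.Ts)
    nf = cfg.noise_frac if noise_frac is None else noise_frac
    rng = _record_rng(record, stage=1)
    tf = cfg.lifetime_s * record.V0_ul / 11.0
    t = np.linspace(0.0, tf, n_samples)
    frac = t / tf
    D = base_diameter_from_volume(record.V0_ul, cfg.theta0_deg)
    H0 = spherical_cap_height(D, cfg.theta0_deg)
    V = record.V0_ul * (1.0 - frac)
    H = H0 * (1.0 - frac)
    theta = cfg.theta0_deg * (1.0 - frac)
    if cfg.dome_onset_s is not None:
        onset = cfg.dome_onset_s * record.V0_ul / 11.0
        rise_end = min(onset + cfg.dome_rise_s, tf)
        bump = np.where(
            t <= rise_end,
            _smoothstep((t - onset) / max(rise_end - onset, 1e-9)),
            np.clip((tf - t) / max(tf - rise_end, 1e-9), 0.0, 1.0),
        )
        H = H + cfg.dome_amp * H0 * bump
        theta = theta + 0.5 * cfg.dome_amp * cfg.theta0_deg * bump
    noise = lambda scale: rng.normal(0.0, nf * scale, size=t.size) if nf > 0 else 0.0
    V = np.clip(V + noise(record.V0_ul), 0.0, None)
    H = np.clip(H + noise(H0), 0.0, None)
    theta_l = np.clip(theta + noise(cfg.theta0_deg), 0.0, 179.0)
    theta_r = np.clip(theta + noise(cfg.theta0_deg), 0.0, 179.0)
    D_arr = np.full(t.size, D)
    if nf > 0:
        D_arr = D_arr + rng.normal(0.0, 0.002 * D, size=t.size)
    return DropletTimeSeries(t=t, V=V, H=H, theta_left=theta_l,
                             theta_right=theta_r, D=D_arr, Ts=record.Ts)


# ---------------------------------------------------------------------------
# Prescribed Ma(t) and its inversion to a temperature schedule
# ---------------------------------------------------------------------------

def ma_target_function(cfg: ScenarioConfig) -> Callable[[np.ndarray], np.ndarray]:
    """Prescribed Ma(t) for a scenario.

    Piecewise linear with rates (``ma_early_rate``, ``ma_late_rate``) and a
    break at ``ma_break_s`` when the scenario has one (37 °C default:
    1.66 / 55 Ma-units/s, break at 900 s), otherwise linear at ``ma_rate``.
    """
    if cfg.ma_break_s is not None:
        tb, r1, r2 = cfg.ma_break_s, cfg.ma_early_rate, cfg.ma_late_rate

        def f(t):
            t = np.asarray(t, dtype=float)
            return np.where(t <= tb, r1 * t, r1 * tb + r2 * (t - tb))

        return f
    rate = cfg.ma_rate
    return lambda t: rate * np.asarray(t, dtype=float)


def invert_marangoni_to_deltaT(
    Ma_target: np.ndarray,
    R_m: float,
    props: BloodProperties,
    T_center: np.ndarray | float,
    alpha_mode: str = "si",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Solve the Marangoni formula pointwise for ΔT(t).

    dσ/dT and η depend on T_TPCL = T_center + ΔT, so the inversion is a
    fixed-point iteration: ΔT ← −Ma·η·α / ((dσ/dT)·10⁻³·R), updated until the
    largest change falls below ``tol`` °C. Raises RuntimeError when the
    iteration has not converged after ``max_iter`` passes. Requires
    Ma_target ≥ 0 and a σ(T) fit with negative slope.
    """
    if props.sigma_fit is None:
        raise ValueError("inversion requires a surface-tension fit")
    Ma = np.asarray(Ma_target, dtype=float)
    if np.any(Ma < 0):
        raise ValueError("Ma_target must be nonnegative")
    Tc = np.broadcast_to(np.asarray(T_center, dtype=float), Ma.shape).copy()
    alpha = props.alpha(mode=alpha_mode)
    dT = np.zeros_like(Ma)
    for _ in range(max_iter):
        T_tpcl = Tc + dT
        dsig = np.asarray(dsigma_dT_mean(props.sigma_fit, T_tpcl, Tc))
        if np.any(dsig >= 0):
            raise ValueError("surface-tension slope must be negative to drive Ma > 0")
        eta = np.asarray(blood_viscosity(0.5 * (T_tpcl + Tc), props.ht))
        new = -Ma * eta * alpha / (dsig * 1e-3 * R_m)
        if np.max(np.abs(new - dT)) < tol:
            return new
        dT = new
    raise RuntimeError("invert_marangoni_to_deltaT did not converge")


def generate_thermal_frames(
    record: StudyRecord,
    deltaT: np.ndarray,
    t: np.ndarray,
    cfg: ScenarioConfig | None = None,
    noise: float | None = None,
) -> ThermalFrameSeries:
    """Render a frame stack with a programmed edge–center difference ΔT(t).

    The surface field is T(r, t) = T_center(t) + A(t)·(r/R)^γ inside the drop
    and the substrate temperature outside. The amplitude A(t) is
    inverse-calibrated with the exact disc/annulus pixel responses used by
    :func:`hemodrop.thermography.edge_center_series`, so the reduced series
    recovers ΔT(t) up to pixel noise. Gaussian noise (default 0.02 °C) is
    added per pixel.
    """
    cfg = cfg or default_scenario(record.Ts)
    sigma = cfg.thermal_noise_degC if noise is None else noise
    t = np.asarray(t, dtype=float)
    deltaT = np.asarray(deltaT, dtype=float)
    if t.shape != deltaT.shape:
        raise ValueError("t and deltaT must have matching shapes")
    n = cfg.grid_size
    center = (n // 2, n // 2)
    R = float(cfg.drop_radius_px)
    rr, cc = np.ogrid[:n, :n]
    d = np.hypot(rr - center[0], cc - center[1])
    shape_field = (d / R) ** cfg.gamma
    inside = d <= R
    disc, annulus = disc_annulus_masks((n, n), center, R, cfg.ring_width_px)
    response = float(shape_field[annulus].mean() - shape_field[disc].mean())
    Tc = record.Ts + cfg.T_center_offset_degC
    T_sub = record.Ts
    amp = deltaT / response
    frames = np.empty((t.size, n, n), dtype=float)
    for i in range(t.size):
        f = np.where(inside, Tc + amp[i] * shape_field, T_sub)
        frames[i] = f
    if sigma > 0:
        rng = _record_rng(record, stage=2)
        frames += rng.normal(0.0, sigma, size=frames.shape)
    # physical pitch from the drop geometry: R pixels spans the contact radius
    D_mm = base_diameter_from_volume(record.V0_ul, cfg.theta0_deg)
    pitch = (D_mm / 2.0) / R
    return ThermalFrameSeries(frames=frames, t=t, pixel_pitch=pitch,
                              center=center, drop_radius=R)


def thermal_time_grid(record: StudyRecord, cfg: ScenarioConfig | None = None
                      ) -> np.ndarray:
    """Frame timestamps: 0 … thermal span (default the dose-scaled lifetime)."""
    cfg = cfg or default_scenario(record.Ts)
    span = cfg.thermal_span_s
    if span is None:
        span = cfg.lifetime_s * record.V0_ul / 11.0
    return np.arange(0.0, span + 0.5 * cfg.thermal_dt_s, cfg.thermal_dt_s)


# ---------------------------------------------------------------------------
# Deposit height maps
# ---------------------------------------------------------------------------

def generate_deposit(record: StudyRecord, cfg: ScenarioConfig | None = None
                     ) -> HeightMap:
    """Synthetic dried-deposit height map for one drop.

    Morphology per the scenario weights: a raised peripheral rim, a central
    cavity (unheated regime) or dome (heated regimes) and a coronal band, cut
    by radial and ortho-radial crack grooves at randomized angles; a smooth
    random plate texture adds within-group variability. The overall relief
    ``amp_um`` and the crack count rise monotonically with Ts, so every
    texture parameter carries a programmed temperature effect. The lateral
    pitch ties the pixel grid to the drop diameter predicted from the dose
    volume. Fully reproducible from the record seed.
    """
    cfg = cfg or default_scenario(record.Ts)
    rng = _record_rng(record, stage=3)
    n = cfg.deposit_grid
    Rpx = float(cfg.deposit_radius_px)
    yy, xx = np.mgrid[:n, :n] - (n - 1) / 2.0
    r = np.hypot(xx, yy)
    phi = np.arctan2(yy, xx)
    inside = r <= Rpx
    u = r / Rpx

    amp = cfg.amp_um * float(np.clip(1.0 + cfg.amp_jitter * rng.standard_normal(),
                                     0.5, 1.5))
    rim = np.exp(-(((u - 0.92) / 0.06) ** 2))
    dome = np.clip(np.cos(0.5 * np.pi * u), 0.0, None) ** 1.5
    cavity = -np.exp(-((u / 0.35) ** 2))
    base = cfg.rim_w * rim + cfg.dome_w * dome + cfg.cavity_w * cavity
    # coronal band pedestal so the mid-radius plates sit above the substrate
    band = 0.35 * np.exp(-(((u - 0.55) / 0.25) ** 2))
    z = amp * (base + band)

    texture = gaussian_filter(rng.standard_normal((n, n)), sigma=3.0)
    texture /= max(float(texture.std()), 1e-12)
    z += cfg.texture_amp_frac * amp * texture

    depth = cfg.crack_depth_frac * amp
    width = cfg.crack_width_px
    groove = np.zeros((n, n), dtype=bool)
    n_rad = cfg.n_radial_cracks
    offsets = rng.uniform(-0.3, 0.3, size=n_rad) * (2 * np.pi / n_rad)
    crack_angles = -np.pi + (np.arange(n_rad) + 0.5) * 2 * np.pi / n_rad + offsets
    # per-sector height modulation: neighboring plates end up with peak
    # differences proportional to the overall relief (drives coplanarity)
    sector = np.searchsorted(np.sort(crack_angles), phi) % n_rad
    sector_gain = 1.0 + cfg.sector_mod * rng.standard_normal(n_rad)
    z = np.where(inside, z * sector_gain[sector], z)
    for k in range(n_rad):
        ang = crack_angles[k]
        dphi = np.angle(np.exp(1j * (phi - ang)))
        groove |= (np.abs(dphi) * np.maximum(r, 1.0) < width / 2.0) & (r > 0.25 * Rpx)
    for rr_frac in cfg.ring_radii:
        r_ring = (rr_frac + rng.uniform(-0.03, 0.03)) * Rpx
        groove |= np.abs(r - r_ring) < width / 2.0
    z = np.where(groove & inside, z - depth, z)
    z = np.where(inside, z, 0.0)
    if cfg.deposit_noise_um > 0:
        z += rng.normal(0.0, cfg.deposit_noise_um, size=z.shape)

    D_mm = base_diameter_from_volume(record.V0_ul, cfg.theta0_deg)
    pitch_um = D_mm * 1000.0 / (2.0 * Rpx)
    return HeightMap(z=z, lateral_pitch=pitch_um, vertical_resolution=0.1)
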