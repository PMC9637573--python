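"""Droplet shape descriptors and evaporation-rate slopes from side-view data.

A sessile drop pinned on a hydrophilic substrate evaporates in constant
contact-radius (CCR) mode: the base diameter D stays fixed while volume V,
height H and contact angle θ shrink. This module turns side-view trajectories
(t, V, H, θ_left, θ_right, D) and contour polylines into the descriptors used
downstream: initial contact angle by local circle fit, the slope of the early
linear volume decrease, the V–D power-law relation per substrate temperature,
and the onset time of dome formation (the height rebound that signals
Marangoni-driven flow on heated substrates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DropletTimeSeries",
    "ShrinkageFit",
    "VolumeDiameterModel",
    "spherical_cap_height",
    "spherical_cap_volume",
    "cap_profile",
    "extract_contact_angle",
    "volume_shrinkage_slope",
    "fit_volume_diameter",
    "detect_dome_formation",
]

CSV_COLUMNS = ["t_s", "V_ul", "H_mm", "theta_l_deg", "theta_r_deg", "D_mm"]


@dataclass
class DropletTimeSeries:
    """Side-view trajectory of one evaporating drop.

    t in seconds (strictly increasing), V in μl, H in mm, contact angles in
    degrees, base diameter D in mm, Ts the substrate temperature in °C.
    """

    t: np.ndarray
    V: np.ndarray
    H: np.ndarray
    theta_left: np.ndarray
    theta_right: np.ndarray
    D: np.ndarray
    Ts: float

    def __post_init__(self) -> None:
        for name in ("t", "V", "H", "theta_left", "theta_right", "D"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        for name in ("V", "H", "theta_left", "theta_right", "D"):
            if getattr(self, name).size != n:
                raise ValueError(f"field {name!r} length mismatch with t")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def base_radius_mm(self) -> float:
        """Contact radius D/2 in mm (median over the series; constant in CCR)."""
        return float(np.median(self.D)) / 2.0

    def is_ccr(self, rtol: float = 0.02) -> bool:
        """True if the base diameter stays constant within ``rtol`` (pinned line)."""
        d0 = float(np.median(self.D))
        return bool(np.all(np.abs(self.D - d0) <= rtol * d0))

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "t_s": self.t,
                "V_ul": self.V,
                "H_mm": self.H,
                "theta_l_deg": self.theta_left,
                "theta_r_deg": self.theta_right,
                "D_mm": self.D,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, Ts: float = math.nan) -> "DropletTimeSeries":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"droplet CSV missing columns: {missing}")
        return cls(
            t=df["t_s"].to_numpy(),
            V=df["V_ul"].to_numpy(),
            H=df["H_mm"].to_numpy(),
            theta_left=df["theta_l_deg"].to_numpy(),
            theta_right=df["theta_r_deg"].to_numpy(),
            D=df["D_mm"].to_numpy(),
            Ts=Ts,
        )


@dataclass(frozen=True)
class ShrinkageFit:
    """OLS fit of the initial linear volume decrease.

    slope in μl/s (negative while evaporating), intercept in μl, r2 in [0, 1],
    window the (t_start, t_end) span of the fitted segment in seconds.
    """

    slope: float
    intercept: float
    r2: float
    window: tuple[float, float]


def spherical_cap_height(D: float, theta_deg: float) -> float:
    """Apex height h = (D/2)·tan(θ/2) of a spherical cap, same unit as D."""
    return (D / 2.0) * math.tan(math.radians(theta_deg) / 2.0)


def spherical_cap_volume(D: float, theta_deg: float) -> float:
    """Volume of a spherical cap with base diameter D (mm) and contact angle θ.

    V = (π·h/6)·(3r² + h²) with r = D/2, h = r·tan(θ/2); mm³ ≡ μl.
    Strictly increasing in both D and θ; θ must lie in (0, 180).
    """
    if D <= 0:
        raise ValueError("base diameter must be positive")
    if not 0.0 < theta_deg < 180.0:
        raise ValueError("contact angle must be in (0, 180) degrees")
    r = D / 2.0
    h = spherical_cap_height(D, theta_deg)
    return math.pi * h * (3.0 * r * r + h * h) / 6.0


def cap_profile(D: float, theta_deg: float, n: int = 201) -> np.ndarray:
    """Exact side-view contour of a spherical cap as an (n, 2) polyline.

    Returns (x, z) points in mm with the baseline at z = 0, contact points at
    x = ±D/2, sampled uniformly in the polar angle of the generating circle.
    """
    if not 0.0 < theta_deg < 180.0:
        raise ValueError("contact angle must be in (0, 180) degrees")
    r = D / 2.0
    theta = math.radians(theta_deg)
    rho = r / math.sin(theta)  # sphere radius
    zc = -rho * math.cos(theta)  # sphere center height (below baseline if theta<90)
    u = np.linspace(-theta, theta, n)
    x = rho * np.sin(u)
    z = zc + rho * np.cos(u)
    z[0] = z[-1] = 0.0  # exact baseline contact against rounding
    return np.column_stack([x, z])


def _fit_circle(x: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) circle fit; returns (xc, zc, radius)."""
    A = np.column_stack([x, z, np.ones_like(x)])
    b = -(x * x + z * z)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("degenerate (collinear) circle fit")
    D_, E_, F_ = sol
    xc, zc = -D_ / 2.0, -E_ / 2.0
    r2 = xc * xc + zc * zc - F_
    if r2 <= 0:
        raise np.linalg.LinAlgError("circle fit returned non-positive radius")
    return float(xc), float(zc), float(math.sqrt(r2))


def _side_angle(x: np.ndarray, z: np.ndarray, span: float) -> float:
    """Tangent angle at the baseline from a local circle fit of one flank."""
    try:
        xc, zc, rho = _fit_circle(x, z)
    except np.linalg.LinAlgError:
        xc = zc = rho = math.nan
    if not math.isfinite(rho) or rho > 1e6 * span or rho < abs(zc):
        # Near-flat flank (or circle not reaching the baseline): tangent-line fallback.
        slope = np.polyfit(x, z, 1)[0]
        return math.degrees(math.atan(abs(float(slope))))
    half_chord = math.sqrt(rho * rho - zc * zc)
    # Interior tangent at the baseline crossing: theta = atan2(half_chord, -zc),
    # which is 90 deg for a hemisphere (zc = 0) and > 90 deg when the sphere
    # center sits above the baseline.
    return math.degrees(math.atan2(half_chord, -zc))


def extract_contact_angle(
    profile: np.ndarray | Sequence[Sequence[float]],
    band: float = 0.35,
    min_points: int = 5,
) -> tuple[float, float]:
    """Left and right contact angles (degrees) from a side-view contour.

    The contour is an (N, 2) polyline of (x, z) points in mm with the
    substrate at z = 0 and must touch the baseline on both sides of the apex.
    Each flank is fitted with a local circle over the points with
    z ≤ ``band``·max(z) (at least ``min_points`` of them) and the tangent
    angle at the baseline intersection is returned, in (0, 180).
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2 * min_points:
        raise ValueError("profile must be an (N, 2) polyline with enough points")
    x, z = p[:, 0], p[:, 1]
    zmax = float(z.max())
    if zmax <= 0:
        raise ValueError("profile has no points above the baseline")
    tol = 1e-6 * zmax
    span = float(x.max() - x.min())
    apex = int(np.argmax(z))
    angles = []
    for side in ("left", "right"):
        if side == "left":
            xs, zs = x[: apex + 1], z[: apex + 1]
        else:
            xs, zs = x[apex:], z[apex:]
        if float(zs.min()) > 0.02 * zmax + tol:
            raise ValueError(f"{side} flank does not reach the baseline z = 0")
        # fit the arc just above the baseline; resting flat runs (z ~ 0 beyond
        # the contact point) would bias the circle fit
        sel = (zs > tol) & (zs <= band * zmax)
        if int(sel.sum()) < min_points:
            above = zs > tol
            if int(above.sum()) >= min_points:
                order = np.argsort(np.where(above, zs, np.inf))
                sel = np.zeros_like(sel)
                sel[order[:min_points]] = True
            else:
                order = np.argsort(zs)
                sel = np.zeros_like(sel)
                sel[order[:min_points]] = True
        angles.append(_side_angle(xs[sel], zs[sel], span))
    return float(angles[0]), float(angles[1])


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)


def volume_shrinkage_slope(
    series: DropletTimeSeries,
    r2_min: float = 0.98,
    initial_fraction: float = 0.2,
) -> ShrinkageFit:
    """Slope of the initial linear segment of V(t), in μl/s.

    Starting from the first max(10, ⌈``initial_fraction``·N⌉) samples, the
    fitting window grows one sample at a time while the OLS r² of the window
    stays at or above ``r2_min``; the first extension that drops r² below the
    bound ends the window. This is the operational definition of the
    "beginning" of the linear volume decrease.
    """
    t, V = series.t, series.V
    n = t.size
    if n < 10:
        raise ValueError("volume_shrinkage_slope needs at least 10 samples")
    if np.allclose(t, t[0]):
        raise ValueError("all timestamps equal")
    k = max(10, int(math.ceil(initial_fraction * n)))
    k = min(k, n)
    slope, intercept, r2 = _ols_line(t[:k], V[:k])
    while k < n:
        s2, i2, q2 = _ols_line(t[: k + 1], V[: k + 1])
        if q2 < r2_min:
            break
        slope, intercept, r2 = s2, i2, q2
        k += 1
    return ShrinkageFit(slope=slope, intercept=intercept, r2=max(0.0, min(1.0, r2)),
                        window=(float(t[0]), float(t[k - 1])))


@dataclass(frozen=True)
class VolumeDiameterModel:
    """Per-temperature power laws V = c·D^k fitted on log–log axes.

    ``models`` maps substrate temperature (°C) to (c, k, r2) with V in μl and
    D in mm. A spherical cap at fixed contact angle gives k = 3 exactly, so
    the power-law family nests the geometric expectation.
    """

    models: dict[float, tuple[float, float, float]]

    def predict_volume(self, D: float, Ts: float) -> float:
        """Predicted drop volume (μl) from base diameter D (mm) at Ts (°C)."""
        if Ts not in self.models:
            raise KeyError(f"no V–D model fitted for Ts = {Ts} degC")
        c, k, _ = self.models[Ts]
        return float(c * D**k)


def fit_volume_diameter(records: Sequence[tuple[float, float, float]]) -> VolumeDiameterModel:
    """Fit V = c·D^k per substrate temperature from (Ts, V, D) records.

    Needs at least 3 drops per temperature with positive V and D; the fit is
    ordinary least squares on (ln D, ln V).
    """
    by_ts: dict[float, list[tuple[float, float]]] = {}
    for Ts, V, D in records:
        if V <= 0 or D <= 0:
            raise ValueError("V and D must be positive")
        by_ts.setdefault(float(Ts), []).append((float(V), float(D)))
    models = {}
    for Ts, vd in by_ts.items():
        if len(vd) < 3:
            raise ValueError(f"need >= 3 drops per temperature, got {len(vd)} at {Ts}")
        V = np.array([v for v, _ in vd])
        D = np.array([d for _, d in vd])
        k, lnc, r2 = _ols_line(np.log(D), np.log(V))
        models[Ts] = (float(math.exp(lnc)), float(k), max(0.0, min(1.0, r2)))
    return VolumeDiameterModel(models=models)


def detect_dome_formation(
    series: DropletTimeSeries,
    rise_fraction: float = 0.05,
    min_rise_samples: int = 3,
    smooth_window: int = 5,
) -> float | None:
    """Earliest time at which the drop height rebounds into a dome.

    Returns the first time t at which the (lightly smoothed) height exceeds
    its running minimum by more than ``rise_fraction`` of the initial height
    and keeps a rising trend over the next ``min_rise_samples`` samples;
    ``None`` for a monotonically decaying height (capillary-dominated
    evaporation). The rise threshold is referenced to H(0) rather than to the
    running minimum itself because the minimum tends to zero near full
    evaporation, where any relative threshold is crossed by measurement noise.
    """
    t = series.t
    n = series.H.size
    if n < min_rise_samples + 2:
        return None
    w = max(1, min(smooth_window, n))
    kernel = np.ones(w) / w
    H = np.convolve(series.H, kernel, mode="same")
    # moving-average edge bias: fall back to raw samples at the borders
    H[: w // 2] = series.H[: w // 2]
    H[n - w // 2 :] = series.H[n - w // 2 :]
    h0 = float(H[0])
    if h0 <= 0:
        return None
    run_min = np.minimum.accumulate(H)
    for i in range(n):
        if H[i] > run_min[i] + rise_fraction * h0:
            j = min(i + min_rise_samples, n - 1)
            if j > i and H[j] > H[i]:
                return float(t[i])
    return None
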