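"""Reduction of infrared frame stacks to edge/center temperature series.

An IR camera looking down on an evaporating drop yields a stack of 2-D
surface-temperature grids. The quantity driving the thermal Marangoni number
is the difference ΔT(t) = T_TPCL(t) − T_center(t) between the three-phase
contact line (TPCL) and the drop center. Because single-pixel reads are noisy,
the center temperature is averaged over a small disc and the TPCL temperature
over a thin annulus just inside the contact radius.

Frames are stored row-major with pixel (0, 0) at the top-left and 0-based
coordinates; physical scale comes from ``pixel_pitch`` (mm/pixel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ThermalFrameSeries",
    "EdgeCenterSeries",
    "center_line_profile",
    "edge_center_series",
    "locate_tpcl",
    "disc_annulus_masks",
]


@dataclass
class ThermalFrameSeries:
    """Time-stamped stack of surface-temperature grids (°C).

    frames: (n_t, H, W) array; t: seconds, strictly increasing;
    pixel_pitch: mm/pixel; center: (row, col) of the drop center in pixels;
    drop_radius: contact radius in pixels (>= 3).
    """

    frames: np.ndarray
    t: np.ndarray
    pixel_pitch: float
    center: tuple[int, int]
    drop_radius: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_t, H, W) stack")
        if self.t.size != self.frames.shape[0]:
            raise ValueError("t length must match number of frames")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.drop_radius < 3:
            raise ValueError("drop_radius must be >= 3 pixels")
        r, c = self.center
        _, h, w = self.frames.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("center must lie inside the grid")

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a float32 multi-page TIFF plus a JSON sidecar of metadata."""
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "t_s": self.t.tolist(),
                    "pixel_pitch_mm": self.pixel_pitch,
                    "center_rc": list(self.center),
                    "drop_radius_px": self.drop_radius,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "ThermalFrameSeries":
        path = Path(path)
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            frames=frames,
            t=np.asarray(meta["t_s"], dtype=float),
            pixel_pitch=float(meta["pixel_pitch_mm"]),
            center=tuple(meta["center_rc"]),
            drop_radius=float(meta["drop_radius_px"]),
        )


@dataclass
class EdgeCenterSeries:
    """TPCL and center temperature time series with ΔT = T_TPCL − T_center."""

    t: np.ndarray
    T_tpcl: np.ndarray
    T_center: np.ndarray

    @property
    def dT(self) -> np.ndarray:
        return self.T_tpcl - self.T_center


def center_line_profile(
    frame: np.ndarray, center: tuple[int, int], radius: int
) -> np.ndarray:
    """Temperature along the horizontal line through the drop center.

    Returns a 1-D array of length 2·radius + 1 (°C); raises if the line
    leaves the grid.
    """
    frame = np.asarray(frame, dtype=float)
    r, c = center
    radius = int(radius)
    if c - radius < 0 or c + radius >= frame.shape[1] or not 0 <= r < frame.shape[0]:
        raise ValueError("center line exits the frame")
    return frame[r, c - radius : c + radius + 1].copy()


def disc_annulus_masks(
    shape: tuple[int, int],
    center: tuple[int, int],
    radius: float,
    ring_width: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks for the center disc and the TPCL annulus.

    Disc: pixels with distance ≤ ``ring_width`` from the center. Annulus:
    pixels with radius − ring_width ≤ distance ≤ radius. These same masks are
    used by the synthetic frame renderer to inverse-calibrate its field
    amplitude, closing the round trip exactly.
    """
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    disc = d <= ring_width
    annulus = (d >= radius - ring_width) & (d <= radius)
    return disc, annulus


def edge_center_series(
    series: ThermalFrameSeries, ring_width: float = 2.0
) -> EdgeCenterSeries:
    """Reduce a frame stack to T_center(t), T_TPCL(t) and ΔT(t).

    Per frame, T_center is the mean over a disc of radius ``ring_width``
    pixels at the drop center and T_TPCL the mean over the annulus
    [drop_radius − ring_width, drop_radius]. Adding a constant to every frame
    leaves ΔT unchanged.
    """
    disc, annulus = disc_annulus_masks(
        series.frames.shape[1:], series.center, series.drop_radius, ring_width
    )
    if not annulus.any():
        raise ValueError("TPCL annulus contains no pixels")
    if not disc.any():
        raise ValueError("center disc contains no pixels")
    flat = series.frames.reshape(series.frames.shape[0], -1)
    T_center = flat[:, disc.ravel()].mean(axis=1)
    T_tpcl = flat[:, annulus.ravel()].mean(axis=1)
    return EdgeCenterSeries(t=series.t.copy(), T_tpcl=T_tpcl, T_center=T_center)


def locate_tpcl(
    frame: np.ndarray,
    center: tuple[int, int],
    mask_radius: float | None = None,
    min_gradient: float = 1e-3,
) -> float:
    """Contact-line radius (pixels) from the azimuthally averaged profile.

    The frame is binned by integer radius around ``center``; the radius of the
    maximum absolute radial gradient of the mean profile is returned. If no
    gradient exceeds ``min_gradient`` °C/px the provided ``mask_radius`` is
    returned instead; with neither, a ValueError is raised. The result is
    invariant to adding a constant to the whole frame.
    """
    frame = np.asarray(frame, dtype=float)
    rr, cc = np.ogrid[: frame.shape[0], : frame.shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    rmax = int(min(center[0], center[1], frame.shape[0] - 1 - center[0],
                   frame.shape[1] - 1 - center[1]))
    if rmax < 2:
        raise ValueError("center too close to the frame border")
    bins = np.clip(np.rint(d).astype(int), 0, rmax)
    inside = (d <= rmax).ravel()
    counts = np.bincount(bins.ravel()[inside], minlength=rmax + 1)
    sums = np.bincount(bins.ravel()[inside], weights=frame.ravel()[inside],
                       minlength=rmax + 1)
    profile = sums / np.maximum(counts, 1)
    grad = np.abs(np.diff(profile))
    if grad.size == 0 or grad.max() < min_gradient:
        if mask_radius is not None:
            return float(mask_radius)
        raise ValueError("no detectable radial gradient and no mask radius given")
    # gradient between bins k and k+1 -> edge at k + 0.5
    return float(np.argmax(grad) + 0.5)
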