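"""Super-resolved map reconstruction from accepted tracks.

Every track localization (optionally densified by linear interpolation along
each step so fast bubbles do not leave gaps) increments its super-resolution
pixel; per-pixel mean step speed, circular-mean flow direction and circular
dispersion are accumulated alongside.  The super-resolution grid refines the
acquisition grid by an integer ``grid_factor``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import Track

__all__ = ["SuperResMaps", "accumulate_maps"]


@dataclass
class SuperResMaps:
    """Density / velocity / direction images on the upsampled grid.

    ``density`` holds localization counts (integers); ``velocity`` (mm/s),
    ``direction`` (radians in (-pi, pi]) and ``dispersion`` (1 - resultant
    length, in [0, 1]) are defined only where density > 0 and are nan
    elsewhere.
    """

    density: np.ndarray
    velocity: np.ndarray
    direction: np.ndarray
    dispersion: np.ndarray
    grid_factor: int
    pixel_size_um: float            # acquisition pixel size

    @property
    def superres_pixel_um(self) -> float:
        return self.pixel_size_um / self.grid_factor


def accumulate_maps(
    tracks: list[Track],
    shape: tuple[int, int],
    pixel_size_um: float,
    frame_rate_hz: float,
    grid_factor: int = 8,
    interpolate: bool = True,
) -> SuperResMaps:
    """Aggregate tracks into density, velocity and direction maps.

    ``shape`` is the acquisition grid (H, W); the output maps have shape
    (H x grid_factor, W x grid_factor).  Acquisition pixel centres sit at
    integer pixel coordinates, so a position x (in pixels) falls in
    super-res column floor((x + 1/2) x grid_factor).

    Each track contributes its localizations, with interior points carrying
    the speed and direction of their outgoing step and the final point those
    of its incoming step.  With ``interpolate=True`` extra points are placed
    along each step at the super-res pixel pitch (counted in the density like
    real localizations, carrying their step's velocity).
    """
    if grid_factor < 1:
        raise ValueError("grid_factor must be >= 1")
    h, w = shape
    gh, gw = h * grid_factor, w * grid_factor
    count = np.zeros((gh, gw), dtype=np.int64)
    speed_sum = np.zeros((gh, gw))
    cos_sum = np.zeros((gh, gw))
    sin_sum = np.zeros((gh, gw))

    pitch = pixel_size_um / grid_factor
    for tr in tracks:
        if len(tr) < 2:
            continue
        xy = tr.xy_um
        steps = np.diff(xy, axis=0)
        lengths = np.hypot(steps[:, 0], steps[:, 1])
        speeds = lengths * frame_rate_hz / 1000.0       # mm/s
        angles = np.arctan2(steps[:, 1], steps[:, 0])
        pts, pt_speed, pt_angle = [], [], []
        for i in range(len(steps)):
            if interpolate:
                k = max(1, int(math.ceil(lengths[i] / pitch)))
            else:
                k = 1
            frac = np.arange(k) / k
            pts.append(xy[i] + frac[:, None] * steps[i])
            pt_speed.append(np.full(k, speeds[i]))
            pt_angle.append(np.full(k, angles[i]))
        pts.append(xy[-1:])
        pt_speed.append(speeds[-1:])
        pt_angle.append(angles[-1:])
        pts = np.concatenate(pts)
        pt_speed = np.concatenate(pt_speed)
        pt_angle = np.concatenate(pt_angle)

        cols = np.floor((pts[:, 0] / pixel_size_um + 0.5) * grid_factor).astype(int)
        rows = np.floor((pts[:, 1] / pixel_size_um + 0.5) * grid_factor).astype(int)
        ok = (rows >= 0) & (rows < gh) & (cols >= 0) & (cols < gw)
        rows, cols = rows[ok], cols[ok]
        np.add.at(count, (rows, cols), 1)
        np.add.at(speed_sum, (rows, cols), pt_speed[ok])
        np.add.at(cos_sum, (rows, cols), np.cos(pt_angle[ok]))
        np.add.at(sin_sum, (rows, cols), np.sin(pt_angle[ok]))

    with np.errstate(invalid="ignore", divide="ignore"):
        velocity = np.where(count > 0, speed_sum / count, np.nan)
        resultant = np.sqrt(cos_sum ** 2 + sin_sum ** 2)
        dispersion = np.where(count > 0, 1.0 - resultant / np.maximum(count, 1), np.nan)
        direction = np.where(count > 0, np.arctan2(sin_sum, cos_sum), np.nan)
    direction[direction == -math.pi] = math.pi
    return SuperResMaps(density=count, velocity=velocity, direction=direction,
                        dispersion=dispersion, grid_factor=grid_factor,
                        pixel_size_um=pixel_size_um)
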