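"""Shared in-memory containers for the ULM pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FrameStack:
    """A beamformed envelope movie: T frames of H x W non-negative amplitudes.

    The pipeline starts here; beamforming of raw channel data is out of scope.
    ``pixel_size_um`` is the acquisition pixel pitch and ``frame_rate_hz`` the
    ultrafast frame rate (compounded plane-wave rate, not the pulse rate).
    """

    frames: np.ndarray          # (T, H, W) float
    pixel_size_um: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.pixel_size_um <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("pixel size and frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class Track:
    """One microbubble trajectory: sub-pixel positions on consecutive frames.

    Positions are in micrometres (x = column axis, y = row axis, pixel centres
    at integer pixel coordinates x/pixel_size).
    """

    frames: np.ndarray          # (n,) int, strictly consecutive
    xy_um: np.ndarray           # (n, 2) float, columns (x, y)
    intensity: np.ndarray = field(default=None)  # (n,) peak amplitudes

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy_um = np.asarray(self.xy_um, dtype=np.float64)
        if self.intensity is None:
            self.intensity = np.ones(len(self.frames))
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.xy_um.shape != (len(self.frames), 2):
            raise ValueError("xy_um must be (n, 2) matching frames")
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.frames)
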