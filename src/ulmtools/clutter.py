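"""SVD clutter filtering of ultrafast movies.

Tissue echo is orders of magnitude brighter than microbubble echo but varies
slowly in time, so in the singular value decomposition of the spatiotemporal
(Casorati) matrix it concentrates in the first few components.  Removing
those components separates moving bubbles from quasi-static background.  The
clutter/bubble boundary is picked automatically at the knee ("inflection
point") of the singular value curve.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import FrameStack

__all__ = ["SingularSpectrum", "casorati_matrix", "select_threshold_inflection", "svd_filter"]


@dataclass
class SingularSpectrum:
    """Singular values of the Casorati matrix and the selected cutoff rank.

    Components with index < ``cutoff`` (0-based) are treated as clutter.
    """

    values: np.ndarray
    cutoff: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0) or np.any(np.diff(self.values) > 1e-9 * self.values[0]):
            raise ValueError("singular values must be non-negative and non-increasing")
        if not (1 <= self.cutoff < len(self.values)):
            raise ValueError("cutoff must satisfy 1 <= cutoff < n_values")


def casorati_matrix(stack: FrameStack) -> np.ndarray:
    """Rearrange a T x H x W movie into the (H*W) x T Casorati matrix.

    Columns are vectorised frames; the rearrangement is lossless
    (``casorati.T.reshape(T, H, W)`` restores the movie).
    """
    t, h, w = stack.frames.shape
    return stack.frames.reshape(t, h * w).T


def select_threshold_inflection(singular_values: np.ndarray) -> int:
    """Pick the clutter cutoff at the knee of the singular value curve.

    The knee is located as the interior index maximising the discrete second
    difference of log10 singular values — the point where the steep clutter
    plateau gives way to the flat bubble/noise tail.  Scale-invariant and
    parameter-free; ties break toward the smallest index.

    Returns the 0-based rank: components with index < cutoff are clutter.
    """
    s = np.asarray(singular_values, dtype=np.float64)
    if s.ndim != 1 or len(s) < 4:
        raise ValueError("need at least 4 singular values to locate a knee")
    floor = max(s[0], 1.0) * 1e-15
    logs = np.log10(np.maximum(s, floor))
    # second difference at interior indices 1 .. n-2
    d2 = logs[2:] - 2.0 * logs[1:-1] + logs[:-2]
    return int(np.argmax(d2)) + 1


def svd_filter(
    stack: FrameStack,
    cutoff: int | str = "auto",
    upper_cutoff: int | None = None,
) -> tuple[FrameStack, SingularSpectrum]:
    """Remove low-order singular components (tissue clutter) from a movie.

    Parameters
    ----------
    stack:
        Input movie, T >= 3 frames.
    cutoff:
        Number of leading components to remove (``1 <= cutoff < T``) or
        ``"auto"`` to place the cutoff at the singular-value-curve knee.
    upper_cutoff:
        Optional high-order cutoff: components with index >= upper_cutoff are
        also dropped (noise floor suppression).  Default keeps all of them.

    Returns the filtered movie (same shape) and the singular spectrum with the
    cutoff actually used.  The decomposition is orthogonal, so removed and
    retained energies add up to the input energy.
    """
    if stack.n_frames < 3:
        raise ValueError("SVD filtering needs at least 3 frames")
    c = casorati_matrix(stack)
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    if cutoff == "auto":
        k = select_threshold_inflection(s)
    else:
        k = int(cutoff)
    if not (1 <= k < len(s)):
        raise ValueError(f"cutoff must be in [1, {len(s) - 1}], got {k}")
    hi = len(s) if upper_cutoff is None else int(upper_cutoff)
    if not (k < hi <= len(s)):
        raise ValueError("upper_cutoff must satisfy cutoff < upper_cutoff <= T")
    filt = (u[:, k:hi] * s[k:hi]) @ vt[k:hi]
    t, h, w = stack.frames.shape
    frames = np.ascontiguousarray(filt.T.reshape(t, h, w))
    out = FrameStack(frames=frames, pixel_size_um=stack.pixel_size_um,
                     frame_rate_hz=stack.frame_rate_hz)
    return out, SingularSpectrum(values=s, cutoff=k)
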