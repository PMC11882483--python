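"""Per-frame microbubble detection, sub-pixel localization, and tracking.

Detection finds intensity maxima above a robust noise threshold; each
candidate is refined to sub-pixel precision by the gradient-based radial
symmetry estimator (least-squares intersection of lines drawn through local
gradient directions, weighted by gradient magnitude).  Detections on
consecutive frames are linked by optimal one-to-one assignment (Hungarian
algorithm) on a distance-gated cost matrix; a missed detection terminates a
track (no gap closing), and tracks shorter than a minimum number of frames
are discarded.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import maximum_filter, uniform_filter
from scipy.optimize import linear_sum_assignment

from .containers import FrameStack, Track

__all__ = [
    "detect_candidates", "localize_radial_symmetry", "localize_frame",
    "localize_stack", "link_tracks", "track_velocities",
]

_FORBIDDEN = 1.0e15      # cost placeholder for pairs outside the linking gate


def detect_candidates(
    frame: np.ndarray,
    nsigma: float = 3.5,
    min_separation: int = 3,
    threshold: float | None = None,
) -> np.ndarray:
    """Integer-pixel bubble candidates: local maxima above a robust threshold.

    The threshold defaults to median + ``nsigma`` robust standard deviations
    (1.4826 x median absolute deviation) of the frame, appropriate after
    clutter filtering where most pixels are background.  Candidates closer
    than ``min_separation`` pixels are thinned greedily by descending
    intensity.  Returns an (n, 2) array of (row, col) indices.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if threshold is None:
        med = np.median(frame)
        mad = np.median(np.abs(frame - med))
        threshold = med + nsigma * 1.4826 * mad
    is_max = (maximum_filter(frame, size=3, mode="constant") == frame)
    cand = np.argwhere(is_max & (frame > threshold))
    if len(cand) == 0:
        return cand.reshape(0, 2)
    inten = frame[cand[:, 0], cand[:, 1]]
    # stable order: intensity desc, then row, then col
    order = np.lexsort((cand[:, 1], cand[:, 0], -inten))
    cand = cand[order]
    kept: list[np.ndarray] = []
    min_sep2 = float(min_separation) ** 2
    for p in cand:
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep2 for q in kept):
            kept.append(p)
    return np.array(kept)


def localize_radial_symmetry(window: np.ndarray) -> tuple[float, float]:
    """Sub-pixel centre offset (dx, dy) of a spot within a square window.

    Gradients are estimated on the dual (half-integer) grid from diagonal
    differences of 2 x 2 pixel cells and smoothed with a 3 x 3 boxcar.  Each
    grid point defines a line through it along its gradient direction; for a
    radially symmetric spot all such lines pass through the centre, which is
    estimated as the gradient-magnitude-weighted least-squares intersection.
    Offsets are in pixels relative to the window centre, clipped to the
    window half-size; a constant window has no defined centre and raises.
    """
    im = np.asarray(window, dtype=np.float64)
    ny, nx = im.shape
    if ny != nx or ny < 5 or ny % 2 == 0:
        raise ValueError("window must be square, odd-sized and at least 5 x 5")
    half = (ny - 1) // 2

    # half-integer coordinate grids of the 2x2 cell midpoints
    xm = np.arange(-(nx - 1) / 2.0 + 0.5, (nx - 1) / 2.0, 1.0)
    ym = np.arange(-(ny - 1) / 2.0 + 0.5, (ny - 1) / 2.0, 1.0)
    xm, ym = np.meshgrid(xm, ym)

    didu = im[:-1, 1:] - im[1:, :-1]      # along (+x, -y) diagonal
    didv = im[:-1, :-1] - im[1:, 1:]      # along (-x, -y) diagonal
    didu = uniform_filter(didu, size=3, mode="constant")
    didv = uniform_filter(didv, size=3, mode="constant")
    grad2 = didu ** 2 + didv ** 2
    if grad2.max() <= 1e-30 * max(np.abs(im).max(), 1.0) ** 2 or grad2.max() == 0.0:
        raise ValueError("constant window: radial-symmetry centre undefined")

    with np.errstate(divide="ignore", invalid="ignore"):
        m = -(didv + didu) / (didu - didv)     # slope dy/dx of the gradient line
    m[np.isnan(m)] = 0.0
    m[np.isinf(m)] = 1.0e9
    b = ym - m * xm

    # weight: gradient energy over distance to the rough (gradient) centroid
    wsum = grad2.sum()
    xc0 = float((grad2 * xm).sum() / wsum)
    yc0 = float((grad2 * ym).sum() / wsum)
    dist = np.sqrt((xm - xc0) ** 2 + (ym - yc0) ** 2)
    w = grad2 / np.maximum(dist, 0.1)

    wm2p1 = w / (m ** 2 + 1.0)
    sw = wm2p1.sum()
    smw = (m * wm2p1).sum()
    smmw = (m * m * wm2p1).sum()
    sbw = (b * wm2p1).sum()
    smbw = (m * b * wm2p1).sum()
    det = smw * smw - smmw * sw
    if abs(det) < 1e-30:
        raise ValueError("degenerate gradient configuration")
    dx = (smbw * sw - smw * sbw) / det
    dy = (smbw * smw - smmw * sbw) / det
    dx = float(np.clip(dx, -half, half))
    dy = float(np.clip(dy, -half, half))
    return dx, dy


def localize_frame(
    frame: np.ndarray,
    pixel_size_um: float,
    half_window: int = 3,
    nsigma: float = 3.5,
    min_separation: int = 3,
    threshold: float | None = None,
) -> np.ndarray:
    """Detect and sub-pixel-localize bubbles in one frame.

    Returns an (n, 3) array of (x_um, y_um, intensity).  Candidates whose
    refinement window does not fit inside the frame, or whose window is
    degenerate, are dropped.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape
    cand = detect_candidates(frame, nsigma=nsigma,
                             min_separation=min_separation, threshold=threshold)
    out = []
    for r, c in cand:
        if not (half_window <= r < h - half_window
                and half_window <= c < w - half_window):
            continue
        win = frame[r - half_window:r + half_window + 1,
                    c - half_window:c + half_window + 1]
        try:
            dx, dy = localize_radial_symmetry(win)
        except ValueError:
            continue
        out.append(((c + dx) * pixel_size_um, (r + dy) * pixel_size_um,
                    frame[r, c]))
    if not out:
        return np.zeros((0, 3))
    arr = np.array(out)
    order = np.lexsort((arr[:, 0], arr[:, 1]))     # canonical: y then x
    return arr[order]


def localize_stack(stack: FrameStack, **kwargs) -> list[np.ndarray]:
    """Localize every frame of a (filtered) movie."""
    return [localize_frame(f, stack.pixel_size_um, **kwargs)
            for f in stack.frames]


def _assign(prev_xy: np.ndarray, next_xy: np.ndarray, gate_um: float):
    """Gated optimal assignment between two point sets.

    Cost is squared Euclidean distance; pairs beyond the gate are forbidden.
    Minimising with a large forbidden-pair placeholder yields the maximum
    number of gated matches at minimum total cost.  Returns matched index
    pairs (i_prev, j_next).
    """
    d2 = ((prev_xy[:, None, :] - next_xy[None, :, :]) ** 2).sum(axis=2)
    cost = np.where(d2 <= gate_um * gate_um, d2, _FORBIDDEN)
    rows, cols = linear_sum_assignment(cost)
    ok = cost[rows, cols] < _FORBIDDEN / 2.0
    return list(zip(rows[ok], cols[ok]))


def link_tracks(
    localizations: list[np.ndarray],
    max_link_distance_um: float,
    min_track_len: int = 15,
) -> list[Track]:
    """Link per-frame localizations into trajectories.

    ``localizations`` is one (n_t, >=2) array of (x_um, y_um[, intensity])
    per frame.  Per consecutive frame pair the Hungarian assignment minimises
    total squared distance over pairs within the gate; unmatched detections
    start new tracks, unmatched tracks terminate.  Tracks shorter than
    ``min_track_len`` frames are discarded (default 15 frames).
    """
    if max_link_distance_um <= 0:
        raise ValueError("max_link_distance must be positive")
    active: list[dict] = []
    done: list[dict] = []
    for t, det in enumerate(localizations):
        det = np.asarray(det, dtype=np.float64)
        if det.ndim != 2:
            det = det.reshape(0, 3)
        n = len(det)
        inten = det[:, 2] if det.shape[1] > 2 else np.ones(n)
        matched_prev: set[int] = set()
        matched_next: set[int] = set()
        if active and n:
            prev_xy = np.array([tr["xy"][-1] for tr in active])
            for i, j in _assign(prev_xy, det[:, :2], max_link_distance_um):
                active[i]["frames"].append(t)
                active[i]["xy"].append(det[j, :2])
                active[i]["intensity"].append(inten[j])
                matched_prev.add(i)
                matched_next.add(j)
        still = []
        for i, tr in enumerate(active):
            (still if i in matched_prev else done).append(tr)
        active = still
        for j in range(n):
            if j not in matched_next:
                active.append({"frames": [t], "xy": [det[j, :2]],
                               "intensity": [inten[j]]})
    done.extend(active)
    tracks = [Track(frames=np.array(tr["frames"]), xy_um=np.array(tr["xy"]),
                    intensity=np.array(tr["intensity"]))
              for tr in done if len(tr["frames"]) >= min_track_len]
    tracks.sort(key=lambda tr: (tr.frames[0], tr.xy_um[0, 1], tr.xy_um[0, 0]))
    return tracks


def track_velocities(track: Track, frame_rate_hz: float) -> tuple[np.ndarray, float]:
    """Per-step velocity vectors (mm/s) and the mean step-speed magnitude.

    Step i velocity is (position[i+1] - position[i]) x frame rate, converted
    from um/s to mm/s.
    """
    if len(track) < 2:
        raise ValueError("velocity needs a track of at least 2 frames")
    v = np.diff(track.xy_um, axis=0) * frame_rate_hz / 1000.0
    speeds = np.hypot(v[:, 0], v[:, 1])
    return v, float(speeds.mean())
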