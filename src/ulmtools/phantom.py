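"""Synthetic vascular phantoms with exact ground truth.

The generator emulates the study design of a rodent brain-tumour imaging
experiment: the field of view is split into labelled regions ("core",
"invasive", "normal"), each populated by a stochastic branching random walk
whose parameters control vessel density, branching, tortuosity, calibre and
flow speed.  Defaults make the invasive region denser, more branched and more
disordered than the core and normal regions, which is the architecture the
pipeline is meant to resolve.

Microbubbles are advected through the network under a Poiseuille profile
(parabolic across the lumen, centreline speed twice the mean), and movies are
rendered as Gaussian spots on top of a low-rank, high-amplitude "tissue"
field plus noise so that SVD clutter filtering is exercised realistically.

Everything carries analytic ground truth: segment polylines and radii give
the true morphometrics, bubble paths give the true trajectories.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import FrameStack
from . import metrics as _metrics

__all__ = [
    "RegionSpec", "VesselSegment", "VascularPhantom", "Bubble",
    "BubbleTrajectorySet", "default_regions", "two_region_config",
    "generate_phantom", "simulate_bubble_flow", "render_movie",
    "phantom_truth_metrics", "true_vessel_mask",
]


@dataclass(frozen=True)
class RegionSpec:
    """Generator parameters for one tissue region.

    tortuosity is the amplitude (rad) of the sinusoidal heading perturbation
    along a vessel; direction_jitter is the spread (rad) of seed headings
    about the region's preferred axis.  branch_prob is per walker step.
    """

    name: str
    n_seeds: int = 3
    branch_prob: float = 0.02
    tortuosity: float = 0.2
    direction_jitter: float = 0.2
    radius_um: tuple[float, float] = (6.0, 14.0)
    speed_mm_s: tuple[float, float] = (2.0, 6.0)
    branch_angle: tuple[float, float] = (0.3, 0.6)   # rad, child heading offset
    wavelength_um: tuple[float, float] = (250.0, 450.0)  # tortuosity wavelength


def default_regions() -> list[RegionSpec]:
    """Three-region layout: tumour core, invasive margin, normal tissue.

    Ordering of the defaults encodes the expected biology: the invasive
    margin carries the densest, most branched, most tortuous and most
    disordered microvasculature, with the largest calibres.
    """
    return [
        RegionSpec("core", n_seeds=3, branch_prob=0.02, tortuosity=0.15,
                   direction_jitter=0.15, radius_um=(6.0, 10.0),
                   speed_mm_s=(3.0, 6.0), branch_angle=(0.2, 0.4)),
        RegionSpec("invasive", n_seeds=8, branch_prob=0.10, tortuosity=0.55,
                   direction_jitter=0.70, radius_um=(8.0, 16.0),
                   speed_mm_s=(4.0, 8.0), branch_angle=(0.5, 1.0),
                   wavelength_um=(120.0, 250.0)),
        RegionSpec("normal", n_seeds=3, branch_prob=0.01, tortuosity=0.10,
                   direction_jitter=0.15, radius_um=(5.0, 9.0),
                   speed_mm_s=(2.0, 5.0), branch_angle=(0.2, 0.4)),
    ]


def two_region_config() -> list[RegionSpec]:
    """Core-like vs invasive-like halves, for recovery experiments."""
    regions = default_regions()
    return [regions[0], regions[1]]


@dataclass
class VesselSegment:
    points_um: np.ndarray       # (n, 2) centreline, columns (x, y) in um
    radius_um: float
    mean_speed_mm_s: float
    region: int                 # index into VascularPhantom.region_names

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=np.float64)
        if self.radius_um <= 0 or self.mean_speed_mm_s <= 0:
            raise ValueError("radius and speed must be positive")

    @property
    def path_length_um(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points_um, axis=0).T)))

    @property
    def chord_length_um(self) -> float:
        return float(np.hypot(*(self.points_um[-1] - self.points_um[0])))

    @property
    def step_directions(self) -> np.ndarray:
        d = np.diff(self.points_um, axis=0)
        return np.arctan2(d[:, 1], d[:, 0])


@dataclass
class VascularPhantom:
    segments: list[VesselSegment]
    region_label_map: np.ndarray        # (H, W) int, index into region_names
    region_names: list[str]
    pixel_size_um: float
    branch_points_um: np.ndarray = field(default=None)  # (k, 2); truth branch sites

    def __post_init__(self) -> None:
        if self.branch_points_um is None:
            self.branch_points_um = np.zeros((0, 2))
        self.branch_points_um = np.asarray(self.branch_points_um, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.region_label_map.shape

    def region_mask(self, name: str) -> np.ndarray:
        return self.region_label_map == self.region_names.index(name)


@dataclass
class Bubble:
    frames: np.ndarray          # (n,) consecutive frame indices
    xy_um: np.ndarray           # (n, 2)
    speed_mm_s: float           # constant advection speed of this bubble
    segment: int                # index of the host vessel segment
    arclength_um: np.ndarray = None     # (n,) position along the centreline

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class BubbleTrajectorySet:
    """Ground-truth bubble paths; the oracle for tracking recovery."""

    bubbles: list[Bubble]
    frame_rate_hz: float
    n_frames: int


# ---------------------------------------------------------------------------
# phantom generation

def generate_phantom(
    regions: list[RegionSpec] | None = None,
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 10.0,
    seed: int = 0,
    step_px: float = 1.2,
    max_steps: int = 140,
    max_segments_per_seed: int = 3,
) -> VascularPhantom:
    """Grow a vascular network by a branching, biased-persistent random walk.

    The field of view is split into vertical bands, one per region (left to
    right in the order given).  Each seed starts a walker at a random point in
    its band heading roughly along +y; the heading is perturbed sinusoidally
    (tortuosity) and the walker may spawn a branch at each step.  Walkers die
    when they leave their band or the grid, so every segment belongs to
    exactly one region.  Deterministic for a fixed seed.
    """
    if regions is None:
        regions = default_regions()
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError("grid must be at least 64 x 64 pixels")
    if all(r.n_seeds == 0 for r in regions):
        raise ValueError("degenerate config: zero seeds in every region")
    for r in regions:
        if not (0.0 <= r.branch_prob <= 1.0):
            raise ValueError("branch probability must be in [0, 1]")

    rng = np.random.default_rng(seed)
    step_um = step_px * pixel_size_um
    band_edges = np.linspace(0, w, len(regions) + 1)
    label_map = np.zeros(shape, dtype=np.int64)
    cols = np.arange(w)
    for i in range(len(regions)):
        label_map[:, (cols >= band_edges[i]) & (cols < band_edges[i + 1])] = i

    segments: list[VesselSegment] = []
    branch_sites: list[np.ndarray] = []
    axis = math.pi / 2.0         # preferred heading: down the image (+y)

    for ridx, spec in enumerate(regions):
        x_lo = band_edges[ridx] * pixel_size_um
        x_hi = band_edges[ridx + 1] * pixel_size_um
        y_hi = (h - 1) * pixel_size_um
        margin = 1.5 * pixel_size_um
        budget = spec.n_seeds * max_segments_per_seed
        queue: list[tuple[np.ndarray, float]] = []
        for _ in range(spec.n_seeds):
            pos = np.array([
                rng.uniform(x_lo + margin, x_hi - margin),
                rng.uniform(0.0, 0.5 * y_hi),
            ])
            theta = axis + rng.normal(0.0, spec.direction_jitter)
            queue.append((pos, theta))
        n_region = 0
        qi = 0
        while qi < len(queue) and n_region < budget:
            pos, theta_base = queue[qi]
            qi += 1
            phase = rng.uniform(0.0, 2.0 * math.pi)
            wavelength = rng.uniform(*spec.wavelength_um)
            pts = [pos.copy()]
            s = 0.0
            for _ in range(max_steps):
                theta = theta_base + spec.tortuosity * math.sin(
                    2.0 * math.pi * s / wavelength + phase)
                pos = pos + step_um * np.array([math.cos(theta), math.sin(theta)])
                s += step_um
                if not (x_lo + margin <= pos[0] <= x_hi - margin
                        and 0.0 <= pos[1] <= y_hi):
                    break
                pts.append(pos.copy())
                if (rng.random() < spec.branch_prob
                        and len(queue) < 4 * budget):
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    child_theta = theta + sign * rng.uniform(*spec.branch_angle)
                    queue.append((pos.copy(), child_theta))
                    branch_sites.append(pos.copy())
            if len(pts) >= 5:
                segments.append(VesselSegment(
                    points_um=np.array(pts),
                    radius_um=rng.uniform(*spec.radius_um),
                    mean_speed_mm_s=rng.uniform(*spec.speed_mm_s),
                    region=ridx,
                ))
                n_region += 1

    if not segments:
        raise ValueError("config produced no vessel segments")
    bp = np.array(branch_sites) if branch_sites else np.zeros((0, 2))
    return VascularPhantom(
        segments=segments,
        region_label_map=label_map,
        region_names=[r.name for r in regions],
        pixel_size_um=pixel_size_um,
        branch_points_um=bp,
    )


def true_vessel_mask(phantom: VascularPhantom) -> np.ndarray:
    """Rasterise the phantom lumen: disks of each segment's radius painted
    along its centreline on the acquisition grid."""
    h, w = phantom.shape
    px = phantom.pixel_size_um
    mask = np.zeros((h, w), dtype=bool)
    for seg in phantom.segments:
        r_px = max(seg.radius_um / px, 0.5)
        rad = int(math.ceil(r_px))
        dy, dx = np.mgrid[-rad:rad + 1, -rad:rad + 1]
        disk = dy * dy + dx * dx <= r_px * r_px
        for x_um, y_um in seg.points_um:
            cx = int(round(x_um / px))
            cy = int(round(y_um / px))
            y0, y1 = max(cy - rad, 0), min(cy + rad + 1, h)
            x0, x1 = max(cx - rad, 0), min(cx + rad + 1, w)
            if y0 >= y1 or x0 >= x1:
                continue
            mask[y0:y1, x0:x1] |= disk[y0 - (cy - rad):y1 - (cy - rad),
                                       x0 - (cx - rad):x1 - (cx - rad)]
    return mask


# ---------------------------------------------------------------------------
# bubble flow

def poiseuille_speed(mean_speed: float, rho: float, radius: float) -> float:
    """Axial speed at radial position rho in a cylindrical Poiseuille profile.

    Parabolic across the lumen: 2 v_mean (1 - (rho/R)^2); twice the mean on
    the centreline, zero at the wall (no slip).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 2.0 * mean_speed * (1.0 - (rho / radius) ** 2)


def _arclength_param(points: np.ndarray):
    steps = np.hypot(*np.diff(points, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    return cum


def _point_and_normal(points: np.ndarray, cum: np.ndarray, s: float):
    """Centreline point and unit normal at arclength s (linear interpolation)."""
    i = int(np.searchsorted(cum, s, side="right")) - 1
    i = min(max(i, 0), len(points) - 2)
    seg_len = cum[i + 1] - cum[i]
    t = 0.0 if seg_len == 0 else (s - cum[i]) / seg_len
    p = points[i] + t * (points[i + 1] - points[i])
    d = points[i + 1] - points[i]
    norm = np.hypot(d[0], d[1])
    tangent = d / norm if norm > 0 else np.array([1.0, 0.0])
    normal = np.array([-tangent[1], tangent[0]])
    return p, normal


def simulate_bubble_flow(
    phantom: VascularPhantom,
    bubbles_per_frame: float = 0.8,
    n_frames: int = 2000,
    frame_rate_hz: float = 1000.0,
    seed: int = 0,
    min_speed_mm_s: float = 0.5,
) -> BubbleTrajectorySet:
    """Advect microbubbles through the phantom under Poiseuille flow.

    Arrivals are Poisson per frame; each bubble enters at the start of a
    segment chosen with probability proportional to its volumetric flux
    (pi r^2 v).  The radial position rho is sampled uniformly over the
    circular cross-section (rho = R sqrt(U)), giving an axial speed
    2 v_mean (1 - rho^2/R^2) — zero at the wall, 2 v_mean on the centreline,
    and mean equal to v_mean over the lumen.  The bubble's 2D position is the
    centreline point offset laterally by the projected radial coordinate.
    """
    if n_frames < 1:
        raise ValueError("duration must be at least 1 frame")
    if bubbles_per_frame <= 0:
        raise ValueError("bubble arrival rate must be positive")
    if not phantom.segments:
        raise ValueError("phantom has no vessel segments")

    rng = np.random.default_rng(seed)
    h, w = phantom.shape
    px = phantom.pixel_size_um
    x_max, y_max = (w - 1) * px, (h - 1) * px

    cums = [_arclength_param(s.points_um) for s in phantom.segments]
    flux = np.array([math.pi * s.radius_um ** 2 * s.mean_speed_mm_s
                     for s in phantom.segments])
    p_seg = flux / flux.sum()

    bubbles: list[Bubble] = []
    for t0 in range(n_frames):
        for _ in range(rng.poisson(bubbles_per_frame)):
            si = int(rng.choice(len(phantom.segments), p=p_seg))
            seg = phantom.segments[si]
            cum = cums[si]
            total = cum[-1]
            rho = seg.radius_um * math.sqrt(rng.random())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            lateral = rho * math.cos(phi)
            speed = poiseuille_speed(seg.mean_speed_mm_s, rho, seg.radius_um)
            if speed <= min_speed_mm_s:
                # near-wall bubbles are quasi-static: indistinguishable from
                # tissue clutter and never tracked in practice
                continue
            step = speed * 1000.0 / frame_rate_hz        # um per frame
            frames, pts, ss = [], [], []
            s = 0.0
            t = t0
            while s <= total and t < n_frames:
                p, n = _point_and_normal(seg.points_um, cum, s)
                pos = p + lateral * n
                if 0.0 <= pos[0] <= x_max and 0.0 <= pos[1] <= y_max:
                    frames.append(t)
                    pts.append(pos)
                    ss.append(s)
                else:
                    break
                s += step
                t += 1
            if len(frames) >= 1:
                bubbles.append(Bubble(
                    frames=np.array(frames, dtype=np.int64),
                    xy_um=np.array(pts),
                    speed_mm_s=speed,
                    segment=si,
                    arclength_um=np.array(ss),
                ))
    return BubbleTrajectorySet(bubbles=bubbles, frame_rate_hz=frame_rate_hz,
                               n_frames=n_frames)


# ---------------------------------------------------------------------------
# movie rendering

def _smooth_spatial_mode(shape, rng, sigma_frac=0.12, zero_mean=False):
    f = gaussian_filter(rng.normal(size=shape), sigma=sigma_frac * min(shape))
    if zero_mean:
        f -= f.mean()
        peak = np.abs(f).max()
        return f / peak if peak > 0 else f
    f -= f.min()
    peak = f.max()
    f = f / peak if peak > 0 else f + 1.0
    return 0.3 + 0.7 * f        # strictly positive tissue brightness


def render_movie(
    trajectories: BubbleTrajectorySet,
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 10.0,
    psf_sigma_um: float = 20.0,
    clutter_rank: int = 0,
    clutter_amplitude: float = 0.0,
    clutter_drift_rate: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> FrameStack:
    """Render bubble trajectories into a movie with tissue clutter and noise.

    Each bubble is an isotropic Gaussian spot of unit peak amplitude.  Tissue
    clutter is a rank-``clutter_rank`` spatiotemporal field: smooth positive
    spatial modes times slowly oscillating temporal modes, scaled so the
    brightest clutter value is ``clutter_amplitude`` times the bubble peak.
    ``clutter_drift_rate`` scales the temporal oscillation frequency (cycles
    over the movie).  Additive Gaussian noise is clipped at zero (envelope
    data are non-negative).
    """
    if psf_sigma_um <= 0:
        raise ValueError("psf_sigma must be positive")
    if clutter_amplitude < 0:
        raise ValueError("clutter amplitude ratio must be >= 0")
    h, w = shape
    t_n = trajectories.n_frames
    rng = np.random.default_rng(seed)
    frames = np.zeros((t_n, h, w), dtype=np.float64)

    sigma_px = psf_sigma_um / pixel_size_um
    rad = int(math.ceil(4.0 * sigma_px))
    for b in trajectories.bubbles:
        for fi, (x_um, y_um) in zip(b.frames, b.xy_um):
            cx = x_um / pixel_size_um
            cy = y_um / pixel_size_um
            x0 = max(int(math.floor(cx)) - rad, 0)
            x1 = min(int(math.floor(cx)) + rad + 1, w)
            y0 = max(int(math.floor(cy)) - rad, 0)
            y1 = min(int(math.floor(cy)) + rad + 1, h)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1) - cx
            ys = np.arange(y0, y1) - cy
            spot = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2)
                          / (2.0 * sigma_px ** 2))
            frames[fi, y0:y1, x0:x1] += spot

    if clutter_rank > 0 and clutter_amplitude > 0:
        # mode 0: bright quasi-static tissue; higher modes: weaker zero-mean
        # spatial patterns oscillating slowly (tissue motion).  Relative mode
        # amplitudes are kept within about an order of magnitude so the
        # singular spectrum shows a clutter plateau followed by a sharp drop
        # to the bubble/noise level.  The sum stays positive, so no clipping
        # disturbs the exact rank of the clutter term.
        clutter = np.zeros((t_n, h, w))
        tt = np.arange(t_n) / max(t_n, 1)
        for k in range(clutter_rank):
            cycles = clutter_drift_rate * rng.uniform(0.5, 2.0)
            phase = rng.uniform(0.0, 2.0 * math.pi)
            if k == 0:
                spatial = _smooth_spatial_mode((h, w), rng)
                temporal = 1.0 + 0.15 * np.sin(2.0 * math.pi * cycles * tt + phase)
            else:
                spatial = _smooth_spatial_mode((h, w), rng, zero_mean=True)
                temporal = 0.25 * np.sin(2.0 * math.pi * cycles * tt + phase)
            clutter += temporal[:, None, None] * spatial[None, :, :]
        clutter *= clutter_amplitude / clutter.max()
        frames += clutter

    if noise_sigma > 0:
        frames += rng.normal(0.0, noise_sigma, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)

    return FrameStack(frames=frames, pixel_size_um=pixel_size_um,
                      frame_rate_hz=trajectories.frame_rate_hz)


# ---------------------------------------------------------------------------
# analytic truth metrics

def phantom_truth_metrics(phantom: VascularPhantom, roi: np.ndarray | str):
    """True region metrics computed from the phantom geometry directly.

    ``roi`` is a boolean mask on the acquisition grid or a region name.
    Segments are assigned to the ROI containing the majority of their
    centreline points.  No imaging or skeletonisation is involved, so this is
    the oracle against which pipeline recovery is tested.
    """
    if isinstance(roi, str):
        roi = phantom.region_mask(roi)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != phantom.shape:
        raise ValueError("roi shape must match the phantom grid")
    if not roi.any():
        raise ValueError("empty ROI")

    px = phantom.pixel_size_um
    h, w = phantom.shape

    def in_roi_frac(points_um: np.ndarray) -> float:
        c = np.clip(np.round(points_um / px).astype(int), 0, [w - 1, h - 1])
        return float(np.mean(roi[c[:, 1], c[:, 0]]))

    segs = [s for s in phantom.segments if in_roi_frac(s.points_um) > 0.5]
    mask = true_vessel_mask(phantom)
    density = float(np.sum(mask & roi) / np.sum(roi))

    if not segs:
        return _metrics.RegionMetrics(
            density=density, diameter_um=0.0, branches=0, branch_points=0,
            curvature=0.0, fractal_dimension=0.0, orientation_variance=0.0,
            velocity_mm_s=0.0, flow_volume_nl_s=0.0, has_vessels=False)

    curvatures, curv_w = [], []
    for s in segs:
        chord = s.chord_length_um
        if chord > 0:
            curvatures.append(s.path_length_um / chord)
            curv_w.append(s.path_length_um)
    directions = np.concatenate([s.step_directions for s in segs])

    bp = phantom.branch_points_um
    if len(bp):
        c = np.clip(np.round(bp / px).astype(int), 0, [w - 1, h - 1])
        n_branch_points = int(np.sum(roi[c[:, 1], c[:, 0]]))
    else:
        n_branch_points = 0

    roi_mask = mask & roi
    fd = _metrics.fractal_dimension(roi_mask).fd if roi_mask.any() else 0.0

    q_total = sum(_metrics.flow_volume(2.0 * s.radius_um, s.mean_speed_mm_s)
                  for s in segs)
    return _metrics.RegionMetrics(
        density=density,
        diameter_um=float(np.mean([2.0 * s.radius_um for s in segs])),
        branches=len(segs),
        branch_points=n_branch_points,
        curvature=(float(np.average(curvatures, weights=curv_w))
                   if curvatures else 0.0),
        fractal_dimension=float(fd),
        orientation_variance=float(_metrics.orientation_variance(directions)),
        velocity_mm_s=float(np.mean([s.mean_speed_mm_s for s in segs])),
        flow_volume_nl_s=float(q_total),
        has_vessels=True,
    )
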