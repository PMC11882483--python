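"""Structural, hemodynamic and functional vascular metrics.

Per-segment quantities:

* curvature (tortuosity)  — path length over chord length, Lc / L, >= 1;
* diameter                — from the distance transform along the centreline;
* flow volume             — Q = A x V with A = pi (d/2)^2 under the
                            Poiseuille (cylindrical lumen) assumption.

Per-region quantities add vascular density (vessel-area fraction of the ROI),
branch/branch-point counts, the box-counting fractal dimension of the vessel
mask, the orientation variance of flow directions, and the mean velocity.
Histology-style mask indices (vascular density VD-H and maturity index VMI-H)
are provided for co-registered binary masks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .graph import VesselGraph
    from .maps import SuperResMaps

__all__ = [
    "SegmentMetrics", "RegionMetrics", "HistologyIndices", "FractalFit",
    "curvature", "fractal_dimension", "orientation_variance", "flow_volume",
    "vascular_density", "region_metrics", "histology_mask_metrics",
]

UM3_PER_NL = 1.0e6  # 1 nL = 1e-9 L = 1e6 um^3


@dataclass
class SegmentMetrics:
    segment_id: int
    curvature: float            # dimensionless, >= 1
    diameter_um: float
    velocity_mm_s: float
    flow_volume_nl_s: float


@dataclass
class RegionMetrics:
    """The nine quantities compared across tissue regions."""

    density: float              # vessel-area fraction of the ROI, in [0, 1]
    diameter_um: float
    branches: int
    branch_points: int
    curvature: float
    fractal_dimension: float
    orientation_variance: float  # rad^2
    velocity_mm_s: float
    flow_volume_nl_s: float
    has_vessels: bool = True

    _FIELDS = ("density", "diameter_um", "branches", "branch_points",
               "curvature", "fractal_dimension", "orientation_variance",
               "velocity_mm_s", "flow_volume_nl_s")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._FIELDS}


@dataclass
class HistologyIndices:
    vd_h: float                 # CD31-positive area fraction of the region
    vmi_h: float                # aSMA-co-positive fraction of CD31 area (nan if undefined)


@dataclass
class FractalFit:
    fd: float
    r2: float
    scales: np.ndarray          # box sizes used for the fit (px)
    flagged: bool               # True if no sub-range reached the R2 criterion


def curvature(path_length_um: float, chord_length_um: float) -> float:
    """Tortuosity of a vessel segment: actual path length over the straight
    distance between its endpoints.  1 for a straight segment."""
    if chord_length_um <= 0:
        raise ValueError("chord length must be positive (closed loops are "
                         "excluded from curvature statistics)")
    return float(path_length_um) / float(chord_length_um)


def _box_count(mask: np.ndarray, r: int) -> int:
    h, w = mask.shape
    hp, wp = -(-h // r) * r, -(-w // r) * r
    padded = np.zeros((hp, wp), dtype=bool)
    padded[:h, :w] = mask
    blocks = padded.reshape(hp // r, r, wp // r, r)
    return int(blocks.any(axis=(1, 3)).sum())


def fractal_dimension(
    mask: np.ndarray,
    scales: np.ndarray | None = None,
    r2_min: float = 0.99,
    min_range: int = 4,
) -> FractalFit:
    """Box-counting fractal dimension of a binary mask.

    M(r) is the number of r x r grid boxes (anchored at the array origin)
    containing at least one foreground pixel; the dimension is the slope of
    the least-squares fit of log M(r) against log(1/r).  Among all contiguous
    sub-ranges of at least ``min_range`` scales, the one with the highest R^2
    above ``r2_min`` is used; if none qualifies the best-R^2 sub-range is
    used and the result is flagged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no fractal dimension")
    if scales is None:
        r_max = min(mask.shape) // 4
        scales = []
        r = 2
        while r <= r_max:
            scales.append(r)
            r *= 2
        scales = np.array(scales, dtype=int)
    else:
        scales = np.sort(np.asarray(scales, dtype=int))
    if len(scales) < min_range:
        raise ValueError(f"need at least {min_range} box scales")

    counts = np.array([_box_count(mask, int(r)) for r in scales], dtype=float)
    log_inv_r = np.log(1.0 / scales.astype(float))
    log_m = np.log(counts)

    def fit(i, j):
        x, y = log_inv_r[i:j], log_m[i:j]
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot <= 1e-30:
            r2 = 1.0 if np.sum(resid ** 2) <= 1e-30 else 0.0
        else:
            r2 = 1.0 - np.sum(resid ** 2) / ss_tot
        return slope, r2

    best = None          # (r2, slope, i, j), among sub-ranges meeting r2_min
    fallback = None
    n = len(scales)
    for i in range(n):
        for j in range(i + min_range, n + 1):
            slope, r2 = fit(i, j)
            cand = (r2, j - i, slope, i, j)
            if fallback is None or cand[:2] > fallback[:2]:
                fallback = cand
            if r2 > r2_min and (best is None or cand[:2] > best[:2]):
                best = cand
    chosen, flagged = (best, False) if best is not None else (fallback, True)
    r2, _, slope, i, j = chosen
    return FractalFit(fd=float(slope), r2=float(r2),
                      scales=scales[i:j].copy(), flagged=flagged)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap into (-pi, pi]."""
    out = np.mod(-np.asarray(a) + math.pi, 2.0 * math.pi)
    return math.pi - out


def circular_mean(angles: np.ndarray, weights: np.ndarray | None = None) -> float:
    angles = np.asarray(angles, dtype=np.float64)
    w = np.ones_like(angles) if weights is None else np.asarray(weights, float)
    return float(np.arctan2(np.sum(w * np.sin(angles)), np.sum(w * np.cos(angles))))


def orientation_variance(
    directions: np.ndarray,
    weights: np.ndarray | None = None,
    axial: bool = False,
) -> float:
    """Dispersion of vessel/flow directions about their circular mean.

    Returns (1/N) sum wrap(theta_i - theta_bar)^2 in rad^2, with differences
    wrapped into (-pi, pi] so that nearly parallel directions on either side
    of the +-pi seam count as nearly parallel.  ``axial=True`` treats theta
    and theta + pi as the same orientation (angles doubled before wrapping,
    residuals halved after), for use when flow sign is unreliable.
    """
    directions = np.asarray(directions, dtype=np.float64).ravel()
    if directions.size == 0:
        raise ValueError("need at least one direction")
    w = np.ones_like(directions) if weights is None else np.asarray(weights, float).ravel()
    if axial:
        d2 = 2.0 * directions
        mean2 = circular_mean(d2, w)
        resid = _wrap_angle(d2 - mean2) / 2.0
    else:
        mean = circular_mean(directions, w)
        resid = _wrap_angle(directions - mean)
    return float(np.sum(w * resid ** 2) / np.sum(w))


def flow_volume(diameter_um: float, velocity_mm_s: float) -> float:
    """Blood flow volume Q = A x V in nL/s, assuming a cylindrical lumen.

    A = pi (d/2)^2 in um^2, V converted to um/s; 1 nL = 1e6 um^3.
    """
    if diameter_um < 0 or velocity_mm_s < 0:
        raise ValueError("diameter and velocity must be non-negative")
    area_um2 = math.pi * (diameter_um / 2.0) ** 2
    q_um3_s = area_um2 * velocity_mm_s * 1000.0
    return q_um3_s / UM3_PER_NL


def vascular_density(mask: np.ndarray, roi: np.ndarray) -> float:
    """Vessel-area fraction: |mask AND roi| / |roi|."""
    mask = np.asarray(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    return float(np.sum(mask & roi) / n_roi)


def segment_metrics(graph: "VesselGraph", maps: "SuperResMaps") -> list[SegmentMetrics]:
    """Per-segment curvature, diameter, velocity and flow volume.

    Velocity is the mean of velocity-map values along the segment centreline;
    segments whose chord is zero (closed loops) get curvature nan.
    """
    out = []
    vel = maps.velocity
    for seg in graph.segments:
        rr, cc = seg.path_rc[:, 0], seg.path_rc[:, 1]
        v_vals = vel[rr, cc]
        v = float(np.nanmean(v_vals)) if np.any(np.isfinite(v_vals)) else 0.0
        curv = (seg.lc_um / seg.l_um) if seg.l_um > 0 else float("nan")
        d = seg.diameter_um if seg.diameter_um is not None else float("nan")
        q = flow_volume(d, v) if np.isfinite(d) else float("nan")
        out.append(SegmentMetrics(segment_id=seg.id, curvature=curv,
                                  diameter_um=d, velocity_mm_s=v,
                                  flow_volume_nl_s=q))
    return out


def region_metrics(
    maps: "SuperResMaps",
    graph: "VesselGraph",
    mask: np.ndarray,
    roi: np.ndarray,
) -> RegionMetrics:
    """Aggregate the nine region parameters for one ROI.

    All inputs live on the super-resolution grid.  Segments are assigned to
    the ROI containing the majority of their centreline pixels; branches is
    the number of assigned segments and branch points the number of branch
    nodes inside the ROI.  An ROI with no vessel pixels yields all-zero
    metrics with ``has_vessels=False`` rather than an error.
    """
    roi = np.asarray(roi, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if roi.shape != mask.shape or roi.shape != maps.density.shape:
        raise ValueError("maps, mask and roi must share the super-res grid")
    density = vascular_density(mask, roi)
    roi_mask = mask & roi
    if not roi_mask.any():
        return RegionMetrics(density=0.0, diameter_um=0.0, branches=0,
                             branch_points=0, curvature=0.0,
                             fractal_dimension=0.0, orientation_variance=0.0,
                             velocity_mm_s=0.0, flow_volume_nl_s=0.0,
                             has_vessels=False)

    segs = [s for s in graph.segments
            if np.mean(roi[s.path_rc[:, 0], s.path_rc[:, 1]]) > 0.5]
    n_bp = sum(1 for node in graph.nodes
               if node.kind == "branch_point"
               and roi[min(int(round(node.yx[0])), roi.shape[0] - 1),
                       min(int(round(node.yx[1])), roi.shape[1] - 1)])

    per_seg = segment_metrics(graph, maps)
    by_id = {m.segment_id: m for m in per_seg}
    assigned = [by_id[s.id] for s in segs]
    # curvature is averaged with path-length weights: short inter-branch
    # fragments carry no tortuosity information and would dilute the mean
    curvs, curv_w = [], []
    for s, m in zip(segs, assigned):
        if np.isfinite(m.curvature):
            curvs.append(m.curvature)
            curv_w.append(s.lc_um)
    diams = [m.diameter_um for m in assigned if np.isfinite(m.diameter_um)]
    q_tot = float(np.nansum([m.flow_volume_nl_s for m in assigned])) if assigned else 0.0

    fd = fractal_dimension(roi_mask).fd

    defined = (maps.density > 0) & roi
    if defined.any():
        ov = orientation_variance(maps.direction[defined])
        v_mean = float(np.mean(maps.velocity[defined]))
    else:
        ov, v_mean = 0.0, 0.0

    return RegionMetrics(
        density=density,
        diameter_um=float(np.mean(diams)) if diams else 0.0,
        branches=len(segs),
        branch_points=n_bp,
        curvature=float(np.average(curvs, weights=curv_w)) if curvs else 0.0,
        fractal_dimension=float(fd),
        orientation_variance=float(ov),
        velocity_mm_s=v_mean,
        flow_volume_nl_s=q_tot,
        has_vessels=True,
    )


def histology_mask_metrics(
    cd31_mask: np.ndarray,
    asma_mask: np.ndarray,
    region_mask: np.ndarray,
) -> HistologyIndices:
    """VD-H and VMI-H from co-registered binary immunostain masks.

    VD-H = CD31-positive area / region area.  VMI-H = area positive for both
    CD31 and aSMA / CD31-positive area (the mural-cell-covered, i.e. mature,
    fraction of the endothelium).  VMI-H is nan when the region contains no
    CD31 signal.
    """
    cd31 = np.asarray(cd31_mask, dtype=bool)
    asma = np.asarray(asma_mask, dtype=bool)
    region = np.asarray(region_mask, dtype=bool)
    if cd31.shape != asma.shape or cd31.shape != region.shape:
        raise ValueError("masks must share one grid")
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("empty region mask")
    n_cd31 = int(np.sum(cd31 & region))
    vd_h = n_cd31 / n_region
    if n_cd31 == 0:
        return HistologyIndices(vd_h=vd_h, vmi_h=float("nan"))
    vmi_h = float(np.sum(cd31 & asma & region)) / n_cd31
    return HistologyIndices(vd_h=vd_h, vmi_h=vmi_h)
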