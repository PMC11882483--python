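"""Vessel segmentation, skeletonization and graph extraction.

The density map is binarized by a deterministic rule (default: at least k
localizations per super-res pixel, followed by morphological closing and
small-object removal), thinned to a one-pixel skeleton, and decomposed into a
graph: branch points (clusters of skeleton pixels with >= 3 skeleton
neighbours, merged into single nodes), endpoints (exactly one neighbour), and
segments (maximal 8-connected skeleton paths between nodes).  Per-segment
path length Lc, chord length L and distance-transform diameters feed the
morphometric stage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, skeletonize

__all__ = [
    "VesselMask", "GraphNode", "GraphSegment", "VesselGraph",
    "binarize_density", "condition_mask", "skeletonize_mask", "extract_graph",
    "estimate_diameters",
]

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_LC_WAYPOINT_PX = 4     # waypoint spacing for path-length estimation


@dataclass
class VesselMask:
    mask: np.ndarray                # bool, super-res grid
    rule: str
    params: dict


@dataclass
class GraphNode:
    id: int
    yx: tuple[float, float]         # (row, col), cluster centroid for branch points
    kind: str                       # "branch_point" | "endpoint"
    pixels: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GraphSegment:
    id: int
    path_rc: np.ndarray             # (n, 2) ordered skeleton pixels (row, col)
    node_a: int
    node_b: int
    lc_um: float                    # path length along the polyline
    l_um: float                     # straight distance between the end pixels
    radii_um: np.ndarray | None = None      # per-point lumen radius
    diameter_um: float | None = None


@dataclass
class VesselGraph:
    nodes: list[GraphNode]
    segments: list[GraphSegment]
    pixel_size_um: float            # super-res pixel size
    shape: tuple[int, int]
    skeleton: np.ndarray = field(default=None, repr=False)

    @property
    def branch_points(self) -> list[GraphNode]:
        return [n for n in self.nodes if n.kind == "branch_point"]

    @property
    def endpoints(self) -> list[GraphNode]:
        return [n for n in self.nodes if n.kind == "endpoint"]


def binarize_density(
    density: np.ndarray,
    k: int = 2,
    min_size: int = 25,
    closing_radius: int = 1,
) -> VesselMask:
    """Binarize a super-res density map: vessel where >= k localizations fell.

    Closing (disk radius ``closing_radius``) bridges single-pixel sampling
    gaps; connected components smaller than ``min_size`` pixels are removed
    as localization noise.  An all-zero map yields an empty (valid) mask.
    """
    density = np.asarray(density)
    if np.any(density < 0):
        raise ValueError("density map must be non-negative")
    mask = density >= k
    if mask.any():
        if closing_radius > 0:
            mask = ndimage.binary_closing(mask, structure=disk(closing_radius))
        if min_size > 1:
            labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
            if n:
                sizes = np.bincount(labels.ravel())
                keep = np.nonzero(sizes >= min_size)[0]
                mask = np.isin(labels, keep[keep != 0])
    return VesselMask(mask=mask, rule="count",
                      params={"k": k, "min_size": min_size,
                              "closing_radius": closing_radius})


def condition_mask(
    mask: VesselMask | np.ndarray,
    opening_radius: int = 2,
    max_hole_px: int = 100,
) -> np.ndarray:
    """Morphological conditioning of a vessel mask before skeletonization.

    Count-thresholded ULM masks carry speckle: ragged lumen edges and small
    enclosed holes where bubble coverage is incomplete.  Thinning such a mask
    yields a thicket of spurious branches and loops.  Conditioning fills
    enclosed background components up to ``max_hole_px`` pixels (real
    inter-vessel gaps are much larger) and opens with a disk of
    ``opening_radius`` to remove strands thinner than the narrowest real
    vessel.  Use radius 0 to keep single-pixel-wide structures.
    """
    m = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, dtype=bool)
    if max_hole_px > 0 and m.any():
        inv_lab, n = ndimage.label(~m)
        if n:
            sizes = np.bincount(inv_lab.ravel())
            # never fill components touching the border (outside background)
            border = np.unique(np.concatenate([
                inv_lab[0], inv_lab[-1], inv_lab[:, 0], inv_lab[:, -1]]))
            fillable = (sizes <= max_hole_px)
            fillable[border] = False
            fillable[0] = False
            m = m | np.isin(inv_lab, np.nonzero(fillable)[0])
    if opening_radius > 0:
        m = ndimage.binary_opening(m, structure=disk(opening_radius))
    return m


def skeletonize_mask(mask: VesselMask | np.ndarray) -> np.ndarray:
    """One-pixel-wide, topology-preserving medial representation (2D thinning)."""
    m = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, dtype=bool)
    # Lee's method leaves cleaner line terminations than Zhang's on blunt
    # vessel ends (no tip hooks)
    return skeletonize(m, method="lee").astype(bool)


def _neighbor_degree(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant") * skel


def extract_graph(
    skeleton: np.ndarray,
    pixel_size_um: float,
    prune_px: int = 3,
) -> VesselGraph:
    """Decompose a skeleton into nodes and measurable segments.

    Adjacent high-degree pixels are merged into one branch node (junctions of
    thick vessels thin into small clusters).  Segment Lc sums per-step pixel
    distances (1 or sqrt 2); L is the Euclidean distance between the two
    attachment pixels, so a loop closing on one node keeps the distance
    between its distinct attachment pixels (possibly 0, in which case the
    segment is excluded from curvature statistics downstream).  Terminal
    spurs shorter than ``prune_px`` skeleton pixels are dropped.
    """
    skel = np.asarray(skeleton, dtype=bool)
    h, w = skel.shape
    deg = _neighbor_degree(skel)
    branch_px = skel & (deg >= 3)
    end_px = skel & (deg == 1)

    node_id_map = np.full((h, w), -1, dtype=np.int64)
    nodes: list[GraphNode] = []
    labels, n_clusters = ndimage.label(branch_px, structure=np.ones((3, 3)))
    for lbl in range(1, n_clusters + 1):
        rc = np.argwhere(labels == lbl)
        nid = len(nodes)
        node_id_map[rc[:, 0], rc[:, 1]] = nid
        nodes.append(GraphNode(id=nid, yx=(float(rc[:, 0].mean()),
                                           float(rc[:, 1].mean())),
                               kind="branch_point",
                               pixels=[tuple(map(int, p)) for p in rc]))
    for r, c in np.argwhere(end_px):
        nid = len(nodes)
        node_id_map[r, c] = nid
        nodes.append(GraphNode(id=nid, yx=(float(r), float(c)),
                               kind="endpoint", pixels=[(int(r), int(c))]))

    is_node = node_id_map >= 0
    visited = np.zeros((h, w), dtype=bool)
    segments: list[GraphSegment] = []
    seen_node_links: set[tuple] = set()

    def neighbors(r, c):
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                yield rr, cc

    def add_segment(path, nid_a, nid_b):
        # Lc from waypoints a few pixels apart rather than per-pixel chain
        # steps: the digital staircase inflates chain length by up to ~8%
        # for oblique straight lines, which would swamp real tortuosity.
        path = np.asarray(path)
        wp = path[::_LC_WAYPOINT_PX].astype(float)
        if not np.array_equal(wp[-1], path[-1]):
            wp = np.vstack([wp, path[-1]])
        lc = float(np.sum(np.hypot(*np.diff(wp, axis=0).T)))
        l = float(np.hypot(*(path[-1] - path[0]).astype(float)))
        segments.append(GraphSegment(
            id=len(segments), path_rc=path, node_a=nid_a, node_b=nid_b,
            lc_um=lc * pixel_size_um, l_um=l * pixel_size_um))

    node_pixels = np.argwhere(is_node)
    for r, c in node_pixels:
        nid = node_id_map[r, c]
        for rr, cc in neighbors(r, c):
            if is_node[rr, cc]:
                oid = node_id_map[rr, cc]
                if oid == nid:
                    continue
                key = (min(nid, oid), max(nid, oid), min((r, c), (rr, cc)),
                       max((r, c), (rr, cc)))
                if key in seen_node_links:
                    continue
                seen_node_links.add(key)
                add_segment([(r, c), (rr, cc)], nid, oid)
            elif not visited[rr, cc]:
                path = [(r, c), (rr, cc)]
                visited[rr, cc] = True
                prev, cur = (r, c), (rr, cc)
                end_nid = None
                while True:
                    nxt = [(a, b) for a, b in neighbors(*cur) if (a, b) != prev]
                    # at a diagonal elbow the previous pixel's orthogonal
                    # neighbour may also touch: drop already-consumed pixels
                    nxt = [p for p in nxt
                           if not (not is_node[p] and visited[p])]
                    nxt_nodes = [p for p in nxt if is_node[p]]
                    if nxt_nodes:
                        # prefer a node pixel not belonging to the start node
                        others = [p for p in nxt_nodes
                                  if node_id_map[p] != nid or len(path) > 2]
                        target = others[0] if others else nxt_nodes[0]
                        path.append(target)
                        end_nid = node_id_map[target]
                        break
                    if not nxt:
                        end_nid = None       # dead end without an endpoint node
                        break
                    step = nxt[0]
                    path.append(step)
                    visited[step] = True
                    prev, cur = cur, step
                if end_nid is None:
                    # terminate with a synthetic endpoint at the last pixel
                    end_nid = len(nodes)
                    nodes.append(GraphNode(id=end_nid,
                                           yx=(float(cur[0]), float(cur[1])),
                                           kind="endpoint",
                                           pixels=[(int(cur[0]), int(cur[1]))]))
                    node_id_map[cur] = end_nid
                add_segment(path, nid, end_nid)

    # pure cycles: remaining unvisited degree-2 pixels with no node anywhere
    remaining = skel & ~is_node & ~visited
    for r0, c0 in np.argwhere(remaining):
        if visited[r0, c0]:
            continue
        nid = len(nodes)
        nodes.append(GraphNode(id=nid, yx=(float(r0), float(c0)),
                               kind="endpoint", pixels=[(int(r0), int(c0))]))
        node_id_map[r0, c0] = nid
        path = [(r0, c0)]
        visited[r0, c0] = True
        prev, cur = None, (r0, c0)
        while True:
            nxt = [p for p in neighbors(*cur)
                   if p != prev and not visited[p] and node_id_map[p] < 0]
            if not nxt:
                break
            step = nxt[0]
            path.append(step)
            visited[step] = True
            prev, cur = cur, step
        path.append((r0, c0))       # close the loop
        add_segment(path, nid, nid)

    if prune_px > 0:
        end_kinds = {n.id: n.kind for n in nodes}
        keep = [s for s in segments
                if not (len(s.path_rc) < prune_px
                        and (end_kinds[s.node_a] == "endpoint"
                             or end_kinds[s.node_b] == "endpoint"))]
        for i, s in enumerate(keep):
            s.id = i
        segments = keep

    return VesselGraph(nodes=nodes, segments=segments,
                       pixel_size_um=pixel_size_um, shape=(h, w),
                       skeleton=skel)


def estimate_diameters(mask: VesselMask | np.ndarray, graph: VesselGraph) -> VesselGraph:
    """Attach per-point radii and segment diameters from the distance transform.

    The lumen radius at a centreline pixel is the Euclidean distance to the
    nearest background pixel; the segment diameter is 2 x median radius minus
    one pixel (the centre pixel is counted by the distance transform on both
    sides), floored at one pixel, converted to micrometres.
    """
    m = mask.mask if isinstance(mask, VesselMask) else np.asarray(mask, dtype=bool)
    edt = ndimage.distance_transform_edt(m)
    px = graph.pixel_size_um
    for seg in graph.segments:
        rr, cc = seg.path_rc[:, 0], seg.path_rc[:, 1]
        if not np.all(m[rr, cc]):
            raise ValueError("skeleton pixel outside the vessel mask")
        radii = edt[rr, cc]
        seg.radii_um = radii * px
        seg.diameter_um = max(2.0 * float(np.median(radii)) - 1.0, 1.0) * px
    return graph
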