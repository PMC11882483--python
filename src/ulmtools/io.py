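"""Reading and writing of pipeline artifacts in open formats.

Movies are multi-page TIFF with a JSON sidecar carrying pixel size and frame
rate; localizations, tracks, graphs and metrics are CSV; maps are 32-bit
TIFF with a JSON sidecar.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import FrameStack, Track
from .graph import VesselGraph
from .maps import SuperResMaps

__all__ = [
    "write_stack", "read_stack", "write_tracks", "read_tracks",
    "write_maps", "read_maps", "write_graph", "write_mask", "read_mask",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(path: str | Path, stack: FrameStack, extra: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {"pixel_size_um": stack.pixel_size_um,
            "frame_rate_hz": stack.frame_rate_hz}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return FrameStack(frames=np.asarray(frames, dtype=np.float64),
                      pixel_size_um=float(meta["pixel_size_um"]),
                      frame_rate_hz=float(meta["frame_rate_hz"]))


def write_tracks(path: str | Path, tracks: list[Track], frame_rate_hz: float) -> None:
    rows = []
    for tid, tr in enumerate(tracks):
        if len(tr) >= 2:
            v = np.diff(tr.xy_um, axis=0) * frame_rate_hz / 1000.0
            v = np.vstack([v, v[-1:]])          # last point repeats its step
        else:
            v = np.zeros((len(tr), 2))
        for i in range(len(tr)):
            rows.append((tid, int(tr.frames[i]), tr.xy_um[i, 0], tr.xy_um[i, 1],
                         v[i, 0], v[i, 1], tr.intensity[i]))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                     "vx_mm_s", "vy_mm_s", "intensity"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_tracks(path: str | Path) -> list[Track]:
    df = pd.read_csv(path)
    tracks = []
    for _, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        tracks.append(Track(frames=g["frame"].to_numpy(),
                            xy_um=g[["x_um", "y_um"]].to_numpy(),
                            intensity=g["intensity"].to_numpy()))
    return tracks


def write_maps(outdir: str | Path, maps: SuperResMaps) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "density.tiff", maps.density.astype(np.float32))
    tifffile.imwrite(outdir / "velocity.tiff", maps.velocity.astype(np.float32))
    tifffile.imwrite(outdir / "direction.tiff", maps.direction.astype(np.float32))
    tifffile.imwrite(outdir / "dispersion.tiff", maps.dispersion.astype(np.float32))
    meta = {"grid_factor": maps.grid_factor,
            "pixel_size_um": maps.pixel_size_um,
            "superres_pixel_um": maps.superres_pixel_um}
    (outdir / "maps.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_maps(outdir: str | Path) -> SuperResMaps:
    outdir = Path(outdir)
    meta = json.loads((outdir / "maps.json").read_text())
    return SuperResMaps(
        density=tifffile.imread(outdir / "density.tiff").astype(np.int64),
        velocity=tifffile.imread(outdir / "velocity.tiff").astype(np.float64),
        direction=tifffile.imread(outdir / "direction.tiff").astype(np.float64),
        dispersion=tifffile.imread(outdir / "dispersion.tiff").astype(np.float64),
        grid_factor=int(meta["grid_factor"]),
        pixel_size_um=float(meta["pixel_size_um"]))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.uint8) * 255)


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_graph(outdir: str | Path, graph: VesselGraph) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    px = graph.pixel_size_um
    nodes = pd.DataFrame(
        [(n.id, n.yx[1] * px, n.yx[0] * px, n.kind) for n in graph.nodes],
        columns=["id", "x_um", "y_um", "kind"])
    nodes.to_csv(outdir / "nodes.csv", index=False, float_format="%.3f")
    segs = pd.DataFrame(
        [(s.id, s.node_a, s.node_b, s.lc_um, s.l_um,
          s.diameter_um if s.diameter_um is not None else np.nan,
          len(s.path_rc)) for s in graph.segments],
        columns=["id", "node_a", "node_b", "Lc_um", "L_um", "diameter_um",
                 "n_pixels"])
    segs.to_csv(outdir / "segments.csv", index=False, float_format="%.3f")
    adjacency = {str(s.id): [int(s.node_a), int(s.node_b)] for s in graph.segments}
    (outdir / "adjacency.json").write_text(json.dumps(adjacency, indent=2,
                                                      sort_keys=True))
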