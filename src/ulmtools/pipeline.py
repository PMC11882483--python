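"""End-to-end orchestration: simulate, filter, track, reconstruct, measure, compare.

A single global seed fans out into per-stage child seeds (derived by hashing
the stage name), so stages can be re-run independently yet the whole run is
bit-reproducible.  All intermediates are written in open formats (TIFF, CSV,
JSON) with the fully-resolved configuration serialized next to them.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import metrics as _metrics
from . import phantom as _phantom
from . import stats as _stats
from .clutter import svd_filter
from .graph import (binarize_density, condition_mask, estimate_diameters,
                    extract_graph, skeletonize_mask)
from .localization import link_tracks, localize_stack
from .maps import accumulate_maps

log = logging.getLogger("ulmtools")

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "load_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class SimulateConfig:
    layout: str = "three_region"        # or "two_region"
    shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 10.0
    bubbles_per_frame: float = 0.8
    n_frames: int = 2000
    frame_rate_hz: float = 1000.0
    psf_sigma_um: float = 10.0
    clutter_rank: int = 2
    clutter_amplitude: float = 100.0
    clutter_drift_rate: float = 1.0
    noise_sigma: float = 0.02


@dataclass
class FilterConfig:
    cutoff: int | str = "auto"


@dataclass
class TrackConfig:
    min_track_len: int = 15
    max_link_distance_um: float = 25.0
    nsigma: float = 3.5
    min_separation: int = 3
    half_window: int = 3


@dataclass
class ReconstructConfig:
    grid_factor: int = 8
    interpolate: bool = True


@dataclass
class SegmentConfig:
    k: int = 2
    min_size: int = 25
    closing_radius: int = 1
    opening_radius: int = 2
    max_hole_px: int = 100
    prune_px: int = 8


@dataclass
class RunConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    track: TrackConfig = field(default_factory=TrackConfig)
    reconstruct: ReconstructConfig = field(default_factory=ReconstructConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)


_SECTIONS = {"simulate": SimulateConfig, "filter": FilterConfig,
             "track": TrackConfig, "reconstruct": ReconstructConfig,
             "segment": SegmentConfig}


def _build_section(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    if "shape" in data:
        data = dict(data, shape=tuple(data["shape"]))
    return cls(**data)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; unknown keys are rejected."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        data.update(overrides)
    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {"seed": int(data.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build_section(cls, data.get(name, {}) or {})
    return RunConfig(**kwargs)


def _config_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full pipeline into ``outdir``; returns a result summary.

    Stage order: phantom generation and bubble simulation, movie rendering,
    SVD clutter filtering, localization + tracking, map reconstruction,
    vessel segmentation and graph extraction, per-region metrics, and
    between-region statistics on per-segment values.  Empty intermediates
    (for example no tracks at an extreme minimum track length) propagate as
    flagged empty outputs rather than errors.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(_config_dict(config), indent=2, sort_keys=True, default=str))
    sim = config.simulate

    stage = "simulate"
    log.info("stage %s", stage)
    regions = (_phantom.two_region_config() if sim.layout == "two_region"
               else _phantom.default_regions())
    ph = _phantom.generate_phantom(regions=regions, shape=sim.shape,
                                   pixel_size_um=sim.pixel_size_um,
                                   seed=stage_seed(config.seed, "phantom"))
    traj = _phantom.simulate_bubble_flow(
        ph, bubbles_per_frame=sim.bubbles_per_frame, n_frames=sim.n_frames,
        frame_rate_hz=sim.frame_rate_hz, seed=stage_seed(config.seed, "flow"))
    stack = _phantom.render_movie(
        traj, shape=sim.shape, pixel_size_um=sim.pixel_size_um,
        psf_sigma_um=sim.psf_sigma_um, clutter_rank=sim.clutter_rank,
        clutter_amplitude=sim.clutter_amplitude,
        clutter_drift_rate=sim.clutter_drift_rate,
        noise_sigma=sim.noise_sigma, seed=stage_seed(config.seed, "render"))
    _io.write_stack(outdir / "movie.tiff", stack, extra={"seed": config.seed})
    _io.write_mask(outdir / "true_mask.tiff", _phantom.true_vessel_mask(ph))

    log.info("stage filter")
    filtered, spectrum = svd_filter(stack, cutoff=config.filter.cutoff)
    pd.DataFrame({"singular_value": spectrum.values}).to_csv(
        outdir / "spectrum.csv", index=False, float_format="%.6g")

    log.info("stage track")
    locs = localize_stack(filtered, half_window=config.track.half_window,
                          nsigma=config.track.nsigma,
                          min_separation=config.track.min_separation)
    tracks = link_tracks(locs, config.track.max_link_distance_um,
                         min_track_len=config.track.min_track_len)
    _io.write_tracks(outdir / "tracks.csv", tracks, stack.frame_rate_hz)

    log.info("stage reconstruct")
    maps = accumulate_maps(tracks, shape=sim.shape,
                           pixel_size_um=sim.pixel_size_um,
                           frame_rate_hz=sim.frame_rate_hz,
                           grid_factor=config.reconstruct.grid_factor,
                           interpolate=config.reconstruct.interpolate)
    _io.write_maps(outdir / "maps", maps)

    log.info("stage segment")
    seg_cfg = config.segment
    vmask = binarize_density(maps.density, k=seg_cfg.k,
                             min_size=seg_cfg.min_size,
                             closing_radius=seg_cfg.closing_radius)
    conditioned = condition_mask(vmask, opening_radius=seg_cfg.opening_radius,
                                 max_hole_px=seg_cfg.max_hole_px)
    skel = skeletonize_mask(conditioned)
    vgraph = extract_graph(skel, maps.superres_pixel_um,
                           prune_px=seg_cfg.prune_px)
    if conditioned.any():
        estimate_diameters(conditioned, vgraph)
    _io.write_mask(outdir / "vessel_mask.tiff", vmask.mask)
    _io.write_graph(outdir / "graph", vgraph)

    log.info("stage metrics")
    gf = config.reconstruct.grid_factor
    region_rows = []
    region_metrics = {}
    for name in ph.region_names:
        roi = np.kron(ph.region_mask(name), np.ones((gf, gf), dtype=bool))
        rm = _metrics.region_metrics(maps, vgraph, vmask.mask, roi)
        region_metrics[name] = rm
        region_rows.append({"region": name, **rm.as_dict(),
                            "has_vessels": rm.has_vessels})
    pd.DataFrame(region_rows).to_csv(outdir / "metrics.csv", index=False,
                                     float_format="%.6f")

    # per-segment table with region assignment, for the statistics stage
    per_seg = _metrics.segment_metrics(vgraph, maps)
    label_sr = np.kron(ph.region_label_map, np.ones((gf, gf), dtype=np.int64))
    seg_rows = []
    for s, m in zip(vgraph.segments, per_seg):
        labels = label_sr[s.path_rc[:, 0], s.path_rc[:, 1]]
        region = ph.region_names[int(np.bincount(labels).argmax())]
        seg_rows.append({"segment_id": s.id, "region": region,
                         "curvature": m.curvature,
                         "diameter_um": m.diameter_um,
                         "v_mm_s": m.velocity_mm_s,
                         "q_nl_s": m.flow_volume_nl_s})
    seg_df = pd.DataFrame(seg_rows, columns=["segment_id", "region",
                                             "curvature", "diameter_um",
                                             "v_mm_s", "q_nl_s"])
    seg_df.to_csv(outdir / "segment_metrics.csv", index=False,
                  float_format="%.6f")

    log.info("stage compare")
    stat_rows = []
    if not seg_df.empty:
        for param in ("curvature", "diameter_um", "v_mm_s", "q_nl_s"):
            groups = {name: seg_df.loc[seg_df.region == name, param]
                      .dropna().to_numpy() for name in ph.region_names}
            groups = {k: v for k, v in groups.items() if v.size >= 2}
            names = list(groups)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    res = _stats.mann_whitney(groups[names[i]], groups[names[j]])
                    stat_rows.append({
                        "parameter": param, "group_a": names[i],
                        "group_b": names[j], "test": res.test,
                        "statistic": res.statistic, "p": res.p,
                        "significance": _stats.significance_tier(res.p)})
    pd.DataFrame(stat_rows, columns=["parameter", "group_a", "group_b",
                                     "test", "statistic", "p",
                                     "significance"]).to_csv(
        outdir / "comparisons.csv", index=False, float_format="%.6g")

    summary = {
        "n_segments": len(vgraph.segments),
        "n_tracks": len(tracks),
        "svd_cutoff": spectrum.cutoff,
        "regions": {k: v.as_dict() for k, v in region_metrics.items()},
        "empty": len(tracks) == 0,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    return summary
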