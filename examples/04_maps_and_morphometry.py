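"""Super-resolved maps, vessel graph and the nine region parameters.

Runs the whole chain in memory on a two-region phantom and prints the
recovered region metrics next to ground truth: the invasive-like region
should exceed the core-like region in density, branching, tortuosity,
fractal dimension and orientation variance.
"""
from ulmtools.recovery import run_end_to_end

res = run_end_to_end(seed=100, n_frames=1200)

print(f"{len(res.tracks)} tracks -> maps {res.maps.density.shape} "
      f"(super-res pixel {res.maps.superres_pixel_um:.2f} um), "
      f"{len(res.graph.segments)} vessel segments")

header = f"{'parameter':24s} {'core rec':>10s} {'core true':>10s} " \
         f"{'inv rec':>10s} {'inv true':>10s}"
print("\n" + header)
for p in ("density", "diameter_um", "branches", "branch_points", "curvature",
          "fractal_dimension", "orientation_variance", "velocity_mm_s",
          "flow_volume_nl_s"):
    print(f"{p:24s} {getattr(res.recovered['core'], p):10.3f} "
          f"{getattr(res.truth['core'], p):10.3f} "
          f"{getattr(res.recovered['invasive'], p):10.3f} "
          f"{getattr(res.truth['invasive'], p):10.3f}")

print("\nAbsolute counts overcount truth (skeletons are finer than the")
print("generative tree), but the between-region ordering is preserved —")
print("that ordering is the quantity the method is built to measure.")
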