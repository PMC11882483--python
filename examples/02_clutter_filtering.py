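"""SVD clutter filtering with automatic threshold selection.

Builds a movie whose tissue clutter is rank-2 by construction and 100x the
bubble amplitude, then shows that the singular-value knee finds the right
cutoff and that the filtered movie retains the bubble signal.
"""
import numpy as np

import ulmtools as u

phantom = u.generate_phantom(regions=u.two_region_config(), seed=11)
traj = u.simulate_bubble_flow(phantom, bubbles_per_frame=0.5, n_frames=200,
                              seed=12)
clean = u.render_movie(traj, psf_sigma_um=10.0, clutter_rank=0, seed=13)
cluttered = u.render_movie(traj, psf_sigma_um=10.0, clutter_rank=2,
                           clutter_amplitude=100.0, seed=13)

filtered, spectrum = u.svd_filter(cluttered, cutoff="auto")
retained = np.sum(filtered.frames ** 2) / np.sum(clean.frames ** 2)

print("leading singular values:", np.round(spectrum.values[:6], 1))
print(f"automatic cutoff: {spectrum.cutoff} (the two clutter modes)")
print(f"bubble-signal energy retained after filtering: {100 * retained:.1f}%")
print("The clutter plateau sits orders of magnitude above the bubble tail;")
print("removing the components left of the knee reveals the bubbles.")
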