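# Methods

`ulmtools` implements single-plane ultrasound localization microscopy (ULM)
analysis for microvascular phenotyping: separating microbubble echoes from
tissue clutter, localizing and tracking individual bubbles, reconstructing
super-resolved vascular maps, and quantifying the vascular architecture and
hemodynamics of labelled tissue regions, with a statistics stage for
between-region comparison.  A synthetic phantom module provides movies with
exact ground truth so every stage is verifiable without experimental data.

## Pipeline model and assumptions

**Clutter filtering.**  The movie is rearranged into a Casorati matrix
(pixels x time) and decomposed by SVD.  Tissue echo is assumed bright,
spatially coherent and slowly varying, so it concentrates in the low-order
singular components; bubbles are sparse and fast-moving and spread over the
high-order components.  The clutter cutoff is selected automatically at the
knee of the singular value curve, operationalized as the interior index
maximizing the discrete second difference of log10 singular values.  The log
domain makes the rule scale-invariant; ties break toward the smallest index.
The curve is inspected globally, so the rule finds the single most convex
point — appropriate when the clutter plateau is within roughly an order of
magnitude per mode, which holds for the renderer's clutter model and for the
block-free processing used here.  No high-order noise cutoff is applied by
default (`upper_cutoff` exposes one).

**Localization.**  Candidates are intensity maxima above
median + 3.5 robust SD (1.4826 x MAD) of the filtered frame, thinned
greedily to a 3 px minimum separation.  Each candidate is refined by the
gradient-based radial-symmetry estimator: image gradients on the dual grid
define lines through each midpoint along the gradient direction; the centre
is the gradient-energy-weighted least-squares intersection of those lines.
Noiseless precision is well under 0.1 px RMS; the practical error on dense
movies is dominated by overlapping point-spread functions, not by the
estimator.

**Tracking.**  Detections on consecutive frames are linked by the Hungarian
algorithm on squared Euclidean distances, with pairs beyond a gate
(default 25 um, i.e. above the fastest plausible per-frame displacement)
forbidden.  Minimizing with a large forbidden-pair placeholder yields the
maximum number of gated matches at minimum cost; this equals the
brute-force optimum (verified exhaustively in tests).  There is no gap
closing: a missed detection terminates a track.  Tracks shorter than 15
frames are discarded — the standard minimum-trajectory-length rule — which
suppresses spurious noise tracks at the cost of short capillary transits.

**Map reconstruction.**  Accepted tracks are rasterized onto a grid refined
by `grid_factor` (default 8).  Each localization increments its super-res
pixel; positions are linearly interpolated along each step at the super-res
pitch so fast bubbles leave no gaps, and interpolated points carry their
step's speed and direction.  Per-pixel velocity is the mean step speed,
direction the circular mean of step angles (with the circular dispersion
retained), defined only where density > 0.  Mean (not per-track maximum)
velocity was chosen for the velocity map; the choice is configurable only by
post-processing the tracks.

**Vessel segmentation and graph.**  The density map is binarized where at
least k = 2 localizations fell, closed with a radius-1 disk, and cleared of
components under 25 px.  Because count thresholding of jittered data leaves
ragged edges and small enclosed holes — which a thinning algorithm would
turn into a thicket of spurious branches — a conditioning step fills
enclosed holes up to 100 px and opens with a radius-2 disk before
skeletonization.  Conditioning is skipped (radius 0) when single-pixel-wide
structures must survive.  Vascular density and the segmentation-quality gate
(Dice >= 0.7 against phantom truth, standing in for a trained classifier's
out-of-bag error check) are computed on the unconditioned mask.

Skeletonization uses Lee's 2D thinning (cleaner line terminations than
Zhang's).  Graph extraction merges adjacent skeleton pixels of degree >= 3
(8-connectivity) into single branch nodes, treats degree-1 pixels as
endpoints, and walks maximal chains between nodes into segments carrying
their ordered pixel polylines.  Terminal spurs shorter than 3 px (package
default; 8 px in the pipeline configuration) are pruned.  Loops that close
on one node keep the distance between their two attachment pixels as the
chord; a zero chord excludes the segment from curvature statistics.

Path length Lc is measured over waypoints every 4 skeleton pixels rather
than per-pixel chain steps: the digital staircase inflates chain length by
up to ~8% even for straight oblique lines, a bias larger than real
capillary tortuosity.  Waypoint chords (endpoints always included) remove
the bias and preserve Lc >= L.  Per-point lumen radii come from the
Euclidean distance transform of the mask; the segment diameter is
2 x median(radius) - 1 px (the centre pixel is otherwise counted twice),
floored at one pixel.

**Metrics.**  For each segment: curvature (tortuosity) = Lc / L; diameter as
above; velocity = mean of velocity-map values along the centreline; flow
volume Q = A x V with A = pi (d/2)^2, assuming a cylindrical lumen
(Poiseuille geometry), reported in nL/s (1 nL = 1e6 um^3).  Per region:
vascular density = vessel-mask area fraction of the ROI (the histology
area-fraction definition transferred to ULM); branches = number of segments
whose centreline lies mostly in the ROI; branch points = branch nodes in the
ROI; curvature averaged with path-length weights (short inter-branch
fragments carry no tortuosity information); fractal dimension of the
ROI-restricted mask by box counting — M(r) counts origin-anchored r x r
boxes containing mask pixels over scales 2, 4, ... min(H,W)/4, and the
dimension is the slope of log M vs log(1/r) over the contiguous sub-range
(>= 4 scales) with the best R^2 above 0.99, falling back (flagged) to the
best available sub-range; orientation variance = mean squared wrapped
deviation of flow-map directions from their circular mean, in rad^2, with an
axial mode (angles identified modulo pi) for data with unreliable flow sign;
mean velocity over defined map pixels; total Q summed over segments.
Histology-style indices for co-registered binary masks: VD-H = CD31-positive
area / region area; VMI-H = (CD31 AND aSMA) area / CD31 area, undefined
(NaN) without CD31 signal.

**Statistics.**  One value per animal per region is assumed (repeated
measurements pre-averaged upstream).  Normality is screened by
Kolmogorov-Smirnov against a normal with the sample moments; because the
parameters are estimated from the same sample this is anti-conservative
(Lilliefors caveat) and is used as a routing rule, not a calibrated test.
Three-group comparisons take one-way ANOVA with Bonferroni-adjusted pairwise
t-tests when all groups screen normal, otherwise Kruskal-Wallis with
Bonferroni-adjusted pairwise Mann-Whitney; the route can be forced.  The
Mann-Whitney test is exact (full enumeration with midranks; cached tie-free
null per sample-size pair) for combined n <= 12 and uses the tie-corrected
normal approximation otherwise.  Correlations use Pearson when both
variables screen normal, Spearman otherwise, labelled weak / moderate
(0.400-0.699) / strong (>= 0.700); two-sided tests throughout.

## Synthetic phantom: what it emulates, and what it does not

The generator grows each tissue region's network by a branching,
biased-persistent random walk with sinusoidal heading perturbation inside a
vertical band of the field of view, so each vessel belongs to exactly one
region.  Region parameters (seeds, branching probability and angle,
tortuosity amplitude and wavelength, heading jitter, radius and speed
ranges) encode the intended biology: the invasive margin gets the densest,
most branched, most tortuous, most disordered and widest vessels; core and
normal tissue are sparse and orderly.  Defaults (128 x 128 px at 10 um):

| parameter | core | invasive | normal |
|---|---|---|---|
| seeds | 3 | 8 | 3 |
| branch probability / step | 0.02 | 0.10 | 0.01 |
| branch angle (rad) | 0.2-0.4 | 0.5-1.0 | 0.2-0.4 |
| tortuosity amplitude (rad) | 0.15 | 0.55 | 0.10 |
| tortuosity wavelength (um) | 250-450 | 120-250 | 250-450 |
| heading jitter (rad) | 0.15 | 0.70 | 0.15 |
| radius (um) | 6-10 | 8-16 | 5-9 |
| mean speed (mm/s) | 3-6 | 4-8 | 2-5 |

The wide-angle branching and short tortuosity wavelength in the invasive
region mirror the classic corkscrew morphology of tumour vessels and make
the between-region contrasts decisive rather than marginal across seeds.

Bubbles arrive as a Poisson process (default 0.8 per frame), enter a segment
chosen proportionally to its volumetric flux pi r^2 v, sample a radial
position uniformly over the cross-section (rho = R sqrt(U)) and advect at
the Poiseuille speed 2 v_mean (1 - rho^2/R^2) — so sampled speeds average to
the segment mean — at a fixed lateral offset from the centreline.  Bubbles
slower than 0.5 mm/s are dropped as indistinguishable from clutter.  Movies
render each bubble as a unit-peak isotropic Gaussian (sigma 10 um), plus a
low-rank clutter field — one bright quasi-static positive mode and weaker
zero-mean slowly oscillating modes, scaled so the brightest clutter pixel is
100x the bubble peak, mode amplitudes within about an order of magnitude so
the singular spectrum shows a plateau and a knee — plus clipped Gaussian
noise.

Default acquisition lengths (2000 frames at 1 kHz for the reference movie;
1200 frames for the repeated two-region recovery runs) put the movie in the
sparse regime ULM assumes: roughly 60-80 concurrent bubbles in the field of
view.  Denser concentrations make overlapping point-spread functions the
dominant error source and are not a meaningful test of the localization
model.

Not emulated: RF physics and beamforming, nonlinear bubble acoustics,
frequency-dependent PSFs, tissue motion beyond smooth low-rank drift,
out-of-plane flow, 3D geometry.  Passing tests therefore demonstrate the
correctness and internal consistency of the analysis chain under the stated
statistical structure, not robustness to acquisition physics the renderer
does not model.  Two known resolution effects documented by the validation
experiments: localization jitter from PSF overlap widens recovered lumen
masks by roughly the jitter scale, and diameters of vessels comparable in
width to the PSF are biased low through the imaging chain (the map-to-
distance-transform estimator itself recovers truth-track diameters within
20%).

## Numerical and design choices

* Coordinates: 0-based, x = column, y = row, pixel centres at integer pixel
  coordinates; positions in um internally, velocities in mm/s.
* A position x (px) maps to super-res column floor((x + 1/2) x grid_factor),
  so block-summing a grid_factor map reproduces the factor-1 map exactly.
* Inflection selection requires >= 4 singular values; singular values are
  floored at 1e-15 of the largest before taking logs.
* Assignment determinism: detections are sorted by (y, x) before the solver,
  so ties resolve identically across runs.
* Box-counting grids are anchored at the array origin; no grid-offset
  averaging (flagged as a possible extension).
* Orientation variance wraps differences into (-pi, pi]; the circular mean
  is used for theta-bar (an arithmetic mean is ill-defined on the circle).
* Degenerate inputs: empty ROIs raise; ROIs without vessels return all-zero
  metrics flagged `has_vessels=False`; an all-zero density map yields an
  empty (valid) mask; constant localization windows raise.
* Determinism: a single run seed fans out to per-stage child seeds by
  CRC-hashing the stage name (all below 2^31); identical configuration and
  seed reproduce every CSV bit-for-bit.
* Problem sizes for the validation experiments: the reference movie is
  128 x 128 x 2000 frames; the ten two-region recovery runs use 1200 frames
  each; the statistics calibration uses 2000 null replicates at n = 6 per
  group.  These sizes were chosen as the smallest at which the measured
  properties are stable.

## Known limitations

* Per-bubble track recovery (recall/precision >= 0.9) holds in the dilute
  regime (tens of concurrent bubbles); the denser map-accumulation
  conditions trade per-bubble recall for coverage, which leaves aggregate
  maps intact but caps track-level recall.  Likewise a subspace clutter
  filter irreducibly removes the quasi-static share of the bubble signal,
  which equals the mean pixel occupancy — high retention figures presume
  dilution.
* Velocity maps average all step speeds per pixel; crossing vessels mix.
* Branch and branch-point counts from skeletons overcount truth by a
  seed-dependent factor (skeleton topology is finer than the generative
  tree); between-region ordering is preserved and is what the recovery
  experiments assert.
* The KS normality screen at n = 6 has very low power; routing between
  parametric and rank paths at study sizes is essentially a formality.
* Complex in-phase/quadrature input is not implemented; the filter operates
  on amplitude frames (a straightforward extension).
* Single-plane only; multiple imaging planes are independent runs.
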