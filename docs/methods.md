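# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinate and unit conventions

Arrays are `(row, col)` / `(plane, row, col)`; points and curves are `(x, y)`
pairs in µm with pixel centres at integer indices, so physical position =
index × pixel size (0-based).  All lengths are µm, all times minutes;
pixel-denominated parameters carry a `_px` suffix.  Thresholds are applied
strictly-greater-than: a pixel exactly at the threshold is background.

## Segmentation

Images are resampled to an isotropic working resolution (default 1 µm/px,
linear interpolation) *before* binarization, so that the pixel-denominated
cleaning parameters have a fixed physical meaning.  Binarization uses a
single global histogram threshold — Otsu, triangle or Yen.  Which method
suits an image depends on its intensity histogram; `select_threshold_method`
automates the choice by computing all three candidate masks and picking the
one with the smallest boundary-length-to-area ratio (the most compact, least
histogram-artefact-fragmented foreground).  The user can always force a
method, and an externally corrected mask can be supplied wholesale — manual
inspection of low-signal images is part of the workflow this replaces, and
the override input is its hook.

Cleaning runs in a fixed order: fill holes < 10 000 px, remove components
< 10 000 px, open with a disk of radius 5 px.  Both size rules are strictly
"smaller than".  The opening can split a component into sub-threshold
fragments, which would make the operation non-idempotent, so a final
debris-removal pass repeats after the opening; with it,
`clean_mask(clean_mask(m)) == clean_mask(m)` holds and the component count
never increases.

Degenerate input (a constant image) yields an empty mask flagged
`degenerate` in its provenance rather than an exception.

## Midline and width profile

The midline is the medial ridge of the Euclidean distance transform (EDT).
A strict 2-D local-maximum test goes blind on tapered bodies, where the EDT
grows monotonically *along* the ridge; instead a pixel is a ridge point when
its EDT value is within 1 µm of the maximum over a 3-µm neighbourhood.
Since the EDT falls off at unit slope perpendicular to the ridge, this keeps
a ribbon about one pixel wide that follows the ridge through ball centres,
necks and tapers.  The ribbon is then skeletonized to a one-pixel chain —
greedy ordering through a multi-pixel ribbon would sweep it column by
column and fold the path, in an image-orientation-dependent way.

Ordering is greedy nearest-neighbour chaining seeded at the point closest to
the posterior anchor, truncated at the point closest to the anterior anchor.
Isolated outliers (nearest-neighbour distance > 3× the median) are dropped
first.  The anchors themselves are prepended/appended: they are trusted
manual annotations of the body extremes, and including them makes the
midline span tip to tip (required for meaningful relative positions such as
"the first somite forms at ~20 % of the midline").  An anchor farther than
150 µm from every ridge point is an error.  The ordered chain is smoothed
with a moving average over a 7-µm *arc-length* window — a physical window,
so sparsely sampled stretches are not averaged across corners — which
removes the ±1 px chaining zigzag without bending the path.

The chain is then fit with a cubic smoothing B-spline (`splprep`).  The
smoothing value (default 10 000) is a residual budget denominated in µm² at
1 µm/px for a full, noisy ridge-point cloud of the kind real microscopy
masks produce; fitting the thinned chain of a clean mask with that same
budget would buy smoothness with fidelity it does not need to spend.  The
pipeline therefore sets the effective budget to FITPACK's recommended
`m·σ²`, with σ estimated from the chain's *lateral* scatter (perpendicular
residual from the secant through each point's neighbours; longitudinal
spacing irregularity must not count as noise), times a safety factor of 3,
and capped at the configured value.  The chain endpoints (the anchors) are
pinned with high weights so the budget cannot pull the curve off them.  The
fitted curve is resampled at a uniform 1-µm arc-length step; arc length is
chord summation at that step.

Width at arc position s is measured by casting rays along ± the local normal
until they exit the mask.  The mask boundary is defined as the 0.5 level set
of the bilinearly interpolated binary mask, located by a vectorised
first-crossing search at 0.25-px ray sampling with linear refinement.  An
independent brute-force validator marches each ray in small steps with a
hand-rolled bilinear lookup and no refinement; the two agree within half a
pixel everywhere on the validation masks.  (A nearest-neighbour staircase
boundary would differ from any sub-pixel definition by up to a pixel per ray
on oblique edges, which is why the boundary definition is shared and only
the mechanism differs.)  Rays that reach the image border before exiting the
mask are truncated there and flagged; samples that start outside the mask
get width 0.

## Somite calling

Extrema of the width profile are detected with prominence ≥ 10 µm and
separation ≥ 40 µm (about one-third of the smallest printed somite width;
both overridable).  Each extremum is refined to the midpoint of the run of
samples within 1 µm of its extremal value: the necks between somites are
flat to within raster noise over the whole gap, so the raw argmin lands
anywhere on the plateau while the boundary belongs at its centre.  Extrema
within the separation distance of the profile ends are discarded, and the
sequence is forced to alternate (the more extreme of two same-type
neighbours wins).

One somite call per width maximum bracketed by two minima, indexed from the
posterior end: index 1 is the newest somite, matching the
posterior-to-anterior growth narrative.  The posterior-most maximum — the
body, containing PSM and NMPs — has no posterior bounding minimum and is
never called.  The anterior-most (oldest) somite often lacks an anterior
minimum; a virtual boundary is placed where the profile first falls below
25 % of that maximum (else at the profile end) and the call is flagged
`end_capped`, because silently dropping the oldest somite would bias counts.

Somite area and circularity are an explicit modelling choice: the somite is
treated as an ellipse with axes L (inter-somite distance) and W (width),
`area = πLW/4`, perimeter by Ramanujan's approximation, `circularity =
4π·area/perimeter²` (=1 iff L = W, symmetric in L and W).

`count_somite_rows` counts calls; a left/right somite pair projects to a
single width maximum in 2-D, so a pair counts once by construction.  Midline
extraction from the EDT ridge assumes a single somite row — for paired
strings the ridge splits into the two ball-centre rows — so paired masks are
profiled along a supplied midline (in validation, the generator truth).

First-somite geometry intersects the annotated left–right (LR) segment with
the midline polyline segment-by-segment.  Exactly one crossing is required;
with none, the closest approach within 5 µm is used and flagged, beyond that
an error reports the distance.  The angle is unsigned in [0°, 90°], via
`arccos |n̂·t̂|` — no sign convention is defined for it.

## Volumetry

Otsu thresholds are computed once per channel over the whole 3-D stack (not
per slice): global thresholding is deterministic and matches how the stacks
are acquired and inspected.  The total-somitoid mask is Otsu on the
voxelwise sum of all channels, computed in float64 so no saturation can
occur; it exploits the fact that the chosen markers jointly cover the
somitoid.  Volumes are positive-voxel counts times the voxel volume
(dz·dy·dx), so the lineage identities Neural + NMP = SOX2⁺ and PSM + NMP =
BRACHYURY⁺ hold exactly at the voxel level, not approximately.  The Somite
domain (UNCX4.1⁺) is deliberately *not* made exclusive of the other
markers, so domain fractions may sum to more than 1.  All domains are
restricted to the total mask; whether the original analysis restricted them
is not documented, and restriction is the declared choice here.  Channel
names map case-insensitively through a configurable role table.

## Oscillation analysis

Registration is translation-only, by foreground centroid.  The threshold
comes from Otsu on the *minimum* intensity projection over time: an
oscillating reporter modulates brightness, and a per-frame threshold would
track the travelling crests instead of the tissue.  Frames without a
coherent foreground object (≥ 50 % of foreground in one component and
Michelson contrast ≥ 0.3 between foreground and background) are flagged
low-confidence and left unshifted.  Rotation and scaling drift are out of
scope.

Kymographs: each frame is median-filtered (disk footprint), then sampled
along the posterior→anterior polyline at one-pixel steps with transverse
averaging over ± the half-width along the local normal; one row per frame,
top row first.

Detrending subtracts a centred moving average (default 50 frames, the
window used for clock traces in this system), with the window shrinking
symmetrically at the edges.  The filter's transfer gain means a sinusoid of
period T frames keeps a fraction |1 − g(W,T)| of its amplitude
(g the Dirichlet kernel gain); components with period ≫ window are largely
removed — that is the detrending cut-off, and it is testable analytically.
NaN gaps of ≤ 3 frames (brief imaging halts) are linearly interpolated;
longer gaps raise an error directing the caller to split the trace.

Phase is the unwrapped analytic-signal (Hilbert) phase of the detrended
trace — adequate for these single-band signals and exactly verifiable on
sinusoids.  The peak-to-peak period detects peaks and troughs with
prominence ≥ 0.3× the trace SD and distance ≥ half the dominant-FFT-bin
period; before detection the trace is low-passed with a quarter-period
moving average (symmetric, so peak positions do not move) so white noise
cannot masquerade as peaks — the imaging pipeline's median filter plays this
role on real movies.  Samples whose smoothing window is truncated at the
trace ends are excluded from peak candidates (the shrinking window
under-attenuates them, which can fake an edge peak).  The period is the
mean successive peak-to-peak interval, with SD and interval count.

Wave lag between two kymograph regions is the circular mean of their
unwrapped-phase difference, converted to minutes via the posterior region's
period; positive lag = posterior leads (a posterior→anterior wave).  Being
circular, the lag is only identifiable within ± half a period — regions
more than half a wavelength apart alias.  The somite-formation period is
the mean successive interval of the annotated event times.

## Synthetic data generator

The somitoid generator emulates the day-6/7 geometry: a tapered body (the
PSM + NMP region, default 300 µm long, 150 µm wide, posterior tip at half
width) followed by a string of ball somites (default 8 × 110 µm — the
paired-somite scale; the printed range 104–157 µm is covered by the
validation studies' 90–160 µm draws) at centre spacing diameter + 10 µm,
threaded on a 40-µm backbone rod so the mask is one connected component,
as a real somite string is.  True boundaries sit at the gap midpoints, so
the true inter-somite distance equals the spacing and the true width the
diameter (with two mirrored rows for `paired`, projecting to one width
maximum per pair).  The midline is straight or sinusoidal (default
amplitude 30 µm, wavelength 500 µm, reparameterized by arc length).
Intensities are foreground 200 / background 20 with additive Gaussian noise
(σ = 30 ⇒ SNR 6 by default; validation studies draw SNR 3–6).

The HCR generator renders a capsule body along x at voxel (2, 0.391, 0.391)
µm with a posterior SOX2⁺/BRACHYURY⁺ cap (NMPs, default 25 % of the length),
a BRACHYURY-only band (PSM, 35 %), and anterior UNCX4.1⁺ spheres (somites;
non-overlap is enforced so truth volumes stay analytic), or optionally a
solid UNCX4.1⁺ anterior slab ("slab" style) whose channels jointly tile the
body.  Truth volumes come from quadrature on the capsule cross-section and
the sphere formula — independent of the rasterisation.  Default dimensions
(220 × 60 µm) are a scaled-down somitoid so stacks stay a few million
voxels.

The clock generator writes `I(x,t) = baseline(t) + A·cos(2π(t/T −
direction·x/λ))` inside a rectangular body, default T = 300 min (the ~5 h
human segmentation clock), λ = 400 µm, 10-min frames; `direction = +1` is a
posterior→anterior wave (posterior leads).  With event coupling on, somite
events are emitted at successive oscillation peaks at the anterior PSM
position — one somite per cycle.  Optional per-frame translation drift
exercises registration; truth records the shifts.

What the generator does **not** emulate: optical blur (no PSF convolution),
photobleaching, Poisson photon statistics (noise is additive Gaussian),
intensity inhomogeneity across the tissue, segmentation-error-inducing
debris, multi-axis somitoids, or cell-level texture.  Passing the recovery
studies therefore demonstrates that the *geometry and dynamics* extraction
is correct and unbiased at realistic scales and SNRs, not that the
thresholding methods are robust to every real-microscopy artefact — that is
what the manual mask-override input is for.

## Validation studies and problem sizes

The seeded studies in `somitometry.studies` (run by `tests/test_acceptance.py`,
`scripts/acceptance.py` and the `analysis/` drivers) use: 20 randomized
somitoids (5–10 somites, diameters 90–160 µm, SNR 3–6) for morphometry
recovery; 20 smaller 3-somite bodies for the width-profile oracle; 3
straight + 3 sinusoidal bodies for midline fidelity; one 50-µm sphere and
one noiseless HCR stack for volumetry; 120-frame movies, 10 noisy period
seeds and 10 random-direction lag movies for the clock; and two end-to-end
pipeline reruns for determinism.  These sizes keep a full validation run a
few minutes on one CPU while spanning the printed parameter regime.

## Known limitations

* Midline extraction assumes one dominant axis and a single somite row;
  multi-axis somitoids (a few % of real samples) and paired rows need a
  supplied midline.
* The anterior end-cap boundary is a convention; the oldest somite's length
  is only defined up to it (calls carry the `end_capped` flag).
* The ellipse area/circularity model is a declared stand-in for an
  undocumented definition; all outputs flag it via the fixed formula.
* Wave lag aliases beyond ± half a period.
* Registration is translation-only.
* Otsu-based volumetry inherits Otsu's bimodality assumption per channel;
  low-signal channels should use the mask-override input.
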