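# somitometry

Quantification toolkit for somite-forming organoids ("somitoids") — stem-cell
derived bodies that sequentially lay down somite-like epithelial balls along a
posterior–anterior axis under the control of the segmentation clock (HES7,
~5 h period in human).

The package implements the image-analysis pipeline such experiments need:

* **Segmentation** — resample 2-D bright-field / nuclear-stain images to
  1 µm/px, binarize with a global histogram threshold (Otsu, triangle or Yen,
  auto-selected or user-chosen), fill holes and remove debris below
  10 000 px, and smooth with a disk-5 morphological opening.
* **Midline morphometry** — extract the posterior→anterior midline from the
  Euclidean distance transform ridge of the body mask, order the ridge
  points between manually annotated posterior/anterior anchors, fit a cubic
  smoothing B-spline, and measure the body width perpendicular to the
  midline at every micrometre of arc length.  Width-profile minima mark
  somite boundaries and maxima somite widths; each bracketed maximum becomes
  a somite call with inter-somite distance `L` (minima-to-minima), width `W`
  (profile maximum), and ellipse-model shape statistics
  `area = πLW/4`, `circularity = 4π·area/perimeter²` (Ramanujan perimeter).
  First-somite geometry: the intersection P of an annotated left–right
  segment with the midline gives the relative position
  `s(P)/L_total` and the angle `arccos |n̂_LR · t̂(P)|`.
* **Volumetry** — per-channel global-Otsu masks of 3-D HCR stacks
  (anisotropic voxels, e.g. Z = 2 µm / XY = 0.391 µm), a total-somitoid mask
  from the sum of all channels, and Boolean lineage domains:
  Neural = SOX2⁺∧BRACHYURY⁻, Somite = UNCX4.1⁺, PSM = BRACHYURY⁺∧SOX2⁻,
  NMP = BRACHYURY⁺∧SOX2⁺, with volumes = voxel counts × voxel volume.
* **Oscillation** — translation registration of reporter movies, kymographs
  along a posterior→anterior axis, 50-frame moving-average detrending,
  Hilbert phase, peak-to-peak period, posterior–anterior wave lag (circular
  mean phase difference), and somite-formation period from annotated event
  times.
* **Synthetic data** — seeded generators for all of the above with exact
  ground truth: tapered-body + somite-chain images, 3-channel HCR stacks
  with analytic domain volumes, travelling-wave luminescence movies with
  optional clock-coupled somite events.

## Worked example

```python
from somitometry import synthgen, segmentation as seg, midline as ml

img, truth = synthgen.generate_somitoid(synthgen.SomitoidSpec(seed=0))
mask  = seg.segment(img, method="yen")
curve = ml.extract_midline(mask, truth.posterior_anchor, truth.anterior_anchor)
prof  = ml.compute_width_profile(mask, curve)
calls = ml.call_somites(prof, ml.find_profile_extrema(prof))
print(ml.count_somite_rows(calls), calls[0].length, calls[0].width)
```

prints `8` somite rows with the first (most posterior, newest) somite at
length ≈ 120 µm and width ≈ 110 µm — the generated truth is eight 110-µm
somites at 120 µm spacing.  The same pipeline is available from the shell:

```bash
somitometry synth somitoid --seed 0 --out demo/
somitometry segment --input demo/somitoid.tif --method yen --pixel-size 1 --out demo/mask.tif
somitometry morph --mask demo/mask.tif --anchors anchors.csv --out-dir demo/morph
```

The numbered scripts under `analysis/` run the validation studies and write
their tables under `results/`.  For example `python
analysis/01_somite_morphometry_recovery.py --seed 0` reports

```
somite count recovered exactly in 20/20 somitoids
mean |width error|              0.36 µm
mean |inter-somite dist error|  2.20 µm
```

i.e. on twenty randomized somitoids spanning the 90–160 µm somite-diameter
range at imaging SNR 3–6, the pipeline recovers every somite count exactly
and measures widths and inter-somite distances to a few µm.

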