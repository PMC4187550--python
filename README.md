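# glut4quant

Quantitative immunofluorescence of the subcellular distribution of GLUT4 —
the insulin-responsive glucose transporter — in skeletal muscle fibre
cross-sections, with the repeated-measures statistics of a pre/post
exercise-training study, validated end to end on a bundled synthetic image
generator with known ground truth.

## Who this is for

Muscle physiologists and image analysts who quantify confocal
immunofluorescence of single fibres: GLUT4 (spot/cluster channel),
dystrophin (sarcolemma/plasma-membrane marker), slow myosin heavy chain
MHCI (fibre typing), and optionally DAPI/DHPR.  The package is a library
first (`import glut4quant`, see `examples/`), with a thin
`glut4quant simulate | quantify | stats` command line for batch runs.

## The method

For each single-fibre image the pipeline:

1. **Segments the plasma membrane (PM) midline** in the dystrophin channel
   with a classical parametric active contour ("snake"): the closed curve
   v(s) minimises E = ∫ (α|v′|² + β|v″|²)/2 ds + ∫ E_ext(v) ds, where the
   external energy attracts the curve to the bright dystrophin ridge.
   Initialisation is automatic (Otsu threshold → largest object → dilated
   boundary); the update is the standard semi-implicit scheme with
   arc-length resampling.
2. **Builds a PM band and twenty concentric 1 μm layers** from a Euclidean
   distance map: the PM layer is a band of half-width 2.5 px (5 px total)
   about the midline; layer k collects intracellular pixels at distance
   (k−1) < d ≤ k μm from the band's inner edge; the remainder is the core.
3. **Detects GLUT4 spots** on a filtered copy of the GLUT4 channel
   (no-neighbour-style background subtraction, then high-pass Gaussian
   "HiGauss" enhancement) using uniform, study-level intensity and size
   thresholds; 8-connected components become spots with intensity-weighted
   centroids.  Each spot's equivalent diameter 2·√(area/π) classifies it as
   **large (≥ 1 μm)** or **small (< 1 μm)**; spots are assigned to layers by
   centroid.
4. **Computes metrics**: whole-fibre mean GLUT4 intensity on the *raw*
   channel within the intracellular dystrophin mask; per-class spot counts,
   densities and mean size (= total spot area / count); per-layer mean
   intensity and large-spot count per layer area.  Fibre type comes from
   batch Otsu thresholding of mean MHCI intensities.
5. **Runs the inference cascade**: a mixed repeated-measures ANOVA
   (training within × training mode between) for whole-fibre metrics; a
   training × layer two-within RM-ANOVA for layered metrics (fibre types
   pooled); Bonferroni pairwise comparisons on significant main effects;
   paired t-tests within layers only when the training×layer interaction is
   significant (α = 0.05).

Because no real images ship with the package, a first-class synthetic
generator (`glut4quant.synth`) emulates the study: one fibre per image with
a dystrophin ring, GLUT4 clusters enriched at the periphery and around
nuclei over a diffuse background, bimodal MHCI, per-subject/section random
factors, and configurable planted training responses — all with
machine-readable ground truth and full seed determinism.

## Worked example

```bash
python examples/run_study.py
```

prints (4 subjects, one endurance-training arm, +15% planted whole-fibre
GLUT4 with a peripherally concentrated increase):

```
simulated 32 fibre images (4 subjects, pre/post)
quantified 32 fibres, 0 QC failures
whole-fibre GLUT4 intensity change: 7.4% (planted +15%, SEM 5.8)
training effect on whole-fibre intensity: p = 0.3779
layer main effect p = 1.17e-49; training x layer interaction p = 1.58e-31
layers with significant within-layer increase: [0, 1]
```

The whole-fibre change is recovered within its (large, n = 4) sampling
error and is not significant at this toy cohort size, while the layered
analysis — far more sensitive — detects the planted redistribution: a
strong layer gradient, a training×layer interaction, and within-layer
significance confined to the PM layer (index 0) and the first 1 μm shell
(index 1).  `examples/simulate_fibre.py`, `examples/segment_and_layer.py`
and `examples/detect_spots.py` walk the individual stages (the snake
recovers the PM midline to ~0.1 px on synthetic fibres; noise-free
detection recovers planted spot counts and size classes exactly).

The same pipeline runs from the shell:

```bash
glut4quant simulate --out ds --subjects 8 --seed 1
glut4quant quantify --dataset ds --out metrics
glut4quant stats --metrics metrics --out report
```

## Layout

```
src/glut4quant/     synth, imageio, config, segmentation, layering,
                    spots, metrics, pipeline, stats, cli
examples/           one narrative script per capability
tests/              unit + property + acceptance suites
docs/methods.md     models, parameters, design choices, limitations
```
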