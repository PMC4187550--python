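# Methods

This note documents the models, parameters and design choices behind
glut4quant: what each stage assumes, which constants matter and why, what
the synthetic generator does and does not emulate, and the known
limitations.

## Coordinate and unit conventions

Origin at the top-left pixel, x rightward (columns), y downward (rows),
0-based indices; a pixel's position is its centre.  Lengths are in μm via
the per-image calibration (μm/pixel); intensities are arbitrary units
preserved from the file — no normalisation happens at I/O time, because
whole-fibre intensity is measured on raw data.

## Segmentation: parametric snake on the dystrophin ridge

The dystrophin stain marks the sarcolemma as a bright closed band ~5 px
wide; the quantity of interest is the band's **midline**, the approximate
PM midline.  The snake minimises

E = ∫ (α|v′|² + β|v″|²)/2 ds + ∫ E_ext(v) ds,
E_ext = −(w_line·G_σ∗I + w_edge·|∇(G_σ∗I)|²),

with both image terms normalised to [0, 1].  The default external energy is
line-dominant (w_line = 1, w_edge = 0): the midline of a *band* is a local
maximum of smoothed intensity but a local **minimum** of gradient
magnitude, so a pure edge energy would lock onto either side of the band
rather than its centre.  The edge term remains available for edge-like
targets.

The update is the standard semi-implicit scheme, (I + τA)·v⁺ = v + τ·f_ext(v),
where A is the cyclic pentadiagonal matrix of the internal energy.  An
explicit Euler update was rejected because it is unstable at useful step
sizes when β ≫ α.  Vertices are resampled to uniform arc length every
iteration; iteration stops when the maximum vertex displacement falls
below `tol_px` (default 0.05 px) or at `max_iter` (2000; a non-converged
snake is returned flagged, with a warning).  Self-intersecting results are
repaired once by periodic Gaussian smoothing + resampling, else rejected.

Defaults (α = 0.05, β = 2, σ = 2 px, τ = 1, external weight 2) were chosen
for stability on the synthetic fixture and give ~0.1 px mean radial error
on noise-free rings and < 1.5 px at SNR 5; they are all exposed in
`PipelineConfig.snake`.  Initialisation: Otsu threshold of the dystrophin
channel, largest connected object (the one-fibre-per-image convention;
smaller objects are ignored), filled, boundary dilated outward 3 px.

## PM band and concentric layers

The PM band is the set of pixels whose centre lies within
`band_halfwidth_px` (default 2.5 px) of the contour polyline — total
thickness 5 px.  The distance to the polyline is computed from a densely
resampled rasterised marker via an exact Euclidean distance transform,
refined near the band by nearest-neighbour distance to a 0.1 px-spaced
polyline (< 0.05 px error), so the thin band mask is unbiased.

Layers are built from the Euclidean distance transform of the
intracellular mask, i.e. distances are measured **from the inner edge of
the PM band**, not from the midline; layer 1 is therefore the first
intracellular 1 μm shell, distinct from the PM layer.  Layer k collects
pixels with (k−1)·t < d ≤ k·t (half-open shells; a pixel exactly on a
boundary joins the outer of the two candidate layers); pixels beyond
n_layers·t form the core.  Defaults: 20 layers of 1.0 μm.  Layers are
emitted even when empty or when they fail to close into a full annulus
(irregular or small fibres), flagged `complete=False`; downstream analysis
decides what to do with them.  For convex fibres layer pixel counts
decrease monotonically with depth — a tested invariant.

## Spot detection and classification

Detection runs on a filtered copy of the GLUT4 channel; intensity metrics
always use the raw channel, and the `FilteredChannel` type cannot be passed
to intensity operations.  Preprocessing has two stages:

1. no-neighbour-deconvolution-style background removal:
   F1 = max(0, I − w·G_σb(I)), σb = 10 px, w = 1.0.  Full subtraction
   (w = 1) removes the peripheral background pedestal that otherwise
   biases spot sizes near the membrane; the weight is configurable.
2. high-pass Gaussian ("HiGauss") enhancement:
   F2 = max(0, F1 + g·(F1 − G_σh(F1))), σh = 2 px, g = 2.

Spots are 8-connected components of F2 ≥ `spot_intensity_threshold`
(default 45 a.u.) within the analysed region (PM band + intracellular),
discarding components below `spot_min_area_px` (default 4 px).  Thresholds
are deliberately **study-level constants** — one value for all images being
compared — not per-image auto-thresholds.  Detection happens once over the
whole region; spots are assigned to layers by centroid, so clusters
straddling a shell boundary are never split (per-layer re-detection would
fragment them).  Merged clusters are reported as one spot; no splitting is
attempted.

Size class uses the equivalent diameter 2·√(area/π) against a 1 μm
boundary; a diameter exactly at the boundary is classed large (the >1/<1
phrasing leaves a measure-zero gap that needs a deterministic tie-break).

A property of this design worth knowing: with a fixed threshold, measured
spot area grows when staining gets brighter.  In studies where overall
intensity rises (e.g. post-training), measured mean spot sizes and
boundary-crossing counts inflate relative to geometric ground truth.  The
validation suite therefore checks exact recovery under noise-free,
gain-stable conditions and uses effect-isolating scenarios elsewhere.

## Metrics and aggregation

Per fibre: mean raw GLUT4 intensity over the intracellular mask; per class
(large/small) spot count, count per μm² of fibre area, total spot area and
mean size = total area / count (reported missing, not zero, for an empty
class).  Per layer: mean raw intensity, large-spot count and count per
layer area.  Aggregation order is fibre → subject × timepoint (× fibre
type where relevant) means → group statistics; per-fibre records are always
retained.  For the layered analysis fibre types are pooled.  Tables can be
expressed relative to a reference group (pre-training type I for
whole-fibre metrics, pre-training PM layer for layered metrics).

## Statistics

All designs are balanced and complete by construction (missing cells raise
rather than impute).  Sums of squares are the closed-form balanced
decompositions:

* mixed design: between stratum (mode vs subjects-within-modes) and within
  stratum (training and training×mode vs training×subjects-within-modes);
* two-within design: each effect (training, layer, training×layer) against
  its own subject-interaction stratum.

Component SS add exactly to the total SS (tested at 1e−9 relative), and F
and p match pingouin's implementations to 1e−9 on toy tables.  No
sphericity correction is applied by default (`gg_correction=True` enables
Greenhouse–Geisser ε on the within factors).  The decision cascade:
Bonferroni-adjusted pairwise comparisons only after a significant main
effect; within-layer paired t-tests only after a significant
training×layer interaction, unadjusted by default (Bonferroni guards the
main-effect comparisons only; `adjust_within_layer=True` switches).
α = 0.05 throughout, configurable.

Calibration, by simulation at the table level: type-I error of the
training effect at α = 0.05 lies in [0.03, 0.07] over 2000 runs; power at
a planted effect of 1 SD of the within-subject change is ≥ 80% for the
training main effect at 8 subjects/mode.  The interaction power simulation
uses 12 subjects × 6 layers (a cohort sized to give ~88% power at a 1 SD
effect confined to the first two layers); at 8 subjects the same effect is
detected in only ~50–60% of runs, which is the honest sensitivity limit of
the design.

## The synthetic generator

The generator is the package's validation instrument; its defaults are the
study conditions everything is tested under:

* design: 8 subjects per training mode (endurance ET, sprint-interval
  SIT), pre/post timepoints, 3 section replicates × 5 fibres per type per
  section = 30 images (15 type I + 15 type II) per subject and timepoint;
* geometry: fibre radius ~N(32, 2) μm clipped to [28, 38], smooth radial
  irregularity ≤ 0.12, 0.2 μm/pixel, 3–8 peripheral nuclei of 2–3.5 μm;
* GLUT4 content: Poisson(18) large clusters (diameter ~N(1.6, 0.25) μm,
  resampled away from [0.95, 1.05]) and Poisson(90) small clusters
  (~N(0.60, 0.08) μm, floored at 0.5 μm — structures below ~2.5 px are
  treated as part of the diffuse background, consistent with confocal
  resolution); 30% of spots within 1 μm of the membrane, 20% within 2 μm
  of a nucleus, the rest uniform; uniform disk intensity 60 a.u. over a
  diffuse background of 20 a.u. with a peripheral gradient
  (1 + e^(−depth/3 μm)); spots are rejected-and-resampled if centres come
  closer than the sum of radii + 0.5 μm so the planted count equals the
  detectable count;
* imaging: Gaussian PSF σ = 0.2 μm, additive Gaussian noise (σ = 2 a.u.),
  optional Poisson noise; MHCI interior mean 150 (type I) vs 30 (type II);
* variance components: per-subject intensity factor (log-σ 0.10, shared
  across that subject's sections pre *and* post — the within-subject
  correlation that gives the paired design its power), per-section factor
  (log-σ 0.05), per-subject spot-abundance factor (log-σ 0.10);
* planted training responses (defaults): ET +15% whole-fibre intensity,
  +24% large-spot count, +10% mean large size, +17% mean small size;
  SIT +14%, +46%, +21%, +36%; no small-count change for either mode.  ET
  concentrates its response at the periphery (peripheral background boost
  0.35, peripheral placement shift +0.15), SIT's is more uniform.  The
  whole-fibre intensity effect is *outcome-calibrated*: the global
  post-training gain is divided by the flux change already implied by the
  count/size/peripheral effects (an analytic approximation), so the
  planted number refers to the measured quantity.  `intensity=None`
  disables this calibration for effect-isolating experiments.

Determinism: one master seed; per-image and per-subject streams derive via
stable `SeedSequence` spawn keys, so identical configurations are
bit-reproducible and pre/post sections share their subject factors.

What the generator does **not** emulate: longitudinal sections and
T-tubule striations, 3D stacks, photobleaching, chromatic shift, fibre
crowding/touching fibres, antibody/staining artefacts, hybrid (I/IIa)
fibres.  Passing tests therefore demonstrate algorithmic correctness under
idealised single-fibre imaging, not robustness to every real-world
artefact.

## Problem sizes used in validation

Full-pipeline runs are sized to keep the whole suite and the acceptance
script in the minutes range on one CPU: the acceptance study uses 8
subjects/mode with 1 replicate × 2 fibres/type per section (256 images);
the peripheral-redistribution experiment 6 subjects × 1 fibre/type (24
images); statistical calibration runs on simulated metric tables (2000 and
500 replicates), which is where simulation effort belongs — the imaging
stages are deterministic given a truth, the statistics are not.

## Known limitations

* The snake needs a dominant, mostly closed dystrophin ring; heavily
  interrupted rings or multiple comparable fibres per image are out of
  scope (the largest object wins).
* Layer assignment by centroid puts a boundary-straddling cluster wholly
  into one shell.
* Threshold-based sizing couples measured spot size to staining intensity
  (see above); cross-condition size comparisons assume comparable gain,
  which the method itself assumes by placing compared sections on one
  slide.
* The no-neighbour deconvolution emulation is a clipped Gaussian
  background subtraction — a declared approximation of the commercial
  algorithm, with configurable parameters.
* The two-within ANOVA assumes sphericity by default; enable the
  Greenhouse–Geisser flag for 21-level layer factors if that worries you.
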