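# Methods

## Problem and pipeline

`granuleseg` segments and measures insulin secretory granules (large
dense-core vesicles) in 2-D electron micrographs of pancreatic beta cells.
Under EM these granules appear as roughly spherical organelles, 100–800 nm
in diameter, with an electron-dense core separated from the limiting
membrane by a bright halo; they occupy only a small fraction of the image,
and dark non-granular structures (notably heterochromatin-rich nuclear
regions) are easy to confuse with them.

The pipeline has four stages, each usable on its own:

1. **Pre-processing** — global histogram equalization,
   `h(v) = round((cdf(v) − cdf_min) / (N − cdf_min) · 255)`, which flattens
   uneven illumination and standardises contrast between micrographs.  The
   mapping is monotone, applied identically at training and prediction time,
   and a constant image (where the mapping is undefined) passes through
   unchanged with a warning.  Equalization is per image; micrographs from a
   serial stack are treated independently.
2. **Semantic segmentation** — the multi-branch fully convolutional network
   (MFCN) described below produces a per-pixel granule probability; a
   threshold (default 0.5, strict inequality) yields the binary map.
3. **Instance segmentation** — marker-based watershed on the Euclidean
   distance transform splits touching granules.
4. **Morphometry** — per-granule area, perimeter, equivalent radius, round
   coefficient, mean gray level, dense-core radius and distance to the
   plasma membrane, plus cohort summaries and two-sample tests.

## The MFCN

Three ideas are combined:

* **Multi-scale inception input.**  The image enters three parallel
  convolutions of kernel 3×3, 5×5 and 7×7 (stride 2), one per branch, so the
  branches start from features of different granularity.
* **Multi-branch encoder–decoders.**  Branch *i* downsamples by a total
  factor of 4, 8 or 16 (counting the inception stride) with {3×3 stride-2
  convolution → batch norm → ReLU} blocks, then upsamples symmetrically back
  to full resolution with learnable 2× upsampling (zero-insertion followed
  by a 3×3 convolution).  There are **no** encoder→decoder skip connections;
  each branch ends in its own 2-channel score map and acts as a binary
  classifier with its own receptive field — small factors preserve detail on
  small granules, large factors carry the context needed to reject dark
  nuclear regions.
* **Ensemble fusion.**  The branch score maps are sliced per class and
  concatenated (background slices first, then granule slices) and fused by a
  1×1 convolution that learns per-branch weights; softmax gives the final
  probabilities.  The slicing order is cosmetic: any fixed channel
  permutation is absorbed by the 1×1 weights.

Channel width at encoder level L is `base_channels · channel_growth^L`
(defaults 16 and 2); one convolution per resolution level.  Batch
normalization follows every convolution except the two score/fusion 1×1
layers, which produce raw logits.  Inputs whose sides are not divisible by
the largest branch factor are reflect-padded and the output cropped back.
The network is implemented directly in numpy (forward and backward passes
written out per layer); convolutions are evaluated as one BLAS matrix
product per kernel tap, which keeps memory linear in the image size and
makes a desk-scale CPU training run take a few minutes.

**Training.**  Pixel-wise 2-class cross-entropy with inverse-frequency class
weighting (granules are rare, so unweighted loss collapses toward
background), Adam (lr 1e-3), batch 4, flips/rotations available but off by
default.  One master seed fans out to parameter initialisation and epoch
shuffling; runs are bit-reproducible on a fixed platform.  Six epochs on 100
synthetic 128×128 scenes suffice for the held-out scores reported by the
test suite; the loss curve is essentially flat afterwards.

**Padding modes.**  Convolutions support reflect (default), periodic and
zero padding.  With periodic padding the whole network is exactly
translation-equivariant at the common stride (16 px), which the test suite
uses as a structural check; gradients fold padded borders back onto their
source pixels, so all modes train correctly.

## Synthetic micrographs

The generator emulates the statistical structure of FIB-SEM beta-cell
images, not their physics.  A scene is a smooth Fourier-perturbed cell blob
(~70% of the frame; its boundary is the plasma-membrane polyline), an
optional dark nucleus-like blob (a distractor with no halo), and granules
placed by rejection sampling: count drawn Poisson with mean
`target_density_per_um2 ×` cytoplasm area, centers strictly inside the
cytoplasm, and no two granule interiors overlapping by more than 20% of the
smaller area (analytic lens test).  Touching granules are deliberately
allowed so the watershed's hard case is exercised.  If more than 5% of the
drawn count cannot be placed the generator raises instead of silently
under-placing.

Defaults are the study conditions: densities 1.03 (control) and 2.3
(metabolic-syndrome-like) granules/μm² are used for the calibration cohorts;
granule radii span 50–400 nm (diameters 100–800 nm).  Radii are sampled from
a lognormal (median 120 nm, σ_log 0.4) truncated to that range: a uniform
law over the full span would put ~44% of the cytoplasm under granules at the
higher density, which no bounded-overlap packing can realise, and measured
granule-size histograms are strongly right-skewed.  A fraction of cores
(default 10%) are rod-shaped capsules with aspect ratio drawn uniformly in
[2, 4] (shrunk if needed to stay inside the granule); the rest are discs at
0.6× the granule radius.  Intensities follow EM contrast (core 40 <
cytoplasm 110 < halo 210 by default), a planar multiplicative illumination
ramp (amplitude 0.15) and additive Gaussian noise (σ 8) are applied, and all
shapes are rendered with anti-aliased sub-pixel coverage so that morphometry
on noise-free scenes recovers ground truth to sub-pixel accuracy.  A pixel
belongs to an instance iff its center lies strictly inside the shape;
contested pixels in an overlap go to the granule they lie deepest inside.

FIB-SEM acquisition pixel sizes vary by instrument and are supplied by the
user for real data; synthetic scenes declare their own (default 25 nm/px,
128×128 frames ≈ 3.2 μm fields).  What the generator does
**not** emulate: 3-D continuity between consecutive sections, detector
noise statistics (only additive Gaussian), membrane-proximal ultrastructure,
and organelles other than the nucleus distractor.  Passing tests therefore
demonstrate that the algorithms recover a known ground truth under
controlled conditions — not performance on real micrographs.

## Watershed numerics

Seeds are local maxima of the Gaussian-smoothed distance transform, at least
`min_seed_separation_px` apart, and the watershed runs on the negated
smoothed distance map restricted to the foreground with 4-connectivity
(diagonal leakage between touching granules is blocked; every foreground
pixel keeps exactly one label, so areas are conserved).

Two numerical choices matter and were set by failure analysis on diagnostic
scenes:

* **Separation default = one minimum granule radius** (50 nm / pixel size,
  2 px at the default scale).  Two granules overlapping by the permitted 20%
  have centers ~1.4 r apart; an exclusion window of a full diameter merges
  exactly the seeds that most need separating.
* **Smoothing σ = 0.5 px, seeds found on a 2× upsampled mask.**  Smoothing
  exists only to break the plateaus of the integer-grid distance transform.
  A small granule leaning on a large one is separated by a saddle less than
  a pixel deep; σ = 1 erases it, and the integer grid itself cannot resolve
  it — the 2× nearest-neighbour upsampling can.  With these defaults the
  exact-count recovery rate on noise-free bounded-overlap scenes is ~97%
  (the residual failures are three-way clusters and granules whose
  cumulative overlap with several neighbours exceeds the pairwise bound).

Size gates (defaults from the 100–800 nm diameter prior at the configured
pixel size) remove sub-granule specks and merged super-granule blobs after
watershed; this filtering is what lifts object-level precision of the
trained pipeline from ~0.70 to ~0.85 on held-out scenes.

## Morphometry choices

* **Round coefficient** = 4π·area / perimeter² (isoperimetric ratio; 1 for a
  circle, lower for elongated shapes).
* **Perimeter** uses the 4-direction Crofton estimate.  A raw pixel-edge
  count biases the ratio to ~0.78 for digital circles; the weighted
  edge-configuration estimator keeps small-disc ratios up to ~1.08.  Crofton
  keeps rendered discs in [0.95, 1.05] for radii ≥ 5 px, which is the
  property the measurement needs.  Values are capped at 1.1 (discretization
  can push tiny instances slightly above 1).
* **Membrane distance** is measured from the granule's sub-pixel outer
  contour (marching squares at level 0.5) to the membrane polyline,
  edge-to-membrane: the docked-granule criterion (< 40 nm) is a gap far
  smaller than any granule radius, so centroid distances would be useless.
* **Dense-core radius** is the equivalent radius of the core instance,
  matched to its parent granule by maximal pixel overlap.
* **Density** = granules per μm² of cytoplasm (nucleus excluded); the s.e.m.
  is computed across cells (sample sd, ddof 1, / √n_cells), matching how
  per-cell cohorts are reported; with one cell it is 0 and flagged
  undefined.
* Group comparisons: Student's t-test (means), two-sample
  Kolmogorov–Smirnov (distributions), via scipy.

## Evaluation choices

Pixel metrics (pixel accuracy, mean per-class accuracy, mean IU) come from
the 2-class confusion matrix; classes absent from the truth are excluded
from the means.  Object-level scoring uses greedy one-to-one matching in
descending IoU order with a 0.5 default threshold; unmatched predictions are
FP, unmatched truths FN.  Object-level "true negatives" are not reported —
there is no countable population of correctly-not-detected objects; the
pixel-level TN is available from the confusion matrix.  When there are no
predictions at all, precision is reported as 0 with an explicit flag rather
than NaN so scene-level aggregation stays stable.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full train–predict–evaluate cycle completes in minutes on one CPU: 128×128
scenes at 25 nm/px, 100 training + 20 held-out scenes, 6 training epochs,
base width 16; watershed recovery on 100 noise-free scenes; density
calibration on 200 scenes per cohort.  These sizes are the package's
validation conditions, not claims about full-scale EM volumes.

## Known limitations

* The numpy network trains at desk scale only; there is no GPU path.
* Watershed seeding fails for granule clusters whose cumulative overlap
  exceeds the pairwise 20% bound (~3% of scenes at the default densities).
* Histogram equalization is global; severe local illumination gradients
  would need CLAHE-style processing, which is intentionally not included.
* Measurements are per 2-D section; no 3-D reconstruction or
  stereological correction is attempted.
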