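# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the accompanying tests do and do not show.

## The two-path pipeline

High-resolution (HR) short-axis volumes (2 mm slices, single breath-hold)
are artefact-free: the network segments them directly and each prediction
(volume + labels + landmarks) is recycled as a new atlas. Low-resolution
(LR) volumes (10 mm slices acquired over multiple breath-holds) carry
inter-slice shift, staircase and missing-slice artefacts that propagate into
any voxel-wise segmentation; the LR path therefore resamples the volume to
the HR lattice, segments it, and refines the result by landmark-initialised
multi-atlas propagation.

## The multi-task network

* **Representation.** A 3D volume enters as a multi-channel 2D image whose
  channels are the short-axis slices, so all convolutions are 2D while the
  slice dimension is mixed from the first layer onward. This keeps memory
  at 2D-network levels yet lets predictions use full 3D context — which the
  landmark task strictly needs.
* **Architecture.** A fine-to-coarse branch of 3x3 convolutions (each
  coarser level reached by 2x2 mean pooling), nearest-neighbour upsampling
  of every level back to the in-plane grid, concatenation, a 1x1 fusion
  convolution, and two 1x1 softmax heads emitting the 5-class tissue and
  7-class landmark distributions for every voxel. The heads additionally
  see the raw input slices (a skip connection): per-slice intensity
  evidence then reaches the per-slice output channels directly instead of
  being squeezed through the fused feature bottleneck — without this the
  small CPU-sized configurations train poorly. The default configuration
  has 15 convolutional layers; the benchmark preset is smaller
  (`NetConfig.tiny`: 10 convolutions, widths 12–32).
* **Loss.** The printed global-quotient Dice loss plus the class-balanced
  landmark cross-entropy plus weight decay (README formulas). The global
  Dice quotient is dominated by the background class on strongly imbalanced
  grids; a per-class variant is available behind
  `NetConfig.dice_per_class` and is what the benchmark preset trains with.
  Balancing weights are computed per sample exactly as `1 − |Y_k|/|Y|`.
  Log-probabilities are clamped at 1e-12; the Dice smoothing constant
  defaults to `ε = 1e-5`. `α` (landmark weight) defaults to 1 in the
  library and 1e-3 in the benchmark preset, where the landmark gradients
  are orders of magnitude larger than the Dice gradients; `β = 1e-4`.
* **Optimisation.** Plain SGD with momentum 0.9 is implemented and is the
  library default. The benchmark preset uses Adam (lr 1e-2, linear decay to
  1e-3, 40 epochs): on the CPU-scale problems used here Adam reaches the
  same accuracy several-fold faster, which is what makes whole-suite runs
  feasible; both optimisers are exposed in `NetConfig`.
* **Training robustness.** Landmark localisation has a rare mirror-swap
  local optimum (both RV insert classes collapse onto one side, ~25 mm
  error) reached from roughly one in six weight initialisations. A held-in
  probe at epoch 10 measures the training-set landmark error (collapsed
  runs read >8 mm where healthy runs read ≤6 mm) and deterministically
  restarts from a derived seed. Augmentation (in-plane translation,
  isotropic scaling, rotation about one random axis, intensity gain — no
  shearing, no flips) is applied on the fly each iteration.
* **Decoding.** Per-voxel argmax (ties towards the lower class index, i.e.
  background-favouring); each landmark is the centre of gravity of the
  largest connected component of its class, weighted by the softmax
  probability so that large low-confidence blobs do not bias the point.

## Shape refinement

* **Landmark affine.** 12-DOF least squares over the six named landmarks;
  exact whenever the target is an affine image of the source (the problem
  is convex), degenerate configurations (<4 correspondences, coplanar)
  raise. Label-based affine initialisation is deliberately not used.
* **Atlas selection.** Studholme NMI, `(H(A)+H(B))/H(A,B)`, on the discrete
  joint label histogram of the target segmentation and each affinely warped
  atlas segmentation; deterministic ordering; default `L = 5` atlases
  (benchmark preset: 3, a runtime choice).
* **FFD registration.** The deformation is a cubic B-spline control lattice
  over the target grid (one control point beyond each edge), composed with
  the affine. The optimised surrogate lifts atlas labels to lightly
  smoothed one-hot fields and scores the masked mean with C2 cubic-spline
  interpolation; piecewise-linear interpolation of raw one-hot fields has
  kinks at every voxel that trap gradient ascent at its initialisation.
  Ascent is coarse-to-fine (default control spacings 40/20/10 mm; benchmark
  20 mm) with backtracking line search, so the optimised agreement is
  non-decreasing within every level; a small quadratic displacement penalty
  (1e-3) suppresses the surrogate's drift-into-interior bias. The field is
  kept only if the hard-label agreement strictly improves on the
  affine-only start, otherwise the identity FFD is returned. Computation is
  restricted to a bounding box around the foreground (+6 voxels).
* **Fusion.** Non-local Gaussian-patch-weighted voting (README formula)
  with patch and window radii of 1 voxel in the benchmark preset (library
  default 2). Patch distances are means over in-frame patch voxels, which
  normalises consistently at borders; window positions outside the frame
  cast no vote; ties resolve to the lower class index. The bandwidth `h`
  defaults to a scale-adaptive rule — the mean over voxels of the minimum
  centred patch distance across atlases — times `h_scale` (benchmark 10;
  wider kernels approach a majority vote, which is more robust when the
  target intensities are themselves artefact-corrupted). Single-voxel
  satellite components left by voting are absorbed into their surrounding
  label.

## The phantom cohort

The generator emulates the statistical structure of an adult ED-frame
short-axis study: the LV as two coaxial truncated half-ellipsoids (cavity
radius 22 mm, wall 8 mm, apex-to-base 80 mm), the RV as a crescent formed by
a larger laterally shifted ellipsoid (radius 30 mm, offset 24 mm, free wall
5 mm) clipped against the LV epicardium, on an 80x80x50 grid at
2 x 2 x 2 mm. The through-plane spacing and the artefact simulation (2 mm →
10 mm thick slices by mean pooling/majority vote, uniform integer-voxel
in-plane shifts ≤5 mm per slice, one truncated apical slice) reproduce the
clinical LR/HR relationship; the in-plane spacing is coarser than a
clinical 1.25 mm acquisition purely to keep whole-cohort experiments
CPU-friendly (1.25 x 1.25 x 2 mm remains the library's preprocessing
default). Intensities are class means on the [0,1] scale (bright blood
pools, mid-grey myocardium), a 0.5-voxel partial-volume blur, and i.i.d.
Gaussian noise (sd 0.04). Landmarks are placed by continuous geometric
rules in the heart frame and mapped through the pose, so rigid pose changes
move them exactly. Cohorts jitter global size (±8%), wall thicknesses
(±10%), RV geometry (±6%), orientation (±5°/±15°) and position per subject.

What the phantoms do **not** model: papillary muscles and trabeculation,
myocardial texture, Rician noise, intensity inhomogeneity, cine motion, a
realistically large RV volume (the crescent is thinner than a real RV, so
absolute RVV values are below clinical norms), and pathology beyond a
simple dilated-RV/compressed-LV preset. Passing benchmarks therefore show
that the algorithms behave as designed under controlled geometry — not that
clinical-grade accuracy would be reached on hospital data.

## Benchmark problem sizes

The end-to-end benchmark uses 30 phantoms (10 train / 10 bank / 10 test)
with the tiny network configuration, and the training benchmark 20 + 5; the
sizes keep a full run in the ten-minute range on a single CPU while leaving
every pipeline stage exercised at realistic anatomy-to-artefact ratios.
With these sizes the low-resolution path recovers all four tissue classes
relative to the corrupted input, with the remaining gap to the
high-resolution path dominated by landmark localisation error (~5–6 mm,
the same order as the artefact magnitudes), which the 12-DOF affine
amplifies; with ground-truth landmarks the identical refinement machinery
scores >0.9 mean foreground Dice. Scaling the training cohorts and network
capacity is the expected route to closing that gap.

## Degenerate inputs and edge conventions

Constant volumes preprocess to all zeros (not NaN). Dice of two empty masks
is 1, one-empty is 0; Hausdorff on an empty mask raises rather than
returning 0. Landmark classes with no predicted voxels are reported absent,
never fabricated. Oversized inputs fail preprocessing unless centre-crop is
explicitly enabled. Myocardial mass uses 1.05 g/ml. Hausdorff distances are
computed between 26-connectivity boundary voxel centres in mm (full, not
percentile). All randomness flows from explicit integer seeds; there are no
wall-clock defaults.
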