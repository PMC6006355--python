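# Methods

This note documents the models, conventions, defaults and limitations of
the package in one place.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic phantoms

The phantom generator emulates the *inputs* of a multi-reader chest-CT
annotation study, not CT physics.

* **Background.** Lung parenchyma is i.i.d. Gaussian HU noise,
  mean −700 HU, sd 60 HU — plausible aerated-lung values; only the
  nodule/background contrast matters downstream.
* **Nodules.** A nodule is a sphere of radius `radius_mm` with HU raised
  by `contrast_hu` (default +500, soft-tissue-like against lung).
  `heterogeneity` scales multiplicative smoothed-Gaussian texture inside
  the nodule; `spiculation` modulates the radius with a smooth random
  function of direction (0 = exact sphere, in which case the rendered
  mask equals the analytic lattice-point set exactly — a tested
  invariant).  "Non-nodule" findings are bright elongated cylinders
  (vessel-like), so the automated segmenter has a real structure to find.
* **Simulated readers** (≤ 4, matching a four-radiologist study) re-draw
  each slice boundary by radial perturbation of the traced contour with
  circularly smoothed Gaussian noise of sd `contour_jitter_mm`, and
  report the true malignancy perturbed ±1 with probability
  `rating_noise`, clipped to [1, 5].
* **Cohort defaults** (the study conditions used by the tests and the
  acceptance script): 64×64×24 voxel volumes at 1 mm isotropic spacing,
  one nodule per patient; benign-like radius ~ N(3.0, 0.4) mm with
  heterogeneity 0.15, spiculation 0.05 and true rating ∈ {1, 2};
  malignant-like radius ~ N(5.5, 0.6) mm with heterogeneity 0.6,
  spiculation 0.3 and rating ∈ {4, 5}; 4 readers with 0.5 mm jitter and
  0.2 rating noise.  The radius gap is the main separability dial and is
  deliberately generous: phantom experiments validate the *machinery*
  (splits, feature plumbing, training loops, fusion), not clinical
  difficulty.

What phantoms do **not** emulate: scanner noise spectra, slice-thickness
anisotropy, partial-volume effects, pleural attachments, or the true
distribution of LIDC-style masses.  Passing the phantom pipeline shows
the implementation is correct and recovers a planted signal; it says
nothing about accuracy on real cohorts.

## Contours, masks and consensus

Contours are stored as closed polygons per transverse slice.  Masks are
converted to polygons by tracing pixel *edges* (vertices at half-integer
coordinates), so the polygon→mask→polygon cycle is exact: no pixel
centre ever lies on a polygon edge.  Generic polygons are rasterised by
even-odd parity (per-ring XOR), which also handles holes.

The consensus vote keeps a voxel iff it appears in ≥ 50% of the member
segmentations.  The denominator is per *nodule* (all member
segmentations of the cluster); a per-slice denominator — counting only
readers who contoured that slice — is available as a flag because the
phrasing "available segmentations" is genuinely ambiguous when readers
contour different slice ranges.  The consensus rating collects one
rating per (member annotation, slice) pair on slices intersecting the
consensus mask, averages, and rounds; exact .5 ties round away from zero
(configurable), a case that cannot arise from 1–4 integer ratings unless
counts are even.  Clustering uses transitive ≥ 1-voxel overlap
(union-find), which guarantees pairwise-disjoint cluster voxel sets.

Selection and splitting follow a two-stage policy: one eligible nodule
uniformly per patient, then the minority class is topped up with all
eligible minority nodules from patients whose stage-1 draw was not
majority-class, trimming any overshoot at random.  The train/validation
split assigns whole patients to one side and balances class counts
within each side by random discard — the exact reconciliation between a
patient-level split and exact balance is under-determined, and
balance-by-discard is the simplest deterministic rule.

## Radiomic features

All 50 features are 2-D, computed on the transverse slice with the
largest in-mask area (ties → lowest index).  Choices for the
under-specified definitions:

* **Perimeter** is the marching-squares boundary polygon length with two
  passes of closed (1,2,1)/4 vertex smoothing, which removes most of the
  staircase rasterisation bias (a rasterised disk measures within ~2% of
  2πr, so circularity 4πA/P² of disks lands near 1).  Rings with < 8
  vertices (e.g. a single pixel) are measured as drawn.
* **Rotational moments** are eigenvalues of the second central moment
  matrix of in-mask pixel areas (each pixel contributes its own
  rectangle inertia), keeping one-pixel-wide masks finite and making a
  single square pixel's moment ratio exactly 1.
* **Entropy** uses 64 equal-width bins over the in-mask HU range
  (constant region → 0 bits); bin count configurable.
* **Difference image** is HU minus the right (+x) neighbour's HU where
  both pixels are in-mask; no valid pair → all six statistics 0.
* **Lacunarity** Λ(s) = var(m_s)/mean(m_s)² + 1 over stride-1 gliding
  s×s boxes inside the mask bounding box, s = 2¹…2¹⁰; boxes exceeding
  the bounding box return the translation-invariant neutral value 1.
* **NGTDM** textures use 32 gray levels over the in-mask HU range,
  validity = full (2d+1)² neighbourhood inside the mask, ε = 10⁻⁶
  denominator guard, coarseness capped at 1/ε.  The implementation is
  vectorised and cross-checked against an independent double-loop oracle
  exhaustively over all 2-level 4×4 images.
* **Distance to surface** is the Euclidean distance (mm, anisotropic
  sampling) of in-mask pixels to the nearest *boundary pixel*, so
  boundary pixels score 0; normalised variants divide by the in-mask
  maximum (0 when degenerate).
* **Fractal dimensions** are least-squares box-counting slopes over
  dyadic box sizes anchored at the bounding box; masks supporting fewer
  than three sizes return 1.
* **Gradient margin** is the mean central-difference HU gradient
  magnitude (HU/mm) over boundary pixels.
* Degenerate inputs map to finite values everywhere (skewness/kurtosis
  of constant data = 0, etc.) so classifiers never see NaN; a fuzz test
  over 1,000 random nodules asserts finiteness.

Features are passed to the Random Forest unstandardised (forests are
scale-insensitive).  The "no-size" forest variant excludes pixel count,
area, both spans, perimeter and summed surface distance — a documented
configuration value, since "direct measures of size" admits several
readings.

## Patch datasets

Patches are axis-aligned X×Y×Z crops whose centre voxel
(index ⌊size/2⌋ per axis) is the half-up-rounded consensus centroid;
out-of-scan voxels are filled with the scan minimum HU (air-like,
configurable).  Each HDF5 record stores the voxels (slice-major
N×Z×Y×X), consensus rating (0 for non-nodules), whole-scan HU extremes,
class id, patient id and a stable key shared with the radiomic table.
The stored scan extremes are used to normalise patches to [0, 1] before
the CNN (configurable) — their presence in the schema is what motivates
normalising there rather than earlier.

## CNN

Two reference layouts: CNN47 = conv(5×5, 32) – pool(2×2, s2) –
conv(3×3, 64) – pool(2×2, s2) – dropout 25% – FC 512 – dropout 50% –
FC 200 – softmax 2; CNN21 identical but with a single pool.  The
200-unit penultimate layer and 2-unit softmax are hard constraints; the
rest is configurable.  Z-slices enter as channels, so convolutions are
2-D.  Inputs 21×21×3 and 31×31×3 are accepted by the patch layer and
train with custom configs.

Training: cross-entropy, batch 64, inner 80/20 record-level split
redrawn per run from the seed (the patient-level guarantee applies to
the outer split only), augmentation per batch sample (uniform shift
≤ 30% per in-plane axis, rotation uniform in [0°, 180°], scale jitter
±10% — the jitter range is unstated upstream and is a configurable
default), bilinear resampling with patch-minimum fill.  A checkpoint is
saved whenever the inner-test loss improves; the final weights plus the
three checkpoints with the highest inner-test accuracy are retained
(≤ 4 entries).

**Optimiser.** Default Adam, lr 10⁻³.  With a few hundred training
records and batch 64 there are only a handful of gradient updates per
epoch, and plain SGD with momentum does not converge in the short
(~30-epoch) runs the test suite uses under full augmentation; Adam does.
SGD + momentum remains available via `TrainConfig(optimizer="sgd")` for
long runs.  Everything is seeded and bit-reproducible on a fixed BLAS
configuration (single-threaded recommended).

## Fusion, baseline and evaluation

The fused vector is the 50 radiomic features followed by the 200 CNN
features (250 total, order fixed).  The fusion classifier is a
1000-tree Random Forest with library defaults otherwise (unlimited
depth, √p features per split).  The size baseline is a one-covariate
logistic fit on √(largest cross-sectional in-mask area) in mm; for
non-nodule regions the automatically segmented mask supplies the area,
accepting that such masks run large and round.

AUC is computed by the rank-based Mann–Whitney construction with ties
counted ½ (verified exhaustively against pair counting on small score
vectors); accuracy/sensitivity/specificity come from the confusion
matrix at probability 0.5 (a Youden-optimal threshold helper is
provided, since the thresholding rule behind reported accuracies is
ambiguous).  The low-data stress test trains the forest on one positive
and one negative example and evaluates on the remainder, averaging over
200 repeats.

## Problem sizes

The test suite and acceptance script run everything at phantom scale,
chosen to exercise every code path at full fidelity: 400-nodule cohorts
on 64×64×24 volumes, CNN21 for 30 epochs, 1000-tree forests, 200
low-data repeats.  These are the package's reference conditions for the
synthetic experiments; larger cohorts and 200–400-epoch runs use the
same code paths unchanged.

## Known limitations

* Radiomics are strictly 2-D (single-slice); no 3-D texture variants.
* The XML dialect is a minimal LIDC-like schema, not a parser for every
  quirk of real LIDC files (blinded sessions, non-malignancy
  characteristics).
* No resampling to isotropic spacing; features honour anisotropic
  spacing where distances are involved, but texture neighbourhoods are
  defined in pixels.
* The automated segmenter is fixed-threshold region growing with
  closing — adequate for bright structures, not a general lesion
  segmenter.
* Phantom results establish implementation correctness, not clinical
  performance.
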