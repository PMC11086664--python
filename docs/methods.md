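# Methods

This note documents the models, algorithmic choices and limitations of
`bpequant`, the automated background parenchymal enhancement (BPE) scoring
pipeline for breast DCE-MRI.

## The quantity being computed

Clinically, BPE is the contrast uptake of normal fibroglandular tissue
(FGT) on dynamic contrast-enhanced MRI, rated visually on the ordinal
BI-RADS scale *minimal / mild / moderate / marked*. Radiologists rate it
from early-phase maximum intensity projections (MIPs) of subtraction
images, and an enhancing tumor inside the field can inflate the rating.
The computer BPE score mimics that reading: it is the **mean pixel
intensity of an 8-bit display version of a subtraction-projection image
within a breast mask**, computed before and after the segmented lesion has
been electronically removed. Scores are produced over a grid of image
variants — region (both / affected / unaffected breast) × projection
(MIP / AIP) × post-contrast time point (first / second) × intensity mode
(original 0–255 / rescaled 0–1).

## Pipeline stages

### Subtraction volumes

`post_t − pre` on the shared exam grid, clipped at 0 by default (negative
differences are noise; MIPs are unaffected, AIPs would be biased downward
without clipping; a flag disables clipping). Axis 0 is the through-plane
slice axis; projections collapse it.

### Lesion segmentation (fuzzy c-means)

The known (diagnosed) lesion is segmented inside a caller-supplied ROI box
by Bezdek-style fuzzy c-means on the subtraction intensities:

    u_ik = 1 / Σ_j (d_ik/d_jk)^(2/(m−1)),   v_i = Σ_k u_ik^m x_k / Σ_k u_ik^m

with fuzziness `m = 2`, tolerance `1e-5` on the maximum centre shift, and
deterministic initialisation of centres at evenly spaced quantile
positions (for `c = 2` exactly the ROI min and max). Voxels whose
membership in the brightest cluster exceeds 0.5 are candidates; the
largest 26-connected component with slice-wise hole filling is the lesion.
The pipeline default is **c = 3**: a lesion ROI on a subtraction volume
contains three intensity populations — fat (≈0), enhancing parenchyma, and
lesion — and with `c = 2` the bright-cluster centre settles between
parenchyma and lesion so the candidate mask merges both. All FCM
hyper-parameters are exposed in `PipelineConfig`.

Lesion size is reported as `sqrt(area)` of the lesion on its centre slice,
the slice of maximal cross-section (ties broken toward the lower index).
For a sphere of diameter d this gives ≈ 0.886·d.

### Electronic lesion removal

On each slice through the lesion, lesion pixels are replaced by one
constant: the mean of the border ring, i.e. the 8-connected dilation of
the slice lesion region (width 1 pixel by default, configurable) minus the
region, clipped to image bounds. The fill is computed from the same volume
being edited; a flag selects the second-post-contrast border mean instead
when editing other time points. A lesion filling an entire slice falls
back to the volume-level 3D border mean with a recorded warning. No other
voxel is modified, and the operation is idempotent.

### Projections

MIP = per-pixel maximum over slices, AIP = per-pixel mean; no resampling,
no oblique or rotating projections.

### Breast segmentation

A compact NumPy U-Net (three resolution levels, widths 8/16/32, 3×3
convolutions + ReLU, 2×2 max-pool, nearest-neighbour upsampling with skip
concatenation, sigmoid head) is trained on second-post-contrast
subtraction MIPs with Adam and a binary cross-entropy loss; forward and
backward passes are written directly in NumPy (im2col + GEMM, float32),
sized for desk-scale training at 128×128. Training is deterministic given
the seed. Post-processing follows the reference recipe: probability
threshold **0.25**, largest 8-connected object, hole filling, then a
vertical split at the horizontal centre of the component's bounding box
(a centroid-column split is available behind a flag) into affected and
unaffected breasts.

A non-learned fallback (Otsu threshold + largest object + hole fill) lets
the pipeline run without training, but a single global threshold cannot
include non-enhancing fat inside the breast outline; on phantoms it
reaches breast Dice of only ~0.5–0.7 and it is a convenience, not the
reference route.

### Scoring and the 8-bit display mapping

Each (region, projection, time point) image is windowed to
`[0, max(in-region intensity)]` and linearly quantized to 0–255 — the
"original" display image; the window percentile is configurable, but a
sub-maximal percentile makes the window depend on whether the lesion's
projected area exceeds the excluded tail, which splits exams into two
display regimes and degrades cross-exam comparability. The "rescaled"
image maps the quantized image's min–max range to [0, 1] (a literal
divide-by-255 mode exists behind a flag). The score is the mean over
in-mask pixels only.

For **lesion-removed variants the window and the rescale min–max are taken
from the matching before-removal image**: removal edits the displayed
image, so its display mapping is held fixed. Without this convention,
per-image min–max renormalization after deleting the brightest structure
would *inflate* the after/before ratio above 1; with it, the ratio is ≤ 1
whenever the lesion is the brightest structure, and the unaffected
breast's score is bit-identical before and after removal.

### Evaluation

* **Kendall tau-b** between ordinal ratings and scores, with significance
  from the normal approximation of S = P − Q under the null using the
  standard tie-corrected variance. Two-sided p-values.
* **ROC**: empirical AUC = Mann–Whitney statistic with the 0.5 tie
  convention; standard error by the DeLong structural-components
  estimator; z = (AUC − 0.5)/SE against chance, two-sided, Bonferroni
  multiplied by a caller-supplied family size (default 13). A conventional
  binormal maximum-likelihood fit (Dorfman–Alf on ~10 rank bins,
  negatives ~ N(0,1), positives ~ N(a/b, 1/b), AUC = Φ(a/√(1+b²))) is
  available as an option; the "proper" degenerate-free binormal model is
  deliberately out of scope, so the empirical estimator is the default and
  the one used in all reported numbers.
* **Tasks**: minimal-vs-marked (intermediate levels dropped) and
  low (minimal+mild) vs high (moderate+marked).
* **Ratio table**: per-exam after/before score ratio joined to lesion
  size, aggregated by rating level and size bin.

## The phantom generator

The phantom provides studies with known BPE level and geometry so every
stage is trainable and testable without clinical data. Defaults define the
study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| grid | 24×128×128 voxels at 3.0×1.5×1.5 mm | exam grid (depth × rows × cols) |
| anatomy | two half-ellipsoid breasts (semi-axes 30/60/46 mm) anterior to a flat chest-wall band, overlapping near the midline | the projected both-breast region is one connected component, so largest-object selection and the vertical split are non-trivial |
| FGT | smoothed Gaussian blob field, top fraction = `fgt_fraction` (0.35) of breast volume inside the inner breast | stands in for parenchymal morphology |
| level → amplitude | 0.10 / 0.25 / 0.45 / 0.70 of a 200-unit dynamic range | enhancement amplitude per BPE level |
| level → enhancing FGT fraction | 0.15 / 0.40 / 0.70 / 0.95 | nested (top-quantile of the same blob field), so enhancing coverage grows monotonically with level |
| uptake | FGT/skin/chest (0, 0.65, 1.0); lesion (0, 0.95, 1.0) | monotone uptake; lesions enhance faster |
| skin rim | thin shell (scaled radius ≥ 0.93, central slab) at amplitude 20 | the enhancing skin outline that delineates breasts on real subtraction MIPs |
| chest band | amplitude 6 | weakly enhancing posterior tissue |
| lesion | sphere, amplitude = FGT amplitude × 3 | `lesion_contrast_multiplier` configurable |
| noise | additive Gaussian, sd 1.0, clipped at 0 | thermal noise at subtraction-image scale |

The two (amplitude, enhancing-fraction) sequences are strictly increasing,
which is what makes the programmed levels recoverable; both are documented
tunables, chosen once. Cohorts draw levels from a caller-supplied
distribution, lesion diameters uniform in 4–30 mm by default (the sizing
check permits larger lesions on larger grids), and derive per-study seeds
deterministically from the cohort seed.

**What the phantom does not emulate**: pharmacokinetics (no Tofts-style
modelling), Rician noise statistics, coil inhomogeneity, motion, major
vasculature, and the real-world variability of parenchymal morphology.
Passing phantom tests therefore demonstrates that the pipeline's logic and
statistics behave as designed under controlled conditions — not that the
trained segmenter or the score thresholds transfer to clinical images.

## Problem sizes and numerical choices

* Cohort experiments use 60 phantoms (15 per level); the segmenter is
  trained on 40 MIPs at 128×128 for 15 epochs (cap 30), batch size 4,
  Adam lr 2e-3 — on these phantoms the held-out breast Dice is ≈ 0.99,
  far above the 0.85 gate, so the shortened schedule is comfortable.
* FCM distances are floored at 1e-12 so coincident voxel/centre pairs get
  full membership without overflow; the objective is tracked per iteration
  and is non-increasing.
* Degenerate inputs: constant ROIs yield an empty lesion mask with a
  warning (not an exception); constant display images rescale to zero with
  a warning; single-valued score vectors yield AUC 0.5 with infinite SE.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical spec + seed reproduces
  bit-identical volumes, training runs and score tables.

## Known limitations

* Scoring is 2D (projection-based); the 3D lesion segmentation is only
  used to edit the volume before projection.
* The ROI box for the lesion must be supplied (manifest or ground truth);
  lesion *detection* is out of scope.
* The binormal ROC option uses the conventional (not degenerate-free)
  parameterisation and is fitted by a derivative-free optimiser; it is an
  option for comparison, not the default inferential route.
* No inter-volume registration: misaligned time points are the caller's
  responsibility.
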