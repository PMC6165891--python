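# Methods

This note documents the models, numerical choices, and limitations behind
`lesionkit`, in the order the pipeline runs them.

## Volume model and storage conventions

A `Volume` is a 3-D scalar grid plus a 4×4 voxel-index→world-mm affine.
On read, the affine is taken from the NIfTI sform when its code is
nonzero, else the qform, else the header's pixdim fallback — the
precedence most neuroimaging tools apply, chosen so convention detection
is deterministic. Inconsistent qform/sform pairs are logged and the
precedence applied without attempting repair; the pipeline assumes
upstream DICOM→NIfTI conversion was correct. Masks are binarized on read
(values > 0 → 1) before any computation.

Storage convention is the sign of det of the affine's spatial 3×3 block:
negative = radiological (patient's left stored on the image's right),
positive = neurological. This is a header-level criterion only; the
package never tries to detect anatomical left/right mislabeling from
image content.

## Orientation harmonization

`to_radiological` flips the first voxel axis and updates the affine
(column negation plus translation), so every voxel center keeps its world
coordinate; an already-radiological volume is returned unchanged, making
the operation idempotent. `to_canonical` permutes/flips axes so each
affine column's dominant entry lands on the diagonal, preserving the
volume's convention; equal-magnitude dominant entries are broken toward
the lower axis index.

Per subject, harmonization is all-or-nothing: if the T1, lesion mask(s),
and any optional brain/WM masks do not share one convention, the subject
is flagged, nothing is modified, and the subject is excluded from every
later stage (recorded in `flagged_subjects.csv` with per-file
conventions). A defensible auto-fix exists for some mixed cases (e.g.
radiological T1 with neurological lesion), but flags are deliberately
never auto-repaired: a convention mismatch usually indicates an upstream
conversion error that only a human can adjudicate. Grid-shape mismatch
between T1 and lesion likewise flags (reason `shape-mismatch`) rather
than aborting the cohort run.

Skip options are uniform across the cohort: if any subject lacks an
optional input whose producing stage the run asked to skip, that stage is
forced back on for **all** subjects, and the override is logged.

## Tissue preparation (stand-ins for external skull stripping / segmentation)

Users with existing brain or WM masks supply them and the stages are
skipped. Otherwise:

* **Intensity normalization** maps [min, max] of the *full* volume
  linearly onto [0, 255] (normalization precedes skull stripping in the
  stage order, so the brain-only range is not yet available). Values stay
  continuous; a constant volume degenerates to all zeros with a warning.
* **Brain extraction**: Otsu threshold (256-bin histogram, parameter-free
  and reproducible), largest 6-connected supra-threshold component,
  morphological closing (2 iterations), hole filling, then a 2-voxel
  dilation margin. The margin retains the peri-cortical CSF layer that
  intensity thresholding excludes, analogous to the way dedicated
  skull-strippers keep a brain-surface margin.
* **WM segmentation**: three-class 1-D k-means (Lloyd) on within-brain
  intensities, class means initialized at the 25th/50th/75th percentiles,
  fixed-point iteration to tolerance 1e-6 or 100 sweeps; WM is the class
  with the highest mean. No RNG is involved, so results are exactly
  reproducible. Fewer than three distinct within-brain intensities is a
  stage error. The segmentation runs on the raw (lesioned) brain, so
  lesion voxels are assigned to whatever intensity class they fall in —
  with the default phantom they land in the GM class, which is the
  desired behavior for the downstream WM mean.

These are documented stand-ins, not numerical reproductions of BET/FAST.

## Lesion correction

On the 0–255 scale, with μ the arithmetic mean T1 intensity over the WM
mask and p the removal percentage (default 5):

    h = 255 · (p/100) / 2        window = [μ − h, μ + h]

Lesion voxels with intensity inside the window (bounds inclusive) are
removed; the survivor mask is re-binarized. The window is not clamped to
[0, 255] — normalized intensities cannot exceed that range, so clamping
would be a no-op. Whether the WM mean should include lesion voxels that
the segmentation placed in the WM class is genuinely open; the default
includes them (the plain mean over the segmentation), and
`exclude_lesion` / `--wm-mean-exclude-lesion` opts into excluding them.
Removal accounting (original/removed/surviving counts, percent removed,
window) is written per (subject, lesion) to
`lesion_correction_report.csv`. Correction is monotone in p: the removed
set at p₁ ≤ p₂ is nested.

Correction targets manual tracings. Automated segmenters typically
already exclude normal-intensity WM, so the pipeline logs a warning when
the config labels lesions as automated provenance.

## Registration and lesion load

The template-space registration is a 12-parameter affine (3 translations
mm, 3 rotations deg, 3 scales, 3 shears) maximizing normalized
cross-correlation, optimized by derivative-free coordinate descent in a
fixed parameter order over a 3-level pyramid (downsample ×4, ×2, ×1 with
Gaussian pre-smoothing; sweep caps 100/50/25). Initialization aligns
centers of mass and scales by foreground bounding-box extents; steps
halve when a sweep yields no improvement and the level stops below step
tolerance (0.25 mm / 0.25° / 0.4 %). The metric is evaluated inside the
fixed image's foreground bounding box so background voxels cannot
dominate. The procedure is wholly deterministic and is *not* numerically
equivalent to FSL flirt; a user-supplied 4×4 world→world matrix file
(`<subject>_to_template.mat`) bypasses estimation. Subjects already on
the template grid take an identity shortcut with bit-identical outputs.

Masks are always resampled with nearest-neighbour interpolation (linear
on a mask is rejected); anatomical volumes use trilinear. On the default
phantom, known perturbations up to 10 mm translation, 5° rotation, and
1.1 scale are recovered to within 1 voxel / 2° / 2 %.

Lesion load binarizes both masks, sums, zeroes below 2, re-binarizes
(equivalently the voxelwise AND), and reports
100·|overlap|/|ROI| — the denominator is the ROI volume, not the lesion
volume. ROI sources: a directory of template-space ROI files plus the
template volume, or per-subject integer label volumes with a code→name
table (used in subject space without registration). Atlas ROI files
(corticospinal tract, cortical/subcortical parcellations) are external
data the user supplies.

## Inter-rater metrics

Dice DC = 2|X∩Y|/(|X|+|Y|); undefined (error) when both masks are empty.
`pairwise_dice` computes all n(n−1)/2 unordered pairs; the summary ±
value is the SEM over pair values (pairs are not independent — they share
tracers — so the SEM is a descriptive label, not a confidence
machinery). Heat maps count per-voxel tracer membership (0..n).

## Visual QC

Each producing stage renders one tri-planar PNG per subject (slices
through the first overlay's centroid when a lesion overlay exists, else
the volume center — slice selection is this package's choice) and
assembles a static HTML gallery. The review state lives in the CSV
beside the page, not in the HTML checkboxes: a CSV is bit-stable,
diff-able, and scriptable. Galleries never overwrite a review CSV that
already contains decisions. In interactive mode the run blocks until
every row is decided; in no-pause mode blank rows default to pass with a
logged warning. Gating is monotone: a subject failed at one stage
appears in no later stage's outputs. The lesion-correction gallery
overlays both the original tracing and the corrected mask in distinct
colors.

## Synthetic phantoms: what they do and do not show

The phantom is a nested-ellipsoid head: CSF shell, GM shell, WM core
(tissue means 40/110/180, arbitrary units), a bright skull shell
(mean 230) separated from the brain by a ≥4-voxel dark gap, additive
Gaussian noise (SD 5), on a 64×80×64 grid at 2 mm isotropic in
neurological convention — so harmonization is exercised by default. The
lesion is an ellipsoid inside the brain, partially overlapping WM, with
intensity reassigned to WM·(1−0.35) ≈ the GM range: clearly hypointense
relative to WM yet outside the default 5 % removal window, as a chronic
stroke lesion on T1 is. All generators are pure functions of (spec,
seed).

Tracer variants model two error sources: whole-boundary dilation/erosion
(signed Normal(0, boundary_sd) steps) and tracer-specific sprinkles of
peri-lesional voxels, drawn by default from the 3-voxel shell around the
truth mask or from a caller-supplied region such as healthy WM. Sprinkle
counts are uniform on [0, 0.15·|lesion|]. Because sprinkles carry WM
intensity, correction removes them and inter-rater Dice rises — the
direction the correction module is designed to produce; the effect size
on real tracings depends on tracer behavior the simulation does not
model.

The phantom omits bias fields, Rician noise, gyral anatomy, partial
volume, and pathology diversity. Passing tests therefore demonstrate
algorithmic correctness (formulas, bookkeeping, geometry, determinism),
not clinical robustness on real MRI.

## Problem sizes and runtime choices

Tests and examples use the default 64×80×64 phantom; the inter-rater
direction check uses 20 replicates × 10 tracers (45 pairs each), and
registration checks use single phantoms with known header perturbations.
These sizes were chosen to keep the full suite fast on a laptop while
leaving every code path exercised at realistic (2 mm template-grid)
resolution.

## Known limitations

* Brain extraction and WM segmentation are intensity-only stand-ins; on
  real data with bias fields they will underperform dedicated tools, and
  the pipeline expects users to supply masks from those tools instead.
* The registration metric is correlation-based and mono-modal; no
  mutual-information or nonlinear warping.
* Logs are written under the output directory (`<output>/logs/`), so a
  read-only installation directory is never a problem.
* 4-D series, NIfTI-2, DICOM, and MGZ inputs are out of scope; convert
  to 3-D NIfTI-1 first.
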