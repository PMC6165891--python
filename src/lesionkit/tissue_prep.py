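"""T1 intensity normalization and brain / white-matter mask production.

The lesion-correction algorithm needs three things from the anatomy: the
T1 rescaled to 0–255, a brain mask, and a white-matter mask.  Users who
already have masks (from BET/FAST, FreeSurfer, or manual editing) supply
them and the stages are skipped; otherwise the stand-ins here are used:

* brain extraction — global Otsu threshold (256-bin histogram), largest
  6-connected component, morphological closing and hole-filling, plus a
  small (2-voxel) dilation margin so peri-cortical CSF is retained the way
  skull-stripping tools retain it;
* WM segmentation — three-class 1-D intensity clustering (k-means/Lloyd on
  the within-brain intensity histogram, class means initialized at the
  25th/50th/75th percentiles), white matter being the brightest class.

Both are deterministic: no RNG is involved anywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "MaskProvenance",
    "TissueSet",
    "StageError",
    "normalize_intensity",
    "extract_brain",
    "segment_white_matter",
]

BRAIN_MARGIN_VOXELS = 2  # peri-cortical CSF margin, in voxels


class StageError(RuntimeError):
    """A processing stage failed for a subject (run continues with others)."""


class MaskProvenance(Enum):
    COMPUTED = "computed"
    PROVIDED = "provided"


@dataclass
class TissueSet:
    """Normalized T1 plus brain and WM masks with their provenance."""

    normalized_t1: Volume
    brain_mask: Volume
    wm_mask: Volume
    brain_provenance: MaskProvenance
    wm_provenance: MaskProvenance


def normalize_intensity(t1: Volume) -> Volume:
    """Linearly rescale the full volume's intensities onto [0, 255].

    The map sends [min, max] -> [0, 255]; output values stay continuous.
    A constant input has no spread to map and yields an all-zero volume
    with a warning.
    """
    data = t1.data.astype(np.float64)
    lo, hi = float(np.min(data)), float(np.max(data))
    if hi == lo:
        warnings.warn("constant T1 volume: degenerate normalization, output is all zeros")
        return t1.with_data(np.zeros_like(data))
    return t1.with_data((data - lo) * (255.0 / (hi - lo)))


def extract_brain(t1: Volume) -> Volume:
    """Stand-in skull stripping: threshold + largest component + morphology.

    Steps: Otsu threshold (256 bins) on the intensity histogram; keep the
    largest 6-connected supra-threshold component; morphological closing;
    hole filling; dilate by the peri-cortical margin.  The returned mask
    has exactly one connected foreground component.
    """
    data = t1.data
    if not np.any(data > 0):
        raise StageError(f"brain extraction: empty volume ({t1.path or '<memory>'})")
    thr = threshold_otsu(data, nbins=256)
    fg = data > thr
    if not fg.any():
        raise StageError(f"brain extraction: empty mask after thresholding ({t1.path or '<memory>'})")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(fg, structure=structure)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_closing(fg, structure=structure, iterations=2)
    fg = ndimage.binary_fill_holes(fg, structure=structure)
    fg = ndimage.binary_dilation(fg, structure=structure, iterations=BRAIN_MARGIN_VOXELS)
    fg = ndimage.binary_fill_holes(fg, structure=structure)
    return Volume(fg.astype(np.float64), t1.affine.copy(), t1.path)


def segment_white_matter(t1_norm: Volume, brain_mask: Volume, *, tol: float = 1e-6, max_iter: int = 100) -> Volume:
    """Stand-in tissue segmentation: 3-class 1-D intensity clustering.

    Within-brain voxels are clustered into CSF/GM/WM by Lloyd iteration on
    intensity alone; class means start at the 25th/50th/75th within-brain
    percentiles and the iteration runs to a fixed point (tolerance ``tol``
    or ``max_iter`` sweeps).  WM is the class with the highest mean.
    """
    inside = brain_mask.data > 0
    if not inside.any():
        raise StageError("WM segmentation: empty brain mask")
    vals = t1_norm.data[inside]
    if np.unique(vals).size < 3:
        raise StageError(
            f"WM segmentation: fewer than 3 distinct within-brain intensities ({t1_norm.path or '<memory>'})"
        )
    means = np.percentile(vals, [25.0, 50.0, 75.0]).astype(np.float64)
    # guard identical starting means (heavily quantized data)
    if np.unique(means).size < 3:
        means = np.linspace(vals.min(), vals.max(), 5)[1:4]
    for _ in range(max_iter):
        # nearest-mean assignment via midpoint cuts (means kept sorted)
        means.sort()
        cuts = (means[:-1] + means[1:]) / 2.0
        labels = np.digitize(vals, cuts)
        new_means = means.copy()
        for k in range(3):
            sel = labels == k
            if sel.any():
                new_means[k] = vals[sel].mean()
        if np.max(np.abs(new_means - means)) < tol:
            means = new_means
            break
        means = new_means
    means.sort()
    cuts = (means[:-1] + means[1:]) / 2.0
    labels = np.digitize(vals, cuts)
    wm = np.zeros(t1_norm.shape, dtype=np.float64)
    wm_flat = np.zeros(vals.shape, dtype=np.float64)
    wm_flat[labels == 2] = 1.0
    wm[inside] = wm_flat
    return Volume(wm, t1_norm.affine.copy(), t1_norm.path)
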