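"""Lesion–ROI overlap ("lesion load") computation.

Lesion load for a region of interest — the corticospinal tract being the
canonical stroke-recovery example — is the fraction of the ROI's voxels
that the lesion covers, reported as a percentage:

    percent overlap = 100 * |lesion AND roi| / |roi|

The overlap mask is formed exactly the way the original shell procedure
did: both masks are binarized, voxelwise summed, thresholded so anything
below 2 is zeroed, and re-binarized — which is the voxelwise AND.

``run_lesion_load`` handles the cohort loop: each subject's T1 is
registered to the ROI template, the transform is applied to each lesion
mask with nearest-neighbour interpolation, every ROI is binarized, and
one result row is emitted per (lesion, ROI).  Subjects already on the
template grid take the identity shortcut and skip registration.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .registration import AffineTransform, register_affine, resample_to
from .tissue_prep import StageError
from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = ["LoadResult", "overlap_mask", "lesion_load", "run_lesion_load", "write_load_report"]


@dataclass
class LoadResult:
    subject_id: str
    lesion_file: str
    roi_name: str
    roi_voxels: int
    overlap_voxels: int
    percent_overlap: float


def overlap_mask(lesion: Volume, roi: Volume) -> Volume:
    """Binarize, sum, threshold below 2 to zero, re-binarize (= voxelwise AND)."""
    if lesion.shape != roi.shape:
        raise StageError(f"overlap: grid mismatch lesion{lesion.shape} vs roi{roi.shape}")
    summed = (lesion.data > 0).astype(np.int8) + (roi.data > 0).astype(np.int8)
    summed[summed < 2] = 0
    return Volume((summed > 0).astype(np.float64), roi.affine.copy())


def lesion_load(
    lesion: Volume,
    roi: Volume,
    *,
    subject_id: str = "",
    lesion_file: str = "",
    roi_name: str = "",
) -> LoadResult:
    """Percent of the ROI's voxels covered by the lesion."""
    roi_voxels = int(np.count_nonzero(roi.data > 0))
    if roi_voxels == 0:
        raise StageError(f"lesion load: empty ROI {roi_name or roi.path}")
    ov = overlap_mask(lesion, roi)
    overlap_voxels = ov.voxel_count()
    return LoadResult(
        subject_id=subject_id,
        lesion_file=lesion_file,
        roi_name=roi_name,
        roi_voxels=roi_voxels,
        overlap_voxels=overlap_voxels,
        percent_overlap=100.0 * overlap_voxels / roi_voxels,
    )


def run_lesion_load(
    subjects: list[dict],
    rois: dict[str, Volume],
    template: Volume,
    *,
    transforms: dict[str, AffineTransform] | None = None,
) -> tuple[list[LoadResult], dict[str, AffineTransform], list[str]]:
    """Compute lesion load for a cohort against template-space ROIs.

    Parameters
    ----------
    subjects
        Each entry: ``{"subject_id": str, "t1": Volume, "lesions": {name: Volume}}``.
    rois
        Named ROI volumes on the template grid (binarized here, >0 -> 1).
    template
        Intensity volume defining the ROI space.
    transforms
        Optional pre-computed per-subject world->world transforms (e.g.
        user-supplied matrix files); missing subjects are estimated.

    Returns results, the transforms used, and the ids of subjects whose
    registration failed (they are skipped, the run continues).
    """
    transforms = dict(transforms or {})
    bin_rois = {name: r.with_data((r.data > 0).astype(np.float64)) for name, r in rois.items()}
    results: list[LoadResult] = []
    failed: list[str] = []
    for subj in subjects:
        sid = subj["subject_id"]
        t1: Volume = subj["t1"]
        try:
            if sid in transforms:
                t = transforms[sid]
            elif t1.shape == template.shape and np.allclose(t1.affine, template.affine):
                t = AffineTransform.identity()
                transforms[sid] = t
            else:
                t = register_affine(t1, template)
                transforms[sid] = t
            for lesion_name, lesion in subj["lesions"].items():
                lesion_t = resample_to(lesion, t, template, interp="nearest")
                for roi_name, roi in bin_rois.items():
                    results.append(
                        lesion_load(
                            lesion_t,
                            roi,
                            subject_id=sid,
                            lesion_file=lesion_name,
                            roi_name=roi_name,
                        )
                    )
        except StageError as exc:
            logger.error("lesion load failed for subject %s: %s", sid, exc)
            failed.append(sid)
    return results, transforms, failed


LOAD_COLUMNS = ["subject_id", "lesion_file", "roi_name", "roi_voxels", "overlap_voxels", "percent_overlap"]


def write_load_report(results: list[LoadResult], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOAD_COLUMNS)
        for r in results:
            writer.writerow(
                [r.subject_id, r.lesion_file, r.roi_name, r.roi_voxels, r.overlap_voxels, f"{r.percent_overlap:.4f}"]
            )


def roi_masks_from_labels(label_volume: Volume, label_table: dict[int, str]) -> dict[str, Volume]:
    """Extract binary ROI masks from an integer label volume (code -> name)."""
    out = {}
    for code, name in label_table.items():
        out[name] = label_volume.with_data((np.rint(label_volume.data) == int(code)).astype(np.float64))
    return out
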