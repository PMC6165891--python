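"""White-matter intensity correction of lesion masks.

Manual lesion tracings routinely include voxels whose intensity is that of
healthy white matter — boundary overshoot that differs from tracer to
tracer.  The correction removes, from each lesion mask, the voxels whose
normalized T1 intensity (0–255 scale) falls inside a window around the
subject's mean white-matter intensity:

    window half-width  h = 255 * (p / 100) / 2
    remove voxels with intensity in  [wm_mean - h, wm_mean + h]

with p the user-chosen removal percentage (default 5).  The surviving
voxels are re-binarized as the final corrected mask.  The window is
inclusive at both bounds and is not clamped to [0, 255] (values outside
that range cannot occur in a normalized T1 anyway).

Correction is intended for manually segmented lesions; automated
segmenters typically already exclude normal-intensity white matter, and
running the correction on their output is warned against.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tissue_prep import StageError
from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_REMOVAL_PERCENT",
    "CorrectionResult",
    "removal_window",
    "wm_mean_intensity",
    "correct_lesion",
    "write_correction_report",
]

DEFAULT_REMOVAL_PERCENT = 5.0


@dataclass
class CorrectionResult:
    """Corrected lesion mask plus removal accounting."""

    corrected_mask: Volume
    original_voxels: int
    removed_voxels: int
    surviving_voxels: int
    wm_mean: float
    window: tuple[float, float]
    percent_param: float
    subject_id: str = ""
    lesion_file: str = ""

    @property
    def percent_removed(self) -> float:
        if self.original_voxels == 0:
            return 0.0
        return 100.0 * self.removed_voxels / self.original_voxels


def removal_window(wm_mean: float, p: float) -> tuple[float, float]:
    """Intensity window to remove: ``wm_mean ± 255*(p/100)/2``, unclamped."""
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"removal percentage must lie in [0, 100], got {p}")
    h = 255.0 * (p / 100.0) / 2.0
    return (wm_mean - h, wm_mean + h)


def wm_mean_intensity(
    t1_norm: Volume,
    wm_mask: Volume,
    lesion_mask: Volume | None = None,
    *,
    exclude_lesion: bool = False,
) -> float:
    """Mean normalized T1 intensity over the white-matter mask.

    With ``exclude_lesion`` the mean is taken over WM voxels outside the
    lesion, so lesioned tissue cannot drag the healthy-WM estimate down;
    the default keeps the plain mean over the whole segmentation.
    """
    sel = wm_mask.data > 0
    if exclude_lesion:
        if lesion_mask is None:
            raise ValueError("exclude_lesion=True requires a lesion mask")
        sel = sel & ~(lesion_mask.data > 0)
    if not sel.any():
        raise StageError("WM mean intensity: empty effective white-matter mask")
    return float(t1_norm.data[sel].mean())


def correct_lesion(
    t1_norm: Volume,
    wm_mask: Volume,
    lesion_mask: Volume,
    p: float = DEFAULT_REMOVAL_PERCENT,
    *,
    exclude_lesion: bool = False,
    subject_id: str = "",
    lesion_file: str = "",
) -> CorrectionResult:
    """Remove healthy-WM-intensity voxels from a lesion mask.

    Lesion voxels whose normalized T1 intensity lies inside the removal
    window (inclusive) are dropped; the survivor mask is binarized.  An
    empty input lesion yields an all-zero result with a warning rather
    than an error, so cohort runs continue.
    """
    if t1_norm.shape != lesion_mask.shape or wm_mask.shape != lesion_mask.shape:
        raise StageError(
            f"lesion correction: grid mismatch T1{t1_norm.shape} WM{wm_mask.shape} lesion{lesion_mask.shape}"
        )
    lesion = lesion_mask.data > 0
    original = int(np.count_nonzero(lesion))
    wm_mean = wm_mean_intensity(t1_norm, wm_mask, lesion_mask, exclude_lesion=exclude_lesion)
    lo, hi = removal_window(wm_mean, p)
    if original == 0:
        warnings.warn(f"empty lesion mask for {subject_id or lesion_mask.path}; nothing to correct")
        return CorrectionResult(
            corrected_mask=lesion_mask.with_data(np.zeros_like(lesion_mask.data)),
            original_voxels=0,
            removed_voxels=0,
            surviving_voxels=0,
            wm_mean=wm_mean,
            window=(lo, hi),
            percent_param=p,
            subject_id=subject_id,
            lesion_file=lesion_file,
        )
    inside_window = (t1_norm.data >= lo) & (t1_norm.data <= hi)
    removed = lesion & inside_window
    surviving = lesion & ~inside_window
    n_removed = int(np.count_nonzero(removed))
    n_surviving = original - n_removed
    if n_surviving == 0:
        warnings.warn(
            f"lesion {lesion_file or lesion_mask.path} for {subject_id or '<subject>'} "
            "lies entirely inside the WM removal window; corrected mask is empty"
        )
    corrected = Volume(surviving.astype(np.float64), lesion_mask.affine.copy(), lesion_mask.path)
    return CorrectionResult(
        corrected_mask=corrected,
        original_voxels=original,
        removed_voxels=n_removed,
        surviving_voxels=n_surviving,
        wm_mean=wm_mean,
        window=(lo, hi),
        percent_param=p,
        subject_id=subject_id,
        lesion_file=lesion_file,
    )


REPORT_COLUMNS = [
    "subject_id",
    "lesion_file",
    "original_voxels",
    "removed_voxels",
    "surviving_voxels",
    "percent_removed",
    "wm_mean",
    "window_lo",
    "window_hi",
]


def write_correction_report(results: list[CorrectionResult], path: str | Path) -> None:
    """Write the per-(subject, lesion) removal accounting CSV."""
    if not results:
        raise ValueError("no correction results to report")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for r in results:
            writer.writerow(
                [
                    r.subject_id,
                    r.lesion_file,
                    r.original_voxels,
                    r.removed_voxels,
                    r.surviving_voxels,
                    f"{r.percent_removed:.4f}",
                    f"{r.wm_mean:.4f}",
                    f"{r.window[0]:.4f}",
                    f"{r.window[1]:.4f}",
                ]
            )
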