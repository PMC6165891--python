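"""Harmonization of subject files to radiological convention.

Storage convention varies across scanners, sites and mask-drawing software;
mixing conventions within a subject silently swaps the lesioned hemisphere.
This module converts every file of a subject to radiological convention and
a canonical axis ordering — but only when all of the subject's files agree
on their convention.  A subject whose T1, lesion mask(s) and optional
brain/WM masks disagree is *flagged* and excluded from all downstream
stages; flags are a manual-review request, never auto-fixed.

A subject missing an optional input (brain or WM mask) while the run asked
to skip the producing stage forces that stage back on — for *all* subjects,
so the option stays uniform across the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .config import SubjectRecord
from .volume_io import (
    InvalidHeaderError,
    StorageConvention,
    Volume,
    read_volume,
    storage_convention,
)

logger = logging.getLogger(__name__)

__all__ = ["OrientationReport", "to_radiological", "to_canonical", "harmonize_subject"]


@dataclass
class OrientationReport:
    """Outcome of harmonizing one subject's files."""

    subject_id: str
    per_file_convention: dict[str, StorageConvention] = field(default_factory=dict)
    flagged: bool = False
    flag_reason: str = ""
    actions: list[str] = field(default_factory=list)
    skip_overrides: set[str] = field(default_factory=set)
    volumes: dict[str, Volume] = field(default_factory=dict)  # role -> harmonized volume


def to_radiological(v: Volume) -> Volume:
    """Convert a volume to radiological convention, preserving world-space anatomy.

    If the volume is already radiological it is returned unchanged (the
    convention is conserved).  Otherwise the first voxel axis is flipped and
    the affine updated so every voxel center keeps its world coordinate and
    intensity; the determinant of the spatial block changes sign.
    """
    if storage_convention(v) is StorageConvention.RADIOLOGICAL:
        return v
    nx = v.shape[0]
    flip = np.eye(4)
    flip[0, 0] = -1.0
    flip[0, 3] = nx - 1  # new index i maps to old index nx-1-i
    new_affine = v.affine @ flip
    new_data = v.data[::-1, :, :].copy()
    return Volume(new_data, new_affine, v.path)


def to_canonical(v: Volume) -> Volume:
    """Permute/flip axes so the affine is closest to diagonal, convention preserved.

    The target axis ordering is the canonical one (voxel axis i along world
    axis i, per-column dominant entry); the sign pattern keeps the volume's
    current storage convention, so radiological volumes stay radiological.
    Equal-magnitude dominant entries are broken toward the lower axis index
    (the behaviour of :func:`nibabel.orientations.io_orientation`).
    """
    conv = storage_convention(v)
    ornt = nib.orientations.io_orientation(v.affine)
    first_sign = -1.0 if conv is StorageConvention.RADIOLOGICAL else 1.0
    target = np.array([[0, first_sign], [1, 1.0], [2, 1.0]])
    transform = nib.orientations.ornt_transform(ornt, target)
    if np.array_equal(transform, np.array([[0, 1.0], [1, 1.0], [2, 1.0]])):
        return v
    new_data = nib.orientations.apply_orientation(v.data, transform).copy()
    new_affine = v.affine @ nib.orientations.inv_ornt_aff(transform, v.shape)
    return Volume(new_data, new_affine, v.path)


def _subject_files(s: SubjectRecord) -> dict[str, object]:
    files: dict[str, object] = {}
    if s.t1_path is not None:
        files["t1"] = s.t1_path
    for i, p in enumerate(s.lesion_paths):
        files[f"lesion{i + 1}" if len(s.lesion_paths) > 1 else "lesion"] = p
    if s.brain_mask_path is not None:
        files["brain"] = s.brain_mask_path
    if s.wm_mask_path is not None:
        files["wm"] = s.wm_mask_path
    return files


def harmonize_subject(
    s: SubjectRecord,
    *,
    skip_brain_extraction: bool = False,
    skip_wm_segmentation: bool = False,
) -> OrientationReport:
    """Check conventions across a subject's files and harmonize if they agree.

    Returns an :class:`OrientationReport`; when not flagged, ``report.volumes``
    maps each file role (``t1``, ``lesion``/``lesionK``, ``brain``, ``wm``) to
    its harmonized (radiological + canonical) volume.  When conventions differ
    across any present files, the subject is flagged and nothing is modified.
    T1/lesion grid-shape mismatch also flags the subject (reason
    ``shape-mismatch``) rather than aborting the run.
    """
    report = OrientationReport(subject_id=s.subject_id)
    if s.t1_path is None or not s.lesion_paths:
        report.flagged = True
        report.flag_reason = s.flag_reason or "missing-required-input"
        return report

    files = _subject_files(s)
    loaded: dict[str, Volume] = {}
    for role, path in files.items():
        try:
            vol = read_volume(path, as_mask=(role != "t1"))
            report.per_file_convention[str(path)] = storage_convention(vol)
            loaded[role] = vol
        except (OSError, ValueError, InvalidHeaderError) as exc:
            raise type(exc)(f"subject {s.subject_id}: {exc}") from exc

    shapes = {role: vol.shape for role, vol in loaded.items()}
    if len(set(shapes.values())) > 1:
        report.flagged = True
        report.flag_reason = "shape-mismatch"
        logger.warning("subject %s flagged: shape mismatch %s", s.subject_id, shapes)
        return report

    conventions = set(report.per_file_convention.values())
    if len(conventions) > 1:
        report.flagged = True
        report.flag_reason = "orientation-mismatch"
        logger.warning(
            "subject %s flagged: mixed storage conventions %s",
            s.subject_id,
            {f: c.value for f, c in report.per_file_convention.items()},
        )
        return report

    for role, vol in loaded.items():
        before = storage_convention(vol)
        radio = to_radiological(vol)
        canon = to_canonical(radio)
        if before is StorageConvention.RADIOLOGICAL:
            report.actions.append(f"{role}: conserved")
        else:
            report.actions.append(f"{role}: flipped")
        if canon is not radio:
            report.actions.append(f"{role}: reoriented-to-canonical")
        report.volumes[role] = canon

    if skip_brain_extraction and s.brain_mask_path is None:
        report.skip_overrides.add("brain_extraction")
        logger.warning(
            "subject %s lacks a brain mask: brain extraction set to run on all subjects",
            s.subject_id,
        )
    if skip_wm_segmentation and s.wm_mask_path is None:
        report.skip_overrides.add("wm_segmentation")
        logger.warning(
            "subject %s lacks a WM mask: WM segmentation set to run on all subjects",
            s.subject_id,
        )
    return report
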