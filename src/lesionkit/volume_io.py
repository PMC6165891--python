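"""NIfTI-1 volume I/O and storage-convention interpretation.

Every stage of the pipeline consumes and produces :class:`Volume` objects:
a 3-D scalar grid plus its voxel-index -> world-mm affine.  The affine is
taken from the file's sform when its code is nonzero, else the qform, else
the header's fallback transform — the precedence most neuroimaging tools
use, and the one that makes storage-convention detection deterministic.

The storage convention (radiological vs. neurological) is read off the
sign of the determinant of the affine's spatial 3x3 block: negative means
the patient's left is stored on the right of the image (radiological),
positive means left-on-left (neurological).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "StorageConvention",
    "VolumeFormatError",
    "InvalidHeaderError",
    "read_volume",
    "write_volume",
    "storage_convention",
]


class VolumeFormatError(ValueError):
    """File is not readable as NIfTI-1."""


class InvalidHeaderError(ValueError):
    """NIfTI header carries a singular (zero-determinant) spatial affine."""


class StorageConvention(Enum):
    RADIOLOGICAL = "radiological"
    NEUROLOGICAL = "neurological"


@dataclass
class Volume:
    """A 3-D volume: scalar grid + 4x4 voxel->world (mm) affine.

    ``data`` is float for anatomical images and {0,1} float for masks.
    ``path`` records provenance (empty string for in-memory volumes).
    """

    data: np.ndarray
    affine: np.ndarray
    path: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def is_mask(self) -> bool:
        """True when all finite values are 0 or 1 (mask-role volume)."""
        vals = self.data[np.isfinite(self.data)]
        return bool(np.all((vals == 0) | (vals == 1)))

    def voxel_count(self) -> int:
        """Number of nonzero voxels (mask volume in voxels)."""
        return int(np.count_nonzero(self.data))

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy(), self.path)


def _preferred_affine(img: nib.Nifti1Image, path: str) -> np.ndarray:
    """sform if coded, else qform, else the header fallback affine."""
    hdr = img.header
    sform_code = int(hdr["sform_code"])
    qform_code = int(hdr["qform_code"])
    if sform_code > 0:
        affine = img.get_sform()
        used = "sform"
    elif qform_code > 0:
        affine = img.get_qform()
        used = "qform"
    else:
        affine = hdr.get_base_affine()
        used = "fallback(pixdim)"
    if sform_code > 0 and qform_code > 0:
        sf, qf = img.get_sform(), img.get_qform()
        if not np.allclose(sf, qf, atol=1e-3):
            logger.warning("inconsistent qform/sform in %s; using sform", path)
    logger.debug("affine source for %s: %s", path, used)
    return np.asarray(affine, dtype=float)


def read_volume(path: str | Path, *, as_mask: bool = False) -> Volume:
    """Read a NIfTI-1 file (.nii or .nii.gz) into a :class:`Volume`.

    Parameters
    ----------
    path
        File to read.  Gzip compression is transparent.
    as_mask
        Binarize on read: values > 0 map to 1 (masks are always binarized
        before any computation).

    Raises
    ------
    VolumeFormatError
        If the file does not parse as NIfTI-1.
    InvalidHeaderError
        If the spatial affine is singular.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"not a readable NIfTI-1 file: {path} ({exc})") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti1Pair)):
        raise VolumeFormatError(f"not NIfTI-1: {path} ({type(img).__name__})")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3-D volume, got shape {data.shape}: {path}")
    affine = _preferred_affine(img, str(path))
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise InvalidHeaderError(f"singular spatial affine in {path}")
    if as_mask:
        data = (data > 0).astype(np.float64)
    return Volume(data=data, affine=affine, path=str(path))


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as NIfTI-1; parent directories are created.

    Masks ({0,1} volumes) are stored as uint8, everything else as float32.
    The affine is written into both sform and qform so the file re-reads
    to an equal Volume under any consumer's precedence.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if v.is_mask():
        data = v.data.astype(np.uint8)
    else:
        data = v.data.astype(np.float32)
    img = nib.Nifti1Image(data, v.affine)
    img.set_sform(v.affine, code=1)
    img.set_qform(v.affine, code=1)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


def storage_convention(v: Volume) -> StorageConvention:
    """Convention of a volume from the sign of det(spatial 3x3 block).

    Negative determinant -> RADIOLOGICAL (left stored on the right);
    positive -> NEUROLOGICAL.  Zero raises :class:`InvalidHeaderError`.
    """
    det = np.linalg.det(v.affine[:3, :3])
    if abs(det) < 1e-12:
        raise InvalidHeaderError(f"singular spatial affine (det={det}) for {v.path or '<memory>'}")
    if det < 0:
        return StorageConvention.RADIOLOGICAL
    return StorageConvention.NEUROLOGICAL
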