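"""Affine registration of subject volumes into a template (ROI) space.

Lesion load is computed in the space the ROIs live in, so native-space T1s
and lesion masks must first be brought there.  The estimator here is a
12-parameter (translation, rotation, scale, shear) affine maximizing
normalized cross-correlation (NCC), optimized by derivative-free
coordinate descent over a 3-level multiresolution pyramid (downsampling
x4, x2, x1).  Initialization is center-of-mass alignment plus a
bounding-box scale guess; the parameter sweep order is fixed, so the
whole procedure is deterministic.  The metric is evaluated inside the
fixed image's foreground bounding box to keep empty background from
dominating the correlation.

The transform convention is world -> world (moving subject mm to fixed
template mm); files on disk are 4-line whitespace-separated 4x4 matrices,
and a user-supplied per-subject matrix bypasses estimation entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .tissue_prep import StageError
from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "AffineTransform",
    "register_affine",
    "resample_to",
    "save_transform",
    "load_transform",
]


@dataclass
class AffineTransform:
    """World->world affine (moving subject mm -> fixed template mm)."""

    matrix: np.ndarray  # 4x4
    dof: int = 12
    similarity_score: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("singular spatial block in transform")

    @classmethod
    def identity(cls, score: float = 0.0) -> "AffineTransform":
        return cls(np.eye(4), similarity_score=score)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.dof, self.similarity_score, self.converged)


def save_transform(t: AffineTransform, path: str | Path) -> None:
    np.savetxt(Path(path), t.matrix, fmt="%.10g")


def load_transform(path: str | Path) -> AffineTransform:
    m = np.loadtxt(Path(path))
    if m.shape != (4, 4):
        raise ValueError(f"transform file {path} is not a 4x4 matrix")
    return AffineTransform(m)


# ---------------------------------------------------------------- helpers


def _rotation(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation about x, then y, then z; angles in degrees."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _params_to_matrix(p: np.ndarray, c_moving: np.ndarray, c_fixed: np.ndarray, s0: np.ndarray) -> np.ndarray:
    """12 parameters -> 4x4 world->world matrix.

    p = [tx ty tz rx ry rz sx sy sz kxy kxz kyz]; scales multiply the
    bounding-box initial guess s0; the rotation/scale center is the
    moving center of mass, mapped onto the fixed center of mass.
    """
    t, r, s, k = p[0:3], p[3:6], s0 * (1.0 + p[6:9]), p[9:12]
    K = np.array([[1.0, k[0], k[1]], [0.0, 1.0, k[2]], [0.0, 0.0, 1.0]])
    A = _rotation(*r) @ K @ np.diag(s)
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = c_fixed + t - A @ c_moving
    return M


def _foreground(data: np.ndarray) -> np.ndarray:
    lo, hi = float(data.min()), float(data.max())
    return data > lo + 0.1 * (hi - lo)


def _center_of_mass_world(v: Volume) -> np.ndarray:
    w = np.clip(v.data - v.data.min(), 0, None)
    total = w.sum()
    if total <= 0:
        raise StageError("registration: constant image, metric undefined")
    com_idx = np.array(ndimage.center_of_mass(w))
    return (v.affine @ np.append(com_idx, 1.0))[:3]


def _bbox_extent_world(v: Volume) -> np.ndarray:
    fg = _foreground(v.data)
    if not fg.any():
        raise StageError("registration: no foreground voxels")
    idx = np.argwhere(fg)
    span_vox = idx.max(axis=0) - idx.min(axis=0) + 1
    pitch = np.sqrt((v.affine[:3, :3] ** 2).sum(axis=0))
    return span_vox * pitch


def _downsample(v: Volume, factor: int) -> Volume:
    if factor == 1:
        return v
    sm = ndimage.gaussian_filter(v.data, sigma=factor / 2.0)
    data = sm[::factor, ::factor, ::factor]
    aff = v.affine.copy()
    aff[:3, :3] *= factor
    return Volume(data, aff, v.path)


def _resample_data(moving: Volume, fixed: Volume, M: np.ndarray, order: int) -> np.ndarray:
    """Sample moving on fixed's grid through the world->world matrix M."""
    C = np.linalg.inv(moving.affine) @ np.linalg.inv(M) @ fixed.affine
    return ndimage.affine_transform(
        moving.data,
        matrix=C[:3, :3],
        offset=C[:3, 3],
        output_shape=fixed.shape,
        order=order,
        mode="constant",
        cval=float(moving.data.min()),
    )


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -1.0
    return float((a * b).sum() / denom)


# ------------------------------------------------------------- estimation

_STEP_INIT = np.array([8.0, 8.0, 8.0, 4.0, 4.0, 4.0, 0.05, 0.05, 0.05, 0.02, 0.02, 0.02])
_STEP_TOL = np.array([0.25, 0.25, 0.25, 0.25, 0.25, 0.25, 0.004, 0.004, 0.004, 0.004, 0.004, 0.004])
_LEVELS = (4, 2, 1)
_ITER_CAPS = {4: 100, 2: 50, 1: 25}


def register_affine(moving: Volume, fixed: Volume) -> AffineTransform:
    """Estimate the 12-dof world->world affine aligning moving to fixed.

    Raises :class:`StageError` when either image is constant (the
    correlation metric is undefined).  ``converged`` is False when the
    per-level sweep cap was hit before the step sizes shrank below
    tolerance.
    """
    for v, name in ((moving, "moving"), (fixed, "fixed")):
        if float(v.data.max()) == float(v.data.min()):
            raise StageError(f"registration: constant {name} image, metric undefined")

    c_m = _center_of_mass_world(moving)
    c_f = _center_of_mass_world(fixed)
    s0 = _bbox_extent_world(fixed) / _bbox_extent_world(moving)

    p = np.zeros(12)
    converged = True
    score = -np.inf
    for factor in _LEVELS:
        mov_l = _downsample(moving, factor)
        fix_l = _downsample(fixed, factor)
        # crop metric evaluation to the fixed foreground bounding box
        fg = _foreground(fix_l.data)
        idx = np.argwhere(fg)
        lo3, hi3 = idx.min(axis=0), idx.max(axis=0) + 1
        fix_crop_data = fix_l.data[lo3[0]:hi3[0], lo3[1]:hi3[1], lo3[2]:hi3[2]]
        crop_aff = fix_l.affine.copy()
        crop_aff[:3, 3] = (fix_l.affine @ np.append(lo3, 1.0))[:3]
        fix_crop = Volume(fix_crop_data, crop_aff)

        def cost(params: np.ndarray) -> float:
            M = _params_to_matrix(params, c_m, c_f, s0)
            res = _resample_data(mov_l, fix_crop, M, order=1)
            return _ncc(res, fix_crop_data)

        steps = _STEP_INIT.copy()
        score = cost(p)
        level_converged = False
        for _ in range(_ITER_CAPS[factor]):
            improved = False
            for j in range(12):
                for sign in (1.0, -1.0):
                    trial = p.copy()
                    trial[j] += sign * steps[j]
                    c = cost(trial)
                    if c > score + 1e-9:
                        p, score = trial, c
                        improved = True
                        break
            if not improved:
                if np.all(steps <= _STEP_TOL):
                    level_converged = True
                    break
                steps = np.maximum(steps / 2.0, _STEP_TOL * 0.99)
        if not level_converged:
            converged = False
        logger.debug("registration level x%d: score=%.4f p=%s", factor, score, np.round(p, 3))

    return AffineTransform(
        matrix=_params_to_matrix(p, c_m, c_f, s0),
        dof=12,
        similarity_score=score,
        converged=converged,
    )


def resample_to(v: Volume, t: AffineTransform, grid_of: Volume, interp: str = "linear") -> Volume:
    """Resample ``v`` onto ``grid_of``'s voxel grid through ``t``.

    Masks must use ``interp="nearest"`` so the output stays binary;
    requesting linear interpolation for a mask-role volume is an error.
    If ``v`` already lives on the target grid and ``t`` is the identity,
    the identity shortcut returns an exact copy.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError(f"interp must be 'linear' or 'nearest', got {interp!r}")
    if interp == "linear" and v.is_mask() and v.voxel_count() > 0:
        raise ValueError("linear interpolation requested for a mask-role volume; use nearest")
    same_grid = v.shape == grid_of.shape and np.allclose(v.affine, grid_of.affine)
    if same_grid and np.allclose(t.matrix, np.eye(4)):
        return Volume(v.data.copy(), v.affine.copy(), v.path)
    order = 1 if interp == "linear" else 0
    out = _resample_data(v, grid_of, t.matrix, order=order)
    if interp == "nearest":
        out = np.rint(out)
    return Volume(out, grid_of.affine.copy(), v.path)
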