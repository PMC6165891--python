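"""Deterministic synthetic head phantoms with exact ground-truth masks.

Every test and example in this package runs on phantoms instead of real
multi-site MRI: a nested-ellipsoid brain (CSF shell, GM shell, WM core)
inside a bright skull shell on a dark background, with an
intensity-lowered ellipsoidal lesion partially overlapping the WM core.
Tissue means default to CSF 40 < GM 110 < WM 180 (arbitrary units) with
additive Gaussian noise; the default affine is 2 mm isotropic in
*neurological* convention, so orientation harmonization is exercised by
default.  All generators are pure functions of (spec, seed).

The phantom deliberately omits real-MRI features — bias fields, Rician
noise, gyral folding, pathology diversity — so passing tests demonstrate
algorithmic correctness, not clinical robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .orientation import to_radiological
from .volume_io import Volume, write_volume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomSpecError",
    "make_head_phantom",
    "make_tracer_variants",
    "make_orientation_case",
    "make_template_with_rois",
    "write_phantom_dataset",
]


class PhantomSpecError(ValueError):
    """Phantom specification is geometrically or numerically invalid."""


@dataclass
class LesionSpec:
    """Ellipsoidal lesion: center/radii in voxel coordinates, intensity drop fraction."""

    center: tuple[float, float, float] = (39.0, 40.0, 32.0)
    radii: tuple[float, float, float] = (5.0, 6.0, 5.0)
    drop: float = 0.35  # lesion intensity = wm_mean * (1 - drop)


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 80, 64)
    tissue_means: tuple[float, float, float] = (40.0, 110.0, 180.0)  # CSF < GM < WM
    skull_mean: float = 230.0
    noise_sd: float = 5.0
    lesion: LesionSpec | None = field(default_factory=LesionSpec)
    voxel_mm: float = 2.0
    seed: int = 0

    # ellipsoid radii (voxels) around the volume center; the >=4-voxel dark
    # gap between brain and skull keeps brain extraction's margin dilation
    # from bridging to the skull shell
    brain_radii: tuple[float, float, float] = (20.0, 26.0, 20.0)
    gm_radii: tuple[float, float, float] = (18.0, 24.0, 18.0)
    wm_radii: tuple[float, float, float] = (14.0, 20.0, 14.0)
    skull_inner_radii: tuple[float, float, float] = (24.0, 30.0, 24.0)
    skull_outer_radii: tuple[float, float, float] = (26.0, 32.0, 26.0)

    def __post_init__(self) -> None:
        csf, gm, wm = self.tissue_means
        if not csf < gm < wm:
            raise PhantomSpecError(f"tissue means must satisfy CSF < GM < WM, got {self.tissue_means}")

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    def default_affine(self) -> np.ndarray:
        """2 mm isotropic, neurological convention (positive determinant)."""
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_mm
        aff[:3, 3] = -self.center * self.voxel_mm
        return aff


def _ellipsoid(shape: tuple[int, int, int], center, radii) -> np.ndarray:
    grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def make_head_phantom(spec: PhantomSpec | None = None) -> dict[str, Volume]:
    """Build the phantom and its exact truth masks.

    Returns ``t1``, ``brain_truth``, ``csf_truth``, ``gm_truth``,
    ``wm_truth``, ``lesion_truth`` (empty mask when the spec has no
    lesion).  CSF/GM/WM truths partition the brain; the lesion only
    reassigns intensity (to ``wm_mean*(1-drop)``), so truth masks stay
    geometric.
    """
    spec = spec or PhantomSpec()
    c = spec.center
    shape = spec.shape
    brain = _ellipsoid(shape, c, spec.brain_radii)
    gm_outer = _ellipsoid(shape, c, spec.gm_radii)
    wm = _ellipsoid(shape, c, spec.wm_radii)
    csf = brain & ~gm_outer
    gm = gm_outer & ~wm
    skull = _ellipsoid(shape, c, spec.skull_outer_radii) & ~_ellipsoid(shape, c, spec.skull_inner_radii)

    csf_mean, gm_mean, wm_mean = spec.tissue_means
    t1 = np.zeros(shape, dtype=np.float64)
    t1[csf] = csf_mean
    t1[gm] = gm_mean
    t1[wm] = wm_mean
    t1[skull] = spec.skull_mean

    if spec.lesion is not None:
        lesion = _ellipsoid(shape, spec.lesion.center, spec.lesion.radii)
        if np.any(lesion & ~brain):
            raise PhantomSpecError("lesion ellipsoid extends outside the brain ellipsoid")
        t1[lesion] = wm_mean * (1.0 - spec.lesion.drop)
    else:
        lesion = np.zeros(shape, dtype=bool)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        t1 = t1 + rng.normal(0.0, spec.noise_sd, size=shape)

    aff = spec.default_affine()
    as_vol = lambda m: Volume(m.astype(np.float64), aff.copy())
    return {
        "t1": Volume(t1, aff.copy()),
        "brain_truth": as_vol(brain),
        "csf_truth": as_vol(csf),
        "gm_truth": as_vol(gm),
        "wm_truth": as_vol(wm),
        "lesion_truth": as_vol(lesion),
    }


def make_tracer_variants(
    lesion_truth: Volume,
    n: int,
    boundary_sd: float,
    seed: int,
    *,
    sprinkle_region: Volume | None = None,
    sprinkle_fraction: float = 0.15,
) -> list[Volume]:
    """Simulate ``n`` human tracers of one lesion.

    Each variant is the truth mask with (a) a seeded random number of
    whole-boundary dilation/erosion steps (signed Normal(0, boundary_sd),
    rounded) and (b) a seeded sprinkling of extra voxels drawn from a
    peri-lesional region — by default the 3-voxel shell around the truth
    mask, or any caller-supplied region such as the healthy white matter
    mask.  The sprinkles model the tracer-specific inclusion of
    normal-intensity white matter that intensity correction removes.
    """
    if n < 2:
        raise ValueError("need at least 2 tracer variants")
    truth = lesion_truth.data > 0
    if not truth.any():
        raise PhantomSpecError("cannot make tracer variants of an empty lesion")
    rng = np.random.default_rng(seed)
    structure = ndimage.generate_binary_structure(3, 1)
    if sprinkle_region is not None:
        pool = (sprinkle_region.data > 0) & ~truth
    else:
        pool = ndimage.binary_dilation(truth, structure, iterations=3) & ~truth
    pool_idx = np.argwhere(pool)
    n_truth = int(truth.sum())
    variants: list[Volume] = []
    for _ in range(n):
        steps = int(np.rint(rng.normal(0.0, boundary_sd)))
        mask = truth.copy()
        if steps > 0:
            mask = ndimage.binary_dilation(mask, structure, iterations=steps)
        elif steps < 0:
            mask = ndimage.binary_erosion(mask, structure, iterations=-steps)
        if sprinkle_fraction > 0 and len(pool_idx) > 0:
            m = int(rng.integers(0, max(1, int(sprinkle_fraction * n_truth)) + 1))
            if m > 0:
                pick = rng.choice(len(pool_idx), size=min(m, len(pool_idx)), replace=False)
                mask[tuple(pool_idx[pick].T)] = True
        if not mask.any():
            raise PhantomSpecError(f"boundary_sd={boundary_sd} emptied a tracer variant")
        variants.append(Volume(mask.astype(np.float64), lesion_truth.affine.copy()))
    return variants


_CASE_CONVENTIONS = {
    # role -> "neuro" | "radio" | None (absent), per the six validation cases
    1: {"T1": "neuro", "Lesion": "neuro", "Brain": "neuro", "WM": "neuro"},
    2: {"T1": "radio", "Lesion": "radio", "Brain": "radio", "WM": "radio"},
    3: {"T1": "neuro", "Lesion": "neuro", "Brain": "radio", "WM": "neuro"},
    4: {"T1": "neuro", "Lesion": "neuro", "Brain": "radio", "WM": "radio"},
    5: {"T1": "radio", "Lesion": "neuro", "Brain": "radio", "WM": "radio"},
    6: {"T1": "neuro", "Lesion": "neuro", "Brain": None, "WM": None},
}


def make_orientation_case(
    case: int,
    out_dir: str | Path,
    subject_id: str = "subj1",
    spec: PhantomSpec | None = None,
) -> Path:
    """Write a phantom subject directory matching one of the six
    orientation-convention validation cases (case 6 omits the optional
    brain/WM inputs).  Returns the subject directory path."""
    if case not in _CASE_CONVENTIONS:
        raise ValueError(f"case must be 1..6, got {case}")
    spec = spec or PhantomSpec()
    vols = make_head_phantom(spec)
    role_map = {
        "T1": vols["t1"],
        "Lesion": vols["lesion_truth"],
        "Brain": vols["brain_truth"],
        "WM": vols["wm_truth"],
    }
    subj_dir = Path(out_dir) / subject_id
    subj_dir.mkdir(parents=True, exist_ok=True)
    for role, conv in _CASE_CONVENTIONS[case].items():
        if conv is None:
            continue
        v = role_map[role]
        if conv == "radio":
            v = to_radiological(v)
        write_volume(v, subj_dir / f"{subject_id}_{role}.nii.gz")
    return subj_dir


def make_template_with_rois(
    spec: PhantomSpec | None = None,
    rois: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] | None = None,
) -> tuple[Volume, dict[str, Volume]]:
    """Lesion-free phantom as a template plus named ellipsoidal ROI masks.

    ``rois`` maps name -> (center, radii) in voxel coordinates; the default
    is a pair of elongated one-hemisphere "CST-like" ROIs, left and right
    of the midline, which supports the contralateral-lesion 0 % check.
    Raises :class:`PhantomSpecError` for an ROI extending outside the brain.
    """
    spec = spec or PhantomSpec()
    template_spec = replace(spec, lesion=None)
    vols = make_head_phantom(template_spec)
    template = vols["t1"]
    brain = vols["brain_truth"].data > 0
    cx, cy, cz = template_spec.center
    if rois is None:
        rois = {
            "L_CST": ((cx - 9.0, cy, cz), (4.0, 5.0, 14.0)),
            "R_CST": ((cx + 9.0, cy, cz), (4.0, 5.0, 14.0)),
        }
    roi_masks: dict[str, Volume] = {}
    for name, (center, radii) in rois.items():
        mask = _ellipsoid(template_spec.shape, center, radii)
        if np.any(mask & ~brain):
            raise PhantomSpecError(f"ROI {name} extends outside the template brain")
        roi_masks[name] = Volume(mask.astype(np.float64), template.affine.copy())
    return template, roi_masks


def write_phantom_dataset(
    out_dir: str | Path,
    n_subjects: int = 2,
    seed: int = 0,
    case: int | None = None,
    with_optional_masks: bool = False,
) -> Path:
    """Write a ready-to-run input directory of phantom subjects.

    Each subject gets its own noise seed and a slightly shifted lesion.
    With ``case`` set, every subject is written per that orientation case
    instead.  Returns the dataset directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(n_subjects):
        sid = f"subj{i + 1}"
        shift = (i % 3) - 1  # -1, 0, +1 voxel lesion shift across subjects
        lesion = LesionSpec(center=(39.0 + shift, 40.0, 32.0))
        spec = PhantomSpec(seed=seed + i, lesion=lesion)
        if case is not None:
            make_orientation_case(case, out_dir, subject_id=sid, spec=spec)
            continue
        vols = make_head_phantom(spec)
        subj_dir = out_dir / sid
        subj_dir.mkdir(exist_ok=True)
        write_volume(vols["t1"], subj_dir / f"{sid}_T1.nii.gz")
        write_volume(vols["lesion_truth"], subj_dir / f"{sid}_Lesion.nii.gz")
        if with_optional_masks:
            write_volume(vols["brain_truth"], subj_dir / f"{sid}_Brain.nii.gz")
            write_volume(vols["wm_truth"], subj_dir / f"{sid}_WM.nii.gz")
    return out_dir
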