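"""Overlap metrics: Dice coefficient, pairwise inter-rater tables, heat maps.

The Dice coefficient DC = 2|X∩Y| / (|X|+|Y|) ranges from 0 (no overlap)
to 1 (complete overlap) and is the standard similarity between two binary
segmentations.  For inter-rater reliability with n tracers the DC is
computed for each of the n(n−1)/2 unordered pairs; the summary is the
mean over pairs with its standard error (SEM over pair values).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tissue_prep import StageError
from .volume_io import Volume

__all__ = ["PairwiseDice", "dice", "pairwise_dice", "overlap_heatmap", "write_interrater_report"]


@dataclass
class PairwiseDice:
    tracer_ids: list[str]
    matrix: np.ndarray  # symmetric n x n, unit diagonal for nonempty masks
    mean_dc: float
    sem: float

    @property
    def pair_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.tracer_ids), k=1)
        return self.matrix[iu]


def dice(x: Volume, y: Volume) -> float:
    """Dice coefficient 2|X∩Y|/(|X|+|Y|) of two same-grid binary masks."""
    if x.shape != y.shape:
        raise StageError(f"dice: grid mismatch {x.shape} vs {y.shape}")
    xm = x.data > 0
    ym = y.data > 0
    nx, ny = int(xm.sum()), int(ym.sum())
    if nx + ny == 0:
        raise ValueError("dice undefined: both masks empty")
    inter = int(np.count_nonzero(xm & ym))
    return 2.0 * inter / (nx + ny)


def pairwise_dice(masks: list[Volume], tracer_ids: list[str] | None = None) -> PairwiseDice:
    """All unordered-pair Dice coefficients among n >= 2 tracer masks."""
    n = len(masks)
    if n < 2:
        raise ValueError("pairwise Dice needs at least 2 masks")
    shape0 = masks[0].shape
    for i, m in enumerate(masks):
        if m.shape != shape0:
            raise StageError(f"pairwise dice: mask {i} grid {m.shape} != {shape0}")
    ids = tracer_ids if tracer_ids is not None else [f"tracer{i + 1}" for i in range(n)]
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = dice(masks[i], masks[j])
    iu = np.triu_indices(n, k=1)
    pairs = mat[iu]
    mean_dc = float(pairs.mean())
    sem = float(pairs.std(ddof=1) / np.sqrt(pairs.size)) if pairs.size > 1 else 0.0
    return PairwiseDice(tracer_ids=ids, matrix=mat, mean_dc=mean_dc, sem=sem)


def overlap_heatmap(masks: list[Volume]) -> Volume:
    """Voxelwise count of how many masks include each voxel (0..n)."""
    if len(masks) < 2:
        raise ValueError("overlap heatmap needs at least 2 masks")
    shape0 = masks[0].shape
    for i, m in enumerate(masks):
        if m.shape != shape0:
            raise StageError(f"heatmap: mask {i} grid {m.shape} != {shape0}")
    counts = np.zeros(shape0, dtype=np.float64)
    for m in masks:
        counts += m.data > 0
    return Volume(counts, masks[0].affine.copy())


def write_interrater_report(
    entries: list[tuple[str, PairwiseDice]],
    path: str | Path,
    *,
    include_pairs: bool = False,
) -> None:
    """Write the inter-rater summary CSV; optional long-format per-pair rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if include_pairs:
            writer.writerow(["lesion_id", "n_tracers", "mean_dc", "sem", "tracer_a", "tracer_b", "dc"])
            for lesion_id, pd in entries:
                n = len(pd.tracer_ids)
                for i in range(n):
                    for j in range(i + 1, n):
                        writer.writerow(
                            [lesion_id, n, f"{pd.mean_dc:.6f}", f"{pd.sem:.6f}",
                             pd.tracer_ids[i], pd.tracer_ids[j], f"{pd.matrix[i, j]:.6f}"]
                        )
        else:
            writer.writerow(["lesion_id", "n_tracers", "mean_dc", "sem"])
            for lesion_id, pd in entries:
                writer.writerow([lesion_id, len(pd.tracer_ids), f"{pd.mean_dc:.6f}", f"{pd.sem:.6f}"])
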