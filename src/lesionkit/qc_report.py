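"""Visual-QC rendering and review gating.

Each processing stage that produces an image result gets a review
gallery: one tri-planar screenshot per subject (axial, coronal, sagittal
slices through the lesion centroid or volume center, masks alpha-blended
in stated colors), concatenated into a single static HTML page with a
pass/fail checkbox per subject.  The *authoritative* review state is a
CSV written beside the page — the checkboxes are a visual aid only — and
downstream stages receive only subjects whose row says passed.

In non-interactive runs missing review rows default to pass with a
logged warning; users are still encouraged to inspect the galleries
after the run.
"""

from __future__ import annotations

import csv
import html
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage

from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = ["ReviewRecord", "render_triplanar", "build_gallery", "apply_review"]


@dataclass
class ReviewRecord:
    """Per-stage map subject -> pass/fail that gates downstream stages."""

    stage: str
    decisions: dict[str, tuple[bool, str]] = field(default_factory=dict)  # sid -> (passed, note)

    def passing(self) -> list[str]:
        return [sid for sid, (ok, _) in self.decisions.items() if ok]


def _slice_indices(base: Volume, overlays: list[tuple[Volume, str]], focus: str) -> tuple[int, int, int]:
    if focus == "mask_centroid" and overlays:
        first = overlays[0][0]
        if first.voxel_count() > 0:
            com = ndimage.center_of_mass(first.data > 0)
            return tuple(int(round(c)) for c in com)  # type: ignore[return-value]
    return tuple(s // 2 for s in base.shape)  # type: ignore[return-value]


def render_triplanar(
    base: Volume,
    overlays: list[tuple[Volume, str]] | None = None,
    focus: str = "center",
    out_path: str | Path = "triplanar.png",
) -> Path:
    """Render axial/coronal/sagittal slices with alpha-blended mask overlays.

    ``overlays`` is a list of (mask volume, matplotlib color); ``focus``
    is ``"center"`` or ``"mask_centroid"`` (centroid of the first
    overlay).  Returns the written PNG path.
    """
    overlays = overlays or []
    if not np.any(np.isfinite(base.data)) or base.data.size == 0 or base.data.max() == base.data.min():
        raise RuntimeError("triplanar render: empty or constant base volume")
    for m, _ in overlays:
        if m.shape != base.shape:
            raise RuntimeError(f"triplanar render: overlay grid {m.shape} != base {base.shape}")
    ix, iy, iz = _slice_indices(base, overlays, focus)

    def planes(vol: np.ndarray) -> list[np.ndarray]:
        return [vol[ix, :, :], vol[:, iy, :], vol[:, :, iz]]

    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2), facecolor="black")
    titles = ["sagittal", "coronal", "axial"]
    for ax, sl, title in zip(axes, planes(base.data), titles):
        ax.imshow(sl.T, cmap="gray", origin="lower", interpolation="nearest")
        for mask, color in overlays:
            msl = planes(mask.data)[titles.index(title)]
            rgba = np.zeros((*msl.T.shape, 4))
            rgb = matplotlib.colors.to_rgb(color)
            on = msl.T > 0
            rgba[on] = (*rgb, 0.45)
            ax.imshow(rgba, origin="lower", interpolation="nearest")
        ax.set_title(title, color="white", fontsize=8)
        ax.axis("off")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=80, facecolor="black", bbox_inches="tight")
    plt.close(fig)
    return out_path


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>QC — {stage}</title>
<style>
 body {{ background:#111; color:#eee; font-family:sans-serif; }}
 .subject {{ margin:1.5em 0; border-bottom:1px solid #444; padding-bottom:1em; }}
 img {{ max-width:100%; }}
</style></head>
<body>
<h1>Quality control: {stage}</h1>
<p>Inspect each subject below, then record pass/fail in
<code>{review_csv}</code> (the CSV is the authoritative review record;
checkboxes here are a note-taking aid only).</p>
{sections}
</body></html>
"""

_SECTION = """<div class="subject">
<h2>{sid}</h2>
<img src="{img}" alt="QC screenshot for {sid}">
<p><label><input type="checkbox" name="pass_{sid}"> passes visual inspection</label>
 &nbsp; note: <input type="text" name="note_{sid}" size="40"></p>
</div>
"""


def build_gallery(stage: str, entries: list[tuple[str, Path]], out_dir: str | Path) -> Path:
    """Assemble the stage's HTML review page and its blank review CSV.

    One section (screenshot + checkbox + note field) per subject.  If a
    review CSV already exists *with any decisions filled in*, it is left
    untouched and the refusal is logged — re-rendering must never clobber
    a completed review.
    """
    if not entries:
        raise ValueError(f"no entries for QC gallery {stage}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sections = "".join(
        _SECTION.format(sid=html.escape(sid), img=html.escape(str(Path(img).name))) for sid, img in entries
    )
    review_csv = out_dir / f"{stage}_review.csv"
    page = out_dir / "index.html"
    page.write_text(_PAGE.format(stage=html.escape(stage), review_csv=review_csv.name, sections=sections))
    if review_csv.exists():
        with open(review_csv) as fh:
            rows = list(csv.DictReader(fh))
        if any((r.get("passed") or "").strip() for r in rows):
            logger.warning("refusing to overwrite filled review CSV %s", review_csv)
            return page
    with open(review_csv, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "passed", "note"])
        for sid, _ in entries:
            writer.writerow([sid, "", ""])
    return page


def apply_review(stage: str, review_csv: str | Path, *, interactive: bool = False) -> ReviewRecord:
    """Parse a review CSV into a :class:`ReviewRecord`.

    ``passed`` accepts true/false, yes/no, 1/0 (case-insensitive).  In
    interactive mode every row must be filled; otherwise blank rows
    default to pass with a warning.  A subject id the caller never
    registered is caught downstream — here any non-empty id is accepted,
    and validation against the known cohort happens in
    :func:`gate_subjects`.
    """
    review_csv = Path(review_csv)
    if not review_csv.exists():
        raise FileNotFoundError(f"review CSV not found: {review_csv}")
    record = ReviewRecord(stage=stage)
    truthy = {"true", "yes", "y", "1", "pass", "passed"}
    falsy = {"false", "no", "n", "0", "fail", "failed"}
    with open(review_csv) as fh:
        for row in csv.DictReader(fh):
            sid = (row.get("subject_id") or "").strip()
            if not sid:
                continue
            raw = (row.get("passed") or "").strip().lower()
            note = (row.get("note") or "").strip()
            if raw in truthy:
                record.decisions[sid] = (True, note)
            elif raw in falsy:
                record.decisions[sid] = (False, note)
            elif raw == "":
                if interactive:
                    raise ValueError(f"review for stage {stage!r} incomplete: no decision for {sid}")
                logger.warning(
                    "no review decision for %s at stage %s; defaulting to pass "
                    "(visual inspection after completion is still encouraged)",
                    sid,
                    stage,
                )
                record.decisions[sid] = (True, "auto-pass (no review)")
            else:
                raise ValueError(f"unparseable passed value {raw!r} for {sid} in {review_csv}")
    return record


def gate_subjects(record: ReviewRecord, known_subjects: list[str]) -> list[str]:
    """Validate the review against the cohort and return passing subjects."""
    unknown = set(record.decisions) - set(known_subjects)
    if unknown:
        raise ValueError(f"review for stage {record.stage!r} names unknown subjects: {sorted(unknown)}")
    return [sid for sid in known_subjects if record.decisions.get(sid, (True, ""))[0]]
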