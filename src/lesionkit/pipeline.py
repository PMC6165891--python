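"""Pipeline orchestration: subject discovery, stage ordering, output layout.

A run takes an input directory of per-subject subdirectories (each with a
T1, one or more lesion masks, and optional brain/WM masks, matched by
filename substring identifiers) and an empty output directory, and
executes the selected modules in pipeline order:

    reorient -> lesion correction -> lesion load -> visual QC

Flagged subjects (mixed orientation conventions, missing required files,
shape mismatch) are excluded from every later stage and listed in
``flagged_subjects.csv``; per-subject errors are recorded and skipped,
never fatal to the run.  The output tree is::

    <output>/
      <subject>/Intermediate_Files/Original_Files/   copies of inputs
      <subject>/Intermediate_Files/                  harmonized files, masks, transforms
      <subject>/                                     corrected lesion masks
      QC_<Stage>/                                    galleries + review CSVs
      lesion_correction_report.csv, lesion_load_report.csv, flagged_subjects.csv
      logs/                                          one timestamped log per run
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
import re
import shutil
from pathlib import Path

import numpy as np

from .config import RunConfig, SubjectRecord
from .lesion_correction import CorrectionResult, correct_lesion, write_correction_report
from .lesion_load import run_lesion_load, write_load_report
from .orientation import harmonize_subject
from .qc_report import apply_review, build_gallery, gate_subjects, render_triplanar
from .registration import load_transform, resample_to, save_transform
from .tissue_prep import (
    MaskProvenance,
    StageError,
    extract_brain,
    normalize_intensity,
    segment_white_matter,
)
from .volume_io import Volume, read_volume, write_volume

logger = logging.getLogger(__name__)

__all__ = ["discover_subjects", "run_pipeline", "visualize"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _nifti_files(d: Path) -> list[Path]:
    return sorted(p for p in d.iterdir() if p.name.endswith(_NIFTI_SUFFIXES))


def _basename(p: Path) -> str:
    name = p.name
    for suf in _NIFTI_SUFFIXES:
        if name.endswith(suf):
            return name[: -len(suf)]
    return name


def discover_subjects(cfg: RunConfig) -> list[SubjectRecord]:
    """Build one SubjectRecord per input subdirectory.

    Files are matched by case-sensitive substring on the basename.
    Multi-lesion files follow ``<id><LesionID><k>`` with k starting at 1
    and are ordered numerically; an unindexed lesion file coexisting with
    indexed ones — or any duplicate identifier match — flags the subject
    as ``ambiguous-files`` rather than guessing.
    """
    input_dir = Path(cfg.input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory does not exist: {input_dir}")
    subject_dirs = sorted(d for d in input_dir.iterdir() if d.is_dir())
    if not subject_dirs:
        raise FileNotFoundError(f"input directory has no subject subdirectories: {input_dir}")

    records: list[SubjectRecord] = []
    for d in subject_dirs:
        rec = SubjectRecord(subject_id=d.name)
        files = _nifti_files(d)

        t1s = [p for p in files if cfg.t1_identifier in _basename(p)]
        lesions = [p for p in files if cfg.lesion_identifier in _basename(p) and p not in t1s]
        brains = [p for p in files if cfg.brain_identifier in _basename(p) and p not in t1s + lesions]
        wms = [p for p in files if cfg.wm_identifier in _basename(p) and p not in t1s + lesions + brains]

        if len(t1s) > 1 or len(brains) > 1 or len(wms) > 1:
            rec.flag("ambiguous-files")
        elif not t1s:
            rec.flag("missing-t1")
        elif not lesions:
            rec.flag("missing-lesion")
        else:
            indexed: list[tuple[int, Path]] = []
            plain: list[Path] = []
            for p in lesions:
                m = re.search(re.escape(cfg.lesion_identifier) + r"(\d+)", _basename(p))
                if m:
                    indexed.append((int(m.group(1)), p))
                else:
                    plain.append(p)
            if (plain and indexed) or len(plain) > 1:
                rec.flag("ambiguous-files")
            else:
                rec.lesion_paths = plain if plain else [p for _, p in sorted(indexed)]
        if not rec.flagged:
            rec.t1_path = t1s[0]
            rec.brain_mask_path = brains[0] if brains else None
            rec.wm_mask_path = wms[0] if wms else None
        if rec.flagged:
            logger.warning("subject %s flagged at discovery: %s", rec.subject_id, rec.flag_reason)
        records.append(rec)
    return records


def _setup_run_logging(output_dir: Path) -> Path:
    log_dir = output_dir / "logs"
    log_dir.mkdir(parents=True, exist_ok=True)
    stamp = datetime.datetime.now().strftime("%Y%m%d_%H%M%S")
    log_path = log_dir / f"run_{stamp}.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lesionkit")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return log_path


def _teardown_run_logging() -> None:
    root = logging.getLogger("lesionkit")
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler):
            root.removeHandler(h)
            h.close()


def _write_flagged_csv(path: Path, rows: list[tuple[str, str, str, str]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "file", "convention", "reason"])
        writer.writerows(rows)


def _review_gate(stage_dir: Path, stage: str, subjects: list[str], interactive: bool) -> list[str]:
    review_csv = stage_dir / f"{stage}_review.csv"
    if interactive:  # pragma: no cover - interactive console path
        input(f"[{stage}] inspect {stage_dir / 'index.html'} , fill {review_csv.name}, then press Enter…")
    record = apply_review(stage, review_csv, interactive=interactive)
    return gate_subjects(record, subjects)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected modules; returns summary counts.

    Raises on a nonempty output directory unless ``cfg.force``; every
    per-subject problem is logged and the subject dropped instead of
    aborting the cohort.
    """
    output_dir = Path(cfg.output_dir)
    if output_dir.exists() and any(output_dir.iterdir()) and not cfg.force:
        raise FileExistsError(f"output directory {output_dir} is not empty (use force to override)")
    output_dir.mkdir(parents=True, exist_ok=True)
    log_path = _setup_run_logging(output_dir)
    try:
        logger.info("run config: %s", json.dumps({k: str(v) for k, v in vars(cfg).items()}, sort_keys=True))
        summary = _run_pipeline_inner(cfg, output_dir)
        logger.info("run summary: %s", summary)
        summary["log"] = str(log_path)
        return summary
    finally:
        _teardown_run_logging()


def _run_pipeline_inner(cfg: RunConfig, output_dir: Path) -> dict:
    subjects = discover_subjects(cfg)
    flagged_rows: list[tuple[str, str, str, str]] = []
    for rec in subjects:
        if rec.flagged:
            flagged_rows.append((rec.subject_id, "", "", rec.flag_reason))

    # copy originals
    for rec in subjects:
        orig_dir = output_dir / rec.subject_id / "Intermediate_Files" / "Original_Files"
        orig_dir.mkdir(parents=True, exist_ok=True)
        for p in filter(None, [rec.t1_path, rec.brain_mask_path, rec.wm_mask_path, *rec.lesion_paths]):
            shutil.copy2(p, orig_dir / Path(p).name)

    # ---- stage 1: reorientation / harmonization ------------------------
    active: dict[str, dict[str, Volume]] = {}  # sid -> role -> volume
    skip_bet = cfg.skip_brain_extraction
    skip_wmseg = cfg.skip_wm_segmentation
    overrides: set[str] = set()
    if "reorient" in cfg.modules:
        reports = {}
        for rec in subjects:
            if rec.flagged:
                continue
            rep = harmonize_subject(
                rec, skip_brain_extraction=skip_bet, skip_wm_segmentation=skip_wmseg
            )
            reports[rec.subject_id] = rep
            if rep.flagged:
                rec.flag(rep.flag_reason)
                for fname, conv in rep.per_file_convention.items():
                    flagged_rows.append((rec.subject_id, Path(fname).name, conv.value, rep.flag_reason))
                continue
            overrides |= rep.skip_overrides
            inter = output_dir / rec.subject_id / "Intermediate_Files"
            for role, vol in rep.volumes.items():
                write_volume(vol, inter / f"{rec.subject_id}_{role}_radiological.nii.gz")
            active[rec.subject_id] = dict(rep.volumes)
            logger.info("subject %s harmonized: %s", rec.subject_id, "; ".join(rep.actions))
        # all-or-none rule: one subject missing an optional input forces the stage for all
        if "brain_extraction" in overrides and skip_bet:
            logger.warning("brain extraction set to run on all subjects (optional input missing)")
            skip_bet = False
        if "wm_segmentation" in overrides and skip_wmseg:
            logger.warning("WM segmentation set to run on all subjects (optional input missing)")
            skip_wmseg = False
    else:
        for rec in subjects:
            if rec.flagged:
                continue
            try:
                vols: dict[str, Volume] = {"t1": read_volume(rec.t1_path)}
                lesion_roles = (
                    [f"lesion{i+1}" for i in range(len(rec.lesion_paths))]
                    if len(rec.lesion_paths) > 1
                    else ["lesion"]
                )
                for role, p in zip(lesion_roles, rec.lesion_paths):
                    vols[role] = read_volume(p, as_mask=True)
                if rec.brain_mask_path:
                    vols["brain"] = read_volume(rec.brain_mask_path, as_mask=True)
                if rec.wm_mask_path:
                    vols["wm"] = read_volume(rec.wm_mask_path, as_mask=True)
                if skip_bet and "brain" not in vols:
                    skip_bet = False
                    logger.warning("brain extraction set to run on all subjects (optional input missing)")
                if skip_wmseg and "wm" not in vols:
                    skip_wmseg = False
                    logger.warning("WM segmentation set to run on all subjects (optional input missing)")
                active[rec.subject_id] = vols
            except (OSError, ValueError) as exc:
                rec.flag("read-error")
                flagged_rows.append((rec.subject_id, "", "", f"read-error: {exc}"))

    if flagged_rows:
        _write_flagged_csv(output_dir / "flagged_subjects.csv", flagged_rows)

    summary = {
        "processed": 0,
        "flagged": sum(1 for r in subjects if r.flagged),
        "failed_review": 0,
        "failed_stage": 0,
    }
    current = [r.subject_id for r in subjects if not r.flagged]

    lesion_roles_of = {
        sid: [k for k in vols if k.startswith("lesion")] for sid, vols in active.items()
    }

    # ---- stage 2: lesion correction ------------------------------------
    if "correct" in cfg.modules and current:
        if cfg.lesion_provenance == "automated":
            logger.warning(
                "lesion correction requested on automated segmentations; "
                "correction is recommended only for manually segmented lesions"
            )
        tissue: dict[str, dict] = {}
        failed: list[str] = []
        for sid in current:
            vols = active[sid]
            try:
                t1n = normalize_intensity(vols["t1"])
                if skip_bet and "brain" in vols:
                    brain, bprov = vols["brain"], MaskProvenance.PROVIDED
                else:
                    brain, bprov = extract_brain(t1n), MaskProvenance.COMPUTED
                if skip_wmseg and "wm" in vols:
                    wm, wprov = vols["wm"], MaskProvenance.PROVIDED
                else:
                    wm, wprov = segment_white_matter(t1n, brain), MaskProvenance.COMPUTED
                inter = output_dir / sid / "Intermediate_Files"
                write_volume(brain, inter / f"{sid}_brain_mask.nii.gz")
                write_volume(wm, inter / f"{sid}_wm_mask.nii.gz")
                tissue[sid] = {"t1n": t1n, "brain": brain, "wm": wm, "bprov": bprov, "wprov": wprov}
            except StageError as exc:
                logger.error("tissue prep failed for %s: %s", sid, exc)
                failed.append(sid)
        summary["failed_stage"] += len(failed)
        current = [sid for sid in current if sid not in failed]

        if "qc" in cfg.modules and current:
            for stage, key, color in (("BrainExtractions", "brain", "tab:red"),
                                      ("WhiteMatterSegmentations", "wm", "tab:blue")):
                qc_dir = output_dir / f"QC_{stage}"
                entries = []
                for sid in current:
                    png = qc_dir / f"{sid}.png"
                    render_triplanar(tissue[sid]["t1n"], [(tissue[sid][key], color)], "center", png)
                    entries.append((sid, png))
                build_gallery(stage, entries, qc_dir)
                passed = _review_gate(qc_dir, stage, current, cfg.interactive)
                summary["failed_review"] += len(current) - len(passed)
                current = passed

        results: list[CorrectionResult] = []
        original_lesions: dict[str, Volume] = {}
        for sid in current:
            vols, tis = active[sid], tissue[sid]
            original_lesions[sid] = vols[lesion_roles_of[sid][0]]
            for role in lesion_roles_of[sid]:
                res = correct_lesion(
                    tis["t1n"],
                    tis["wm"],
                    vols[role],
                    cfg.wm_removal_percent,
                    exclude_lesion=cfg.wm_mean_exclude_lesion,
                    subject_id=sid,
                    lesion_file=role,
                )
                write_volume(res.corrected_mask, output_dir / sid / f"{sid}_{role}_corrected.nii.gz")
                active[sid][role] = res.corrected_mask  # downstream stages use corrected masks
                results.append(res)
        if results:
            write_correction_report(results, output_dir / "lesion_correction_report.csv")
        if "qc" in cfg.modules and current:
            qc_dir = output_dir / "QC_LesionCorrections"
            entries = []
            for sid in current:
                png = qc_dir / f"{sid}.png"
                role = lesion_roles_of[sid][0]
                # corrected mask in blue over the original tracing in red
                overlays = [(active[sid][role], "tab:blue"), (original_lesions[sid], "tab:red")]
                render_triplanar(tissue[sid]["t1n"], overlays, "mask_centroid", png)
                entries.append((sid, png))
            build_gallery("LesionCorrections", entries, qc_dir)
            passed = _review_gate(qc_dir, "LesionCorrections", current, cfg.interactive)
            summary["failed_review"] += len(current) - len(passed)
            current = passed

    # ---- stage 3: lesion load ------------------------------------------
    if "load" in cfg.modules and current:
        if not cfg.roi_config:
            raise ValueError("lesion load requested but no roi_config given")
        rois, template = _load_roi_config(cfg.roi_config)
        transforms = {}
        for sid in current:  # user-supplied transforms bypass estimation
            mat = Path(cfg.input_dir) / sid / f"{sid}_to_template.mat"
            if mat.exists():
                transforms[sid] = load_transform(mat)
                logger.info("using user-supplied transform for %s", sid)
        cohort = [
            {
                "subject_id": sid,
                "t1": active[sid]["t1"],
                "lesions": {role: active[sid][role] for role in lesion_roles_of[sid]},
            }
            for sid in current
        ]
        results, transforms, failed = run_lesion_load(cohort, rois, template, transforms=transforms)
        summary["failed_stage"] += len(failed)
        current = [sid for sid in current if sid not in failed]
        for sid, t in transforms.items():
            if sid in current:
                save_transform(t, output_dir / sid / "Intermediate_Files" / f"{sid}_to_template.mat")
        if "qc" in cfg.modules and current:
            qc_dir = output_dir / "QC_Registrations"
            entries = []
            for sid in current:
                png = qc_dir / f"{sid}.png"
                t1_reg = resample_to(active[sid]["t1"], transforms[sid], template, interp="linear")
                brain_fg = template.with_data((template.data > np.percentile(template.data, 75)).astype(float))
                render_triplanar(t1_reg, [(brain_fg, "tab:green")], "center", png)
                entries.append((sid, png))
            build_gallery("Registrations", entries, qc_dir)
            passed = _review_gate(qc_dir, "Registrations", current, cfg.interactive)
            summary["failed_review"] += len(current) - len(passed)
            current = passed
            results = [r for r in results if r.subject_id in current]
        write_load_report(results, output_dir / "lesion_load_report.csv")
        if "qc" in cfg.modules and current:
            qc_dir = output_dir / "QC_LesionLoads"
            entries = []
            roi_name, roi0 = next(iter(rois.items()))
            for sid in current:
                png = qc_dir / f"{sid}.png"
                lesion_t = resample_to(
                    active[sid][lesion_roles_of[sid][0]], transforms[sid], template, interp="nearest"
                )
                render_triplanar(template, [(lesion_t, "tab:blue"), (roi0, "tab:orange")], "mask_centroid", png)
                entries.append((sid, png))
            build_gallery("LesionLoads", entries, qc_dir)
            passed = _review_gate(qc_dir, "LesionLoads", current, cfg.interactive)
            summary["failed_review"] += len(current) - len(passed)
            current = passed

    summary["processed"] = len(current)
    return summary


def _load_roi_config(roi_config: dict) -> tuple[dict[str, Volume], Volume]:
    """Resolve the ROI block: template-space ROI directory + template volume."""
    mode = roi_config.get("mode", "template")
    if mode != "template":
        raise ValueError(f"unsupported roi_config mode for a cohort run: {mode!r}")
    template = read_volume(roi_config["template_path"])
    roi_dir = Path(roi_config["roi_dir"])
    rois = {}
    for p in _nifti_files(roi_dir):
        rois[_basename(p)] = read_volume(p, as_mask=True)
    if not rois:
        raise ValueError(f"no ROI volumes found in {roi_dir}")
    return rois, template


def visualize(cfg: RunConfig) -> Path:
    """Stand-alone QC: lesion-over-T1 gallery with no other processing."""
    subjects = discover_subjects(cfg)
    out_dir = Path(cfg.output_dir) / "QC_Lesions"
    entries = []
    for rec in subjects:
        if rec.flagged:
            logger.warning("skipping flagged subject %s (%s)", rec.subject_id, rec.flag_reason)
            continue
        t1 = read_volume(rec.t1_path)
        lesion = read_volume(rec.lesion_paths[0], as_mask=True)
        png = out_dir / f"{rec.subject_id}.png"
        render_triplanar(t1, [(lesion, "tab:blue")], "mask_centroid", png)
        entries.append((rec.subject_id, png))
    if not entries:
        raise ValueError("no unflagged subjects to visualize")
    return build_gallery("Lesions", entries, out_dir)
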