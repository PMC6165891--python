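"""Shared run-level domain types: per-subject file records and run configuration."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

DEFAULT_WM_REMOVAL_PERCENT = 5.0


@dataclass
class SubjectRecord:
    """One subject's discovered file set plus flag status.

    ``lesion_paths`` is ordered: multi-lesion files follow
    ``<id><LesionID><k>`` with k starting at 1 and are sorted numerically.
    """

    subject_id: str
    t1_path: Path | None = None
    lesion_paths: list[Path] = field(default_factory=list)
    brain_mask_path: Path | None = None
    wm_mask_path: Path | None = None
    label_volume_path: Path | None = None
    flagged: bool = False
    flag_reason: str = ""

    def flag(self, reason: str) -> None:
        self.flagged = True
        self.flag_reason = reason


@dataclass
class RunConfig:
    """Configuration for one pipeline run (mirrors the CLI flags and the JSON config)."""

    input_dir: Path
    output_dir: Path
    t1_identifier: str = "T1"
    lesion_identifier: str = "Lesion"
    brain_identifier: str = "Brain"
    wm_identifier: str = "WM"
    modules: tuple[str, ...] = ("reorient", "correct", "load", "qc")
    wm_removal_percent: float = DEFAULT_WM_REMOVAL_PERCENT
    skip_brain_extraction: bool = False
    skip_wm_segmentation: bool = False
    wm_mean_exclude_lesion: bool = False
    lesion_provenance: str = "manual"  # "manual" or "automated"
    roi_config: dict | None = None
    interactive: bool = False
    force: bool = False
    seed: int = 0

    VALID_MODULES = ("reorient", "correct", "load", "qc")

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        self.modules = tuple(self.modules)
        if not self.modules:
            raise ValueError("modules must be a nonempty subset of " + str(self.VALID_MODULES))
        bad = [m for m in self.modules if m not in self.VALID_MODULES]
        if bad:
            raise ValueError(f"unknown modules {bad}; valid: {self.VALID_MODULES}")
        if not 0 <= self.wm_removal_percent <= 100:
            raise ValueError("wm_removal_percent must lie in [0, 100]")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "modules" in raw:
            raw["modules"] = tuple(raw["modules"])
        return cls(**raw)
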