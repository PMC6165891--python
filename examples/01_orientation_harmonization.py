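"""Harmonize a subject's files to radiological convention.

Builds a phantom subject whose files are stored in neurological
convention (patient's left on the image's left), harmonizes them, and
shows the determinant-sign test flipping from positive to negative.
"""

import tempfile
from pathlib import Path

from lesionkit import RunConfig, discover_subjects, harmonize_subject, storage_convention
from lesionkit.phantoms import PhantomSpec, make_orientation_case

with tempfile.TemporaryDirectory() as tmp:
    make_orientation_case(1, tmp, subject_id="subj1", spec=PhantomSpec(seed=0))
    cfg = RunConfig(input_dir=tmp, output_dir=Path(tmp) / "out")
    (record,) = discover_subjects(cfg)
    report = harmonize_subject(record)

    print(f"subject: {report.subject_id}   flagged: {report.flagged}")
    for fname, conv in report.per_file_convention.items():
        print(f"  input  {Path(fname).name:24s} {conv.value}")
    for role, vol in report.volumes.items():
        print(f"  output {role:24s} {storage_convention(vol).value}")

# Every output reports 'radiological': the first voxel axis was flipped and
# the affine updated, so anatomy is unchanged in world coordinates but the
# stored left/right ordering now matches the radiological standard.
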