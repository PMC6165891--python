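import numpy as np
import pytest

from lesionkit.config import SubjectRecord
from lesionkit.orientation import harmonize_subject, to_canonical, to_radiological
from lesionkit.phantoms import PhantomSpec, make_head_phantom, make_orientation_case
from lesionkit.pipeline import discover_subjects
from lesionkit.config import RunConfig
from lesionkit.volume_io import StorageConvention, Volume, storage_convention


def world_samples(v, n=50, seed=0):
    """Intensities at a fixed set of world coordinates, via exact voxel lookup."""
    rng = np.random.default_rng(seed)
    idx = np.stack([rng.integers(0, s, n) for s in v.shape], axis=1)
    world = (v.affine @ np.c_[idx, np.ones(n)].T).T[:, :3]
    vals = v.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return world, vals


def sample_at_world(v, world):
    inv = np.linalg.inv(v.affine)
    idx = np.rint((inv @ np.c_[world, np.ones(len(world))].T).T[:, :3]).astype(int)
    return v.data[idx[:, 0], idx[:, 1], idx[:, 2]]


class TestToRadiological:
    def test_anatomy_preserved_in_world_space(self, phantom):
        v = phantom["t1"]
        world, vals = world_samples(v)
        out = to_radiological(v)
        assert storage_convention(out) is StorageConvention.RADIOLOGICAL
        np.testing.assert_allclose(sample_at_world(out, world), vals)

    def test_already_radiological_returned_unchanged(self, phantom):
        r = to_radiological(phantom["t1"])
        assert to_radiological(r) is r

    def test_idempotent(self, phantom):
        once = to_radiological(phantom["t1"])
        twice = to_radiological(once)
        np.testing.assert_array_equal(once.data, twice.data)
        np.testing.assert_array_equal(once.affine, twice.affine)

    def test_voxel_count_preserved(self, phantom):
        m = phantom["lesion_truth"]
        assert to_radiological(m).voxel_count() == m.voxel_count()


class TestToCanonical:
    def _permuted(self, v):
        perm = (2, 0, 1)
        data = np.transpose(v.data, perm)
        P = np.zeros((4, 4))
        P[3, 3] = 1.0
        for new_ax, old_ax in enumerate(perm):
            P[old_ax, new_ax] = 1.0  # new index axis -> old index axis
        return Volume(data, v.affine @ P)

    def test_restores_canonical_axis_order(self, phantom):
        v = phantom["t1"]
        out = to_canonical(self._permuted(v))
        np.testing.assert_array_equal(out.data, v.data)
        np.testing.assert_allclose(out.affine, v.affine)

    def test_already_canonical_unchanged(self, phantom):
        v = phantom["t1"]
        assert to_canonical(v) is v

    def test_world_anatomy_and_convention_preserved(self, phantom):
        v = to_radiological(phantom["t1"])
        perm = self._permuted(v)
        out = to_canonical(perm)
        assert storage_convention(out) is StorageConvention.RADIOLOGICAL
        world, vals = world_samples(v)
        np.testing.assert_allclose(sample_at_world(out, world), vals)


# outcome per case: "radiological" (all files converted) or "flagged"
CASE_OUTCOMES = {1: "radiological", 2: "radiological", 3: "flagged", 4: "flagged", 5: "flagged", 6: "radiological"}


class TestOrientationCaseMatrix:
    @pytest.mark.parametrize("case", [1, 2, 3, 4, 5, 6])
    def test_case(self, case, tmp_path):
        make_orientation_case(case, tmp_path, subject_id="subj1", spec=PhantomSpec(seed=case))
        cfg = RunConfig(input_dir=tmp_path, output_dir=tmp_path / "out")
        (rec,) = discover_subjects(cfg)
        report = harmonize_subject(rec, skip_brain_extraction=True, skip_wm_segmentation=True)
        if CASE_OUTCOMES[case] == "flagged":
            assert report.flagged
            assert not report.volumes
        else:
            assert not report.flagged
            for vol in report.volumes.values():
                assert storage_convention(vol) is StorageConvention.RADIOLOGICAL
        if case == 6:
            assert report.skip_overrides == {"brain_extraction", "wm_segmentation"}
        else:
            assert not report.skip_overrides

    def test_flagged_subject_files_untouched(self, tmp_path):
        subj_dir = make_orientation_case(5, tmp_path, subject_id="s", spec=PhantomSpec(seed=9))
        before = {p.name: p.read_bytes() for p in subj_dir.iterdir()}
        cfg = RunConfig(input_dir=tmp_path, output_dir=tmp_path / "out")
        (rec,) = discover_subjects(cfg)
        assert harmonize_subject(rec).flagged
        after = {p.name: p.read_bytes() for p in subj_dir.iterdir()}
        assert before == after


class TestHarmonizeSubject:
    def test_shape_mismatch_flags_not_raises(self, phantom, tmp_path):
        from lesionkit.volume_io import write_volume

        t1 = phantom["t1"]
        small = Volume(phantom["lesion_truth"].data[:32, :40, :32], t1.affine.copy())
        d = tmp_path / "s1"
        d.mkdir()
        write_volume(t1, d / "s1_T1.nii.gz")
        write_volume(small, d / "s1_Lesion.nii.gz")
        rec = SubjectRecord("s1", t1_path=d / "s1_T1.nii.gz", lesion_paths=[d / "s1_Lesion.nii.gz"])
        report = harmonize_subject(rec)
        assert report.flagged and report.flag_reason == "shape-mismatch"

    def test_mask_counts_preserved_by_harmonization(self, tmp_path):
        make_orientation_case(1, tmp_path, subject_id="s", spec=PhantomSpec(seed=3))
        cfg = RunConfig(input_dir=tmp_path, output_dir=tmp_path / "out")
        (rec,) = discover_subjects(cfg)
        from lesionkit.volume_io import read_volume

        counts_in = {r: read_volume(p, as_mask=True).voxel_count()
                     for r, p in [("lesion", rec.lesion_paths[0]), ("brain", rec.brain_mask_path), ("wm", rec.wm_mask_path)]}
        report = harmonize_subject(rec)
        assert not report.flagged
        assert {r: report.volumes[r].voxel_count() for r in counts_in} == counts_in
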