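import numpy as np
import pytest

from lesionkit.metrics import pairwise_dice
from lesionkit.phantoms import (
    LesionSpec,
    PhantomSpec,
    PhantomSpecError,
    make_head_phantom,
    make_orientation_case,
    make_template_with_rois,
    make_tracer_variants,
    write_phantom_dataset,
)
from lesionkit.volume_io import StorageConvention, read_volume, storage_convention


class TestHeadPhantom:
    def test_same_seed_bit_identical(self):
        a = make_head_phantom(PhantomSpec(seed=5))
        b = make_head_phantom(PhantomSpec(seed=5))
        np.testing.assert_array_equal(a["t1"].data, b["t1"].data)

    def test_different_seed_differs(self):
        a = make_head_phantom(PhantomSpec(seed=5))
        b = make_head_phantom(PhantomSpec(seed=6))
        assert not np.array_equal(a["t1"].data, b["t1"].data)

    def test_lesion_inside_brain(self, phantom):
        assert not np.any((phantom["lesion_truth"].data > 0) & ~(phantom["brain_truth"].data > 0))

    def test_tissues_partition_brain(self, phantom):
        csf, gm, wm = (phantom[k].data > 0 for k in ("csf_truth", "gm_truth", "wm_truth"))
        brain = phantom["brain_truth"].data > 0
        np.testing.assert_array_equal(csf | gm | wm, brain)
        assert not np.any(csf & gm) and not np.any(gm & wm) and not np.any(csf & wm)

    def test_default_convention_neurological(self, phantom):
        assert storage_convention(phantom["t1"]) is StorageConvention.NEUROLOGICAL

    def test_lesion_outside_brain_rejected(self):
        bad = PhantomSpec(lesion=LesionSpec(center=(5.0, 5.0, 5.0)))
        with pytest.raises(PhantomSpecError):
            make_head_phantom(bad)

    def test_bad_tissue_order_rejected(self):
        with pytest.raises(PhantomSpecError):
            PhantomSpec(tissue_means=(180.0, 110.0, 40.0))


class TestTracerVariants:
    def test_count_and_pairs(self, phantom):
        variants = make_tracer_variants(phantom["lesion_truth"], 10, 0.5, seed=1)
        assert len(variants) == 10
        assert pairwise_dice(variants).pair_values.size == 45

    def test_no_perturbation_degenerate(self, phantom):
        variants = make_tracer_variants(
            phantom["lesion_truth"], 3, 0.0, seed=1, sprinkle_fraction=0.0
        )
        assert pairwise_dice(variants).mean_dc == 1.0

    def test_variants_nonempty_and_seeded(self, phantom):
        a = make_tracer_variants(phantom["lesion_truth"], 5, 0.8, seed=9)
        b = make_tracer_variants(phantom["lesion_truth"], 5, 0.8, seed=9)
        for va, vb in zip(a, b):
            assert va.voxel_count() > 0
            np.testing.assert_array_equal(va.data, vb.data)

    def test_mean_dice_decreases_with_boundary_sd(self):
        lows, highs = [], []
        for rep in range(20):
            ph = make_head_phantom(PhantomSpec(seed=300 + rep))
            lows.append(pairwise_dice(make_tracer_variants(ph["lesion_truth"], 6, 0.3, seed=rep)).mean_dc)
            highs.append(pairwise_dice(make_tracer_variants(ph["lesion_truth"], 6, 1.5, seed=rep)).mean_dc)
        assert np.mean(highs) < np.mean(lows)

    def test_empty_lesion_rejected(self, phantom):
        empty = phantom["lesion_truth"].with_data(np.zeros_like(phantom["lesion_truth"].data))
        with pytest.raises(PhantomSpecError):
            make_tracer_variants(empty, 3, 0.5, seed=0)


EXPECTED_CASES = {
    1: {"T1": "neuro", "Lesion": "neuro", "Brain": "neuro", "WM": "neuro"},
    2: {"T1": "radio", "Lesion": "radio", "Brain": "radio", "WM": "radio"},
    5: {"T1": "radio", "Lesion": "neuro", "Brain": "radio", "WM": "radio"},
}


class TestOrientationCases:
    @pytest.mark.parametrize("case", [1, 2, 5])
    def test_file_conventions(self, case, tmp_path):
        d = make_orientation_case(case, tmp_path, subject_id="s", spec=PhantomSpec(seed=case))
        for role, conv in EXPECTED_CASES[case].items():
            v = read_volume(d / f"s_{role}.nii.gz")
            expected = StorageConvention.RADIOLOGICAL if conv == "radio" else StorageConvention.NEUROLOGICAL
            assert storage_convention(v) is expected

    def test_case6_omits_optional_files(self, tmp_path):
        d = make_orientation_case(6, tmp_path, subject_id="s", spec=PhantomSpec(seed=6))
        names = {p.name for p in d.iterdir()}
        assert names == {"s_T1.nii.gz", "s_Lesion.nii.gz"}


class TestTemplateRois:
    def test_left_roi_left_of_midline(self, template_and_rois):
        template, rois = template_and_rois
        idx = np.argwhere(rois["L_CST"].data > 0)
        world_x = (template.affine @ np.c_[idx, np.ones(len(idx))].T).T[:, 0]
        assert np.all(world_x < 0)  # midline is world x = 0

    def test_two_rois_written(self, template_and_rois):
        _, rois = template_and_rois
        assert set(rois) == {"L_CST", "R_CST"}

    def test_roi_volume_matches_analytic_ellipsoid(self, template_and_rois):
        _, rois = template_and_rois
        analytic = 4.0 / 3.0 * np.pi * 4.0 * 5.0 * 14.0
        count = rois["L_CST"].voxel_count()
        assert abs(count - analytic) / analytic < 0.05

    def test_roi_outside_brain_rejected(self):
        with pytest.raises(PhantomSpecError):
            make_template_with_rois(rois={"bad": ((2.0, 2.0, 2.0), (4.0, 4.0, 4.0))})


class TestPhantomDataset:
    def test_ready_to_run_layout(self, tmp_path):
        d = write_phantom_dataset(tmp_path / "input", n_subjects=2, seed=1, with_optional_masks=True)
        for sid in ("subj1", "subj2"):
            names = {p.name for p in (d / sid).iterdir()}
            assert names == {f"{sid}_T1.nii.gz", f"{sid}_Lesion.nii.gz",
                             f"{sid}_Brain.nii.gz", f"{sid}_WM.nii.gz"}
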