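import numpy as np
import pytest

from lesionkit.lesion_load import lesion_load, overlap_mask, roi_masks_from_labels, run_lesion_load
from lesionkit.tissue_prep import StageError
from lesionkit.volume_io import Volume

from conftest import make_mask


class TestOverlapMask:
    def test_identical_masks(self):
        m = make_mask((5, 5, 5), [(i, j, 0) for i in range(5) for j in range(5)][:50])
        ov = overlap_mask(m, m)
        assert ov.voxel_count() == m.voxel_count()

    def test_disjoint_empty(self):
        a = make_mask((4, 4, 4), [(0, 0, 0)])
        b = make_mask((4, 4, 4), [(3, 3, 3)])
        assert overlap_mask(a, b).voxel_count() == 0

    def test_sum_threshold_semantics(self):
        # before thresholding an overlapping voxel sums to exactly 2
        a = make_mask((3, 3, 3), [(1, 1, 1), (0, 0, 0)])
        b = make_mask((3, 3, 3), [(1, 1, 1), (2, 2, 2)])
        summed = (a.data > 0).astype(int) + (b.data > 0).astype(int)
        assert summed[1, 1, 1] == 2
        ov = overlap_mask(a, b)
        np.testing.assert_array_equal(ov.data > 0, summed >= 2)

    def test_equals_logical_and(self):
        rng = np.random.default_rng(11)
        a = Volume((rng.random((6, 6, 6)) < 0.5).astype(float), np.eye(4))
        b = Volume((rng.random((6, 6, 6)) < 0.5).astype(float), np.eye(4))
        np.testing.assert_array_equal(overlap_mask(a, b).data > 0, (a.data > 0) & (b.data > 0))

    def test_grid_mismatch(self):
        with pytest.raises(StageError):
            overlap_mask(make_mask((3, 3, 3), []), make_mask((4, 4, 4), []))


class TestLesionLoad:
    def test_hand_counted_percentage(self):
        roi = make_mask((10, 10, 1), [(i, j, 0) for i in range(10) for j in range(10)])  # 100 voxels
        lesion = make_mask((10, 10, 1), [(i, j, 0) for i in range(4) for j in range(10)])  # covers 40
        res = lesion_load(lesion, roi)
        assert (res.roi_voxels, res.overlap_voxels, res.percent_overlap) == (100, 40, 40.0)

    def test_full_coverage(self):
        roi = make_mask((5, 5, 1), [(i, 0, 0) for i in range(5)])
        lesion = make_mask((5, 5, 1), [(i, j, 0) for i in range(5) for j in range(2)])
        assert lesion_load(lesion, roi).percent_overlap == 100.0

    def test_contralateral_lesion_zero_percent(self, template_and_rois, phantom):
        # phantom lesion sits in the right hemisphere; left-hemisphere ROI load is exactly 0
        template, rois = template_and_rois
        res = lesion_load(phantom["lesion_truth"], rois["L_CST"])
        assert res.percent_overlap == 0.0
        assert lesion_load(phantom["lesion_truth"], rois["R_CST"]).percent_overlap > 0.0

    def test_empty_roi_errors(self):
        with pytest.raises(StageError, match="empty ROI"):
            lesion_load(make_mask((3, 3, 3), [(0, 0, 0)]), make_mask((3, 3, 3), []))

    def test_swap_changes_denominator_not_overlap(self):
        roi = make_mask((6, 6, 1), [(i, 0, 0) for i in range(6)])
        lesion = make_mask((6, 6, 1), [(i, 0, 0) for i in range(3)] + [(0, 1, 0)])
        a, b = lesion_load(lesion, roi), lesion_load(roi, lesion)
        assert a.overlap_voxels == b.overlap_voxels == 3
        assert a.percent_overlap != b.percent_overlap

    def test_dilation_monotone(self, phantom, template_and_rois):
        from scipy import ndimage

        _, rois = template_and_rois
        lesion = phantom["lesion_truth"]
        grown = lesion.with_data(
            ndimage.binary_dilation(lesion.data > 0, iterations=2).astype(float)
        )
        assert (
            lesion_load(grown, rois["R_CST"]).percent_overlap
            >= lesion_load(lesion, rois["R_CST"]).percent_overlap
        )


class TestRunLesionLoad:
    def test_cartesian_row_count_identity_grid(self, template_and_rois, phantom):
        template, rois = template_and_rois
        rois = dict(rois)
        rois["third"] = rois["L_CST"]
        # subjects already on the template grid -> identity shortcut, no registration
        subjects = [
            {"subject_id": f"s{i}", "t1": template, "lesions": {"lesion": phantom["lesion_truth"]}}
            for i in range(2)
        ]
        results, transforms, failed = run_lesion_load(subjects, rois, template)
        assert len(results) == 6 and not failed
        for t in transforms.values():
            np.testing.assert_array_equal(t.matrix, np.eye(4))

    def test_identity_shortcut_equals_native(self, template_and_rois, phantom):
        template, rois = template_and_rois
        subjects = [{"subject_id": "s", "t1": template, "lesions": {"lesion": phantom["lesion_truth"]}}]
        results, _, _ = run_lesion_load(subjects, rois, template)
        native = {name: lesion_load(phantom["lesion_truth"], r.with_data((r.data > 0).astype(float))).percent_overlap
                  for name, r in rois.items()}
        for r in results:
            assert r.percent_overlap == native[r.roi_name]


class TestLabelRois:
    def test_label_extraction(self):
        labels = Volume(np.array([[[0, 3, 3, 7, 0]]], dtype=float), np.eye(4))
        rois = roi_masks_from_labels(labels, {3: "putamen", 7: "thalamus"})
        assert rois["putamen"].voxel_count() == 2
        assert rois["thalamus"].voxel_count() == 1
        assert rois["putamen"].is_mask()
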