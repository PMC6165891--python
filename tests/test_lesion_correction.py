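import csv

import numpy as np
import pytest

from lesionkit.lesion_correction import (
    CorrectionResult,
    correct_lesion,
    removal_window,
    wm_mean_intensity,
    write_correction_report,
)
from lesionkit.tissue_prep import StageError
from lesionkit.volume_io import Volume


def vols_for(intensities, lesion_sel, wm_sel=None):
    """1-D arrangement: T1 intensities plus lesion/WM masks over them."""
    n = len(intensities)
    t1 = Volume(np.asarray(intensities, float).reshape(1, 1, n), np.eye(4))
    lesion = np.zeros(n)
    lesion[list(lesion_sel)] = 1
    wm = np.ones(n) if wm_sel is None else np.zeros(n)
    if wm_sel is not None:
        wm[list(wm_sel)] = 1
    return t1, t1.with_data(wm.reshape(1, 1, n)), t1.with_data(lesion.reshape(1, 1, n))


class TestRemovalWindow:
    def test_default_five_percent(self):
        assert removal_window(128.0, 5.0) == (121.625, 134.375)

    def test_zero_percent_zero_width(self):
        assert removal_window(128.0, 0.0) == (128.0, 128.0)

    def test_hundred_percent_unclamped(self):
        assert removal_window(200.0, 100.0) == (72.5, 327.5)

    @pytest.mark.parametrize("p", [-1.0, 101.0])
    def test_out_of_range_percent_rejected(self, p):
        with pytest.raises(ValueError):
            removal_window(128.0, p)


class TestWmMeanIntensity:
    def test_plain_mean(self):
        t1, wm, lesion = vols_for([180.0, 190.0, 200.0], lesion_sel=[])
        assert wm_mean_intensity(t1, wm) == 190.0

    def test_exclude_lesion(self):
        t1, wm, lesion = vols_for([180.0, 190.0, 200.0], lesion_sel=[2])
        assert wm_mean_intensity(t1, wm, lesion, exclude_lesion=True) == 185.0

    def test_empty_mask_errors(self):
        t1, wm, lesion = vols_for([1.0, 2.0], lesion_sel=[], wm_sel=[])
        with pytest.raises(StageError):
            wm_mean_intensity(t1, wm)


class TestCorrectLesion:
    def test_constructed_ten_voxel_lesion_matches_brute_force(self):
        # 10 lesion voxels with chosen intensities; WM voxels at mean 128
        intensities = [120, 121, 122, 125, 128, 131, 134, 135, 140, 200, 128, 128]
        t1, wm, lesion = vols_for(intensities, lesion_sel=range(10), wm_sel=[10, 11])
        res = correct_lesion(t1, wm, lesion, 5.0)
        lo, hi = removal_window(128.0, 5.0)
        brute = sum(1 for x in intensities[:10] if lo <= x <= hi)
        assert res.removed_voxels == brute == 5  # 122,125,128,131,134
        assert res.surviving_voxels == 10 - brute
        assert res.original_voxels == 10

    def test_zero_percent_removes_nothing_off_mean(self):
        t1, wm, lesion = vols_for([100.0, 150.0, 128.0, 128.0], lesion_sel=[0, 1], wm_sel=[2, 3])
        res = correct_lesion(t1, wm, lesion, 0.0)
        np.testing.assert_array_equal(res.corrected_mask.data, lesion.data)

    def test_total_removal_warns(self):
        t1, wm, lesion = vols_for([128.0, 128.0, 128.0], lesion_sel=[0, 1], wm_sel=[2])
        with pytest.warns(UserWarning, match="entirely inside"):
            res = correct_lesion(t1, wm, lesion, 5.0)
        assert res.surviving_voxels == 0 and res.corrected_mask.voxel_count() == 0

    def test_empty_lesion_warns_zero_counts(self):
        t1, wm, lesion = vols_for([128.0, 130.0], lesion_sel=[], wm_sel=[0, 1])
        with pytest.warns(UserWarning, match="empty lesion"):
            res = correct_lesion(t1, wm, lesion, 5.0)
        assert (res.original_voxels, res.removed_voxels, res.surviving_voxels) == (0, 0, 0)

    def test_grid_mismatch_errors(self, phantom):
        t1 = Volume(np.zeros((4, 4, 4)), np.eye(4))
        with pytest.raises(StageError):
            correct_lesion(t1, phantom["wm_truth"], phantom["lesion_truth"], 5.0)

    def test_counts_conserve_and_subset(self, phantom):
        from lesionkit.tissue_prep import normalize_intensity

        t1n = normalize_intensity(phantom["t1"])
        res = correct_lesion(t1n, phantom["wm_truth"], phantom["lesion_truth"], 25.0)
        assert res.original_voxels == res.removed_voxels + res.surviving_voxels
        assert not np.any((res.corrected_mask.data > 0) & ~(phantom["lesion_truth"].data > 0))

    @pytest.mark.parametrize("p_pair", [(0.0, 5.0), (5.0, 20.0), (20.0, 100.0)])
    def test_monotone_in_percent(self, phantom, p_pair):
        from lesionkit.tissue_prep import normalize_intensity

        p1, p2 = p_pair
        t1n = normalize_intensity(phantom["t1"])
        r1 = correct_lesion(t1n, phantom["wm_truth"], phantom["lesion_truth"], p1)
        r2 = correct_lesion(t1n, phantom["wm_truth"], phantom["lesion_truth"], p2)
        removed1 = (phantom["lesion_truth"].data > 0) & ~(r1.corrected_mask.data > 0)
        removed2 = (phantom["lesion_truth"].data > 0) & ~(r2.corrected_mask.data > 0)
        assert not np.any(removed1 & ~removed2)  # removed@p1 subset of removed@p2


class TestCorrectionReport:
    def _result(self, sid, lesion_file, removed=3):
        mask = Volume(np.zeros((2, 2, 2)), np.eye(4))
        return CorrectionResult(
            corrected_mask=mask, original_voxels=10, removed_voxels=removed,
            surviving_voxels=10 - removed, wm_mean=128.0, window=(121.625, 134.375),
            percent_param=5.0, subject_id=sid, lesion_file=lesion_file,
        )

    def test_row_per_subject_lesion(self, tmp_path):
        out = tmp_path / "report.csv"
        write_correction_report(
            [self._result("s1", "lesion"), self._result("s2", "lesion1"), self._result("s2", "lesion2")], out
        )
        rows = list(csv.DictReader(open(out)))
        assert len(rows) == 3
        assert [r["subject_id"] for r in rows] == ["s1", "s2", "s2"]

    def test_percent_removed(self, tmp_path):
        out = tmp_path / "report.csv"
        write_correction_report([self._result("s1", "lesion", removed=3)], out)
        (row,) = csv.DictReader(open(out))
        assert float(row["percent_removed"]) == 30.0
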