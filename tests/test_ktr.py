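"""Illumination correction, segmentation, ring geometry, and C/N measurement."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import rescuekit as rk
from rescuekit import ktr
from rescuekit.exceptions import ParameterError


class TestIlluminationCorrection:
    def test_flat_image_unchanged(self):
        img = np.full((64, 64), 37.0)
        np.testing.assert_allclose(ktr.correct_illumination(img), img,
                                   rtol=1e-9)

    def test_all_zero_image_returned_uncorrected(self, caplog):
        img = np.zeros((32, 32))
        with caplog.at_level("WARNING"):
            out = ktr.correct_illumination(img)
        np.testing.assert_array_equal(out, img)
        assert "uncorrected" in caplog.text

    def test_gradient_field_ratios_recovered(self):
        spec = rk.ImageSimSpec(n_cells=30, true_cn_ratio=2.5,
                               illumination_gradient=0.3, noise_sd=0.0, seed=5)
        nuc, rep, _ = rk.gen_ktr_field(spec)
        meas = rk.quantify_field(nuc, rep)
        assert np.all(np.abs(meas.cn_ratio - 2.5) / 2.5 < 0.05)


class TestSegmentNuclei:
    def test_blank_field_gives_no_labels(self, caplog):
        with caplog.at_level("WARNING"):
            labels = ktr.segment_nuclei(np.full((50, 50), 7.0))
        assert labels.max() == 0

    def test_disks_found_with_correct_area(self, disk_image):
        img, centers = disk_image
        labels = ktr.segment_nuclei(img)
        assert labels.max() == len(centers)
        # pixel-count oracle: rasterized disk area
        expected = int(np.sum((np.arange(-10, 11)[:, None] ** 2
                               + np.arange(-10, 11)[None, :] ** 2) <= 64))
        for k in range(1, labels.max() + 1):
            assert abs((labels == k).sum() - expected) / expected < 0.05

    def test_separated_disks_get_distinct_labels(self):
        img = np.full((60, 120), 5.0)
        img[20:30, 20:30] = 200.0
        img[20:30, 80:90] = 200.0
        labels = ktr.segment_nuclei(img, min_area=10)
        assert labels.max() == 2

    def test_size_gate_removes_outliers(self, disk_image):
        img, centers = disk_image
        img[0:2, 0:2] = 200.0  # 4-px speck
        labels = ktr.segment_nuclei(img, min_area=50)
        assert labels.max() == len(centers)


class TestExtendCytoplasm:
    def test_ring_area_matches_rasterized_annulus(self):
        nuclei = np.zeros((101, 101), dtype=np.int32)
        yy, xx = np.mgrid[0:101, 0:101]
        d2 = (yy - 50) ** 2 + (xx - 50) ** 2
        nuclei[d2 <= 8 ** 2] = 1
        rings = ktr.extend_cytoplasm(nuclei, width=10)
        # brute-force oracle: pixels within 10 px (EDT) of the nucleus
        dist = ndimage.distance_transform_edt(nuclei == 0)
        expected = int(((nuclei == 0) & (dist <= 10)).sum())
        assert (rings == 1).sum() == expected
        assert not np.any((rings > 0) & (nuclei > 0))

    def test_distant_nuclei_have_disjoint_complete_rings(self):
        nuclei = np.zeros((80, 200), dtype=np.int32)
        nuclei[35:45, 35:45] = 1
        nuclei[35:45, 155:165] = 2
        rings = ktr.extend_cytoplasm(nuclei, width=10)
        assert set(np.unique(rings)) == {0, 1, 2}
        assert (rings == 1).sum() == (rings == 2).sum()

    def test_contested_pixels_go_to_nearest_nucleus(self):
        nuclei = np.zeros((60, 60), dtype=np.int32)
        nuclei[28:32, 10:14] = 1
        nuclei[28:32, 22:26] = 2  # 8 px gap < 2 * width
        rings = ktr.extend_cytoplasm(nuclei, width=10)
        dist1 = ndimage.distance_transform_edt(nuclei != 1)
        dist2 = ndimage.distance_transform_edt(nuclei != 2)
        contested = (rings > 0) & (dist1 <= 10) & (dist2 <= 10)
        assert contested.any()
        np.testing.assert_array_equal(
            rings[contested], np.where(dist1[contested] <= dist2[contested],
                                       1, 2))

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ParameterError):
            ktr.extend_cytoplasm(np.zeros((5, 5), dtype=int), width=0)


class TestMeasureKTR:
    @pytest.fixture()
    def simple_cell(self):
        nuclei = np.zeros((40, 40), dtype=np.int32)
        nuclei[15:25, 15:25] = 1
        rings = ktr.extend_cytoplasm(nuclei, width=5)
        return nuclei, rings

    @pytest.mark.parametrize("nuc_val,cyt_val,expected",
                             [(100.0, 250.0, 2.5), (80.0, 80.0, 1.0)])
    def test_uniform_intensities_give_exact_ratio(self, simple_cell, nuc_val,
                                                  cyt_val, expected):
        nuclei, rings = simple_cell
        reporter = np.zeros((40, 40))
        reporter[nuclei == 1] = nuc_val
        reporter[rings == 1] = cyt_val
        meas = ktr.measure_ktr(nuclei, rings, reporter)
        assert meas.cn_ratio.iloc[0] == pytest.approx(expected)

    def test_ratio_invariant_under_reporter_scaling(self, simple_cell):
        nuclei, rings = simple_cell
        rng = np.random.default_rng(0)
        reporter = rng.uniform(50, 500, (40, 40))
        r1 = ktr.measure_ktr(nuclei, rings, reporter).cn_ratio.iloc[0]
        r2 = ktr.measure_ktr(nuclei, rings, 7.3 * reporter).cn_ratio.iloc[0]
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_nuclear_median_flagged(self, simple_cell):
        nuclei, rings = simple_cell
        reporter = np.zeros((40, 40))
        reporter[rings == 1] = 100.0
        meas = ktr.measure_ktr(nuclei, rings, reporter)
        assert meas.flag_zero_nuc.iloc[0]
        assert np.isnan(meas.cn_ratio.iloc[0])


class TestRemoveArtifacts:
    def test_clean_measurements_unchanged(self):
        m = pd.DataFrame({"cell": [1, 2], "nucleus_area": [200, 220],
                          "cn_ratio": [2.0, 2.4], "sat_frac": [0.0, 0.0],
                          "flag_zero_nuc": [False, False]})
        assert len(ktr.remove_artifacts(m)) == 2

    def test_planted_artifact_cells_exactly_excluded(self):
        spec = rk.ImageSimSpec(n_cells=30, true_cn_ratio=2.5, n_artifacts=3,
                               seed=13)
        nuc, rep, truth = rk.gen_ktr_field(spec)
        meas = rk.quantify_field(nuc, rep)
        kept = ktr.remove_artifacts(meas)
        removed = meas.loc[~meas.index.isin(kept.index)]
        # match removed cells to planted centers
        planted = truth[truth.artifact]
        assert len(removed) == len(planted)
        for _, cell in removed.iterrows():
            d = np.hypot(planted.y - cell.y, planted.x - cell.x)
            assert d.min() < spec.nucleus_radius

    def test_all_artifactual_yields_empty_with_warning(self, caplog):
        m = pd.DataFrame({"cell": [1], "nucleus_area": [200],
                          "cn_ratio": [2.0], "sat_frac": [0.5],
                          "flag_zero_nuc": [False]})
        with caplog.at_level("WARNING"):
            out = ktr.remove_artifacts(m)
        assert out.empty and "removed" in caplog.text


class TestSummarizeCondition:
    def test_constant_ratios_single_replicate(self):
        m = pd.DataFrame({"condition": "a", "replicate": 1,
                          "cn_ratio": [1.7] * 5})
        per_rep, per_cond = ktr.summarize_condition(m)
        assert per_rep["median"].iloc[0] == pytest.approx(1.7)
        assert per_cond.sd_of_medians.iloc[0] == 0.0

    def test_condition_mean_of_replicate_medians(self):
        m = pd.DataFrame({
            "condition": ["a"] * 6, "replicate": [1] * 3 + [2] * 3,
            "cn_ratio": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]})
        _, per_cond = ktr.summarize_condition(m)
        assert per_cond.mean_of_medians.iloc[0] == pytest.approx(1.5)

    def test_normalization_to_reference(self):
        m = pd.DataFrame({
            "condition": ["ctrl"] * 3 + ["drug"] * 3,
            "replicate": [1, 2, 3] * 2,
            "cn_ratio": [2.5, 2.5, 2.5, 1.0, 1.0, 1.0]})
        _, per_cond = ktr.summarize_condition(m, normalize_to="ctrl")
        drug = per_cond.set_index("condition").loc["drug", "normalized"]
        assert drug == pytest.approx(0.4)
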