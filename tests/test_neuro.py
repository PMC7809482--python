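"""Segmentation chain: kernels, DoG, nuclei splitting, ROIs, marker masks,
classification — each stage against independent literal re-execution or
hand-built scenes."""

import numpy as np
import pytest
from scipy import ndimage

import plateqc as pq
from plateqc import neuro as nr

import _literal_chain as lit

T = nr.DEFAULT_THRESHOLDS


def _blob(img, cy, cx, amp=200.0, sigma=4.0):
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    return img


class TestKernelsAndDog:
    @pytest.mark.parametrize("size, sigma", [(10, 2), (60, 20), (11, 1),
                                             (11, 3), (99, 3), (99, 11)])
    def test_kernel_normalized(self, size, sigma):
        k = nr.GaussianKernelSpec(size, sigma).kernel2d()
        assert k.shape == (size, size)
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert (k > 0).all()

    def test_constant_image_maps_to_zero(self):
        out = nr.dog_filter(np.full((80, 80), 123.0), (10, 2), (60, 20))
        assert np.abs(out).max() < 1e-9

    def test_impulse_response_matches_full_2d_correlation(self):
        im = np.zeros((70, 70))
        im[35, 35] = 1.0
        ours = nr.dog_filter(im, (10, 2), (11, 3))
        ref = (ndimage.correlate(im, nr.GaussianKernelSpec(10, 2).kernel2d(), mode="reflect")
               - ndimage.correlate(im, nr.GaussianKernelSpec(11, 3).kernel2d(), mode="reflect"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_fine_sigma_must_be_smaller(self):
        with pytest.raises(ValueError):
            nr.dog_filter(np.zeros((32, 32)), (11, 3), (11, 1))

    def test_blob_centers_exceed_nuclei_threshold(self, neuro_scene):
        image, truth = neuro_scene
        dog = nr.dog_filter(image.channel(1), T.nuc_fine, T.nuc_coarse)
        for cy, cx in truth.centers:
            assert dog[int(round(cy)), int(round(cx))] > T.nuc_dog


class TestSegmentNuclei:
    def test_empty_channel_zero_nuclei(self):
        mask, labels = nr.segment_nuclei(np.zeros((64, 64)))
        assert not mask.any() and labels.max() == 0

    def test_single_blob_single_label(self):
        img = _blob(np.zeros((96, 96)), 48, 48)
        mask, labels = nr.segment_nuclei(img)
        assert labels.max() == 1

    def test_touching_blobs_are_split(self):
        # compact bright nuclei 12 px apart: one component before splitting
        img = _blob(_blob(np.zeros((96, 96)), 48, 42, amp=300, sigma=3),
                    48, 54, amp=300, sigma=3)
        mask, labels = nr.segment_nuclei(img)
        # the thresholded mask itself is one merged component ...
        merged, n_merged = ndimage.label(mask, structure=np.ones((3, 3), int))
        assert n_merged == 1
        # ... the watershed split yields two labels
        assert labels.max() == 2

    def test_raising_threshold_never_adds_nuclei(self, neuro_scene):
        image, _ = neuro_scene
        counts = []
        for thr in (50.0, 80.0, 120.0, 160.0):
            t = nr.PipelineThresholds(nuc_dog=thr)
            _, labels = nr.segment_nuclei(image.channel(1), t)
            counts.append(int(labels.max()))
        assert counts == sorted(counts, reverse=True)

    def test_matches_literal_chain(self, neuro_scene):
        image, _ = neuro_scene
        nuc = image.channel(1)
        mask, labels = nr.segment_nuclei(nuc)
        ref_mask = lit.nuclei_mask(nuc)
        ref_labels, n_ref = lit.nuclei_labels(ref_mask)
        np.testing.assert_array_equal(mask, ref_mask)
        assert labels.max() == n_ref


class TestCellRois:
    def test_single_nucleus_roi_is_superset(self):
        img = _blob(np.zeros((96, 96)), 48, 48)
        mask, labels = nr.segment_nuclei(img)
        rois = nr.build_cell_rois(mask, labels)
        nucleus = labels == 1
        roi = rois == 1
        assert (roi[nucleus & (rois > 0)]).all()
        assert roi.sum() > nucleus.sum()

    def test_adjacent_nuclei_rois_disjoint(self):
        img = _blob(_blob(np.zeros((96, 96)), 48, 40), 48, 56)
        mask, labels = nr.segment_nuclei(img)
        rois = nr.build_cell_rois(mask, labels)
        assert set(np.unique(rois)) == {0, 1, 2}
        # label maps are disjoint by construction; check both ROIs nonempty
        assert (rois == 1).any() and (rois == 2).any()

    def test_border_nucleus_clipped_not_wrapped(self):
        img = _blob(np.zeros((96, 96)), 10, 48)
        mask, labels = nr.segment_nuclei(img)
        rois = nr.build_cell_rois(mask, labels)
        assert rois.max() == 1
        # nothing may appear at the opposite border (no wraparound)
        assert not rois[-15:, :].any()

    def test_each_roi_contains_its_nucleus(self, segmented_scene):
        result, _ = segmented_scene
        for lab in np.unique(result.nuc_labels)[1:]:
            roi_ids = np.unique(result.roi_labels[result.nuc_labels == lab])
            roi_ids = roi_ids[roi_ids > 0]
            assert roi_ids.tolist() == [lab]


class TestMarkerMasks:
    def test_zero_channel_empty_mask(self):
        m = nr.segment_marker_mask(np.zeros((64, 64)), T.marker_fine_pair,
                                   T.marker_big_pair, T.th_fine, T.th_big,
                                   T.th_median_global)
        assert not m.any()

    def test_uniform_bright_channel_global_clause(self):
        """Median clause covers a flat bright field except the 4 corner
        pixels, whose zero-padded 3x3 window has majority padding."""
        m = nr.segment_marker_mask(np.full((64, 64), 100.0), T.marker_fine_pair,
                                   T.marker_big_pair, T.th_fine, T.th_big,
                                   T.th_median_global)
        assert m[1:-1, 1:-1].all()
        assert m.sum() >= m.size - 4

    def test_thin_dim_line_caught_by_fine_dog(self):
        im = np.zeros((64, 64))
        im[30:32, 8:56] = 40.0  # 2 px wide, intensity below the global clause
        line = im > 0
        mask_global = nr.median3x3(im) > T.th_median_global
        assert not mask_global.any()  # global clause alone misses it
        m = nr.segment_marker_mask(im, T.marker_fine_pair, T.marker_big_pair,
                                   T.th_fine, T.th_big, T.th_median_global)
        assert (m & line).sum() / line.sum() >= 0.8

    def test_matches_literal_chain(self, neuro_scene):
        image, _ = neuro_scene
        th, tuj1 = image.channel(0), image.channel(2)
        ours_th = nr.segment_marker_mask(th, T.marker_fine_pair, T.marker_big_pair,
                                         T.th_fine, T.th_big, T.th_median_global)
        np.testing.assert_array_equal(ours_th, lit.marker_mask(th, 3, 10, 50))
        ours_tj = nr.segment_marker_mask(tuj1, T.marker_fine_pair, T.marker_big_pair,
                                         T.tuj1_fine, T.tuj1_big, T.tuj1_median_global)
        np.testing.assert_array_equal(ours_tj, lit.marker_mask(tuj1, 2, 3, 20))


class TestClassifyCells:
    def test_zero_th_channel_no_positives(self, neuro_scene):
        image, _ = neuro_scene
        nuc_mask, nuc_labels = nr.segment_nuclei(image.channel(1))
        rois = nr.build_cell_rois(nuc_mask, nuc_labels)
        full = np.ones_like(nuc_mask, bool)
        res = nr.classify_cells(rois, nuc_mask, np.zeros_like(image.channel(0)),
                                full, full, nuc_labels=nuc_labels)
        assert res.n_th_positive == 0

    def test_threshold_is_strict(self):
        """A cell whose background-subtracted ROI mean is exactly 20 is NOT
        TH-positive; infinitesimally above, it is."""
        rois = np.ones((20, 20), int)
        nuc_mask = np.ones((20, 20), bool)  # background fallback b = 0
        full = np.ones((20, 20), bool)
        at = nr.classify_cells(rois, nuc_mask, np.full((20, 20), 20.0), full, full)
        above = nr.classify_cells(rois, nuc_mask, np.full((20, 20), 20.0 + 1e-9),
                                  full, full)
        assert at.n_th_positive == 0
        assert above.n_th_positive == 1

    def test_background_is_mean_outside_nuclei(self):
        nuc_mask = np.zeros((30, 30), bool)
        nuc_mask[10:14, 10:14] = True
        rois = np.zeros((30, 30), int)
        rois[8:16, 8:16] = 1
        nuc_labels = nuc_mask.astype(int)
        th = np.full((30, 30), 7.0)
        th[rois == 1] = 40.0
        full = np.ones((30, 30), bool)
        res = nr.classify_cells(rois, nuc_mask, th, full, full, nuc_labels=nuc_labels)
        outside = ~nuc_mask
        expected_b = th[outside].mean()
        assert res.cells.loc[0, "th_mean_bgsub"] == pytest.approx(40.0 - expected_b)

    def test_result_invariants(self, segmented_scene):
        result, truth = segmented_scene
        np.testing.assert_array_equal(result.neuro_mask,
                                      result.th_mask | result.tuj1_mask)
        assert result.n_th_positive <= result.n_neurons <= result.n_nuclei
        assert result.neuron_fraction == pytest.approx(
            result.n_neurons / result.n_nuclei)

    def test_recovers_truth_identities(self, segmented_scene):
        result, truth = segmented_scene
        assert result.n_nuclei == truth.n_cells_true
        assert result.neuron_fraction == pytest.approx(1.0)
        assert abs(result.th_fraction_of_neurons - 0.25) <= 0.05

    def test_deterministic(self, neuro_scene):
        image, _ = neuro_scene
        r1 = nr.segment_scene(image.channel(1), image.channel(2), image.channel(0))
        r2 = nr.segment_scene(image.channel(1), image.channel(2), image.channel(0))
        np.testing.assert_array_equal(r1.roi_labels, r2.roi_labels)
        assert r1.summary() == r2.summary()
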