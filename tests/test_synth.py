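"""Generator determinism, exact truth bookkeeping and scene feasibility."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import plateqc as pq


class TestAdherentField:
    def test_zero_coverage_pure_background(self):
        image, truth = pq.gen_adherent_field(64, 64, 0.0, seed=1)
        assert not truth.mask.any()
        assert truth.coverage_true == 0.0

    def test_full_coverage(self):
        image, truth = pq.gen_adherent_field(64, 64, 1.0, seed=1)
        assert truth.mask.all() and truth.coverage_true == 1.0

    def test_quota_hit_and_truth_recomputable(self):
        image, truth = pq.gen_adherent_field(256, 256, 0.40, seed=7)
        # truth fraction equals an independent pixel count of the emitted mask
        assert truth.coverage_true == truth.mask.sum() / truth.mask.size
        assert 0.39 <= truth.coverage_true <= 0.41

    def test_bit_identical_for_same_seed(self):
        a_img, a_truth = pq.gen_adherent_field(128, 128, 0.4, seed=7)
        b_img, b_truth = pq.gen_adherent_field(128, 128, 0.4, seed=7)
        np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
        np.testing.assert_array_equal(a_truth.mask, b_truth.mask)

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            pq.gen_adherent_field(64, 64, 1.2, seed=0)

    def test_foreground_speckle_contrast(self):
        image, truth = pq.gen_adherent_field(256, 256, 0.5, seed=3)
        fg_sd = image.pixels[truth.mask].std()
        bg_sd = image.pixels[~truth.mask].std()
        assert fg_sd >= 5 * bg_sd


class TestWellScan:
    def test_homogeneous_well_constant_truth(self):
        layout = pq.default_layout("six_well")
        scan, truth = pq.gen_well_scan(layout, 0.5, 0.0, seed=2,
                                       width=64, height=64)
        cov = np.asarray(truth.per_field_coverage)
        assert len(scan) == 38
        assert np.all(cov == cov[0]) and cov[0] == pytest.approx(0.5, abs=0.001)

    def test_gradient_produces_spread(self):
        layout = pq.default_layout("six_well")
        _, truth = pq.gen_well_scan(layout, 0.5, 0.2, seed=2, width=64, height=64)
        cov = np.asarray(truth.per_field_coverage)
        assert cov.std(ddof=1) / cov.mean() > 0

    def test_clipping_keeps_truth_in_unit_interval(self):
        layout = pq.default_layout("one_well")
        _, truth = pq.gen_well_scan(layout, 0.9, 0.5, seed=3, width=64, height=64)
        cov = np.asarray(truth.per_field_coverage)
        assert len(cov) == 384
        assert cov.max() <= 1.0 and cov.min() >= 0.0


class TestNeuroScene:
    def test_empty_scene_background_only(self):
        image, truth = pq.gen_neuro_scene(64, 64, 0, seed=1)
        assert truth.n_cells_true == 0
        assert image.pixels.max() < 20  # no structure in any channel

    def test_exact_fraction_rounding(self):
        _, truth = pq.gen_neuro_scene(256, 256, 20, 1.0, 0.25, seed=1)
        assert truth.n_cells_true == 20
        assert len(truth.centers) == 20
        assert len(truth.th_positive_ids) == 5
        assert set(truth.th_positive_ids) <= set(truth.neuron_ids)
        assert set(truth.neuron_ids) <= set(range(1, 21))

    def test_rounding_ties_go_up(self):
        _, truth = pq.gen_neuro_scene(256, 256, 10, 1.0, 0.25, seed=1)
        assert len(truth.th_positive_ids) == 3  # 2.5 rounds up

    def test_minimum_center_spacing(self):
        _, truth = pq.gen_neuro_scene(256, 256, 50, seed=3)
        centers = np.asarray(truth.centers)
        assert pdist(centers).min() >= 8.0
        assert centers.min() >= 12.0
        assert (256 - centers.max()) >= 12.0

    def test_infeasible_density_raises_capacity_error(self):
        with pytest.raises(pq.CapacityError):
            pq.gen_neuro_scene(64, 64, 500, seed=0)

    def test_deterministic(self):
        a, ta = pq.gen_neuro_scene(128, 128, 12, 1.0, 0.25, seed=9)
        b, tb = pq.gen_neuro_scene(128, 128, 12, 1.0, 0.25, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert ta.th_positive_ids == tb.th_positive_ids

    def test_nuclei_blob_amplitude_over_background(self):
        image, truth = pq.gen_neuro_scene(128, 128, 8, seed=5)
        nuc = image.channel(1)
        bg = np.median(nuc)
        assert bg <= 10
        for cy, cx in truth.centers:
            assert nuc[int(round(cy)), int(round(cx))] - bg >= 150


class TestOrganoidScene:
    def test_disk_area_close_to_continuous(self):
        _, truth = pq.gen_organoid_image("disk", 50, pixel_size=1.0, seed=0)
        assert truth.organoid_area_true == pytest.approx(np.pi * 50 ** 2, rel=0.02)

    def test_single_pixel_object_feret_zero(self):
        _, truth = pq.gen_organoid_image("disk", 0.4, seed=0)
        assert truth.mask.sum() == 1
        assert truth.organoid_feret_true == 0.0

    def test_truth_feret_recomputable_from_mask(self):
        for seed in (0, 1, 2):
            _, truth = pq.gen_organoid_image("blob", 20, pixel_size=3.0, seed=seed)
            pts = np.column_stack(np.nonzero(truth.mask)).astype(float)
            brute = pdist(pts).max() * 3.0
            assert truth.organoid_feret_true == pytest.approx(brute, abs=1e-9)
            assert truth.organoid_area_true == truth.mask.sum() * 9.0

    def test_object_darker_than_background(self):
        image, truth = pq.gen_organoid_image("ellipse", (40, 25), seed=1)
        inside = image.pixels[truth.mask].mean()
        outside = image.pixels[~truth.mask].mean()
        assert inside <= 0.4 * outside

    def test_oversized_object_rejected(self):
        with pytest.raises(ValueError):
            pq.gen_organoid_image("disk", 80, seed=0, width=100, height=100)


class TestDilutionSeries:
    def test_noiseless_points_on_curve(self):
        table, truth = pq.gen_dilution_series([1, 2, 4, 8], noise_sd=0, seed=0)
        y = truth.params["ymax"] * (1 - np.exp(-truth.params["k"] * table.seeded_amount))
        np.testing.assert_allclose(table.confluency_pct, y, atol=1e-12)

    def test_reproducible_table(self):
        t1, _ = pq.gen_dilution_series([1, 2, 4, 8, 16], noise_sd=2, seed=42)
        t2, _ = pq.gen_dilution_series([1, 2, 4, 8, 16], noise_sd=2, seed=42)
        assert t1.equals(t2)

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            pq.gen_dilution_series([1, 2, 4], noise_sd=0, seed=0)
        with pytest.raises(ValueError):
            pq.gen_dilution_series([1, 2, 2, 4], noise_sd=0, seed=0)
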