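"""Three-step quantification: segmentation, viability gating, PGCC calling."""

import numpy as np
import pytest

from pgccscreen import fixtures as fx
from pgccscreen import imaging


class TestSegmentation:
    def test_recovers_all_fixture_blobs(self, fixture_image, default_params):
        img, truth = fixture_image
        records = imaging.segment_nuclei(img[0], default_params)
        assert len(records) == len(truth.nuclei) == 17

    def test_blank_image_yields_no_records(self, default_params, rng):
        noise = rng.normal(100, 30, size=(256, 256)).clip(0)
        assert imaging.segment_nuclei(noise, default_params) == []

    def test_min_area_filter_removes_small_blob(self):
        img = np.full((128, 128), 100.0)
        fx._draw_disk(img, (64, 64), 3.0, 10_000.0)  # area ~28 px^2
        params = imaging.SegmentationParams(min_area=100, max_area=10_000)
        assert imaging.segment_nuclei(img, params) == []
        params_loose = imaging.SegmentationParams(min_area=5, max_area=10_000)
        assert len(imaging.segment_nuclei(img, params_loose)) == 1

    def test_measured_area_close_to_disk_area(self, fixture_image, default_params):
        """Measured areas within 5% of pi r^2 for non-overlapping disks."""
        img, truth = fixture_image
        records = imaging.segment_nuclei(img[0], default_params)
        true_areas = sorted(np.pi * n.radius**2 for n in truth.nuclei)
        meas_areas = sorted(r.area for r in records)
        np.testing.assert_allclose(meas_areas, true_areas, rtol=0.05)

    def test_invalid_image_shape_rejected(self, default_params):
        with pytest.raises(ValueError):
            imaging.segment_nuclei(np.zeros((4, 4, 4)), default_params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            imaging.SegmentationParams(min_area=10, max_area=5)
        with pytest.raises(ValueError):
            imaging.SegmentationParams(threshold_method="fixed")


class TestViability:
    def test_fixture_viability_recovered(self, fixture_image, default_params):
        img, truth = fixture_image
        records, labels = imaging.segment_nuclei(img[0], default_params, return_labels=True)
        records = imaging.classify_viability(records, labels, img[1], img[2], default_params)
        n_dead = sum(r.viability == "dead" for r in records)
        n_live = sum(r.viability == "live" for r in records)
        assert (n_live, n_dead) == (truth.n_live, truth.n_dead)

    def test_zero_ethidium_means_all_live(self, fixture_image, default_params):
        img, _ = fixture_image
        records, labels = imaging.segment_nuclei(img[0], default_params, return_labels=True)
        zero = np.zeros_like(img[2])
        records = imaging.classify_viability(records, labels, img[1], zero, default_params)
        assert all(r.viability == "live" for r in records)

    def test_channel_shape_mismatch_rejected(self, fixture_image, default_params):
        img, _ = fixture_image
        records, labels = imaging.segment_nuclei(img[0], default_params, return_labels=True)
        with pytest.raises(ValueError):
            imaging.classify_viability(records, labels, img[1][:100], img[2], default_params)


class TestPgccCalling:
    def test_threshold_is_multiplier_times_median(self):
        assert imaging.calibrate_pgcc_threshold([100.0] * 25, 2.0) == 200.0
        with pytest.warns(UserWarning):
            assert imaging.calibrate_pgcc_threshold([80.0, 100.0, 120.0], 2.0) == 200.0

    def test_threshold_input_validation(self):
        with pytest.raises(ValueError):
            imaging.calibrate_pgcc_threshold([])
        with pytest.raises(ValueError):
            imaging.calibrate_pgcc_threshold([100.0] * 30, multiplier=1.0)

    def test_inclusive_boundary_and_dead_exclusion(self):
        def rec(area, viability):
            r = imaging.NucleusRecord(
                label=1, centroid=(0, 0), area=area, mean_hoechst=1.0
            )
            r.viability = viability
            return r

        records = [rec(200.0, "live"), rec(199.9, "live"), rec(400.0, "dead")]
        imaging.classify_pgcc(records, area_threshold=200.0)
        assert records[0].is_pgcc is True  # exactly at threshold -> PGCC
        assert records[1].is_pgcc is False
        assert records[2].is_pgcc is None  # dead never tallied as PGCC

    def test_requires_viability_and_positive_threshold(self):
        r = imaging.NucleusRecord(label=1, centroid=(0, 0), area=5.0, mean_hoechst=1.0)
        with pytest.raises(ValueError):
            imaging.classify_pgcc([r], area_threshold=0.0)
        with pytest.raises(ValueError):
            imaging.classify_pgcc([r], area_threshold=100.0)

    def test_monotonicity_in_threshold(self, fixture_image, default_params):
        """Raising the area threshold never increases the PGCC count."""
        img, _ = fixture_image
        prev = np.inf
        for thresh in [50, 150, 250, 350, 600, 1200]:
            params = imaging.SegmentationParams(
                pgcc_area_threshold=thresh,
                dead_intensity_threshold=default_params.dead_intensity_threshold,
                min_area=default_params.min_area,
                max_area=default_params.max_area,
            )
            counts = imaging.quantify_well(img, params)
            assert counts.n_pgcc <= prev
            prev = counts.n_pgcc


class TestQuantifyWell:
    def test_fixture_round_trip(self, fixture_image, default_params):
        img, _ = fixture_image
        counts = imaging.quantify_well(img, default_params, well_id="A01")
        assert counts == imaging.WellCounts("A01", n_live=15, n_dead=2, n_pgcc=3, n_nonpgcc=12)

    def test_balanced_pgcc_fixture_round_trip(self, default_params):
        img, _ = fx.generate_plate_image(5, 5, 0, seed=3)
        counts = imaging.quantify_well(img, default_params)
        assert (counts.n_pgcc, counts.n_nonpgcc, counts.n_dead) == (5, 5, 0)

    def test_empty_fixture_all_zero(self, default_params):
        img, _ = fx.generate_plate_image(0, 0, 0, seed=1)
        counts = imaging.quantify_well(img, default_params)
        assert (counts.n_live, counts.n_dead, counts.n_pgcc, counts.n_nonpgcc) == (0, 0, 0, 0)

    def test_determinism(self, fixture_image, default_params):
        img, _ = fixture_image
        a = imaging.quantify_well(img, default_params)
        b = imaging.quantify_well(img, default_params)
        assert a == b

    def test_count_conservation(self, default_params):
        """n_live + n_dead equals the number of surviving segmented records."""
        img, _ = fx.generate_plate_image(9, 2, 4, seed=13)
        counts, records = imaging.quantify_well(img, default_params, return_records=True)
        assert counts.n_live + counts.n_dead == len(records)
        assert counts.n_live == counts.n_pgcc + counts.n_nonpgcc

    def test_bad_stack_shape_rejected(self, default_params):
        with pytest.raises(ValueError):
            imaging.quantify_well(np.zeros((2, 64, 64)), default_params)

    def test_wellcounts_invariant_enforced(self):
        with pytest.raises(ValueError):
            imaging.WellCounts("w", n_live=5, n_dead=0, n_pgcc=1, n_nonpgcc=1)
        with pytest.raises(ValueError):
            imaging.WellCounts("w", n_live=-1, n_dead=0, n_pgcc=0, n_nonpgcc=-1)


class TestPseudocolor:
    def test_larger_nucleus_is_redder(self, default_params):
        img, _ = fx.generate_plate_image(1, 1, 0, seed=21)
        records, labels = imaging.segment_nuclei(img[0], default_params, return_labels=True)
        out = imaging.render_size_pseudocolor(records, labels)
        small, large = sorted(records, key=lambda r: r.area)
        small_px = out[labels == small.label][0]
        large_px = out[labels == large.label][0]
        assert large_px[0] > small_px[0]  # red channel
        assert large_px[2] < small_px[2]  # blue channel
        assert np.all(out[labels == 0] == 0)  # black background

    def test_single_nucleus_mid_scale(self, default_params):
        img, _ = fx.generate_plate_image(1, 0, 0, seed=4)
        records, labels = imaging.segment_nuclei(img[0], default_params, return_labels=True)
        out = imaging.render_size_pseudocolor(records, labels)
        px = out[labels == records[0].label][0]
        from matplotlib import colormaps

        np.testing.assert_allclose(px, colormaps["coolwarm"](0.5)[:3])

    def test_zero_nuclei_all_background(self):
        out = imaging.render_size_pseudocolor([], np.zeros((32, 32), dtype=int))
        assert out.shape == (32, 32, 3)
        assert np.all(out == 0)
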