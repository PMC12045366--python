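"""Nucleus segmentation, background subtraction, and positivity calls."""

import numpy as np
import pytest

from sirnakit import imaging_quant as iq
from sirnakit import synthetic_data as syn


def draw_disks(shape, centers, radius, value, background=0.0):
    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for r, c in centers:
        img[(yy - r) ** 2 + (xx - c) ** 2 <= radius ** 2] = value
    return img


class TestSegmentNuclei:
    def test_blank_image(self):
        assert iq.segment_nuclei(np.zeros((64, 64))) == []

    def test_grid_of_disks_counted(self):
        centers = [(r, c) for r in range(20, 200, 20)
                   for c in range(20, 200, 20)]
        img = draw_disks((220, 220), centers, radius=5, value=100.0,
                         background=1.0)
        rois = iq.segment_nuclei(img, method="fixed:50")
        assert len(rois) == len(centers)
        # labels in raster order of first pixel
        assert [r.label for r in rois] == list(range(1, len(centers) + 1))

    def test_otsu_matches_fixed_on_bimodal(self):
        centers = [(30, 30), (30, 70), (70, 30)]
        img = draw_disks((100, 100), centers, radius=6, value=100.0,
                         background=5.0)
        assert len(iq.segment_nuclei(img, method="otsu")) == 3

    def test_touching_disks_merge(self):
        img = draw_disks((60, 60), [(30, 25), (30, 33)], radius=5,
                         value=100.0)
        rois = iq.segment_nuclei(img, method="fixed:50")
        assert len(rois) == 1  # documented limitation: no watershed split

    def test_size_filter(self):
        img = draw_disks((80, 80), [(20, 20)], radius=2, value=100.0)
        img = np.maximum(img, draw_disks((80, 80), [(60, 60)], radius=8,
                                         value=100.0))
        rois = iq.segment_nuclei(img, method="fixed:50", min_area=20,
                                 max_area=250)
        assert len(rois) == 1  # small disk (area ~13) filtered out
        assert 20 <= rois[0].area <= 250


class TestRollingBall:
    def test_constant_image_goes_to_zero(self):
        img = np.full((128, 128), 17.0)
        corrected = iq.rolling_ball_subtract(img, radius=20)
        assert np.allclose(corrected, 0.0)

    def test_small_spot_preserved(self):
        img = np.full((128, 128), 10.0)
        img[60:66, 60:66] += 50.0
        corrected = iq.rolling_ball_subtract(img, radius=25)
        assert corrected[62, 62] == pytest.approx(50.0, abs=1.0)
        assert corrected[10, 10] == pytest.approx(0.0, abs=1.0)

    def test_ramp_background_contrast_improves(self):
        ramp = np.tile(np.linspace(0, 40, 160), (160, 1))
        spots = draw_disks((160, 160), [(80, 40), (80, 120)], radius=3,
                           value=30.0)
        img = ramp + spots
        corrected = iq.rolling_ball_subtract(img, radius=30)
        raw_contrast = img[80, 120] / max(img[80, 100], 1e-9)
        new_contrast = corrected[80, 120] / max(corrected[80, 100], 1e-9)
        assert new_contrast > raw_contrast

    def test_idempotent_on_own_output(self):
        img = np.full((96, 96), 10.0)
        img[40:44, 40:44] += 30.0
        once = iq.rolling_ball_subtract(img, radius=20)
        twice = iq.rolling_ball_subtract(once, radius=20)
        assert np.allclose(once, twice, atol=1e-9)

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            iq.rolling_ball_subtract(np.zeros((10, 10)), radius=0)
        with pytest.raises(ValueError):
            iq.rolling_ball_subtract(np.zeros((10, 10)), radius=11)


class TestNucleusIntensities:
    def test_constant_region(self):
        img = np.full((40, 40), 7.0)
        rois = iq.segment_nuclei(
            draw_disks((40, 40), [(20, 20)], radius=5, value=100.0),
            method="fixed:50",
        )
        table = iq.nucleus_intensities(rois, img)
        assert table["mean_intensity"].iloc[0] == pytest.approx(7.0)
        assert table["median_intensity"].iloc[0] == pytest.approx(7.0)

    def test_checkerboard_mean(self):
        marker = np.indices((40, 40)).sum(axis=0) % 2 * 10.0
        dapi = np.zeros((40, 40))
        dapi[10:20, 10:20] = 100.0  # 10x10 square ROI: 50 zeros, 50 tens
        rois = iq.segment_nuclei(dapi, method="fixed:50")
        table = iq.nucleus_intensities(rois, marker)
        assert table["mean_intensity"].iloc[0] == pytest.approx(5.0)

    def test_matches_per_pixel_loop_oracle(self, rng):
        dapi = draw_disks((80, 80), [(20, 20), (60, 30), (40, 65)],
                          radius=5, value=100.0)
        marker = rng.uniform(0, 50, (80, 80))
        rois = iq.segment_nuclei(dapi, method="fixed:50")
        table = iq.nucleus_intensities(rois, marker)
        for roi, row in zip(rois, table.itertuples()):
            pixels = [marker[r, c] for r, c in zip(roi.rows, roi.cols)]
            assert row.mean_intensity == pytest.approx(sum(pixels) / len(pixels))
            assert row.median_intensity == pytest.approx(np.median(pixels))

    def test_empty_roi_errors(self):
        roi = iq.NucleusROI(label=1, rows=np.array([], dtype=int),
                            cols=np.array([], dtype=int), area=0,
                            centroid=(0.0, 0.0))
        with pytest.raises(ValueError, match="empty"):
            iq.nucleus_intensities([roi], np.zeros((10, 10)))


class TestClassifyPositive:
    def test_bimodal_otsu(self, rng):
        means = np.concatenate([
            np.full(40, 10.0) + rng.normal(0, 1, 40),
            np.full(20, 100.0) + rng.normal(0, 5, 20),
        ])
        positive = iq.classify_positive(means)
        assert positive[40:].all()
        assert not positive[:40].any()

    def test_fixed_above_all(self):
        assert not iq.classify_positive([1.0, 2.0, 3.0], "fixed:10").any()

    def test_fixed_zero_all_positive(self):
        assert iq.classify_positive([1.0, 2.0, 3.0], "fixed:0").all()

    def test_fixed_without_value_errors(self):
        with pytest.raises(ValueError):
            iq.classify_positive([1.0], "fixed")


class TestQuantifyRegions:
    def _image_with_masks(self, shape=(60, 60)):
        masks = {
            "left": np.zeros(shape, dtype=bool),
            "right": np.zeros(shape, dtype=bool),
        }
        masks["left"][:, :30] = True
        masks["right"][:, 30:] = True
        return iq.TwoChannelImage(
            dapi=np.zeros(shape), marker=np.zeros(shape), region_masks=masks
        )

    def _rois_at(self, centers):
        return [
            iq.NucleusROI(label=i + 1, rows=np.array([int(r)]),
                          cols=np.array([int(c)]), area=1,
                          centroid=(float(r), float(c)))
            for i, (r, c) in enumerate(centers)
        ]

    def test_counts_and_percent(self):
        image = self._image_with_masks()
        rois = self._rois_at([(10, 10), (20, 10), (30, 40), (40, 40)])
        results = iq.quantify_regions(image, rois, [True, False, True, True])
        by_region = {r.region: r for r in results}
        assert by_region["left"].n_nuclei == 2
        assert by_region["left"].percent_positive == pytest.approx(50.0)
        assert by_region["right"].percent_positive == pytest.approx(100.0)

    def test_empty_region_percent_is_null(self):
        image = self._image_with_masks()
        rois = self._rois_at([(10, 10)])
        results = iq.quantify_regions(image, rois, [True])
        by_region = {r.region: r for r in results}
        assert by_region["right"].n_nuclei == 0
        assert by_region["right"].percent_positive is None

    def test_overlapping_masks_error(self):
        image = self._image_with_masks()
        image.region_masks["right"][:, 29] = True  # overlap with left
        with pytest.raises(ValueError, match="overlap"):
            iq.quantify_regions(image, self._rois_at([(5, 5)]), [True])

    def test_no_masks_whole_image(self):
        image = iq.TwoChannelImage(dapi=np.zeros((20, 20)),
                                   marker=np.zeros((20, 20)))
        results = iq.quantify_regions(image, self._rois_at([(5, 5)]), [False])
        assert [r.region for r in results] == ["whole_image"]


class TestEndToEnd:
    def test_translation_invariance(self):
        params = syn.SlideParams(
            shape=(256, 256), n_nuclei_per_region=25,
            positive_fractions={"whole": 0.4},
        )
        image, _ = syn.render_slide(params, seed=3)
        pad = ((7, 0), (11, 0))  # shift by padding: nothing wraps or clips
        shifted = iq.TwoChannelImage(
            dapi=np.pad(image.dapi, pad, mode="edge"),
            marker=np.pad(image.marker, pad, mode="edge"),
        )
        base = iq.TwoChannelImage(dapi=image.dapi, marker=image.marker)
        res_a, _ = iq.quantify_image(base, rolling_ball_radius=25)
        res_b, _ = iq.quantify_image(shifted, rolling_ball_radius=25)
        assert res_a[0].n_nuclei == res_b[0].n_nuclei
        assert res_a[0].n_positive == res_b[0].n_positive

    def test_recovers_planted_fractions_small_slide(self):
        params = syn.SlideParams(shape=(512, 512), n_nuclei_per_region=150)
        image, truth = syn.render_slide(params, seed=9)
        results, provenance = iq.quantify_image(image)
        assert provenance["rolling_ball_radius"] == 50
        for r in results:
            planted = truth[truth.region == r.region]["positive"].mean() * 100
            assert abs(r.percent_positive - planted) <= 3.0
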