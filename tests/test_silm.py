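import numpy as np
import pytest

from ibt.metrics import profile_maxima, ssim
from ibt.silm import (detect_and_localize, localization_precision,
                      localize_stack, render_silm, upsample)
from ibt.simulate import (NoiseModel, PSFModel, nanotag_fixture,
                          nanotag_pair_fixture, simulate_stack,
                          six_point_geometry)
from ibt.stack import AcquisitionGeometry, IonStack

PSF120 = PSFModel(lateral_fwhm_nm=120.0)


def upsampled_geom(n=192, px_nm=50.0 / 3):
    area = n * px_nm / 1000.0
    return AcquisitionGeometry(area, area, n, n, beam_width_nm=120.0)


class TestUpsample:
    def test_constant_stays_constant(self, geom_256):
        g = AcquisitionGeometry(1.0, 1.0, 8, 8)
        st = IonStack(np.full((2, 1, 8, 8), 5.0), ["a"], g)
        out = upsample(st, 3)
        assert np.allclose(out.counts, 5.0)

    def test_dimensions_and_pixel_size_scale_by_factor(self):
        g = AcquisitionGeometry(1.0, 1.0, 8, 8)
        st = IonStack(np.zeros((1, 1, 8, 8)), ["a"], g)
        out = upsample(st, 3)
        assert out.counts.shape == (1, 1, 24, 24)
        assert out.geometry.dx_nm == pytest.approx(g.dx_nm / 3)

    def test_checkerboard_center_is_corner_mean(self):
        # hand bilinear evaluation: field center is equidistant from the
        # four pixel centers, so its value is their mean
        g = AcquisitionGeometry(0.1, 0.1, 2, 2)
        board = np.array([[1.0, 2.0], [5.0, 10.0]])
        st = IonStack(board[None, None], ["a"], g)
        out = upsample(st, 2)  # 4x4; inner 2x2 pixels sit symmetric around center
        # output pixel centers at input coords -0.25, 0.25, 0.75, 1.25;
        # value at (0.25, 0.25): bilinear between the four corners
        # direct hand evaluation at (x=0.25, y=0.25):
        hand = (1 - 0.25) * ((1 - 0.25) * 1 + 0.25 * 2) + \
            0.25 * ((1 - 0.25) * 5 + 0.25 * 10)
        assert out.counts[0, 0, 1, 1] == pytest.approx(hand)

    def test_invalid_factor_rejected(self):
        g = AcquisitionGeometry(1.0, 1.0, 4, 4)
        st = IonStack(np.zeros((1, 1, 4, 4)), ["a"], g)
        with pytest.raises(ValueError):
            upsample(st, 0)


class TestDetectAndLocalize:
    def test_all_zero_slice_gives_empty_list(self):
        g = upsampled_geom()
        assert detect_and_localize(np.zeros((192, 192)), g, PSF120) == []

    def test_subpixel_recovery_of_injected_spot(self):
        g = upsampled_geom()
        yy, xx = np.mgrid[0:192, 0:192].astype(float)
        x0, y0 = 90.3, 100.6  # deliberate sub-pixel offsets
        img = 50.0 * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * 3.0 ** 2))
        locs = detect_and_localize(img, g, PSF120)
        assert len(locs) == 1
        loc = locs[0]
        assert loc.x_nm / g.dx_nm - 0.5 == pytest.approx(x0, abs=0.1)
        assert loc.y_nm / g.dy_nm - 0.5 == pytest.approx(y0, abs=0.1)
        assert loc.fit_kind == "gaussian-fit"
        assert loc.precision_nm > 0

    def test_two_well_separated_spots(self):
        g = upsampled_geom()
        yy, xx = np.mgrid[0:192, 0:192].astype(float)
        img = np.zeros((192, 192))
        sep_px = 5 * 120.0 / g.dx_nm  # 5 FWHM
        for cx in (96 - sep_px / 2, 96 + sep_px / 2):
            img += 40.0 * np.exp(-((xx - cx) ** 2 + (yy - 96) ** 2) / (2 * 3 ** 2))
        assert len(detect_and_localize(img, g, PSF120)) == 2


class TestRender:
    def test_total_mass_equals_counts(self):
        g = upsampled_geom()
        from ibt.silm import Localization
        loc = Localization(x_nm=1000.0, y_nm=1500.0, slice_index=0,
                           counts=42.0, precision_nm=10.0,
                           fit_kind="gaussian-fit")
        img = render_silm([loc], g, render_sigma_nm=15.0, window=(0, 0))
        assert img.image.sum() == pytest.approx(42.0, rel=1e-6)
        peak = np.unravel_index(img.image.argmax(), img.image.shape)
        assert peak[1] == pytest.approx(1000.0 / g.dx_nm - 0.5, abs=1)

    def test_order_permutation_invariant(self, rng):
        g = upsampled_geom(96)
        from ibt.silm import Localization
        locs = [Localization(rng.uniform(200, 1300), rng.uniform(200, 1300),
                             int(rng.integers(0, 5)), rng.uniform(1, 50),
                             10.0, "gaussian-fit") for _ in range(20)]
        a = render_silm(locs, g, 15.0, (0, 4)).image
        shuffled = list(locs)
        rng.shuffle(shuffled)
        b = render_silm(shuffled, g, 15.0, (0, 4)).image
        assert np.array_equal(a, b)

    def test_empty_set_renders_zero_image(self):
        g = upsampled_geom(48)
        img = render_silm([], g, 15.0, (0, 10))
        assert np.all(img.image == 0)
        assert img.n_localizations == 0


class TestPairSplitting:
    """A nanotag pair below the beam width merges in the raw sum but
    separates in the SILM render (localizations accumulate at each tag)."""

    @pytest.fixture(scope="class")
    def pair_result(self):
        geom = six_point_geometry(64)
        obj = nanotag_pair_fixture(geom, seed=0)
        st = simulate_stack(obj, PSF120, NoiseModel(seed=0), geom, 80)
        up = upsample(st, 3)
        locs = {c: localize_stack(up, PSF120, channel=c) for c in (0, 1)}
        renders = {c: render_silm(locs[c], up.geometry, 15.0, (0, 79))
                   for c in (0, 1)}
        return geom, st, up, renders

    def test_raw_sum_single_maximum_silm_two(self, pair_result):
        geom, st, up, renders = pair_result
        cy = geom.field_y_nm / 2
        ri = int(cy / geom.dy_nm)
        raw_profile = st.counts[:, 0].sum(axis=0)[ri - 2:ri + 3].sum(axis=0)
        assert len(profile_maxima(raw_profile, 0.5, 1.0)) == 1
        riu = int(cy / up.geometry.dy_nm)
        silm_profile = renders[0].image[riu - 5:riu + 6].sum(axis=0)
        assert len(profile_maxima(silm_profile, 0.5, 1.5)) == 2

    def test_silm_channel_ssim_not_below_raw_per_depth(self, pair_result):
        # raw per-depth channel pairs are noise-dominated and dissimilar;
        # the windowed SILM renders of the two channels must agree at
        # least as well
        _, st, _, renders = pair_result
        raw_per_depth = [ssim(st.counts[z, 0], st.counts[z, 1]).value
                         for z in range(st.n_slices)
                         if st.counts[z].sum() > 0]
        silm_ssim = ssim(renders[0].image, renders[1].image).value
        assert silm_ssim >= np.median(raw_per_depth)


class TestPrecision:
    def test_identical_repeated_spot_has_zero_scatter(self):
        g = upsampled_geom()
        yy, xx = np.mgrid[0:192, 0:192].astype(float)
        img = 50.0 * np.exp(-((xx - 96.0) ** 2 + (yy - 96.0) ** 2) / (2 * 9))
        locs = []
        for z in range(20):
            locs += detect_and_localize(img, g, PSF120, slice_index=z)
        assert len(locs) == 20
        summary = localization_precision(locs, cluster_radius_nm=60.0)
        assert summary["n_clusters"] == 1
        assert summary["median_precision_nm"] <= 0.01 * g.dx_nm

    @pytest.fixture(scope="class")
    def nanotag_precision(self):
        # paper-like regime: sparse tags, < 10 counts/pixel
        g = AcquisitionGeometry(6.4, 6.4, 128, 128, beam_width_nm=120.0)
        obj = nanotag_fixture(g, n_tags=8, seed=5, depth_nm=250.0,
                              min_gap_nm=200.0)
        st = simulate_stack(obj, PSF120, NoiseModel(seed=5), g, 50)
        assert st.counts.max() <= 10.0
        up = upsample(st, 3)
        locs = localize_stack(up, PSF120, channel=0, upsample_factor=3)
        truth = [(s.x_nm, s.y_nm) for s in obj.spheres]
        return localization_precision(locs, cluster_radius_nm=60.0,
                                      ground_truth_nm=truth), locs

    def test_median_cluster_precision_within_25nm(self, nanotag_precision):
        summary, _ = nanotag_precision
        assert summary["n_clusters"] >= 4
        assert summary["median_precision_nm"] <= 25.0

    def test_estimator_within_factor_two_of_empirical(self, nanotag_precision):
        summary, locs = nanotag_precision
        predicted = np.median([l.precision_nm for l in locs])
        empirical = summary["median_precision_nm"]
        assert 0.5 <= predicted / empirical <= 2.0
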