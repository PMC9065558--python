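"""QA metrics: optimal values on the ideal phantom, constructed distortions,
and independence oracles for the geometric estimators."""

import numpy as np
import pytest
from scipy import ndimage

from qmrikit import make_qa_phantom
from qmrikit.phantom_qa import (
    QaLayout,
    QaNominal,
    compute_qa_report,
    measure_contrast_detectability,
    measure_diameter,
    measure_pixel_size,
    measure_slice_geometry,
    measure_spatial_linearity,
    measure_uniformity,
)


@pytest.fixture(scope="module")
def ideal_stack():
    return make_qa_phantom()


@pytest.fixture(scope="module")
def nominal():
    return QaNominal()


def _disk(diameter_mm, pixel_mm=1.02, n=200, value=1.0, stretch_x=1.0):
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    r2 = ((yy - cy) * pixel_mm) ** 2 + ((xx - cx) * pixel_mm / stretch_x) ** 2
    return value * (r2 <= (diameter_mm / 2.0) ** 2)


class TestDiameter:
    def test_ideal_disk_within_one_pixel(self, ideal_stack, nominal):
        d, dist = measure_diameter(ideal_stack.data[0], nominal)
        assert d == pytest.approx(190.0, abs=1.02)
        assert dist < 100 * 1.02 / 190.0

    def test_scaled_disk_reports_one_percent_distortion(self, nominal):
        img = _disk(190.0 * 1.01)
        _, dist = measure_diameter(img, nominal)
        assert dist == pytest.approx(1.0, abs=0.4)

    def test_anisotropic_disk_matches_elliptical_caliper_oracle(self, nominal):
        """Mean caliper of an x-stretched disk equals the analytic mean of
        the ellipse's central chord lengths over the same directions."""
        img = _disk(190.0, stretch_x=1.02)
        d, _ = measure_diameter(img, nominal)
        a, b = 95.0 * 1.02, 95.0  # semi-axes (x, y)
        angles = np.deg2rad(np.arange(0, 180, 5))
        chord = 2 * a * b / np.sqrt((b * np.cos(angles)) ** 2 + (a * np.sin(angles)) ** 2)
        assert d == pytest.approx(chord.mean(), abs=1.02)

    def test_empty_image_rejected(self, nominal):
        with pytest.raises(ValueError):
            measure_diameter(np.zeros((50, 50)), nominal)

    def test_intensity_scaling_invariance(self, ideal_stack, nominal):
        d1, _ = measure_diameter(ideal_stack.data[0], nominal)
        d2, _ = measure_diameter(ideal_stack.data[0] * 7.3, nominal)
        assert d1 == d2


class TestLinearityAndPixelSize:
    def test_ideal_grid_linearity_zero(self, ideal_stack, nominal):
        assert measure_spatial_linearity(ideal_stack.data[1], nominal) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_shrunken_grid_reports_minus_one_percent(self):
        nom = QaNominal(landmark_spacing_mm=20.4)
        render_nom = QaNominal(landmark_spacing_mm=20.4 * 0.99)
        img = make_qa_phantom(render_nom).data[1]
        assert measure_spatial_linearity(img, nom) == pytest.approx(-1.0, abs=0.1)

    def test_jittered_grid_matches_pairwise_distance_oracle(self, nominal):
        """Seeded sub-pixel jitter: the measured linearity must equal the
        value computed directly from the known jittered positions."""
        from qmrikit.synthetic_data import _add_rect

        rng = np.random.default_rng(9)
        layout = QaLayout(nominal)
        base = layout.landmark_positions_mm()
        jitter = rng.uniform(-0.4, 0.4, base.shape)
        pos = base + jitter
        img = _disk(190.0)
        for y, x in pos:
            _add_rect(img, layout, y, x, layout.DOT_SIZE_MM / 2, layout.DOT_SIZE_MM / 2)
        measured = measure_spatial_linearity(img, nominal)

        grid = pos.reshape(5, 5, 2)
        dists = []
        for r in range(5):
            for c in range(5):
                if c + 1 < 5:
                    dists.append(np.hypot(*(grid[r, c + 1] - grid[r, c])))
                if r + 1 < 5:
                    dists.append(np.hypot(*(grid[r + 1, c] - grid[r, c])))
        expected = 100.0 * np.mean((np.array(dists) - 20.4) / 20.4)
        assert measured == pytest.approx(expected, abs=0.05)

    def test_ideal_grid_pixel_size_recovered_exactly(self, ideal_stack, nominal):
        assert measure_pixel_size(ideal_stack.data[1], nominal) == pytest.approx(
            (1.02, 1.02), abs=1e-9
        )

    def test_two_mm_grid(self):
        nom = QaNominal(pixel_size_mm=(2.0, 2.0))
        img = make_qa_phantom(nom).data[1]
        assert measure_pixel_size(img, nom) == pytest.approx((2.0, 2.0), abs=0.02)

    def test_anisotropic_pixels_recovered_per_axis(self):
        nom = QaNominal(pixel_size_mm=(1.0, 1.1))
        img = make_qa_phantom(nom).data[1]
        sx, sy = measure_pixel_size(img, nom)
        assert sx == pytest.approx(1.0, abs=0.01)
        assert sy == pytest.approx(1.1, abs=0.01)

    def test_blank_disk_has_no_landmarks(self, ideal_stack, nominal):
        with pytest.raises(ValueError):
            measure_spatial_linearity(ideal_stack.data[0] * 0 + _disk(190.0), nominal)


class TestSliceGeometry:
    def test_ideal_ramp_recovers_nominal_thickness_and_increment(
        self, ideal_stack, nominal
    ):
        thickness, increment = measure_slice_geometry(ideal_stack, nominal)
        assert thickness == pytest.approx(2.5, abs=0.05)
        assert increment == pytest.approx(2.5, abs=0.05)

    def test_doubled_ramp_tangent_halves_apparent_width(self):
        steep = QaNominal(ramp_angle_deg=np.degrees(np.arctan(2.0)))
        flat = QaNominal(ramp_angle_deg=45.0)
        assert QaLayout(steep).ramp_width_mm == pytest.approx(
            QaLayout(flat).ramp_width_mm / 2.0
        )
        # The measurement compensates up to raster quantization (the steeper
        # bar is narrower than 2 px, so its plateau is never fully sampled).
        t_steep, _ = measure_slice_geometry(make_qa_phantom(steep), steep)
        assert t_steep == pytest.approx(2.5, abs=0.25)

    def test_blurred_ramp_matches_numeric_profile_oracle(self, ideal_stack, nominal):
        """Gaussian-blurred ramp: the width estimate must equal the one
        computed directly from an independently blurred analytic profile."""
        sigma = 0.6  # px; tails stay inside the measurement band
        blurred = np.stack([ndimage.gaussian_filter(s, sigma) for s in ideal_stack.data])
        thickness, _ = measure_slice_geometry(blurred, nominal)

        # Independent profile oracle: pixel-bin coverage of the bar at its
        # true sub-pixel position, blurred identically, width = integral/peak.
        px = 1.02
        layout = QaLayout(nominal)
        shape = ideal_stack.data.shape[1:]
        row_c, _ = layout.mm_to_px(layout.ramp_y_mm, 0.0, shape)
        half_w_px = layout.ramp_width_mm / 2.0 / px
        rows = np.arange(int(row_c) - 15, int(row_c) + 16)
        cov = np.clip(
            np.minimum(row_c + half_w_px, rows + 0.5) - np.maximum(row_c - half_w_px, rows - 0.5),
            0.0,
            1.0,
        )
        smooth = ndimage.gaussian_filter1d(cov, sigma)
        oracle_width = smooth.sum() * px / smooth.max()
        assert thickness == pytest.approx(oracle_width * np.tan(np.deg2rad(45.0)), abs=0.05)

    def test_missing_ramp_raises(self, nominal):
        blank = np.stack([_disk(190.0)] * 3)
        with pytest.raises(ValueError):
            measure_slice_geometry(blank, nominal)


class TestContrastAndNoise:
    def test_fine_render_resolves_highest_group(self):
        nom = QaNominal(pixel_size_mm=(0.25, 0.25))
        stack = make_qa_phantom(nom)
        plcm, snr, noise = measure_contrast_detectability(stack.data[2], nom)
        assert plcm == 10.0
        assert noise == 0.0

    def test_lowpass_filtered_pattern_drops_high_groups(self):
        nom = QaNominal(pixel_size_mm=(0.25, 0.25))
        img = make_qa_phantom(nom).data[2]
        sigma_mm = 0.65  # suppresses the 7+ pl/cm groups
        blurred = ndimage.gaussian_filter(img, sigma_mm / 0.25)
        plcm, _, _ = measure_contrast_detectability(blurred, nom)
        assert plcm <= 7.0

    def test_rician_noise_snr_matches_monte_carlo_oracle(self, nominal):
        rng = np.random.default_rng(31)
        sigma = 0.05
        img = make_qa_phantom(nominal).data[2]
        noisy = np.hypot(img + rng.normal(0, sigma, img.shape), rng.normal(0, sigma, img.shape))
        _, snr, noise = measure_contrast_detectability(noisy, nominal)
        draws = np.hypot(1.0 + rng.normal(0, sigma, 200_000), rng.normal(0, sigma, 200_000))
        expected = draws.mean() / draws.std(ddof=1)
        assert snr == pytest.approx(expected, rel=0.1)
        assert noise == pytest.approx(100.0 / expected, rel=0.1)


class TestUniformity:
    def test_constant_disk_is_perfectly_uniform(self, ideal_stack, nominal):
        assert measure_uniformity(ideal_stack.data[0], nominal) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_formula_on_constructed_extremes(self, nominal):
        img = _disk(190.0, value=100.0)
        # 5x5 blocks survive the 3x3 smoothing with their plateau intact.
        img[95:100, 80:85] = 110.0
        img[95:100, 110:115] = 90.0
        assert measure_uniformity(img, nominal) == pytest.approx(90.0, abs=1e-9)

    def test_bias_field_matches_formula_oracle(self, nominal):
        from qmrikit.synthetic_data import smooth_bias_field

        img = _disk(190.0) * smooth_bias_field((200, 200), amplitude=0.08, seed=4)
        measured = measure_uniformity(img, nominal)

        smoothed = ndimage.uniform_filter(img, size=3)
        layout = QaLayout(nominal)
        yy, xx = np.mgrid[0:200, 0:200]
        r2 = ((yy - 99.5) * 1.02) ** 2 + ((xx - 99.5) * 1.02) ** 2
        roi = r2 <= 0.75 * layout.radius_mm**2
        smax, smin = smoothed[roi].max(), smoothed[roi].min()
        assert measured == pytest.approx(100 * (1 - (smax - smin) / (smax + smin)), abs=1e-9)

    def test_positive_scaling_invariance(self, ideal_stack, nominal):
        u1 = measure_uniformity(ideal_stack.data[0], nominal)
        u2 = measure_uniformity(ideal_stack.data[0] * 3.7, nominal)
        assert u1 == pytest.approx(u2, abs=1e-12)

    def test_roi_exceeding_phantom_rejected(self, nominal):
        small = _disk(120.0)
        with pytest.raises(ValueError, match="beyond"):
            measure_uniformity(small, nominal)


def test_full_report_on_ideal_phantom(ideal_stack, nominal):
    rep = compute_qa_report(ideal_stack, nominal)
    assert rep.mean_diameter_mm == pytest.approx(190.0, abs=1.02)
    assert rep.spatial_linearity_percent == pytest.approx(0.0, abs=1e-9)
    assert rep.pixel_size_mm == pytest.approx((1.02, 1.02), abs=1e-9)
    assert rep.slice_thickness_mm == pytest.approx(2.5, abs=0.05)
    assert rep.slice_increment_mm == pytest.approx(2.5, abs=0.05)
    assert rep.uniformity_percent == pytest.approx(100.0, abs=1e-9)
    assert rep.noise_percent == 0.0
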