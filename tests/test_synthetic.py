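"""Phantom generator: determinism, cohort statistics, margin-localized signal."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from margincnn import (
    ADENOMA,
    CARCINOMA,
    SyntheticConfig,
    extract_test_patches,
    generate_case,
    generate_cohort,
    rim_roughness,
    with_interior_contours,
)
from margincnn.synthetic import ConfigurationError


class TestGenerateCase:
    def test_fixed_seed_bit_determinism(self, small_config):
        a = generate_case(ADENOMA, "A", small_config, seed=11)
        b = generate_case(ADENOMA, "A", small_config, seed=11)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.contour, b.contour)
        c = generate_case(ADENOMA, "A", small_config, seed=12)
        assert not np.array_equal(a.image, c.image)

    def test_image_is_valid_case(self, small_config):
        case = generate_case(CARCINOMA, "B", small_config, seed=3).validate()
        assert case.image.dtype == np.uint8
        assert case.image.shape == (170, 170)
        # contour closed and 8-connected is enforced by densify; all inside
        assert case.contour.min() >= 0
        assert case.contour.max() < 170

    def test_cohort_mean_intensity_targets(self, default_config):
        means_a = [
            generate_case(ADENOMA, "A", default_config, seed=s).image.mean()
            for s in range(30)
        ]
        assert abs(np.mean(means_a) - 63.819) < 5.0
        means_b = [
            generate_case(ADENOMA, "B", default_config, seed=s).image.mean()
            for s in range(10)
        ]
        assert np.mean(means_b) > np.mean(means_a) + 10

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(image_size=150).validate()  # nodule + patch too big
        with pytest.raises(ConfigurationError):
            SyntheticConfig(interior_mean=300.0).validate()
        with pytest.raises(ConfigurationError):
            SyntheticConfig(speckle_shape=0.0).validate()
        with pytest.raises(ConfigurationError):
            generate_case(ADENOMA, "Z", SyntheticConfig(), seed=0)
        with pytest.raises(ValueError):
            generate_case("papillary", "A", SyntheticConfig(), seed=0)


class TestGenerateCohort:
    def test_empty(self, small_config):
        assert generate_cohort(0, 0, "A", small_config, seed=1) == []

    def test_counts_and_label_proportion(self, small_config):
        cases = generate_cohort(5, 3, "A", small_config, seed=7)
        assert len(cases) == 8
        assert sum(c.label == ADENOMA for c in cases) == 5
        assert sum(c.label == CARCINOMA for c in cases) == 3
        assert len({c.case_id for c in cases}) == 8

    def test_master_seed_changes_output(self, small_config):
        a = generate_cohort(2, 0, "A", small_config, seed=1)
        b = generate_cohort(2, 0, "A", small_config, seed=2)
        assert any(not np.array_equal(x.image, y.image) for x, y in zip(a, b))

    def test_deterministic(self, small_config):
        a = generate_cohort(2, 2, "A", small_config, seed=5)
        b = generate_cohort(2, 2, "A", small_config, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)
            assert np.array_equal(x.contour, y.contour)


class TestRimRoughness:
    def test_circle_is_smooth(self):
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts = np.column_stack([100 + 60 * np.sin(theta), 100 + 60 * np.cos(theta)])
        assert rim_roughness(np.rint(pts)) < 0.02

    def test_ellipse_matches_closed_form(self):
        # centroid-distance profile of a 2:1 ellipse sampled at uniform angles
        a, b = 80.0, 40.0
        theta = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        expected = r.std() / r.mean()
        pts = np.column_stack([r * np.sin(theta), r * np.cos(theta)])
        assert rim_roughness(pts) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("freq", [5, 8])
    def test_star_amplitude_monotonic(self, freq):
        theta = np.linspace(0, 2 * np.pi, 1440, endpoint=False)
        values = []
        for amp in (0.0, 0.05, 0.1, 0.2):
            r = 70.0 * (1 + amp * np.sin(freq * theta))
            pts = np.column_stack([r * np.sin(theta), r * np.cos(theta)])
            values.append(rim_roughness(pts))
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            rim_roughness(np.zeros((10, 2)))  # too few points
        with pytest.raises(ValueError):
            rim_roughness(np.zeros((20, 2)))  # zero mean radius

    def test_class_separation(self, default_config):
        ra = [
            rim_roughness(generate_case(ADENOMA, "A", default_config, seed=s).contour)
            for s in range(50)
        ]
        rc = [
            rim_roughness(generate_case(CARCINOMA, "A", default_config, seed=1000 + s).contour)
            for s in range(50)
        ]
        p = mannwhitneyu(ra, rc, alternative="less").pvalue
        assert p < 0.01


class TestSignalLocality:
    def test_margin_signal_dwarfs_interior_signal(self, default_config):
        """Class-conditional mean-intensity contrast lives in the margin band."""
        margin_means = {ADENOMA: [], CARCINOMA: []}
        interior_means = {ADENOMA: [], CARCINOMA: []}
        for label in (ADENOMA, CARCINOMA):
            for s in range(50):
                case = generate_case(label, "A", default_config, seed=5000 + s)
                patches, _ = extract_test_patches(case, 50)
                margin_means[label].append(
                    np.mean([p.pixels.mean() for p in patches])
                )
                (inner,) = with_interior_contours([case])
                ipatches, _ = extract_test_patches(inner, 50)
                interior_means[label].append(
                    np.mean([p.pixels.mean() for p in ipatches])
                )
        margin_diff = abs(
            np.mean(margin_means[ADENOMA]) - np.mean(margin_means[CARCINOMA])
        )
        interior_diff = abs(
            np.mean(interior_means[ADENOMA]) - np.mean(interior_means[CARCINOMA])
        )
        assert margin_diff >= 4 * interior_diff
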