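"""Generator statistics, determinism and layout guarantees."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from focicount.config import ConfigError, GeneratorConfig
from focicount.fixtures import (generate_sample, render_pattern_cell,
                                sample_ground_truth, truth_to_frame)
from conftest import small_config


class TestGroundTruthStatistics:
    def test_control_focus_rate_matches_poisson_mean(self):
        """Mean focus count at 0 Gy converges to the 1.12 foci/cell control rate."""
        cfg = GeneratorConfig(doses_Gy=(0.0,), cells_per_dose=10000,
                              control_mean_foci=1.12, foci_per_Gy=0.0,
                              s_fraction=0.0, m_fraction=0.0,
                              g2_foci_multiplier=1.0, seed=5)
        truth = sample_ground_truth(cfg, 0.0)
        counts = np.array([t.true_focus_count for t in truth], dtype=float)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 1.12) < 3 * se

    @pytest.mark.parametrize("dose,rate", [(0.0, 1.12), (0.5, 4.75), (1.0, 8.38)])
    def test_dose_law_rate(self, dose, rate):
        cfg = GeneratorConfig(doses_Gy=(0.0, 0.5, 1.0), cells_per_dose=8000,
                              s_fraction=0.0, m_fraction=0.0,
                              g2_foci_multiplier=1.0, seed=6)
        counts = np.array([t.true_focus_count
                           for t in sample_ground_truth(cfg, dose)], dtype=float)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - rate) < 3 * se

    def test_mean_foci_strictly_increases_with_dose(self):
        cfg = GeneratorConfig(doses_Gy=(0.0, 0.5, 1.0), cells_per_dose=4000, seed=8)
        means = []
        for d in cfg.doses_Gy:
            tf = truth_to_frame(sample_ground_truth(cfg, d))
            inter = tf[tf.true_phase.isin(["G1", "G2"])]
            means.append(inter.true_focus_count.mean())
        assert means[0] < means[1] < means[2]

    def test_pericentrin_area_copula_correlation(self):
        cfg = GeneratorConfig(doses_Gy=(0.0,), cells_per_dose=1000,
                              s_fraction=0.0, m_fraction=0.0,
                              g2_two_pericentrin_prob=0.0,
                              pericentrin_area_correlation=0.4942, seed=9)
        tf = truth_to_frame(sample_ground_truth(cfg, 0.0))
        r, _ = spearmanr(tf.true_area_points, tf.true_pericentrin_intensity)
        assert abs(r - 0.4942) < 0.05

    def test_g2_background_multiplier_orders_phase_means(self):
        cfg = GeneratorConfig(doses_Gy=(0.0,), cells_per_dose=8000,
                              s_fraction=0.0, m_fraction=0.0, g2_fraction=0.4,
                              seed=10)
        tf = truth_to_frame(sample_ground_truth(cfg, 0.0))
        g1 = tf[tf.true_phase == "G1"].true_focus_count.mean()
        g2 = tf[tf.true_phase == "G2"].true_focus_count.mean()
        assert g2 > 1.5 * g1

    def test_areas_respect_phase_ranges(self):
        cfg = small_config(cells_per_dose=300)
        tf = truth_to_frame(sample_ground_truth(cfg, 0.0))
        for phase, (lo, hi) in [("G1", cfg.g1_area_range_points),
                                ("G2", cfg.g2_area_range_points)]:
            sub = tf[tf.true_phase == phase]
            assert ((sub.true_area_points >= lo) & (sub.true_area_points <= hi)).all()
        two = tf[tf.true_pericentrin_count == 2]
        assert set(two.true_phase) <= {"G2", "M"}


class TestGenerateSample:
    def test_deterministic_given_seed(self):
        cfg = small_config(cells_per_dose=10)
        f1, t1 = generate_sample(cfg, 0.5)
        f2, t2 = generate_sample(cfg, 0.5)
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.pixels, b.pixels)
        assert t1 == t2

    def test_zero_cells_gives_empty_sample(self):
        cfg = small_config(cells_per_dose=0)
        fields, truth = generate_sample(cfg, 0.0)
        assert fields == [] and truth == []

    def test_unknown_dose_rejected(self):
        with pytest.raises(ConfigError):
            generate_sample(small_config(), 0.123)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(control_mean_foci=-1.0)
        with pytest.raises(ConfigError):
            GeneratorConfig(foci_per_Gy=float("nan"))
        with pytest.raises(ConfigError):
            generate_sample(small_config(), 0.0, mean_foci=-2.0)

    def test_nuclei_disjoint_in_default_layout(self):
        sample = small_config(cells_per_dose=40, seed=3)
        fields, truth = generate_sample(sample, 0.0)
        tf = truth_to_frame(truth)
        for fid, grp in tf.groupby("field_id"):
            xy = grp[["x", "y"]].to_numpy()
            radii = np.sqrt(grp.true_area_points.to_numpy()
                            / sample.points_scale / np.pi)
            for i in range(len(xy)):
                for j in range(i + 1, len(xy)):
                    d = np.linalg.norm(xy[i] - xy[j])
                    assert d > radii[i] + radii[j]

    def test_touching_mode_places_overlapping_pairs(self):
        cfg = small_config(cells_per_dose=40, touching_fraction=0.5, seed=3)
        fields, truth = generate_sample(cfg, 0.0)
        tf = truth_to_frame(truth)
        n_touch = 0
        for _, grp in tf.groupby("field_id"):
            xy = grp[["x", "y"]].to_numpy()
            # circle-equivalent radius is a lower bound on the ellipse extent
            radii = np.sqrt(grp.true_area_points.to_numpy()
                            / cfg.points_scale / np.pi)
            for i in range(len(xy)):
                for j in range(i + 1, len(xy)):
                    if np.linalg.norm(xy[i] - xy[j]) < 1.2 * (radii[i] + radii[j]):
                        n_touch += 1
        assert n_touch >= 5


class TestPatternRendering:
    def test_m_pattern_truth_has_two_pericentrin(self):
        # two pericentrin spots are a structural invariant of the M phase
        cfg = small_config()
        field = render_pattern_cell("M", cfg)
        peri = field.max_projection("pericentrin").astype(float)
        bg = np.median(peri)
        from scipy import ndimage
        _, n = ndimage.label(peri - bg > 150.0)
        assert n == 2

    def test_s_pattern_covers_most_of_nucleus(self):
        """Pixel-count oracle: supra-threshold coverage of the S pattern > 0.6."""
        cfg = small_config()
        field = render_pattern_cell("S", cfg)
        dapi = field.max_projection("DAPI").astype(float)
        from skimage.filters import threshold_otsu
        mask = dapi > threshold_otsu(dapi)
        g = field.max_projection("gH2AX").astype(float)
        g = g - np.median(g)
        coverage = (g[mask] > 250.0).mean()
        assert coverage > 0.6

    def test_pattern_rendering_deterministic(self):
        cfg = small_config(noise_sd=0.0)
        a = render_pattern_cell("S", cfg, seed=2)
        b = render_pattern_cell("S", cfg, seed=2)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_rejects_non_pattern_phase(self):
        with pytest.raises(ValueError):
            render_pattern_cell("G1", small_config())
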