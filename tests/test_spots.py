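"""Spot detection, cross-plane merging and footprint-merge behavior."""

import numpy as np
import pytest
from scipy import ndimage

from focicount.config import CaptureSettings, GeneratorConfig
from focicount.fixtures import (_plan_cells, generate_sample,
                                match_nuclei_to_truth, render_field)
from focicount.nuclei import segment_nuclei
from focicount.spots import (FocusRecord, brightest_focus_intensity,
                             detect_spots, max_diameter_filter)


def one_nucleus_field(foci_offsets, seed=5, noise_sd=0.0, amp=900.0):
    """A single centered G1 nucleus with foci at explicit xy offsets."""
    cfg = GeneratorConfig(doses_Gy=(0.0,), cells_per_dose=1, seed=seed,
                          width_px=360, height_px=360, noise_sd=noise_sd,
                          s_fraction=0.0, m_fraction=0.0, g2_fraction=0.0)
    rng = np.random.default_rng(seed)
    (cell,) = _plan_cells(cfg, 0.0, rng, 1, 0.0)
    cell.cx = cell.cy = 180.0
    offs = np.asarray(foci_offsets, dtype=float)
    if offs.size:
        z_mid = 0.5 * (cfg.z_planes - 1) * cfg.z_step_um
        cell.foci_xyz = np.column_stack([offs, np.full(len(offs), z_mid)])
        cell.foci_amp = np.full(len(offs), amp)
    field = render_field([cell], cfg, rng, "one")
    return field, cfg


def detect_on(field, settings):
    nuclei, labels = segment_nuclei(field, settings)
    return nuclei, detect_spots(field, nuclei, "gH2AX", settings, labels=labels)


class TestDetectSpots:
    def test_single_focus_detected_at_truth_position(self, settings):
        field, _ = one_nucleus_field([(0.0, 0.0)])
        nuclei, recs = detect_on(field, settings)
        assert len(recs) == 1
        cx, cy = nuclei[0].centroid
        assert recs[0].centroid[0] == pytest.approx(cx, abs=1.0)
        assert recs[0].centroid[1] == pytest.approx(cy, abs=1.0)

    def test_two_close_foci_merge_into_one(self, settings):
        """Footprints merging at threshold count once (connected-components oracle)."""
        field, _ = one_nucleus_field([(-2.0, 0.0), (2.0, 0.0)])
        nuclei, recs = detect_on(field, settings)
        proj = field.max_projection("gH2AX").astype(float)
        fg = proj - np.median(proj) > settings.gH2AX_threshold
        _, n_cc = ndimage.label(fg)
        assert n_cc == 1
        assert len(recs) == 1

    def test_blank_channel_yields_no_spots(self, settings):
        field, _ = one_nucleus_field([])
        nuclei, labels = segment_nuclei(field, settings)
        assert detect_spots(field, nuclei, "gH2AX", settings, labels=labels) == []

    def test_unknown_channel_rejected(self, settings):
        field, _ = one_nucleus_field([])
        with pytest.raises(ValueError):
            detect_spots(field, [], "CENPF", settings)

    def test_focus_spanning_planes_counted_once(self, settings):
        # axial sigma 1.7 um vs plane step 2.1 um: every focus hits >= 2 planes
        field, _ = one_nucleus_field([(0.0, 0.0)])
        nuclei, labels = segment_nuclei(field, settings)
        per_plane_total = 0
        from focicount.spots import _detect_plane
        for z in range(field.z_planes):
            per_plane_total += len(_detect_plane(field.channel("gH2AX")[z],
                                                 settings.gH2AX_threshold, settings))
        recs = detect_spots(field, nuclei, "gH2AX", settings, labels=labels)
        assert per_plane_total >= 2
        assert len(recs) == 1

    def test_merge_switch_matches_footprint_oracle(self, settings):
        """Two foci merge to one by the time their footprints touch.

        At every separation the detected count equals the
        connected-components-at-threshold oracle, the count transition is
        monotone (2 -> 1 as the spots approach), and at the sum of the
        isolated footprint radii they are already scored as one.
        """
        isolated, _ = one_nucleus_field([(-20.0, 0.0), (20.0, 0.0)])
        _, far = detect_on(isolated, settings)
        assert len(far) == 2
        radius_sum = sum(r.diameter_px for r in far) / 2.0
        counts = []
        for sep in np.arange(16.0, 3.0, -1.0):
            field, _ = one_nucleus_field([(-sep / 2, 0.0), (sep / 2, 0.0)])
            _, recs = detect_on(field, settings)
            proj = field.max_projection("gH2AX").astype(float)
            fg = proj - np.median(proj) > settings.gH2AX_threshold
            _, n_cc = ndimage.label(fg)
            assert len(recs) == n_cc
            counts.append((sep, len(recs)))
        assert counts[0][1] == 2 and counts[-1][1] == 1
        vals = [c for _, c in counts]
        assert all(a >= b for a, b in zip(vals, vals[1:]))   # monotone 2 -> 1
        assert all(c == 1 for s, c in counts if s <= radius_sum)

    def test_counts_equal_truth_on_noise_free_sample(self, noise_free_sample, settings):
        truth = noise_free_sample["truth"]
        for field in noise_free_sample["fields"]:
            nuclei, labels = segment_nuclei(field, settings)
            interior = [n for n in nuclei if not n.boundary_touching]
            recs = detect_spots(field, interior, "gH2AX", settings, labels=labels)
            per_nucleus = {}
            for r in recs:
                per_nucleus[r.nucleus_id] = per_nucleus.get(r.nucleus_id, 0) + 1
            idx = match_nuclei_to_truth(
                np.array([n.centroid for n in interior]), truth)
            for n, i in zip(interior, idx):
                assert per_nucleus.get(n.nucleus_id, 0) == truth[i].true_focus_count

    def test_intensity_min_le_max_for_all_records(self, clean_sample, settings):
        for field in clean_sample["fields"]:
            nuclei, labels = segment_nuclei(field, settings)
            for ch in ("gH2AX", "pericentrin"):
                for r in detect_spots(field, nuclei, ch, settings, labels=labels):
                    assert r.intensity_min <= r.intensity_max

    def test_pericentrin_count_recovered(self, clean_sample, settings):
        truth = clean_sample["truth"]
        good = total = 0
        for field in clean_sample["fields"]:
            nuclei, labels = segment_nuclei(field, settings)
            interior = [n for n in nuclei if not n.boundary_touching]
            recs = detect_spots(field, interior, "pericentrin", settings, labels=labels)
            per_nucleus = {}
            for r in recs:
                per_nucleus[r.nucleus_id] = per_nucleus.get(r.nucleus_id, 0) + 1
            idx = match_nuclei_to_truth(
                np.array([n.centroid for n in interior]), truth)
            for n, i in zip(interior, idx):
                total += 1
                good += per_nucleus.get(n.nucleus_id, 0) == truth[i].true_pericentrin_count
        assert good / total >= 0.95


class TestDiameterFilter:
    def rec(self, d):
        return FocusRecord("f", "gH2AX", "n", (0, 0, 0), d, 0.0, 1.0, 1.0)

    def test_acceptance_table(self, settings):
        assert max_diameter_filter(self.rec(5.0), settings, 2.0)          # 5 <= 5.6
        assert not max_diameter_filter(self.rec(5.7), settings, 2.0)
        s100 = CaptureSettings(spot_diameter_pct=100.0)
        assert max_diameter_filter(self.rec(2.0), s100, 2.0)              # inclusive

    def test_invalid_reference_rejected(self, settings):
        with pytest.raises(ValueError):
            max_diameter_filter(self.rec(5.0), settings, 0.0)


class TestBrightestFocus:
    def test_max_and_empty(self):
        recs = [FocusRecord(f"f{i}", "gH2AX", "n", (0, 0, 0), 3.0, 0.0, v, v)
                for i, v in enumerate((10.0, 40.0, 25.0))]
        assert brightest_focus_intensity(recs) == 40.0
        assert brightest_focus_intensity([]) == 0.0

    def test_per_dose_mean_brightest_increases_with_dose(self, settings, gates):
        from focicount.pipeline import score_sample
        cfg = GeneratorConfig(doses_Gy=(0.0, 1.0), cells_per_dose=40, seed=31,
                              width_px=760, height_px=760,
                              s_fraction=0.0, m_fraction=0.0)
        means = []
        for d in (0.0, 1.0):
            fields, _ = generate_sample(cfg, d)
            _, res = score_sample(fields, settings, gates, dose_Gy=d,
                                  minimum_nuclei=1, stratify=False)
            means.append(res.mean_brightest_intensity)
        assert means[1] > means[0]
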