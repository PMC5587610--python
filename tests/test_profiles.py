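"""Curvature flattening, anisotropic smoothing, profile extraction/metrics."""

import copy

import numpy as np
import pytest

import retoxim as rx
from retoxim.oximetry import PO2Map
from retoxim.profiles import (
    DepthProfile,
    extract_profiles,
    flatten_curvature,
    inner_tpo2_trace,
    profile_metrics,
    smooth_anisotropic,
)


class TestSmoothAnisotropic:
    def test_constant_map_unchanged(self):
        v = np.full((30, 20), 7.5)
        out, ok = smooth_anisotropic(v, np.ones_like(v, bool))
        np.testing.assert_allclose(out, 7.5)
        assert ok.all()

    def test_interior_pixel_equals_brute_force_window_mean(self):
        """Window convention: offsets -s//2 .. s-1-s//2 about each pixel."""
        rng = np.random.default_rng(0)
        v = rng.normal(size=(25, 18))
        out, _ = smooth_anisotropic(v, np.ones_like(v, bool), 6, 4)
        for y, z in [(10, 9), (12, 5), (20, 10)]:
            window = v[y - 3 : y + 3, z - 2 : z + 2]
            assert out[y, z] == pytest.approx(window.mean(), rel=1e-12)

    def test_border_windows_truncated_and_renormalized(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(10, 10))
        out, _ = smooth_anisotropic(v, np.ones_like(v, bool), 6, 4)
        assert out[0, 0] == pytest.approx(v[0:3, 0:2].mean(), rel=1e-12)

    def test_isolated_valid_pixel_preserved(self):
        v = np.zeros((9, 9))
        valid = np.zeros((9, 9), bool)
        v[4, 4] = 13.0
        valid[4, 4] = True
        out, ok = smooth_anisotropic(v, valid)
        assert out[4, 4] == pytest.approx(13.0)

    def test_invalid_pixels_do_not_leak_into_mean(self):
        v = np.ones((12, 12))
        v[5, 5] = 1e6  # poisoned but invalid
        valid = np.ones((12, 12), bool)
        valid[5, 5] = False
        out, _ = smooth_anisotropic(v, valid)
        np.testing.assert_allclose(out, 1.0)


class TestFlattenCurvature:
    def test_zero_curvature_shifts_near_zero(self, g2):
        scene = rx.build_scene(curvature_px_per_px2=0.0, noise_sigma=0.0, seed=2)
        tissue, _ = rx.render_phase_stacks(scene)
        pm = rx.po2_map(rx.estimate_lifetime_map(tissue[0]), g2)
        fm = flatten_curvature(pm)
        assert np.abs(fm.shifts[fm.row_valid]).max() < 0.5

    def test_quadratic_interface_recovered(self, scene_clean, tissue_po2_mean):
        """Detected pre-flattening interface within 1 px of ground truth."""
        fm = flatten_curvature(tissue_po2_mean)
        detected = fm.interface_trace + fm.shifts  # undo shift: raw detection
        err = np.abs(detected[fm.row_valid] - scene_clean.interface_trace[fm.row_valid])
        assert err.max() < 1.0
        # inner boundary likewise
        det_inner = fm.inner_boundary_trace + fm.shifts
        err_in = np.abs(det_inner[fm.row_valid] - scene_clean.inner_trace[fm.row_valid])
        assert err_in.max() < 1.0

    def test_interface_variance_small_after_flattening(self, tissue_po2_mean):
        fm = flatten_curvature(tissue_po2_mean)
        assert np.var(fm.interface_trace[fm.row_valid]) <= 1.0

    def test_flattening_is_idempotent(self, tissue_po2_mean):
        """A second pass moves rows by less than half a pixel."""
        fm = flatten_curvature(tissue_po2_mean)
        again = flatten_curvature(fm)
        assert np.abs(again.shifts[again.row_valid]).max() < 0.5

    def test_signal_free_map_rejected(self):
        pm = PO2Map(po2_mmHg=np.full((20, 20), np.nan),
                    valid=np.zeros((20, 20), bool), channel="tissue")
        with pytest.raises(ValueError):
            flatten_curvature(pm)


class TestExtractProfiles:
    def test_350_rows_10px_bins_give_35_profiles(self, tissue_po2_mean):
        fm = flatten_curvature(tissue_po2_mean)
        profs = extract_profiles(fm, bin_px=10)
        assert len(profs) == 35
        assert all(p.usable for p in profs)

    def test_bin_values_equal_brute_force_row_mean(self, tissue_po2_mean):
        fm = flatten_curvature(tissue_po2_mean)
        profs = extract_profiles(fm, bin_px=10)
        b = 17
        r0, r1 = b * 10, (b + 1) * 10
        vals = fm.po2_mmHg[r0:r1]
        mask = fm.valid[r0:r1]
        p = profs[b]
        inner = np.mean(fm.inner_boundary_trace[r0:r1][fm.row_valid[r0:r1]])
        thick = np.mean(fm.interface_trace[r0:r1][fm.row_valid[r0:r1]]) - inner
        for frac, tpo2 in zip(p.fractional_depth, p.tpo2_mmHg):
            z = int(round(frac * thick + inner))
            col_mask = mask[:, z]
            expected = vals[col_mask, z].mean()
            assert tpo2 == pytest.approx(expected, rel=1e-9)

    def test_too_short_image_gives_no_profiles(self, tissue_po2_mean):
        fm = flatten_curvature(tissue_po2_mean)
        short = copy.copy(fm)
        short.po2_mmHg = fm.po2_mmHg[:9]
        short.valid = fm.valid[:9]
        short.row_valid = fm.row_valid[:9]
        short.interface_trace = fm.interface_trace[:9]
        short.inner_boundary_trace = fm.inner_boundary_trace[:9]
        short.shifts = fm.shifts[:9]
        assert extract_profiles(short, bin_px=10) == []

    def test_extracted_shape_matches_truth_profile(self, scene_clean, tissue_po2_mean):
        """Flatten -> extract reproduces the ground-truth depth profile."""
        fm = flatten_curvature(tissue_po2_mean)
        profs = extract_profiles(fm, bin_px=10)
        p = profs[0]  # far from arteries and vein
        row = 5
        truth = np.interp(p.fractional_depth, scene_clean.depth_grid,
                          scene_clean.tissue_po2[row])
        rms = np.sqrt(np.mean((p.tpo2_mmHg - truth) ** 2))
        assert rms < 1.0


class TestMetricsAndTrace:
    def test_constant_profile_metrics(self):
        p = DepthProfile(np.linspace(0, 1, 21), np.full(21, 23.0), 0.0, 230.0)
        m = profile_metrics(p)
        assert (m.max_outer_tpo2, m.min_outer_tpo2, m.mean_inner_tpo2) == (23, 23, 23)

    def test_monotone_profile_max_at_interface(self):
        d = np.linspace(0, 1, 21)
        p = DepthProfile(d, 20 + 30 * d, 0.0, 230.0)
        m = profile_metrics(p)
        assert m.max_outer_tpo2 == pytest.approx(50.0)
        assert m.min_outer_tpo2 == pytest.approx(20 + 30 * 0.5)

    def test_boundary_sample_at_half_depth_is_outer(self):
        d = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        p = DepthProfile(d, np.array([1.0, 2.0, 9.0, 3.0, 4.0]), 0.0, 230.0)
        m = profile_metrics(p)
        assert m.max_outer_tpo2 == pytest.approx(9.0)
        assert m.mean_inner_tpo2 == pytest.approx(1.5)

    def test_simulated_metrics_match_brute_force_truth(self, scene_clean, tissue_po2_mean):
        fm = flatten_curvature(tissue_po2_mean)
        profs = extract_profiles(fm, bin_px=10)
        m = profile_metrics(profs[0])
        field = scene_clean.tissue_po2[5]
        outer = scene_clean.depth_grid >= 0.5
        assert m.max_outer_tpo2 == pytest.approx(field[outer].max(), rel=0.05)
        assert m.mean_inner_tpo2 == pytest.approx(field[~outer].mean(), rel=0.05)

    def test_metrics_invariant_under_vertical_flip(self, tissue_po2_mean):
        fm = flatten_curvature(tissue_po2_mean)
        flipped = copy.copy(fm)
        flipped.po2_mmHg = fm.po2_mmHg[::-1].copy()
        flipped.valid = fm.valid[::-1].copy()
        flipped.row_valid = fm.row_valid[::-1].copy()
        flipped.interface_trace = fm.interface_trace[::-1].copy()
        flipped.inner_boundary_trace = fm.inner_boundary_trace[::-1].copy()
        flipped.shifts = fm.shifts[::-1].copy()
        a = [profile_metrics(p) for p in extract_profiles(fm, 10)]
        b = [profile_metrics(p) for p in extract_profiles(flipped, 10)]
        for ma, mb in zip(a, b[::-1]):
            assert ma.max_outer_tpo2 == pytest.approx(mb.max_outer_tpo2, rel=1e-9)
            assert ma.mean_inner_tpo2 == pytest.approx(mb.mean_inner_tpo2, rel=1e-9)

    def test_inner_trace_peaks_near_artery(self, scene_clean, tissue_po2_mean):
        """The inner tPO2 elevation localizes arteries to within 60 um."""
        fm = flatten_curvature(tissue_po2_mean)
        profs = extract_profiles(fm, bin_px=10)
        trace = inner_tpo2_trace(profs)
        assert trace.shape[0] == sum(p.usable for p in profs)
        artery_y_um = scene_clean.vessels[0].center_y * scene_clean.y_pixel_um
        half = trace[trace[:, 0] < 2 * artery_y_um]  # window around first artery
        peak_y = half[np.argmax(half[:, 1]), 0]
        assert abs(peak_y - artery_y_um) <= 60.0

    def test_uniform_inner_field_gives_constant_trace(self, g2):
        scene = rx.build_scene(artery_elevation_mmHg=0.0, noise_sigma=0.0, seed=3)
        tissue, _ = rx.render_phase_stacks(scene)
        pm = rx.po2_map(rx.estimate_lifetime_map(tissue[0]), g2)
        fm = flatten_curvature(pm)
        trace = inner_tpo2_trace(extract_profiles(fm, 10))
        assert np.ptp(trace[:, 1]) < 0.5
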