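"""HARP module: harmonic isolation, phase tracking, midwall contours."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tagsync as ts
from tagsync.errors import TrackingError, ValidationError
from tagsync.harp import _ray_crossings, isolate_harmonic, track_points, wrap_phase
from tagsync.phantom import (motion_displacement, render_tagged_frame, unit_vector)


class TestWrapPhase:
    @given(st.floats(-20.0, 20.0), st.floats(-20.0, 20.0),
           st.integers(-3, 3), st.integers(-3, 3))
    @settings(max_examples=200, deadline=None)
    def test_wrap_invariant_to_2pi_shifts(self, a, b, ka, kb):
        base = wrap_phase(a - b)
        shifted = wrap_phase((a + 2 * np.pi * ka) - (b + 2 * np.pi * kb))
        # compare on the circle: rounding at the ±π boundary may flip the sign
        assert abs(wrap_phase(base - shifted)) < 1e-6

    @given(st.floats(-50.0, 50.0))
    @settings(max_examples=200, deadline=None)
    def test_range_is_half_open(self, x):
        w = wrap_phase(x)
        assert -np.pi < w <= np.pi


class TestIsolateHarmonic:
    def test_plane_wave_phase_is_linear_ramp(self):
        """A pure cosine tag gives a wrapped ramp of slope 2π/tag_spacing."""
        n, spacing, tag = 96, 1.0, 8.0
        rows = np.arange(n)[:, None] * spacing
        img = 0.5 * (1.0 + np.cos(2 * np.pi * rows / tag)) * np.ones((n, n))
        h = isolate_harmonic(img, (1.0, 0.0), tag, spacing)
        interior = h.phase[20:70, 20:70]
        grad = wrap_phase(np.diff(interior, axis=0))
        assert np.allclose(grad, 2 * np.pi * spacing / tag, atol=0.02)

    def test_phase_difference_tracks_ground_truth_motion(self, quiet_config):
        """Inter-frame phase change equals -2π e·u / tag_spacing on myocardium."""
        cfg = quiet_config
        e = (1.0, 0.0)
        f = 3
        h0 = isolate_harmonic(render_tagged_frame(cfg, 0, e), e, cfg.tag_spacing,
                              cfg.pixel_spacing)
        h1 = isolate_harmonic(render_tagged_frame(cfg, f, e), e, cfg.tag_spacing,
                              cfg.pixel_spacing)
        from tagsync.phantom import position_angle, reference_angle, reference_radius

        coords = np.arange(cfg.grid_size) * cfg.pixel_spacing
        cr, cc = cfg.center_mm
        drow = coords[:, None] - cr
        dcol = coords[None, :] - cc
        R = np.hypot(drow, dcol)
        t = f * cfg.frame_interval
        refR = reference_radius(cfg, R, t)
        interior = (refR >= cfg.endo_radius + 2) & (refR <= cfg.epi_radius - 2)
        theta_ref = reference_angle(cfg, position_angle(drow, dcol), t)
        ref_pos = refR[..., None] * unit_vector(theta_ref)
        disp_row = drow - ref_pos[..., 0]   # e = (1, 0): project on rows
        dphi = wrap_phase(h1.phase - h0.phase)
        expected = wrap_phase(-2 * np.pi * disp_row / cfg.tag_spacing)
        rms = np.sqrt(np.mean(wrap_phase(dphi[interior] - expected[interior]) ** 2))
        assert rms < 0.05

    def test_filter_reaching_dc_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValidationError, match="filter overlaps DC"):
            isolate_harmonic(img, (1.0, 0.0), 8.0, 1.0, filter_radius=0.2)

    def test_zero_image_has_zero_magnitude(self):
        h = isolate_harmonic(np.zeros((48, 48)), (1.0, 0.0), 8.0, 1.0)
        assert np.all(h.magnitude == 0.0)

    def test_dc_leakage_below_one_percent(self, quiet_config):
        img = render_tagged_frame(quiet_config, 0, (1.0, 0.0))
        h = isolate_harmonic(img, (1.0, 0.0), quiet_config.tag_spacing,
                             quiet_config.pixel_spacing)
        F = np.fft.fft2(h.data)
        dc = abs(F[0, 0]) ** 2
        total = (np.abs(F) ** 2).sum()
        assert dc / total < 0.01


def _harmonic_pair(cfg, frame):
    pair = []
    for e in cfg.tag_directions:
        img = render_tagged_frame(cfg, frame, e)
        pair.append(isolate_harmonic(img, e, cfg.tag_spacing, cfg.pixel_spacing))
    return tuple(pair)


class TestTrackPoint:
    def test_stationary_point_stays_put(self, static_config):
        cfg = static_config
        pair = _harmonic_pair(cfg, 0)
        c = cfg.center_mm[0]
        point = np.array([c + 25.0, c])
        new = ts.track_point(pair, pair, point)
        assert np.linalg.norm(new - point) < 0.05 * cfg.pixel_spacing

    def test_rigid_translation_recovered(self, static_config):
        cfg = static_config
        shift = np.array([1.2, -0.7])
        pair0 = _harmonic_pair(cfg, 0)
        pair1 = []
        for e in cfg.tag_directions:
            img = render_tagged_frame(cfg, 0, e, center_offset_mm=tuple(shift))
            pair1.append(isolate_harmonic(img, e, cfg.tag_spacing, cfg.pixel_spacing))
        c = cfg.center_mm[0]
        for ang in (0.0, 45.0, 140.0, 260.0):
            point = np.array([c, c]) + 25.0 * unit_vector(ang)
            new = ts.track_point(pair0, tuple(pair1), point)
            assert np.linalg.norm(new - (point + shift)) < 0.1 * cfg.pixel_spacing

    def test_background_point_is_signal_void(self, static_config):
        pair = _harmonic_pair(static_config, 0)
        with pytest.raises(TrackingError, match="signal void"):
            ts.track_point(pair, pair, np.array([3.0, 3.0]))


class TestMidwallContour:
    def test_perfect_annulus_lands_on_midwall(self, quiet_config):
        masks = ts.render_cine_masks(quiet_config)
        contour = ts.init_midwall_contour(masks.myocardium[0, 0], 1.0)
        c = quiet_config.center_mm[0]
        radii = np.linalg.norm(contour.positions[0] - np.array([c, c]), axis=1)
        assert contour.n_points == 72
        assert np.all(np.abs(radii - 25.0) <= 0.5 + 1e-9)

    def test_coarse_angular_step_gives_six_landmarks(self, quiet_config):
        masks = ts.render_cine_masks(quiet_config)
        contour = ts.init_midwall_contour(masks.myocardium[0, 0], 1.0, angular_step=60.0)
        assert contour.n_points == 6

    def test_elliptical_annulus_equidistant_from_boundaries(self):
        """Boundary-distance oracle: landmarks sit midway through the wall."""
        from skimage import measure

        n = 120
        yy, xx = np.mgrid[:n, :n]
        cy = cx = (n - 1) / 2
        r_out = ((yy - cy) / 33.0) ** 2 + ((xx - cx) / 28.0) ** 2 <= 1.0
        r_in = ((yy - cy) / 21.0) ** 2 + ((xx - cx) / 17.0) ** 2 <= 1.0
        mask = r_out & ~r_in
        contour = ts.init_midwall_contour(mask, 1.0)
        endo = np.vstack(measure.find_contours(r_in.astype(float), 0.5))
        epi = np.vstack(measure.find_contours(r_out.astype(float), 0.5))
        for p in contour.positions[0]:
            d_endo = np.min(np.linalg.norm(endo - p, axis=1))
            d_epi = np.min(np.linalg.norm(epi - p, axis=1))
            assert abs(d_endo - d_epi) <= 1.0

    def test_open_myocardium_rejected(self):
        mask = np.zeros((64, 64), dtype=bool)
        yy, xx = np.mgrid[:64, :64]
        rr = np.hypot(yy - 32, xx - 32)
        mask[(rr > 12) & (rr < 20)] = True
        mask[:, 32:] = False   # half-moon: rays on the right find nothing
        with pytest.raises(ValidationError, match="open myocardium"):
            ts.init_midwall_contour(mask, 1.0)

    def test_non_annular_mask_rejected(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:24, 8:24] = True   # solid block, no cavity
        with pytest.raises(ValidationError, match="annular"):
            ts.init_midwall_contour(mask, 1.0)


class TestTrackContour:
    def test_uniform_contraction_recovers_circumference_change(self):
        cfg = ts.PhantomConfig(sector_amplitudes=(10.0,) * 6, noise_sd=0.0)
        series = tuple(ts.render_tagged_series(cfg, 0, e) for e in cfg.tag_directions)
        masks = ts.render_cine_masks(cfg)
        contour = ts.init_midwall_contour(masks.myocardium[0, 0], 1.0,
                                          frame_times=cfg.frame_times)
        track = ts.track_contour(series, contour)

        def circumference(pts):
            return np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum()

        change = 100.0 * (1.0 - circumference(track.positions[cfg.avc_frame])
                          / circumference(track.positions[0]))
        assert change == pytest.approx(10.0, abs=0.5)

    def test_static_phantom_drift_below_fifth_of_pixel(self, tracked_static):
        drift = np.linalg.norm(tracked_static.positions - tracked_static.positions[0],
                               axis=2)
        assert drift.max() < 0.2

    def test_failed_landmark_interpolated_and_flagged(self, static_config):
        cfg = static_config
        series = []
        # carve a signal void under landmark at angle 0 (top of the annulus)
        c = cfg.grid_size // 2
        for e in cfg.tag_directions:
            s = ts.render_tagged_series(cfg, 0, e)
            imgs = s.images.copy()
            imgs[1:, c - 31 : c - 19, c - 6 : c + 7] = 0.0
            series.append(ts.TaggedSeries(images=imgs, pixel_spacing=s.pixel_spacing,
                                          frame_times=s.frame_times,
                                          tag_direction=s.tag_direction,
                                          tag_spacing=s.tag_spacing))
        masks = ts.render_cine_masks(cfg)
        contour = ts.init_midwall_contour(masks.myocardium[0, 0], 1.0,
                                          frame_times=cfg.frame_times)
        track = ts.track_contour(tuple(series), contour, magnitude_floor=0.5)
        assert track.n_flagged > 0
        # flagged landmarks are near angle 0; neighbours at 90-270 are untouched
        flagged_angles = set()
        for f, i in zip(*np.nonzero(track.flags)):
            flagged_angles.add(track.angles_deg[i])
        assert all(a <= 30 or a >= 330 for a in flagged_angles)
        side = np.where(track.angles_deg == 90.0)[0][0]
        drift = np.linalg.norm(track.positions[:, side] - track.positions[0, side], axis=1)
        assert drift.max() < 0.2
        # interpolated positions stay finite and near the annulus
        assert np.isfinite(track.positions).all()

    def test_track_quality_gate(self, static_config):
        cfg = static_config
        series = tuple(ts.render_tagged_series(cfg, 0, e) for e in cfg.tag_directions)
        masks = ts.render_cine_masks(cfg)
        contour = ts.init_midwall_contour(masks.myocardium[0, 0], 1.0,
                                          frame_times=cfg.frame_times)
        with pytest.raises(TrackingError, match="track quality"):
            ts.track_contour(series, contour, magnitude_floor=2.0)

    def test_mismatched_series_rejected(self, static_config):
        cfg = static_config
        s0 = ts.render_tagged_series(cfg, 0, cfg.tag_directions[0])
        s1 = ts.render_tagged_series(cfg, 0, cfg.tag_directions[1])
        short = ts.TaggedSeries(images=s1.images[:-1], pixel_spacing=s1.pixel_spacing,
                                frame_times=s1.frame_times[:-1],
                                tag_direction=s1.tag_direction, tag_spacing=s1.tag_spacing)
        masks = ts.render_cine_masks(cfg)
        contour = ts.init_midwall_contour(masks.myocardium[0, 0], 1.0,
                                          frame_times=cfg.frame_times)
        with pytest.raises(ValidationError, match="identical frames"):
            ts.track_contour((s0, short), contour)
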