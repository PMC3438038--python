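"""Synthetic-data module: motion model, renderers, masks, cohort draws."""

import dataclasses

import numpy as np
import pytest

import tagsync as ts
from tagsync.config import CohortParams, acute_mi_config
from tagsync.errors import QuantError, ValidationError
from tagsync.phantom import (deformed_angle, ground_truth_csh, render_tagged_frame,
                             unit_vector)


def midwall_arc_by_displacement(cfg, frame, n=7200):
    """Independent oracle: arc length of the displaced midwall polyline."""
    theta = (np.arange(n) + 0.5) * 360.0 / n
    ref = cfg.midwall_radius * unit_vector(theta)
    disp = ts.motion_displacement(cfg, theta, np.full(n, cfg.midwall_radius), frame)
    pts = ref + disp
    return np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum()


class TestMotionModel:
    def test_frame0_is_undeformed_reference(self, quiet_config):
        angles = np.array([0.0, 33.3, 123.4, 359.9])
        radii = np.array([20.0, 25.0, 27.5, 30.0])
        disp = ts.motion_displacement(quiet_config, angles, radii, 0)
        assert np.allclose(disp, 0.0)

    def test_angle_wrapping_not_an_error(self, quiet_config):
        d1 = ts.motion_displacement(quiet_config, 370.0, 25.0, 5)
        d2 = ts.motion_displacement(quiet_config, 10.0, 25.0, 5)
        assert np.allclose(d1, d2)

    def test_uniform_contraction_gives_configured_peak_csh(self, quiet_config):
        """Numeric arc-length integration recovers the 15% peak exactly."""
        cfg = quiet_config
        L0 = midwall_arc_by_displacement(cfg, 0)
        L = midwall_arc_by_displacement(cfg, cfg.avc_frame)
        csh = 100.0 * (L0 - L) / L0
        assert csh == pytest.approx(15.0, abs=1e-6)

    def test_delayed_sector_curve_is_time_shifted(self):
        """Sector 4's csh(t) equals sector 1's shifted by the 90 ms delay."""
        cfg = ts.PhantomConfig(sector_delays=(0, 0, 0, 90, 0, 0), noise_sd=0.0,
                               n_frames=22)
        gt = ground_truth_csh(cfg)
        t = cfg.frame_times
        # cross-correlation oracle on finely interpolated curves
        tt = np.linspace(0, t[-1], 2000)
        c1 = np.interp(tt, t, gt[0])
        c4 = np.interp(tt, t, gt[3])
        lags = np.arange(0, 200.0, 1.0)
        scores = [np.corrcoef(np.interp(tt, tt + lag, c1, left=0.0), c4)[0, 1]
                  for lag in lags]
        best = lags[int(np.argmax(scores))]
        assert best == pytest.approx(90.0, abs=cfg.frame_interval / 2)
        # pointwise shift identity away from sector-boundary blending
        shifted = np.interp(t, t + 90.0, gt[0], left=0.0)
        assert np.max(np.abs(gt[3] - shifted)) < 0.5

    def test_ground_truth_matches_configured_amplitudes(self, hypokinetic_config):
        gt = ground_truth_csh(hypokinetic_config)
        at_avc = gt[:, hypokinetic_config.avc_frame]
        assert np.all(np.abs(at_avc - np.array([15, 15, 15, 5, 5, 15])) < 1.0)

    def test_annulus_area_is_conserved(self, hypokinetic_config):
        cfg = hypokinetic_config
        from tagsync.phantom import deformed_radius

        for f in (3, cfg.avc_frame):
            t = f * cfg.frame_interval
            r_en = deformed_radius(cfg, cfg.endo_radius, t)
            r_ep = deformed_radius(cfg, cfg.epi_radius, t)
            area = np.pi * (r_ep ** 2 - r_en ** 2)
            area0 = np.pi * (cfg.epi_radius ** 2 - cfg.endo_radius ** 2)
            assert area == pytest.approx(area0, rel=1e-9)

    def test_deformed_angle_is_monotone_and_periodic(self, hypokinetic_config):
        cfg = hypokinetic_config
        theta = np.linspace(0, 359.9, 1000)
        phi = deformed_angle(cfg, theta, cfg.avc_time)
        diffs = np.diff(np.unwrap(np.deg2rad(phi)))
        assert np.all(diffs > 0)


class TestTaggedRendering:
    def test_reference_frame_shows_pure_tag_pattern(self, quiet_config):
        """Spectral peak of frame 0 sits at 1/tag_spacing along the tag normal."""
        img = render_tagged_frame(quiet_config, 0, (1.0, 0.0))
        F = np.abs(np.fft.fft2(img))
        fr = np.fft.fftfreq(img.shape[0], d=quiet_config.pixel_spacing)
        fc = np.fft.fftfreq(img.shape[1], d=quiet_config.pixel_spacing)
        kr, kc = np.meshgrid(fr, fc, indexing="ij")
        band = np.hypot(kr, kc) > 0.07  # exclude the shape spectrum around DC
        peak = np.unravel_index(np.argmax(np.where(band, F, 0.0)), F.shape)
        assert abs(abs(fr[peak[0]]) - 1.0 / quiet_config.tag_spacing) < 0.01
        assert abs(fc[peak[1]]) < 0.01

    def test_rigid_translation_shifts_tag_phase(self, quiet_config):
        """Translating the phantom by t shifts the phase by 2π e·t / tag_spacing."""
        cfg = quiet_config
        e = (1.0, 0.0)
        shift = (2.0, 0.0)   # mm along the tag normal
        img0 = render_tagged_frame(cfg, 0, e)
        img1 = render_tagged_frame(cfg, 0, e, center_offset_mm=shift)
        h0 = ts.isolate_harmonic(img0, e, cfg.tag_spacing, cfg.pixel_spacing)
        h1 = ts.isolate_harmonic(img1, e, cfg.tag_spacing, cfg.pixel_spacing)
        # compare phases at pixels interior to the myocardium in both images
        c = cfg.grid_size // 2
        rows = np.arange(c + 22, c + 28)
        dphi = ts.wrap_phase(h1.phase[rows, c] - h0.phase[rows, c])
        expected = ts.wrap_phase(-2.0 * np.pi * shift[0] / cfg.tag_spacing)
        assert np.allclose(dphi, expected, atol=0.05)

    def test_same_seed_is_bit_identical(self):
        cfg = ts.PhantomConfig(noise_sd=5.0)
        a = ts.render_tagged_series(cfg, 2, (1.0, 0.0)).images
        b = ts.render_tagged_series(cfg, 2, (1.0, 0.0)).images
        assert np.array_equal(a, b)
        c = ts.render_tagged_series(dataclasses.replace(cfg, seed=1), 2, (1.0, 0.0)).images
        assert not np.array_equal(a, c)

    def test_unresolvable_tags_rejected(self):
        cfg = ts.PhantomConfig(tag_spacing=1.5)
        with pytest.raises(ValidationError, match="tags unresolvable"):
            ts.render_tagged_series(cfg, 0, (1.0, 0.0))

    def test_unknown_tag_direction_rejected(self, quiet_config):
        with pytest.raises(ValidationError, match="tag_direction"):
            ts.render_tagged_series(quiet_config, 0, (0.6, 0.8))


class TestCineMasks:
    def test_end_diastolic_mask_matches_configured_radii(self, quiet_config):
        masks = ts.render_cine_masks(quiet_config)
        px_area = quiet_config.pixel_spacing ** 2
        epi_area = masks.epi[0, 0].sum() * px_area
        assert epi_area == pytest.approx(np.pi * 30.0 ** 2, rel=0.02)
        endo_area = masks.endo[0, 0].sum() * px_area
        assert endo_area == pytest.approx(np.pi * 20.0 ** 2, rel=0.02)

    def test_disc_summation_edv_matches_analytic_cylinder(self, quiet_config):
        cfg = quiet_config
        masks = ts.render_cine_masks(cfg)
        vols = ts.lv_volumes(masks.endo[:, 0], masks.epi[:, 0],
                             masks.endo[:, cfg.avc_frame], masks.epi[:, cfg.avc_frame],
                             cfg.pixel_spacing, cfg.slice_thickness)
        analytic = np.pi * cfg.endo_radius ** 2 * cfg.slice_thickness * cfg.n_slices / 1000.0
        assert vols.lvedv_ml == pytest.approx(analytic, rel=0.03)

    def test_cavity_area_monotone_from_ed_to_avc(self, quiet_config):
        masks = ts.render_cine_masks(quiet_config)
        areas = masks.endo[0, : quiet_config.avc_frame + 1].sum(axis=(1, 2))
        assert np.all(np.diff(areas) < 0)


class TestTissueMaps:
    def test_90_degree_edema_measures_quarter_circumference(self):
        cfg = ts.PhantomConfig(noise_sd=0.0, edema_arc=(0.0, 90.0),
                               necrosis_arc=(0.0, 0.0),
                               signal_levels=ts.SignalLevels(remote_sd=1e-6))
        ext = ts.quantify_tissue(ts.render_tissue_maps(cfg))
        # exact 90/360 up to one blended midline sample per arc boundary
        assert ext.edema_extent == pytest.approx(25.0, abs=0.6)

    def test_empty_necrosis_means_salvage_equals_edema(self):
        cfg = ts.PhantomConfig(noise_sd=0.0, edema_arc=(0.0, 90.0),
                               necrosis_arc=(0.0, 0.0),
                               signal_levels=ts.SignalLevels(remote_sd=1e-6))
        ext = ts.quantify_tissue(ts.render_tissue_maps(cfg))
        assert ext.necrosis_extent == 0.0
        assert ext.necrosis_mass == 0.0
        assert ext.salvage == ext.edema_extent

    def test_transmural_108_degree_sector_is_30pct_mass(self):
        cfg = ts.PhantomConfig(noise_sd=0.0, necrosis_arc=(49.5, 157.5),
                               signal_levels=ts.SignalLevels(remote_sd=1e-6))
        ext = ts.quantify_tissue(ts.render_tissue_maps(cfg))
        assert ext.necrosis_mass == pytest.approx(30.0, abs=0.5)

    def test_arc_nesting_validated(self):
        cfg = ts.PhantomConfig(edema_arc=(0.0, 90.0), necrosis_arc=(180.0, 270.0))
        with pytest.raises(ValidationError, match="nested"):
            ts.render_tissue_maps(cfg)

    def test_insufficient_lesion_contrast_rejected(self):
        cfg = ts.PhantomConfig(signal_levels=ts.SignalLevels(remote_mean=100, remote_sd=30,
                                                             edema_mean=120, necrosis_mean=300))
        with pytest.raises(ValidationError, match="edema_mean"):
            ts.render_tissue_maps(cfg)


class TestCohortGenerator:
    def test_large_sample_recovers_configured_means(self):
        table = ts.generate_cohort_measures(5000, seed=11)
        assert table["edema_extent"].mean() == pytest.approx(57.5, abs=1.0)
        assert table["necrosis_mass"].mean() == pytest.approx(30.0, abs=1.5)
        assert table["CURE_acute"].mean() == pytest.approx(0.91, abs=0.01)
        assert table["CURE_followup"].mean() == pytest.approx(0.94, abs=0.01)

    def test_salvage_is_definitionally_edema_minus_necrosis(self):
        table = ts.generate_cohort_measures(500, seed=3)
        assert np.array_equal(table["salvage"],
                              np.clip(table["edema_extent"] - table["necrosis_extent"], 0, None))

    def test_zero_link_and_noise_gives_constant_cure(self):
        params = CohortParams(cure_link_slope=0.0, cure_link_intercept=0.91,
                              cure_link_noise_sd=0.0)
        table = ts.generate_cohort_measures(50, params, seed=0)
        assert table["CURE_acute"].nunique() == 1
        with pytest.raises(QuantError, match="zero variance"):
            ts.correlate(table["edema_extent"], table["CURE_acute"])

    def test_reproducible_given_seed(self):
        a = ts.generate_cohort_measures(30, seed=9)
        b = ts.generate_cohort_measures(30, seed=9)
        assert a.equals(b)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValidationError):
            ts.generate_cohort_measures(1)
        with pytest.raises(ValidationError, match="positive"):
            ts.generate_cohort_measures(10, CohortParams(edema_sd=-1.0))

    def test_image_level_subject_config_is_valid(self):
        table = ts.generate_cohort_measures(5, seed=2)
        cfg = ts.subject_config_from_measures(table.iloc[0])
        assert isinstance(cfg, ts.PhantomConfig)
        from tagsync.config import arc_width

        assert arc_width(cfg.edema_arc) == pytest.approx(table.iloc[0]["edema_extent"] * 3.6)
        # infarct sectors are hypokinetic relative to the base amplitudes
        assert min(cfg.sector_amplitudes) < 15.0


class TestAcuteMiPreset:
    def test_preset_is_dyssynchronous(self):
        cfg = acute_mi_config(noise_sd=0.0)
        rep = ts.dyssynchrony_report(ts.ground_truth_strain(cfg))
        sync = ts.dyssynchrony_report(ts.ground_truth_strain(ts.PhantomConfig()))
        assert rep.cure < sync.cure
        assert rep.t_max_sd_ms > 0
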