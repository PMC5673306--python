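"""Laser-cut recoil, thickness, kymograph and cortical intensity readouts."""

import numpy as np
import pytest

from polcortex import mechanics as mech
from polcortex import scenes as sc


def cut_scene(**kw):
    base = dict(
        cell_radius_um=7.0,
        pixel_size_um=0.15,
        depolarization_floor=0.25,
        emission_floor=0.85,
        n_dipole_samples=128,
        noise=False,
        seed=4,
    )
    base.update(kw)
    scene = sc.SceneConfig(**base)
    c = (scene.image_shape()[1] - 1) / 2 * scene.pixel_size_um
    return scene, c


class TestInitialOutwardMovement:
    def cut_px(self, cut, px):
        return (
            (cut.start_um[0] / px, cut.start_um[1] / px),
            (cut.end_um[0] / px, cut.end_um[1] / px),
        )

    def test_no_displacement_recovers_gap_width(self):
        scene, c = cut_scene()
        cut = sc.CutSpec(
            (c - 2.5, c), (c + 2.5, c),
            gap_width_um=0.6, baseline_damage_um=0.0, retraction_amplitude_um=0.0,
        )
        series = sc.generate_cut_series(scene, cut, n_pre=1, n_post=2)
        p0, p1 = self.cut_px(cut, scene.pixel_size_um)
        out = mech.initial_outward_movement(
            series.horizontal[0], series.horizontal[1], p0, p1, scene.pixel_size_um
        )
        assert out["edge_distance_um"] == pytest.approx(0.6, abs=scene.pixel_size_um)

    def test_recoil_edges_match_ground_truth(self):
        scene, c = cut_scene(noise=True)
        cut = sc.CutSpec(
            (c - 2.5, c), (c + 2.5, c),
            gap_width_um=0.2, baseline_damage_um=0.4, retraction_amplitude_um=2.0,
            retraction_timescale_s=2.0,
        )
        series = sc.generate_cut_series(
            scene, cut, n_pre=1, n_post=4, frame_interval_s=0.45
        )
        p0, p1 = self.cut_px(cut, scene.pixel_size_um)
        for k in range(1, 5):
            out = mech.initial_outward_movement(
                series.horizontal[0], series.horizontal[k], p0, p1, scene.pixel_size_um
            )
            assert out["edge_distance_um"] == pytest.approx(
                series.truth.edge_separation_um[k], abs=scene.pixel_size_um
            )

    def test_symmetric_scene_symmetric_edges(self):
        scene, c = cut_scene()
        cut = sc.CutSpec((c - 2.5, c), (c + 2.5, c), baseline_damage_um=0.6)
        series = sc.generate_cut_series(scene, cut, n_pre=1, n_post=1)
        p0, p1 = self.cut_px(cut, scene.pixel_size_um)
        out = mech.initial_outward_movement(
            series.horizontal[0], series.horizontal[1], p0, p1, scene.pixel_size_um
        )
        assert abs(out["edge_right_um"] + out["edge_left_um"]) < scene.pixel_size_um

    def test_blank_frames_rejected(self):
        blank = np.zeros((60, 60))
        with pytest.raises(ValueError):
            mech.initial_outward_movement(blank, blank, (10, 30), (43, 30), 0.15)


class TestBaselineCorrection:
    def test_subtraction_arithmetic(self):
        table = {("late ingression", "perpendicular"): 0.4}
        m = mech.baseline_correct(2.0, table, "late ingression", "perpendicular")
        assert m.tension_proxy_um == pytest.approx(1.6)
        assert not m.flagged_negative

    def test_equal_values_give_zero(self):
        m = mech.baseline_correct(0.4, {("metaphase", "parallel"): 0.4},
                                  "metaphase", "parallel")
        assert m.tension_proxy_um == pytest.approx(0.0)

    def test_negative_proxy_flagged_not_clipped(self):
        m = mech.baseline_correct(0.3, {("metaphase", "parallel"): 0.4},
                                  "metaphase", "parallel")
        assert m.tension_proxy_um == pytest.approx(-0.1)
        assert m.flagged_negative

    def test_missing_entry_rejected(self):
        with pytest.raises(KeyError):
            mech.baseline_correct(1.0, {}, "metaphase", "parallel")

    def test_myosin_off_cohort_recovers_imposed_baseline(self):
        """Cohort with no active recoil: mean edge distance = gap + damage."""
        distances = []
        for seed in range(4):
            scene, c = cut_scene(noise=True, seed=40 + seed)
            cut = sc.CutSpec(
                (c - 2.5, c), (c + 2.5, c),
                gap_width_um=0.3, baseline_damage_um=0.5, retraction_amplitude_um=0.0,
            )
            series = sc.generate_cut_series(scene, cut, n_pre=1, n_post=1)
            p0 = (cut.start_um[0] / scene.pixel_size_um, cut.start_um[1] / scene.pixel_size_um)
            p1 = (cut.end_um[0] / scene.pixel_size_um, cut.end_um[1] / scene.pixel_size_um)
            out = mech.initial_outward_movement(
                series.horizontal[0], series.horizontal[1], p0, p1, scene.pixel_size_um
            )
            distances.append(out["edge_distance_um"] - 0.3)  # remove known gap
        assert np.mean(distances) == pytest.approx(0.5, rel=0.05)


class TestRecoilFit:
    def test_exponential_parameters_recovered(self):
        t = np.arange(1, 12) * 0.45
        d = 0.7 + 2.0 * (1 - np.exp(-t / 2.0))
        off, amp, tau = mech.fit_recoil(t, d)
        assert off == pytest.approx(0.7, abs=1e-6)
        assert amp == pytest.approx(2.0, abs=1e-6)
        assert tau == pytest.approx(2.0, abs=1e-6)


class TestThickness:
    def test_noiseless_thickness_recovered(self):
        x, mem, act = sc.generate_linescan_pair(0.2)
        meas = mech.cortex_thickness(x, mem, act)
        assert meas.thickness_um == pytest.approx(0.2, abs=1e-3)

    def test_zero_thickness(self):
        x, mem, act = sc.generate_linescan_pair(0.0, noise_sd=0.01, seed=6)
        meas = mech.cortex_thickness(x, mem, act)
        assert meas.thickness_um == pytest.approx(0.0, abs=0.03)

    def test_ignoring_chromatic_shift_biases_thickness(self):
        shift = (0.0735, 0.0398)
        x, mem, act = sc.generate_linescan_pair(0.2, chromatic_shift_um=shift)
        biased = mech.cortex_thickness(x, mem, act)
        corrected = mech.cortex_thickness(x, mem, act, chromatic_shift_um=shift)
        assert corrected.thickness_um == pytest.approx(0.2, abs=1e-3)
        # the x-shift moves the actin center outward: bias = 2 * shift_x
        assert biased.thickness_um == pytest.approx(0.2 - 2 * 0.0735, abs=5e-3)

    @pytest.mark.parametrize("thickness", [0.0, 0.1, 0.2, 0.4])
    def test_unbiased_across_thicknesses_at_good_snr(self, thickness):
        px = 0.05
        errors = []
        for seed in range(5):
            x, mem, act = sc.generate_linescan_pair(
                thickness, noise_sd=0.05, seed=100 + seed, pixel_size_um=px
            )
            meas = mech.cortex_thickness(x, mem, act)
            errors.append(meas.thickness_um - thickness)
        assert abs(np.mean(errors)) < px / 4

    def test_border_maximum_rejected(self):
        x = np.arange(30) * 0.05
        ramp = np.linspace(0, 1, 30)
        with pytest.raises(ValueError):
            mech.cortex_thickness(x, ramp, ramp)


class TestKymograph:
    def test_static_scene_identical_rows(self, rng):
        frame = rng.uniform(0, 1, (50, 100))
        ky = mech.kymograph([frame] * 5, (5, 25), (95, 25))
        assert np.allclose(ky, ky[0][None, :])

    def test_moving_spot_slope(self):
        frames = []
        for k in range(8):
            xx = np.arange(120)
            frames.append(
                np.tile(np.exp(-((xx - (15 + 6 * k)) ** 2) / (2 * 3.0**2)), (60, 1))
            )
        ky = mech.kymograph(frames, (2, 30), (118, 30), width_px=25)
        peaks = ky.argmax(axis=1)
        slope = np.polyfit(np.arange(8), peaks, 1)[0]
        assert slope == pytest.approx(6.0, rel=0.05)

    def test_width_one_equals_line_sampling(self, rng):
        frame = rng.uniform(0, 1, (40, 80))
        wide = mech.kymograph([frame], (5, 20), (75, 20), width_px=1)
        from scipy import ndimage

        along = np.linspace(0, 70, wide.shape[1])
        direct = ndimage.map_coordinates(
            frame, np.stack([np.full_like(along, 20.0), 5 + along]), order=1
        )
        assert np.allclose(wide[0], direct)

    def test_line_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            mech.kymograph([np.ones((20, 20))], (1, 10), (40, 10))


class TestCorticalIntensityProfile:
    @staticmethod
    def make_series(density_factor=1.0, n=6):
        """Constant-geometry contour series with optional equatorial ramp."""
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        contour = np.column_stack([80 + 60 * np.cos(t), 80 + 60 * np.sin(t)])
        from polcortex.polscope import locate_equator_poles

        anchors = locate_equator_poles(
            np.column_stack([80 + 60 * np.cos(t), 80 + 59 * np.sin(t)])
        )
        frames = []
        yy, xx = np.mgrid[0:160, 0:160]
        r = np.hypot(xx - 80, yy - 80)
        ring = np.exp(-((r - 60) ** 2) / (2 * 2.0**2))
        for k in range(n):
            scalemap = np.ones_like(ring)
            if density_factor != 1.0 and k >= 3:
                # enrich disks around the equatorial anchor points
                boost = np.ones_like(ring)
                for ax, ay in anchors.equator_xy:
                    boost = np.where(
                        np.hypot(xx - ax, yy - ay) < 16, density_factor, boost
                    )
                scalemap = boost
            frames.append(ring * scalemap)
        contours = [contour] * n
        return frames, contours, [anchors] * n

    def test_constant_series_normalizes_to_one(self):
        frames, contours, anchors = self.make_series()
        out = mech.cortical_intensity_profile(
            frames, contours, anchors, np.arange(6) * 15.0 - 45.0, 0.15,
            profile_from_s=1e9,
        )
        tc = out["time_course"]
        assert np.allclose(tc["equator"], 1.0, atol=1e-9)
        assert np.allclose(tc["pole"], 1.0, atol=1e-9)

    def test_equatorial_ramp_reaches_factor(self):
        frames, contours, anchors = self.make_series(density_factor=2.0)
        out = mech.cortical_intensity_profile(
            frames, contours, anchors, np.arange(6) * 15.0 - 45.0, 0.15,
            profile_from_s=1e9,
        )
        tc = out["time_course"]
        assert tc["equator"].iloc[-1] == pytest.approx(2.0, rel=0.05)
        assert tc["pole"].iloc[-1] == pytest.approx(1.0, abs=0.05)

    def test_missing_reference_frames_rejected(self):
        frames, contours, anchors = self.make_series(n=4)
        with pytest.raises(ValueError):
            mech.cortical_intensity_profile(
                frames, contours, anchors, np.arange(4) * 15.0, 0.15
            )

    def test_density_zone_width_recovered_from_rendered_cell(self):
        """Generator density FWHM 8.4 um is read back from the profile."""
        from polcortex import emission as em
        from polcortex import polscope as ps
        from scipy import ndimage as ndi
        import warnings

        scene = sc.SceneConfig(
            density_equator_factor=2.0, density_zone_fwhm_um=8.4,
            pixel_size_um=0.15, noise=False, n_dipole_samples=256, seed=15,
        )
        stack, truth = sc.generate_polscope_stack(scene)
        mean_img = stack.mean_image()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, outline = ps.segment_cell(mean_img, truth.center_px, closing_radius=2)
        prov = em.fit_cortex_spline(
            outline, scene.pixel_size_um, furrow_point_px=truth.equator_anchor_px
        )
        refined = em.refine_contour_to_ridge(mean_img, prov)
        cont = em.fit_cortex_spline(
            refined, scene.pixel_size_um, furrow_point_px=truth.equator_anchor_px
        )
        prof = ndi.map_coordinates(
            mean_img, np.stack([cont.positions_px[:, 1], cont.positions_px[:, 0]]),
            order=1,
        )
        sel = np.abs(cont.arc_um) < 15.0
        fit = ps.anisotropic_zone_width(cont.arc_um[sel], prof[sel], center_um=0.0)
        assert fit["fwhm_um"] == pytest.approx(8.4, abs=1.0)
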