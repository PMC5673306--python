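"""Live-cell emission-ratio pipeline: CTF, splines, sin^2 regression, gates."""

import numpy as np
import pandas as pd
import pytest

from polcortex import emission as em


def make_pair(h, v, px=0.15, roi=None):
    return em.RatioPair(np.asarray(h, float), np.asarray(v, float), px, roi)


class TestCTF:
    def test_identical_images_give_unity(self):
        img = np.full((10, 10), 7.0)
        ctf = em.estimate_ctf(make_pair(img, img))
        assert ctf.scalar == pytest.approx(1.0)

    def test_doubled_vertical_halves_ctf(self):
        img = np.full((10, 10), 7.0)
        ctf = em.estimate_ctf(make_pair(img, 2 * img))
        assert ctf.scalar == pytest.approx(0.5)

    def test_ctf_flattens_plastic_ratio(self, rng):
        h = rng.poisson(400, (32, 32)).astype(float)
        v = rng.poisson(520, (32, 32)).astype(float)
        ctf = em.estimate_ctf(make_pair(h, v))
        flattened = np.median(v * ctf.scalar / h)
        assert flattened == pytest.approx(1.0, abs=0.02)

    def test_ctf_invariance_of_downstream_ratio(self, rng):
        """Scaling the vertical channel is absorbed exactly by the CTF."""
        h = rng.uniform(10, 20, (16, 16))
        v = rng.uniform(10, 20, (16, 16))
        gamma = 3.7
        ctf1 = em.estimate_ctf(make_pair(h, v))
        ctf2 = em.estimate_ctf(make_pair(h, gamma * v))
        r1 = v * ctf1.scalar / h
        r2 = (gamma * v) * ctf2.scalar / h
        assert np.allclose(r1, r2, rtol=1e-9)

    def test_zero_images_rejected(self):
        with pytest.raises(ValueError):
            em.estimate_ctf(make_pair(np.zeros((4, 4)), np.zeros((4, 4))))


class TestBackgroundSubtract:
    def test_uniform_offset_removed_exactly(self):
        h = np.full((20, 20), 30.0)
        h[5:15, 5:15] = 100.0
        pair = make_pair(h, h + 5.0, roi=(slice(0, 4), slice(0, 4)))
        corrected, qc = em.background_subtract(pair)
        assert corrected.horizontal[0, 0] == pytest.approx(0.0)
        assert corrected.horizontal[10, 10] == pytest.approx(70.0)
        assert qc["horizontal_background"] == pytest.approx(30.0)

    def test_clip_count_reported(self, rng):
        h = rng.normal(10.0, 3.0, (20, 20))
        pair = make_pair(h, h, roi=(slice(0, 20), slice(0, 20)))
        corrected, qc = em.background_subtract(pair)
        assert qc["horizontal_clipped_px"] > 0
        assert (corrected.horizontal >= 0).all()

    def test_missing_roi_rejected(self):
        with pytest.raises(ValueError):
            em.background_subtract(make_pair(np.ones((4, 4)), np.ones((4, 4))))


def circle_outline(radius=40.0, center=(60.0, 60.0), n=600):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )


class TestCortexSpline:
    def test_circle_tangent_perpendicular_to_radius(self):
        contour = em.fit_cortex_spline(circle_outline(), 0.15)
        radial = contour.positions_px - np.array([60.0, 60.0])
        radial_deg = np.rad2deg(np.arctan2(radial[:, 1], radial[:, 0]))
        diff = (contour.tangent_deg - (radial_deg + 90.0)) % 180.0
        diff = np.minimum(diff, 180.0 - diff)
        assert diff.max() < 1.0

    def test_ellipse_tangents_match_closed_form(self):
        a, b = 45.0, 25.0
        t = np.linspace(0, 2 * np.pi, 800, endpoint=False)
        outline = np.column_stack([60 + a * np.cos(t), 60 + b * np.sin(t)])
        contour = em.fit_cortex_spline(outline, 0.15, n_points=400)
        # closed-form tangent of the ellipse at the nearest parameter
        for pos, tang in zip(contour.positions_px[::37], contour.tangent_deg[::37]):
            tt = np.arctan2((pos[1] - 60) / b, (pos[0] - 60) / a)
            want = np.rad2deg(np.arctan2(b * np.cos(tt), -a * np.sin(tt))) % 180.0
            d = abs(tang - want) % 180.0
            assert min(d, 180.0 - d) < 2.0

    def test_smoothing_stays_near_input(self):
        outline = circle_outline()
        contour = em.fit_cortex_spline(outline, 0.15)
        radii = np.linalg.norm(contour.positions_px - np.array([60.0, 60.0]), axis=1)
        assert np.sqrt(np.mean((radii - 40.0) ** 2)) < 1.0

    def test_open_contour_rejected(self):
        with pytest.raises(ValueError):
            em.fit_cortex_spline(circle_outline()[:200], 0.15)

    def test_tangent_angles_continuous(self):
        contour = em.fit_cortex_spline(circle_outline(), 0.15)
        jumps = np.abs(np.diff(contour.tangent_deg))
        jumps = np.minimum(jumps, 180.0 - jumps)
        assert jumps.max() < 45.0

    def test_subregions_cover_four_sites(self):
        contour = em.fit_cortex_spline(
            circle_outline(), 0.15, furrow_point_px=(100.0, 60.0),
            subregion_length_um=10.0,
        )
        assert set(contour.subregions) == {
            "furrow", "pole_0", "furrow_opposite", "pole_1",
        }
        for idx in contour.subregions.values():
            assert len(idx) > 0


class TestSampleRatio:
    def test_uniform_images_give_flat_ctf_corrected_ratio(self):
        h = np.full((120, 120), 50.0)
        v = np.full((120, 120), 80.0)
        ctf = em.ChannelTransmissionFactor(50.0 / 80.0)
        contour = em.fit_cortex_spline(circle_outline(), 0.15)
        samples = em.sample_cortex_ratio(make_pair(h, v), ctf, contour)
        ok = samples.dropna(subset=["ratio"])
        assert np.allclose(ok["ratio"], 1.0, atol=1e-9)

    def test_scale_invariance(
        self, metaphase_samples, live_metaphase, live_ctf, contour_pipeline
    ):
        scene, series = live_metaphase
        frame = series.frames[0]
        pair = make_pair(
            2.0 * frame.horizontal, 2.0 * frame.vertical, scene.pixel_size_um
        )
        _, contour = contour_pipeline(
            frame.horizontal + frame.vertical,
            frame.truth.center_px,
            frame.truth.equator_anchor_px,
            scene.pixel_size_um,
        )
        scaled = em.sample_cortex_ratio(pair, live_ctf, contour).dropna(
            subset=["ratio"]
        )
        assert np.allclose(
            scaled["ratio"].to_numpy(), metaphase_samples["ratio"].to_numpy(), rtol=1e-9
        )

    def test_metaphase_ratio_follows_sine_squared(self, metaphase_samples):
        """Rendered kappa=0 metaphase cortex: geometry model fits with R^2 > 0.9."""
        res = em.fit_geometry_model(metaphase_samples)
        assert res.rsquared > 0.9
        assert res.a1 > 0  # co-polarized ratio peaks at tangent 90 deg


class TestGeometryModel:
    def test_exact_recovery_from_model_class(self):
        alpha = np.linspace(0, 179, 720)
        ratio = 1.0 + 0.5 * np.sin(np.deg2rad(alpha)) ** 2
        res = em.SineSquaredModel(alpha, ratio).fit()
        assert res.a0 == pytest.approx(1.0, abs=1e-9)
        assert res.a1 == pytest.approx(0.5, abs=1e-9)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_tolerance(self, rng):
        alpha = rng.uniform(0, 180, 1200)
        ratio = 1.0 + 0.5 * np.sin(np.deg2rad(alpha)) ** 2 + rng.normal(0, 0.05, 1200)
        res = em.SineSquaredModel(alpha, ratio).fit()
        assert res.a0 == pytest.approx(1.0, abs=0.02)
        assert res.a1 == pytest.approx(0.5, abs=0.02)

    def test_constant_data_zero_amplitude(self):
        alpha = np.linspace(0, 179, 360)
        res = em.SineSquaredModel(alpha, np.full_like(alpha, 2.0)).fit()
        assert res.a1 == pytest.approx(0.0, abs=1e-9)

    def test_narrow_angle_range_rejected(self):
        alpha = np.linspace(0, 40, 100)
        with pytest.raises(ValueError):
            em.SineSquaredModel(alpha, np.ones_like(alpha))


class TestCorrectRatio:
    def test_model_data_corrects_to_unity(self):
        alpha = np.linspace(0, 179, 360)
        res = em.SineSquaredModel(
            alpha, 1.2 + 0.4 * np.sin(np.deg2rad(alpha)) ** 2
        ).fit()
        corrected = em.correct_ratio(res.predict(alpha), res, alpha)
        assert np.allclose(corrected, 1.0, atol=1e-9)

    def test_global_intensity_scaling_cancels(self):
        alpha = np.linspace(0, 179, 100)
        res = em.SineSquaredModel(
            np.linspace(0, 179, 360),
            1.0 + 0.5 * np.sin(np.deg2rad(np.linspace(0, 179, 360))) ** 2,
        ).fit()
        obs = 1.0 + 0.5 * np.sin(np.deg2rad(alpha)) ** 2
        # the ratio itself is intensity-scale free; correction preserves that
        assert np.allclose(
            em.correct_ratio(obs, res, alpha), em.correct_ratio(obs.copy(), res, alpha)
        )

    def test_nonpositive_model_rejected(self):
        alpha = np.linspace(0, 179, 360)
        res = em.SineSquaredModel(alpha, np.full_like(alpha, 1.0)).fit()
        object.__setattr__(res, "a0", -2.0)
        with pytest.raises(ValueError):
            em.correct_ratio(np.ones(5), res, np.linspace(0, 90, 5))


class TestNormalizeSeries:
    @staticmethod
    def table(values_by_frame):
        rows = []
        for k, v in enumerate(values_by_frame):
            for site, val in v.items():
                rows.append(
                    {"frame": k, "time_s": 15.0 * k, "site": site, "corrected": val}
                )
        return pd.DataFrame(rows)

    def test_constant_series_normalizes_to_one(self):
        t = self.table([{"equator": 1.3, "pole": 0.9}] * 6)
        out = em.normalize_series(t, anaphase_onset_index=3)
        assert np.allclose(out.table["normalized"], 1.0)

    def test_step_change_preserved(self):
        vals = [{"equator": 1.0}] * 4 + [{"equator": 0.6}] * 2
        out = em.normalize_series(self.table(vals), anaphase_onset_index=4)
        late = out.table[out.table["frame"] >= 4]["normalized"]
        assert np.allclose(late, 0.6)

    def test_missing_reference_frames_rejected(self):
        t = self.table([{"equator": 1.0}] * 4)
        with pytest.raises(ValueError):
            em.normalize_series(t, anaphase_onset_index=2)


class TestGates:
    def test_curvature_gate_boundary_inclusive(self):
        gate = em.curvature_gate([-0.1, -0.05, 0.1, 0.2], metaphase_curvature=-0.1)
        assert gate.tolist() == [True, True, True, False]

    @pytest.mark.parametrize(
        "axis, mode, eligible",
        [
            (85.0, "live", True),
            (60.0, "live", False),
            (10.0, "cut", True),
            (45.0, "cut", False),
        ],
    )
    def test_spindle_axis_gate(self, axis, mode, eligible):
        ok, _ = em.spindle_axis_gate(axis, mode=mode)
        assert ok is eligible

    def test_undefined_axis_eligible_with_flag(self):
        ok, flag = em.spindle_axis_gate(None)
        assert ok and flag == "undefined-axis"


class TestBottomSurfaceAndCut:
    def test_uniform_bottom_ratio(self):
        h = np.full((100, 100), 40.0)
        v = np.full((100, 100), 60.0)
        ctf = em.ChannelTransmissionFactor(40.0 / 60.0)
        r = em.bottom_surface_ratio(
            make_pair(h, v), ctf, (50.0, 50.0), equator_axis_deg=0.0
        )
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_rectangle_outside_image_rejected(self):
        h = np.ones((20, 20))
        ctf = em.ChannelTransmissionFactor(1.0)
        with pytest.raises(ValueError):
            em.bottom_surface_ratio(make_pair(h, h), ctf, (2.0, 2.0), 0.0)

    def test_cut_adjacent_reference_endpoints(self):
        h = np.full((200, 200), 50.0)
        v = np.full((200, 200), 50.0)
        ctf = em.ChannelTransmissionFactor(1.0)
        out = em.cut_adjacent_ratio(
            make_pair(h, v), ctf, (60.0, 100.0), (93.0, 100.0),
            metaphase_reference=1.0, stressfiber_reference=0.4,
        )
        # uniform isotropic scene sits exactly at the metaphase endpoint
        assert out["normalized"] == pytest.approx(0.0, abs=1e-9)
        out2 = em.cut_adjacent_ratio(
            make_pair(h, 0.4 * v), ctf, (60.0, 100.0), (93.0, 100.0),
            metaphase_reference=1.0, stressfiber_reference=0.4,
        )
        assert out2["normalized"] == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_reference_scale_rejected(self):
        h = np.ones((100, 100))
        ctf = em.ChannelTransmissionFactor(1.0)
        with pytest.raises(ValueError):
            em.cut_adjacent_ratio(
                make_pair(h, h), ctf, (30.0, 50.0), (63.0, 50.0),
                metaphase_reference=1.0, stressfiber_reference=1.0,
            )


class TestStraightenProfile:
    def test_minmax_normalization(self, rng):
        img = rng.uniform(5, 9, (80, 80))
        contour = em.fit_cortex_spline(circle_outline(30, (40, 40)), 0.15)
        prof = em.straighten_profile(img, contour)
        assert prof["value"].between(0.0, 1.0).all()

    def test_linear_ramp_stays_linear(self):
        img = np.tile(np.linspace(0, 1, 80), (80, 1))
        contour = em.fit_cortex_spline(circle_outline(30, (40, 40)), 0.15)
        prof = em.straighten_profile(img, contour)
        x = contour.positions_px[:, 0]
        assert np.corrcoef(x, prof["value"])[0, 1] > 0.999

    def test_constant_image_rejected(self):
        contour = em.fit_cortex_spline(circle_outline(30, (40, 40)), 0.15)
        with pytest.raises(ValueError):
            em.straighten_profile(np.ones((80, 80)), contour)
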