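"""Shared synthetic fixtures.

Rendering a cell scene takes a few seconds, so the expensive renders are
session-scoped and reused across tests.  All randomness is seeded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from polcortex import emission as em
from polcortex import polscope as ps
from polcortex import scenes as sc


@pytest.fixture(scope="session")
def sphere_scene():
    return sc.SceneConfig(noise=False, pixel_size_um=0.15, seed=1)


@pytest.fixture(scope="session")
def sphere_stack(sphere_scene):
    """Noiseless LC-PolScope stack of a kappa=0 sphere, with ground truth."""
    return sc.generate_polscope_stack(sphere_scene)


@pytest.fixture(scope="session")
def calibration_refs():
    plastic = sc.generate_calibration_samples("plastic", 2, noise=False)
    fibers = sc.generate_calibration_samples("stressfiber", 3, noise=False)
    return ps.calibration_from_stacks(plastic, fibers)


@pytest.fixture(scope="session")
def live_metaphase():
    """Noisy metaphase two-analyzer pair, its scene and ground truth."""
    scene = sc.default_live_scene(seed=3)
    kinetics = sc.DivisionKinetics()
    series = sc.generate_live_pair_series(scene, kinetics, n_frames=4, t_start_s=-60.0)
    return scene, series


@pytest.fixture(scope="session")
def live_ctf():
    scene = sc.default_live_scene(seed=3)
    h, v = sc.generate_plastic_pair(
        channel_gain_v=scene.channel_gain_v,
        depolarization_floor=scene.depolarization_floor,
        emission_floor=scene.emission_floor,
        seed=9,
    )
    return em.estimate_ctf(em.RatioPair(h, v, scene.pixel_size_um))


@pytest.fixture(scope="session")
def contour_pipeline():
    """The segmentation -> ridge-refined periodic spline helper."""
    return segment_and_spline


def segment_and_spline(pair_total, seed_point, furrow_point, pixel_size_um):
    """Segmentation -> ridge-refined periodic spline contour."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask, outline = ps.segment_cell(pair_total, seed_point, closing_radius=2)
    provisional = em.fit_cortex_spline(
        outline, pixel_size_um, furrow_point_px=furrow_point
    )
    refined = em.refine_contour_to_ridge(pair_total, provisional)
    contour = em.fit_cortex_spline(refined, pixel_size_um, furrow_point_px=furrow_point)
    return mask, contour


@pytest.fixture(scope="session")
def metaphase_samples(live_metaphase, live_ctf):
    """Cortex ratio samples of the first metaphase frame."""
    scene, series = live_metaphase
    frame = series.frames[0]
    pair = em.RatioPair(frame.horizontal, frame.vertical, scene.pixel_size_um)
    _, contour = segment_and_spline(
        frame.horizontal + frame.vertical,
        frame.truth.center_px,
        frame.truth.equator_anchor_px,
        scene.pixel_size_um,
    )
    return em.sample_cortex_ratio(pair, live_ctf, contour).dropna(subset=["ratio"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
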