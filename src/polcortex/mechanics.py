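"""Cortical mechanics readouts: laser-cut recoil, thickness, kymographs.

The cortical tension proxy is the initial outward movement of the cortex
after a 5-um linear laser cut: the distance between the two fluorescence
edges adjacent to the cut in the first post-ablation frame, minus a
baseline measured in myosin-inhibited cells (laser damage contribution).
The proxy is reported in um of displacement, never in force units.

Cortex thickness uses two-channel linescans (membrane marker vs actin):
after chromatic-shift correction, each channel is fitted with a Gaussian
in an 11-pixel window around its maximum, and thickness is twice the
center offset (the actin peak sits half a thickness inside the membrane).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = [
    "CutMeasurement",
    "ThicknessMeasurement",
    "initial_outward_movement",
    "baseline_correct",
    "fit_recoil",
    "cortex_thickness",
    "kymograph",
    "cortical_intensity_profile",
]


@dataclass
class CutMeasurement:
    """Edge distance and baseline-corrected tension proxy for one cut."""

    edge_distance_um: float
    baseline_um: float
    stage: str = ""
    orientation: str = ""  # perpendicular | parallel | 45deg

    @property
    def tension_proxy_um(self) -> float:
        return self.edge_distance_um - self.baseline_um

    @property
    def flagged_negative(self) -> bool:
        return self.tension_proxy_um < 0


@dataclass
class ThicknessMeasurement:
    center_membrane_um: float
    center_actin_um: float

    @property
    def thickness_um(self) -> float:
        return 2.0 * (self.center_membrane_um - self.center_actin_um)


def _band_profile(image, p0, p1, halfwidth_px, step=0.5):
    """Intensity profile along the normal of segment p0-p1, averaged over
    the segment extent.  Returns (offsets_px, profile)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    seg = p1 - p0
    length = np.linalg.norm(seg)
    u = seg / length
    n = np.array([-u[1], u[0]])
    along = np.linspace(0.15 * length, 0.85 * length, 25)
    offsets = np.arange(-halfwidth_px, halfwidth_px + 1e-9, step)
    base = p0[None, :] + along[:, None] * u[None, :]
    x = base[:, 0][:, None] + offsets[None, :] * n[0]
    y = base[:, 1][:, None] + offsets[None, :] * n[1]
    if x.min() < 0 or y.min() < 0 or x.max() > image.shape[1] - 1 or y.max() > image.shape[0] - 1:
        raise ValueError("cut-profile band exits the image")
    vals = ndimage.map_coordinates(
        np.asarray(image, float), np.stack([y.ravel(), x.ravel()]), order=1
    )
    return offsets, vals.reshape(x.shape).mean(axis=0)


def _half_max_crossing(offsets, profile, start_idx, direction, level):
    """Sub-pixel offset where the profile first rises through ``level``
    moving from start_idx in +/-1 index direction."""
    i = start_idx
    while 0 <= i + direction < len(profile):
        j = i + direction
        if profile[i] < level <= profile[j]:
            frac = (level - profile[i]) / (profile[j] - profile[i])
            return offsets[i] + frac * (offsets[j] - offsets[i])
        i = j
    raise ValueError("edge not detectable: no half-maximum crossing found")


def initial_outward_movement(
    pre_frame: np.ndarray,
    post_frame: np.ndarray,
    cut_start_px: tuple[float, float],
    cut_end_px: tuple[float, float],
    pixel_size_um: float,
    *,
    search_halfwidth_um: float = 5.0,
) -> dict:
    """Distance between the cortex edges flanking the cut (um).

    The post-ablation intensity profile across the cut (averaged along the
    path) shows a dark gap between two retracted edges; each edge is
    localized at the half-maximum crossing (half of the flanking cortex
    plateau, above the gap floor), sub-pixel by linear interpolation.
    ``pre_frame`` provides the undamaged reference level for diagnostics.
    """
    halfwidth_px = search_halfwidth_um / pixel_size_um
    offsets, post = _band_profile(post_frame, cut_start_px, cut_end_px, halfwidth_px)
    _, pre = _band_profile(pre_frame, cut_start_px, cut_end_px, halfwidth_px)
    mid = len(offsets) // 2
    gap_floor = post[mid - 1 : mid + 2].min()
    plateau = np.median(pre)
    if plateau <= gap_floor + 1e-9:
        raise ValueError(
            "edge not detectable: no intensity contrast between gap and cortex"
        )
    level = gap_floor + 0.5 * (plateau - gap_floor)
    right = _half_max_crossing(offsets, post, mid, +1, level)
    left = _half_max_crossing(offsets, post, mid, -1, level)
    return {
        "edge_distance_um": float((right - left) * pixel_size_um),
        "edge_left_um": float(left * pixel_size_um),
        "edge_right_um": float(right * pixel_size_um),
        "gap_floor": float(gap_floor),
        "plateau": float(plateau),
    }


def baseline_correct(
    edge_distance_um: float,
    baseline_table: pd.DataFrame | dict,
    stage: str,
    orientation: str,
) -> CutMeasurement:
    """Subtract the myosin-inhibited baseline for the matching condition.

    ``baseline_table`` maps (stage, orientation) to a baseline edge
    distance in um (a DataFrame with those columns plus ``baseline_um``,
    or a dict keyed by the tuple).  Negative proxies are flagged, not
    clipped.
    """
    if isinstance(baseline_table, dict):
        key = (stage, orientation)
        if key not in baseline_table:
            raise KeyError(f"no baseline entry for {key}")
        baseline = float(baseline_table[key])
    else:
        sel = baseline_table[
            (baseline_table["stage"] == stage)
            & (baseline_table["orientation"] == orientation)
        ]
        if sel.empty:
            raise KeyError(f"no baseline entry for ({stage}, {orientation})")
        baseline = float(sel["baseline_um"].iloc[0])
    return CutMeasurement(edge_distance_um, baseline, stage, orientation)


def fit_recoil(times_s, edge_distances_um):
    """Fit ``d(t) = offset + amplitude (1 - exp(-t/tau))`` to post-cut edges.

    Returns (offset_um, amplitude_um, tau_s).  The offset absorbs the
    ablated gap plus instantaneous damage; the amplitude is the
    tension-driven recoil.
    """
    t = np.asarray(times_s, float)
    d = np.asarray(edge_distances_um, float)

    def model(t, off, amp, tau):
        return off + amp * (1.0 - np.exp(-t / tau))

    span = max(d.max() - d.min(), 1e-6)
    popt, _ = optimize.curve_fit(
        model,
        t,
        d,
        p0=[d[0], span, max(t.max() / 3.0, 1e-3)],
        maxfev=10_000,
    )
    return float(popt[0]), float(popt[1]), float(abs(popt[2]))


def _gaussian(x, amp, center, sigma, offset):
    return offset + amp * np.exp(-((x - center) ** 2) / (2 * sigma**2))


def _fit_gaussian_center(x, y, window_px: int = 11) -> float:
    imax = int(np.argmax(y))
    half = window_px // 2
    if imax - half < 0 or imax + half >= len(y):
        raise ValueError("profile maximum at the border; cannot fit Gaussian")
    sel = slice(imax - half, imax + half + 1)
    popt, _ = optimize.curve_fit(
        _gaussian,
        x[sel],
        y[sel],
        p0=[y[imax] - y[sel].min(), x[imax], 2 * (x[1] - x[0]), y[sel].min()],
        maxfev=10_000,
    )
    return float(popt[1])


def cortex_thickness(
    positions_um: np.ndarray,
    membrane_profile: np.ndarray,
    actin_profile: np.ndarray,
    *,
    chromatic_shift_um: tuple[float, float] = (0.0, 0.0),
    line_direction_deg: float = 0.0,
    fit_window_px: int = 11,
) -> ThicknessMeasurement:
    """Cortex thickness from a membrane/actin linescan pair.

    The chromatic shift (x, y, um; measured on multicolor beads) is
    projected onto the line direction and removed from the actin channel;
    each channel is then fitted with a Gaussian restricted to an 11-pixel
    window centered on the profile maximum.  Thickness is
    ``2 (X_membrane - X_actin)``.
    """
    x = np.asarray(positions_um, float)
    direction = np.array(
        [np.cos(np.deg2rad(line_direction_deg)), np.sin(np.deg2rad(line_direction_deg))]
    )
    shift = float(np.asarray(chromatic_shift_um) @ direction)
    cm = _fit_gaussian_center(x, np.asarray(membrane_profile, float), fit_window_px)
    ca = _fit_gaussian_center(x, np.asarray(actin_profile, float), fit_window_px)
    return ThicknessMeasurement(cm, ca - shift)


def kymograph(
    frames: list[np.ndarray] | np.ndarray,
    line_start_px: tuple[float, float],
    line_end_px: tuple[float, float],
    width_px: int = 25,
) -> np.ndarray:
    """Arc-position x time image along a wide line (pole-to-pole reslice).

    Per frame, intensity is averaged across ``width_px`` samples
    perpendicular to the line; rows are stacked over time.
    """
    p0 = np.asarray(line_start_px, float)
    p1 = np.asarray(line_end_px, float)
    seg = p1 - p0
    length = np.linalg.norm(seg)
    u = seg / length
    n = np.array([-u[1], u[0]])
    n_samples = int(np.ceil(length)) + 1
    along = np.linspace(0.0, length, n_samples)
    lateral = (np.arange(width_px) - (width_px - 1) / 2.0) if width_px > 1 else np.array([0.0])
    rows = []
    for frame in frames:
        frame = np.asarray(frame, float)
        x = p0[0] + along[:, None] * u[0] + lateral[None, :] * n[0]
        y = p0[1] + along[:, None] * u[1] + lateral[None, :] * n[1]
        if x.min() < 0 or y.min() < 0 or x.max() > frame.shape[1] - 1 or y.max() > frame.shape[0] - 1:
            raise ValueError("kymograph line exits the frame")
        vals = ndimage.map_coordinates(frame, np.stack([y.ravel(), x.ravel()]), order=1)
        rows.append(vals.reshape(x.shape).mean(axis=1))
    return np.asarray(rows)


def cortical_intensity_profile(
    frames: list[np.ndarray],
    contours: list[np.ndarray],
    anchors: list,
    times_s: np.ndarray,
    pixel_size_um: float,
    *,
    anaphase_onset_s: float = 0.0,
    window_um: float = 4.0,
    n_reference_frames: int = 3,
    profile_from_s: float = 180.0,
    background: float = 0.0,
) -> dict:
    """Normalized cortical intensity time courses and late spatial profile.

    Per frame, background-subtracted intensity is averaged in ``window_um``
    arc windows centered at the equator and pole anchors; the courses are
    normalized by the mean of the last ``n_reference_frames`` frames before
    anaphase onset.  The spatial profile averages the per-frame cortical
    line profiles from ``profile_from_s`` after onset, max-normalized.
    """
    from .polscope import contour_arc_length

    times = np.asarray(times_s, float)
    eq_vals, pole_vals, late_profiles = [], [], []
    ref_arc = None
    for frame, contour, anch in zip(frames, contours, anchors):
        img = np.asarray(frame, float) - background
        contour = np.asarray(contour, float)
        arc = contour_arc_length(contour, pixel_size_um)
        total = arc[-1] + np.linalg.norm(contour[0] - contour[-1]) * pixel_size_um
        coords = np.stack([contour[:, 1], contour[:, 0]])
        prof = ndimage.map_coordinates(img, coords, order=1, mode="nearest")

        def window_mean(center_idx):
            d = np.abs(arc - arc[center_idx])
            d = np.minimum(d, total - d)
            sel = d <= window_um / 2.0
            return float(prof[sel].mean())

        eq_vals.append(
            np.mean([window_mean(i) for i in anch.equator_idx])
        )
        pole_vals.append(np.mean([window_mean(i) for i in anch.pole_idx]))
    eq_vals = np.asarray(eq_vals)
    pole_vals = np.asarray(pole_vals)
    pre = times < anaphase_onset_s
    if pre.sum() < n_reference_frames:
        raise ValueError("missing pre-anaphase reference frames")
    ref_idx = np.flatnonzero(pre)[-n_reference_frames:]
    out = pd.DataFrame(
        {
            "time_s": times,
            "equator": eq_vals / eq_vals[ref_idx].mean(),
            "pole": pole_vals / pole_vals[ref_idx].mean(),
        }
    )
    # late spatial profile aligned on the equator anchor
    profiles = []
    for k, (frame, contour, anch) in enumerate(zip(frames, contours, anchors)):
        if times[k] < anaphase_onset_s + profile_from_s:
            continue
        img = np.asarray(frame, float) - background
        contour = np.asarray(contour, float)
        arc = contour_arc_length(contour, pixel_size_um)
        total = arc[-1] + np.linalg.norm(contour[0] - contour[-1]) * pixel_size_um
        coords = np.stack([contour[:, 1], contour[:, 0]])
        prof = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
        rel = arc - arc[anch.equator_idx[0]]
        rel = (rel + total / 2.0) % total - total / 2.0
        order = np.argsort(rel)
        grid = np.linspace(-total / 2, total / 2, 301)
        profiles.append(np.interp(grid, rel[order], prof[order]))
        ref_arc = grid
    spatial = None
    if profiles:
        spatial = np.mean([p / max(p.max(), 1e-12) for p in profiles], axis=0)
    return {"time_course": out, "profile_arc_um": ref_arc, "profile": spatial}
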