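"""Live-cell two-polarizer emission-ratio pipeline.

With a fixed 90-degree polarized excitation and two sequentially recorded
emission analyzers (horizontal, 0 deg; vertical, 90 deg), relative changes
of cortical filament orientation are read out as the emission ratio

    r(x) = I_vertical(x) * CTF / I_horizontal(x)

the co-polarized (parallel to the excitation) channel over the
cross-polarized one.  The channel transmission factor (CTF), measured as
the horizontal/vertical pixel ratio of an isotropic fluorescent-plastic
sample, scales the vertical channel so an isotropic specimen gives r = 1.
With this orientation the metaphase geometry regression has a positive
sine-squared amplitude and equatorial filament alignment drives the
furrow ratio below 1.  At a central optical section the ratio also
depends on the cortex orientation relative to the excitation polarization;
this geometry contribution is removed with a regression model fitted on
metaphase cells (whose cortical network is orientationally random):

    R(alpha) = a0 + a1 * sin^2(alpha * pi / 180)

with alpha the local cortex tangent angle in degrees (from a periodic
B-spline fit of the segmented outline).  Dividing the observed ratio by
R(alpha) yields the corrected ratio (1 along a metaphase cortex); dividing
by the mean of three pre-anaphase frames yields the normalized ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage

__all__ = [
    "RatioPair",
    "ChannelTransmissionFactor",
    "CortexContour",
    "SineSquaredModel",
    "SineSquaredResults",
    "NormalizedRatioSeries",
    "estimate_ctf",
    "background_subtract",
    "fit_cortex_spline",
    "sample_cortex_ratio",
    "fit_geometry_model",
    "correct_ratio",
    "normalize_series",
    "curvature_gate",
    "spindle_axis_gate",
    "bottom_surface_ratio",
    "cut_adjacent_ratio",
    "straighten_profile",
]


@dataclass
class RatioPair:
    """One horizontal/vertical analyzer image pair."""

    horizontal: np.ndarray
    vertical: np.ndarray
    pixel_size_um: float
    background_roi: tuple[slice, slice] | None = None

    def __post_init__(self):
        self.horizontal = np.asarray(self.horizontal, float)
        self.vertical = np.asarray(self.vertical, float)
        if self.horizontal.shape != self.vertical.shape:
            raise ValueError("channel images must share a shape")


@dataclass
class ChannelTransmissionFactor:
    """Transmission imbalance of the two emission analyzers.

    Measured as the robust (median) horizontal/vertical pixel ratio of an
    isotropic reference sample; the vertical channel is multiplied by the
    CTF before ratios are formed.
    """

    ctf: float | np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.ctf) <= 0):
            raise ValueError("CTF must be > 0")

    @property
    def scalar(self) -> float:
        return float(np.median(np.asarray(self.ctf)))


def estimate_ctf(plastic_pair: RatioPair, per_pixel: bool = False) -> ChannelTransmissionFactor:
    """CTF from a fluorescent-plastic (isotropic dipole) analyzer pair."""
    h, v = plastic_pair.horizontal, plastic_pair.vertical
    valid = (h > 0) & (v > 0)
    if not valid.any():
        raise ValueError("plastic pair contains no positive pixels")
    if per_pixel:
        ctf = np.where(valid, h / np.where(valid, v, 1.0), np.nan)
        ctf = np.where(np.isnan(ctf), np.nanmedian(ctf), ctf)
        return ChannelTransmissionFactor(ctf)
    return ChannelTransmissionFactor(float(np.median(h[valid] / v[valid])))


def background_subtract(pair: RatioPair) -> tuple[RatioPair, dict]:
    """Subtract the mean intensity of the outside-cell ROI per channel.

    Negative pixels (noise driven) are clipped to zero; the clip counts are
    reported for QC.
    """
    if pair.background_roi is None:
        raise ValueError("background_roi is not defined")
    roi = pair.background_roi
    out = []
    qc = {}
    for name, img in (("horizontal", pair.horizontal), ("vertical", pair.vertical)):
        level = float(img[roi].mean())
        sub = img - level
        qc[f"{name}_background"] = level
        qc[f"{name}_clipped_px"] = int((sub < 0).sum())
        out.append(np.clip(sub, 0.0, None))
    corrected = RatioPair(out[0], out[1], pair.pixel_size_um, pair.background_roi)
    return corrected, qc


@dataclass
class CortexContour:
    """Smoothed cortical path with per-position tangent angles.

    Positions are sub-pixel (x, y); ``tangent_deg`` in [0, 180);
    ``arc_um`` is signed arc length with 0 at the furrow midpoint.
    """

    positions_px: np.ndarray  # (N, 2)
    tangent_deg: np.ndarray  # (N,)
    arc_um: np.ndarray  # (N,)
    pixel_size_um: float
    furrow_index: int = 0
    subregions: dict | None = None

    def normals(self) -> np.ndarray:
        t = np.deg2rad(self.tangent_deg)
        return np.column_stack([-np.sin(t), np.cos(t)])


def fit_cortex_spline(
    outline_px: np.ndarray,
    pixel_size_um: float,
    *,
    furrow_point_px: tuple[float, float] | None = None,
    n_points: int = 800,
    smoothing_factor: float = 3.0,
    subregion_length_um: float | None = None,
) -> CortexContour:
    """Periodic smoothing B-spline through a closed segmented outline.

    Tangent angles come from the spline derivative; consecutive angles are
    continuous modulo 180 deg.  The smoothing budget adapts to the
    outline's local roughness (estimated from neighbor-midpoint residuals),
    so analytic contours are followed closely while stair-stepped pixel
    outlines are genuinely smoothed.  The position nearest
    ``furrow_point_px`` becomes arc position 0 (furrow midpoint).  If
    ``subregion_length_um`` is given, the contour is split into four
    sub-regions of that arc length centered on the furrow/pole positions
    (the quarter-turn points).
    """
    outline = np.asarray(outline_px, float)
    if len(outline) < 8:
        raise ValueError("outline too short")
    if np.linalg.norm(outline[0] - outline[-1]) > max(
        4.0, 0.05 * len(outline)
    ) and not np.allclose(outline[0], outline[-1]):
        raise ValueError("outline is not closed")
    pts = outline[:-1] if np.allclose(outline[0], outline[-1]) else outline
    # light decimation keeps splprep well conditioned on pixel-dense outlines
    step = max(1, len(pts) // 400)
    pts = pts[::step]
    mid = (np.roll(pts, 1, axis=0) + np.roll(pts, -1, axis=0)) / 2.0
    roughness = (2.0 / 3.0) * float(np.mean(np.sum((pts - mid) ** 2, axis=1)))
    tck, _ = interpolate.splprep(
        [pts[:, 0], pts[:, 1]],
        per=True,
        s=smoothing_factor * len(pts) * max(roughness, 1e-8),
    )
    u = np.linspace(0.0, 1.0, n_points, endpoint=False)
    x, y = interpolate.splev(u, tck)
    dx, dy = interpolate.splev(u, tck, der=1)
    positions = np.column_stack([x, y])
    tangent = np.rad2deg(np.arctan2(dy, dx)) % 180.0
    steps = np.linalg.norm(np.diff(positions, axis=0, prepend=positions[-1:]), axis=1)
    arc = np.cumsum(steps) * pixel_size_um
    arc -= arc[0]
    if furrow_point_px is not None:
        furrow_index = int(
            np.argmin(np.linalg.norm(positions - np.asarray(furrow_point_px), axis=1))
        )
    else:
        furrow_index = 0
    total = arc[-1] + steps[0] * pixel_size_um
    arc = arc - arc[furrow_index]
    arc = (arc + total / 2.0) % total - total / 2.0  # signed, furrow at 0
    subregions = None
    if subregion_length_um is not None:
        subregions = {}
        for name, frac in (
            ("furrow", 0.0),
            ("pole_0", 0.25),
            ("furrow_opposite", 0.5),
            ("pole_1", 0.75),
        ):
            center = (furrow_index + int(frac * n_points)) % n_points
            d = np.abs(arc - arc[center])
            d = np.minimum(d, total - d)
            subregions[name] = np.flatnonzero(d <= subregion_length_um / 2.0)
    return CortexContour(
        positions, tangent, arc, pixel_size_um, furrow_index, subregions
    )


def refine_contour_to_ridge(
    intensity: np.ndarray,
    contour: CortexContour,
    *,
    halfwidth_px: float = 6.0,
    step_px: float = 0.5,
) -> np.ndarray:
    """Snap contour points to the cortical intensity ridge along the normals.

    A watershed outline follows the outer gradient edge of the blurred
    cortex band rather than its center; each point is moved to the
    parabolic-interpolated intensity maximum within ``halfwidth_px`` along
    the local normal so the sampling band is centered on the cortex signal.
    Returns the refined (N, 2) positions.
    """
    img = np.asarray(intensity, float)
    offsets = np.arange(-halfwidth_px, halfwidth_px + 1e-9, step_px)
    normals = contour.normals()
    sx = contour.positions_px[:, 0][:, None] + offsets[None, :] * normals[:, 0][:, None]
    sy = contour.positions_px[:, 1][:, None] + offsets[None, :] * normals[:, 1][:, None]
    vals = ndimage.map_coordinates(
        img, np.stack([sy.ravel(), sx.ravel()]), order=1, mode="nearest"
    ).reshape(sx.shape)
    imax = np.argmax(vals, axis=1)
    shift = offsets[imax].astype(float)
    interior = (imax > 0) & (imax < len(offsets) - 1)
    i = imax[interior]
    rows = np.flatnonzero(interior)
    y0, y1, y2 = (
        vals[rows, i - 1],
        vals[rows, i],
        vals[rows, i + 1],
    )
    denom = y0 - 2 * y1 + y2
    ok = np.abs(denom) > 1e-12
    frac = np.zeros_like(y1)
    frac[ok] = 0.5 * (y0 - y2)[ok] / denom[ok]
    shift[rows] += np.clip(frac, -1.0, 1.0) * step_px
    return contour.positions_px + shift[:, None] * normals


def sample_cortex_ratio(
    pair: RatioPair,
    ctf: ChannelTransmissionFactor,
    contour: CortexContour,
    *,
    normal_halfwidth_px: int = 3,
) -> pd.DataFrame:
    """Observed emission ratio per contour position.

    Each channel is averaged over ``2 * normal_halfwidth_px + 1`` samples
    along the local contour normal (the segmented pixel as the center, a
    band wide enough to contain the cortex signal even under a small
    inter-channel shift), then ratio = V * CTF / H.  Positions whose
    normal band leaves the image are masked (NaN ratio).
    """
    offsets = np.arange(-normal_halfwidth_px, normal_halfwidth_px + 1)
    normals = contour.normals()
    sx = contour.positions_px[:, 0][:, None] + offsets[None, :] * normals[:, 0][:, None]
    sy = contour.positions_px[:, 1][:, None] + offsets[None, :] * normals[:, 1][:, None]
    h_img, v_img = pair.horizontal, pair.vertical
    inside = (
        (sx >= 0) & (sx <= h_img.shape[1] - 1) & (sy >= 0) & (sy <= h_img.shape[0] - 1)
    ).all(axis=1)
    coords = np.stack([sy.ravel(), sx.ravel()])
    h_samp = ndimage.map_coordinates(h_img, coords, order=1, mode="nearest")
    v_samp = ndimage.map_coordinates(v_img, coords, order=1, mode="nearest")
    h_mean = h_samp.reshape(sx.shape).mean(axis=1)
    v_mean = v_samp.reshape(sx.shape).mean(axis=1)
    v_corr = v_mean * ctf.scalar
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((h_mean > 0) & inside, v_corr / h_mean, np.nan)
    return pd.DataFrame(
        {
            "arc_um": contour.arc_um,
            "tangent_deg": contour.tangent_deg,
            "intensity_h": h_mean,
            "intensity_v": v_mean,
            "ratio": ratio,
        }
    )


@dataclass
class SineSquaredResults:
    """Fitted geometry-correction regression R(alpha) = a0 + a1 sin^2(alpha)."""

    a0: float
    a1: float
    bse: tuple[float, float]
    rsquared: float
    nobs: int
    _sm_results: object | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a0, self.a1])

    def predict(self, tangent_deg) -> np.ndarray:
        alpha = np.deg2rad(np.asarray(tangent_deg, float))
        out = self.a0 + self.a1 * np.sin(alpha) ** 2
        return float(out) if out.ndim == 0 else out

    def summary(self):
        if self._sm_results is not None:
            return self._sm_results.summary()
        return (
            f"R(alpha) = {self.a0:.4f} + {self.a1:.4f} sin^2(alpha)  "
            f"(R^2 = {self.rsquared:.4f}, n = {self.nobs})"
        )


class SineSquaredModel:
    """OLS regression of emission ratio on sin^2 of the tangent angle.

    Fitted on metaphase data only, where the cortical network is random and
    all ratio modulation is geometric.
    """

    def __init__(self, tangent_deg, ratio):
        tangent = np.asarray(tangent_deg, float)
        ratio = np.asarray(ratio, float)
        keep = np.isfinite(tangent) & np.isfinite(ratio)
        self.tangent_deg = tangent[keep]
        self.ratio = ratio[keep]
        span = self._angle_span(self.tangent_deg)
        if span < 90.0:
            raise ValueError(
                f"tangent angles span only {span:.1f} deg (< 90): "
                "sin^2 regression is ill conditioned"
            )

    @staticmethod
    def _angle_span(deg):
        """Covered extent of the mod-180 angles: 180 minus the largest gap."""
        if len(deg) < 3:
            return 0.0
        a = np.sort(np.asarray(deg, float) % 180.0)
        gaps = np.diff(np.concatenate([a, [a[0] + 180.0]]))
        return float(180.0 - gaps.max())

    def fit(self) -> SineSquaredResults:
        import statsmodels.api as sm

        x = np.sin(np.deg2rad(self.tangent_deg)) ** 2
        exog = sm.add_constant(x)
        res = sm.OLS(self.ratio, exog).fit()
        return SineSquaredResults(
            a0=float(res.params[0]),
            a1=float(res.params[1]),
            bse=(float(res.bse[0]), float(res.bse[1])),
            rsquared=float(res.rsquared),
            nobs=int(res.nobs),
            _sm_results=res,
        )


def fit_geometry_model(samples: pd.DataFrame) -> SineSquaredResults:
    """Fit the sin^2 geometry model to metaphase ratio-vs-angle samples."""
    return SineSquaredModel(samples["tangent_deg"], samples["ratio"]).fit()


def correct_ratio(
    observed_ratio, model: SineSquaredResults, tangent_deg
) -> np.ndarray:
    """Divide the observed ratio by the fitted geometry model (corrected ratio)."""
    expected = model.predict(tangent_deg)
    if np.any(np.asarray(expected) <= 0):
        raise ValueError("geometry model predicts non-positive ratio")
    out = np.asarray(observed_ratio, float) / expected
    return float(out) if out.ndim == 0 else out


@dataclass
class NormalizedRatioSeries:
    """Per-frame equator/pole corrected ratios and their normalized course."""

    table: pd.DataFrame  # frame, time_s, site, corrected, normalized
    reference: dict  # site -> pre-anaphase mean corrected ratio


def normalize_series(
    per_frame_site_values: pd.DataFrame,
    anaphase_onset_index: int,
    n_reference_frames: int = 3,
) -> NormalizedRatioSeries:
    """Divide corrected site ratios by their pre-anaphase reference mean.

    ``per_frame_site_values`` needs columns frame, time_s, site, corrected.
    The reference is the mean over the last ``n_reference_frames`` frames
    before ``anaphase_onset_index``; the mean of those frames is 1 by
    construction in the output.
    """
    df = per_frame_site_values.copy()
    pre = df[df["frame"] < anaphase_onset_index]
    if pre["frame"].nunique() < n_reference_frames:
        raise ValueError(
            f"need >= {n_reference_frames} frames before anaphase onset"
        )
    ref_frames = sorted(pre["frame"].unique())[-n_reference_frames:]
    reference = (
        pre[pre["frame"].isin(ref_frames)].groupby("site")["corrected"].mean().to_dict()
    )
    df["normalized"] = df.apply(
        lambda row: row["corrected"] / reference[row["site"]], axis=1
    )
    return NormalizedRatioSeries(df, reference)


def measure_site_ratios(
    samples: pd.DataFrame,
    model: SineSquaredResults,
    *,
    site_window_um: float = 1.0,
) -> dict[str, float]:
    """Corrected ratio averaged in 1-um windows at the equator and poles.

    ``samples`` comes from :func:`sample_cortex_ratio` (arc 0 = furrow
    midpoint).  The equator value averages the two opposing furrow-side
    windows (arc 0 and half the perimeter), the pole value the two
    quarter-perimeter windows.
    """
    s = samples.dropna(subset=["ratio"])
    arc = s["arc_um"].to_numpy()
    corrected = correct_ratio(s["ratio"].to_numpy(), model, s["tangent_deg"].to_numpy())
    total = arc.max() - arc.min()

    def window_mean(center):
        d = np.abs(arc - center)
        d = np.minimum(d, total - d)
        sel = d <= site_window_um / 2.0
        if not sel.any():
            return np.nan
        return float(corrected[sel].mean())

    # arc is signed with the furrow midpoint at 0: the opposing furrow side
    # sits half a perimeter away (wrap), the poles at +/- a quarter
    eq = np.nanmean([window_mean(0.0), window_mean(total / 2.0)])
    pole = np.nanmean([window_mean(total / 4.0), window_mean(-total / 4.0)])
    return {"equator": float(eq), "pole": float(pole)}


def analyze_live_series(
    pairs: list[RatioPair],
    ctf: ChannelTransmissionFactor,
    seed_points: list[tuple[float, float]],
    furrow_points: list[tuple[float, float]],
    times_s,
    anaphase_onset_index: int,
    *,
    model: SineSquaredResults | None = None,
    n_metaphase_fit_frames: int = 3,
    site_window_um: float = 1.0,
) -> tuple[NormalizedRatioSeries, SineSquaredResults]:
    """Full live-cell pipeline over a frame series.

    Per frame: seeded-watershed segmentation of the summed channels,
    periodic B-spline contour with the furrow midpoint at arc 0, 7-pixel
    normal-averaged channel sampling, ratio per Eq. r = H/(V*CTF).  The
    geometry model is fitted on the pre-anaphase (metaphase) frames unless
    given, applied to all frames, and the site values are normalized to
    the pre-anaphase reference.
    """
    from .polscope import segment_cell

    if len(pairs) != len(seed_points) or len(pairs) != len(furrow_points):
        raise ValueError("pairs, seed_points and furrow_points must align")
    all_samples = []
    for pair, seed, furrow in zip(pairs, seed_points, furrow_points):
        total = pair.horizontal + pair.vertical
        _, outline = segment_cell(total, seed, closing_radius=2)
        provisional = fit_cortex_spline(
            outline, pair.pixel_size_um, furrow_point_px=furrow
        )
        refined = refine_contour_to_ridge(total, provisional)
        contour = fit_cortex_spline(
            refined, pair.pixel_size_um, furrow_point_px=furrow
        )
        all_samples.append(sample_cortex_ratio(pair, ctf, contour))
    if model is None:
        fit_frames = range(
            max(0, anaphase_onset_index - n_metaphase_fit_frames), anaphase_onset_index
        )
        meta = pd.concat([all_samples[i] for i in fit_frames])
        model = fit_geometry_model(meta.dropna(subset=["ratio"]))
    rows = []
    times = np.asarray(times_s, float)
    for k, samples in enumerate(all_samples):
        sites = measure_site_ratios(samples, model, site_window_um=site_window_um)
        for site, value in sites.items():
            rows.append(
                {"frame": k, "time_s": times[k], "site": site, "corrected": value}
            )
    series = normalize_series(pd.DataFrame(rows), anaphase_onset_index)
    return series, model


def curvature_gate(
    curvature_series, metaphase_curvature: float
) -> np.ndarray:
    """Frames whose |furrow curvature| does not exceed the metaphase value.

    Boundary equality is admissible (<=).  Returns a boolean mask.
    """
    kappa = np.asarray(curvature_series, float)
    return np.abs(kappa) <= abs(metaphase_curvature)


def spindle_axis_gate(
    spindle_axis_deg: float | None,
    *,
    mode: str = "live",
    tolerance_deg: float = 20.0,
) -> tuple[bool, str]:
    """Eligibility of a cell by spindle-axis alignment.

    Live central-section series require the axis within +/-20 deg of 90;
    laser-cutting experiments accept 90 +/- 20 or 0 +/- 20.  A cell without
    a defined axis (metaphase, single chromatin mass) is eligible with an
    ``undefined-axis`` flag.
    """
    if spindle_axis_deg is None:
        return True, "undefined-axis"
    axis = float(spindle_axis_deg) % 180.0
    targets = (90.0,) if mode == "live" else (90.0, 0.0)
    for t in targets:
        d = abs(axis - t)
        if min(d, 180.0 - d) <= tolerance_deg:
            return True, "ok"
    return False, "misaligned"


def _rectangle_mean(img, center_px, long_axis_deg, length_px, width_px):
    t = np.deg2rad(long_axis_deg)
    u = np.array([np.cos(t), np.sin(t)])
    v = np.array([-np.sin(t), np.cos(t)])
    nl = max(2, int(np.ceil(length_px)))
    nw = max(2, int(np.ceil(width_px)))
    lu = np.linspace(-length_px / 2, length_px / 2, nl)
    lv = np.linspace(-width_px / 2, width_px / 2, nw)
    LU, LV = np.meshgrid(lu, lv, indexing="ij")
    x = center_px[0] + LU * u[0] + LV * v[0]
    y = center_px[1] + LU * u[1] + LV * v[1]
    if x.min() < 0 or y.min() < 0 or x.max() > img.shape[1] - 1 or y.max() > img.shape[0] - 1:
        raise ValueError("sampling rectangle exits the image")
    vals = ndimage.map_coordinates(img, np.stack([y.ravel(), x.ravel()]), order=1)
    return float(vals.mean())


def bottom_surface_ratio(
    pair: RatioPair,
    ctf: ChannelTransmissionFactor,
    equator_center_px: tuple[float, float],
    equator_axis_deg: float,
    *,
    length_um: float = 4.0,
    width_um: float = 1.0,
) -> float:
    """Mean V*CTF/H ratio in a 1 x 4 um rectangle at the cell equator.

    For bottom-section (planar cortex) acquisitions; no tangent-angle
    correction applies.  The long axis runs along the equator line.
    """
    px = pair.pixel_size_um
    h = _rectangle_mean(
        pair.horizontal, equator_center_px, equator_axis_deg, length_um / px, width_um / px
    )
    v = _rectangle_mean(
        pair.vertical, equator_center_px, equator_axis_deg, length_um / px, width_um / px
    )
    if h <= 0:
        raise ValueError("horizontal-channel rectangle mean is non-positive")
    return v * ctf.scalar / h


def cut_adjacent_ratio(
    pair: RatioPair,
    ctf: ChannelTransmissionFactor,
    cut_start_px: tuple[float, float],
    cut_end_px: tuple[float, float],
    *,
    metaphase_reference: float,
    stressfiber_reference: float,
    square_um: float = 2.0,
    clearance_um: float = 1.5,
) -> dict[str, float]:
    """Normalized emission ratio adjacent to a laser cut.

    Four 2 x 2 um squares sit perpendicular and adjacent to the cut, two on
    each side; their mean ratio is min-max normalized between the metaphase
    (random network) and stress-fiber (aligned) reference medians.
    """
    if abs(stressfiber_reference - metaphase_reference) < 1e-12:
        raise ValueError("degenerate reference scale")
    p0 = np.asarray(cut_start_px, float)
    p1 = np.asarray(cut_end_px, float)
    seg = p1 - p0
    length = np.linalg.norm(seg)
    u = seg / length
    n = np.array([-u[1], u[0]])
    px = pair.pixel_size_um
    off = (clearance_um + square_um / 2.0) / px
    centers = []
    for frac in (0.25, 0.75):
        base = p0 + frac * length * u
        centers += [base + off * n, base - off * n]
    axis_deg = float(np.rad2deg(np.arctan2(u[1], u[0])))
    ratios = []
    for c in centers:
        h = _rectangle_mean(pair.horizontal, c, axis_deg, square_um / px, square_um / px)
        v = _rectangle_mean(pair.vertical, c, axis_deg, square_um / px, square_um / px)
        if h <= 0:
            raise ValueError("horizontal-channel square mean is non-positive")
        ratios.append(v * ctf.scalar / h)
    mean_ratio = float(np.mean(ratios))
    normalized = (mean_ratio - metaphase_reference) / (
        stressfiber_reference - metaphase_reference
    )
    return {"ratio": mean_ratio, "normalized": normalized, "n_squares": len(ratios)}


def straighten_profile(image: np.ndarray, contour: CortexContour) -> pd.DataFrame:
    """Display profile along the cortex, image-normalized to [0, 1].

    The image is first normalized by subtracting its minimum and dividing
    by its maximum (so 0 maps to the darkest and 1 to the brightest pixel),
    then sampled along the contour positions.
    """
    img = np.asarray(image, float)
    lo, hi = img.min(), img.max()
    if hi - lo <= 0:
        raise ValueError("constant image cannot be normalized")
    norm = (img - lo) / (hi - lo)
    coords = np.stack([contour.positions_px[:, 1], contour.positions_px[:, 0]])
    vals = ndimage.map_coordinates(norm, coords, order=1, mode="nearest")
    return pd.DataFrame({"arc_um": contour.arc_um, "value": vals})
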