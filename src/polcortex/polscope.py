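"""Fixed-cell LC-PolScope pipeline: per-pixel polarization factor and azimuth.

The acquisition is a stack of four frames recorded with linearly polarized
excitation at 0, 45, 90 and 135 degrees plus a fifth 0-degree frame used to
correct acquisition photobleaching.  Per pixel,

    a = I0 - I90,  b = I45 - I135,  c = I0 + I45 + I90 + I135
    p = sqrt(a^2 + b^2) / c
    azimuth = 0.5 * atan2(b, a)   (mapped to [0, 180) degrees)

p is normalized against two calibration references: a maximally aligned
in-plane dipole sample (stress fibers, p_norm = 1) and an isotropic sample
(fluorescent plastic, p_norm = 0).

Region extraction follows the segmented cell contour: an ellipse fit locates
two equatorial and two polar anchors; arc-length windows (2 um equator,
16 um poles) dilated to a 640 nm band normal to the contour define the
measurement regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, spatial
from skimage import filters, measure, morphology, segmentation

__all__ = [
    "PolStack",
    "AnisotropyImage",
    "CalibrationRefs",
    "AmbiguousAxesWarning",
    "bleach_correct",
    "anisotropy_image",
    "normalize_polarization",
    "segment_cell",
    "locate_equator_poles",
    "cortical_regions",
    "region_polarization",
    "anisotropic_zone_width",
    "contour_arc_length",
    "calibration_from_stacks",
]

POLSCOPE_ANGLES = (0.0, 45.0, 90.0, 135.0, 0.0)


class AmbiguousAxesWarning(UserWarning):
    """Ellipse axes too close to circular to assign equator and poles."""


@dataclass
class PolStack:
    """One five-frame excitation-polarization acquisition.

    Frames are in acquisition order 0, 45, 90, 135, 0 degrees; the repeated
    0-degree frame supports photobleaching correction.
    """

    frames: np.ndarray  # (5, H, W)
    pixel_size_um: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != 5:
            raise ValueError("PolStack requires 5 frames (0,45,90,135,0 deg)")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def mean_image(self) -> np.ndarray:
        """Average of the four distinct-angle frames (watershed input)."""
        return self.frames[:4].mean(axis=0)


@dataclass
class AnisotropyImage:
    """Per-pixel polarization factor, dipole azimuth and mean intensity."""

    p: np.ndarray
    azimuth_deg: np.ndarray  # NaN where masked
    mean_intensity: np.ndarray  # c / 4
    mask: np.ndarray  # True where p/azimuth are valid
    pixel_size_um: float


@dataclass
class CalibrationRefs:
    """Median polarization factors of the two calibration samples."""

    p_plastic: float
    p_stressfibers: float

    def __post_init__(self):
        if not self.p_stressfibers > self.p_plastic >= 0:
            raise ValueError("need p_stressfibers > p_plastic >= 0")


def bleach_correct(stack: PolStack) -> np.ndarray:
    """Multiplicative photobleaching correction using the repeated frame.

    The global ratio sum(frame1)/sum(frame5) gives the total signal loss
    over the acquisition; per-frame factors are interpolated geometrically
    in acquisition index (frame k scaled by ratio**(k/4)), which is exact
    for a constant per-frame bleach fraction.  Returns the four corrected
    distinct-angle frames.
    """
    total_first = float(stack.frames[0].sum())
    total_last = float(stack.frames[4].sum())
    if total_last <= 0:
        raise ValueError("frame-5 total intensity is zero; cannot bleach-correct")
    ratio = total_first / total_last
    factors = ratio ** (np.arange(4) / 4.0)
    return stack.frames[:4] * factors[:, None, None]


def anisotropy_image(
    frames: np.ndarray, pixel_size_um: float = 1.0, intensity_floor: float = 1e-9
) -> AnisotropyImage:
    """Per-pixel polarization factor and azimuth from four corrected frames.

    Pixels with total intensity c below ``intensity_floor`` (or with zero
    modulation, where the azimuth is undefined) are masked rather than
    propagated as NaN in p.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] != 4:
        raise ValueError("need exactly 4 frames (0,45,90,135 deg)")
    i0, i45, i90, i135 = frames
    a = i0 - i90
    b = i45 - i135
    c = i0 + i45 + i90 + i135
    valid = c > intensity_floor
    p = np.zeros_like(c)
    np.divide(np.hypot(a, b), c, out=p, where=valid)
    azimuth = np.full_like(c, np.nan)
    modulated = valid & (np.hypot(a, b) > intensity_floor)
    azimuth[modulated] = (np.rad2deg(0.5 * np.arctan2(b, a)) % 180.0)[modulated]
    return AnisotropyImage(
        p=p,
        azimuth_deg=azimuth,
        mean_intensity=c / 4.0,
        mask=valid,
        pixel_size_um=pixel_size_um,
    )


def normalize_polarization(p, refs: CalibrationRefs):
    """p_norm = (p - p_plastic) / (p_stressfibers - p_plastic).

    Values outside [0, 1] are legitimate under noise and are returned as-is
    (callers may flag them); the span of the references must be non-zero.
    """
    span = refs.p_stressfibers - refs.p_plastic
    if span <= 0:
        raise ValueError("degenerate calibration references")
    p = np.asarray(p, dtype=float)
    out = (p - refs.p_plastic) / span
    return float(out) if out.ndim == 0 else out


def calibration_from_stacks(
    plastic: PolStack, stressfibers: PolStack, intensity_fraction: float = 0.5
) -> CalibrationRefs:
    """Median p over the bright pixels of each calibration acquisition.

    Bright pixels are those above ``intensity_fraction`` of the mean-image
    dynamic range (stress-fiber images are mostly background; plastic is
    uniform, where the threshold selects everything).
    """

    def _median_p(stack: PolStack) -> float:
        aniso = anisotropy_image(bleach_correct(stack), stack.pixel_size_um)
        mi = aniso.mean_intensity
        thresh = mi.min() + intensity_fraction * (mi.max() - mi.min())
        sel = aniso.mask & (mi >= thresh - 1e-12)
        if not sel.any():
            raise ValueError("no usable calibration pixels")
        return float(np.median(aniso.p[sel]))

    return CalibrationRefs(
        p_plastic=_median_p(plastic), p_stressfibers=_median_p(stressfibers)
    )


def segment_cell(
    mean_image: np.ndarray,
    seed_point: tuple[float, float],
    *,
    closing_radius: int = 5,
    background_quantile: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded-watershed segmentation of one cell from the mean-angle image.

    ``seed_point`` is (x, y) in pixels and must lie inside the cell.
    Morphological closing with ``closing_radius`` (pixels) excludes thin
    protrusions (filopodia) from the contour.  Returns (mask, contour),
    the contour as an ordered closed (N, 2) array of (x, y) pixel positions.
    """
    img = np.asarray(mean_image, dtype=float)
    x0, y0 = int(round(seed_point[0])), int(round(seed_point[1]))
    if not (0 <= y0 < img.shape[0] and 0 <= x0 < img.shape[1]):
        raise ValueError("seed point outside image")
    elevation = filters.sobel(img)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[0, :] = markers[-1, :] = markers[:, 0] = markers[:, -1] = 1
    markers[y0, x0] = 2
    labels = segmentation.watershed(elevation, markers)
    mask = labels == 2
    if not mask.any():
        raise ValueError("empty mask: watershed assigned no pixels to the seed")
    # a seed in the background floods a region reaching the image border;
    # a cell (even with a dark interior) is bounded by its bright cortex
    border = np.concatenate([mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]])
    if border.mean() > 0.2 or mask.mean() > 0.9:
        raise ValueError("seed point does not lie inside a fluorescent cell")
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    mask = morphology.remove_small_holes(mask, max_size=64)
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        warnings.warn("cell mask touches the image border", stacklevel=2)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask: no contour found")
    contour_rc = max(contours, key=len)
    background = np.quantile(img, background_quantile)
    rr = np.clip(np.round(contour_rc[:, 0]).astype(int), 0, img.shape[0] - 1)
    cc = np.clip(np.round(contour_rc[:, 1]).astype(int), 0, img.shape[1] - 1)
    if img[rr, cc].mean() <= background + 0.05 * (img.max() - background):
        raise ValueError("segmented boundary carries no fluorescence signal")
    contour = contour_rc[:, ::-1]  # (row, col) -> (x, y)
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[:1]])
    return mask, contour[:-1]  # closed implicitly, no duplicate point


def contour_arc_length(contour: np.ndarray, pixel_size_um: float = 1.0) -> np.ndarray:
    """Cumulative arc length (um) along a closed contour, starting at 0."""
    contour = np.asarray(contour, float)
    steps = np.linalg.norm(np.diff(contour, axis=0, append=contour[:1]), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)[:-1]]) * pixel_size_um


@dataclass
class ContourAnchors:
    """Equatorial and polar anchor indices and positions on a contour."""

    equator_idx: tuple[int, int]
    pole_idx: tuple[int, int]
    equator_xy: np.ndarray  # (2, 2)
    pole_xy: np.ndarray  # (2, 2)
    center_xy: tuple[float, float]
    major_axis_deg: float
    axis_ratio: float
    ambiguous: bool = False


def _ellipse_fit(contour: np.ndarray):
    model = measure.EllipseModel()
    if not model.estimate(np.asarray(contour, float)):
        raise ValueError("ellipse fit failed")
    xc, yc, a, b, theta = model.params
    if a < b:  # enforce a = semi-major
        a, b = b, a
        theta = theta + np.pi / 2
    return xc, yc, a, b, theta % np.pi


def _axis_intersections(contour, center, direction):
    """Contour points nearest the line through center along +/- direction."""
    rel = contour - center
    proj = rel @ direction
    perp = np.abs(rel @ np.array([-direction[1], direction[0]]))
    out = []
    for sign in (1.0, -1.0):
        side = proj * sign > 0
        if not side.any():
            raise ValueError("contour does not intersect axis")
        idx = np.flatnonzero(side)[np.argmin(perp[side])]
        out.append(int(idx))
    return out


def locate_equator_poles(
    contour: np.ndarray, min_axis_ratio: float = 1.02
) -> ContourAnchors:
    """Anchor points from an ellipse fit to the segmented contour.

    Poles are the contour intersections with the fitted major axis (the
    pole-to-pole elongation axis of an anaphase cell), the equator those
    with the minor axis.  Near-circular contours (axis ratio below
    ``min_axis_ratio``) raise :class:`AmbiguousAxesWarning` and keep the
    (arbitrary) fitted axes.
    """
    contour = np.asarray(contour, float)
    if len(contour) < 20:
        raise ValueError("contour too short for ellipse fit")
    xc, yc, a, b, theta = _ellipse_fit(contour)
    ratio = a / b
    ambiguous = ratio < min_axis_ratio
    if ambiguous:
        warnings.warn(
            f"axis ratio {ratio:.4f} < {min_axis_ratio}: equator/pole "
            "assignment is ambiguous",
            AmbiguousAxesWarning,
            stacklevel=2,
        )
    center = np.array([xc, yc])
    major = np.array([np.cos(theta), np.sin(theta)])
    minor = np.array([-np.sin(theta), np.cos(theta)])
    pole_idx = _axis_intersections(contour, center, major)
    eq_idx = _axis_intersections(contour, center, minor)
    return ContourAnchors(
        equator_idx=tuple(eq_idx),
        pole_idx=tuple(pole_idx),
        equator_xy=contour[eq_idx],
        pole_xy=contour[pole_idx],
        center_xy=(xc, yc),
        major_axis_deg=float(np.rad2deg(theta) % 180.0),
        axis_ratio=float(ratio),
        ambiguous=ambiguous,
    )


def _arc_window_indices(n, arc, center_idx, window_um):
    """Contour indices within +/- window/2 arc length of center (wrapping)."""
    total = arc[-1] + (arc[1] - arc[0] if n > 1 else 0.0)
    # arc is cumulative from index 0; distance along contour, wrapped
    d = np.abs(arc - arc[center_idx])
    d = np.minimum(d, total - d)
    return np.flatnonzero(d <= window_um / 2.0)


def cortical_regions(
    contour: np.ndarray,
    anchors: ContourAnchors,
    pixel_size_um: float,
    *,
    image_shape: tuple[int, int],
    equator_window_um: float = 2.0,
    pole_window_um: float = 16.0,
    band_width_um: float = 0.64,
) -> dict[str, np.ndarray]:
    """Pixel masks of the cortical measurement regions.

    Arc-length windows centered on each anchor (2 um at the equator, 16 um
    at the poles) are dilated to a band of 640 nm width normal to the
    contour.  Keys: equator_0, equator_1, pole_0, pole_1.
    """
    contour = np.asarray(contour, float)
    arc = contour_arc_length(contour, pixel_size_um)
    total = arc[-1] + np.linalg.norm(contour[0] - contour[-1]) * pixel_size_um
    regions = {}
    specs = [
        ("equator_0", anchors.equator_idx[0], equator_window_um),
        ("equator_1", anchors.equator_idx[1], equator_window_um),
        ("pole_0", anchors.pole_idx[0], pole_window_um),
        ("pole_1", anchors.pole_idx[1], pole_window_um),
    ]
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    for name, idx, window in specs:
        if window > total:
            raise ValueError(f"{name}: window {window} um exceeds contour length")
        sel = _arc_window_indices(len(contour), arc, idx, window)
        pts = contour[sel]
        tree = spatial.cKDTree(pts)
        dist, _ = tree.query(grid, distance_upper_bound=band_width_um / (2 * pixel_size_um) + 1)
        mask = (dist * pixel_size_um <= band_width_um / 2.0).reshape(h, w)
        regions[name] = mask
    return regions


def region_polarization(
    aniso: AnisotropyImage,
    regions: dict[str, np.ndarray],
    refs: CalibrationRefs | None = None,
) -> dict[str, float]:
    """Mean (normalized) polarization factor per region and per-cell site.

    Averages p over the region pixels and normalizes if calibration
    references are given.  Also returns ``equator`` / ``pole``: the mean of
    the two opposing regions of each site.
    """
    out = {}
    for name, mask in regions.items():
        sel = mask & aniso.mask
        if not sel.any():
            raise ValueError(f"region {name} fully masked")
        p = float(aniso.p[sel].mean())
        out[name] = float(normalize_polarization(p, refs)) if refs else p
    for site in ("equator", "pole"):
        pair = [v for k, v in out.items() if k.startswith(site + "_")]
        if pair:
            out[site] = float(np.mean(pair))
    return out


def anisotropic_zone_width(
    arc_um: np.ndarray, p_profile: np.ndarray, center_um: float | None = None
) -> dict[str, float]:
    """FWHM of the anisotropy zone from a Gaussian fit to p along the cortex.

    Fits ``offset + amplitude * exp(-(s - s0)^2 / (2 sigma^2))`` (amplitude
    of either sign: the zone may be a dip in p) by least squares and returns
    the full width at half maximum ``2 sqrt(2 ln 2) sigma``.
    """
    arc = np.asarray(arc_um, float)
    prof = np.asarray(p_profile, float)
    if arc.shape != prof.shape or arc.size < 5:
        raise ValueError("need matching arc/profile arrays with >= 5 samples")

    def gauss(s, offset, amp, s0, sigma):
        return offset + amp * np.exp(-((s - s0) ** 2) / (2.0 * sigma**2))

    offset0 = np.median(prof)
    i_ext = np.argmax(np.abs(prof - offset0))
    amp0 = prof[i_ext] - offset0
    s00 = arc[i_ext] if center_um is None else center_um
    span = arc.max() - arc.min()
    if abs(amp0) < 1e-6 * max(1.0, abs(offset0)):
        raise RuntimeError("profile has no dominant extremum; Gaussian fit not possible")
    try:
        popt, pcov = optimize.curve_fit(
            gauss,
            arc,
            prof,
            p0=[offset0, amp0, s00, span / 8.0],
            maxfev=10_000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"Gaussian fit did not converge: {err}") from err
    offset, amp, s0, sigma = popt
    sigma = abs(sigma)
    if sigma > span:
        raise RuntimeError(
            f"Gaussian fit degenerate (sigma {sigma:.3g} um exceeds profile span)"
        )
    return {
        "fwhm_um": 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma,
        "sigma_um": sigma,
        "center_um": float(s0),
        "amplitude": float(amp),
        "offset": float(offset),
    }
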