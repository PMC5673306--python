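"""Synthetic dipole-optics scenes with ground truth for every estimator.

Renders the image data the analysis pipelines expect — LC-PolScope
five-frame stacks, live two-analyzer channel pairs with an H2B chromatin
channel, laser-cut time series and two-channel linescans — from an explicit
physical scene: a cell modelled as a surface of revolution (sphere deformed
by an equatorial neck) carrying a thin cortical shell of filament-bound
fluorophore dipoles.  Per surface patch, dipoles are drawn from an axial
von Mises distribution in the local tangent plane (concentration kappa
following a Gaussian spatial profile around the equator), photoselected by
the polarized excitation, projected through the emission optics, weighted
by a Gaussian optical section along z, splatted to the pixel grid, blurred
with a Gaussian PSF, bleached per acquired frame, and noised
(Poisson shot noise plus Gaussian read noise).

Every generator is deterministic for a fixed seed and emits a
:class:`GroundTruth` sufficient to score the downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize
from scipy.special import i0, i1

from .optics import FilamentOrientationModel, TangentPlane, polarization_factor, polscope_intensities
from .polscope import POLSCOPE_ANGLES, PolStack

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "DivisionKinetics",
    "CutSpec",
    "LiveFrame",
    "LiveSeries",
    "CutSeries",
    "generate_polscope_stack",
    "generate_live_pair_series",
    "generate_cut_series",
    "generate_linescan_pair",
    "generate_calibration_samples",
    "generate_plastic_pair",
    "default_live_scene",
    "anisotropy_vs_kappa",
    "kappa_profile_sigma",
]

_CHUNK = 4096  # patches per sampling chunk (memory / determinism unit)


# --------------------------------------------------------------------------
# configuration


@dataclass
class SceneConfig:
    """Full description of a synthetic cell scene.

    Lengths in um; angles in degrees from the image +x axis.  The
    ``anisotropy_zone_fwhm_um`` is the FWHM of the *normalized anisotropy
    profile* along the cortex implied by the Gaussian kappa profile; the
    internal kappa width is solved from the forward kappa -> p map so the
    imposed value is exact by construction.  ``density_zone_fwhm_um`` is the
    FWHM of the Gaussian equatorial fluorophore-density enrichment.
    """

    cell_radius_um: float = 10.0
    furrow_ingression: float = 0.0  # 0 = sphere, 1 = fully closed neck
    elongation: float = 0.0  # fractional pole-pole elongation
    neck_width_um: float = 3.5
    spindle_axis_deg: float = 90.0
    cortex_thickness_um: float = 0.2

    kappa_peak: float = 0.0  # equatorial alignment concentration
    anisotropy_zone_fwhm_um: float = 4.4
    filament_mean_axis_deg: float = 0.0  # from the circumferential direction
    dipole_tilt_deg: float = 0.0
    depolarization_floor: float = 0.0  # excitation-side isotropic fraction
    emission_floor: float | None = None  # emission side; None = same as above

    density_equator_factor: float = 1.0  # peak relative density at equator
    density_zone_fwhm_um: float = 8.4
    cytoplasm_level: float = 0.0  # isotropic interior signal, rel. to cortex

    pixel_size_um: float = 0.1
    margin_um: float = 2.0
    psf_sigma_um: float = 0.15
    section_fwhm_um: float = 0.9
    patch_size_um: float | None = None  # default: one pixel

    peak_counts: float = 500.0
    noise: bool = True
    read_noise_sd: float = 3.0
    bleach_per_frame: float = 0.0
    channel_gain_v: float = 1.0  # transmission imbalance of the V analyzer

    n_dipole_samples: int = 512
    seed: int = 0

    def __post_init__(self):
        for name in (
            "cell_radius_um",
            "neck_width_um",
            "cortex_thickness_um",
            "pixel_size_um",
            "psf_sigma_um",
            "section_fwhm_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.furrow_ingression < 1.0):
            raise ValueError("furrow_ingression must be in [0, 1)")
        if self.kappa_peak < 0:
            raise ValueError("kappa_peak must be >= 0")

    @property
    def furrow_diameter_um(self) -> float:
        return 2.0 * self.cell_radius_um * (1.0 - self.furrow_ingression)

    def image_shape(self) -> tuple[int, int]:
        half = self.cell_radius_um * (1.0 + self.elongation) + self.margin_um
        n = int(np.ceil(2.0 * half / self.pixel_size_um))
        return (n, n)


def default_live_scene(**overrides) -> SceneConfig:
    """Scene defaults emulating the live two-analyzer SiR-actin setup.

    A 1.4-NA oil objective depolarizes the illumination moderately
    (excitation floor 0.25) and the collected emission strongly (emission
    floor 0.85: full collection cone plus fluorophore wobble); a small
    cytoplasmic probe pool adds isotropic interior signal.  These defaults
    give the moderate cortex-ratio modulation under which the sine-squared
    geometry regression is well conditioned along the full contour.
    """
    cfg = dict(
        depolarization_floor=0.25,
        emission_floor=0.85,
        cytoplasm_level=0.05,
        channel_gain_v=1.15,
        pixel_size_um=0.15,
        psf_sigma_um=0.2,
        peak_counts=1000.0,
    )
    cfg.update(overrides)
    return SceneConfig(**cfg)


@dataclass
class GroundTruth:
    """True scene quantities for scoring downstream estimators."""

    contour_xy_px: np.ndarray | None = None  # closed central-section contour
    contour_arc_um: np.ndarray | None = None  # signed arc from equator anchor
    tangent_deg: np.ndarray | None = None
    kappa_profile: np.ndarray | None = None
    density_profile: np.ndarray | None = None
    anisotropy_profile: np.ndarray | None = None  # normalized p(kappa(s))
    anisotropy_zone_fwhm_um: float | None = None
    density_zone_fwhm_um: float | None = None
    furrow_diameter_um: float | None = None
    pole_distance_um: float | None = None
    center_px: tuple[float, float] | None = None
    spindle_axis_deg: float | None = None
    equator_anchor_px: np.ndarray | None = None
    pole_anchor_px: np.ndarray | None = None
    chromatin_centers_px: np.ndarray | None = None
    chromatin_separation_um: float | None = None
    edge_separation_um: np.ndarray | None = None  # cut series, per post frame
    time_s: np.ndarray | None = None
    intensity_scale: float | None = None
    expected_p: float | None = None


# --------------------------------------------------------------------------
# kappa profile calibration


def anisotropy_vs_kappa(
    kappas,
    *,
    tilt_deg: float = 0.0,
    depolarization_floor: float = 0.0,
    n_samples: int = 200_000,
    seed: int = 12345,
) -> np.ndarray:
    """Polarization factor of an equatorial cortex patch versus kappa.

    The patch contains the optical axis (central-section contour); the mean
    filament axis is the circumferential direction, i.e. perpendicular to
    the optical plane at the equator.  Used to convert an imposed
    anisotropy-zone width into the internal kappa-profile width.
    """
    plane = TangentPlane((0.0, 0.0, 1.0), (1.0, 0.0, 0.0))  # (circumf., merid.)
    out = np.empty(len(kappas))
    for i, k in enumerate(np.asarray(kappas, float)):
        model = FilamentOrientationModel(0.0, float(k), tilt_deg)
        ints = polscope_intensities(
            model, plane, n_samples, seed, depolarization_floor
        )
        out[i] = polarization_factor(*ints)
    return out


_KAPPA_MAP_CACHE: dict = {}


def _kappa_dip_map(kappa_peak: float, tilt_deg: float, floor: float):
    """Monotone kappa -> equatorial polarization-factor table up to the peak."""
    key = (round(kappa_peak, 6), round(tilt_deg, 6), round(floor, 6))
    if key not in _KAPPA_MAP_CACHE:
        ks = np.unique(np.concatenate([np.linspace(0.0, kappa_peak, 9), [kappa_peak]]))
        ps = anisotropy_vs_kappa(
            ks, tilt_deg=tilt_deg, depolarization_floor=floor, n_samples=120_000
        )
        _KAPPA_MAP_CACHE[key] = (ks, ps)
    return _KAPPA_MAP_CACHE[key]


def kappa_profile_sigma(scene: SceneConfig) -> float:
    """Gaussian sigma (um of arc) of the kappa profile.

    Solved so that the anisotropy dip p(kappa(s)) along the central-section
    cortex has FWHM ``anisotropy_zone_fwhm_um``: the kappa value at the
    half-dip level comes from the forward single-patch kappa -> p map under
    the scene's dipole tilt and depolarization floor.  Under perfectly
    ideal optics (no tilt, no depolarization) a single patch shows no
    kappa dependence of p at all; the von Mises alignment proxy
    R2(kappa) = I1(kappa)/I0(kappa) is used for the inversion instead.
    """
    kp = scene.kappa_peak
    if kp <= 0:
        return scene.anisotropy_zone_fwhm_um / 2.355  # unused, nominal
    ks, ps = _kappa_dip_map(kp, scene.dipole_tilt_deg, scene.depolarization_floor)
    dip = ps[0] - ps[-1]
    if dip > 1e-3:
        half_level = ps[0] - dip / 2.0
        # ps decreases with kappa: invert on the reversed axis
        k_half = float(np.interp(-half_level, -ps, ks))
    else:  # ideal-optics fallback: alignment proxy

        def r2(k):
            return i1(k) / i0(k) if k > 0 else 0.0

        half = 0.5 * r2(kp)
        k_half = optimize.brentq(lambda k: r2(k) - half, 1e-9, kp)
    s_half = np.sqrt(2.0 * np.log(kp / max(k_half, 1e-9)))
    return (scene.anisotropy_zone_fwhm_um / 2.0) / s_half


# --------------------------------------------------------------------------
# cell surface geometry


class CellSurface:
    """Surface of revolution: sphere/spheroid with an equatorial neck.

    The radius profile along the symmetry (spindle) axis t is
    ``rho(t) = R sqrt(1 - (t/La)^2) * (1 - ingression * exp(-t^2/(2 w^2)))``
    with La = R (1 + elongation); the furrow diameter 2 rho(0) decreases
    monotonically with ingression.
    """

    def __init__(self, scene: SceneConfig):
        self.R = scene.cell_radius_um
        self.La = self.R * (1.0 + scene.elongation)
        self.ingression = scene.furrow_ingression
        self.w = scene.neck_width_um

    def rho(self, t):
        t = np.asarray(t, float)
        base = self.R * np.sqrt(np.clip(1.0 - (t / self.La) ** 2, 0.0, None))
        neck = 1.0 - self.ingression * np.exp(-(t**2) / (2.0 * self.w**2))
        return base * neck

    def meridian_table(self, n=8001):
        """Dense meridian samples without pole singularities.

        Parametrized by the polar angle eta in [-pi/2, pi/2] via
        t = La sin(eta), where the profile slope stays finite.  Returns
        (t, rho, s, mt, mr): axial position, radius, signed arc length from
        the equator, and the unit meridian tangent's (axial, radial)
        components per sample.
        """
        eta = np.linspace(-np.pi / 2, np.pi / 2, n)
        t = self.La * np.sin(eta)
        r = self.rho(t)
        dt = np.gradient(t)
        dr = np.gradient(r)
        seg = np.hypot(dt, dr)
        s = np.concatenate([[0.0], np.cumsum((seg[1:] + seg[:-1]) / 2.0)])
        s -= np.interp(0.0, t, s)
        mt, mr = dt / seg, dr / seg
        return t, r, s, mt, mr

    def meridian_arc(self, n=8001):
        """Dense (t, s) table; s is signed arc length from the equator."""
        t, _, s, _, _ = self.meridian_table(n)
        return t, s


def _central_section_truth(scene: SceneConfig, surface: CellSurface, n=1600):
    """Closed central-section contour with per-point tangent, kappa, density."""
    t, s_table = surface.meridian_arc()
    # sample the upper branch uniformly in meridian arc, then mirror
    s_max = s_table[-1]
    s_samples = np.linspace(s_table[0] * (1 - 1e-9), s_max * (1 - 1e-9), n // 2)
    t_samples = np.interp(s_samples, s_table, t)
    rho = surface.rho(t_samples)
    axis = np.deg2rad(scene.spindle_axis_deg)
    a_hat = np.array([np.cos(axis), np.sin(axis)])
    b_hat = np.array([-np.sin(axis), np.cos(axis)])
    h, w = scene.image_shape()
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0]) * scene.pixel_size_um
    upper = center + np.outer(t_samples, a_hat) + np.outer(rho, b_hat)
    lower = center + np.outer(t_samples[::-1], a_hat) - np.outer(rho[::-1], b_hat)
    contour_um = np.vstack([upper, lower])
    arc = np.concatenate([s_samples, s_samples[::-1]])
    sigma_k = kappa_profile_sigma(scene)
    kappa = scene.kappa_peak * np.exp(-(arc**2) / (2.0 * sigma_k**2))
    sig_d = scene.density_zone_fwhm_um / 2.355
    density = 1.0 + (scene.density_equator_factor - 1.0) * np.exp(
        -(arc**2) / (2.0 * sig_d**2)
    )
    d = np.diff(contour_um, axis=0, append=contour_um[:1])
    tangent = np.rad2deg(np.arctan2(d[:, 1], d[:, 0])) % 180.0
    return GroundTruth(
        contour_xy_px=contour_um / scene.pixel_size_um,
        contour_arc_um=arc,
        tangent_deg=tangent,
        kappa_profile=kappa,
        density_profile=density,
        anisotropy_zone_fwhm_um=(
            scene.anisotropy_zone_fwhm_um if scene.kappa_peak > 0 else None
        ),
        density_zone_fwhm_um=(
            scene.density_zone_fwhm_um if scene.density_equator_factor != 1.0 else None
        ),
        furrow_diameter_um=scene.furrow_diameter_um,
        pole_distance_um=2.0 * surface.La,
        center_px=tuple(center / scene.pixel_size_um),
        spindle_axis_deg=scene.spindle_axis_deg,
        equator_anchor_px=(center + surface.rho(0.0) * b_hat) / scene.pixel_size_um,
        pole_anchor_px=(center + surface.La * a_hat) / scene.pixel_size_um,
    )


# --------------------------------------------------------------------------
# patch construction and rendering


def _surface_patches(scene: SceneConfig, surface: CellSurface):
    """Discretize the cortical shell into surface patches near the section.

    Returns positions (P, 3) in um (lab frame, z = optical axis, origin at
    image corner), orthonormal bases (circumferential, meridional, normal),
    per-patch weights (area x density x section), and kappa values.
    """
    h_patch = scene.patch_size_um or scene.pixel_size_um
    z_sigma = scene.section_fwhm_um / 2.355
    z_cut = 3.5 * z_sigma + scene.cortex_thickness_um
    t_dense, r_dense, s_dense, mt_dense, mr_dense = surface.meridian_table()
    s_grid = np.arange(s_dense[0] + h_patch / 2, s_dense[-1], h_patch)
    t_grid = np.interp(s_grid, s_dense, t_dense)
    r_grid = np.interp(s_grid, s_dense, r_dense)
    mt_grid = np.interp(s_grid, s_dense, mt_dense)
    mr_grid = np.interp(s_grid, s_dense, mr_dense)
    axis = np.deg2rad(scene.spindle_axis_deg)
    a2 = np.array([np.cos(axis), np.sin(axis)])  # axis direction, image plane
    b2 = np.array([-np.sin(axis), np.cos(axis)])
    hh, ww = scene.image_shape()
    center = np.array([(ww - 1) / 2.0, (hh - 1) / 2.0]) * scene.pixel_size_um

    sigma_k = kappa_profile_sigma(scene)
    sig_d = scene.density_zone_fwhm_um / 2.355

    pos, base_c, base_m, base_n, weight, kappa = [], [], [], [], [], []
    for t, s, rho, mt, mr in zip(t_grid, s_grid, r_grid, mt_grid, mr_grid):
        if rho <= 0:
            continue
        n_psi = max(8, int(np.ceil(2 * np.pi * rho / h_patch)))
        psi = 2 * np.pi * (np.arange(n_psi) + 0.5) / n_psi
        z = rho * np.sin(psi)
        keep = np.abs(z) <= z_cut
        if not keep.any():
            continue
        psi, z = psi[keep], z[keep]
        cpsi, spsi = np.cos(psi), np.sin(psi)
        # lab-frame positions: center + t*a2 + rho*cos(psi)*b2 (in plane), z
        xy = center + t * a2 + np.outer(rho * cpsi, b2)
        pos.append(np.column_stack([xy, z]))
        # meridian tangent: mt along the axis, mr along the local radial
        m = np.column_stack(
            [mt * a2[0] + mr * cpsi * b2[0], mt * a2[1] + mr * cpsi * b2[1], mr * spsi]
        )
        c = np.column_stack([-spsi * b2[0], -spsi * b2[1], cpsi])
        n = np.cross(c, m)
        base_c.append(c)
        base_m.append(m)
        base_n.append(n)
        dens = 1.0 + (scene.density_equator_factor - 1.0) * np.exp(
            -(s**2) / (2.0 * sig_d**2)
        )
        area = h_patch * (2 * np.pi * rho / n_psi)
        sect = np.exp(-(z**2) / (2.0 * z_sigma**2))
        weight.append(area * dens * sect)
        k = scene.kappa_peak * np.exp(-(s**2) / (2.0 * sigma_k**2))
        kappa.append(np.full(len(psi), k))
    if not pos:
        raise ValueError("no cortical patches intersect the optical section")
    return (
        np.concatenate(pos),
        np.concatenate(base_c),
        np.concatenate(base_m),
        np.concatenate(base_n),
        np.concatenate(weight),
        np.concatenate(kappa),
    )


def _patch_channel_intensities(
    scene: SceneConfig,
    bases_c: np.ndarray,
    bases_m: np.ndarray,
    bases_n: np.ndarray,
    kappa: np.ndarray,
    channels: list[tuple[float, float | None]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Expected intensity per patch for each (excitation, analyzer) channel.

    Per patch, ``n_dipole_samples`` dipoles are drawn independently (labeling
    stochasticity); one draw serves all channels of the acquisition, as in a
    sequential recording of the same specimen.
    """
    P = len(kappa)
    N = scene.n_dipole_samples
    fe = scene.depolarization_floor
    fm = scene.emission_floor if scene.emission_floor is not None else fe
    mu = np.deg2rad(scene.filament_mean_axis_deg)
    beta = np.deg2rad(scene.dipole_tilt_deg)
    cb, sb = np.cos(beta), np.sin(beta)
    out = np.zeros((len(channels), P))
    for lo in range(0, P, _CHUNK):
        hi = min(lo + _CHUNK, P)
        k = kappa[lo:hi, None]
        with np.errstate(over="ignore"):
            phi = 0.5 * rng.vonmises(2.0 * mu, np.broadcast_to(k, (hi - lo, N)))
        xi = rng.uniform(0.0, 2.0 * np.pi, (hi - lo, N))
        cphi, sphi = np.cos(phi), np.sin(phi)
        cxi = np.cos(xi)
        a = cb * cphi - sb * cxi * sphi
        b = cb * sphi + sb * cxi * cphi
        c = sb * np.sin(xi)
        del phi, xi, cphi, sphi, cxi
        cB, mB, nB = bases_c[lo:hi], bases_m[lo:hi], bases_n[lo:hi]
        dx = a * cB[:, 0:1] + b * mB[:, 0:1] + c * nB[:, 0:1]
        dy = a * cB[:, 1:2] + b * mB[:, 1:2] + c * nB[:, 1:2]
        del a, b, c
        dxx, dyy, dxy = dx * dx, dy * dy, dx * dy
        for j, (exc_deg, ana_deg) in enumerate(channels):
            te = np.deg2rad(exc_deg)
            exc = (
                np.cos(te) ** 2 * dxx + np.sin(te) ** 2 * dyy + np.sin(2 * te) * dxy
            )
            exc = (1.0 - fe) * exc + fe / 3.0
            if ana_deg is None:
                em = (1.0 - fm) * (dxx + dyy) + 2.0 * fm / 3.0
            else:
                ta = np.deg2rad(ana_deg)
                em = (
                    np.cos(ta) ** 2 * dxx
                    + np.sin(ta) ** 2 * dyy
                    + np.sin(2 * ta) * dxy
                )
                em = (1.0 - fm) * em + fm / 3.0
            out[j, lo:hi] = (exc * em).mean(axis=1)
    return out


def _splat(scene: SceneConfig, pos_um: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Bilinear deposition of patch values onto the pixel grid."""
    h, w = scene.image_shape()
    x = pos_um[:, 0] / scene.pixel_size_um
    y = pos_um[:, 1] / scene.pixel_size_um
    if (x.min() < 0) or (y.min() < 0) or (x.max() > w - 1) or (y.max() > h - 1):
        raise ValueError("pixel grid too small to contain the cell")
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    img = np.zeros((h, w))
    for dxi, dyi, wgt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        np.add.at(
            img,
            (np.clip(y0 + dyi, 0, h - 1), np.clip(x0 + dxi, 0, w - 1)),
            values * wgt,
        )
    return img


def _interior_mask(scene: SceneConfig, truth: GroundTruth) -> np.ndarray:
    h, w = scene.image_shape()
    yy, xx = np.mgrid[0:h, 0:w]
    from matplotlib.path import Path

    path = Path(truth.contour_xy_px)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return path.contains_points(pts).reshape(h, w)


def _render_expected(
    scene: SceneConfig,
    channels: list[tuple[float, float | None]],
    rng: np.random.Generator,
    surface: CellSurface | None = None,
    truth: GroundTruth | None = None,
):
    """Noiseless expected images (one per channel) and ground truth."""
    surface = surface or CellSurface(scene)
    truth = truth or _central_section_truth(scene, surface)
    pos, bc, bm, bn, wgt, kappa = _surface_patches(scene, surface)
    inten = _patch_channel_intensities(scene, bc, bm, bn, kappa, channels, rng)
    sigma_px = scene.psf_sigma_um / scene.pixel_size_um
    images = []
    # thin-shell thickness: three sub-shells along the patch normal
    offsets = (
        [(0.0, 1.0)]
        if scene.cortex_thickness_um <= scene.pixel_size_um / 4
        else [(-scene.cortex_thickness_um / 2, 0.25), (0.0, 0.5), (scene.cortex_thickness_um / 2, 0.25)]
    )
    for j in range(len(channels)):
        img = np.zeros(scene.image_shape())
        for off, ow in offsets:
            img += _splat(scene, pos + off * bn, inten[j] * wgt * ow)
        images.append(ndimage.gaussian_filter(img, sigma_px))
    if scene.cytoplasm_level > 0:
        interior = _interior_mask(scene, truth)
        cortex_scale = max(float(img.max()) for img in images)
        # isotropic 3-D dipole background: 4th moments of the uniform sphere
        # give E[di^4]=1/5, E[di^2 dj^2]=1/15 (co-polarized emission excess)
        fe = scene.depolarization_floor
        fm = scene.emission_floor if scene.emission_floor is not None else fe
        for j, (exc_deg, ana_deg) in enumerate(channels):
            if ana_deg is None:
                # E[exc * (dx^2+dy^2)] with E[di^2]=1/3
                val = (1 - fe) * (1 - fm) * (1 / 5 + 1 / 15) + (1 - fe) * (
                    2 * fm / 3
                ) / 3 + (fe / 3) * ((1 - fm) * 2 / 3 + 2 * fm / 3)
            else:
                delta = abs((exc_deg - ana_deg) % 180.0)
                co = min(delta, 180 - delta) < 45.0
                m4 = 1 / 5 if co else 1 / 15
                val = (
                    (1 - fe) * (1 - fm) * m4
                    + (1 - fe) * (fm / 3) / 3
                    + (fe / 3) * (1 - fm) / 3
                    + fe * fm / 9
                )
            level = scene.cytoplasm_level * cortex_scale * val / (1 / 5)
            cyto = ndimage.gaussian_filter(interior * level, sigma_px)
            images[j] = images[j] + cyto
    return images, truth


def _apply_counts(
    scene: SceneConfig,
    expected: list[np.ndarray],
    rng: np.random.Generator,
    scale: float | None = None,
    bleach_start: int = 0,
):
    """Scale to counts, apply cumulative bleach, then shot and read noise."""
    if scale is None:
        peak = max(float(img.max()) for img in expected)
        if peak <= 0:
            raise ValueError("scene renders to zero intensity")
        scale = scene.peak_counts / peak
    frames = []
    for k, img in enumerate(expected):
        e = img * scale * (1.0 - scene.bleach_per_frame) ** (bleach_start + k)
        if scene.noise:
            e = rng.poisson(e).astype(float)
            if scene.read_noise_sd > 0:
                e = e + rng.normal(0.0, scene.read_noise_sd, e.shape)
            e = np.clip(e, 0.0, None)
        frames.append(e)
    return frames, scale


# --------------------------------------------------------------------------
# generators


def generate_polscope_stack(scene: SceneConfig) -> tuple[PolStack, GroundTruth]:
    """Five-frame LC-PolScope stack (0, 45, 90, 135, 0 deg excitation).

    Photobleaching is cumulative in acquisition order; the repeated
    0-degree frame therefore records the total acquisition loss.
    """
    rng = np.random.default_rng(scene.seed)
    channels = [(ang, None) for ang in POLSCOPE_ANGLES]
    expected, truth = _render_expected(scene, channels, rng)
    # frames 0 and 4 share the excitation state: identical expectation
    expected[4] = expected[0]
    frames, scale = _apply_counts(scene, expected, rng)
    truth.intensity_scale = scale
    # expected p along the contour from the single-patch kappa -> p map
    if scene.kappa_peak > 0:
        ks, ps = _kappa_dip_map(
            scene.kappa_peak, scene.dipole_tilt_deg, scene.depolarization_floor
        )
        truth.anisotropy_profile = np.interp(truth.kappa_profile, ks, ps)
    return PolStack(np.stack(frames), scene.pixel_size_um), truth


@dataclass
class DivisionKinetics:
    """Imposed division kinetics: furrow ingression and chromatid separation.

    Times in seconds, zero at anaphase onset.  The furrow diameter is
    non-increasing after ``ingression_onset_s`` (linear ramp over
    ``ingression_duration_s`` down to ``1 - max_ingression`` of the initial
    diameter); chromatin separation rises as a saturating exponential after
    anaphase onset.
    """

    anaphase_onset_s: float = 0.0
    frame_interval_s: float = 15.0
    ingression_onset_s: float = 90.0
    ingression_duration_s: float = 210.0
    max_ingression: float = 0.85
    chromatin_max_separation_um: float = 12.0
    chromatin_tau_s: float = 90.0
    elongation_per_ingression: float = 0.3

    def ingression(self, t_s: float) -> float:
        u = (t_s - self.ingression_onset_s) / self.ingression_duration_s
        return self.max_ingression * float(np.clip(u, 0.0, 1.0))

    def furrow_diameter(self, t_s: float, initial_diameter_um: float) -> float:
        return initial_diameter_um * (1.0 - self.ingression(t_s))

    def chromatin_separation(self, t_s: float) -> float:
        dt = t_s - self.anaphase_onset_s
        if dt <= 0:
            return 0.0
        return self.chromatin_max_separation_um * (
            1.0 - float(np.exp(-dt / self.chromatin_tau_s))
        )

    def elongation(self, t_s: float) -> float:
        return self.elongation_per_ingression * self.ingression(t_s)

    def sample_table(
        self,
        n_cells: int,
        *,
        initial_diameter_um: float = 20.0,
        t_start_s: float = -45.0,
        t_end_s: float = 300.0,
        timing_noise_s: float = 0.0,
        measurement_noise_um: float = 0.1,
        seed: int = 0,
    ):
        """Synthetic per-cell geometry tables for the staging regression.

        Each cell's true acquisition times get Gaussian timing jitter
        (asynchrony of fixation relative to anaphase onset) and each
        measurement Gaussian noise in um.  Returns a pandas DataFrame with
        cell, time_s, furrow_diameter_um, chromatin_distance_um.
        """
        import pandas as pd

        rng = np.random.default_rng(seed)
        rows = []
        times = np.arange(t_start_s, t_end_s + 1e-9, self.frame_interval_s)
        for cell in range(n_cells):
            jitter = rng.normal(0.0, timing_noise_s) if timing_noise_s else 0.0
            for t in times:
                tt = t + jitter
                rows.append(
                    {
                        "cell": cell,
                        "time_s": tt,
                        "furrow_diameter_um": self.furrow_diameter(
                            tt, initial_diameter_um
                        )
                        + rng.normal(0.0, measurement_noise_um),
                        "chromatin_distance_um": max(
                            self.chromatin_separation(tt)
                            + rng.normal(0.0, measurement_noise_um),
                            0.0,
                        ),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class LiveFrame:
    time_s: float
    horizontal: np.ndarray
    vertical: np.ndarray
    h2b: np.ndarray
    truth: GroundTruth


@dataclass
class LiveSeries:
    frames: list[LiveFrame]
    pixel_size_um: float
    anaphase_onset_index: int

    @property
    def times_s(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])


def _h2b_image(scene: SceneConfig, center_um, axis_deg, separation_um, rng):
    h, w = scene.image_shape()
    yy, xx = np.mgrid[0:h, 0:w]
    x_um = xx * scene.pixel_size_um
    y_um = yy * scene.pixel_size_um
    a = np.deg2rad(axis_deg)
    ah = np.array([np.cos(a), np.sin(a)])
    sigma = 1.8
    img = np.zeros((h, w))
    if separation_um <= 0:
        centers = [np.asarray(center_um)]
    else:
        centers = [
            np.asarray(center_um) + 0.5 * separation_um * ah,
            np.asarray(center_um) - 0.5 * separation_um * ah,
        ]
    for cpos in centers:
        img += np.exp(
            -((x_um - cpos[0]) ** 2 + (y_um - cpos[1]) ** 2) / (2 * sigma**2)
        )
    img *= scene.peak_counts / max(img.max(), 1e-12)
    if scene.noise:
        img = np.clip(
            rng.poisson(img) + rng.normal(0, scene.read_noise_sd, img.shape), 0, None
        ).astype(float)
    return img, np.array([c / scene.pixel_size_um for c in centers])


def generate_live_pair_series(
    scene: SceneConfig,
    kinetics: DivisionKinetics,
    n_frames: int = 20,
    t_start_s: float = -45.0,
    kappa_schedule=None,
) -> LiveSeries:
    """Two-analyzer time series (H, V, H2B) of a dividing cell.

    Excitation is fixed at 90 deg; emission analyzers at 0 (horizontal
    channel) and 90 deg (vertical channel, scaled by the channel gain).
    ``kappa_schedule`` optionally maps time (s) to the peak equatorial
    kappa, emulating progressive filament alignment.  At least three frames
    must precede anaphase onset (needed by the pre-anaphase normalization).
    """
    times = t_start_s + kinetics.frame_interval_s * np.arange(n_frames)
    n_pre = int(np.sum(times < kinetics.anaphase_onset_s))
    if n_pre < 3:
        raise ValueError("need >= 3 frames before anaphase onset")
    rng = np.random.default_rng(scene.seed)
    frames = []
    scale = None
    for k, t in enumerate(times):
        kp = float(kappa_schedule(t)) if kappa_schedule is not None else scene.kappa_peak
        frame_scene = replace(
            scene,
            furrow_ingression=kinetics.ingression(t),
            elongation=scene.elongation + kinetics.elongation(t),
            kappa_peak=kp,
        )
        channels = [(90.0, 0.0), (90.0, 90.0)]
        expected, truth = _render_expected(frame_scene, channels, rng)
        expected[1] = expected[1] * scene.channel_gain_v
        imgs, scale = _apply_counts(
            frame_scene, expected, rng, scale=scale, bleach_start=2 * k
        )
        sep = kinetics.chromatin_separation(t)
        h2b, centers = _h2b_image(
            scene,
            np.array(truth.center_px) * scene.pixel_size_um,
            scene.spindle_axis_deg,
            sep,
            rng,
        )
        truth.chromatin_centers_px = centers
        truth.chromatin_separation_um = sep
        truth.intensity_scale = scale
        frames.append(LiveFrame(float(t), imgs[0], imgs[1], h2b, truth))
    return LiveSeries(frames, scene.pixel_size_um, n_pre)


@dataclass
class CutSpec:
    """A 5-um linear laser cut and the imposed cortical response."""

    start_um: tuple[float, float]
    end_um: tuple[float, float]
    gap_width_um: float = 0.3
    baseline_damage_um: float = 0.4
    retraction_amplitude_um: float = 2.0
    retraction_timescale_s: float = 2.0

    def __post_init__(self):
        if self.length_um <= 0:
            raise ValueError("cut path has zero length")

    @property
    def length_um(self) -> float:
        return float(
            np.hypot(
                self.end_um[0] - self.start_um[0], self.end_um[1] - self.start_um[1]
            )
        )

    def validate_length(self, pixel_size_um: float, nominal_um: float = 5.0):
        if abs(self.length_um - nominal_um) > pixel_size_um:
            raise ValueError(
                f"cut path length {self.length_um:.3f} um differs from "
                f"{nominal_um} um by more than one pixel"
            )

    def edge_separation_um(self, t_after_cut_s: float) -> float:
        """Imposed distance between the two fluorescence edges."""
        if t_after_cut_s < 0:
            return 0.0
        recoil = self.retraction_amplitude_um * (
            1.0 - float(np.exp(-t_after_cut_s / self.retraction_timescale_s))
        )
        return self.gap_width_um + self.baseline_damage_um + recoil


@dataclass
class CutSeries:
    times_s: np.ndarray  # relative to the cut (negative = pre frames)
    horizontal: list[np.ndarray]
    vertical: list[np.ndarray]
    pixel_size_um: float
    cut: CutSpec
    truth: GroundTruth


def generate_cut_series(
    scene: SceneConfig,
    cut: CutSpec,
    n_pre: int = 2,
    n_post: int = 6,
    frame_interval_s: float = 0.3,
) -> CutSeries:
    """Bottom-section cortex sheet with a laser cut and exponential recoil.

    The planar cortex (image-plane tangent everywhere, orientation model
    from the scene) is rendered as an H/V analyzer pair; after the cut,
    fluorescence is removed in a band along the path whose half-width
    follows ``(gap + baseline + amplitude (1 - exp(-t/tau))) / 2``: the two
    retracting edges.  Only the noise is stochastic; edge positions are
    deterministic.
    """
    cut.validate_length(scene.pixel_size_um)
    rng = np.random.default_rng(scene.seed)
    h, w = scene.image_shape()
    yy, xx = np.mgrid[0:h, 0:w]
    x_um, y_um = xx * scene.pixel_size_um, yy * scene.pixel_size_um
    cx = (w - 1) / 2.0 * scene.pixel_size_um
    cy = (h - 1) / 2.0 * scene.pixel_size_um
    footprint = (x_um - cx) ** 2 + (y_um - cy) ** 2 <= scene.cell_radius_um**2

    plane = TangentPlane((1.0, 0.0, 0.0), (0.0, 1.0, 0.0))
    model = FilamentOrientationModel(
        scene.filament_mean_axis_deg, scene.kappa_peak, scene.dipole_tilt_deg
    )
    from .optics import OpticalConfig, emission_factor, excitation_factor, sample_dipoles

    vals = {}
    d = sample_dipoles(model, plane, scene.n_dipole_samples * 64, scene.seed + 1)
    for name, ana in (("h", 0.0), ("v", 90.0)):
        cfg = OpticalConfig(90.0, ana, scene.depolarization_floor, scene.emission_floor)
        vals[name] = float(np.mean(excitation_factor(d, cfg) * emission_factor(d, cfg)))

    p0 = np.array(cut.start_um)
    p1 = np.array(cut.end_um)
    seg = p1 - p0
    seg_len = np.linalg.norm(seg)
    seg_dir = seg / seg_len
    rel_x = x_um - p0[0]
    rel_y = y_um - p0[1]
    along = rel_x * seg_dir[0] + rel_y * seg_dir[1]
    perp = -rel_x * seg_dir[1] + rel_y * seg_dir[0]
    in_extent = (along >= 0) & (along <= seg_len)
    if not (footprint[np.abs(perp) < 0.5] & in_extent[np.abs(perp) < 0.5]).any():
        raise ValueError("cut path lies outside the imaged cortex")

    # the cut fires at t = 0; the first post frame is acquired one frame
    # interval later
    times = frame_interval_s * (np.arange(n_pre + n_post) - n_pre + 1)
    sigma_px = scene.psf_sigma_um / scene.pixel_size_um
    h_frames, v_frames, edge_sep = [], [], []
    base_h = footprint * vals["h"]
    base_v = footprint * vals["v"] * scene.channel_gain_v
    peak = max(base_h.max(), base_v.max())
    scale = scene.peak_counts / peak
    for idx, t in enumerate(times):
        if idx < n_pre:
            mh, mv = base_h, base_v
            edge_sep.append(0.0)
        else:
            half = cut.edge_separation_um(t) / 2.0
            # sub-pixel edges: linear coverage ramp over one pixel width
            cov = np.clip(
                (np.abs(perp) - half) / scene.pixel_size_um + 0.5, 0.0, 1.0
            )
            cov = np.where(in_extent, cov, 1.0)
            mh = base_h * cov
            mv = base_v * cov
            edge_sep.append(2 * half)
        eh = ndimage.gaussian_filter(mh * scale, sigma_px)
        ev = ndimage.gaussian_filter(mv * scale, sigma_px)
        if scene.noise:
            eh = np.clip(
                rng.poisson(eh) + rng.normal(0, scene.read_noise_sd, eh.shape), 0, None
            ).astype(float)
            ev = np.clip(
                rng.poisson(ev) + rng.normal(0, scene.read_noise_sd, ev.shape), 0, None
            ).astype(float)
        h_frames.append(eh)
        v_frames.append(ev)
    truth = GroundTruth(edge_separation_um=np.array(edge_sep), time_s=times)
    return CutSeries(times, h_frames, v_frames, scene.pixel_size_um, cut, truth)


def generate_linescan_pair(
    true_thickness_um: float,
    *,
    chromatic_shift_um: tuple[float, float] = (0.0, 0.0),
    line_direction_deg: float = 0.0,
    psf_sigma_um: float = 0.17,
    pixel_size_um: float = 0.05,
    n_pixels: int = 81,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Two-channel linescan across the cortex (membrane and actin markers).

    The membrane channel is a Gaussian at the outer cortex reference; the
    actin channel center is displaced inward by thickness/2.  The chromatic
    shift (x, y, um) is applied to the actin channel, projected onto the
    line direction.  Returns (positions_um, membrane, actin).
    """
    if true_thickness_um < 0:
        raise ValueError("thickness must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.arange(n_pixels) * pixel_size_um
    center = x[n_pixels // 2]
    direction = np.array(
        [np.cos(np.deg2rad(line_direction_deg)), np.sin(np.deg2rad(line_direction_deg))]
    )
    shift = float(np.asarray(chromatic_shift_um) @ direction)
    mem = np.exp(-((x - center) ** 2) / (2 * psf_sigma_um**2))
    actin_center = center - true_thickness_um / 2.0 + shift
    act = np.exp(-((x - actin_center) ** 2) / (2 * psf_sigma_um**2))
    if noise_sd > 0:
        mem = mem + rng.normal(0, noise_sd, n_pixels)
        act = act + rng.normal(0, noise_sd, n_pixels)
    return x, mem, act


def generate_flat_sheet_stack(
    scene: SceneConfig, shape: tuple[int, int] = (8, 8)
) -> tuple[PolStack, GroundTruth]:
    """Five-frame stack of a planar bottom-section cortex sheet.

    Every pixel carries the same orientation statistics (``kappa_peak``,
    ``filament_mean_axis_deg``, tilt, floors) in the image-plane tangent
    plane, rendered through the same per-patch dipole sampling engine as
    the full cell scenes; no PSF or optical-section weighting applies.
    Useful for checking the pixel-level anisotropy estimator against the
    dipole-ensemble oracle.
    """
    rng = np.random.default_rng(scene.seed)
    P = shape[0] * shape[1]
    ones = np.ones(P)
    zeros = np.zeros(P)
    bc = np.column_stack([ones, zeros, zeros])
    bm = np.column_stack([zeros, ones, zeros])
    bn = np.column_stack([zeros, zeros, ones])
    kappa = np.full(P, scene.kappa_peak)
    channels = [(ang, None) for ang in POLSCOPE_ANGLES]
    inten = _patch_channel_intensities(scene, bc, bm, bn, kappa, channels, rng)
    inten[4] = inten[0]  # repeated 0-degree state, same specimen
    expected = [inten[j].reshape(shape) for j in range(5)]
    frames, scale = _apply_counts(scene, expected, rng)
    truth = GroundTruth(intensity_scale=scale)
    return PolStack(np.stack(frames), scene.pixel_size_um), truth


def generate_calibration_samples(
    scene_kind: str, seed: int = 0, *, pixel_size_um: float = 0.1, shape=(64, 64),
    peak_counts: float = 500.0, noise: bool = False, read_noise_sd: float = 3.0,
    depolarization_floor: float = 0.0, emission_floor: float | None = None,
) -> PolStack:
    """Calibration acquisitions: aligned stress fibers or fluorescent plastic.

    ``stressfiber``: fully aligned in-image-plane dipoles at 0 deg, imaged
    at the flat bottom surface.  ``plastic``: uniform 3-D dipole
    orientations (isotropic reference).  Pass the cell scene's
    depolarization floors so the references share the cells' optics.
    """
    rng = np.random.default_rng(seed)
    if scene_kind == "stressfiber":
        d = np.tile([1.0, 0.0, 0.0], (200_000, 1))
    elif scene_kind == "plastic":
        v = rng.normal(size=(200_000, 3))
        d = v / np.linalg.norm(v, axis=1, keepdims=True)
    else:
        raise ValueError("scene_kind must be 'stressfiber' or 'plastic'")
    from .optics import OpticalConfig, emission_factor, excitation_factor

    frames = []
    base = np.ones(shape)
    if scene_kind == "stressfiber":
        # a few bright fiber bands on dark background
        base = np.zeros(shape)
        for r0 in range(8, shape[0] - 8, 12):
            base[r0 : r0 + 3, 4:-4] = 1.0
    vals = []
    for ang in POLSCOPE_ANGLES:
        cfg = OpticalConfig(ang, None, depolarization_floor, emission_floor)
        vals.append(float(np.mean(excitation_factor(d, cfg) * emission_factor(d, cfg))))
    scale = peak_counts / max(vals)
    for v_ in vals:
        img = base * v_ * scale
        if noise:
            img = np.clip(
                rng.poisson(img) + rng.normal(0, read_noise_sd, img.shape), 0, None
            ).astype(float)
        frames.append(img)
    return PolStack(np.stack(frames), pixel_size_um)


def generate_plastic_pair(
    *,
    channel_gain_v: float = 1.15,
    depolarization_floor: float = 0.0,
    emission_floor: float | None = None,
    shape=(64, 64),
    pixel_size_um: float = 0.15,
    peak_counts: float = 500.0,
    noise: bool = True,
    read_noise_sd: float = 3.0,
    seed: int = 0,
):
    """H/V analyzer pair of a fluorescent plastic slide (CTF calibration)."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(400_000, 3))
    d = v / np.linalg.norm(v, axis=1, keepdims=True)
    from .optics import OpticalConfig, emission_factor, excitation_factor

    out = []
    vals = []
    for ana in (0.0, 90.0):
        cfg = OpticalConfig(90.0, ana, depolarization_floor, emission_floor)
        vals.append(float(np.mean(excitation_factor(d, cfg) * emission_factor(d, cfg))))
    scale = peak_counts / max(vals)
    gains = (1.0, channel_gain_v)
    for v_, g in zip(vals, gains):
        img = np.full(shape, v_ * g * scale)
        if noise:
            img = np.clip(
                rng.poisson(img) + rng.normal(0, read_noise_sd, img.shape), 0, None
            ).astype(float)
        out.append(img)
    return out[0], out[1]
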