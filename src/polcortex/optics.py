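"""Dipole photoselection forward model for polarized fluorescence microscopy.

A fluorophore is modelled as a linear absorption/emission dipole, a unit
3-vector ``d`` in the microscope frame (x, y span the image plane, z is the
optical axis).  Excitation with linearly polarized light along the in-plane
unit vector ``e`` photoselects with probability proportional to ``(d.e)^2``;
detection through a linear emission analyzer projects the emitted field onto
the analyzer axis, again quadratically.  Without an analyzer the detected
power is the sum of the two in-plane field components, ``dx^2 + dy^2``
(a dipole along the optical axis radiates no in-plane field toward the
objective in the paraxial picture).

High-NA and fluorophore-wobble depolarization are absorbed into a single
scalar ``depolarization_floor`` f: each quadratic projection ``q`` is blended
as ``(1-f)*q + f/3``, i.e. a fraction f of the interaction is orientation
independent.

Filament-bound fluorophores are described by :class:`FilamentOrientationModel`:
the filament axis lies in a local tangent plane with an axial (mod-180deg)
von Mises orientation distribution, and the dipole sits on a cone of fixed
half-angle (``dipole_tilt_deg``) around the filament axis with uniform cone
azimuth.

Angles are in degrees, measured from the +x axis toward +y, and are treated
modulo 180 (dipole intensities are quadratic, so antipodal directions are
equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Dipole",
    "OpticalConfig",
    "FilamentOrientationModel",
    "TangentPlane",
    "image_plane",
    "meridian_plane",
    "excitation_factor",
    "emission_factor",
    "sample_dipoles",
    "dipole_coefficients",
    "ensemble_intensity",
    "polscope_intensities",
    "polarization_factor",
]

_UNIT_TOL = 1e-9


def _as_unit(direction: np.ndarray) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    norms = np.linalg.norm(d, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("dipole direction must be a unit vector")
    return d


@dataclass(frozen=True)
class Dipole:
    """A single fluorophore transition dipole (unit 3-vector, lab frame)."""

    direction: tuple[float, float, float]

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError(f"|direction| = {np.linalg.norm(d):g} != 1")

    @classmethod
    def in_plane(cls, angle_deg: float) -> "Dipole":
        t = np.deg2rad(angle_deg)
        return cls((float(np.cos(t)), float(np.sin(t)), 0.0))

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass(frozen=True)
class OpticalConfig:
    """Excitation polarization and emission analyzer geometry.

    ``emission_analyzer_deg`` of ``None`` means no analyzer: all in-plane
    emitted light is collected.  ``depolarization_floor`` in [0, 1) is the
    orientation-independent fraction of each quadratic interaction
    (default 0: ideal dipole optics).
    """

    excitation_angle_deg: float
    emission_analyzer_deg: float | None = None
    depolarization_floor: float = 0.0
    emission_depolarization_floor: float | None = None

    @property
    def emission_floor(self) -> float:
        """Emission-side isotropic fraction; defaults to the excitation one.

        High-NA collection and fluorophore wobble depolarize the emission
        path much more strongly than the illumination, so the two floors
        are independently settable.
        """
        if self.emission_depolarization_floor is None:
            return self.depolarization_floor
        return self.emission_depolarization_floor

    def __post_init__(self):
        if not (0.0 <= self.depolarization_floor < 1.0):
            raise ValueError("depolarization_floor must be in [0, 1)")
        if self.emission_depolarization_floor is not None and not (
            0.0 <= self.emission_depolarization_floor < 1.0
        ):
            raise ValueError("emission_depolarization_floor must be in [0, 1)")
        object.__setattr__(
            self, "excitation_angle_deg", float(self.excitation_angle_deg) % 180.0
        )
        if self.emission_analyzer_deg is not None:
            object.__setattr__(
                self, "emission_analyzer_deg", float(self.emission_analyzer_deg) % 180.0
            )


@dataclass(frozen=True)
class FilamentOrientationModel:
    """Orientation statistics of filament-bound dipoles in a tangent plane.

    ``mean_axis_deg``: mean filament axis, measured within the tangent plane
    from its first basis vector.  ``kappa``: concentration of the axial
    (doubled-angle) von Mises distribution; 0 is uniform in-plane.
    ``dipole_tilt_deg``: fixed cone half-angle between dipole and filament
    axis (0 = dipole parallel to filament, the default).
    """

    mean_axis_deg: float = 0.0
    kappa: float = 0.0
    dipole_tilt_deg: float = 0.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass(frozen=True)
class TangentPlane:
    """Orthonormal in-plane basis (u, v) of a surface patch, lab frame."""

    u: tuple[float, float, float]
    v: tuple[float, float, float]

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        u = np.asarray(self.u, float)
        v = np.asarray(self.v, float)
        return u / np.linalg.norm(u), v / np.linalg.norm(v)

    def normal(self) -> np.ndarray:
        u, v = self.basis()
        return np.cross(u, v)


def image_plane() -> TangentPlane:
    """Patch lying in the image plane (bottom cortex of an adherent cell)."""
    return TangentPlane((1.0, 0.0, 0.0), (0.0, 1.0, 0.0))


def meridian_plane(tangent_angle_deg: float = 0.0) -> TangentPlane:
    """Patch containing the optical axis, e.g. the cortex at the contour of a
    central optical section.  ``tangent_angle_deg`` is the in-plane direction
    of the contour tangent (the plane's in-image-plane basis vector)."""
    t = np.deg2rad(tangent_angle_deg)
    return TangentPlane((float(np.cos(t)), float(np.sin(t)), 0.0), (0.0, 0.0, 1.0))


def _in_plane_unit(angle_deg: float) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    return np.array([np.cos(t), np.sin(t), 0.0])


def excitation_factor(dipole, cfg: OpticalConfig) -> np.ndarray | float:
    """Photoselection factor ``(1-f)(d.e)^2 + f/3`` in [0, 1]."""
    d = dipole.vector if isinstance(dipole, Dipole) else _as_unit(dipole)
    e = _in_plane_unit(cfg.excitation_angle_deg)
    f = cfg.depolarization_floor
    q = np.square(d @ e)
    out = (1.0 - f) * q + f / 3.0
    return float(out) if np.ndim(out) == 0 else out


def emission_factor(dipole, cfg: OpticalConfig) -> np.ndarray | float:
    """Analyzer projection factor, or total in-plane collection if no analyzer.

    With an analyzer at angle a: ``(1-f)(d.a)^2 + f/3``.  Without: the sum of
    the two in-plane projections, ``(1-f)(dx^2+dy^2) + 2f/3``.
    """
    d = dipole.vector if isinstance(dipole, Dipole) else _as_unit(dipole)
    f = cfg.emission_floor
    if cfg.emission_analyzer_deg is None:
        q = np.square(d[..., 0]) + np.square(d[..., 1])
        out = (1.0 - f) * q + 2.0 * f / 3.0
    else:
        a = _in_plane_unit(cfg.emission_analyzer_deg)
        out = (1.0 - f) * np.square(d @ a) + f / 3.0
    return float(out) if np.ndim(out) == 0 else out


def dipole_coefficients(
    model: FilamentOrientationModel, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample dipole coordinates in the tangent-plane frame.

    Returns an (n, 3) array of components along (u, v, n) of the patch:
    filament in-plane angle phi drawn from the axial von Mises distribution,
    cone azimuth uniform.  These coefficients are frame-free: the lab-frame
    dipole is ``a*u + b*v + c*n``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mu = np.deg2rad(model.mean_axis_deg)
    if model.kappa == 0.0:
        phi = rng.uniform(0.0, np.pi, n_samples)
    elif np.isinf(model.kappa):
        phi = np.full(n_samples, mu)
    else:
        # doubled-angle convention for axial (mod-pi) data
        phi = 0.5 * rng.vonmises(2.0 * mu, model.kappa, n_samples)
    beta = np.deg2rad(model.dipole_tilt_deg)
    cb, sb = np.cos(beta), np.sin(beta)
    xi = rng.uniform(0.0, 2.0 * np.pi, n_samples)
    cphi, sphi = np.cos(phi), np.sin(phi)
    cxi, sxi = np.cos(xi), np.sin(xi)
    # filament F = (cphi, sphi, 0); cone basis e1 = (-sphi, cphi, 0), e2 = n
    a = cb * cphi - sb * cxi * sphi
    b = cb * sphi + sb * cxi * cphi
    c = sb * sxi
    return np.stack([a, b, c], axis=1)


def sample_dipoles(
    model: FilamentOrientationModel,
    plane: TangentPlane,
    n_samples: int,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw (n, 3) lab-frame unit dipoles for a patch with the given basis."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    u, v = plane.basis()
    n = plane.normal()
    coef = dipole_coefficients(model, n_samples, rng)
    return coef @ np.stack([u, v, n])


def ensemble_intensity(
    model: FilamentOrientationModel,
    plane: TangentPlane,
    cfg: OpticalConfig,
    n_samples: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo expected intensity per unit fluorophore density.

    The mean of excitation_factor * emission_factor over dipoles drawn from
    ``model`` within ``plane``.  Deterministic for a fixed seed.
    """
    d = sample_dipoles(model, plane, n_samples, seed)
    return float(np.mean(excitation_factor(d, cfg) * emission_factor(d, cfg)))


def polscope_intensities(
    model: FilamentOrientationModel,
    plane: TangentPlane,
    n_samples: int = 100_000,
    seed: int | np.random.Generator = 0,
    depolarization_floor: float = 0.0,
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
) -> np.ndarray:
    """Expected intensities under the four excitation polarization states.

    A common dipole sample is reused across the four angles, which mimics a
    noiseless acquisition of the same specimen and cancels most Monte-Carlo
    error from the intensity differences entering the polarization factor.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = sample_dipoles(model, plane, n_samples, rng)
    out = np.empty(len(angles))
    for i, ang in enumerate(angles):
        cfg = OpticalConfig(ang, None, depolarization_floor)
        out[i] = np.mean(excitation_factor(d, cfg) * emission_factor(d, cfg))
    return out


def polarization_factor(i0, i45, i90, i135):
    """p = sqrt((I0-I90)^2 + (I45-I135)^2) / (I0+I45+I90+I135)."""
    a = np.asarray(i0, float) - np.asarray(i90, float)
    b = np.asarray(i45, float) - np.asarray(i135, float)
    c = np.asarray(i0, float) + i45 + np.asarray(i90, float) + i135
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.hypot(a, b) / c
    return float(p) if np.ndim(p) == 0 else p
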