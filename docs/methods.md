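# Methods

`polcortex` quantifies actin-filament order, cell geometry and cortical
tension in dividing cells from fluorescence-polarization microscopy, and
ships a physically explicit synthetic-scene generator so that every stage of
the analysis can be verified against ground truth without microscope data.
This note records the models, the parameters that matter, the numerical
choices, and the limits of what the synthetic tests demonstrate.

## Dipole photoselection model

Each fluorophore is a linear absorption/emission dipole, a unit 3-vector
`d` in the microscope frame (x, y image plane, z optical axis). Excitation
with in-plane polarization `ê` photoselects with probability `(d·ê)²`;
a linear emission analyzer at `â` transmits `(d·â)²`; without an analyzer
the collected power is the sum of the two in-plane field components,
`dx² + dy²` (a dipole along the optical axis radiates no in-plane field
toward the objective in the paraxial picture). High-NA and wobble
depolarization are absorbed into scalar floors: each quadratic projection
`q` is blended as `(1−f)q + f/3`. The excitation and emission floors are
independently settable because a 1.4-NA oil objective depolarizes the
collected emission (full collection cone, fluorophore wobble during the
excited-state lifetime) far more strongly than the illumination.

Filament-bound fluorophores follow a `FilamentOrientationModel`: the
filament axis lies in the local surface tangent plane with an axial
(mod-180°) von Mises orientation distribution — sampled through the
standard doubled-angle construction, so κ = 0 reproduces the uniform
in-plane case — and the dipole sits on a cone of fixed half-angle
(`dipole_tilt_deg`, default 0°: dipole parallel to the filament, consistent
with reports that phalloidin-coupled fluorophores bind F-actin with defined
orientation) with uniform cone azimuth.

`ensemble_intensity` is the Monte-Carlo mean of excitation × emission
factors over seeded dipole samples; it is the independent oracle against
which the rendered images are checked. One dipole sample set is reused
across the polarization states of one acquisition, as a real specimen
would be, which cancels most Monte-Carlo error in the intensity
*differences* that enter the polarization factor.

## The isotropic-network prediction, and why the package computes ≈ 1

A classical mixed-population argument for a central optical section through
a cell whose cortical filaments are random within the local tangent plane
goes: filaments parallel to the section contribute fully polarized signal,
filaments perpendicular to it contribute equal-brightness unpolarized
signal, so the normalized polarization factor should be ≈ 0.5. A
self-consistent dipole model does not reproduce this number under ideal
optics. With zero dipole tilt and zero depolarization, a dipole along the
optical axis is never excited by in-plane-polarized light and is invisible
to the in-plane collection — perpendicular filaments are *dark*, not
unpolarized, so they cannot dilute the modulation. Every tangent-plane
patch then yields a fully modulated four-angle intensity (p = 0.5 raw, the
same as a perfectly aligned in-plane sample), and the normalized equatorial
value computes to ≈ 1.0, not 0.5 (the package's acceptance script reports
≈ 0.998; the small deficit is azimuthal mixing within the optical section).
Dipole tilt does not rescue the mixture argument either: the stress-fiber
calibration sample carries the same fluorophore and the same tilt, so the
dilution largely cancels in the normalization (we compute normalized values
of 0.92–1.04 for tilts of 20–45°) until the magic angle is approached,
where the calibration itself degenerates. The mixture prediction is exact
only in the limit of orientation-independent brightness with a cos²
polarized fraction — equivalent to fully depolarized excitation.
Experimentally measured intermediate values are therefore informative about
depolarization, dipole tilt, labeling background and cytoplasmic signal;
the generator exposes all of these as parameters rather than asserting a
mechanism.

## Synthetic scenes

The cell is a surface of revolution about the spindle axis: a spheroid of
radius R (default 10 µm, elongation configurable) times an equatorial
Gaussian neck `1 − ingression·exp(−t²/2w²)` (neck width default 3.5 µm),
so the furrow diameter `2R(1−ingression)` decreases monotonically and
tangent planes stay analytic. The meridian is parametrized by polar angle
(no pole singularity) and discretized at pixel pitch; each patch carries an
orthonormal (circumferential, meridional, normal) frame, an area weight,
a fluorophore density, and a κ value. Rendering: per-patch dipole sampling
(default 512 dipoles per patch — per-patch independent draws emulate
labeling stochasticity), channel intensities, Gaussian optical-section
weight along z (FWHM default 0.9 µm), bilinear splatting, Gaussian PSF
(σ default 0.15 µm), cumulative per-frame photobleaching, Poisson shot
noise plus Gaussian read noise, and a peak-count intensity scale (default
500–1000 counts, comparable to good confocal acquisitions). The cortex
thickness (default 0.2 µm) is modelled as three radial sub-shells.
All randomness is drawn from a generator seeded by the scene seed;
renders are bit-reproducible.

Spatial profiles around the equator: the κ profile is Gaussian in meridian
arc length and is parametrized by the *observable* it produces — the FWHM
of the anisotropy dip along the cortex (default 4.4 µm). The internal κ
width is solved from the forward single-patch κ → p map computed under the
scene's tilt and depolarization floor; under perfectly ideal optics a
single patch shows no κ dependence of p at all (see above) and the solver
falls back to the von Mises alignment proxy I₁(κ)/I₀(κ). The fluorophore
density enrichment is likewise Gaussian with an imposed FWHM (default
8.4 µm, peak factor configurable). The two widths are independent by
construction, emulating the empirical observation that the oriented zone
is substantially narrower than the actin-accumulation zone.

Live-cell scenes (`default_live_scene`) add: fixed 90° excitation with 0°
and 90° emission analyzers, a vertical-channel transmission gain (CTF
target, default 1.15), excitation floor 0.25, emission floor 0.85, and a
small isotropic cytoplasmic probe pool (5 % of the cortex scale). The two
floors and the cytoplasm level were chosen once so that the rendered
metaphase ratio-versus-tangent-angle relation is well described by the
sin² regression (R² ≈ 0.9–0.95, as observed in real metaphase cortices)
while the geometry correction stays null-safe during ingression; a large
*cytoplasmic* dilution instead of *on-cortex* (emission-floor) dilution
would make the band ratio sensitive to the cortex-to-cytoplasm mixing
weight, which changes as the furrow flattens, and would let pure geometry
masquerade as signal.

Division kinetics impose a linear furrow-diameter ramp (onset 90 s after
anaphase onset, full ingression over 210 s to 15 % of the initial
diameter), saturating-exponential chromatid separation (12 µm plateau,
τ = 90 s), 15 s frame interval, and mild pole-to-pole elongation coupled
to ingression. Laser-cut scenes are planar bottom-section sheets; after
the cut the fluorescence edges separate as
`gap + baseline + amplitude(1 − e^(−t/τ))` with sub-pixel (coverage-ramp)
edges, the first post frame one interval after the cut.

## Analysis pipelines

**LC-PolScope (fixed cells).** Five frames (0°, 45°, 90°, 135°, 0°).
Bleach correction interpolates a multiplicative factor geometrically in
acquisition index between 1 and the frame-1/frame-5 total ratio — exact
for a constant per-frame loss. Per pixel, `a = I0−I90`, `b = I45−I135`,
`c = ΣI`, `p = √(a²+b²)/c`, azimuth `½·atan2(b,a)` in [0°, 180°); pixels
below an intensity floor are masked, not NaN-propagated. p is normalized
between the plastic (0) and stress-fiber (1) calibration medians.
Segmentation is a seeded watershed on the Sobel elevation of the
mean-angle image with border background markers, followed by morphological
closing (filopodia exclusion, default radius 5 px; the synthetic cells have
no filopodia, so quantitative paths use radius 2). An ellipse fit assigns
poles (major axis) and equator (minor axis), flagging near-circular
contours (axis ratio < 1.02) as ambiguous. Measurement regions are
arc-length windows (2 µm equator, 16 µm poles) dilated to a 640 nm band
normal to the contour. The anisotropic-zone width is a least-squares
Gaussian (offset plus signed amplitude) on the p profile,
FWHM = 2√(2 ln 2)·σ.

**Two-polarizer emission ratio (live cells).** The emission ratio is
defined co-polarized over cross-polarized, `r = I_V·CTF / I_H` with
CTF = median(H/V) of a fluorescent-plastic pair — the orientation under
which the metaphase geometry regression `R(α) = a0 + a1·sin²(α)` has a
positive amplitude and equatorial filament alignment drives the furrow
ratio *below* 1 (with the horizontal channel in the numerator every
deviation direction inverts; the convention is fixed here so directions
are reproducible). Cortex tangents come from a periodic smoothing B-spline
of the segmented outline whose smoothing budget adapts to the outline's
local roughness; because a watershed boundary follows the outer gradient
edge of the blurred cortex band rather than its center, contour points are
snapped to the cortical intensity ridge along their normals (parabolic
sub-pixel) before the final spline fit. Channels are averaged over seven
samples along the local normal, the sin² model is fitted on metaphase
frames (per experiment by default), the observed ratio is divided by the
model, site values are taken in 1 µm arc windows at the furrow (both
sides) and the poles (quarter-perimeter points), and normalized by the
mean of three pre-anaphase frames. Frames whose furrow curvature magnitude
exceeds the metaphase value are excluded from interpretation (curvature
gate); cells with spindle axes outside 90° ± 20° (live) or
90°/0° ± 20° (cutting) are ineligible. Bottom-section variants use a
1 × 4 µm equatorial rectangle, and cut-adjacent measurements average four
2 × 2 µm squares flanking the cut, min–max normalized between metaphase
and stress-fiber reference medians.

**Geometry and staging.** Chromatin centers are intensity-weighted
centroids of the two largest thresholded H2B components (one component =
metaphase). Furrow diameter and pole-pole distance are anchor-to-anchor
distances. Equatorial curvature is a Pratt algebraic circle fit on a 4 µm
arc window (the plain Kasa fit is strongly radius-biased on short pixelated
arcs); the sign is negative when the fitted center lies inside the cell
mask (convex cortex) and positive outside (ingressed furrow). Onset
detection runs a per-timepoint two-tailed Welch t-test against the pooled
metaphase reference (α default 0.01; note that with many timepoints the
per-test α implies a nonzero family-wise false-positive rate). The staging
model regresses time after anaphase onset on furrow diameter and chromatin
distance with the full bivariate quartic basis (all monomials of total
degree ≤ 4; an additive per-predictor basis is available); only the linear
part is rank-checked because higher-order monomials are legitimately
near-collinear on smooth kinetics, where OLS resolves them by
pseudo-inverse. Stage bins: pre-ingression [0, 100) s, early [100, 150),
mid [150, 200), late [200, 301] (printed gaps closed as half-open
intervals, boundaries to the later stage); the diameter-ratio rule uses
ratio > 1, (0.8, 1], ≤ 0.8 with the same boundary convention.

**Mechanics.** The tension proxy is the distance between the half-maximum
crossings of the band-normal intensity profile flanking the cut in the
first post-ablation frame (sub-pixel by linear interpolation), minus the
myosin-inhibited baseline; it is reported in µm of displacement, never in
force units, and negative values are flagged rather than clipped.
`fit_recoil` fits `offset + amplitude(1 − e^(−t/τ))` across post frames.
Cortex thickness is twice the Gaussian-center offset of an 11-pixel-window
fit to membrane and actin linescans after projecting the bead-measured
chromatic shift onto the line direction. Kymographs average 25 pixels
across a pole-to-pole line per frame. Cortical intensity time courses use
4 µm arc windows, pre-anaphase normalization, and a late (≥ 180 s)
max-normalized spatial profile.

## What the synthetic tests do and do not show

The generator shares its dipole physics with the oracle used to check the
estimators, so the end-to-end tests demonstrate *internal consistency*:
the estimators recover what the forward model imposed (zone widths,
thickness, recoil, staging times), the geometry correction manufactures no
signal from shape changes alone, and the pixel-level anisotropy estimator
matches the ensemble oracle to 10⁻³. They do not validate the optical
model against a real microscope: real data add non-Gaussian PSF structure,
sequential-channel motion, labeling heterogeneity, filopodia and
out-of-focus background that the scenes only approximate (the
inter-channel temporal shift is available but defaults to zero, handled by
the 7-pixel normal band as in the original protocol). Absolute intensity
scales and noise levels are choices, not measurements.

## Known limitations

- No vectorial high-NA PSF: all aperture effects are collapsed into two
  scalar depolarization floors.
- The sin² geometry regression is an empirical model; the true
  ratio-versus-angle relation of the forward model is a rational function
  that sin² approximates well only under strong emission-side
  depolarization. With weakly depolarized optics the correction would be
  systematically wrong at the poles.
- The curvature gate admits early-ingression frames by design (the furrow
  transiently *flattens*); residual geometry sensitivity of the band ratio
  in that regime is kept below 5 % by the on-cortex dilution model, not
  eliminated.
- The central-section anisotropy dip at an aligned furrow is partly an
  emergent mixing effect of the optical section; its width matches the
  imposed zone width to ±0.5 µm only for moderate alignment (κ ≲ 2) and
  moderate ingression, the regime the defaults emulate.
- Staging is only identifiable after anaphase onset; metaphase cells are
  classified by their single chromatin mass, not by the regression.
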