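"""Cell geometry during division: furrow, chromatin, curvature, staging.

Times are in seconds relative to anaphase onset (first frame of sister
chromatid separation).  The staging regression maps the two geometry
readouts available in fixed cells — cleavage-furrow diameter and
chromatin-chromatin distance — to time after anaphase onset with a
degree-4 polynomial, fitted on live-cell calibration measurements; cells
are then binned into mitotic stages.

Curvature sign convention: a circle fitted to the equatorial cortex whose
center lies inside the cell gives negative curvature (convex cortex), a
center outside gives positive curvature (ingressed furrow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "GeometrySample",
    "StagingModel",
    "StagingResults",
    "chromatin_centers",
    "furrow_and_pole_metrics",
    "fit_circle",
    "equatorial_curvature",
    "detect_onset",
    "infer_time_and_stage",
    "stage_by_diameter_ratio",
    "stage_from_time",
    "STAGE_BINS",
]

# half-open time bins [lo, hi) in seconds; the last bin is closed at 301
STAGE_BINS = (
    ("pre-ingression", 0.0, 100.0),
    ("early ingression", 100.0, 150.0),
    ("mid ingression", 150.0, 200.0),
    ("late ingression", 200.0, 301.0),
)


@dataclass
class GeometrySample:
    """One time point of division geometry."""

    time_s: float
    furrow_diameter_um: float
    chromatin_distance_um: float
    curvature_per_um: float | None = None


def chromatin_centers(
    h2b_image: np.ndarray,
    *,
    threshold_fraction: float = 0.3,
    pixel_size_um: float = 1.0,
) -> dict:
    """Weighted centers of mass of the segregating chromatin masses.

    The H2B image is thresholded at ``threshold_fraction`` of its dynamic
    range; the two largest connected components give intensity-weighted
    centroids and their separation.  Before sister-chromatid separation a
    single component yields one center and an undefined distance.
    """
    img = np.asarray(h2b_image, float)
    lo, hi = img.min(), img.max()
    if hi - lo <= 0:
        raise ValueError("no chromatin signal in image")
    mask = img >= lo + threshold_fraction * (hi - lo)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no chromatin signal above threshold")
    sizes = ndimage.sum_labels(np.ones_like(img), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    keep = [int(order[i]) + 1 for i in range(min(2, n))]
    qc_flag = "extra-components" if n > 2 else "ok"
    centers = []
    for lab in keep:
        sel = labels == lab
        w = img * sel
        total = w.sum()
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        centers.append([float((xx * w).sum() / total), float((yy * w).sum() / total)])
    centers = np.asarray(centers)
    if len(centers) == 2:
        dist = float(np.linalg.norm(centers[0] - centers[1]) * pixel_size_um)
    else:
        dist = None
    return {
        "centers_px": centers,
        "separation_um": dist,
        "n_components": int(n),
        "qc": qc_flag,
    }


def furrow_and_pole_metrics(anchors, pixel_size_um: float) -> dict[str, float]:
    """Furrow diameter and pole-pole distance from contour anchors (um).

    ``anchors`` is a :class:`polcortex.polscope.ContourAnchors`; distances
    are Euclidean between the opposing equatorial / polar anchor points.
    """
    if anchors.ambiguous:
        raise ValueError("ambiguous ellipse axes: cannot assign furrow and poles")
    eq = np.asarray(anchors.equator_xy, float)
    po = np.asarray(anchors.pole_xy, float)
    return {
        "furrow_diameter_um": float(np.linalg.norm(eq[0] - eq[1]) * pixel_size_um),
        "pole_pole_distance_um": float(np.linalg.norm(po[0] - po[1]) * pixel_size_um),
    }


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Pratt algebraic circle fit; returns (center, radius).

    Minimizes the algebraic distance with Pratt's normalization, which is
    far less radius-biased than the plain Kasa fit on short noisy arcs
    (the regime of a 4-um curvature window on a pixelated contour).
    """
    pts = np.asarray(points, float)
    x = pts[:, 0] - pts[:, 0].mean()
    y = pts[:, 1] - pts[:, 1].mean()
    z = x**2 + y**2
    Zm = np.column_stack([z, x, y, np.ones_like(x)])
    M = Zm.T @ Zm / len(x)
    B = np.zeros((4, 4))
    B[0, 3] = B[3, 0] = -2.0
    B[1, 1] = B[2, 2] = 1.0
    from scipy.linalg import eig

    vals, vecs = eig(M, B)
    vals = np.real(vals)
    # the optimum is the smallest non-negative eigenvalue; noiseless data
    # put it at numerical zero
    good = np.isfinite(vals) & (vals > -1e-8)
    if not good.any():  # degenerate (e.g. exactly collinear) input
        return np.array([np.inf, np.inf]), np.inf
    k = np.flatnonzero(good)[np.argmin(vals[good])]
    A_, B_, C_, D_ = np.real(vecs[:, k])
    if abs(A_) < 1e-14:  # straight line limit
        return np.array([np.inf, np.inf]), np.inf
    cx = -B_ / (2 * A_)
    cy = -C_ / (2 * A_)
    r = float(np.sqrt(max(cx**2 + cy**2 - D_ / A_, 0.0)))
    return np.array([cx + pts[:, 0].mean(), cy + pts[:, 1].mean()]), r


def equatorial_curvature(
    contour_px: np.ndarray,
    anchor_index: int,
    cell_mask: np.ndarray,
    pixel_size_um: float,
    *,
    arc_window_um: float = 4.0,
) -> dict:
    """Signed curvature (1/um) of the cortex around the equatorial anchor.

    A circle is fitted to the contour points within ``arc_window_um`` of
    arc length centered on the anchor; curvature is 1/radius with the sign
    set by whether the fitted center lies inside (negative) or outside
    (positive) the cell mask.  Nearly collinear windows return ~0 with a
    flag instead of failing.
    """
    contour = np.asarray(contour_px, float)
    steps = np.linalg.norm(np.diff(contour, axis=0, append=contour[:1]), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)[:-1]]) * pixel_size_um
    total = arc[-1] + steps[-1] * pixel_size_um
    d = np.abs(arc - arc[anchor_index])
    d = np.minimum(d, total - d)
    window = contour[d <= arc_window_um / 2.0]
    if len(window) < 3:
        raise ValueError("curvature window contains fewer than 3 points")
    center, radius = fit_circle(window)
    flat_flag = radius * pixel_size_um > 1e3
    if flat_flag:
        return {"curvature_per_um": 0.0, "radius_um": np.inf, "flag": "collinear"}
    xi = int(round(center[0]))
    yi = int(round(center[1]))
    inside = (
        0 <= yi < cell_mask.shape[0]
        and 0 <= xi < cell_mask.shape[1]
        and bool(cell_mask[yi, xi])
    )
    sign = -1.0 if inside else 1.0
    curvature = sign / (radius * pixel_size_um)
    return {
        "curvature_per_um": float(curvature),
        "radius_um": float(radius * pixel_size_um),
        "flag": "ok",
    }


def detect_onset(
    series_by_cell: pd.DataFrame,
    metaphase_reference: np.ndarray,
    *,
    alpha_level: float = 0.01,
    value_column: str = "value",
) -> dict:
    """First time point whose across-cell values differ from metaphase.

    Runs a per-timepoint two-tailed two-sample t-test of the cells' values
    at that time against the pooled metaphase reference and returns the
    earliest time with p < ``alpha_level``.  ``series_by_cell`` needs
    columns time_s, cell and ``value_column``; missing cells at a time
    point are simply absent from that test.
    """
    ref = np.asarray(metaphase_reference, float)
    times = np.sort(series_by_cell["time_s"].unique())
    pvals = {}
    onset = None
    for t in times:
        vals = series_by_cell.loc[
            series_by_cell["time_s"] == t, value_column
        ].to_numpy()
        if len(vals) < 2:
            continue
        p = stats.ttest_ind(vals, ref, equal_var=False).pvalue
        pvals[float(t)] = float(p)
        if onset is None and p < alpha_level:
            onset = float(t)
    return {"onset_time_s": onset, "pvalues": pvals, "alpha_level": alpha_level}


def _quartic_design(diameter, distance, bivariate: bool):
    d1 = np.asarray(diameter, float)
    d2 = np.asarray(distance, float)
    cols, names = [], []
    if bivariate:
        for i in range(5):
            for j in range(5 - i):
                cols.append(d1**i * d2**j)
                names.append(f"d^{i} c^{j}")
    else:
        cols.append(np.ones_like(d1))
        names.append("1")
        for k in range(1, 5):
            cols.append(d1**k)
            names.append(f"d^{k}")
            cols.append(d2**k)
            names.append(f"c^{k}")
    return np.column_stack(cols), names


@dataclass
class StagingResults:
    """Fitted degree-4 staging regression with its fit domain."""

    params: np.ndarray
    term_names: list[str]
    bivariate: bool
    rsquared: float
    nobs: int
    domain: dict  # predictor ranges seen during fitting
    _sm_results: object | None = None

    def predict_time(self, furrow_diameter_um, chromatin_distance_um):
        """Inferred time after anaphase onset (s); flags extrapolation."""
        d1 = np.atleast_1d(np.asarray(furrow_diameter_um, float))
        d2 = np.atleast_1d(np.asarray(chromatin_distance_um, float))
        X, _ = _quartic_design(d1, d2, self.bivariate)
        t = X @ self.params
        extrapolated = (
            (d1 < self.domain["furrow_diameter_um"][0])
            | (d1 > self.domain["furrow_diameter_um"][1])
            | (d2 < self.domain["chromatin_distance_um"][0])
            | (d2 > self.domain["chromatin_distance_um"][1])
        )
        if np.isscalar(furrow_diameter_um) or np.ndim(furrow_diameter_um) == 0:
            return float(t[0]), bool(extrapolated[0])
        return t, extrapolated

    def summary(self):
        if self._sm_results is not None:
            return self._sm_results.summary()
        return f"degree-4 staging fit, R^2 = {self.rsquared:.4f}, n = {self.nobs}"


class StagingModel:
    """Degree-4 polynomial regression of division time on geometry.

    Regresses time after anaphase onset on cleavage-furrow diameter and
    chromatin-chromatin distance using the full bivariate quartic basis
    (all monomials of total degree <= 4); an additive per-predictor
    alternative is available via ``bivariate=False``.
    """

    def __init__(self, table: pd.DataFrame, bivariate: bool = True):
        required = {"time_s", "furrow_diameter_um", "chromatin_distance_um"}
        if not required.issubset(table.columns):
            raise ValueError(f"staging table needs columns {sorted(required)}")
        self.table = table.dropna(subset=sorted(required)).copy()
        self.bivariate = bivariate

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kw) -> "StagingModel":
        return cls(table, **kw)

    def fit(self) -> StagingResults:
        import statsmodels.api as sm

        X, names = _quartic_design(
            self.table["furrow_diameter_um"],
            self.table["chromatin_distance_um"],
            self.bivariate,
        )
        d1 = self.table["furrow_diameter_um"].to_numpy()
        d2 = self.table["chromatin_distance_um"].to_numpy()
        linear = np.column_stack([np.ones_like(d1), d1, d2])
        if np.linalg.matrix_rank(linear) < 3:
            raise ValueError(
                "rank-deficient staging design (constant or collinear predictors)"
            )
        # higher-order terms may be near-collinear on smooth kinetics; OLS
        # resolves them by pseudo-inverse
        res = sm.OLS(self.table["time_s"].to_numpy(), X).fit()
        domain = {
            "furrow_diameter_um": (
                float(self.table["furrow_diameter_um"].min()),
                float(self.table["furrow_diameter_um"].max()),
            ),
            "chromatin_distance_um": (
                float(self.table["chromatin_distance_um"].min()),
                float(self.table["chromatin_distance_um"].max()),
            ),
        }
        return StagingResults(
            params=np.asarray(res.params),
            term_names=names,
            bivariate=self.bivariate,
            rsquared=float(res.rsquared),
            nobs=int(res.nobs),
            domain=domain,
            _sm_results=res,
        )


def stage_from_time(time_s: float) -> str:
    """Stage label from time after anaphase onset (half-open bins)."""
    for name, lo, hi in STAGE_BINS:
        if lo <= time_s < hi or (name == "late ingression" and time_s == hi):
            return name
    return "pre-ingression" if time_s < 0 else "late ingression"


def infer_time_and_stage(
    sample: GeometrySample | dict,
    model: StagingResults,
    *,
    n_chromatin_centers: int = 2,
) -> dict:
    """Inferred time after anaphase onset and mitotic-stage label.

    A cell with a single chromatin mass is metaphase by definition; for
    others the staging regression provides the time, binned into the
    pre/early/mid/late-ingression stages.  Out-of-domain geometry sets an
    extrapolation flag.
    """
    if n_chromatin_centers < 2:
        return {"time_s": None, "stage": "metaphase", "extrapolated": False}
    if isinstance(sample, GeometrySample):
        d, c = sample.furrow_diameter_um, sample.chromatin_distance_um
    else:
        d, c = sample["furrow_diameter_um"], sample["chromatin_distance_um"]
    t, extrapolated = model.predict_time(d, c)
    return {"time_s": t, "stage": stage_from_time(t), "extrapolated": extrapolated}


def stage_by_diameter_ratio(
    furrow_diameter_um: float,
    cell_diameter_at_chromatin_um: float,
    *,
    pre_chromosome_segregation: bool = False,
) -> str:
    """Stage from the furrow / chromatin-position diameter ratio.

    pre-ingression: ratio > 1; early ingression: 0.8 < ratio <= 1;
    late ingression: ratio <= 0.8 (boundary values go to the later stage).
    """
    if furrow_diameter_um <= 0 or cell_diameter_at_chromatin_um <= 0:
        raise ValueError("diameters must be > 0")
    if pre_chromosome_segregation:
        return "metaphase"
    ratio = furrow_diameter_um / cell_diameter_at_chromatin_um
    if ratio > 1.0:
        return "pre-ingression"
    if ratio > 0.8:
        return "early ingression"
    return "late ingression"
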