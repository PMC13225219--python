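"""Actomyosin-ring morphometry from time-lapse stacks.

Per frame: optional classical denoising, Huang thresholding, extraction of
the sub-pixel inner-edge contour of the ring, low-pass Fourier-descriptor
smoothing, and the ImageJ circularity measure 4πA/P². Trajectories whose
final area has not contracted are flagged excluded. The population trend of
circularity over time is fitted per genotype with a penalized B-spline
smooth plus a per-sample random intercept, the smoothing parameter chosen
by restricted maximum likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .image_io import ImageStack, Mask
from . import roi as roi_mod


class TopologyError(ValueError):
    """Mask does not have exactly one hole."""

    def __init__(self, n_holes: int):
        super().__init__(f"expected exactly 1 hole, found {n_holes}")
        self.n_holes = n_holes


@dataclass
class RingParams:
    denoise_method: str = "none"        # none | gaussian | median
    denoise_strength: float = 1.0
    threshold_method: str = "huang"
    relative_descriptors_pct: float = 8.0
    absolute_descriptors: int | None = None
    n_resample: int = 384
    min_contraction_frac: float = 0.2


@dataclass
class RingOutline:
    vertices: np.ndarray        # closed polygon, (y, x) sub-pixel
    area: float
    perimeter: float
    circularity: float
    frame_time_min: float


@dataclass
class RingTrajectory:
    sample_id: str
    genotype: str
    outlines: list[RingOutline]
    included: bool
    exclusion_reason: str | None = None
    missing_frames: list[int] = field(default_factory=list)


@dataclass
class TrendFit:
    genotype: str
    grid_times: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    sigma2: float               # residual variance
    var_sample: float           # random-intercept variance
    var_smooth: float           # wiggle-component variance
    sample_intercepts: dict


# ---------------------------------------------------------------------------
# per-frame operations


def denoise(image: np.ndarray, method: str = "none",
            strength: float = 1.0) -> np.ndarray:
    """Classical denoiser: identity, Gaussian blur, or median filter."""
    image = np.asarray(image, dtype=float)
    if method == "none":
        return image
    if method == "gaussian":
        return ndimage.gaussian_filter(image, sigma=strength)
    if method == "median":
        size = max(3, int(2 * round(strength) + 1))
        return ndimage.median_filter(image, size=size)
    raise ValueError(f"unknown denoise method {method!r}")


def segment_ring(frame: np.ndarray, params: RingParams | None = None
                 ) -> Mask | None:
    """Huang-threshold the frame and keep the largest foreground component.

    Returns ``None`` (segmentation failed) when there is no contrast or no
    foreground component.
    """
    params = params or RingParams()
    img = denoise(frame, params.denoise_method, params.denoise_strength)
    try:
        thr = roi_mod.auto_threshold(img, params.threshold_method)
    except roi_mod.DegenerateInputError:
        return None
    fg = img > thr
    labels, n = ndimage.label(fg)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return Mask(labels == keep)


def extract_inner_outline(mask: Mask) -> np.ndarray:
    """Sub-pixel closed contour of the ring's single hole (the inner edge).

    The contour is traced at the 0.5 iso-level of the hole region,
    oriented counter-clockwise (positive shoelace area in (y, x) axes),
    with the first vertex repeated at the end.
    """
    from skimage import measure

    m = mask.pixels
    filled = ndimage.binary_fill_holes(m)
    holes = filled & ~m
    _, n_holes = ndimage.label(holes)
    if n_holes != 1:
        raise TopologyError(n_holes)
    contours = measure.find_contours(holes.astype(float), 0.5)
    contour = max(contours, key=len)
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[0]])
    if _signed_area(contour) < 0:
        contour = contour[::-1]
    return contour


def _signed_area(closed: np.ndarray) -> float:
    y, x = closed[:-1, 0], closed[:-1, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def resample_polygon(polygon: np.ndarray, n: int = 128) -> np.ndarray:
    """Resample a closed polygon to n equally spaced vertices (closed)."""
    v = np.asarray(polygon, dtype=float)
    if not np.allclose(v[0], v[-1]):
        v = np.vstack([v, v[0]])
    seg = np.sqrt(np.sum(np.diff(v, axis=0) ** 2, axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate polygon")
    si = np.linspace(0, total, n, endpoint=False)
    out = np.column_stack([np.interp(si, s, v[:, 0]), np.interp(si, s, v[:, 1])])
    return np.vstack([out, out[0]])


def fourier_smooth(polygon: np.ndarray,
                   relative_descriptors_pct: float = 8.0,
                   absolute_descriptors: int | None = None) -> np.ndarray:
    """Low-pass the contour in Fourier-descriptor space.

    Vertices are treated as a complex sequence x + iy; the lowest
    ``max(2, round(pct% of n))`` frequency pairs (or an absolute count) are
    retained symmetrically and the rest zeroed. Vertex count and the
    open/closed convention of the input are preserved.
    """
    v = np.asarray(polygon, dtype=float)
    closed = np.allclose(v[0], v[-1])
    if closed:
        v = v[:-1]
    n = len(v)
    if n < 8:
        raise ValueError("need at least 8 vertices")
    if _shoelace_abs(v) == 0:
        raise ValueError("degenerate polygon (zero area)")
    if absolute_descriptors is not None:
        k = int(absolute_descriptors)
    else:
        k = max(2, round(relative_descriptors_pct / 100.0 * n))
    z = v[:, 1] + 1j * v[:, 0]
    F = np.fft.fft(z)
    keep = np.zeros(n, dtype=bool)
    keep[0] = True
    for j in range(1, min(k, n // 2) + 1):
        keep[j] = True
        keep[-j] = True
    F[~keep] = 0
    zs = np.fft.ifft(F)
    out = np.column_stack([zs.imag, zs.real])
    if closed:
        out = np.vstack([out, out[0]])
    return out


def _shoelace_abs(v: np.ndarray) -> float:
    y, x = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def measure_circularity(polygon: np.ndarray) -> tuple[float, float, float]:
    """Shoelace area, vertex-chain perimeter and circularity 4πA/P².

    Raises on self-intersecting polygons.
    """
    import shapely

    v = np.asarray(polygon, dtype=float)
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    ring = shapely.LinearRing(np.column_stack([v[:, 1], v[:, 0]]))
    if not ring.is_simple:
        raise ValueError("polygon is self-intersecting")
    area = _shoelace_abs(v)
    d = np.sqrt(np.sum((v - np.roll(v, -1, axis=0)) ** 2, axis=1))
    perim = float(d.sum())
    if perim == 0:
        raise ValueError("degenerate polygon")
    return float(area), perim, 4 * math.pi * area / perim**2


# ---------------------------------------------------------------------------
# trajectories


def build_trajectory(stack: ImageStack, params: RingParams | None = None,
                     time_zero_frame: int = 0, sample_id: str = "",
                     genotype: str = "") -> RingTrajectory:
    """Segment → inner outline → resample → Fourier smooth → measure, per frame.

    Frame times are minutes since ``time_zero_frame`` (the first frame after
    the 14th nuclear division). Frames that fail segmentation or contouring
    are recorded as missing. A trajectory whose final area exceeds
    ``(1 − min_contraction_frac) ×`` the initial area is flagged excluded
    ("no contraction").
    """
    params = params or RingParams()
    dt_min = stack.time_interval_s / 60.0
    outlines: list[RingOutline] = []
    missing: list[int] = []
    for t in range(time_zero_frame, stack.n_frames):
        frame = stack.plane(t=t)
        seg = segment_ring(frame, params)
        if seg is None:
            missing.append(t)
            continue
        try:
            contour = extract_inner_outline(seg)
            poly = resample_polygon(contour, params.n_resample)
            poly = fourier_smooth(poly, params.relative_descriptors_pct,
                                  params.absolute_descriptors)
            area, perim, circ = measure_circularity(poly)
        except (TopologyError, ValueError):
            missing.append(t)
            continue
        outlines.append(RingOutline(vertices=poly, area=area, perimeter=perim,
                                    circularity=circ,
                                    frame_time_min=(t - time_zero_frame) * dt_min))
    included, reason = True, None
    if len(outlines) >= 2:
        if outlines[-1].area > (1 - params.min_contraction_frac) * outlines[0].area:
            included, reason = False, "no contraction"
    elif not outlines:
        included, reason = False, "no measurable frames"
    return RingTrajectory(sample_id=sample_id, genotype=genotype,
                          outlines=outlines, included=included,
                          exclusion_reason=reason, missing_frames=missing)


def trajectory_table(trajectories: list[RingTrajectory]) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        for o in tr.outlines:
            rows.append((tr.sample_id, tr.genotype, o.frame_time_min,
                         o.area, o.perimeter, o.circularity, tr.included))
    return pd.DataFrame(rows, columns=["sample", "genotype", "time_min",
                                       "area", "perimeter", "circularity",
                                       "included"])


# ---------------------------------------------------------------------------
# trend model: penalized B-spline smooth + per-sample random intercept


def _bspline_design(t: np.ndarray, tmin: float, tmax: float,
                    n_basis: int) -> tuple[np.ndarray, np.ndarray]:
    degree = 3
    n_interior = n_basis - degree - 1
    interior = np.linspace(tmin, tmax, n_interior + 2)[1:-1]
    knots = np.concatenate([[tmin] * (degree + 1), interior,
                            [tmax] * (degree + 1)])
    tt = np.clip(t, tmin, tmax)
    B = BSpline.design_matrix(tt, knots, degree).toarray()
    return B, knots


def _reparam(n_basis: int, penalty_order: int
             ) -> tuple[np.ndarray, np.ndarray]:
    """Split the coefficient space into penalty null space and unit-penalty
    wiggle space (the standard splines-as-mixed-models transform)."""
    D = np.diff(np.eye(n_basis), n=penalty_order, axis=0)
    S = D.T @ D
    lam, U = np.linalg.eigh(S)
    null = lam < 1e-10
    U0 = U[:, null]
    Up = U[:, ~null] / np.sqrt(lam[~null])
    return U0, Up


def fit_circularity_trend(data: pd.DataFrame, n_basis: int = 10,
                          penalty_order: int = 1,
                          lam: float | None = None,
                          grid_n: int = 50) -> dict[str, TrendFit]:
    """Fit, per genotype, a REML-penalized spline of circularity on time with
    a zero-mean random intercept per sample.

    ``data`` needs columns ``time_min, circularity, sample, genotype``.
    ``lam`` fixes the smoothing parameter instead of REML when given
    (``lam → ∞`` collapses the smooth to the weighted mean; ``lam → 0``
    interpolates).
    """
    required = {"time_min", "circularity", "sample", "genotype"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    fits = {}
    for g, sub in data.groupby("genotype"):
        fits[str(g)] = _fit_one_trend(sub, n_basis, penalty_order, lam, grid_n)
    return fits


def _fit_one_trend(sub: pd.DataFrame, n_basis: int, penalty_order: int,
                   lam: float | None, grid_n: int) -> TrendFit:
    t = sub["time_min"].to_numpy(dtype=float)
    y = sub["circularity"].to_numpy(dtype=float)
    samples = sub["sample"].astype(str).to_numpy()
    uniq = sorted(set(samples))
    if len(uniq) < 3 or len(set(t)) < 4:
        raise ValueError("need >=3 samples and >=4 distinct time points")
    tmin, tmax = float(t.min()), float(t.max())
    B, knots = _bspline_design(t, tmin, tmax, n_basis)
    U0, Up = _reparam(n_basis, penalty_order)
    X = B @ U0                                   # penalty null space
    Z1 = B @ Up                                  # unit-penalty wiggles
    Z2 = (samples[:, None] == np.array(uniq)[None, :]).astype(float)
    n, p = len(y), X.shape[1]
    q1, q2 = Z1.shape[1], Z2.shape[1]

    def neg_reml(logpsi: np.ndarray) -> float:
        psi1, psi2 = np.exp(np.clip(logpsi, -30, 30))
        V0 = np.eye(n) + psi1 * (Z1 @ Z1.T) + psi2 * (Z2 @ Z2.T)
        try:
            L = np.linalg.cholesky(V0)
        except np.linalg.LinAlgError:
            return 1e12
        logdetV = 2 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V0, y)
        Vi_X = np.linalg.solve(V0, X)
        XtViX = X.T @ Vi_X
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(V0, r))
        sig2 = quad / (n - p)
        return 0.5 * ((n - p) * np.log(sig2) + logdetV + logdetX)

    if lam is not None:
        psi = np.array([1.0 / lam, 1e-8])
        # still estimate the sample-intercept ratio by 1-D REML
        res = minimize(lambda v: neg_reml(np.array([np.log(psi[0]), v[0]])),
                       x0=[0.0], method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6})
        logpsi = np.array([np.log(psi[0]), res.x[0]])
    else:
        res = minimize(neg_reml, x0=[0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-8, "maxiter": 400})
        logpsi = res.x
    psi1, psi2 = np.exp(logpsi)

    # ridge (Henderson) form at the chosen variance ratios
    W = np.hstack([X, Z1, Z2])
    Dpen = np.diag(np.concatenate([np.zeros(p), np.full(q1, 1 / psi1),
                                   np.full(q2, 1 / psi2)]))
    A = W.T @ W + Dpen
    coef = np.linalg.solve(A, W.T @ y)
    resid = y - W @ coef
    edf = float(np.trace(np.linalg.solve(A, W.T @ W)))
    sig2 = float(resid @ resid / max(n - edf, 1.0))

    grid = np.linspace(tmin, tmax, grid_n)
    Bg = BSpline.design_matrix(grid, knots, 3).toarray()
    G = np.hstack([Bg @ U0, Bg @ Up, np.zeros((grid_n, q2))])
    fitted = G @ coef
    cov = sig2 * np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, cov, G), 0.0))

    intercepts = dict(zip(uniq, coef[p + q1:]))
    return TrendFit(genotype=str(sub["genotype"].iloc[0]),
                    grid_times=grid, fitted=fitted, se=se, sigma2=sig2,
                    var_sample=float(psi2 * sig2),
                    var_smooth=float(psi1 * sig2),
                    sample_intercepts=intercepts)
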