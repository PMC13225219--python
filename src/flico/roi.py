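"""Region-of-interest construction for colocalization analysis.

Rebuilds the analyzable region from the Filamin channel: the bright
cell-boundary network is kept (Otsu on a mean-filtered image), nuclear
voids fall below threshold, bright autofluorescent spots are masked out
per channel (rolling-ball + mean-filter difference + MaxEntropy + one
dilation), and user-supplied manual exclusions are honoured.

Thresholds follow ImageJ AutoThreshold semantics: a 256-bin histogram of
the min–max-rescaled masked intensities; "above threshold" is strict (>).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import Mask


class DegenerateInputError(ValueError):
    """Input has no contrast to threshold."""


@dataclass
class RoiParams:
    mean_radius_roi_px: int = 4
    mean_radius_spot_px: int = 3
    rolling_ball_radius_px: int = 50
    dilation_iterations: int = 1
    roi_threshold_method: str = "otsu"
    spot_threshold_method: str = "maxentropy"
    max_spot_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_radius_roi_px < 1 or self.mean_radius_spot_px < 1:
            raise ValueError("filter radii must be >= 1")
        if self.dilation_iterations < 0:
            raise ValueError("dilation_iterations must be >= 0")


@dataclass
class RoiResult:
    roi: Mask
    spot_masks: list[Mask]
    empty: bool
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# filters


def _disc_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    return (dy**2 + dx**2 <= r**2)


def mean_filter(image: np.ndarray, radius_px: int) -> np.ndarray:
    """Mean over a circular neighborhood of the given radius, reflected edges."""
    image = np.asarray(image, dtype=float)
    fp = _disc_footprint(radius_px)
    kernel = fp / fp.sum()
    return ndimage.convolve(image, kernel, mode="reflect")


def rolling_ball_background(image: np.ndarray, radius_px: int,
                            kernel: str = "ball") -> np.ndarray:
    """Subtract a smooth morphological background estimate, clipped at 0.

    ``kernel='ball'`` uses the classical rolling-ball estimate;
    ``kernel='paraboloid'`` a flattened-ellipsoid approximation of it.
    """
    from skimage import restoration

    image = np.asarray(image, dtype=float)
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    if radius_px > max(image.shape):
        raise ValueError("rolling-ball radius exceeds image extent")
    if kernel == "ball":
        bg = restoration.rolling_ball(image, radius=radius_px)
    elif kernel == "paraboloid":
        k = restoration.ellipsoid_kernel((2 * radius_px + 1,) * 2,
                                         radius_px * 0.5)
        bg = restoration.rolling_ball(image, kernel=k)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return np.clip(image - bg, 0, None)


# ---------------------------------------------------------------------------
# histogram thresholds


def _histogram_256(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise DegenerateInputError("constant image: no threshold exists")
    scaled = np.clip((values - lo) / (hi - lo) * 255.0, 0, 255)
    hist = np.bincount(scaled.astype(np.int64), minlength=256)[:256]
    return hist.astype(float), lo, hi


def _otsu_bin(hist: np.ndarray) -> int:
    total = hist.sum()
    p = hist / total
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(256))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def _maxentropy_bin(hist: np.ndarray) -> int:
    """Kapur–Sahoo–Wong maximum-entropy threshold bin."""
    p = hist / hist.sum()
    P = np.cumsum(p)
    eps = 1e-12
    best_t, best_h = 0, -np.inf
    plogp = np.where(p > eps, p * np.log(p + eps), 0.0)
    c_plogp = np.cumsum(plogp)
    for t in range(256):
        w0, w1 = P[t], 1.0 - P[t]
        if w0 < eps or w1 < eps:
            continue
        h0 = np.log(w0) - c_plogp[t] / w0
        h1 = np.log(w1) - (c_plogp[-1] - c_plogp[t]) / w1
        if h0 + h1 > best_h:
            best_h, best_t = h0 + h1, t
    return best_t


def _huang_bin(hist: np.ndarray) -> int:
    """Huang–Wang fuzzy-entropy minimization threshold bin."""
    nz = np.nonzero(hist)[0]
    first, last = nz[0], nz[-1]
    lev = np.arange(256, dtype=float)
    w = np.cumsum(hist)
    s = np.cumsum(hist * lev)
    w_tot, s_tot = w[-1], s[-1]
    c = float(last - first)
    best_t, best_e = first, np.inf
    for t in range(first, last + 1):
        if w[t] == 0 or w_tot - w[t] == 0:
            mu0 = lev[t] if w[t] == 0 else s[t] / w[t]
            mu1 = lev[t] if w_tot - w[t] == 0 else (s_tot - s[t]) / (w_tot - w[t])
        else:
            mu0 = s[t] / w[t]
            mu1 = (s_tot - s[t]) / (w_tot - w[t])
        mu = np.where(lev <= t, mu0, mu1)
        m = 1.0 / (1.0 + np.abs(lev - mu) / c)      # membership in [0.5, 1]
        valid = (hist > 0) & (m > 1e-12) & (m < 1 - 1e-12)
        mm = m[valid]
        ent = np.sum(hist[valid] * (-mm * np.log(mm)
                                    - (1 - mm) * np.log(1 - mm)))
        if ent < best_e:
            best_e, best_t = ent, t
    return int(best_t)


_THRESHOLD_FUNCS = {"otsu": _otsu_bin, "maxentropy": _maxentropy_bin,
                    "huang": _huang_bin}


def auto_threshold(image: np.ndarray, method: str = "otsu",
                   mask: Mask | None = None) -> float:
    """Histogram threshold (Otsu / Kapur max-entropy / Huang) in intensity units.

    Computed on a 256-bin histogram of the (masked) min–max-rescaled pixels,
    mirroring ImageJ AutoThreshold on 16-bit data. Foreground is strictly
    above the returned value.
    """
    if method not in _THRESHOLD_FUNCS:
        raise ValueError(f"unknown threshold method {method!r}")
    image = np.asarray(image, dtype=float)
    vals = image[mask.pixels] if mask is not None else image.ravel()
    if vals.size == 0:
        raise DegenerateInputError("empty mask")
    hist, lo, hi = _histogram_256(vals)
    t_bin = _THRESHOLD_FUNCS[method](hist)
    return lo + (t_bin / 255.0) * (hi - lo)


# ---------------------------------------------------------------------------
# the ROI macro


def build_spot_mask(channel: np.ndarray, params: RoiParams | None = None) -> Mask:
    """Segment bright autofluorescent spots in one channel.

    Rolling-ball background subtraction, then the difference between the
    background-removed image and its mean-filtered copy isolates sharp
    bright features; MaxEntropy thresholds that difference and the result
    is dilated once (3x3 square).

    Spots are by construction sparse: a "detection" whose footprint exceeds
    ``max_spot_fraction`` of the image means the entropy split landed inside
    noise or structure-edge residuals (there are no spots to find) and an
    empty mask is returned instead.
    """
    params = params or RoiParams()
    bg_removed = rolling_ball_background(np.asarray(channel, dtype=float),
                                         params.rolling_ball_radius_px)
    smooth = mean_filter(bg_removed, params.mean_radius_spot_px)
    diff = np.clip(bg_removed - smooth, 0, None)
    try:
        thr = auto_threshold(diff, params.spot_threshold_method)
    except DegenerateInputError:
        return Mask(np.zeros_like(diff, dtype=bool))
    spots = diff > thr
    if spots.mean() > params.max_spot_fraction:
        return Mask(np.zeros_like(diff, dtype=bool))
    if params.dilation_iterations > 0:
        spots = ndimage.binary_dilation(
            spots, structure=np.ones((3, 3), dtype=bool),
            iterations=params.dilation_iterations)
    return Mask(spots)


def build_embryo_roi(filamin_channel: np.ndarray,
                     params: RoiParams | None = None,
                     manual_exclusion: Mask | None = None,
                     spot_channels: list[np.ndarray] | None = None,
                     background_value: float = 0.0) -> RoiResult:
    """Build the colocalization ROI from the Filamin channel.

    The scalar ``background_value`` (e.g. the control-image mean) is
    subtracted, the image is mean-filtered (radius 4) and Otsu-thresholded;
    above-threshold pixels form the boundary-network ROI (nuclear voids fall
    below). Manual exclusions and per-channel spot masks are then removed.
    An all-background image yields an empty-flagged result, not an error.
    """
    params = params or RoiParams()
    img = np.clip(np.asarray(filamin_channel, dtype=float) - background_value,
                  0, None)
    smooth = mean_filter(img, params.mean_radius_roi_px)
    thr = None
    try:
        thr = auto_threshold(smooth, params.roi_threshold_method)
        roi = smooth > thr
    except DegenerateInputError:
        roi = np.zeros_like(img, dtype=bool)

    if manual_exclusion is not None:
        roi &= ~manual_exclusion.pixels

    channels = spot_channels if spot_channels is not None else [filamin_channel]
    spot_masks = [build_spot_mask(np.asarray(ch, dtype=float), params)
                  for ch in channels]
    for sm in spot_masks:
        roi &= ~sm.pixels

    return RoiResult(
        roi=Mask(roi),
        spot_masks=spot_masks,
        empty=not roi.any(),
        provenance={
            "roi_threshold": thr,
            "background_value": background_value,
            "order": "subtract-scalar-background, mean-filter, otsu, "
                     "manual-exclusion, spot-exclusion",
            "params": vars(params),
        },
    )
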