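"""Control-calibrated colocalization statistics.

Per-channel global thresholds come from single-fluorophore control images
(pooled pixel mean + 3 SD). Per image, within the ROI:

* M1 — sum of above-threshold channel-A intensities at pixels where channel
  B is also above threshold, divided by the sum of all above-threshold
  channel-A intensities (M2 symmetric);
* tPCC — Pearson correlation of (a, b) over pixels above threshold in BOTH
  channels.

Images aggregate to samples by pixel-count-weighted means/SDs (n_a weights
M1, n_b weights M2, n_ab weights tPCC); samples aggregate to a population
one-sample t-interval, on the Fisher-z scale for tPCC.

"Above threshold" is strict (>): ties at the threshold are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .image_io import Mask


class InferenceError(ValueError):
    pass


@dataclass
class ChannelPair:
    """Two registered 2-D channels, an inclusion ROI and global thresholds."""

    a: np.ndarray
    b: np.ndarray
    roi: Mask
    t_a: float
    t_b: float

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (self.a.shape == self.b.shape == self.roi.shape):
            raise ValueError("channels and ROI must share a shape")
        if not (math.isfinite(self.t_a) and math.isfinite(self.t_b)):
            raise ValueError("thresholds must be finite")


@dataclass
class ColocResult:
    m1: float | None
    m2: float | None
    tpcc: float | None
    n_a: int
    n_b: int
    n_ab: int


@dataclass
class SampleSummary:
    sample_id: str
    m1_w: float | None
    m2_w: float | None
    tpcc_w: float | None
    sd_m1: float | None
    sd_m2: float | None
    sd_tpcc: float | None
    w_m1: float
    w_m2: float
    w_tpcc: float


@dataclass
class PopulationInference:
    statistic: str
    mean: float
    ci_low: float
    ci_high: float
    p: float
    n_samples: int


# ---------------------------------------------------------------------------
# thresholds from single-fluorophore controls


def estimate_threshold(control_images: list[tuple[np.ndarray, Mask]],
                       k_sd: float = 3.0) -> float:
    """Pooled pixel mean of the masked control intensities plus ``k_sd`` SDs.

    Per-image means are weighted by masked pixel count, which makes the
    weighted mean the pooled mean over all masked pixels; the SD is likewise
    pooled over all masked control pixels.
    """
    pools = []
    for img, mask in control_images:
        vals = np.asarray(img, dtype=float)[mask.pixels]
        if vals.size:
            pools.append(vals)
    if not pools:
        raise InferenceError("all control masks are empty")
    allvals = np.concatenate(pools)
    mean = allvals.mean()
    sd = allvals.std(ddof=1) if allvals.size > 1 else 0.0
    return float(mean + k_sd * sd)


# ---------------------------------------------------------------------------
# per-image statistics


def compute_coloc(pair: ChannelPair) -> ColocResult:
    """Thresholded Manders M1/M2 and thresholded Pearson for one image."""
    roi = pair.roi.pixels
    if not roi.any():
        raise ValueError("ROI is empty")
    a = pair.a[roi]
    b = pair.b[roi]
    above_a = a > pair.t_a
    above_b = b > pair.t_b
    joint = above_a & above_b
    n_a, n_b, n_ab = int(above_a.sum()), int(above_b.sum()), int(joint.sum())

    m1 = float(a[joint].sum() / a[above_a].sum()) if n_a else None
    m2 = float(b[joint].sum() / b[above_b].sum()) if n_b else None

    tpcc = None
    if n_ab >= 2:
        aj, bj = a[joint], b[joint]
        if aj.std() > 0 and bj.std() > 0:
            tpcc = float(np.corrcoef(aj, bj)[0, 1])
    return ColocResult(m1=m1, m2=m2, tpcc=tpcc, n_a=n_a, n_b=n_b, n_ab=n_ab)


def randomize_channel(image: np.ndarray, roi: Mask, seed: int) -> np.ndarray:
    """Permute pixel values within the ROI uniformly at random.

    The multiset of ROI intensities is preserved; pixels outside the ROI
    are untouched. Used to build the empirical null for tPCC.
    """
    rng = np.random.default_rng(seed)
    out = np.array(image, dtype=float, copy=True)
    vals = out[roi.pixels]
    out[roi.pixels] = rng.permutation(vals)
    return out


# ---------------------------------------------------------------------------
# hierarchical aggregation


def _weighted_mean_sd(values: list[float], weights: list[float]
                      ) -> tuple[float | None, float | None, float]:
    """Frequency-weight mean and SD (Σw(x−x̄)²/(Σw−1)); missing excluded."""
    pairs = [(v, w) for v, w in zip(values, weights) if v is not None and w > 0]
    if not pairs:
        return None, None, 0.0
    x = np.array([p[0] for p in pairs])
    w = np.array([p[1] for p in pairs])
    wm = float(np.sum(w * x) / w.sum())
    if w.sum() > 1 and len(x) > 1:
        sd = float(np.sqrt(np.sum(w * (x - wm) ** 2) / (w.sum() - 1)))
    else:
        sd = 0.0
    return wm, sd, float(w.sum())


def aggregate_sample(results: list[ColocResult], sample_id: str = ""
                     ) -> SampleSummary:
    """Pixel-count-weighted sample summary over that sample's images."""
    if not results:
        raise ValueError("no images for sample")
    m1, sd1, w1 = _weighted_mean_sd([r.m1 for r in results],
                                    [r.n_a for r in results])
    m2, sd2, w2 = _weighted_mean_sd([r.m2 for r in results],
                                    [r.n_b for r in results])
    tp, sdt, wt = _weighted_mean_sd([r.tpcc for r in results],
                                    [r.n_ab for r in results])
    return SampleSummary(sample_id=sample_id, m1_w=m1, m2_w=m2, tpcc_w=tp,
                         sd_m1=sd1, sd_m2=sd2, sd_tpcc=sdt,
                         w_m1=w1, w_m2=w2, w_tpcc=wt)


# ---------------------------------------------------------------------------
# population inference


def fisher_z(r: float) -> float:
    """z = atanh(r), mapping (−1, 1) to the real line."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    return math.atanh(r)


def fisher_z_inverse(z: float) -> float:
    return math.tanh(z)


_CLAMP = 1.0 - 1e-6


def scatter_plot(pair: ChannelPair, path, bins: int = 120) -> None:
    """Density scatter of ROI pixel intensities with threshold lines and an
    OLS regression line fitted on jointly-above-threshold pixels (the line is
    descriptive only; inference runs through :func:`population_inference`)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roi = pair.roi.pixels
    a, b = pair.a[roi], pair.b[roi]
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.hist2d(a, b, bins=bins, cmap="viridis", cmin=1)
    ax.axvline(pair.t_a, ls="--", c="w", lw=1)
    ax.axhline(pair.t_b, ls="--", c="w", lw=1)
    joint = (a > pair.t_a) & (b > pair.t_b)
    if joint.sum() >= 2 and a[joint].std() > 0:
        slope, intercept = np.polyfit(a[joint], b[joint], 1)
        xs = np.linspace(a[joint].min(), a[joint].max(), 50)
        ax.plot(xs, slope * xs + intercept, c="r", lw=1)
    ax.set_xlabel("channel A intensity")
    ax.set_ylabel("channel B intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def population_inference(sample_summaries: list[SampleSummary],
                         statistic: str) -> PopulationInference:
    """One-sample t inference on the sample means of a statistic.

    M1/M2 are tested and interval-estimated on the raw scale (intervals are
    deliberately not clipped to [0, 1]); tPCC sample means are Fisher
    z-transformed first and the estimate/CI back-transformed, so the
    reported interval always lies inside (−1, 1).
    """
    attr = {"m1": "m1_w", "m2": "m2_w", "tpcc": "tpcc_w"}[statistic]
    vals = [getattr(s, attr) for s in sample_summaries
            if getattr(s, attr) is not None]
    if len(vals) < 2:
        raise InferenceError(f"need >=2 samples with {statistic}, "
                             f"got {len(vals)}")
    x = np.asarray(vals, dtype=float)
    if statistic == "tpcc":
        if np.any(np.abs(x) >= 1):
            warnings.warn("tPCC sample mean at |r|>=1; clamping for Fisher z",
                          stacklevel=2)
            x = np.clip(x, -_CLAMP, _CLAMP)
        x = np.arctanh(x)
    n = len(x)
    mean = x.mean()
    se = x.std(ddof=1) / math.sqrt(n)
    if se > 0:
        tstat = mean / se
        p = float(2 * stats.t.sf(abs(tstat), df=n - 1))
        half = stats.t.ppf(0.975, df=n - 1) * se
    else:
        p = 0.0 if mean != 0 else 1.0
        half = 0.0
    lo, hi = mean - half, mean + half
    if statistic == "tpcc":
        mean, lo, hi = (math.tanh(v) for v in (mean, lo, hi))
    return PopulationInference(statistic=statistic, mean=float(mean),
                               ci_low=float(lo), ci_high=float(hi),
                               p=p, n_samples=n)
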