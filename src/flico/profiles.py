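"""Intensity-course analyses.

Cortical recruitment: per timepoint, the mean intensity of the first
``n_slices`` z-slices from the embryo edge, background-corrected against
matched single-fluorophore controls at the same timepoint, then min–max
normalized per sample. Depth profiles are per-plane ROI means aligned on
the reference-channel (Filamin) peak. Myotube displacement is tracked as
the junction x-coordinate relative to the first timepoint, plotted against
normalized signal intensity and fitted with tricube local regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import ImageStack, Mask


@dataclass
class IntensitySeries:
    sample_id: str
    times: np.ndarray
    values: np.ndarray          # background-corrected, min-max normalized
    raw_values: np.ndarray
    background_values: np.ndarray
    constant_flag: bool = False


@dataclass
class DepthProfile:
    depths: np.ndarray          # µm from the embryo surface
    intensity: np.ndarray       # per depth
    peak_depth: float


@dataclass
class DisplacementSeries:
    sample_id: str
    times: np.ndarray
    junction_x: np.ndarray
    displacement: np.ndarray
    intensity: np.ndarray       # background-corrected, min-max normalized


def minmax_normalize(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale to [0, 1]; a constant series maps to all zeros with a flag."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.zeros_like(v), True
    return (v - lo) / (hi - lo), False


def cortical_intensity(stack_series: list[ImageStack],
                       control_series: list[ImageStack],
                       n_slices: int = 7, edge_offset: int = 0,
                       times: np.ndarray | None = None,
                       sample_id: str = "") -> IntensitySeries:
    """Cortical recruitment curve for one sample.

    ``stack_series`` and ``control_series`` hold one stack per timepoint;
    the mean over slices ``edge_offset .. edge_offset+n_slices-1`` is taken,
    the matched control mean subtracted per timepoint, and the corrected
    series min–max normalized.
    """
    if len(stack_series) != len(control_series):
        raise ValueError("signal and control series must have equal length")
    raw, bg = [], []
    for sig, ctl in zip(stack_series, control_series):
        sl = slice(edge_offset, edge_offset + n_slices)
        raw.append(float(sig.pixels[:, sl].mean()))
        bg.append(float(ctl.pixels[:, sl].mean()))
    raw = np.array(raw)
    bg = np.array(bg)
    corrected = raw - bg
    values, flag = minmax_normalize(corrected)
    t = np.asarray(times, dtype=float) if times is not None \
        else np.arange(len(raw), dtype=float)
    return IntensitySeries(sample_id=sample_id, times=t, values=values,
                           raw_values=raw, background_values=bg,
                           constant_flag=flag)


def depth_profile(stack: ImageStack, channel: int = 0,
                  roi: Mask | None = None, t: int = 0) -> DepthProfile:
    """Mean (ROI) intensity per z-plane; depth = plane index × z-step."""
    planes = stack.pixels[t, :, channel]
    if roi is not None:
        vals = np.array([p[roi.pixels].mean() for p in planes])
    else:
        vals = planes.mean(axis=(1, 2))
    depths = np.arange(stack.n_slices) * stack.z_step_um
    return DepthProfile(depths=depths, intensity=vals,
                        peak_depth=float(depths[int(np.argmax(vals))]))


def align_profiles(profiles: list[tuple[DepthProfile, DepthProfile]],
                   reference: int = 1
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align profile pairs on the reference channel's peak.

    Each pair is shifted so the reference channel's peak sits at depth 0,
    linearly interpolated onto a shared grid, and averaged across samples.
    Returns ``(grid, mean_channel0, mean_channel1)``.

    A reference profile whose maximum sits on the boundary of its depth
    range has no interior peak and raises an alignment error.
    """
    if not profiles:
        raise ValueError("no profiles to align")
    shifted = []
    for pair in profiles:
        ref = pair[reference]
        imax = int(np.argmax(ref.intensity))
        if imax in (0, len(ref.depths) - 1):
            raise ValueError("reference profile has no interior maximum")
        shift = ref.depths[imax]
        shifted.append(tuple((p.depths - shift, p.intensity) for p in pair))
    step = float(np.min(np.diff(profiles[0][0].depths)))
    lo = max(d[0][0].min() for d in shifted)
    hi = min(d[0][0].max() for d in shifted)
    grid = np.arange(lo, hi + step / 2, step)
    means = []
    for ch in (0, 1):
        curves = [np.interp(grid, d[ch][0], d[ch][1]) for d in shifted]
        means.append(np.mean(curves, axis=0))
    return grid, means[0], means[1]


def displacement_series(junction_xs: np.ndarray, signal_means: np.ndarray,
                        control_means: np.ndarray,
                        times: np.ndarray | None = None,
                        sample_id: str = "") -> DisplacementSeries:
    """Displacement (junction x minus its first value) paired with
    background-corrected, min–max normalized signal intensity."""
    jx = np.asarray(junction_xs, dtype=float)
    sig = np.asarray(signal_means, dtype=float)
    ctl = np.asarray(control_means, dtype=float)
    if not (len(jx) == len(sig) == len(ctl)):
        raise ValueError("series lengths differ")
    disp = jx - jx[0]
    norm, _ = minmax_normalize(sig - ctl)
    t = np.asarray(times, dtype=float) if times is not None \
        else np.arange(len(jx), dtype=float)
    return DisplacementSeries(sample_id=sample_id, times=t, junction_x=jx,
                              displacement=disp, intensity=norm)


def align_time_by_minimum(series: list[DisplacementSeries],
                          origin_h: float = 24.0) -> list[DisplacementSeries]:
    """Shift each sample's time axis so the minimum junction-x coordinates
    coincide, with the earliest aligned timepoint placed at ``origin_h``."""
    argmins = [s.times[int(np.argmin(s.junction_x))] for s in series]
    out = []
    for s, tmin in zip(series, argmins):
        shifted = s.times - tmin
        out.append(DisplacementSeries(sample_id=s.sample_id,
                                      times=shifted, junction_x=s.junction_x,
                                      displacement=s.displacement,
                                      intensity=s.intensity))
    start = min(s.times.min() for s in out)
    for s in out:
        s.times = s.times - start + origin_h
    return out


def local_regression(x: np.ndarray, y: np.ndarray, span: float = 0.75,
                     degree: int = 2, grid: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Tricube-weighted local polynomial regression (LOESS) on a grid.

    At each grid point the nearest ``span`` fraction of the data is fitted
    with a weighted degree-``degree`` polynomial and evaluated there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < degree + 1:
        raise ValueError("need at least degree+1 points")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    k = max(degree + 1, int(np.ceil(span * len(x))))
    fit = np.empty(len(grid))
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        idx = np.argsort(d)[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(k)
        w = np.clip(w, 1e-12, None)
        coeffs = np.polyfit(x[idx] - g, y[idx], deg=degree, w=np.sqrt(w))
        fit[i] = coeffs[-1]
    return np.asarray(grid), fit
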