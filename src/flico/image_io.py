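"""Image-stack and table I/O plus the projection/reslice primitives.

All stacks are canonicalized to a five-axis ``(t, z, c, y, x)`` grid with
0-based indices and the usual image convention (y increases downward).
A plain 2-D image is simply a stack with singleton t, z and c axes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

AXES = "TZCYX"


class FormatError(ValueError):
    """Raised when a file's layout cannot be interpreted."""


@dataclass
class ImageStack:
    """An n-dimensional grayscale intensity grid with physical metadata.

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensities, shape ``(t, z, c, y, x)``.
    pixel_size_um : tuple of float
        Physical pixel size ``(dy, dx)`` in micrometres.
    z_step_um : float
        Slice spacing in micrometres.
    time_interval_s : float
        Frame interval in seconds.
    channel_names : list of str
        One label per channel.
    """

    pixels: np.ndarray
    pixel_size_um: tuple[float, float] = (1.0, 1.0)
    z_step_um: float = 1.0
    time_interval_s: float = 1.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim > 5:
            raise ValueError(f"at most 5 axes supported, got {px.ndim}")
        # left-pad singleton axes so a 2-D image becomes (1,1,1,H,W)
        while px.ndim < 5:
            px = px[np.newaxis]
        if not np.all(np.isfinite(px)):
            raise ValueError("intensities must be finite")
        if px.min() < 0:
            raise ValueError("intensities must be non-negative")
        for name, val in [("z_step_um", self.z_step_um),
                          ("time_interval_s", self.time_interval_s)]:
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be positive")
        if any(s <= 0 for s in self.pixel_size_um):
            raise ValueError("pixel_size_um entries must be positive")
        self.pixels = px
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(px.shape[2])]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def plane(self, t: int = 0, z: int = 0, c: int = 0) -> np.ndarray:
        """Return one 2-D (y, x) plane."""
        return self.pixels[t, z, c]


@dataclass
class Mask:
    """Boolean (y, x) grid marking included pixels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def n_true(self) -> int:
        return int(self.pixels.sum())

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.pixels & other.pixels)

    def __invert__(self) -> "Mask":
        return Mask(~self.pixels)


def _axes_to_tzcyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Permute/expand a tifffile array with the given axes string to TZCYX."""
    axes = axes.upper().replace("S", "C").replace("Q", "T").replace("I", "T")
    if len(axes) != data.ndim:
        raise FormatError(f"axes string {axes!r} does not match ndim {data.ndim}")
    unknown = set(axes) - set(AXES)
    if unknown:
        raise FormatError(f"unsupported axes {sorted(unknown)} in TIFF")
    if len(set(axes)) != len(axes):
        raise FormatError(f"duplicate axis in {axes!r}")
    for ax in AXES:
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in AXES]
    return np.transpose(data, order)


def read_stack(path, axes_hint: str | None = None) -> ImageStack:
    """Read a TIFF into a canonical (t, z, c, y, x) :class:`ImageStack`.

    Axis order is taken from OME/ImageJ metadata when present, from
    ``axes_hint`` otherwise; a bare 2-D page is treated as a single plane.
    Missing physical metadata defaults to 1.0 with a warning.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = axes_hint or series.axes
    except (OSError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        axes = "YX"
    elif axes_hint:
        axes = axes_hint
    arr = _axes_to_tzcyx(data, axes)

    meta = {}
    with tifffile.TiffFile(str(path)) as tif:
        ij = tif.imagej_metadata or {}
        if "spacing" in ij:
            meta["z_step_um"] = float(ij["spacing"])
        if "finterval" in ij and ij["finterval"]:
            meta["time_interval_s"] = float(ij["finterval"])
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            if num:
                meta["pixel_size_um"] = (den / num, den / num)
    if "pixel_size_um" not in meta:
        warnings.warn(f"{path}: no pixel-size metadata; defaulting to 1.0 um",
                      stacklevel=2)
    return ImageStack(arr, **meta)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as an ImageJ-style TIFF, preserving axis order and spacing."""
    dy, _ = stack.pixel_size_um
    tifffile.imwrite(
        str(path),
        stack.pixels.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dy, 1.0 / dy),
        metadata={
            "axes": AXES,
            "spacing": stack.z_step_um,
            "finterval": stack.time_interval_s,
            "unit": "um",
        },
    )


def _resolve_axis(axis: str) -> int:
    try:
        return {"t": 0, "z": 1}[axis]
    except KeyError:
        raise ValueError(f"projection axis must be 't' or 'z', got {axis!r}")


def project(stack: ImageStack, method: str = "mean", axis: str = "z",
            index_range: tuple[int, int] | None = None) -> ImageStack:
    """Project a stack along z or t over an inclusive index range.

    ``method`` is one of ``sum``, ``mean``, ``max``; the projected axis
    becomes a singleton.
    """
    ax = _resolve_axis(axis)
    extent = stack.pixels.shape[ax]
    lo, hi = index_range if index_range is not None else (0, extent - 1)
    if lo > hi:
        raise ValueError(f"empty index range ({lo}, {hi})")
    if lo < 0 or hi >= extent:
        raise ValueError(f"index range ({lo}, {hi}) outside axis extent {extent}")
    sl = [slice(None)] * 5
    sl[ax] = slice(lo, hi + 1)
    sub = stack.pixels[tuple(sl)]
    funcs = {"sum": np.sum, "mean": np.mean, "max": np.max}
    if method not in funcs:
        raise ValueError(f"unknown projection method {method!r}")
    out = funcs[method](sub, axis=ax, keepdims=True)
    return replace(stack, pixels=out)


def reslice_sagittal(stack: ImageStack, y_range: tuple[int, int],
                     projection: str = "sum") -> ImageStack:
    """Produce an XZ view: for each (z, x), sum intensity over the y rows.

    The output stack is indexed (t, 1, c, z, x) — z runs vertically, as in
    ImageJ's Reslice followed by a sum projection over the selected rows.
    Physical anisotropy is carried through: the output row spacing is the
    input z-step.
    """
    if projection != "sum":
        raise ValueError("only sum projection supported for reslice")
    lo, hi = y_range
    ny = stack.pixels.shape[3]
    if lo > hi or lo < 0 or hi >= ny:
        raise ValueError(f"y_range ({lo}, {hi}) outside image rows [0, {ny})")
    # (t,z,c,y,x) -> sum over y -> (t,z,c,x) -> move z to the row axis
    summed = stack.pixels[:, :, :, lo:hi + 1, :].sum(axis=3)
    out = np.moveaxis(summed, 1, 2)[:, np.newaxis]  # (t,1,c,z,x)
    return ImageStack(
        out,
        pixel_size_um=(stack.z_step_um, stack.pixel_size_um[1]),
        z_step_um=stack.pixel_size_um[0],
        time_interval_s=stack.time_interval_s,
        channel_names=stack.channel_names,
    )


REQUIRED_TABLE_COLUMNS = ("value",)


def write_table(records: pd.DataFrame, path) -> None:
    """Write a measurement table as UTF-8 CSV with a header row."""
    records.to_csv(path, index=False)


def read_table(path, required: tuple[str, ...] = REQUIRED_TABLE_COLUMNS) -> pd.DataFrame:
    """Read a measurement table, checking the required columns exist."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_mask_png(path) -> Mask:
    """Read a 0/255 PNG as a boolean mask."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return Mask(arr > 0)


def write_mask_png(mask: Mask, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), (mask.pixels.astype(np.uint8) * 255))
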