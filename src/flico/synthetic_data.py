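"""Synthetic confocal-style inputs with exact ground truth.

Every generator is a pure function of its spec (seed included), so repeated
calls with the same spec are bit-identical. Truth records carry the planted
structure masks / polygons / effects so downstream recovery can be scored
without re-running the generator.

The colocalization field emulates a cellularizing embryo surface: a bright
cell-boundary network surrounding dark elliptical nuclei, sparse
high-intensity autofluorescent spots present in both channels at the same
coordinates, and Gaussian noise on a constant background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image_io import ImageStack

# ---------------------------------------------------------------------------
# specs


@dataclass
class ColocFieldSpec:
    """Parameters of a two-channel colocalization field.

    ``coloc_fraction`` is the fraction f of channel-A structural signal
    duplicated (with gain ``gain_b``) into channel B; ``independent_signal_level``
    scales a channel-B-only boundary network disjoint from channel A's.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 25
    nucleus_radius_px: tuple[float, float] = (12.0, 2.0)  # mean, sd
    boundary_width_px: float = 4.0
    boundary_amplitude: float = 120.0
    coloc_fraction: float = 1.0
    gain_b: float = 0.8
    independent_signal_level: float = 0.0
    n_spots: int = 6
    spot_amplitude: float = 400.0
    spot_radius_px: float = 2.0
    background_mean: float = 20.0
    background_sd: float = 3.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if min(self.image_shape) < 32:
            raise ValueError("image_shape must be at least 32x32")


@dataclass
class RingSeriesSpec:
    """A contractile ring relaxing from a regular polygon toward a circle.

    ``circularity_profile`` gives the target circularity per frame;
    ``area_profile`` the per-frame area relative to frame 0 (contraction).
    """

    n_frames: int = 8
    frame_interval_min: float = 3.0
    n_vertices: int = 6           # initial regular n-gon (hexagon)
    initial_radius_px: float = 40.0
    circularity_profile: tuple[float, ...] | None = None
    area_profile: tuple[float, ...] | None = None
    ring_thickness_px: float = 4.0
    amplitude: float = 200.0
    background_mean: float = 10.0
    noise_sd: float = 0.0
    image_shape: tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.circularity_profile is None:
            c0 = _regular_polygon_circularity(self.n_vertices)
            self.circularity_profile = tuple(
                float(c) for c in np.linspace(c0, 1.0, self.n_frames))
        if self.area_profile is None:
            self.area_profile = tuple(
                float(a) for a in np.linspace(1.0, 0.5, self.n_frames))
        if any(not (0 < c <= 1) for c in self.circularity_profile):
            raise ValueError("target circularities must lie in (0, 1]")
        if any(a <= 0 for a in self.area_profile):
            raise ValueError("areas must stay positive")


@dataclass
class AttachmentSimSpec:
    """Generative twin of the attachment-site length model.

    Lengths are Gamma(shape=alpha) with log-link mean
    ``exp(beta_genotype + u_sample + u_image)``; the double mutant's effect is
    ``beta_closed + beta_ko + interaction_delta``.
    """

    beta_reference: float = 1.3          # log µm, wild-type baseline
    beta_closed: float = -0.25
    beta_ko: float = -0.20
    interaction_delta: float = 0.0
    gamma_shape: float = 20.0
    sd_sample: float = 0.10
    sd_image: float = 0.05
    n_flies_per_genotype: int = 14
    n_images_per_fly: int = 2
    n_sites_per_image: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.sd_sample < 0 or self.sd_image < 0:
            raise ValueError("random-intercept SDs must be >= 0")
        if min(self.n_flies_per_genotype, self.n_images_per_fly,
               self.n_sites_per_image) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def genotype_effects(self) -> dict[str, float]:
        return {
            "wt": 0.0,
            "filamin_closed": self.beta_closed,
            "drak_ko": self.beta_ko,
            "double": self.beta_closed + self.beta_ko + self.interaction_delta,
        }


GENOTYPES = ("wt", "filamin_closed", "drak_ko", "double")


# ---------------------------------------------------------------------------
# geometry helpers


def _regular_polygon_circularity(n: int) -> float:
    """Closed-form 4πA/P² of a regular n-gon."""
    return np.pi / (n * np.tan(np.pi / n))


def regular_polygon(n: int, radius: float,
                    center: tuple[float, float] = (0.0, 0.0),
                    phase: float = 0.0) -> np.ndarray:
    """Vertices (y, x) of a regular n-gon with given circumradius."""
    th = phase + 2 * np.pi * np.arange(n) / n
    cy, cx = center
    return np.column_stack([cy + radius * np.sin(th), cx + radius * np.cos(th)])


def polygon_area_perimeter(vertices: np.ndarray) -> tuple[float, float]:
    """Shoelace area and summed edge lengths of a closed polygon."""
    v = np.asarray(vertices, dtype=float)
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    y, x = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    d = np.sqrt(np.sum((v - np.roll(v, -1, axis=0)) ** 2, axis=1))
    return float(area), float(d.sum())


def polygon_circularity(vertices: np.ndarray) -> float:
    area, perim = polygon_area_perimeter(vertices)
    if perim == 0:
        raise ValueError("degenerate polygon")
    return 4 * np.pi * area / perim**2


def _blend_polygon(n_gon: np.ndarray, s: float, n_dense: int = 256) -> np.ndarray:
    """Blend a polygon radially toward its circumscribed circle.

    s=0 returns a densely resampled copy of the polygon boundary, s=1 a
    circle of the same circumradius; circularity is monotone increasing in s.
    """
    import shapely

    poly = shapely.Polygon(np.column_stack([n_gon[:, 1], n_gon[:, 0]]))
    cx, cy = poly.centroid.x, poly.centroid.y
    # include the source vertices' angles so s=0 reproduces the polygon
    # exactly (uniform angles alone would cut its corners)
    vth = np.mod(np.arctan2(n_gon[:, 0] - cy, n_gon[:, 1] - cx), 2 * np.pi)
    th = np.union1d(2 * np.pi * np.arange(n_dense) / n_dense, vth)
    # radius of the polygon boundary along each ray
    rmax = 2 * np.max(np.abs(n_gon)) + 1
    rays = [shapely.LineString([(cx, cy), (cx + rmax * np.cos(a),
                                           cy + rmax * np.sin(a))]) for a in th]
    r_poly = np.array([shapely.intersection(ray, poly.exterior).distance(
        shapely.Point(cx, cy)) if not shapely.intersection(
            ray, poly.exterior).is_empty else 0.0 for ray in rays])
    r_circ = np.full(len(th), r_poly.max())
    r = (1 - s) * r_poly + s * r_circ
    return np.column_stack([cy + r * np.sin(th), cx + r * np.cos(th)])


def polygon_for_circularity(n_gon: np.ndarray, target: float,
                            tol: float = 1e-4) -> np.ndarray:
    """Bisect the polygon→circle blend so circularity matches ``target``."""
    lo, hi = 0.0, 1.0
    c_lo = polygon_circularity(_blend_polygon(n_gon, 0.0))
    if target <= c_lo + tol:
        return _blend_polygon(n_gon, 0.0)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if polygon_circularity(_blend_polygon(n_gon, mid)) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    return _blend_polygon(n_gon, 0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# colocalization fields


def _voronoi_network(shape: tuple[int, int], centers: np.ndarray,
                     width: float) -> np.ndarray:
    """Soft [0,1] image of the boundaries between Voronoi cells of ``centers``."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    d, _ = cKDTree(centers).query(pts, k=2)
    ridge = d[:, 1] - d[:, 0]          # 0 on the boundary between two cells
    band = np.clip(width / 2 + 0.5 - ridge, 0, 1).reshape(shape)
    return band


def _place_centers(rng: np.random.Generator, shape: tuple[int, int],
                   n: int, min_dist: float) -> np.ndarray:
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n and tries < 200 * n:
        cand = rng.uniform([0, 0], shape)
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
        tries += 1
    return np.array(centers)


def _render_spots(rng: np.random.Generator, shape: tuple[int, int],
                  n_spots: int, radius: float, amplitude: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Compact bright spots (soft-edged top hats); returns (image, support mask).

    The support is ``distance < radius + 0.5`` — exactly the pixels the spot
    touches — so spot-exclusion fidelity can be scored against it.
    """
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_spots):
        cy, cx = rng.uniform([6, 6], [shape[0] - 6, shape[1] - 6])
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        prof = np.clip(radius + 0.5 - d, 0, 1)
        img += amplitude * prof
        mask |= prof > 0
    return img, mask


def gen_coloc_field(spec: ColocFieldSpec) -> tuple[ImageStack, ImageStack, dict]:
    """Generate a registered two-channel field plus its truth record.

    Channel A carries the full boundary network; channel B carries a
    Bernoulli(f) pixel subset of it at gain ``gain_b`` plus an optional
    disjoint independent network. Nuclei are intensity voids in both
    channels; autofluorescent spots are identical in both.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    rad_mean, rad_sd = spec.nucleus_radius_px

    centers = _place_centers(rng, shape, spec.n_nuclei, min_dist=2.2 * rad_mean)
    network = _voronoi_network(shape, centers, spec.boundary_width_px)

    # nuclei: dark ellipses around each center, carved out of everything
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    nucleus_mask = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        ry = max(2.0, rng.normal(rad_mean, rad_sd))
        rx = max(2.0, rng.normal(rad_mean, rad_sd))
        nucleus_mask |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1
    network[nucleus_mask] = 0.0

    net_px = network > 0.05
    # channel-B structural intensity on the shared support: a fraction f of
    # channel A's profile plus a (1-f) share of independent per-pixel
    # intensity, so the thresholded correlation rises smoothly with f while
    # the spatial co-occurrence (Manders) stays high
    u_field = rng.random(shape) * net_px
    f = spec.coloc_fraction
    coloc_structure = f * network + (1 - f) * u_field

    # channel-B-only structure: a second, independently placed network,
    # carved away from channel A's support so it stays disjoint
    indep = np.zeros(shape)
    if spec.independent_signal_level > 0:
        centers_b = _place_centers(rng, shape, spec.n_nuclei,
                                   min_dist=2.2 * rad_mean)
        indep = _voronoi_network(shape, centers_b, spec.boundary_width_px)
        indep[nucleus_mask | net_px] = 0.0

    spot_rng = np.random.default_rng(spec.seed + 777_000_003)
    spots, spot_mask = _render_spots(spot_rng, shape, spec.n_spots,
                                     spec.spot_radius_px, spec.spot_amplitude)

    def _noisy(structure: np.ndarray) -> np.ndarray:
        img = spec.background_mean + structure + spots
        img = img + rng.normal(0.0, spec.background_sd, shape)
        if spec.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        return np.clip(img, 0, None)

    a = _noisy(spec.boundary_amplitude * network)
    b = _noisy(spec.gain_b * spec.boundary_amplitude * coloc_structure
               + spec.independent_signal_level * indep)

    truth = {
        "coloc_fraction": spec.coloc_fraction,
        "network_mask": net_px,
        "coloc_mask": net_px if f > 0 else np.zeros(shape, dtype=bool),
        "independent_mask": indep > 0.05,
        "nucleus_mask": nucleus_mask,
        "spot_mask": spot_mask,
        "background_mean": spec.background_mean,
        "background_sd": spec.background_sd,
    }
    return ImageStack(a), ImageStack(b), truth


def gen_control_field(spec: ColocFieldSpec, channel: str = "a") -> ImageStack:
    """Single-fluorophore control: background noise + the shared spots only.

    Paired a/b controls with the same seed put the spots at identical
    coordinates, mirroring autofluorescence visible in both channels.
    """
    if channel not in ("a", "b"):
        raise ValueError("channel must be 'a' or 'b'")
    rng = np.random.default_rng(spec.seed + (0 if channel == "a" else 1))
    spot_rng = np.random.default_rng(spec.seed + 777_000_003)
    spots, _ = _render_spots(spot_rng, spec.image_shape, spec.n_spots,
                             spec.spot_radius_px, spec.spot_amplitude)
    img = spec.background_mean + spots + rng.normal(
        0.0, spec.background_sd, spec.image_shape)
    if spec.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    return ImageStack(np.clip(img, 0, None))


# ---------------------------------------------------------------------------
# ring time series


def render_polygon_band(polygon: np.ndarray, shape: tuple[int, int],
                        thickness: float, amplitude: float) -> np.ndarray:
    """Render a polygon outline as an anti-aliased bright band.

    Intensity falls off linearly over one pixel at the band edges so
    sub-pixel contouring of the rendered ring is meaningful.
    """
    import shapely

    ring = shapely.LinearRing(np.column_stack([polygon[:, 1], polygon[:, 0]]))
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    pts = shapely.points(xx.ravel().astype(float), yy.ravel().astype(float))
    d = shapely.distance(ring, pts).reshape(shape)
    return amplitude * np.clip(thickness / 2 + 0.5 - d, 0, 1)


def gen_ring_series(spec: RingSeriesSpec) -> tuple[ImageStack, dict]:
    """Time-lapse of a polygonal ring relaxing toward a circle and contracting.

    Truth holds the exact per-frame polygon and its analytic 4πA/P²
    circularity.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    center = (h / 2, w / 2)
    base = regular_polygon(spec.n_vertices, spec.initial_radius_px)

    frames = []
    polygons = []
    circ_truth = []
    for k in range(spec.n_frames):
        poly = polygon_for_circularity(base, spec.circularity_profile[k])
        a0, _ = polygon_area_perimeter(poly)
        target_area = polygon_area_perimeter(
            _blend_polygon(base, 0.0))[0] * spec.area_profile[k]
        poly = poly * np.sqrt(target_area / a0)
        poly = poly + np.array(center)
        img = spec.background_mean + render_polygon_band(
            poly, spec.image_shape, spec.ring_thickness_px, spec.amplitude)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, spec.image_shape)
        frames.append(np.clip(img, 0, None))
        polygons.append(poly)
        circ_truth.append(polygon_circularity(poly))

    stack = ImageStack(np.stack(frames)[:, np.newaxis, np.newaxis],
                       time_interval_s=spec.frame_interval_min * 60.0)
    truth = {
        "polygons": polygons,
        "circularity": np.array(circ_truth),
        "area": np.array([polygon_area_perimeter(p)[0] for p in polygons]),
        "times_min": np.arange(spec.n_frames) * spec.frame_interval_min,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# attachment-site lengths


def gen_attachment_table(spec: AttachmentSimSpec):
    """Simulate attachment-site lengths with genotype effects and nested
    (sample, image-within-sample) random intercepts.

    Returns a long-format DataFrame with columns
    ``length, genotype, sample, image``.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    effects = spec.genotype_effects
    rows = []
    for g in GENOTYPES:
        for fly in range(spec.n_flies_per_genotype):
            sample_id = f"{g}_fly{fly:02d}"
            u_s = rng.normal(0.0, spec.sd_sample)
            for img in range(spec.n_images_per_fly):
                image_id = f"{sample_id}_img{img}"
                u_i = rng.normal(0.0, spec.sd_image)
                mu = np.exp(spec.beta_reference + effects[g] + u_s + u_i)
                lengths = rng.gamma(spec.gamma_shape,
                                    mu / spec.gamma_shape,
                                    size=spec.n_sites_per_image)
                for L in lengths:
                    rows.append((L, g, sample_id, image_id))
    return pd.DataFrame(rows, columns=["length", "genotype", "sample", "image"])


# ---------------------------------------------------------------------------
# cortical intensity time courses


def gen_intensity_series(n_samples: int, recruitment_curve: np.ndarray,
                         background_mean: float = 10.0, noise_sd: float = 0.0,
                         seed: int = 0, n_slices: int = 7,
                         image_shape: tuple[int, int] = (32, 32)
                         ) -> tuple[list, list]:
    """Per-sample time series of small z-stacks whose cortical band follows
    ``recruitment_curve``; matched controls carry background only.

    Returns ``(signal_series, control_series)`` where each element is a list
    of per-timepoint :class:`ImageStack` objects for one sample.
    """
    rng = np.random.default_rng(seed)
    curve = np.asarray(recruitment_curve, dtype=float)
    nz = n_slices + 3          # a few sub-cortical slices beyond the band
    signals, controls = [], []
    for _ in range(n_samples):
        sig_t, ctl_t = [], []
        for v in curve:
            planes = np.full((nz,) + image_shape, background_mean)
            planes[:n_slices] += v
            if noise_sd > 0:
                planes = planes + rng.normal(0, noise_sd, planes.shape)
            sig_t.append(ImageStack(np.clip(planes, 0, None)[np.newaxis, :, np.newaxis]))
            ctl = np.full((nz,) + image_shape, background_mean)
            if noise_sd > 0:
                ctl = ctl + rng.normal(0, noise_sd, ctl.shape)
            ctl_t.append(ImageStack(np.clip(ctl, 0, None)[np.newaxis, :, np.newaxis]))
        signals.append(sig_t)
        controls.append(ctl_t)
    return signals, controls
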