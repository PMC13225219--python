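import numpy as np
import pandas as pd
import pytest

from flico import ringshape as rs
from flico import synthetic_data as sd
from flico.image_io import ImageStack, Mask


def annulus_mask(shape=(64, 64), r_in=12.0, r_out=20.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    d = np.sqrt((yy - shape[0] / 2) ** 2 + (xx - shape[1] / 2) ** 2)
    return Mask((d >= r_in) & (d <= r_out))


class TestDenoise:
    def test_none_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 5, (10, 10))
        np.testing.assert_array_equal(rs.denoise(img, "none"), img)

    def test_gaussian_constant_unchanged(self):
        img = np.full((12, 12), 3.0)
        np.testing.assert_allclose(rs.denoise(img, "gaussian", 2.0), img)

    def test_median_removes_impulses(self):
        spec = sd.RingSeriesSpec(n_frames=1, noise_sd=0.0)
        stack, _ = sd.gen_ring_series(spec)
        frame = stack.plane(t=0)
        rng = np.random.default_rng(1)
        noisy = frame.copy()
        idx = rng.integers(0, frame.shape[0], (30, 2))
        noisy[idx[:, 0], idx[:, 1]] = 1000.0
        out = rs.denoise(noisy, "median", 1.0)
        assert (out > 500).sum() == 0


class TestSegmentRing:
    def test_blank_frame_fails(self):
        assert rs.segment_ring(np.full((32, 32), 4.0)) is None

    def test_hexagon_band_recovered(self):
        spec = sd.RingSeriesSpec(n_frames=1, noise_sd=0.0)
        stack, truth = sd.gen_ring_series(spec)
        mask = rs.segment_ring(stack.plane(t=0))
        band = stack.plane(t=0) > spec.background_mean + spec.amplitude / 2
        # mask and band agree to a 1-px rim
        from scipy import ndimage
        grown = ndimage.binary_dilation(band, iterations=1)
        shrunk = ndimage.binary_erosion(band, iterations=1)
        assert mask.pixels[shrunk].all()
        assert not mask.pixels[~grown].any()

    def test_threshold_offset_invariance(self):
        spec = sd.RingSeriesSpec(n_frames=1, noise_sd=1.0)
        stack, _ = sd.gen_ring_series(spec)
        m1 = rs.segment_ring(stack.plane(t=0))
        m2 = rs.segment_ring(stack.plane(t=0) + 40.0)
        assert (m1.pixels != m2.pixels).mean() < 0.01


class TestInnerOutline:
    def test_annulus_inner_radius_recovered(self):
        contour = rs.extract_inner_outline(annulus_mask(r_in=12.0))
        d = np.sqrt(((contour - 32.0) ** 2).sum(axis=1))
        assert abs(d.mean() - 12.0) <= 0.5

    def test_filled_disc_raises_topology_error(self):
        yy, xx = np.mgrid[0:32, 0:32]
        disc = Mask((yy - 16) ** 2 + (xx - 16) ** 2 <= 100)
        with pytest.raises(rs.TopologyError) as exc:
            rs.extract_inner_outline(disc)
        assert exc.value.n_holes == 0

    def test_contour_closed_and_ccw(self):
        contour = rs.extract_inner_outline(annulus_mask())
        np.testing.assert_array_equal(contour[0], contour[-1])
        assert rs._signed_area(contour) > 0


class TestFourierSmooth:
    def test_circle_unchanged(self):
        poly = sd.regular_polygon(128, 10.0)
        out = rs.fourier_smooth(poly, 8.0)
        np.testing.assert_allclose(out, poly, atol=1e-6)

    def test_full_retention_is_identity(self):
        rng = np.random.default_rng(2)
        poly = sd.regular_polygon(64, 10.0)
        poly = poly + rng.normal(0, 0.3, poly.shape)
        out = rs.fourier_smooth(poly, 100.0)
        np.testing.assert_allclose(out, poly, atol=1e-9)

    def test_ripple_smoothing_raises_circularity(self):
        th = 2 * np.pi * np.arange(256) / 256
        for seed in range(20):
            rng = np.random.default_rng(seed)
            phase = rng.uniform(0, 2 * np.pi)
            r = 20 + 0.8 * np.sin(24 * th + phase)
            poly = np.column_stack([r * np.sin(th), r * np.cos(th)])
            raw = sd.polygon_circularity(poly)
            smoothed = rs.fourier_smooth(poly, 8.0)
            assert sd.polygon_circularity(smoothed) >= raw

    def test_closed_input_stays_closed(self):
        poly = sd.regular_polygon(32, 5.0)
        closed = np.vstack([poly, poly[0]])
        out = rs.fourier_smooth(closed, 50.0)
        assert len(out) == len(closed)
        np.testing.assert_allclose(out[0], out[-1])

    def test_absolute_descriptor_mode(self):
        poly = sd.regular_polygon(128, 10.0)
        out_abs = rs.fourier_smooth(poly, absolute_descriptors=10)
        out_rel = rs.fourier_smooth(poly, relative_descriptors_pct=100 * 10 / 128)
        np.testing.assert_allclose(out_abs, out_rel, atol=1e-9)


class TestMeasureCircularity:
    @pytest.mark.parametrize("n,expected", [
        (6, np.sqrt(3) * np.pi / 6),
        (4, np.pi / 4),
        (256, 1.0),
    ])
    def test_closed_forms(self, n, expected):
        _, _, c = rs.measure_circularity(sd.regular_polygon(n, 7.0))
        assert c == pytest.approx(expected, abs=1e-3)

    def test_scale_rotation_invariance(self):
        poly = sd.regular_polygon(6, 3.0)
        _, _, c0 = rs.measure_circularity(poly)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        _, _, c1 = rs.measure_circularity(5.3 * poly @ rot.T)
        assert abs(c1 - c0) < 1e-10

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        with pytest.raises(ValueError, match="self-intersect"):
            rs.measure_circularity(bowtie)


class TestTrajectory:
    def test_contracting_series_recovered(self):
        spec = sd.RingSeriesSpec(n_frames=6, noise_sd=0.0)
        stack, truth = sd.gen_ring_series(spec)
        traj = rs.build_trajectory(stack, sample_id="s1", genotype="wt")
        assert traj.included
        meas = np.array([o.circularity for o in traj.outlines])
        np.testing.assert_allclose(meas, truth["circularity"], atol=0.02)
        times = [o.frame_time_min for o in traj.outlines]
        np.testing.assert_allclose(times, truth["times_min"])

    def test_constant_area_excluded(self):
        spec = sd.RingSeriesSpec(n_frames=4, area_profile=(1.0,) * 4,
                                 noise_sd=0.0)
        stack, _ = sd.gen_ring_series(spec)
        traj = rs.build_trajectory(stack)
        assert not traj.included
        assert traj.exclusion_reason == "no contraction"

    def test_missing_middle_frame_keeps_time_order(self):
        spec = sd.RingSeriesSpec(n_frames=4, noise_sd=0.0)
        stack, _ = sd.gen_ring_series(spec)
        px = stack.pixels.copy()
        px[2] = spec.background_mean            # blank one frame
        broken = ImageStack(px, time_interval_s=stack.time_interval_s)
        traj = rs.build_trajectory(broken)
        assert traj.missing_frames == [2]
        times = [o.frame_time_min for o in traj.outlines]
        assert times == sorted(times)
        assert len(traj.outlines) == 3


class TestTrendFit:
    @staticmethod
    def _simulate(curve_fn, n_samples=6, times=None, offset_sd=0.05,
                  noise_sd=0.01, seed=0):
        rng = np.random.default_rng(seed)
        times = times if times is not None else np.arange(0, 30, 3.0)
        rows = []
        for s in range(n_samples):
            off = rng.normal(0, offset_sd)
            for t in times:
                rows.append((f"s{s}", "wt", t,
                             curve_fn(t) + off + rng.normal(0, noise_sd)))
        return pd.DataFrame(rows, columns=["sample", "genotype", "time_min",
                                           "circularity"])

    def test_known_smooth_recovered(self):
        curve = lambda t: 0.90 + 0.08 * (t / 30.0) ** 2
        data = self._simulate(curve, seed=1)
        fit = rs.fit_circularity_trend(data)["wt"]
        err = np.abs(fit.fitted - curve(fit.grid_times))
        assert err.max() < 0.03

    def test_infinite_penalty_gives_weighted_mean(self):
        curve = lambda t: 0.90 + 0.05 * np.sin(t / 5)
        data = self._simulate(curve, seed=2, offset_sd=0.0)
        fit = rs.fit_circularity_trend(data, lam=1e10)["wt"]
        np.testing.assert_allclose(fit.fitted,
                                   data["circularity"].mean(), atol=2e-3)

    def test_identical_samples_zero_intercept_variance(self):
        data = self._simulate(lambda t: 0.92, offset_sd=0.0, noise_sd=0.005,
                              seed=3)
        fit = rs.fit_circularity_trend(data)["wt"]
        assert fit.var_sample < 1e-4

    def test_monotone_truth_gives_monotone_fit_within_se(self):
        curve = lambda t: 0.88 + 0.10 * t / 30.0
        data = self._simulate(curve, seed=4)
        fit = rs.fit_circularity_trend(data)["wt"]
        diffs = np.diff(fit.fitted)
        tol = 2 * np.max(fit.se)
        assert (diffs > -tol).all()

    def test_insufficient_samples_rejected(self):
        data = self._simulate(lambda t: 0.9, n_samples=2)
        with pytest.raises(ValueError):
            rs.fit_circularity_trend(data)
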