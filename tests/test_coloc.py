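import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flico import coloc
from flico.image_io import Mask

from conftest import brute_force_coloc


def full_mask(shape):
    return Mask(np.ones(shape, dtype=bool))


class TestEstimateThreshold:
    def test_constant_control(self):
        img = np.full((10, 10), 10.0)
        t = coloc.estimate_threshold([(img, full_mask((10, 10)))])
        assert t == pytest.approx(10.0)

    def test_gaussian_controls_mu_plus_3_sigma(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 10, (400, 250))  # 1e5 pixels
        t = coloc.estimate_threshold([(img, full_mask(img.shape))])
        assert t == pytest.approx(130.0, abs=0.5)

    def test_two_controls_pooled_moments(self):
        """Hand-pooled: (8 x100, 12 x300) -> mean 11, SD pooled over 400 px."""
        c1 = np.full((10, 10), 8.0)
        c2 = np.full((20, 15), 12.0)
        t = coloc.estimate_threshold([(c1, full_mask(c1.shape)),
                                      (c2, full_mask(c2.shape))])
        pooled = np.concatenate([c1.ravel(), c2.ravel()])
        expected = pooled.mean() + 3 * pooled.std(ddof=1)
        assert pooled.mean() == pytest.approx(11.0)
        assert t == pytest.approx(expected)

    def test_empty_masks_rejected(self):
        empty = Mask(np.zeros((5, 5), dtype=bool))
        with pytest.raises(coloc.InferenceError):
            coloc.estimate_threshold([(np.ones((5, 5)), empty)])


class TestComputeColoc:
    def test_worked_3x3_example(self):
        a = np.array([[5, 0, 0], [0, 9, 0], [0, 0, 2]], dtype=float)
        b = np.array([[7, 0, 0], [0, 0, 0], [0, 0, 4]], dtype=float)
        r = coloc.compute_coloc(coloc.ChannelPair(a, b, full_mask((3, 3)), 1, 1))
        assert r.m1 == pytest.approx((5 + 2) / (5 + 9 + 2))
        assert r.m2 == pytest.approx(1.0)
        assert r.tpcc == pytest.approx(1.0)
        assert (r.n_a, r.n_b, r.n_ab) == (3, 2, 2)

    def test_identical_channels_all_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 100, (12, 12))
        r = coloc.compute_coloc(coloc.ChannelPair(a, a, full_mask(a.shape),
                                                  30, 30))
        assert r.m1 == pytest.approx(1.0)
        assert r.m2 == pytest.approx(1.0)
        assert r.tpcc == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = np.zeros((4, 4)); a[:2] = 10.0
        b = np.zeros((4, 4)); b[2:] = 10.0
        r = coloc.compute_coloc(coloc.ChannelPair(a, b, full_mask((4, 4)), 1, 1))
        assert r.m1 == 0.0
        assert r.m2 == 0.0
        assert r.tpcc is None
        assert r.n_ab == 0

    def test_matches_brute_force_on_random_pairs(self):
        """Implementation agrees bit-for-bit with an explicit-loop oracle."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            a = rng.integers(0, 5, (3, 3)).astype(float)
            b = rng.integers(0, 5, (3, 3)).astype(float)
            t_a, t_b = rng.integers(0, 5, 2)
            got = coloc.compute_coloc(
                coloc.ChannelPair(a, b, full_mask((3, 3)), t_a, t_b))
            m1, m2, tpcc, n_a, n_b, n_ab = brute_force_coloc(
                a, b, np.ones((3, 3), bool), t_a, t_b)
            assert (got.n_a, got.n_b, got.n_ab) == (n_a, n_b, n_ab)
            assert got.m1 == m1 if m1 is None else got.m1 == pytest.approx(m1)
            assert got.m2 == m2 if m2 is None else got.m2 == pytest.approx(m2)
            if tpcc is None:
                assert got.tpcc is None
            else:
                assert got.tpcc == pytest.approx(tpcc)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, seed, lam):
        """Scaling a channel and its threshold by lambda leaves all three
        statistics unchanged."""
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 100, (8, 8))
        b = rng.uniform(0, 100, (8, 8))
        r1 = coloc.compute_coloc(coloc.ChannelPair(a, b, full_mask((8, 8)),
                                                   40, 40))
        r2 = coloc.compute_coloc(coloc.ChannelPair(lam * a, b,
                                                   full_mask((8, 8)),
                                                   lam * 40, 40))
        assert (r1.n_a, r1.n_b, r1.n_ab) == (r2.n_a, r2.n_b, r2.n_ab)
        if r1.m1 is not None:
            assert r2.m1 == pytest.approx(r1.m1)
        if r1.tpcc is not None:
            assert r2.tpcc == pytest.approx(r1.tpcc)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            coloc.compute_coloc(coloc.ChannelPair(
                np.ones((3, 3)), np.ones((3, 3)),
                Mask(np.zeros((3, 3), bool)), 0, 0))


def test_scatter_plot_writes_png(tmp_path):
    rng = np.random.default_rng(8)
    a = rng.uniform(0, 100, (32, 32))
    b = 0.7 * a + rng.normal(0, 5, (32, 32)).clip(-20, 20) + 30
    pair = coloc.ChannelPair(a, b.clip(0), full_mask((32, 32)), 40, 40)
    out = tmp_path / "scatter.png"
    coloc.scatter_plot(pair, out)
    assert out.stat().st_size > 0


class TestRandomize:
    def test_multiset_preserved_and_outside_untouched(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 10, (10, 10))
        m = Mask(rng.random((10, 10)) < 0.6)
        out = coloc.randomize_channel(img, m, seed=0)
        assert sorted(out[m.pixels]) == pytest.approx(sorted(img[m.pixels]))
        np.testing.assert_array_equal(out[~m.pixels], img[~m.pixels])

    def test_seed_reproducible(self):
        img = np.arange(100.0).reshape(10, 10)
        m = Mask(np.ones((10, 10), bool))
        np.testing.assert_array_equal(coloc.randomize_channel(img, m, 7),
                                      coloc.randomize_channel(img, m, 7))


class TestAggregateSample:
    def test_single_image_passthrough(self):
        r = coloc.ColocResult(m1=0.7, m2=0.6, tpcc=0.3, n_a=10, n_b=20, n_ab=5)
        s = coloc.aggregate_sample([r], "s1")
        assert (s.m1_w, s.m2_w, s.tpcc_w) == (0.7, 0.6, 0.3)

    def test_pixel_count_weighting(self):
        """(0.8, n=100) and (0.4, n=300) average to 0.5 under count weights."""
        r1 = coloc.ColocResult(0.8, None, None, n_a=100, n_b=0, n_ab=0)
        r2 = coloc.ColocResult(0.4, None, None, n_a=300, n_b=0, n_ab=0)
        s = coloc.aggregate_sample([r1, r2])
        assert s.m1_w == pytest.approx(0.5)
        assert s.m2_w is None

    def test_equal_weights_reduce_to_plain_mean(self):
        rs = [coloc.ColocResult(v, v, v, 50, 50, 50) for v in (0.2, 0.4, 0.9)]
        s = coloc.aggregate_sample(rs)
        assert s.m1_w == pytest.approx(np.mean([0.2, 0.4, 0.9]))
        assert s.sd_m1 == pytest.approx(
            np.sqrt((50 * ((np.array([0.2, 0.4, 0.9]) - 0.5) ** 2)).sum()
                    / (150 - 1)))


class TestFisherZ:
    def test_closed_forms(self):
        assert coloc.fisher_z(0.0) == 0.0
        assert coloc.fisher_z(0.5) == pytest.approx(math.atanh(0.5))
        assert coloc.fisher_z_inverse(coloc.fisher_z(0.5)) == pytest.approx(0.5)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            coloc.fisher_z(1.0)


class TestPopulationInference:
    def _summaries(self, tpcc_means):
        return [coloc.SampleSummary(f"s{i}", 0.9, 0.8, r, 0, 0, 0, 1, 1, 1)
                for i, r in enumerate(tpcc_means)]

    def test_equal_sample_means_zero_width(self):
        s = self._summaries([0.5] * 5)
        inf = coloc.population_inference(s, "tpcc")
        assert inf.mean == pytest.approx(0.5)
        assert inf.ci_low == pytest.approx(inf.ci_high)
        assert inf.p == 0.0

    def test_tpcc_ci_back_transformed_and_asymmetric(self):
        s = self._summaries([0.5, 0.7, 0.8, 0.6, 0.75])
        inf = coloc.population_inference(s, "tpcc")
        assert -1 < inf.ci_low < inf.mean < inf.ci_high < 1
        # tanh curvature: upper half-width shorter than lower half-width
        assert (inf.ci_high - inf.mean) < (inf.mean - inf.ci_low)

    def test_m_intervals_not_clipped(self):
        """High means with spread can push the raw-scale CI above 1."""
        sums = [coloc.SampleSummary(f"s{i}", m, m, None, 0, 0, 0, 1, 1, 0)
                for i, m in enumerate([0.99, 0.80, 1.0, 0.95])]
        inf = coloc.population_inference(sums, "m2")
        assert inf.ci_high > 1.0

    def test_clamping_at_unit_correlation(self):
        s = self._summaries([1.0, 0.999, 0.998])
        with pytest.warns(UserWarning, match="clamping"):
            inf = coloc.population_inference(s, "tpcc")
        assert math.isfinite(inf.mean)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(coloc.InferenceError):
            coloc.population_inference(self._summaries([0.5]), "tpcc")

    def test_matches_scipy_t_interval_on_raw_scale(self):
        from scipy import stats
        vals = [0.91, 0.95, 0.99, 0.97, 0.92, 0.96]
        sums = [coloc.SampleSummary(f"s{i}", v, v, None, 0, 0, 0, 1, 1, 0)
                for i, v in enumerate(vals)]
        inf = coloc.population_inference(sums, "m1")
        lo, hi = stats.t.interval(0.95, len(vals) - 1, loc=np.mean(vals),
                                  scale=stats.sem(vals))
        assert inf.ci_low == pytest.approx(lo)
        assert inf.ci_high == pytest.approx(hi)
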