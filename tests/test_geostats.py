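import numpy as np
import pytest
from scipy import stats

from laiscape import geostats as G
from laiscape.grid import GridSpec
from laiscape.scene import SceneConfig, generate_gaussian_field


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_force_variogram(x, y, v, lag_width, max_lag):
    """O(n^2) pair loop, the stated reference implementation."""
    sums = {}
    counts = {}
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(x[i] - x[j], y[i] - y[j])
            if d >= max_lag:
                continue
            b = int(d // lag_width)
            sums[b] = sums.get(b, 0.0) + (v[i] - v[j]) ** 2
            counts[b] = counts.get(b, 0) + 1
    bins = sorted(counts)
    gamma = np.array([sums[b] / (2 * counts[b]) for b in bins])
    centers = np.array([(b + 0.5) * lag_width for b in bins])
    npairs = np.array([counts[b] for b in bins], dtype=float)
    return centers, gamma, npairs


def dense_simple_kriging(coords, values, model, node):
    """Full-system SK solve with every datum as neighbor."""
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    K = model.covariance(d)
    k = model.covariance(np.sqrt(((coords - node) ** 2).sum(-1)))
    lam = np.linalg.solve(K, k)
    return float(lam @ values), float(model.sill - lam @ k)


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------


class TestMinMax:
    def test_endpoints(self):
        scaled, _ = G.minmax_normalize([2, 4, 6])
        assert np.allclose(scaled, [0.0, 0.5, 1.0])

    def test_min_maps_to_zero(self):
        scaled, _ = G.minmax_normalize([5.0, 7.0])
        assert scaled[0] == 0.0

    def test_roundtrip(self):
        out = G.minmax_denormalize([0.3, 0.7], (10.0, 20.0))
        assert np.allclose(out, [13.0, 17.0])

    def test_constant_raises(self):
        with pytest.raises(G.DegenerateRangeError):
            G.minmax_normalize([3.0, 3.0, 3.0])


class TestNormality:
    def test_normal_sample_passes_mostly(self):
        hits = 0
        for seed in range(50):
            x = np.random.default_rng(seed).standard_normal(500)
            decision, _, _ = G.normality_check(x)
            hits += decision == "normal"
        assert hits >= 45  # >= 90% pass rate on truly normal draws

    def test_lognormal_rejected(self):
        x = np.random.default_rng(0).lognormal(0.0, 1.0, 500)
        decision, _, _ = G.normality_check(x)
        assert decision == "non_normal"

    def test_cube_root_signed(self):
        assert G.cube_root_transform(-8.0) == pytest.approx(-2.0)
        assert np.allclose(G.cube_root_transform([27.0, -27.0]), [3.0, -3.0])


# ---------------------------------------------------------------------------
# empirical variogram
# ---------------------------------------------------------------------------


class TestEmpiricalVariogram:
    def test_collinear_example(self):
        pts = G.PointSamples([0, 1, 2], [0, 0, 0], [0.0, 1.0, 2.0])
        emp = G.empirical_variogram(pts, lag_width=1.0, max_lag=3.0)
        # two pairs at distance 1 -> gamma 0.5; one pair at distance 2 -> gamma 2
        assert emp.gamma[list(emp.lag_centers).index(1.5)] == pytest.approx(0.5)
        assert emp.gamma[list(emp.lag_centers).index(2.5)] == pytest.approx(2.0)
        assert emp.pair_counts.sum() == 3

    def test_constant_field_zero_gamma(self, rng):
        pts = G.PointSamples(rng.random(40), rng.random(40), np.full(40, 2.5))
        emp = G.empirical_variogram(pts, lag_width=0.1, max_lag=1.0)
        assert np.allclose(emp.gamma, 0.0)

    def test_matches_bruteforce_oracle(self, rng):
        x, y = rng.random(200) * 100, rng.random(200) * 100
        v = rng.standard_normal(200)
        pts = G.PointSamples(x, y, v)
        emp = G.empirical_variogram(pts, lag_width=10.0, max_lag=70.0)
        c0, g0, n0 = brute_force_variogram(pts.x, pts.y, pts.value, 10.0, 70.0)
        assert np.allclose(emp.lag_centers, c0, atol=1e-12)
        assert np.allclose(emp.gamma, g0, atol=1e-12)
        assert np.allclose(emp.pair_counts, n0)

    def test_no_pairs_raises(self):
        pts = G.PointSamples([0.0, 100.0], [0.0, 0.0], [1.0, 2.0])
        with pytest.raises(G.EmptyVariogramError):
            G.empirical_variogram(pts, lag_width=1.0, max_lag=5.0)


# ---------------------------------------------------------------------------
# model curves and fitting
# ---------------------------------------------------------------------------


class TestModelValue:
    def test_spherical_at_and_beyond_range(self):
        m = G.VariogramModel("spherical", 0.2, 0.8, 30.0)
        assert G.variogram_model_value(m, 30.0) == pytest.approx(1.0)
        assert G.variogram_model_value(m, 100.0) == pytest.approx(1.0)

    def test_exponential_at_range(self):
        m = G.VariogramModel("exponential", 0.1, 1.0, 50.0)
        assert G.variogram_model_value(m, 50.0) == pytest.approx(0.1 + (1 - np.exp(-3.0)))

    @pytest.mark.parametrize("kind", G.VARIOGRAM_KINDS)
    def test_zero_lag_convention(self, kind):
        m = G.VariogramModel(kind, 0.3, 0.7, 25.0)
        assert G.variogram_model_value(m, 0.0) == 0.0

    def test_nugget_limit(self):
        m = G.VariogramModel("spherical", 0.3, 0.7, 25.0)
        assert G.variogram_model_value(m, 1e-9) == pytest.approx(0.3, abs=1e-6)

    def test_negative_lag_rejected(self):
        m = G.VariogramModel("spherical", 0.0, 1.0, 10.0)
        with pytest.raises(G.GeostatsError):
            G.variogram_model_value(m, -1.0)


class TestFitVariogram:
    def test_exact_spherical_curve(self):
        truth = G.VariogramModel("spherical", 0.1, 0.9, 40.0)
        h = np.linspace(2.0, 80.0, 20)
        emp = G.EmpiricalVariogram(h, truth(h), np.full(20, 50.0))
        models = G.fit_variogram(emp)
        best = models[0]
        assert best.kind == "spherical"
        assert best.fit_rss <= 1e-10
        assert best.fit_r2 >= 1 - 1e-9
        assert best.nugget == pytest.approx(0.1, abs=1e-4)
        assert best.range_a == pytest.approx(40.0, abs=1e-2)

    def test_degenerate_flat_gamma(self):
        h = np.linspace(1.0, 10.0, 6)
        emp = G.EmpiricalVariogram(h, np.full(6, 0.5), np.full(6, 10.0))
        models = G.fit_variogram(emp)
        assert models, "flat gamma should still fit"
        assert all(m.fit_r2 == 0.0 and m.degenerate for m in models)

    def test_parameter_recovery(self):
        # spherical(C0=0.1, C=0.9, a=30 px) on 128x128, 2000 samples
        px = 15.0
        truth = G.VariogramModel("spherical", 0.1, 0.9, 30 * px)
        ranges, sills, kinds = [], [], []
        for seed in range(3):
            cfg = SceneConfig(rows=128, cols=128, seed=seed, lai_mean=10.0,
                              lai_sd=1.0, truth_variogram=truth)
            f = generate_gaussian_field(cfg)
            rng = np.random.default_rng(seed)
            idx = rng.choice(f.size, 2000, replace=False)
            gx, gy = cfg.grid.pixel_centers()
            pts = G.PointSamples(gx.ravel()[idx], gy.ravel()[idx], f.ravel()[idx])
            emp = G.empirical_variogram(pts, lag_width=px, max_lag=64 * px)
            best = G.fit_variogram(emp)[0]
            kinds.append(best.kind)
            ranges.append(best.range_a)
            sills.append(best.sill)
        assert np.median(ranges) == pytest.approx(truth.range_a, rel=0.25)
        assert np.median(sills) == pytest.approx(truth.sill, rel=0.15)
        assert max(set(kinds), key=kinds.count) == "spherical"


# ---------------------------------------------------------------------------
# normal scores
# ---------------------------------------------------------------------------


class TestNormalScores:
    def test_roundtrip_identity(self, rng):
        data = rng.lognormal(1.0, 0.6, 400)
        ns = G.NormalScoreMap.fit(data)
        back = ns.inverse(ns.forward(data))
        assert np.max(np.abs(back - data)) <= 1e-9

    def test_roundtrip_with_ties(self):
        data = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 9.0])
        ns = G.NormalScoreMap.fit(data)
        assert np.max(np.abs(ns.inverse(ns.forward(data)) - data)) <= 1e-9

    def test_monotone_both_directions(self, rng):
        data = rng.standard_normal(100)
        ns = G.NormalScoreMap.fit(data)
        q = np.linspace(data.min() - 1, data.max() + 1, 500)
        assert np.all(np.diff(ns.forward(q)) >= 0)
        s = np.linspace(-4, 4, 500)
        assert np.all(np.diff(ns.inverse(s)) >= 0)

    def test_scores_are_standard_normal_quantiles(self, rng):
        data = rng.random(1000)
        ns = G.NormalScoreMap.fit(data)
        scores = ns.forward(data)
        assert stats.kstest(scores, "norm").statistic < 0.05


# ---------------------------------------------------------------------------
# simple kriging
# ---------------------------------------------------------------------------


class TestSimpleKriging:
    def test_exact_at_datum_with_zero_nugget(self, unit_spherical):
        grid = GridSpec(4, 4, 10.0)
        # datum exactly on the pixel center of (1, 1)
        pts = G.PointSamples([15.0, 25.0], [15.0, 35.0], [2.0, -1.0])
        est, var = G.simple_kriging(pts, unit_spherical, grid)
        assert est[1, 1] == pytest.approx(2.0, abs=1e-9)
        assert var[1, 1] == pytest.approx(0.0, abs=1e-9)

    def test_far_node_reverts_to_mean(self, unit_spherical):
        grid = GridSpec(1, 1, 10.0)
        far = 5 * unit_spherical.range_a
        pts = G.PointSamples([far], [far], [3.0])
        est, var = G.simple_kriging(pts, unit_spherical, grid)
        assert est[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert var[0, 0] == pytest.approx(unit_spherical.sill, abs=1e-12)

    def test_matches_dense_solve(self, rng, unit_spherical):
        pts = G.PointSamples(rng.random(5) * 100, rng.random(5) * 100,
                             rng.standard_normal(5))
        grid = GridSpec(3, 3, 40.0)
        est, var = G.simple_kriging(pts, unit_spherical, grid, neighbors=5)
        gx, gy = grid.pixel_centers()
        for r in range(3):
            for c in range(3):
                e0, v0 = dense_simple_kriging(
                    pts.coords, pts.value, unit_spherical,
                    np.array([gx[r, c], gy[r, c]]),
                )
                assert est[r, c] == pytest.approx(e0, abs=1e-8)
                assert var[r, c] == pytest.approx(v0, abs=1e-8)

    def test_variance_within_bounds(self, rng, unit_spherical):
        pts = G.PointSamples(rng.random(30) * 500, rng.random(30) * 500,
                             rng.standard_normal(30))
        grid = GridSpec(8, 8, 60.0)
        _, var = G.simple_kriging(pts, unit_spherical, grid, neighbors=8)
        assert np.all(var >= -1e-12)
        assert np.all(var <= unit_spherical.sill + 1e-9)


# ---------------------------------------------------------------------------
# SGCS
# ---------------------------------------------------------------------------


class TestSGCS:
    def test_conditioning_honored(self, rng, unit_spherical, grid64):
        gx, gy = grid64.pixel_centers()
        idx = rng.choice(grid64.rows * grid64.cols, 50, replace=False)
        values = rng.lognormal(0.5, 0.4, 50)
        pts = G.PointSamples(gx.ravel()[idx], gy.ravel()[idx], values)
        ens = G.sgcs(pts, unit_spherical, grid64, n_realizations=2, seed=4)
        r, c = grid64.point_to_rc(pts.x, pts.y)
        for k in range(2):
            assert np.max(np.abs(ens.realizations[k][r, c] - pts.value)) <= 1e-6

    def test_identical_subseeds_zero_cv(self, rng, unit_spherical, grid64):
        pts = G.PointSamples(rng.random(30) * 900, rng.random(30) * 900,
                             rng.standard_normal(30))
        one = G.sgcs(pts, unit_spherical, grid64, n_realizations=1, seed=9,
                     transform=False)
        stack = np.concatenate([one.realizations, one.realizations])
        ens = G.SGCSEnsemble.from_stack(stack, seed=9)
        assert np.nanmax(ens.pixel_cv) == pytest.approx(0.0, abs=1e-12)

    def test_mean_surface_is_pixelwise_mean(self, rng, unit_spherical):
        grid = GridSpec(16, 16, 15.0)
        pts = G.PointSamples(rng.random(20) * 200, rng.random(20) * 200,
                             rng.standard_normal(20))
        ens = G.sgcs(pts, unit_spherical, grid, n_realizations=3, seed=0,
                     transform=False)
        assert np.allclose(ens.mean_surface, ens.realizations.mean(axis=0))

    def test_budget_error(self, rng, unit_spherical, grid64):
        pts = G.PointSamples(rng.random(5) * 900, rng.random(5) * 900,
                             rng.standard_normal(5))
        with pytest.raises(G.BudgetExceededError):
            G.sgcs(pts, unit_spherical, grid64, n_realizations=10, seed=0,
                   node_budget=100)

    def test_reproducible(self, rng, unit_spherical):
        grid = GridSpec(16, 16, 15.0)
        pts = G.PointSamples(rng.random(20) * 200, rng.random(20) * 200,
                             rng.lognormal(0, 0.5, 20))
        a = G.sgcs(pts, unit_spherical, grid, n_realizations=2, seed=5)
        b = G.sgcs(pts, unit_spherical, grid, n_realizations=2, seed=5)
        assert np.array_equal(a.realizations, b.realizations)


class TestRealizationCount:
    def test_single_count_flagged(self, rng, unit_spherical):
        grid = GridSpec(16, 16, 15.0)
        pts = G.PointSamples(rng.random(20) * 200, rng.random(20) * 200,
                             rng.standard_normal(20))
        selected, curve, ens = G.choose_realization_count(
            pts, unit_spherical, grid, counts=(1,), seed=0, transform=False
        )
        assert selected == 1
        assert np.isnan(curve[1])
        assert np.all(np.isnan(ens.pixel_cv))

    def test_stabilization_point_exists(self, rng, unit_spherical):
        grid = GridSpec(24, 24, 15.0)
        pts = G.PointSamples(rng.random(60) * 360, rng.random(60) * 360,
                             rng.lognormal(1.0, 0.3, 60))
        selected, curve, _ = G.choose_realization_count(
            pts, unit_spherical, grid, counts=(1, 5, 10, 20), seed=3
        )
        assert selected <= 20
        assert np.isfinite(curve[20])


class TestEnsembleConvergence:
    def test_mean_rmse_to_kriging_decreases_with_count(self, rng, unit_spherical):
        grid = GridSpec(32, 32, 15.0)
        pts = G.PointSamples(rng.random(100) * 480, rng.random(100) * 480,
                             rng.standard_normal(100))
        ens = G.sgcs(pts, unit_spherical, grid, n_realizations=100, seed=2,
                     transform=False)
        sk, _ = G.simple_kriging(pts, unit_spherical, grid)
        rmses = []
        for n in (10, 25, 50, 100):
            mean = ens.realizations[:n].mean(axis=0)
            rmses.append(float(np.sqrt(np.mean((mean - sk) ** 2))))
        assert np.all(np.diff(rmses) < 0), rmses


class TestInterpolationFidelity:
    def test_exact_surface(self, grid64, rng):
        gx, gy = grid64.pixel_centers()
        idx = rng.choice(grid64.rows * grid64.cols, 30, replace=False)
        surface = rng.standard_normal(grid64.shape)
        pts = G.PointSamples(gx.ravel()[idx], gy.ravel()[idx], surface.ravel()[idx])
        assert G.interpolation_fidelity(pts, surface, grid64) == pytest.approx(1.0)

    def test_constant_mean_surface_r2_zero(self, grid64, rng):
        gx, gy = grid64.pixel_centers()
        idx = rng.choice(grid64.rows * grid64.cols, 30, replace=False)
        v = rng.standard_normal(30)
        pts = G.PointSamples(gx.ravel()[idx], gy.ravel()[idx], v)
        surface = np.full(grid64.shape, v.mean())
        assert G.interpolation_fidelity(pts, surface, grid64) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points(self, grid64):
        pts = G.PointSamples([10.0, 20.0], [10.0, 20.0], [1.0, 2.0])
        with pytest.raises(G.GeostatsError):
            G.interpolation_fidelity(pts, np.zeros(grid64.shape), grid64)
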