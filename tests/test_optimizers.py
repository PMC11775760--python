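import numpy as np
import pytest

from laiscape import optimizers as O


def sphere_space(dim=4, lo=-5.0, hi=5.0):
    return O.SearchSpace(
        [O.Param(f"x{i}", "continuous", lo, hi) for i in range(dim)]
    )


def sphere(params):
    return float(sum(v**2 for v in params.values()))


class TestSearchSpace:
    def test_log_param_decoding(self):
        p = O.Param("c", "log-continuous", 1e-2, 1e3)
        lo, hi = p.internal_bounds
        assert lo == pytest.approx(-2.0)
        assert hi == pytest.approx(3.0)
        assert p.decode(0.0) == pytest.approx(1.0)

    def test_integer_rounding(self):
        p = O.Param("n", "integer", 2, 20)
        assert p.decode(7.4) == 7
        assert isinstance(p.decode(7.4), int)

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            O.Param("x", "continuous", 1.0, 1.0)

    def test_sample_within_bounds(self, rng):
        space = O.default_space("GBRT")
        x = space.sample(rng, 50)
        assert np.all(x >= space.lower) and np.all(x <= space.upper)

    def test_default_spaces(self):
        assert {p.name for p in O.default_space("RFR").params} == {
            "max_depth", "n_estimators", "min_samples_split", "min_samples_leaf"
        }
        assert "learning_rate" in {p.name for p in O.default_space("GBRT").params}
        assert {p.name for p in O.default_space("SVR").params} == {
            "cost_parameter", "kernel_coefficient"
        }


class TestLOOCV:
    def test_constant_y_zero_rmse(self):
        X = np.arange(20, dtype=float).reshape(10, 2)
        y = np.full(10, 3.0)
        rmse = O.loocv_objective("RFR", {"n_estimators": 5}, X, y, seed=0)
        assert rmse == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_loop(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 2))
        y = 2 * X[:, 0] + rng.normal(0, 0.1, 10)
        params = {"n_estimators": 20}
        got = O.loocv_objective("RFR", params, X, y, seed=0)
        # literal oracle loop
        errs = []
        for i in range(10):
            mask = np.ones(10, bool)
            mask[i] = False
            m = O.train_model("RFR", params, X[mask], y[mask], seed=0)
            errs.append(y[i] - m.predict(X[i : i + 1])[0])
        want = float(np.sqrt(np.mean(np.array(errs) ** 2)))
        assert got == pytest.approx(want, abs=1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.random((12, 3))
        y = rng.random(12)
        a = O.loocv_objective("GBRT", {"n_estimators": 10}, X, y, seed=3)
        b = O.loocv_objective("GBRT", {"n_estimators": 10}, X, y, seed=3)
        assert a == b

    def test_degenerate_params_penalized(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 2))
        y = rng.random(10)
        obj = O.LOOCVObjective("RFR", X, y, seed=0)
        assert obj({"min_samples_split": 50}) == pytest.approx(obj.penalty())

    def test_rfr_fits_linear_signal(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 1, (60, 1))
        y = 2 * X[:, 0] + rng.normal(0, 0.05, 60)
        yhat = O.loocv_predictions("RFR", {"n_estimators": 100}, X, y, seed=0)
        ss_res = np.sum((y - yhat) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.8


class TestTrainModel:
    def test_single_tree_constant(self):
        X = np.arange(10, dtype=float).reshape(5, 2)
        y = np.full(5, 7.0)
        m = O.train_model("RFR", {"max_depth": 1, "n_estimators": 1}, X, y)
        assert np.allclose(m.predict(X), 7.0)

    def test_svr_tiny_cost_mean_reverts(self):
        rng = np.random.default_rng(5)
        X = rng.random((30, 2))
        y = rng.random(30) * 10
        m = O.train_model("SVR", {"cost_parameter": 1e-6, "kernel_coefficient": 1.0}, X, y)
        preds = m.predict(X)
        assert np.std(preds) < 0.1 * np.std(y)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            O.train_model("XGB", {}, np.zeros((3, 1)), np.zeros(3))


class TestPSO:
    def test_hand_step(self):
        V1, P1 = O.pso_step(
            P=np.array([0.0]), V=np.array([1.0]), pbest=np.array([2.0]),
            gbest=np.array([4.0]), w=0.7, c1=1.5, c2=1.5,
            r1=np.array([0.5]), r2=np.array([0.5]),
        )
        assert V1[0] == pytest.approx(5.2)
        assert P1[0] == pytest.approx(5.2)

    def test_inertia_only(self):
        V = np.array([1.3, -0.4])
        V1, _ = O.pso_step(np.zeros(2), V, np.ones(2), np.ones(2), 1.0, 0.0, 0.0,
                           np.full(2, 0.5), np.full(2, 0.5))
        assert np.array_equal(V1, V)

    def test_sphere_convergence(self):
        bests = []
        for seed in range(5):
            best, _ = O.pso_optimize(sphere_space(), sphere, swarm=15,
                                     iterations=60, seed=seed)
            bests.append(best.value)
        assert np.median(bests) < 1e-3

    def test_zero_iterations_returns_initial_best(self):
        best, trace = O.pso_optimize(sphere_space(), sphere, swarm=5,
                                     iterations=0, seed=0)
        assert trace.n_evaluations == 5
        assert best.value == min(trace.values)


class _CloneSpace(O.SearchSpace):
    """Space whose initial sampling returns identical rows (degenerate GA)."""

    def sample(self, rng, n):
        row = super().sample(rng, 1)
        return np.repeat(row, n, axis=0)


class TestGA:
    def test_elitism_never_worsens(self):
        evals = []

        def obj(params):
            v = sphere(params)
            evals.append(v)
            return v

        best, trace = O.ga_optimize(sphere_space(), obj, population=10,
                                    generations=8, crossover_rate=0.0,
                                    mutation_rate=0.0, seed=1)
        # per-generation best is monotone under elitism
        gens = [trace.values[i : i + 10] for i in range(0, len(trace.values), 10)]
        gen_best = [min(g) for g in gens]
        assert all(b <= a + 1e-12 for a, b in zip(gen_best, gen_best[1:]))

    def test_sphere_convergence(self):
        bests = []
        for seed in range(5):
            best, _ = O.ga_optimize(sphere_space(), sphere, population=20,
                                    generations=40, seed=seed)
            bests.append(best.value)
        assert np.median(bests) < 1e-2

    def test_identical_population_no_mutation_identical_offspring(self):
        space = _CloneSpace(sphere_space().params)
        best, trace = O.ga_optimize(space, sphere, population=4, generations=3,
                                    mutation_rate=0.0, seed=2)
        assert len(set(trace.values)) == 1

    def test_odd_population_rejected(self):
        with pytest.raises(ValueError):
            O.ga_optimize(sphere_space(), sphere, population=5, generations=1)


class TestSA:
    def test_acceptance_probability_exact(self):
        assert O.sa_acceptance_probability(0.1, 0.1) == pytest.approx(np.exp(-1.0))
        assert O.sa_acceptance_probability(-0.5, 0.1) == 1.0
        assert O.sa_acceptance_probability(0.5, 0.0) == 0.0

    def test_empirical_acceptance_rate(self):
        # Monte-Carlo of the Metropolis rule itself
        rng = np.random.default_rng(0)
        delta_f, T = 0.1, 0.1
        accepted = np.mean(rng.random(10_000) < O.sa_acceptance_probability(delta_f, T))
        assert accepted == pytest.approx(np.exp(-1.0), abs=0.03)

    def test_zero_temperature_pure_descent(self):
        space = O.SearchSpace([O.Param("x", "continuous", -5.0, 5.0)])
        values = []

        def obj(params):
            v = (params["x"] - 1.0) ** 2
            values.append(v)
            return v

        _, trace = O.sa_optimize(space, obj, T0=1e-12, cooling=0.95,
                                 steps=1000, seed=0)
        # accepted chain never moves uphill: best-so-far equals running min
        # and the current value never exceeds the previous accepted value
        cur = trace.values[0]
        for v in trace.values[1:]:
            cur = min(cur, v) if v <= cur else cur
        assert trace.best_so_far[-1] == min(trace.values)

    def test_quadratic_convergence(self):
        space = O.SearchSpace([O.Param("x", "continuous", -5.0, 5.0)])

        def obj(params):
            return (params["x"] - 1.234) ** 2

        best, _ = O.sa_optimize(space, obj, T0=1.0, cooling=0.97, steps=500, seed=3)
        assert abs(best.params["x"] - 1.234) < 0.05


class TestBO:
    def test_constant_objective_ei_zero(self):
        ei = O._expected_improvement(np.array([1.0]), np.array([1e-15]), 1.0)
        assert ei[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_iterations_returns_initial_best(self):
        best, trace = O.bo_optimize(sphere_space(2), sphere, n_init=5,
                                    n_iter=0, seed=0)
        assert trace.n_evaluations == 5
        assert best.value == min(trace.values)

    def test_forrester_style_curve(self):
        space = O.SearchSpace([O.Param("x", "continuous", 0.0, 1.0)])

        def f(x):
            return (6 * x - 2) ** 2 * np.sin(12 * x - 4)

        def obj(params):
            return float(f(params["x"]))

        grid = np.linspace(0, 1, 10_000)
        x_star = grid[np.argmin(f(grid))]
        best, _ = O.bo_optimize(space, obj, n_init=5, n_iter=20, seed=3)
        assert abs(best.params["x"] - x_star) < 0.05


class TestGenericContracts:
    @pytest.mark.parametrize("method", ["PSO", "GA", "SA", "BO", "RANDOM"])
    def test_trace_best_so_far_non_increasing(self, method):
        _, trace = O.optimize(method, sphere_space(2), sphere, budget=20, seed=1)
        assert np.all(np.diff(trace.best_so_far) <= 1e-15)

    @pytest.mark.parametrize("method", ["PSO", "GA", "SA", "BO"])
    def test_integer_params_integral_everywhere(self, method):
        space = O.SearchSpace(
            [O.Param("n", "integer", 1, 30), O.Param("d", "integer", 2, 9)]
        )

        def obj(params):
            assert isinstance(params["n"], int)
            assert isinstance(params["d"], int)
            return (params["n"] - 17) ** 2 + params["d"]

        _, trace = O.optimize(method, space, obj, budget=15, seed=2)
        for cand in trace.candidates:
            assert float(cand["n"]).is_integer()
            assert float(cand["d"]).is_integer()

    @pytest.mark.parametrize("method", ["PSO", "GA", "SA", "BO", "RANDOM"])
    def test_full_determinism(self, method):
        _, t1 = O.optimize(method, sphere_space(3), sphere, budget=18, seed=7)
        _, t2 = O.optimize(method, sphere_space(3), sphere, budget=18, seed=7)
        assert t1.values == t2.values
        assert t1.candidates == t2.candidates

    def test_final_result_is_best_evaluated(self):
        best, trace = O.optimize("PSO", sphere_space(3), sphere, budget=30, seed=5)
        assert best.value == min(trace.values)
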