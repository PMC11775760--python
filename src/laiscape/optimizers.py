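"""Regressor families (RFR / GBRT / SVR) and four from-scratch
hyperparameter optimizers — Bayesian optimization, particle swarm, genetic
algorithm, simulated annealing — minimizing a leave-one-out cross-validation
RMSE objective over mixed integer/continuous search spaces.

Integer parameters are represented continuously inside every optimizer and
rounded only at evaluation time; log-scaled parameters are optimized in
log10 space. All methods are fully deterministic given a seed and record a
per-evaluation trace with a non-increasing best-so-far column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sciopt
from scipy import stats
from scipy.stats import qmc

log = logging.getLogger(__name__)

MODEL_KINDS = ("RFR", "GBRT", "SVR")


# ---------------------------------------------------------------------------
# search spaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Param:
    name: str
    kind: str  # "integer" | "continuous" | "log-continuous"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("integer", "continuous", "log-continuous"):
            raise ValueError(f"unknown param kind {self.kind!r}")
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ValueError(f"bad bounds for {self.name}: [{self.low}, {self.high}]")

    @property
    def internal_bounds(self) -> tuple[float, float]:
        if self.kind == "log-continuous":
            return (np.log10(self.low), np.log10(self.high))
        return (float(self.low), float(self.high))

    def decode(self, x: float) -> float | int:
        lo, hi = self.internal_bounds
        x = min(max(x, lo), hi)
        if self.kind == "log-continuous":
            return float(10.0**x)
        if self.kind == "integer":
            return int(round(x))
        return float(x)


@dataclass
class SearchSpace:
    params: list[Param]

    @property
    def dim(self) -> int:
        return len(self.params)

    @property
    def lower(self) -> np.ndarray:
        return np.array([p.internal_bounds[0] for p in self.params])

    @property
    def upper(self) -> np.ndarray:
        return np.array([p.internal_bounds[1] for p in self.params])

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def decode(self, x: np.ndarray) -> dict[str, float | int]:
        return {p.name: p.decode(v) for p, v in zip(self.params, x)}

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.random((n, self.dim))
        return self.lower + u * (self.upper - self.lower)


def default_space(model_kind: str, n_estimators_max: int = 800) -> SearchSpace:
    """Default hyperparameter bounds per model family (the published table
    names the parameters but no ranges; these bounds are configuration)."""
    if model_kind in ("RFR", "GBRT"):
        params = [
            Param("max_depth", "integer", 2, 20),
            Param("n_estimators", "integer", 50, n_estimators_max),
            Param("min_samples_split", "integer", 2, 20),
            Param("min_samples_leaf", "integer", 1, 10),
        ]
        if model_kind == "GBRT":
            # boosting is ill-defined without a shrinkage rate
            params.append(Param("learning_rate", "log-continuous", 0.01, 0.3))
        return SearchSpace(params)
    if model_kind == "SVR":
        return SearchSpace(
            [
                Param("cost_parameter", "log-continuous", 1e-2, 1e3),
                Param("kernel_coefficient", "log-continuous", 1e-4, 10.0),
            ]
        )
    raise ValueError(f"unknown model kind {model_kind!r}")


@dataclass
class Candidate:
    params: dict[str, float | int]
    value: float


@dataclass
class OptimizationTrace:
    """Per-evaluation record: candidate, objective, best-so-far."""

    candidates: list[dict] = field(default_factory=list)
    values: list[float] = field(default_factory=list)
    best_so_far: list[float] = field(default_factory=list)
    seed: int = 0

    def record(self, params: dict, value: float) -> None:
        self.candidates.append(dict(params))
        self.values.append(float(value))
        prev = self.best_so_far[-1] if self.best_so_far else np.inf
        self.best_so_far.append(min(prev, float(value)))

    @property
    def n_evaluations(self) -> int:
        return len(self.values)

    def best(self) -> Candidate:
        i = int(np.argmin(self.values))
        return Candidate(self.candidates[i], self.values[i])


class _Evaluator:
    """Decode-and-evaluate wrapper that owns the trace."""

    def __init__(self, space: SearchSpace, objective, seed: int):
        self.space = space
        self.objective = objective
        self.trace = OptimizationTrace(seed=seed)

    def __call__(self, x: np.ndarray) -> float:
        params = self.space.decode(np.asarray(x, dtype=float))
        value = float(self.objective(params))
        self.trace.record(params, value)
        return value


# ---------------------------------------------------------------------------
# regressors & LOOCV objective
# ---------------------------------------------------------------------------


def train_model(kind: str, params: dict | None, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit one regressor of the requested family; ``params=None`` uses the
    library defaults (the untuned baselines)."""
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.svm import SVR

    params = dict(params or {})
    if kind == "RFR":
        model = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    elif kind == "GBRT":
        model = GradientBoostingRegressor(random_state=seed, **params)
    elif kind == "SVR":
        kwargs = {}
        if "cost_parameter" in params:
            kwargs["C"] = params["cost_parameter"]
        if "kernel_coefficient" in params:
            kwargs["gamma"] = params["kernel_coefficient"]
        model = SVR(kernel="rbf", **kwargs)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return model


def predict(model, X: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(X, dtype=float))


def loocv_predictions(
    kind: str, params: dict | None, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Literal leave-one-out loop: refit on n-1 points, predict the held-out
    one, for every point."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    yhat = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = train_model(kind, params, X[mask], y[mask], seed=seed)
        yhat[i] = model.predict(X[i : i + 1])[0]
        mask[i] = True
    return yhat


class LOOCVObjective:
    """Callable params -> LOOCV RMSE, with a cache so the winning candidate's
    fold predictions can be reused for reporting without refitting."""

    def __init__(self, kind: str, X: np.ndarray, y: np.ndarray, seed: int = 0):
        self.kind = kind
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.seed = seed
        self.cache: dict[tuple, tuple[float, np.ndarray]] = {}

    def _key(self, params: dict) -> tuple:
        return tuple(sorted(params.items()))

    def penalty(self) -> float:
        return 10.0 * float(np.std(self.y))

    def _degenerate(self, params: dict) -> bool:
        n_train = len(self.y) - 1
        if params.get("min_samples_split", 2) > n_train:
            return True
        if params.get("min_samples_leaf", 1) > n_train // 2:
            return True
        return False

    def __call__(self, params: dict) -> float:
        key = self._key(params)
        if key in self.cache:
            return self.cache[key][0]
        if self._degenerate(params):
            log.warning("degenerate params %s: penalty objective", params)
            value, yhat = self.penalty(), np.full(len(self.y), np.nan)
        else:
            try:
                yhat = loocv_predictions(self.kind, params, self.X, self.y, self.seed)
                value = float(np.sqrt(np.mean((self.y - yhat) ** 2)))
            except Exception as e:  # defensive: a bad corner of the space
                log.warning("objective failed for %s (%s): penalty", params, e)
                value, yhat = self.penalty(), np.full(len(self.y), np.nan)
        self.cache[key] = (value, yhat)
        return value

    def predictions_for(self, params: dict) -> np.ndarray:
        key = self._key(params)
        if key not in self.cache:
            self(params)
        return self.cache[key][1]


def loocv_objective(
    kind: str, params: dict | None, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> float:
    yhat = loocv_predictions(kind, params, X, y, seed=seed)
    return float(np.sqrt(np.mean((np.asarray(y, dtype=float) - yhat) ** 2)))


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


def pso_step(
    P: np.ndarray,
    V: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    w: float,
    c1: float,
    c2: float,
    r1: np.ndarray,
    r2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One velocity/position update:
    ``V' = w V + c1 (pbest - P) r1 + c2 (gbest - P) r2; P' = P + V'``."""
    V1 = w * V + c1 * (pbest - P) * r1 + c2 * (gbest - P) * r2
    return V1, P + V1


def pso_optimize(
    space: SearchSpace,
    objective,
    swarm: int = 10,
    iterations: int = 30,
    w: float = 0.7,
    c1: float = 1.5,
    c2: float = 1.5,
    seed: int = 0,
) -> tuple[Candidate, OptimizationTrace]:
    """Particle swarm search; positions clamped to bounds, fresh uniform
    draws per term and dimension."""
    if swarm < 2:
        raise ValueError("swarm must be >= 2")
    rng = np.random.default_rng(seed)
    ev = _Evaluator(space, objective, seed)
    P = space.sample(rng, swarm)
    V = np.zeros_like(P)
    fitness = np.array([ev(p) for p in P])
    pbest = P.copy()
    pbest_f = fitness.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), pbest_f[g]
    for _ in range(iterations):
        for i in range(swarm):
            r1 = rng.random(space.dim)
            r2 = rng.random(space.dim)
            V[i], newP = pso_step(P[i], V[i], pbest[i], gbest, w, c1, c2, r1, r2)
            P[i] = space.clip(newP)
            f = ev(P[i])
            if f < pbest_f[i]:
                pbest[i], pbest_f[i] = P[i].copy(), f
                if f < gbest_f:
                    gbest, gbest_f = P[i].copy(), f
    return ev.trace.best(), ev.trace


def ga_optimize(
    space: SearchSpace,
    objective,
    population: int = 20,
    generations: int = 30,
    crossover_rate: float = 0.8,
    mutation_rate: float = 0.1,
    seed: int = 0,
) -> tuple[Candidate, OptimizationTrace]:
    """Real-coded GA: tournament selection (size 2), blend crossover,
    Gaussian mutation at 10% of each bound width, elitism of one."""
    if population % 2 != 0 or population < 2:
        raise ValueError("population must be even and >= 2")
    rng = np.random.default_rng(seed)
    ev = _Evaluator(space, objective, seed)
    width = space.upper - space.lower
    pop = space.sample(rng, population)
    fit = np.array([ev(p) for p in pop])
    for _ in range(generations):
        elite_idx = int(np.argmin(fit))
        elite, elite_f = pop[elite_idx].copy(), fit[elite_idx]

        def tournament() -> np.ndarray:
            a, b = rng.integers(0, population, size=2)
            return pop[a] if fit[a] <= fit[b] else pop[b]

        children = []
        for _ in range(population // 2):
            p1, p2 = tournament().copy(), tournament().copy()
            if rng.random() < crossover_rate:
                u = rng.random(space.dim)
                c1v = u * p1 + (1 - u) * p2
                c2v = u * p2 + (1 - u) * p1
            else:
                c1v, c2v = p1, p2
            for child in (c1v, c2v):
                mut = rng.random(space.dim) < mutation_rate
                child[mut] += 0.1 * width[mut] * rng.standard_normal(mut.sum())
                children.append(space.clip(child))
        pop = np.array(children)
        fit = np.array([ev(p) for p in pop])
        worst = int(np.argmax(fit))
        if elite_f < fit[worst]:  # elitism: best survives unconditionally
            pop[worst], fit[worst] = elite, elite_f
    return ev.trace.best(), ev.trace


def sa_acceptance_probability(delta_f: float, T: float) -> float:
    if delta_f <= 0:
        return 1.0
    if T <= 0:
        return 0.0
    return float(np.exp(-delta_f / T))


def sa_optimize(
    space: SearchSpace,
    objective,
    T0: float = 1.0,
    cooling: float = 0.95,
    steps: int = 200,
    seed: int = 0,
) -> tuple[Candidate, OptimizationTrace]:
    """Simulated annealing: Gaussian proposals at 10% of bound width
    (shrinking with temperature), Metropolis acceptance, geometric cooling,
    best-ever returned."""
    if T0 <= 0:
        raise ValueError("T0 must be positive")
    if not 0 < cooling < 1:
        raise ValueError("cooling must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ev = _Evaluator(space, objective, seed)
    width = space.upper - space.lower
    x = space.sample(rng, 1)[0]
    fx = ev(x)
    T = T0
    for _ in range(steps):
        scale = 0.1 * max(np.sqrt(T / T0), 0.02)
        prop = space.clip(x + scale * width * rng.standard_normal(space.dim))
        fp = ev(prop)
        if rng.random() < sa_acceptance_probability(fp - fx, T):
            x, fx = prop, fp
        T *= cooling
    return ev.trace.best(), ev.trace


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, y_best: float, xi: float = 0.01):
    sigma = np.maximum(sigma, 1e-12)
    z = (y_best - mu - xi) / sigma
    return sigma * (z * stats.norm.cdf(z) + stats.norm.pdf(z))


def bo_optimize(
    space: SearchSpace,
    objective,
    n_init: int = 8,
    n_iter: int = 30,
    seed: int = 0,
    n_acq_samples: int = 1024,
) -> tuple[Candidate, OptimizationTrace]:
    """Bayesian optimization: Latin-hypercube initial design, Matern-5/2
    Gaussian-process surrogate on unit-scaled inputs, expected-improvement
    acquisition maximized by random multistart plus a local polish."""
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
    import warnings

    if n_init < 3:
        raise ValueError("n_init must be >= 3")
    rng = np.random.default_rng(seed)
    ev = _Evaluator(space, objective, seed)
    lo, hi = space.lower, space.upper
    span = hi - lo

    sampler = qmc.LatinHypercube(d=space.dim, seed=rng)
    U = sampler.random(n_init)  # unit cube
    X_unit = list(U)
    Y = [ev(lo + u * span) for u in U]

    for _ in range(n_iter):
        kernel = ConstantKernel(1.0) * Matern(
            length_scale=np.full(space.dim, 0.3), nu=2.5,
            length_scale_bounds=(1e-2, 1e2),
        ) + WhiteKernel(1e-6, noise_level_bounds=(1e-10, 1e1))
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31))
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(np.array(X_unit), np.array(Y))
        except Exception as e:
            log.warning("GP fit failed (%s): random proposal", e)
            u = rng.random(space.dim)
            X_unit.append(u)
            Y.append(ev(lo + u * span))
            continue
        y_best = min(Y)
        cand = rng.random((n_acq_samples, space.dim))
        mu, sd = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sd, y_best)
        u0 = cand[int(np.argmax(ei))]

        def neg_ei(u: np.ndarray) -> float:
            m, s = gp.predict(u[None], return_std=True)
            return -float(_expected_improvement(m, s, y_best)[0])

        res = sciopt.minimize(
            neg_ei, u0, method="L-BFGS-B", bounds=[(0.0, 1.0)] * space.dim
        )
        u = res.x if res.success else u0
        X_unit.append(u)
        Y.append(ev(lo + u * span))
    return ev.trace.best(), ev.trace


def random_search(
    space: SearchSpace, objective, budget: int, seed: int = 0
) -> tuple[Candidate, OptimizationTrace]:
    """Uniform random baseline at the same evaluation budget."""
    rng = np.random.default_rng(seed)
    ev = _Evaluator(space, objective, seed)
    for x in space.sample(rng, budget):
        ev(x)
    return ev.trace.best(), ev.trace


OPTIMIZER_NAMES = ("BO", "PSO", "GA", "SA")


def optimize(
    method: str, space: SearchSpace, objective, budget: int, seed: int = 0
) -> tuple[Candidate, OptimizationTrace]:
    """Dispatch one optimizer with its evaluation budget equalized so the
    four methods are comparable."""
    method = method.upper()
    if budget < 2:
        raise ValueError("budget must be >= 2")
    if method == "PSO":
        swarm = max(2, min(10, budget // 2))
        iterations = max(budget // swarm - 1, 0)
        return pso_optimize(space, objective, swarm=swarm, iterations=iterations, seed=seed)
    if method == "GA":
        population = max(2, min(20, (budget // 2) * 2 // 2 * 2))
        population = population if population % 2 == 0 else population - 1
        population = max(population, 2)
        generations = max(budget // population - 1, 0)
        return ga_optimize(space, objective, population=population, generations=generations, seed=seed)
    if method == "SA":
        return sa_optimize(space, objective, steps=budget - 1, seed=seed)
    if method == "BO":
        n_init = min(8, max(3, budget // 2))
        return bo_optimize(space, objective, n_init=n_init, n_iter=budget - n_init, seed=seed)
    if method == "RANDOM":
        return random_search(space, objective, budget, seed=seed)
    raise ValueError(f"unknown optimizer {method!r}")
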