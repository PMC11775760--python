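"""Variogram analysis, simple kriging and sequential Gaussian conditional
simulation (SGCS).

The workflow mirrors classical geostatistical practice: point samples are
normal-score transformed, an empirical variogram is computed and a
theoretical model (spherical / exponential / gaussian, effective-range
parameterisation) fitted by count-weighted least squares; surfaces are then
produced either by simple kriging (smooth, minimum error variance) or by
SGCS, which draws equiprobable realizations that honor the conditioning
data, the histogram and the variogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

VARIOGRAM_KINDS = ("spherical", "exponential", "gaussian")

#: hard cap on simulated nodes per sgcs() call (n_realizations * unknown nodes)
DEFAULT_NODE_BUDGET = 20_000_000


class GeostatsError(ValueError):
    """Base error for geostatistical routines."""


class DegenerateRangeError(GeostatsError):
    pass


class EmptyVariogramError(GeostatsError):
    pass


class BudgetExceededError(GeostatsError):
    pass


# ---------------------------------------------------------------------------
# point samples
# ---------------------------------------------------------------------------


@dataclass
class PointSamples:
    """Scattered point observations ``value`` at metric coordinates (x, y).

    Duplicate coordinates are averaged on construction so downstream kriging
    systems stay non-singular.
    """

    x: np.ndarray
    y: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if not (self.x.shape == self.y.shape == self.value.shape):
            raise GeostatsError("x, y and value must have equal shapes")
        if not np.all(np.isfinite(self.value)):
            raise GeostatsError("non-finite sample values")
        # average duplicates
        coords = np.column_stack([self.x, self.y])
        uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
        if len(uniq) != len(coords):
            sums = np.zeros(len(uniq))
            counts = np.zeros(len(uniq))
            np.add.at(sums, inverse, self.value)
            np.add.at(counts, inverse, 1.0)
            self.x = uniq[:, 0]
            self.y = uniq[:, 1]
            self.value = sums / counts

    def __len__(self) -> int:
        return len(self.value)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


# ---------------------------------------------------------------------------
# scaling / transforms
# ---------------------------------------------------------------------------


def minmax_normalize(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Scale values to [0, 1] via ``(y - ymin) / (ymax - ymin)``.

    Returns the scaled array and ``(ymin, ymax)`` so the map can be inverted
    with :func:`minmax_denormalize`.
    """
    values = np.asarray(values, dtype=float)
    ymin = float(np.min(values))
    ymax = float(np.max(values))
    if ymax <= ymin:
        raise DegenerateRangeError("constant input: min-max range is degenerate")
    return (values - ymin) / (ymax - ymin), (ymin, ymax)


def minmax_denormalize(scaled: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    ymin, ymax = bounds
    return np.asarray(scaled, dtype=float) * (ymax - ymin) + ymin


def cube_root_transform(values: np.ndarray) -> np.ndarray:
    """Signed cube root: preserves sign, ``cbrt(-8) == -2``."""
    return np.cbrt(np.asarray(values, dtype=float))


def normality_check(values: np.ndarray, alpha: float = 0.05) -> tuple[str, float, float]:
    """Shapiro-Wilk normality decision at ``alpha``.

    Returns ``(decision, statistic, p_value)`` with decision in
    {"normal", "non_normal"}.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise GeostatsError("normality_check requires n >= 8")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.shapiro(values)
    return ("normal" if p >= alpha else "non_normal"), float(stat), float(p)


@dataclass
class NormalScoreMap:
    """Rank-based map between data values and standard-normal quantiles.

    Forward and inverse are piecewise-linear in the (value, score) table
    with linear tail extrapolation from the edge slopes; tied data values
    collapse to the average of their scores so both directions are strictly
    monotone functions.
    """

    values: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)

    @classmethod
    def fit(cls, data: np.ndarray) -> "NormalScoreMap":
        data = np.asarray(data, dtype=float)
        if data.size < 2:
            raise GeostatsError("need at least 2 values for a normal-score map")
        order = np.argsort(data, kind="stable")
        srt = data[order]
        n = data.size
        raw_scores = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        uniq, start_idx = np.unique(srt, return_index=True)
        # average scores over each run of tied values
        bounds = np.append(start_idx, n)
        mean_scores = np.array(
            [raw_scores[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        )
        if len(uniq) < 2:
            raise DegenerateRangeError("constant data: normal-score map is degenerate")
        return cls(values=uniq, scores=mean_scores)

    def _interp(self, q: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        out = np.interp(q, xs, ys)
        lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        below = q < xs[0]
        above = q > xs[-1]
        out = np.where(below, ys[0] + (q - xs[0]) * lo_slope, out)
        out = np.where(above, ys[-1] + (q - xs[-1]) * hi_slope, out)
        return out

    def forward(self, values: np.ndarray) -> np.ndarray:
        return self._interp(values, self.values, self.scores)

    def inverse(self, scores: np.ndarray) -> np.ndarray:
        return self._interp(scores, self.scores, self.values)


# ---------------------------------------------------------------------------
# variograms
# ---------------------------------------------------------------------------


@dataclass
class EmpiricalVariogram:
    """Binned semivariance: gamma(h) against lag-bin centers with pair counts."""

    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag_centers) <= 0):
            raise GeostatsError("lag centers must be strictly increasing")
        if np.any(self.gamma < 0) or np.any(self.pair_counts < 0):
            raise GeostatsError("gamma and pair counts must be non-negative")


@dataclass
class VariogramModel:
    """Theoretical variogram: nugget ``c0``, partial sill ``c`` and effective
    range ``range_a`` for one of the three closed-form kinds."""

    kind: str
    nugget: float
    partial_sill: float
    range_a: float
    fit_r2: float = float("nan")
    fit_rss: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VARIOGRAM_KINDS:
            raise GeostatsError(f"unknown variogram kind {self.kind!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise GeostatsError("nugget and partial sill must be >= 0")
        if self.range_a <= 0:
            raise GeostatsError("range must be positive")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h: np.ndarray) -> np.ndarray:
        return variogram_model_value(self, h)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h); C(0) = sill."""
        return self.sill - variogram_model_value(self, h)


def variogram_model_value(model: VariogramModel, h: np.ndarray) -> np.ndarray:
    """Evaluate gamma(h). gamma(0) = 0 by convention; the h -> 0+ limit is the
    nugget. Effective-range parameterisation (factor 3 for exponential and in
    the gaussian exponent) follows GS+ conventions."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise GeostatsError("negative lag distance")
    c0, c, a = model.nugget, model.partial_sill, model.range_a
    if model.kind == "spherical":
        u = np.minimum(h / a, 1.0)
        g = c0 + c * (1.5 * u - 0.5 * u**3)
    elif model.kind == "exponential":
        g = c0 + c * (1.0 - np.exp(-3.0 * h / a))
    else:  # gaussian
        g = c0 + c * (1.0 - np.exp(-3.0 * h**2 / a**2))
    return np.where(h == 0, 0.0, g)


def empirical_variogram(
    points: PointSamples, lag_width: float, max_lag: float
) -> EmpiricalVariogram:
    """Matheron estimator gamma(h) = sum (Z_i - Z_j)^2 / (2 n(h)) with pairs
    binned by Euclidean separation into ``[k*lag_width, (k+1)*lag_width)``."""
    if len(points) < 2:
        raise GeostatsError("need at least 2 points")
    if lag_width <= 0:
        raise GeostatsError("lag_width must be positive")
    from scipy.spatial.distance import pdist

    d = pdist(points.coords)
    dz2 = pdist(points.value[:, None], metric="sqeuclidean")
    keep = d < max_lag
    if not np.any(keep):
        raise EmptyVariogramError("no point pairs within max_lag")
    d = d[keep]
    dz2 = dz2[keep]
    bins = np.floor(d / lag_width).astype(int)
    nbins = bins.max() + 1
    counts = np.bincount(bins, minlength=nbins).astype(float)
    sums = np.bincount(bins, weights=dz2, minlength=nbins)
    nonempty = counts > 0
    centers = (np.arange(nbins) + 0.5) * lag_width
    gamma = np.zeros(nbins)
    gamma[nonempty] = sums[nonempty] / (2.0 * counts[nonempty])
    return EmpiricalVariogram(
        lag_centers=centers[nonempty],
        gamma=gamma[nonempty],
        pair_counts=counts[nonempty],
    )


def fit_variogram(
    emp: EmpiricalVariogram,
    kinds: tuple[str, ...] = VARIOGRAM_KINDS,
) -> list[VariogramModel]:
    """Fit each requested model kind by pair-count-weighted least squares and
    return models ranked by fit R^2 (ties broken by lower RSS)."""
    from scipy.optimize import least_squares

    h = emp.lag_centers
    g = emp.gamma
    w = np.sqrt(emp.pair_counts.astype(float))
    if len(h) < 4:
        raise GeostatsError("need at least 4 non-empty lag bins to fit")

    max_lag = float(h[-1])
    gvar = float(np.average(g, weights=emp.pair_counts))
    degenerate = np.allclose(g, g[0])
    models: list[VariogramModel] = []
    for kind in kinds:
        def resid(p: np.ndarray, kind: str = kind) -> np.ndarray:
            m = VariogramModel(kind, max(p[0], 0.0), max(p[1], 0.0), p[2])
            return w * (variogram_model_value(m, h) - g)

        best = None
        for a0 in (max_lag / 4, max_lag / 2, max_lag):
            try:
                sol = least_squares(
                    resid,
                    x0=[0.0, max(gvar, 1e-12), a0],
                    bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, 2 * max_lag]),
                )
            except Exception:  # pragma: no cover - optimizer failure path
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            log.warning("variogram fit failed for kind %s; skipped", kind)
            continue
        c0, c, a = best.x
        m = VariogramModel(kind, max(c0, 0.0), max(c, 0.0), a)
        res = w * (variogram_model_value(m, h) - g)
        rss = float(np.sum(res**2))
        tss = float(np.sum((w * (g - np.average(g, weights=w**2))) ** 2))
        if tss <= 0:
            r2, flag = 0.0, True
        else:
            r2, flag = 1.0 - rss / tss, degenerate
        m.fit_r2 = r2
        m.fit_rss = rss
        m.degenerate = flag
        models.append(m)
    models.sort(key=lambda m: (-m.fit_r2, m.fit_rss))
    return models


# ---------------------------------------------------------------------------
# kriging / simulation
# ---------------------------------------------------------------------------


def _sk_solve(
    model: VariogramModel,
    neigh_xy: np.ndarray,
    neigh_val: np.ndarray,
    node_xy: np.ndarray,
) -> tuple[float, float]:
    """Solve one simple-kriging system (known mean 0 in transformed space)."""
    diff = neigh_xy[:, None, :] - neigh_xy[None, :, :]
    dmat = np.sqrt((diff**2).sum(-1))
    K = model.covariance(dmat)
    d0 = np.sqrt(((neigh_xy - node_xy) ** 2).sum(-1))
    k = model.covariance(d0)
    try:
        lam = np.linalg.solve(K, k)
    except np.linalg.LinAlgError:
        K = K + np.eye(len(K)) * 1e-10 * model.sill
        log.debug("singular SK system jittered")
        lam = np.linalg.solve(K, k)
    est = float(lam @ neigh_val)
    var = float(model.sill - lam @ k)
    return est, max(var, 0.0)


def simple_kriging(
    data: PointSamples,
    model: VariogramModel,
    grid,
    neighbors: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Simple kriging of ``data`` (assumed mean-0 transformed values) onto
    every pixel center of ``grid``. Returns (estimate, kriging variance)."""
    if neighbors < 1:
        raise GeostatsError("neighbors must be >= 1")
    k = min(neighbors, len(data))
    tree = cKDTree(data.coords)
    gx, gy = grid.pixel_centers()
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    _, idx = tree.query(nodes, k=k)
    idx = np.atleast_2d(idx.T).T  # k=1 -> (n,1)
    est = np.empty(len(nodes))
    var = np.empty(len(nodes))
    for i, node in enumerate(nodes):
        ni = idx[i]
        est[i], var[i] = _sk_solve(model, data.coords[ni], data.value[ni], node)
    return est.reshape(grid.shape), var.reshape(grid.shape)


@dataclass
class SGCSEnsemble:
    """Stack of equiprobable simulated surfaces plus summary grids."""

    realizations: np.ndarray  # (n_realizations, rows, cols)
    mean_surface: np.ndarray
    pixel_cv: np.ndarray
    n_realizations: int
    seed: int

    @classmethod
    def from_stack(cls, stack: np.ndarray, seed: int) -> "SGCSEnsemble":
        n = stack.shape[0]
        mean = stack.mean(axis=0)
        if n > 1:
            sd = stack.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv = np.where(np.abs(mean) > 0, sd / np.abs(mean), np.nan)
        else:
            cv = np.full(mean.shape, np.nan)  # undefined for one realization
        return cls(stack, mean, cv, n, seed)


def _simulate_one(
    data_xy: np.ndarray,
    data_scores: np.ndarray,
    model: VariogramModel,
    grid,
    neighbors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    rows, cols = grid.shape
    n_nodes = rows * cols
    gx, gy = grid.pixel_centers()
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    sim = np.full(n_nodes, np.nan)
    # relocate data to their pixels: collocated nodes take the (averaged)
    # datum score exactly so conditioning is honored bit-for-bit
    r, c = grid.point_to_rc(data_xy[:, 0], data_xy[:, 1])
    inside = (r >= 0) & (r < rows) & (c >= 0) & (c < cols)
    flat = r[inside] * cols + c[inside]
    sums = np.bincount(flat, weights=data_scores[inside], minlength=n_nodes)
    cnts = np.bincount(flat, minlength=n_nodes)
    occupied = cnts > 0
    sim[occupied] = sums[occupied] / cnts[occupied]

    # known points: conditioning data first, simulated nodes appended
    n_data = len(data_xy)
    known_xy = np.empty((n_data + n_nodes, 2))
    known_val = np.empty(n_data + n_nodes)
    known_xy[:n_data] = data_xy
    known_val[:n_data] = data_scores
    n_known = n_data

    todo = np.flatnonzero(~occupied)
    path = rng.permutation(todo)
    # neighbor search: kd-tree over the bulk, rebuilt periodically, plus a
    # brute-force sweep over points inserted since the last rebuild
    rebuild_every = 256
    tree = cKDTree(known_xy[:n_known])
    n_tree = n_known
    for node_idx in path:
        node = nodes[node_idx]
        m = min(neighbors, n_known)
        k_tree = min(m, n_tree)
        dt, it = tree.query(node, k=k_tree)
        dt = np.atleast_1d(dt)
        it = np.atleast_1d(it)
        if n_known > n_tree:
            recent = np.arange(n_tree, n_known)
            dr = np.sqrt(((known_xy[recent] - node) ** 2).sum(1))
            d_all = np.concatenate([dt, dr])
            i_all = np.concatenate([it, recent])
            order = np.argsort(d_all)[:m]
            ni = i_all[order]
        else:
            ni = it[:m]
        est, var = _sk_solve(model, known_xy[ni], known_val[ni], node)
        value = est + np.sqrt(var) * rng.standard_normal()
        sim[node_idx] = value
        known_xy[n_known] = node
        known_val[n_known] = value
        n_known += 1
        if n_known - n_tree >= rebuild_every:
            tree = cKDTree(known_xy[:n_known])
            n_tree = n_known
    return sim.reshape(rows, cols)


def sgcs(
    data: PointSamples,
    model: VariogramModel,
    grid,
    n_realizations: int,
    neighbors: int = 16,
    seed: int = 0,
    transform: bool = True,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> SGCSEnsemble:
    """Sequential Gaussian conditional simulation.

    Each realization visits the unknown grid nodes on a seeded random path,
    simple-krigs from the nearest conditioning values (data plus previously
    simulated nodes), draws from Normal(SK mean, SK variance) and finally
    back-transforms through the inverse normal-score map. With
    ``transform=False`` the data are taken to be normal scores already and
    realizations stay in score space.

    ``model`` must describe the variogram of the (normal-score) transformed
    data; per-realization seeds are spawned from ``seed`` so individual
    realizations are reproducible.
    """
    if n_realizations < 1:
        raise GeostatsError("n_realizations must be >= 1")
    n_nodes = grid.rows * grid.cols
    if n_realizations * n_nodes > node_budget:
        raise BudgetExceededError(
            f"{n_realizations} realizations x {n_nodes} nodes exceeds the "
            f"node budget ({node_budget}); use a smaller grid or fewer "
            "realizations"
        )
    if transform:
        nsmap = NormalScoreMap.fit(data.value)
        scores = nsmap.forward(data.value)
    else:
        nsmap = None
        scores = data.value

    seeds = np.random.SeedSequence(seed).spawn(n_realizations)
    stack = np.empty((n_realizations, grid.rows, grid.cols))
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        real = _simulate_one(data.coords, scores, model, grid, neighbors, rng)
        if nsmap is not None:
            real = nsmap.inverse(real)
        stack[i] = real
    return SGCSEnsemble.from_stack(stack, seed=seed)


def choose_realization_count(
    data: PointSamples,
    model: VariogramModel,
    grid,
    counts: tuple[int, ...] = (1, 10, 25, 50, 75, 100),
    neighbors: int = 16,
    seed: int = 0,
    transform: bool = True,
    rel_change: float = 0.05,
) -> tuple[int, dict[int, float], SGCSEnsemble]:
    """Sweep ensemble sizes and pick the smallest count at which the mean
    pixel coefficient of variation has stabilized (< ``rel_change`` relative
    change from the previous count).

    The full ensemble at ``max(counts)`` is simulated once and prefixes are
    reused, so the sweep costs one simulation run.
    """
    counts = tuple(counts)
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise GeostatsError("counts must be strictly ascending")
    full = sgcs(
        data, model, grid, n_realizations=counts[-1], neighbors=neighbors,
        seed=seed, transform=transform,
    )
    curve: dict[int, float] = {}
    for n in counts:
        sub = SGCSEnsemble.from_stack(full.realizations[:n], seed=seed)
        curve[n] = float(np.nanmean(sub.pixel_cv)) if n > 1 else float("nan")
    selected = counts[-1]
    finite = [n for n in counts if np.isfinite(curve[n])]
    for prev, cur in zip(finite[:-1], finite[1:]):
        denom = abs(curve[prev])
        if denom > 0 and abs(curve[cur] - curve[prev]) / denom < rel_change:
            selected = cur
            break
    if len(counts) == 1:
        selected = counts[0]
    return selected, curve, full


def interpolation_fidelity(points: PointSamples, surface: np.ndarray, grid) -> float:
    """R^2 between point values and the surface sampled at the point pixels."""
    if len(points) < 3:
        raise GeostatsError("need at least 3 points")
    r, c = grid.point_to_rc(points.x, points.y)
    inside = (r >= 0) & (r < grid.rows) & (c >= 0) & (c < grid.cols)
    if not np.all(inside):
        raise GeostatsError("points outside grid")
    y = points.value
    yhat = surface[r, c]
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - ss_res / ss_tot
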