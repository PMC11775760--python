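"""Synthetic landscape generator.

Builds a toy scene with fully known ground truth — a spatially
autocorrelated LAI field with a prescribed variogram, terrain, a canopy
that tracks LAI, optical bands with a saturating vegetation response, SAR
backscatter tied to canopy structure, quasi-regular laser footprints,
noisy circular field plots, and labelled photon transects — so every
downstream stage has a parameter-recovery test bed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geostats import VariogramModel, variogram_model_value
from .grid import GridSpec
from .photons import PhotonCloud

OPTICAL_BANDS = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A")
SAR_BANDS = ("VV", "VH")

# soil / dense-leaf endmember reflectances per band; the scene mixes them
# with fraction 1 - exp(-k * LAI), which yields the light-saturation shape
_SOIL = {"B2": 0.09, "B3": 0.11, "B4": 0.24, "B5": 0.25,
         "B6": 0.26, "B7": 0.27, "B8": 0.28, "B8A": 0.29}
_LEAF = {"B2": 0.04, "B3": 0.09, "B4": 0.01, "B5": 0.20,
         "B6": 0.35, "B7": 0.42, "B8": 0.45, "B8A": 0.47}
_MIX_K = 0.5
_CANOPY_HMAX = 22.0  # asymptotic canopy height, m
_CANOPY_K = 0.35


class SceneConfigError(ValueError):
    pass


def _default_variogram() -> VariogramModel:
    return VariogramModel("spherical", nugget=0.05, partial_sill=0.95, range_a=450.0)


@dataclass
class SceneConfig:
    """Everything needed to synthesize one scene deterministically."""

    rows: int = 128
    cols: int = 128
    pixel_size: float = 15.0
    lai_mean: float = 3.0
    lai_sd: float = 1.0
    truth_variogram: VariogramModel = field(default_factory=_default_variogram)
    terrain_relief: float = 40.0
    plot_count: int = 51
    plot_radius: float = 8.5
    track_spacing: float = 300.0
    along_track_step: float = 100.0
    optical_noise_sd: float = 0.01
    sar_noise_sd: float = 0.5
    lidar_noise_sd: float = 0.1
    plot_noise_sd: float = 0.1
    photon_tracks: int = 2
    photon_spacing: float = 0.7
    photon_noise_rate: float = 0.2  # noise photons per along-track metre
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 16 or self.cols < 16:
            raise SceneConfigError("grid must be at least 16 x 16")
        if self.pixel_size <= 0:
            raise SceneConfigError("pixel_size must be positive")
        if self.lai_sd < 0:
            raise SceneConfigError("lai_sd must be >= 0")
        if self.truth_variogram.range_a <= 0:
            raise SceneConfigError("variogram range must be positive")
        if self.truth_variogram.sill < 0:
            raise SceneConfigError("variogram sill must be >= 0")
        extent = min(self.rows, self.cols) * self.pixel_size
        if self.plot_radius >= extent / 2:
            raise SceneConfigError("plot_radius must be well inside the grid extent")
        if self.plot_count < 2:
            raise SceneConfigError("plot_count must be >= 2")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.rows, self.cols, self.pixel_size)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truth_variogram"] = {
            "kind": self.truth_variogram.kind,
            "nugget": self.truth_variogram.nugget,
            "partial_sill": self.truth_variogram.partial_sill,
            "range_a": self.truth_variogram.range_a,
        }
        return d


@dataclass
class SyntheticScene:
    """A generated scene plus its ground truth."""

    config: SceneConfig
    lai_truth: np.ndarray
    terrain: np.ndarray
    canopy_height: np.ndarray
    optical_bands: dict[str, np.ndarray]
    sar_bands: dict[str, np.ndarray]
    footprints: pd.DataFrame
    plots: pd.DataFrame
    photon_transects: list[PhotonCloud]

    @property
    def grid(self) -> GridSpec:
        return self.config.grid


# ---------------------------------------------------------------------------
# random fields
# ---------------------------------------------------------------------------


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _correlated_field(
    rows: int,
    cols: int,
    pixel_size: float,
    model: VariogramModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-structure Gaussian field with the model's correlation function,
    variance = sill, via circulant embedding / spectral synthesis on a
    2x-padded torus (exact up to eigenvalue clipping)."""
    P, Q = 2 * rows, 2 * cols
    ii = np.minimum(np.arange(P), P - np.arange(P)) * pixel_size
    jj = np.minimum(np.arange(Q), Q - np.arange(Q)) * pixel_size
    d = np.hypot(ii[:, None], jj[None, :])
    psill = model.partial_sill
    if psill > 0:
        struct = VariogramModel(model.kind, 0.0, psill, model.range_a)
        cov = psill - variogram_model_value(struct, d)
        lam = np.fft.fft2(cov).real
        lam = np.maximum(lam, 0.0)
        w = rng.standard_normal((P, Q))
        f = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(w)).real
        f = f[:rows, :cols]
    else:
        f = np.zeros((rows, cols))
    if model.nugget > 0:
        f = f + np.sqrt(model.nugget) * rng.standard_normal((rows, cols))
    return f


def generate_gaussian_field(config: SceneConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Unconditional Gaussian random field with the configured variogram,
    rescaled to (lai_mean, lai_sd) and truncated at 0.

    With a degenerate variogram (sill 0) the field is constant ``lai_mean``.
    """
    model = config.truth_variogram
    if model.sill == 0:
        return np.full((config.rows, config.cols), max(config.lai_mean, 0.0))
    rng = rng if rng is not None else _child_rng(config.seed, 0)
    f = _correlated_field(config.rows, config.cols, config.pixel_size, model, rng)
    z = f / np.sqrt(model.sill)
    lai = config.lai_mean + config.lai_sd * z
    return np.maximum(lai, 0.0)


def generate_terrain(config: SceneConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Smooth terrain with total relief ``terrain_relief``."""
    rng = rng if rng is not None else _child_rng(config.seed, 1)
    extent = min(config.rows, config.cols) * config.pixel_size
    model = VariogramModel("gaussian", 0.0, 1.0, 0.6 * extent)
    f = _correlated_field(config.rows, config.cols, config.pixel_size, model, rng)
    lo, hi = f.min(), f.max()
    if hi <= lo:
        return np.full(f.shape, 100.0)
    return 100.0 + config.terrain_relief * (f - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------


def canopy_from_lai(lai: np.ndarray) -> np.ndarray:
    return _CANOPY_HMAX * (1.0 - np.exp(-_CANOPY_K * np.asarray(lai)))


def render_sensors(
    lai_truth: np.ndarray,
    terrain: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Forward-model optical reflectances, SAR backscatter and canopy height.

    Optical bands mix soil and leaf endmembers with vegetation fraction
    ``1 - exp(-0.5 LAI)`` (saturating, so index-LAI correlations flatten at
    high LAI); VV/VH are affine in canopy height plus speckle-like noise;
    canopy height is a saturating monotone function of LAI plus noise.
    """
    if lai_truth.shape != terrain.shape:
        raise SceneConfigError("lai and terrain grids must share geometry")
    rng = rng if rng is not None else _child_rng(config.seed, 2)
    frac = 1.0 - np.exp(-_MIX_K * lai_truth)
    optical: dict[str, np.ndarray] = {}
    for b in OPTICAL_BANDS:
        band = _SOIL[b] + (_LEAF[b] - _SOIL[b]) * frac
        band = band + config.optical_noise_sd * rng.standard_normal(band.shape)
        optical[b] = np.clip(band, 0.0, 1.0)
    canopy = canopy_from_lai(lai_truth)
    canopy = np.maximum(
        canopy + config.lidar_noise_sd * rng.standard_normal(canopy.shape), 0.0
    )
    sar = {
        "VV": -16.0 + 0.30 * canopy + config.sar_noise_sd * rng.standard_normal(canopy.shape),
        "VH": -23.0 + 0.35 * canopy + config.sar_noise_sd * rng.standard_normal(canopy.shape),
    }
    return optical, sar, canopy


def solar_elevation_field(config: SceneConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic smooth low-frequency pseudo solar-elevation surface."""
    rng = _child_rng(config.seed, 3)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    w = config.cols * config.pixel_size
    h = config.rows * config.pixel_size
    return 35.0 + 8.0 * np.sin(2 * np.pi * np.asarray(x) / w + p1) * np.cos(
        2 * np.pi * np.asarray(y) / h + p2
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def track_positions(config: SceneConfig) -> np.ndarray:
    width = config.cols * config.pixel_size
    xs = np.arange(config.track_spacing / 2, width, config.track_spacing)
    return xs


def sample_footprints(
    terrain: np.ndarray,
    canopy: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Footprint attribute table along parallel north-south tracks.

    Rows sit at ``along_track_step`` intervals; terrain/canopy attributes
    carry independent Gaussian sensor noise; solar elevation is a smooth
    low-frequency field sampled at the footprint.
    """
    rng = rng if rng is not None else _child_rng(config.seed, 4)
    grid = config.grid
    xs = track_positions(config)
    if len(xs) == 0:
        raise SceneConfigError("track_spacing larger than grid: no tracks fit")
    ys = np.arange(config.along_track_step / 2, grid.height_m, config.along_track_step)
    X, Y = np.meshgrid(xs, ys)
    x, y = X.ravel(), Y.ravel()
    r, c = grid.point_to_rc(x, y)
    sd = config.lidar_noise_sd
    n = len(x)
    df = pd.DataFrame(
        {
            "x_m": x,
            "y_m": y,
            "h_te_best_fit": terrain[r, c] + sd * rng.standard_normal(n),
            "h_te_interp": terrain[r, c] + sd * rng.standard_normal(n),
            "h_mean_canopy_abs": canopy[r, c] + sd * rng.standard_normal(n),
            "solar_elevation": solar_elevation_field(config, x, y),
        }
    )
    return df


def sample_plots(
    lai_truth: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Circular field plots: truth LAI averaged within the plot radius plus
    Gaussian measurement noise, at locations spread by a minimum-distance
    rejection rule."""
    rng = rng if rng is not None else _child_rng(config.seed, 5)
    grid = config.grid
    margin = config.plot_radius
    min_dist = max(
        4 * config.plot_radius,
        0.5 * np.sqrt(grid.width_m * grid.height_m / config.plot_count),
    )
    xs: list[float] = []
    ys: list[float] = []
    while len(xs) < config.plot_count:
        placed = False
        for _ in range(2000):
            px = rng.uniform(margin, grid.width_m - margin)
            py = rng.uniform(margin, grid.height_m - margin)
            if all((px - a) ** 2 + (py - b) ** 2 >= min_dist**2 for a, b in zip(xs, ys)):
                xs.append(px)
                ys.append(py)
                placed = True
                break
        if not placed:  # relax spacing rather than fail on crowded grids
            min_dist *= 0.8
    gx, gy = grid.pixel_centers()
    lai = []
    for px, py in zip(xs, ys):
        within = (gx - px) ** 2 + (gy - py) ** 2 <= config.plot_radius**2
        if within.any():
            val = lai_truth[within].mean()
        else:  # plot smaller than a pixel: fall back to the owning pixel
            r, c = grid.point_to_rc(px, py)
            val = lai_truth[int(r), int(c)]
        lai.append(val)
    lai = np.asarray(lai) + config.plot_noise_sd * rng.standard_normal(len(xs))
    return pd.DataFrame(
        {
            "plot_id": np.arange(1, config.plot_count + 1),
            "x_m": xs,
            "y_m": ys,
            "lai": np.maximum(lai, 1e-6),
        }
    )


# ---------------------------------------------------------------------------
# photon transects
# ---------------------------------------------------------------------------


def sample_photon_transect(
    terrain_profile,
    canopy_profile,
    length: float,
    config: SceneConfig,
    rng: np.random.Generator,
) -> PhotonCloud:
    """One labelled 2-D photon transect over callable terrain/canopy profiles."""
    step = config.photon_spacing
    t = np.arange(0.0, length, step)
    ground_t = t[rng.random(len(t)) < 0.7]
    ground_z = terrain_profile(ground_t) + 0.1 * rng.standard_normal(len(ground_t))
    ct = t[rng.random(len(t)) < 0.5]
    ch = canopy_profile(ct)
    keep = ch > 2.0
    ct, ch = ct[keep], ch[keep]
    canopy_z = terrain_profile(ct) + ch * rng.uniform(0.4, 1.0, len(ct))
    n_noise = rng.poisson(config.photon_noise_rate * length)
    nt = rng.uniform(0, length, n_noise)
    base = terrain_profile(nt)
    nz = base + rng.uniform(-20.0, 40.0, n_noise)
    along = np.concatenate([ground_t, ct, nt])
    elev = np.concatenate([ground_z, canopy_z, nz])
    labels = np.concatenate(
        [
            np.full(len(ground_t), "ground", dtype="<U12"),
            np.full(len(ct), "canopy", dtype="<U12"),
            np.full(len(nt), "noise", dtype="<U12"),
        ]
    )
    return PhotonCloud(along, elev, true_label=labels)


def sample_photon_transects(
    terrain: np.ndarray,
    canopy: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
) -> list[PhotonCloud]:
    rng = rng if rng is not None else _child_rng(config.seed, 6)
    grid = config.grid
    xs = track_positions(config)[: config.photon_tracks]
    length = grid.height_m
    yy = (np.arange(grid.rows) + 0.5) * grid.pixel_size
    clouds = []
    for x in xs:
        col = int(np.clip(x // grid.pixel_size, 0, grid.cols - 1))
        tprof = lambda q, col=col: np.interp(q, yy, terrain[:, col])
        cprof = lambda q, col=col: np.interp(q, yy, canopy[:, col])
        clouds.append(sample_photon_transect(tprof, cprof, length, config, rng))
    return clouds


# ---------------------------------------------------------------------------
# full scene
# ---------------------------------------------------------------------------


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Deterministically generate the full scene from ``config.seed``."""
    lai = generate_gaussian_field(config, _child_rng(config.seed, 0))
    terrain = generate_terrain(config, _child_rng(config.seed, 1))
    optical, sar, canopy = render_sensors(lai, terrain, config, _child_rng(config.seed, 2))
    footprints = sample_footprints(terrain, canopy, config, _child_rng(config.seed, 4))
    plots = sample_plots(lai, config, _child_rng(config.seed, 5))
    transects = sample_photon_transects(terrain, canopy, config, _child_rng(config.seed, 6))
    return SyntheticScene(
        config=config,
        lai_truth=lai,
        terrain=terrain,
        canopy_height=canopy,
        optical_bands=optical,
        sar_bands=sar,
        footprints=footprints,
        plots=plots,
        photon_transects=transects,
    )
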