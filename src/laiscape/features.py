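"""Raster feature engineering: resampling, GLCM textures, vegetation
indices, and plot-level feature extraction."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec

log = logging.getLogger(__name__)

TEXTURE_NAMES = (
    "Mean",
    "Variance",
    "Homogeneity",
    "Contrast",
    "Dissimilarity",
    "Entropy",
    "SecondMoment",
    "Correlation",
)

INDEX_NAMES = (
    "NDVI", "DVI", "SAVI", "OSAVI", "EVI", "EVI2",
    "RVI", "MSAVI", "GNDVI", "GRVI", "RDVI", "IDVI",
)


class MissingBandError(KeyError):
    pass


@dataclass
class RasterStack:
    """Named co-registered bands on one grid."""

    bands: dict[str, np.ndarray]
    grid: GridSpec
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError("all bands must share one shape")
        if shapes and shapes.pop() != self.grid.shape:
            raise ValueError("band shape does not match grid")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError as e:
            raise MissingBandError(f"band {name!r} not in stack") from e

    def __contains__(self, name: str) -> bool:
        return name in self.bands

    def names(self) -> list[str]:
        return list(self.bands)


@dataclass
class GLCMSpec:
    """Gray-level co-occurrence configuration: 5x5 window, unit step,
    64 gray levels, four orientations averaged, symmetric counting."""

    window: int = 5
    displacement: int = 1
    levels: int = 64
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be odd and positive")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.displacement < 1:
            raise ValueError("displacement must be >= 1")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample_to_grid(
    stack: RasterStack,
    target_pixel: float = 15.0,
    temporal: dict[str, list[np.ndarray]] | None = None,
) -> RasterStack:
    """Reduce temporal stacks by pixelwise median, then resample spatially by
    cubic convolution to ``target_pixel`` resolution."""
    if target_pixel <= 0:
        raise ValueError("target_pixel must be positive")
    src = stack.grid
    if target_pixel >= min(src.width_m, src.height_m):
        raise ValueError("target pixel coarser than the full extent")
    bands = dict(stack.bands)
    if temporal:
        for name, series in temporal.items():
            bands[name] = np.median(np.stack(series), axis=0)
    factor = src.pixel_size / target_pixel
    out_rows = max(int(round(src.rows * factor)), 1)
    out_cols = max(int(round(src.cols * factor)), 1)
    out = {}
    for name, band in bands.items():
        out[name] = ndimage.zoom(
            band, (out_rows / band.shape[0], out_cols / band.shape[1]),
            order=3, mode="reflect", grid_mode=True,
        )
    grid = GridSpec(out_rows, out_cols, target_pixel, src.x0, src.y0)
    return RasterStack(out, grid, stack.nodata)


def pixel_plot_area_mismatch(pixel_size: float = 15.0, plot_area_m2: float = 226.865) -> float:
    """Relative mismatch (%) between the resampled pixel footprint area and
    the circular field-plot area."""
    pixel_area = pixel_size * pixel_size
    return abs(plot_area_m2 - pixel_area) / plot_area_m2 * 100.0


# ---------------------------------------------------------------------------
# GLCM textures
# ---------------------------------------------------------------------------


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Global min-max quantization to ``levels`` gray levels."""
    band = np.asarray(band, dtype=float)
    lo, hi = band.min(), band.max()
    if hi <= lo:
        return np.zeros(band.shape, dtype=np.int64)
    q = np.floor((band - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _orientation_offset(angle: float, d: int) -> tuple[int, int]:
    # (row, col) offset of the co-occurring pixel; 0 deg = east,
    # angles counted counter-clockwise as usual for GLCMs
    a = angle % 180.0
    if a == 0.0:
        return (0, d)
    if a == 45.0:
        return (-d, d)
    if a == 90.0:
        return (-d, 0)
    if a == 135.0:
        return (-d, -d)
    raise ValueError(f"unsupported orientation {angle}")


def glcm_features_from_counts(
    codes: np.ndarray, counts: np.ndarray, levels: int
) -> dict[str, float]:
    """The eight texture statistics from sparse co-occurrence counts.

    ``codes`` are flattened pair codes ``i * levels + j`` with ``counts``
    occurrences; counts are normalized to probabilities F(i, j) first.
    Entropy uses the natural log with 0 ln 0 = 0; correlation on a
    zero-variance matrix is defined as 0.
    """
    total = counts.sum()
    if total == 0:
        return {name: 0.0 for name in TEXTURE_NAMES}
    p = counts / total
    i = codes // levels
    j = codes % levels
    mean_i = float(np.sum(p * i))
    mean_j = float(np.sum(p * j))
    var_i = float(np.sum(p * (i - mean_i) ** 2))
    var_j = float(np.sum(p * (j - mean_j) ** 2))
    diff = i - j
    feats = {
        "Mean": mean_i,
        "Variance": var_i,
        "Homogeneity": float(np.sum(p / (1.0 + diff**2))),
        "Contrast": float(np.sum(p * diff**2)),
        "Dissimilarity": float(np.sum(p * np.abs(diff))),
        "Entropy": float(np.sum(p * -np.log(p))),
        "SecondMoment": float(np.sum(p**2)),
    }
    if var_i > 0 and var_j > 0:
        feats["Correlation"] = float(
            np.sum(p * (i - mean_i) * (j - mean_j)) / np.sqrt(var_i * var_j)
        )
    else:
        feats["Correlation"] = 0.0  # zero-variance window: flagged value
    return feats


def cooccurrence_counts(
    q: np.ndarray,
    levels: int,
    orientations: tuple[float, ...] = (0.0,),
    displacement: int = 1,
    symmetric: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse co-occurrence counts (pair codes ``i*levels+j``) of a whole
    quantized matrix, pooled over orientations."""
    q = np.asarray(q, dtype=np.int64)
    allcodes = []
    for ang in orientations:
        dr, dc = _orientation_offset(ang, displacement)
        H, W = q.shape
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        allcodes.append(a * levels + b)
        if symmetric:
            allcodes.append(b * levels + a)
    codes = np.concatenate(allcodes) if allcodes else np.array([], dtype=np.int64)
    return np.unique(codes, return_counts=True)


def glcm_textures(band: np.ndarray, spec: GLCMSpec | None = None) -> dict[str, np.ndarray]:
    """Eight sliding-window GLCM texture grids for one band.

    The band is quantized globally, reflect-padded, and for every window the
    symmetric co-occurrence counts at ``displacement`` are accumulated over
    all orientations (orientation matrices averaged by pooling counts),
    normalized to probabilities, and reduced to the texture statistics.
    """
    spec = spec or GLCMSpec()
    band = np.asarray(band, dtype=float)
    if not np.all(np.isfinite(band)):
        raise ValueError("band contains non-finite values")
    rows, cols = band.shape
    half = spec.window // 2
    q = quantize(band, spec.levels)
    qp = np.pad(q, half, mode="reflect")
    w = spec.window
    d = spec.displacement
    L = spec.levels

    # per-orientation pair-code maps over the padded image
    pair_maps = []
    for ang in spec.orientations:
        dr, dc = _orientation_offset(ang, d)
        H, W = qp.shape
        r0 = max(0, -dr)
        r1 = min(H, H - dr)
        c0 = max(0, -dc)
        c1 = min(W, W - dc)
        a = qp[r0:r1, c0:c1]
        b = qp[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        codes = a * L + b
        if spec.symmetric:
            codes = np.stack([codes, b * L + a])
        else:
            codes = codes[None]
        pair_maps.append((codes, (r0, c0), (dr, dc)))

    out = {name: np.empty((rows, cols)) for name in TEXTURE_NAMES}
    for rr in range(rows):
        for cc in range(cols):
            # window in padded coords: rows rr..rr+w-1, cols cc..cc+w-1
            win_codes = []
            for codes, (r0, c0), (dr, dc) in pair_maps:
                # both pixels of a pair must fall inside the window
                ra = max(rr, r0, rr - dr) - r0
                rb = min(rr + w, rr + w - dr) - r0
                ca = max(cc, c0, cc - dc) - c0
                cb = min(cc + w, cc + w - dc) - c0
                ra = max(ra, 0)
                ca = max(ca, 0)
                if rb > ra and cb > ca:
                    win_codes.append(codes[:, ra:rb, ca:cb].ravel())
            if win_codes:
                allc = np.concatenate(win_codes)
                codes_u, counts = np.unique(allc, return_counts=True)
            else:
                codes_u = np.array([], dtype=np.int64)
                counts = np.array([], dtype=np.int64)
            feats = glcm_features_from_counts(codes_u, counts, L)
            for name in TEXTURE_NAMES:
                out[name][rr, cc] = feats[name]
    return out


def texture_stack(
    stack: RasterStack, bands: tuple[str, ...] = ("VV", "VH"), spec: GLCMSpec | None = None
) -> RasterStack:
    """Texture layers named ``<band>_<Feature>`` for the requested bands."""
    layers = {}
    for b in bands:
        tex = glcm_textures(stack[b], spec)
        for name, gridvals in tex.items():
            layers[f"{b}_{name}"] = gridvals
    return RasterStack(layers, stack.grid, stack.nodata)


# ---------------------------------------------------------------------------
# vegetation indices
# ---------------------------------------------------------------------------


def vegetation_indices(
    stack: RasterStack, savi_l: float = 0.5, conventional_rdvi: bool = False
) -> dict[str, np.ndarray]:
    """The twelve index grids computed from B2/B3/B4/B8.

    Formulas follow the published table verbatim, which prints RDVI
    identical to NDVI and IDVI identical to GNDVI; pass
    ``conventional_rdvi=True`` for the square-root-denominator RDVI instead.
    Zero denominators become NaN (nodata).
    """
    for b in ("B2", "B3", "B4", "B8"):
        if b not in stack:
            raise MissingBandError(f"vegetation_indices requires band {b!r}")
    b2, b3, b4, b8 = (np.asarray(stack[b], dtype=float) for b in ("B2", "B3", "B4", "B8"))

    def safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num / den
        return np.where(den == 0, np.nan, out)

    ndvi = safe_div(b8 - b4, b8 + b4)
    gndvi = safe_div(b8 - b3, b8 + b3)
    with np.errstate(invalid="ignore"):
        msavi = (2 * b8 + 1 - np.sqrt((2 * b8 + 1) ** 2 - 8 * (b8 - b4))) / 2
    idx = {
        "NDVI": ndvi,
        "DVI": b8 - b4,
        "SAVI": safe_div((b8 - b4) * (1 + savi_l), b8 + b4 + savi_l),
        "OSAVI": safe_div(b8 - b4, b8 + b4 + 0.16),
        "EVI": safe_div(2.5 * (b8 - b4), b8 + 6 * b4 - 7.5 * b2 + 1),
        "EVI2": safe_div(2.5 * (b8 - b4), b8 + b4 + 1),
        "RVI": safe_div(b8, b4),
        "MSAVI": msavi,
        "GNDVI": gndvi,
        "GRVI": safe_div(b3, b4),
        "RDVI": safe_div(b8 - b4, np.sqrt(b8 + b4)) if conventional_rdvi else ndvi.copy(),
        "IDVI": gndvi.copy(),
    }
    return idx


def index_stack(stack: RasterStack, savi_l: float = 0.5) -> RasterStack:
    return RasterStack(vegetation_indices(stack, savi_l), stack.grid, stack.nodata)


# ---------------------------------------------------------------------------
# plot-level extraction
# ---------------------------------------------------------------------------


def merge_stacks(*stacks: RasterStack) -> RasterStack:
    grid = stacks[0].grid
    bands: dict[str, np.ndarray] = {}
    for s in stacks:
        if s.grid != grid:
            raise ValueError("stacks must share one grid")
        for name, b in s.bands.items():
            if name in bands:
                raise ValueError(f"duplicate layer name {name!r}")
            bands[name] = b
    return RasterStack(bands, grid)


def extract_at_points(
    stack: RasterStack,
    points: pd.DataFrame,
    target_column: str = "lai",
    id_column: str = "plot_id",
) -> pd.DataFrame:
    """Sample every layer at the pixel containing each point center.

    Rows falling outside the raster extent or hitting any NaN layer value
    are dropped (with a log entry). The result is the model feature table:
    one row per surviving point, the target column first.
    """
    grid = stack.grid
    x = points["x_m"].to_numpy(dtype=float)
    y = points["y_m"].to_numpy(dtype=float)
    inside = grid.contains(x, y)
    if not inside.all():
        log.warning("extract_at_points: %d point(s) outside extent dropped", (~inside).sum())
    pts = points.loc[inside].reset_index(drop=True)
    r, c = grid.point_to_rc(pts["x_m"].to_numpy(), pts["y_m"].to_numpy())
    data = {}
    if id_column in pts:
        data[id_column] = pts[id_column].to_numpy()
    if target_column in pts:
        data[target_column] = pts[target_column].to_numpy(dtype=float)
    for name, band in stack.bands.items():
        data[name] = band[r, c]
    out = pd.DataFrame(data)
    complete = out.notna().all(axis=1)
    if not complete.all():
        log.warning("extract_at_points: %d row(s) with nodata dropped", (~complete).sum())
    out = out.loc[complete].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError("all rows dropped: empty feature table")
    return out
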