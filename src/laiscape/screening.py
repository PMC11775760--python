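"""Pearson significance screening of candidate predictors against measured
LAI, with three nested significance tiers and a modeling-factor selection
policy."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ATLAS_VARIABLES = ("h_te_best_fit", "h_te_interp", "h_mean_canopy_abs", "solar_elevation")
DEFAULT_ALPHAS = (0.01, 0.05, 0.1)


@dataclass
class ScreeningResult:
    """Per-variable correlation, p-value, significance tier and selection."""

    table: pd.DataFrame  # columns: variable, r, p, tier, selected
    n: int
    alphas: tuple[float, ...]

    def tiered(self) -> pd.DataFrame:
        return self.table[self.table["tier"].notna()]


def pearson_p_value(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r via t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def critical_r(n: int, alpha: float) -> float:
    """Smallest |r| significant at ``alpha`` for sample size ``n``."""
    t = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


def pearson_screen(
    features: pd.DataFrame,
    target: str = "lai",
    alphas: tuple[float, ...] = DEFAULT_ALPHAS,
    id_column: str = "plot_id",
) -> ScreeningResult:
    """Correlate every predictor column with the target and assign each the
    smallest significance level it clears (p < alpha); tiers are nested."""
    alphas = tuple(sorted(alphas))
    y = features[target].to_numpy(dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 rows to screen")
    rows = []
    for col in features.columns:
        if col in (target, id_column):
            continue
        x = features[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            log.warning("pearson_screen: column %r non-finite, skipped", col)
            continue
        if np.std(x) == 0:
            rows.append({"variable": col, "r": np.nan, "p": np.nan,
                         "tier": np.nan, "selected": False})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        p = pearson_p_value(r, n)
        tier = next((a for a in alphas if p < a), np.nan)
        rows.append({"variable": col, "r": r, "p": p, "tier": tier,
                     "selected": not np.isnan(tier)})
    return ScreeningResult(pd.DataFrame(rows), n=n, alphas=alphas)


def _duplicate_groups(features: pd.DataFrame, names: list[str]) -> dict[str, str]:
    """Map each variable to the representative of its exact-duplicate group."""
    rep: dict[str, str] = {}
    seen: list[str] = []
    for name in names:
        match = None
        for s in seen:
            if np.array_equal(
                features[name].to_numpy(dtype=float), features[s].to_numpy(dtype=float)
            ):
                match = s
                break
        rep[name] = match or name
        if match is None:
            seen.append(name)
    return rep


def select_modeling_factors(
    result: ScreeningResult,
    features: pd.DataFrame | None = None,
    policy: str | list[str] = "group_quota",
    index_names: tuple[str, ...] | None = None,
) -> list[str]:
    """Reduce the screened set to the modeling factors.

    ``policy="group_quota"`` (default) keeps every tiered ATLAS variable, the
    two strongest tiered SAR layers and the two strongest tiered optical
    indices after dropping exact formula-duplicate columns (requires
    ``features`` for duplicate detection). Passing an explicit list of names
    selects exactly those columns.
    """
    from .features import INDEX_NAMES

    if isinstance(policy, (list, tuple)):
        return list(policy)
    index_names = index_names or INDEX_NAMES
    t = result.tiered().copy()
    if t.empty:
        log.warning("select_modeling_factors: no variable cleared any tier")
        return []
    t["abs_r"] = t["r"].abs()
    names = t["variable"].tolist()
    if features is not None:
        rep = _duplicate_groups(features, names)
        t = t[t["variable"].map(lambda v: rep[v] == v)]
    atlas = [v for v in t["variable"] if v in ATLAS_VARIABLES]
    sar = t[t["variable"].str.startswith(("VV", "VH"))]
    optical = t[t["variable"].isin(index_names)]
    selected = list(atlas)
    for group, label in ((sar, "SAR"), (optical, "optical")):
        if group.empty:
            log.warning("select_modeling_factors: no tiered %s variable", label)
            continue
        top = group.sort_values("abs_r", ascending=False)["variable"].head(2)
        selected.extend(top.tolist())
    return selected


def correlation_matrix(features: pd.DataFrame, id_column: str = "plot_id") -> pd.DataFrame:
    cols = [c for c in features.columns if c != id_column]
    return features[cols].corr(method="pearson")
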