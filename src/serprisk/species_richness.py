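"""Stacked species richness from suitability surfaces.

Covariate screening by stepwise variance-inflation-factor (VIF) removal,
presence/background thresholding at maximum sensitivity + specificity
(maxSSS), binarization and stacking into an integer richness layer, and
EA-level zonal aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridLayer, require_same_grid
from .synthetic_landscape import EATable


@dataclass
class RichnessLayer:
    layer: GridLayer
    species_count: int


def _vif_single(x: np.ndarray, others: np.ndarray) -> float:
    """VIF of column x against the remaining columns (with intercept).

    1/(1 - R^2); exact collinearity gives +inf.
    """
    design = np.column_stack([np.ones(len(x)), others])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coef
    sst = float(np.sum((x - x.mean()) ** 2))
    ssr = float(np.sum(resid ** 2))
    if sst == 0.0:
        return np.inf
    r2 = 1.0 - ssr / sst
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def compute_vifs(matrix: pd.DataFrame) -> pd.Series:
    """VIF of every column against all the others."""
    X = matrix.to_numpy(dtype=float)
    vifs = {}
    for j, name in enumerate(matrix.columns):
        others = np.delete(X, j, axis=1)
        if others.shape[1] == 0:
            vifs[name] = 1.0
        else:
            vifs[name] = _vif_single(X[:, j], others)
    return pd.Series(vifs)


def vif_stepwise(matrix: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the single worst-VIF column while it exceeds the
    threshold; returns the surviving column names in input order.

    Constant columns have undefined VIF and are dropped first with a
    warning. Ties on the maximum VIF break toward the earlier column.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to compute VIFs")
    if matrix.shape[1] < 1:
        raise ValueError("need at least 1 column")
    current = matrix.copy()
    for name in list(current.columns):
        if current[name].nunique() <= 1:
            warnings.warn(f"constant column {name!r} removed (VIF undefined)")
            current = current.drop(columns=[name])
    while current.shape[1] > 1:
        vifs = compute_vifs(current)
        worst = vifs.idxmax()
        if vifs[worst] <= threshold:
            break
        current = current.drop(columns=[worst])
    return [c for c in matrix.columns if c in current.columns]


def max_sss_threshold(scores_presence, scores_background) -> float:
    """Smallest candidate threshold maximizing sensitivity + specificity.

    Candidates are the unique pooled scores; presence is predicted when
    score >= threshold (closed interval).
    """
    pres = np.asarray(scores_presence, dtype=float)
    bg = np.asarray(scores_background, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("presence and background scores must be non-empty")
    candidates = np.unique(np.concatenate([pres, bg]))
    best_t, best_sss = None, -np.inf
    for t in candidates:  # ascending, so the first maximizer is smallest
        sens = float(np.mean(pres >= t))
        spec = float(np.mean(bg < t))
        sss = sens + spec
        if sss > best_sss + 1e-12:
            best_t, best_sss = float(t), sss
    return best_t


def species_thresholds(occurrences: pd.DataFrame) -> dict[int, float]:
    """maxSSS threshold per species from an occurrence table with columns
    species / presence / suitability."""
    out = {}
    for s, grp in occurrences.groupby("species"):
        out[int(s)] = max_sss_threshold(
            grp.loc[grp["presence"] == 1, "suitability"],
            grp.loc[grp["presence"] == 0, "suitability"])
    return out


def binarize_and_stack(suitabilities: list[GridLayer],
                       thresholds) -> RichnessLayer:
    """Cell richness = number of species whose suitability >= threshold.

    ``thresholds`` is a sequence or dict indexed by species position.
    Nodata in any layer propagates to the richness layer.
    """
    if isinstance(thresholds, dict):
        thresholds = [thresholds[s] for s in range(len(suitabilities))]
    if len(thresholds) != len(suitabilities):
        raise ValueError("one threshold per species required")
    require_same_grid(*suitabilities)
    ref = suitabilities[0]
    richness = np.zeros(ref.shape, dtype=float)
    invalid = np.zeros(ref.shape, dtype=bool)
    for layer, t in zip(suitabilities, thresholds):
        invalid |= ~layer.mask()
        richness += (layer.data >= t)
    richness[invalid] = ref.nodata
    return RichnessLayer(layer=ref.copy_with(richness),
                         species_count=len(suitabilities))


def zonal_mean(layer: GridLayer, eas: EATable) -> pd.Series:
    """Mean of valid cells per EA; EAs with no valid cell get NaN."""
    if layer.shape != eas.labels.shape:
        raise ValueError("layer and EA labels must share the grid frame")
    valid = layer.mask()
    if not valid.any():
        raise ValueError("no valid cells overlap any EA")
    labels = eas.labels
    n = eas.n_eas
    sums = np.bincount(labels[valid].ravel(),
                       weights=layer.data[valid].ravel(), minlength=n)
    counts = np.bincount(labels[valid].ravel(), minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=eas.table["ea_id"], name="zonal_mean")
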