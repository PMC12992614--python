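"""Trait design-matrix pipeline.

Builds the standardized predictor matrix used by the dispersal models:
log transforms for body mass and hand-wing index, z-standardization (sample
standard deviation, n-1 denominator), the slow-fast life-history axis as the
first principal component of five life-history traits, variance-inflation
screening and complete-case filtering.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

__all__ = [
    "LIFE_HISTORY_COLUMNS",
    "PREDICTOR_COLUMNS",
    "LifeHistoryAxis",
    "standardize",
    "back_transform",
    "life_history_axis",
    "vif",
    "complete_cases",
    "check_vif",
]

#: the five life-history traits entering the slow-fast axis
LIFE_HISTORY_COLUMNS = [
    "egg_mass",
    "clutch_size",
    "age_first_breeding",
    "broods_per_season",
    "life_span",
]

#: the seven model predictors
PREDICTOR_COLUMNS = [
    "body_mass",
    "hwi",
    "diet",
    "life_history",
    "habitat_openness",
    "breeding_latitude",
    "migration_distance",
]

#: predictors log-transformed before standardization
LOG_COLUMNS = {"body_mass", "hwi"}


@dataclass
class LifeHistoryAxis:
    """First principal component of the five life-history traits.

    Scores increase toward the fast pace-of-life end: the sign is fixed so
    that clutch size loads positively (short-lived, highly fecund species
    score high).
    """

    scores: pd.Series
    loadings: pd.Series
    explained_variance_ratio: float
    sign_flipped: bool = False


def standardize(
    table: pd.DataFrame,
    log_columns=(),
    columns=None,
) -> tuple[pd.DataFrame, dict]:
    """Z-standardize predictor columns, optionally log-transforming first.

    Each requested column is transformed to mean 0 and unit sample variance
    (n-1 denominator).  Returns the transformed table and a transform record
    ``{column: {"log": bool, "mean": m, "sd": s}}`` sufficient for exact
    back-transformation and for applying the same transform to held-out data.

    Raises on nonpositive values in a log column (naming the offending
    species) and on zero-variance columns.
    """
    out = table.copy()
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    log_columns = set(log_columns)
    record: dict[str, dict] = {}
    for c in cols:
        x = out[c].astype(float)
        if c in log_columns:
            bad = x.index[(x <= 0) | x.isna()]
            if (x.dropna() <= 0).any():
                raise ValueError(
                    f"column {c!r}: nonpositive values for species "
                    f"{[str(s) for s in x.index[x <= 0]]}; cannot log-transform"
                )
            x = np.log(x)
        m = x.mean()
        s = x.std(ddof=1)
        if not np.isfinite(s) or s == 0:
            raise ValueError(f"column {c!r} has zero variance; cannot standardize")
        out[c] = (x - m) / s
        record[c] = {"log": c in log_columns, "mean": float(m), "sd": float(s)}
    return out, record


def apply_transform(table: pd.DataFrame, record: dict) -> pd.DataFrame:
    """Apply a stored transform record to new data (no refitting of means/sds)."""
    out = table.copy()
    for c, r in record.items():
        x = out[c].astype(float)
        if r["log"]:
            if (x.dropna() <= 0).any():
                raise ValueError(f"column {c!r}: nonpositive values under stored log transform")
            x = np.log(x)
        out[c] = (x - r["mean"]) / r["sd"]
    return out


def back_transform(table: pd.DataFrame, record: dict) -> pd.DataFrame:
    """Invert :func:`standardize` exactly using its transform record."""
    out = table.copy()
    for c, r in record.items():
        x = out[c] * r["sd"] + r["mean"]
        if r["log"]:
            x = np.exp(x)
        out[c] = x
    return out


def life_history_axis(table: pd.DataFrame) -> LifeHistoryAxis:
    """Slow-fast life-history axis: PC1 of the five life-history traits.

    Traits are standardized internally (PCA on the correlation matrix).  The
    sign convention orients scores so that ``clutch_size`` loads positively,
    making the axis increase toward the fast end of the continuum and the
    output reproducible bit-for-bit.
    """
    missing = [c for c in LIFE_HISTORY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"life-history columns missing from table: {missing}")
    sub = table[LIFE_HISTORY_COLUMNS].astype(float)
    if sub.isna().any().any():
        raise ValueError("life-history columns contain missing values; filter first")
    std, _ = standardize(sub, columns=LIFE_HISTORY_COLUMNS)
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(std.to_numpy())[:, 0]
    loadings = pca.components_[0]
    flipped = False
    clutch = loadings[LIFE_HISTORY_COLUMNS.index("clutch_size")]
    pivot = clutch if clutch != 0 else loadings[np.flatnonzero(loadings)[0]]
    if pivot < 0:
        scores, loadings, flipped = -scores, -loadings, True
    return LifeHistoryAxis(
        scores=pd.Series(scores - scores.mean(), index=table.index, name="life_history"),
        loadings=pd.Series(loadings, index=LIFE_HISTORY_COLUMNS),
        explained_variance_ratio=float(pca.explained_variance_ratio_[0]),
        sign_flipped=flipped,
    )


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R2_j).

    R2_j comes from an ordinary least-squares regression (with intercept) of
    predictor j on all other predictors.  Perfect collinearity is reported as
    ``inf`` rather than raising.
    """
    cols = list(design.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = design.to_numpy(dtype=float)
    n = X.shape[0]
    if n <= len(cols):
        raise ValueError("VIF needs more observations than predictors")
    out = {}
    for j, c in enumerate(cols):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        sst = ((y - y.mean()) ** 2).sum()
        if sst == 0:
            out[c] = np.inf
            continue
        r2 = 1.0 - (resid ** 2).sum() / sst
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else max(1.0, 1.0 / (1.0 - r2))
    return pd.Series(out, name="vif")


def check_vif(design: pd.DataFrame, threshold: float = 5.0, override: bool = False) -> pd.Series:
    """Refuse to proceed when any VIF >= threshold unless ``override`` is set."""
    v = vif(design)
    bad = v[v >= threshold]
    if len(bad) and not override:
        raise ValueError(
            f"variance inflation at or above {threshold} for {list(bad.index)}: "
            f"{bad.round(2).to_dict()}; drop predictors or pass override=True"
        )
    if len(bad):
        log.warning("VIF >= %s for %s (override set)", threshold, list(bad.index))
    return v


def complete_cases(table: pd.DataFrame, required) -> pd.DataFrame:
    """Keep species with no missing values in the required columns."""
    required = [c for c in required]
    before = len(table)
    out = table.dropna(subset=required)
    log.info("complete-case filter on %s: %d -> %d species", required, before, len(out))
    if out.empty:
        raise ValueError("no species left after complete-case filtering")
    return out
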