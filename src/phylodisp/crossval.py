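"""Within-order and between-order cross-prediction of dispersal distances.

Within-order: species of each taxonomic order are split into k folds, the
model refit on k-1 folds (phylogenetic covariance restricted to training
species) and predicted marginally onto the hold-out fold; predictions are
pooled per order before scoring.  Between-order: the model is trained on one
qualifying order at a time and predicted marginally to every other
qualifying order — test species are previously unobserved levels of the
phylogenetic effect, so predictions use its zero mean.

R2 is the squared Pearson correlation between observed and predicted values
(affine-invariant); a residual-based 1 - SSE/SST variant is available via
``r2_method="variance_explained"``.  Standardization statistics for the
predictors are computed on training species only and applied to test
species, so no information leaks across the split.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pglmm import fit_pglmm, predict_conditional, predict_marginal

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "CVResult",
    "within_order_cv",
    "between_order_cv",
    "r2_score",
    "weighted_mean_r2",
    "baseline_models",
]


@dataclass(frozen=True)
class ModelSpec:
    """One cross-validated model: a trait subset, or a baseline.

    kind 'trait' fits predictors with the phylogenetic term; 'phylo_only' is
    an intercept-plus-phylogeny model whose test predictions condition on the
    training species via the BLUP; 'permuted' refits the trait model to a
    seeded permutation of the training response (the random-calibration
    baseline).
    """

    name: str
    predictors: tuple = ()
    kind: str = "trait"

    def __post_init__(self):
        if self.kind not in ("trait", "phylo_only", "permuted"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class CVResult:
    design: str
    records: pd.DataFrame  # unit, model, species, observed, predicted
    unit_r2: pd.DataFrame  # model, unit, r2, n_test
    summary: pd.DataFrame  # model, mean_r2, sd_r2, weighted_mean_r2


def r2_score(observed, predicted, method: str = "correlation") -> float:
    """Predictive R2 between observed and predicted values.

    'correlation' (default): squared Pearson correlation, invariant to
    affine recalibration of the predictions.  'variance_explained':
    1 - SSE/SST, which penalizes calibration bias and can be negative.
    Returns NaN with a warning when either vector is constant.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) < 3:
        raise ValueError("need at least 3 observation/prediction pairs")
    if np.std(obs) == 0 or np.std(pred) == 0:
        warnings.warn("constant observed or predicted vector; R2 undefined",
                      stacklevel=2)
        return np.nan
    if method == "correlation":
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)
    if method == "variance_explained":
        return float(1.0 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2))
    raise ValueError(f"unknown R2 method {method!r}")


def weighted_mean_r2(per_unit_r2, unit_sizes) -> float:
    """Size-weighted mean R2: sum w_u R2_u with w_u = size_u / sum sizes.

    Missing R2 entries are dropped and the weights renormalized (logged).
    """
    r2 = np.asarray(per_unit_r2, dtype=float)
    sizes = np.asarray(unit_sizes, dtype=float)
    if len(r2) != len(sizes):
        raise ValueError("r2 values and unit sizes must align")
    if (sizes <= 0).any():
        raise ValueError("unit sizes must be positive")
    ok = ~np.isnan(r2)
    if not ok.all():
        log.info("dropping %d missing R2 entries; weights renormalized", (~ok).sum())
    if not ok.any():
        return np.nan
    w = sizes[ok] / sizes[ok].sum()
    return float(np.sum(w * r2[ok]))


def baseline_models(predictors) -> list[ModelSpec]:
    """The two reference baselines of the predictive experiments:
    phylogeny-only (conditional BLUP predictions) and a random calibration
    (trait model refit to a permuted training response)."""
    return [
        ModelSpec("phylogeny_only", (), kind="phylo_only"),
        ModelSpec("random", tuple(predictors), kind="permuted"),
    ]


def _standardize_split(X_tr: pd.DataFrame, X_te: pd.DataFrame, cols):
    """Z-score columns on training statistics only (leakage guard)."""
    Xtr, Xte = X_tr.copy(), X_te.copy()
    for c in cols:
        m = Xtr[c].mean()
        s = Xtr[c].std(ddof=1)
        if not np.isfinite(s) or s == 0:
            s = 1.0
        Xtr[c] = (Xtr[c] - m) / s
        Xte[c] = (Xte[c] - m) / s
    return Xtr, Xte


def _fit_and_predict(spec: ModelSpec, y, X, Cm, train, test, rng) -> np.ndarray:
    assert len(np.intersect1d(train, test)) == 0, "train/test overlap"
    yv = np.asarray(y, dtype=float)
    y_tr = yv[train]
    C_tr = Cm[np.ix_(train, train)]
    if spec.kind == "permuted":
        y_tr = rng.permutation(y_tr)
    if spec.kind == "phylo_only" or (spec.kind == "permuted" and not spec.predictors):
        # intercept + phylogenetic effect; permuted variant keeps the same
        # structure so the two baselines differ only in the response
        fit = fit_pglmm(y_tr, pd.DataFrame(index=np.arange(len(train))), C_tr)
        C_cross = Cm[np.ix_(test, train)]
        return predict_conditional(fit, np.ones((len(test), 0)), C_cross)
    cols = list(spec.predictors)
    X_tr, X_te = _standardize_split(X.iloc[train][cols], X.iloc[test][cols], cols)
    fit = fit_pglmm(y_tr, X_tr, C_tr)
    return predict_marginal(fit, X_te)


def _summarize(records: pd.DataFrame, design: str, r2_method: str) -> CVResult:
    unit_rows = []
    for (model, unit), grp in records.groupby(["model", "unit"], sort=True):
        unit_rows.append(
            {
                "model": model,
                "unit": unit,
                "r2": r2_score(grp["observed"], grp["predicted"], method=r2_method),
                "n_test": len(grp),
            }
        )
    unit_r2 = pd.DataFrame(unit_rows)
    summary_rows = []
    for model, grp in unit_r2.groupby("model", sort=True):
        summary_rows.append(
            {
                "model": model,
                "mean_r2": float(grp["r2"].mean()),
                "sd_r2": float(grp["r2"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "weighted_mean_r2": weighted_mean_r2(grp["r2"], grp["n_test"]),
            }
        )
    return CVResult(design, records, unit_r2, pd.DataFrame(summary_rows))


def within_order_cv(
    y: pd.Series,
    X: pd.DataFrame,
    C,
    orders: pd.Series,
    specs,
    k: int = 5,
    seed: int = 0,
    min_order_size: int = 11,
    r2_method: str = "correlation",
) -> CVResult:
    """Within-order k-fold cross-prediction, one model per order per fold.

    Orders smaller than ``min_order_size`` (or than ``k``) are excluded with
    a warning — the same inclusion rule as the between-order design.  Folds
    are drawn with a seeded generator, so results are reproducible
    bit-for-bit; predictions are pooled within each order before scoring.
    """
    from .pglmm import _as_matrix

    Cm = _as_matrix(C)
    yv = np.asarray(y, dtype=float)
    species = np.asarray(y.index)
    ovec = np.asarray(orders.loc[y.index])
    rng = np.random.default_rng(seed)
    rows = []
    for order in pd.unique(ovec):
        members = np.flatnonzero(ovec == order)
        if len(members) < max(k, min_order_size):
            warnings.warn(
                f"order {order!r} has {len(members)} species "
                f"(< max(k={k}, min_order_size={min_order_size})); excluded",
                stacklevel=2,
            )
            continue
        perm = rng.permutation(members)
        folds = [np.sort(perm[j::k]) for j in range(k)]
        for fold_id, test in enumerate(folds):
            train = np.setdiff1d(members, test)
            for spec in specs:
                pred = _fit_and_predict(spec, yv, X, Cm, train, test,
                                        np.random.default_rng(rng.integers(2 ** 31)))
                for s_idx, p_val in zip(test, pred):
                    rows.append(
                        {
                            "unit": order,
                            "fold": fold_id,
                            "model": spec.name,
                            "species": species[s_idx],
                            "observed": yv[s_idx],
                            "predicted": float(p_val),
                        }
                    )
    if not rows:
        raise ValueError(f"no order has at least {k} species")
    return _summarize(pd.DataFrame(rows), "within_order", r2_method)


def between_order_cv(
    y: pd.Series,
    X: pd.DataFrame,
    C,
    orders: pd.Series,
    specs,
    min_order_size: int = 11,
    seed: int = 0,
    r2_method: str = "correlation",
) -> CVResult:
    """Leave-order-out cross-prediction between qualifying orders.

    Each order with at least ``min_order_size`` species is used in turn as
    the sole training set; models are predicted marginally to every other
    qualifying order (a training order never predicts itself).  R2 is scored
    per (train order, test order) pair.
    """
    from .pglmm import _as_matrix

    Cm = _as_matrix(C)
    yv = np.asarray(y, dtype=float)
    species = np.asarray(y.index)
    ovec = np.asarray(orders.loc[y.index])
    sizes = pd.Series(ovec).value_counts()
    qualifying = sorted(sizes.index[sizes >= min_order_size])
    if len(qualifying) < 2:
        raise ValueError(
            f"need at least 2 orders with >= {min_order_size} species; "
            f"found {len(qualifying)}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for train_order in qualifying:
        train = np.flatnonzero(ovec == train_order)
        for test_order in qualifying:
            if test_order == train_order:
                continue
            test = np.flatnonzero(ovec == test_order)
            for spec in specs:
                pred = _fit_and_predict(spec, yv, X, Cm, train, test,
                                        np.random.default_rng(rng.integers(2 ** 31)))
                unit = f"{train_order}->{test_order}"
                for s_idx, p_val in zip(test, pred):
                    rows.append(
                        {
                            "unit": unit,
                            "train_order": train_order,
                            "model": spec.name,
                            "species": species[s_idx],
                            "observed": yv[s_idx],
                            "predicted": float(p_val),
                        }
                    )
    return _summarize(pd.DataFrame(rows), "between_order", r2_method)
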