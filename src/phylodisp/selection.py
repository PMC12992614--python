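"""Projection-predictive variable selection, LOO comparison and stacking.

The reference model is the full PGLMM (all candidate traits plus the
phylogenetic term).  Submodels are evaluated by projecting the reference
fitted values onto subsets of trait columns: the projected coefficients are
the least-squares fit of X beta_ref on the submodel columns, the projected
variance absorbs the mean squared projection deficit, and submodels are
ranked by the Gaussian predictive Kullback-Leibler divergence from the
reference.  Forward selection adds the trait minimizing KL at each step; the
phylogenetic term is delayed to the final step so it cannot soak up trait
variance during the search.  Submodel size is chosen on K-fold expected log
predictive density (ELPD) with a one-standard-error parsimony rule, models
are compared by exact leave-one-out cross-validation, and models within two
standard errors of the best are combined by Bayesian stacking of predictive
densities.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .pglmm import PGLMMFit, fit_pglmm, predict_conditional

__all__ = [
    "SelectionPath",
    "StackedModel",
    "ElpdResult",
    "project_submodel",
    "forward_select",
    "select_size",
    "elpd_loo",
    "stack_models",
    "competitive_models",
]

PHYLO_TERM = "__phylo__"


@dataclass
class SelectionPath:
    """Forward-selection trajectory.

    ``order_added`` lists the candidates in inclusion order with the
    phylogenetic term last; ``kl`` and ``elpd``/``elpd_se`` are indexed by
    submodel size 0..p followed by the final phylogenetic step.  The chosen
    size counts trait predictors only: the final fitted model always carries
    the phylogenetic term, whose delayed entry ends the path.
    """

    candidates: list
    order_added: list
    kl: np.ndarray
    elpd: np.ndarray
    elpd_se: np.ndarray
    chosen_size: int
    folds: int
    seed: int

    @property
    def chosen_subset(self) -> list:
        return self.order_added[: self.chosen_size]

    def as_frame(self) -> pd.DataFrame:
        p = len(self.candidates)
        labels = [str(s) for s in range(p + 1)] + ["phylo"]
        added = ["(intercept)"] + self.order_added
        return pd.DataFrame(
            {"size": labels, "added": added, "kl": self.kl,
             "elpd": self.elpd, "elpd_se": self.elpd_se}
        )


@dataclass
class StackedModel:
    names: list
    weights: np.ndarray
    lpd_matrix: np.ndarray = field(repr=False, default=None)

    @property
    def objective(self) -> float:
        return _stack_objective(self.weights, self.lpd_matrix)


@dataclass
class ElpdResult:
    pointwise: np.ndarray
    elpd: float
    se: float
    n_skipped: int = 0


def _submodel_design(ref: PGLMMFit, subset) -> np.ndarray:
    cols = [c for c in ref.X_.columns if c == "(Intercept)"] + list(subset)
    Xs = ref.X_[cols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        raise ValueError(f"rank-deficient submodel design for subset {list(subset)}")
    return Xs


def project_submodel(ref: PGLMMFit, subset):
    """Project the reference fit onto a trait subset.

    Returns (projected coefficients, projected predictive variance, KL).
    The projected variance is sigma2_ref plus the mean squared deficit of the
    mean projection; KL is the observation-averaged Gaussian predictive KL
    divergence between reference and projection, which reduces to
    0.5 * log(1 + deficit / sigma2_ref).
    """
    subset = list(subset)
    unknown = [c for c in subset if c not in ref.X_.columns]
    if unknown:
        raise ValueError(f"subset contains non-reference predictors {unknown}")
    Xs = _submodel_design(ref, subset)
    mu_ref = ref.fitted.to_numpy()
    beta_s, *_ = np.linalg.lstsq(Xs, mu_ref, rcond=None)
    mu_s = Xs @ beta_s
    dev2 = (mu_ref - mu_s) ** 2
    s2_ref = ref.sigma2_total
    s2_proj = s2_ref + float(dev2.mean())
    kl = float(
        np.mean(0.5 * (np.log(s2_proj / s2_ref) + (s2_ref + dev2) / s2_proj - 1.0))
    )
    names = (["(Intercept)"] if "(Intercept)" in ref.X_.columns else []) + subset
    return pd.Series(beta_s, index=names), s2_proj, max(kl, 0.0)


def _kfold_indices(n: int, k: int, rng: np.random.Generator, orders=None):
    """K folds, stratified by taxonomic order when labels are given."""
    folds = [[] for _ in range(k)]
    if orders is not None:
        orders = np.asarray(orders)
        for o in pd.unique(orders):
            members = np.flatnonzero(orders == o)
            rng.shuffle(members)
            offset = int(rng.integers(k))
            for j, m in enumerate(members):
                folds[(j + offset) % k].append(int(m))
    else:
        perm = rng.permutation(n)
        for j, m in enumerate(perm):
            folds[j % k].append(int(m))
    return [np.array(sorted(f), dtype=int) for f in folds if len(f)]


def forward_select(
    ref: PGLMMFit,
    candidates,
    y,
    X: pd.DataFrame,
    C,
    k: int = 10,
    seed: int = 0,
    orders=None,
    se_rule: float = 1.0,
) -> SelectionPath:
    """Forward projection-predictive selection with delayed phylogenetic term.

    At each step the candidate whose inclusion minimizes KL from the
    reference is added (ties broken by candidate order); the phylogenetic
    term enters only after every trait candidate.  Per-size ELPD comes from
    K-fold cross-validation: the reference is refit on each training fold,
    projected onto the growing subset, and the held-out log predictive
    density scored (marginally for trait-only submodels, conditionally via
    the phylogenetic BLUP at the final step).
    """
    candidates = list(candidates)
    p = len(candidates)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    from .pglmm import _as_matrix

    Cm = _as_matrix(C)

    # --- greedy KL path on the full-data reference -------------------------
    order_added: list = []
    kls = []
    _, _, kl0 = project_submodel(ref, [])
    kls.append(kl0)
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:  # config order breaks ties deterministically
            _, _, kl = project_submodel(ref, order_added + [cand])
            if best is None or kl < best[1] - 1e-15:
                best = (cand, kl)
        order_added.append(best[0])
        kls.append(best[1])
        remaining.remove(best[0])
    kls.append(0.0)  # phylogenetic step: submodel equals the reference

    # --- K-fold ELPD along the path ---------------------------------------
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(n, k, rng, orders=orders)
    pointwise = np.full((p + 2, n), np.nan)
    Xfull = X[candidates]
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        fit_tr = fit_pglmm(yv[train], Xfull.iloc[train], Cm[np.ix_(train, train)])
        for size in range(p + 1):
            subset = order_added[:size]
            beta_s, s2_proj, _ = project_submodel(fit_tr, subset)
            cols = ["(Intercept)"] + subset
            Xte = np.column_stack(
                [np.ones(len(test))] + [Xfull.iloc[test][c].to_numpy() for c in subset]
            )
            mu = Xte @ beta_s.to_numpy()
            pointwise[size, test] = stats.norm.logpdf(yv[test], mu, np.sqrt(s2_proj))
        # final step: trait-complete submodel plus the phylogenetic BLUP
        C_cross = Cm[np.ix_(test, train)]
        mu = predict_conditional(fit_tr, Xfull.iloc[test], C_cross)
        V = fit_tr.sigma2_phylo * Cm[np.ix_(train, train)] + fit_tr.sigma2_resid * np.eye(
            len(train)
        )
        cf = cho_factor(V, lower=True)
        shrink = fit_tr.sigma2_phylo ** 2 * np.einsum(
            "ij,ij->i", C_cross, cho_solve(cf, C_cross.T).T
        )
        var = fit_tr.sigma2_phylo * np.diag(Cm)[test] - shrink + fit_tr.sigma2_resid
        var = np.maximum(var, 1e-12)
        pointwise[p + 1, test] = stats.norm.logpdf(yv[test], mu, np.sqrt(var))

    elpd = pointwise.sum(axis=1)
    se = np.sqrt(n * pointwise.var(axis=1, ddof=1))
    chosen = select_size(elpd[: p + 1], se[: p + 1], se_rule=se_rule)
    return SelectionPath(
        candidates=candidates,
        order_added=order_added + [PHYLO_TERM],
        kl=np.array(kls),
        elpd=elpd,
        elpd_se=se,
        chosen_size=chosen,
        folds=k,
        seed=seed,
    )


def select_size(elpd, elpd_se, se_rule: float = 1.0) -> int:
    """Parsimony rule: smallest size whose ELPD is within ``se_rule``
    standard errors of the best ELPD along the path."""
    elpd = np.asarray(elpd, dtype=float)
    se = np.asarray(elpd_se, dtype=float)
    best = int(np.argmax(elpd))
    threshold = elpd[best] - se_rule * se[best]
    for size in range(len(elpd)):
        if elpd[size] >= threshold:
            return size
    return best


def elpd_loo(y, X, C, predictors=None, progress: bool = False) -> ElpdResult:
    """Exact leave-one-out ELPD for a PGLMM.

    Refits the model n times; each held-out observation is scored under the
    marginal Gaussian predictive (mean x_i' beta, variance s2p + s2e).
    Non-converging refits are skipped with a warning and counted.
    """
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < 10:
        raise ValueError("LOO requires n >= 10")
    from .pglmm import _as_matrix

    Cm = _as_matrix(C)
    Xdf = X[list(predictors)] if predictors is not None else X
    pointwise = np.full(n, np.nan)
    skipped = 0
    for i in range(n):
        keep = np.setdiff1d(np.arange(n), [i])
        try:
            fit = fit_pglmm(yv[keep], Xdf.iloc[keep], Cm[np.ix_(keep, keep)])
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"LOO refit failed for observation {i}: {exc}", stacklevel=2)
            skipped += 1
            continue
        xi = np.concatenate([[1.0], Xdf.iloc[i].to_numpy(dtype=float)])
        mu = float(xi @ fit.beta.to_numpy())
        pointwise[i] = stats.norm.logpdf(yv[i], mu, np.sqrt(fit.sigma2_total))
    ok = ~np.isnan(pointwise)
    vals = pointwise[ok]
    return ElpdResult(
        pointwise=pointwise,
        elpd=float(vals.sum()),
        se=float(np.sqrt(len(vals) * vals.var(ddof=1))),
        n_skipped=skipped,
    )


def _stack_objective(w: np.ndarray, lpd: np.ndarray) -> float:
    m = lpd.max(axis=1, keepdims=True)
    return float(np.sum(np.log((np.exp(lpd - m) @ w)) + m[:, 0]))


def stack_models(lpd_matrix, names=None, tol: float = 1e-9, max_iter: int = 200_000) -> StackedModel:
    """Bayesian stacking weights maximizing the summed log mixture density.

    Solves max_w sum_i log sum_k w_k exp(lpd_ik) over the probability simplex
    by exponentiated-gradient ascent from uniform weights.  The problem is
    convex; identical models keep their (equal) starting weights, which is
    the documented tie rule.
    """
    lpd = np.asarray(lpd_matrix, dtype=float)
    if lpd.ndim != 2:
        raise ValueError("lpd_matrix must be 2-D (observations x models)")
    if not np.isfinite(lpd).all():
        raise ValueError("non-finite pointwise log predictive densities")
    n, kmod = lpd.shape
    if names is None:
        names = [f"model_{j}" for j in range(kmod)]
    if kmod == 1:
        return StackedModel(list(names), np.array([1.0]), lpd)
    m = lpd.max(axis=1, keepdims=True)
    expl = np.exp(lpd - m)
    w = np.full(kmod, 1.0 / kmod)
    eta = 0.5
    obj = _stack_objective(w, lpd)
    for _ in range(max_iter):
        denom = expl @ w
        grad = (expl / denom[:, None]).sum(axis=0) / n
        w_new = w * np.exp(eta * (grad - grad @ w))
        w_new /= w_new.sum()
        obj_new = _stack_objective(w_new, lpd)
        if obj_new < obj - 1e-12:
            eta *= 0.5
            continue
        if abs(obj_new - obj) < tol and np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w, obj = w_new, obj_new
    return StackedModel(list(names), w, lpd)


def competitive_models(loos: dict[str, ElpdResult], se_threshold: float = 2.0) -> list[str]:
    """Names of models whose LOO is within ``se_threshold`` standard errors
    of the best model (pairwise SE of the pointwise differences)."""
    best = max(loos, key=lambda k: loos[k].elpd)
    keep = [best]
    for name, res in loos.items():
        if name == best:
            continue
        diff = loos[best].pointwise - res.pointwise
        ok = ~np.isnan(diff)
        d = diff[ok]
        se_diff = float(np.sqrt(len(d) * d.var(ddof=1)))
        if d.sum() < se_threshold * max(se_diff, 1e-12):
            keep.append(name)
    return keep
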