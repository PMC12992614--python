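"""Gaussian phylogenetic mixed model (PGLMM).

Model
-----
    y = X beta + u + e,   u ~ N(0, sigma2_p * C),   e ~ N(0, sigma2_e * I)

with C a species-level phylogenetic covariance matrix (normally in
correlation form, unit diagonal).  Writing rho = sigma2_p / (sigma2_p +
sigma2_e) and sigma2 = sigma2_p + sigma2_e, the marginal covariance is

    V = sigma2 * W(rho),   W(rho) = rho * C + (1 - rho) * I.

Estimation is by profile maximum likelihood: for fixed rho, beta is the
generalized least-squares solution and sigma2 has a closed form, leaving a
one-dimensional bounded search over rho.  Pagel's lambda is reported in its
variance-ratio form, lambda = sigma2_p / (sigma2_p + sigma2_e) = rho.
Confidence intervals are Wald by default with a parametric-bootstrap option,
and a lightweight random-walk posterior sampler with flat priors is available
for users who want draws.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize_scalar

__all__ = [
    "PGLMMFit",
    "fit_pglmm",
    "loglik",
    "r2_nakagawa",
    "predict_marginal",
    "predict_conditional",
    "parametric_bootstrap_ci",
    "sample_posterior",
]

_Z95 = stats.norm.ppf(0.975)
_RHO_MAX = 1.0 - 1e-9
_GRID = np.linspace(0.0, _RHO_MAX, 21)


@dataclass
class PGLMMFit:
    """Converged PGLMM fit: coefficients, variance components and signal."""

    beta: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    sigma2_phylo: float
    sigma2_resid: float
    lam: float
    loglik: float
    fitted: pd.Series
    r2_marginal: float
    r2_conditional: float
    n: int
    converged: bool
    degenerate: bool
    # training data retained for prediction, projection and LOO
    y_: np.ndarray = field(repr=False, default=None)
    X_: pd.DataFrame = field(repr=False, default=None)
    C_: np.ndarray = field(repr=False, default=None)
    profile_: dict = field(repr=False, default_factory=dict)

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_phylo + self.sigma2_resid

    @property
    def species(self) -> list:
        return list(self.X_.index)

    def summary_dict(self) -> dict:
        return {
            "coefficients": {
                name: {
                    "estimate": float(self.beta[name]),
                    "se": float(self.se[name]),
                    "ci_low": float(self.ci_low[name]),
                    "ci_high": float(self.ci_high[name]),
                }
                for name in self.beta.index
            },
            "sigma2_phylo": float(self.sigma2_phylo),
            "sigma2_resid": float(self.sigma2_resid),
            "lambda": float(self.lam),
            "loglik": float(self.loglik),
            "r2_marginal": float(self.r2_marginal),
            "r2_conditional": float(self.r2_conditional),
            "n": int(self.n),
            "converged": bool(self.converged),
            "degenerate": bool(self.degenerate),
        }


def _as_matrix(C) -> np.ndarray:
    from .trees import PhyloCov

    if isinstance(C, PhyloCov):
        return C.matrix.to_numpy(dtype=float)
    if isinstance(C, pd.DataFrame):
        return C.to_numpy(dtype=float)
    return np.asarray(C, dtype=float)


def _chol(W: np.ndarray):
    """Cholesky with a one-shot 1e-8 diagonal jitter on near-singular input."""
    try:
        return cho_factor(W, lower=True)
    except np.linalg.LinAlgError:
        warnings.warn("near-singular covariance; adding 1e-8 to the diagonal",
                      stacklevel=2)
        return cho_factor(W + 1e-8 * np.eye(W.shape[0]), lower=True)


def gls_solve(y: np.ndarray, X: np.ndarray, W: np.ndarray):
    """Generalized least squares for covariance W (up to a scalar).

    Returns (beta, residual quadratic form r' W^-1 r, log|W|, X' W^-1 X).
    """
    cf = _chol(W)
    Wi_X = cho_solve(cf, X)
    Wi_y = cho_solve(cf, y)
    XtWiX = X.T @ Wi_X
    beta = np.linalg.solve(XtWiX, X.T @ Wi_y)
    r = y - X @ beta
    qform = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return beta, qform, logdet, XtWiX


def _profile(rho: float, y: np.ndarray, X: np.ndarray, C: np.ndarray):
    n = len(y)
    W = rho * C + (1.0 - rho) * np.eye(n)
    beta, qform, logdet, XtWiX = gls_solve(y, X, W)
    s2 = qform / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)
    return ll, beta, s2, XtWiX


def fit_pglmm(
    y,
    X,
    C,
    add_intercept: bool = True,
    ci_level: float = 0.95,
) -> PGLMMFit:
    """Fit the Gaussian PGLMM by profile maximum likelihood.

    Parameters
    ----------
    y : pandas.Series or array
        Response (log dispersal distance), indexed by species.
    X : pandas.DataFrame
        Predictor columns aligned with ``y``.  An intercept column is added
        unless ``add_intercept`` is False.
    C : PhyloCov, DataFrame or array
        Phylogenetic covariance aligned with ``y`` (correlation form
        recommended so that the variance components share a scale).

    Notes
    -----
    The mixing ratio rho is optimized by a coarse grid scan followed by a
    bounded Brent refinement; ties on a flat profile (e.g. C = I, where the
    two variance components are unidentifiable) resolve to the rho = 0
    boundary with a degeneracy flag.
    """
    yv = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        Xdf = X.copy()
    else:
        Xdf = pd.DataFrame(np.asarray(X, dtype=float))
        Xdf.columns = [f"x{j}" for j in range(Xdf.shape[1])]
    if add_intercept and "(Intercept)" not in Xdf.columns:
        Xdf.insert(0, "(Intercept)", 1.0)
    Xv = Xdf.to_numpy(dtype=float)
    Cm = _as_matrix(C)
    n, p = Xv.shape
    if not (len(yv) == n == Cm.shape[0] == Cm.shape[1]):
        raise ValueError("y, X and C must be aligned on the same species")
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    if not np.allclose(Cm, Cm.T, atol=1e-8):
        raise ValueError("C must be symmetric")
    dgn = np.diag(Cm)
    if (dgn <= 0).any():
        raise ValueError("C must have a positive diagonal")
    if not np.allclose(dgn, 1.0, atol=1e-8):
        # scale to correlation form so sigma2_p and sigma2_e share a scale
        # and lambda is the variance ratio regardless of input scaling
        Cm = Cm / np.sqrt(np.outer(dgn, dgn))
    evmin = float(np.linalg.eigvalsh(Cm).min())
    if evmin < -1e-6:
        raise ValueError(f"C is not positive semi-definite (min eigenvalue {evmin:.3g})")

    grid_ll = np.array([_profile(r, yv, Xv, Cm)[0] for r in _GRID])
    degenerate = bool(
        np.allclose(Cm, np.eye(n), atol=1e-10)
        or grid_ll.max() - grid_ll.min() < 1e-10
    )
    if degenerate:
        warnings.warn(
            "variance components unidentifiable (flat profile, C ~ identity); "
            "lambda pinned to 0",
            stacklevel=2,
        )
        rho_hat = 0.0
    else:
        k = int(np.argmax(grid_ll))
        lo = _GRID[max(k - 1, 0)]
        hi = _GRID[min(k + 1, len(_GRID) - 1)]
        res = minimize_scalar(
            lambda r: -_profile(r, yv, Xv, Cm)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        rho_hat = float(res.x)
        # prefer the boundary when it is at least as good (ties -> boundary)
        for b in (0.0, _RHO_MAX):
            if _profile(b, yv, Xv, Cm)[0] >= -res.fun:
                rho_hat = b
        if not res.success:
            raise RuntimeError(
                f"rho search failed to converge; profile trace: "
                f"{dict(zip(np.round(_GRID, 3), np.round(grid_ll, 3)))}"
            )

    ll, beta, s2, XtWiX = _profile(rho_hat, yv, Xv, Cm)
    cov_beta = s2 * np.linalg.inv(XtWiX)
    se = np.sqrt(np.diag(cov_beta))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    fitted = Xv @ beta
    s2p = rho_hat * s2
    s2e = (1.0 - rho_hat) * s2
    idx = Xdf.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    names = list(Xdf.columns)
    fit = PGLMMFit(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        ci_low=pd.Series(beta - z * se, index=names),
        ci_high=pd.Series(beta + z * se, index=names),
        sigma2_phylo=float(s2p),
        sigma2_resid=float(s2e),
        lam=float(rho_hat),
        loglik=float(ll),
        fitted=pd.Series(fitted, index=idx),
        r2_marginal=np.nan,
        r2_conditional=np.nan,
        n=n,
        converged=True,
        degenerate=degenerate,
        y_=yv,
        X_=Xdf,
        C_=Cm,
        profile_={"rho_grid": _GRID.copy(), "loglik_grid": grid_ll},
    )
    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit)
    return fit


def loglik(beta, s2p: float, s2e: float, y, X, C) -> float:
    """Exact multivariate-normal log-density of y at mean X beta,
    covariance s2p * C + s2e * I, via Cholesky factorization."""
    if s2e <= 0 or s2p < 0:
        raise ValueError("require s2e > 0 and s2p >= 0")
    yv = np.asarray(y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    Cm = _as_matrix(C)
    n = len(yv)
    V = s2p * Cm + s2e * np.eye(n)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance matrix V") from exc
    r = yv - Xv @ np.asarray(beta, dtype=float)
    qform = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + qform)


def r2_nakagawa(fit: PGLMMFit) -> tuple[float, float]:
    """Marginal and conditional R2 for the mixed model.

    R2m = var(X beta) / (var(X beta) + s2p + s2e); R2c adds the phylogenetic
    variance to the numerator.  ``var`` is the sample variance of the fitted
    values (zero for an intercept-only model).
    """
    vf = float(np.var(fit.fitted.to_numpy(), ddof=1)) if fit.n > 1 else 0.0
    denom = vf + fit.sigma2_phylo + fit.sigma2_resid
    return vf / denom, (vf + fit.sigma2_phylo) / denom


def _align_design(fit: PGLMMFit, X_new) -> np.ndarray:
    if isinstance(X_new, pd.DataFrame):
        Xn = X_new.copy()
        if "(Intercept)" not in Xn.columns and "(Intercept)" in fit.X_.columns:
            Xn.insert(0, "(Intercept)", 1.0)
        missing = [c for c in fit.X_.columns if c not in Xn.columns]
        if missing:
            raise ValueError(f"X_new is missing fitted columns {missing}")
        return Xn[list(fit.X_.columns)].to_numpy(dtype=float)
    Xn = np.asarray(X_new, dtype=float)
    if Xn.ndim == 1:
        Xn = Xn[None, :]
    if Xn.shape[1] == fit.X_.shape[1] - 1 and "(Intercept)" in fit.X_.columns:
        Xn = np.column_stack([np.ones(len(Xn)), Xn])
    if Xn.shape[1] != fit.X_.shape[1]:
        raise ValueError(
            f"X_new has {Xn.shape[1]} columns, fit expects {fit.X_.shape[1]}"
        )
    return Xn


def predict_marginal(fit: PGLMMFit, X_new) -> np.ndarray:
    """Population-level prediction X_new beta-hat (phylogenetic effect at its
    zero mean) — what the model predicts for previously unobserved species."""
    return _align_design(fit, X_new) @ fit.beta.to_numpy()


def predict_conditional(fit: PGLMMFit, X_new, C_cross) -> np.ndarray:
    """BLUP prediction using phylogenetic covariance with the training set.

    mu = X_new beta + s2p * C_cross V^-1 (y - X beta), with V the training
    marginal covariance.  C_cross rows are new species, columns training
    species (same order as the fit).
    """
    Xn = _align_design(fit, X_new)
    Cc = np.atleast_2d(_as_matrix(C_cross))
    if Cc.shape[1] != fit.n:
        raise ValueError(
            f"C_cross has {Cc.shape[1]} training columns, expected {fit.n}"
        )
    V = fit.sigma2_phylo * fit.C_ + fit.sigma2_resid * np.eye(fit.n)
    cf = _chol(V)
    resid = fit.y_ - fit.X_.to_numpy() @ fit.beta.to_numpy()
    return Xn @ fit.beta.to_numpy() + fit.sigma2_phylo * (Cc @ cho_solve(cf, resid))


def parametric_bootstrap_ci(
    fit: PGLMMFit, replicates: int = 200, seed: int = 0, ci_level: float = 0.95
) -> pd.DataFrame:
    """Percentile bootstrap intervals from data simulated under the fit."""
    rng = np.random.default_rng(seed)
    n = fit.n
    L = cholesky(
        fit.sigma2_phylo * fit.C_ + fit.sigma2_resid * np.eye(n) + 1e-12 * np.eye(n),
        lower=True,
    )
    mu = fit.X_.to_numpy() @ fit.beta.to_numpy()
    draws = np.empty((replicates, len(fit.beta)))
    for b in range(replicates):
        yb = mu + L @ rng.standard_normal(n)
        refit = fit_pglmm(yb, fit.X_, fit.C_, add_intercept=False)
        draws[b] = refit.beta.to_numpy()
    alpha = 1.0 - ci_level
    lo = np.quantile(draws, alpha / 2, axis=0)
    hi = np.quantile(draws, 1 - alpha / 2, axis=0)
    return pd.DataFrame(
        {"estimate": fit.beta, "ci_low": lo, "ci_high": hi}, index=fit.beta.index
    )


def _split_rhat(chains: np.ndarray) -> float:
    # chains: (n_chain, n_iter)
    m, niter = chains.shape
    half = niter // 2
    splits = chains[:, :half], chains[:, half : 2 * half]
    seqs = np.concatenate(splits, axis=0)
    means = seqs.mean(axis=1)
    vars_ = seqs.var(axis=1, ddof=1)
    W = vars_.mean()
    B = half * means.var(ddof=1)
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W)) if W > 0 else np.inf


def sample_posterior(
    y,
    X,
    C,
    chains: int = 4,
    iterations: int = 1000,
    warmup: int = 500,
    seed: int = 0,
    add_intercept: bool = True,
):
    """Random-walk Metropolis sampler for (beta, log sigma2, logit rho) under
    flat priors on the fixed effects.

    Returns (draws DataFrame, diagnostics dict).  Convergence is flagged when
    any split-Rhat exceeds 1.02.  Intended as a cross-check on the profile-ML
    point estimates, not as the primary estimator.
    """
    fit = fit_pglmm(y, X, C, add_intercept=add_intercept)
    rng = np.random.default_rng(seed)
    yv, Xv, Cm = fit.y_, fit.X_.to_numpy(), fit.C_
    p = Xv.shape[1]
    names = list(fit.X_.columns)

    def logpost(theta):
        beta, ls2, lrho = theta[:p], theta[p], theta[p + 1]
        s2 = np.exp(ls2)
        rho = 1.0 / (1.0 + np.exp(-lrho))
        ll = loglik(beta, rho * s2, (1 - rho) * s2, yv, Xv, Cm)
        # Jacobians of the log / logit transforms (flat priors on natural scale)
        return ll + ls2 + np.log(rho * (1 - rho) + 1e-300)

    scale = np.concatenate(
        [fit.se.to_numpy() * 1.5, [0.3, 0.6]]
    )
    start_rho = min(max(fit.lam, 0.02), 0.98)
    start = np.concatenate(
        [fit.beta.to_numpy(), [np.log(fit.sigma2_total), np.log(start_rho / (1 - start_rho))]]
    )
    kept = []
    accept = 0
    total = 0
    for _ in range(chains):
        theta = start + 0.1 * scale * rng.standard_normal(len(start))
        lp = logpost(theta)
        out = np.empty((iterations - warmup, len(start)))
        for it in range(iterations):
            prop = theta + scale * rng.standard_normal(len(start)) * 0.35
            lp_prop = logpost(prop)
            total += 1
            if np.log(rng.uniform()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                accept += 1
            if it >= warmup:
                out[it - warmup] = theta
        kept.append(out)
    draws = np.stack(kept)  # (chains, iter, dim)
    rhats = {}
    colnames = names + ["log_sigma2", "logit_rho"]
    for j, cn in enumerate(colnames):
        rhats[cn] = _split_rhat(draws[:, :, j])
    flat = draws.reshape(-1, draws.shape[-1])
    df = pd.DataFrame(flat, columns=colnames)
    df["sigma2"] = np.exp(df["log_sigma2"])
    df["lambda"] = 1.0 / (1.0 + np.exp(-df["logit_rho"]))
    diag = {
        "rhat": rhats,
        "max_rhat": max(rhats.values()),
        "converged": max(rhats.values()) <= 1.02,
        "acceptance_rate": accept / total,
    }
    return df, diag


def lambda_pi2_compat(fit: PGLMMFit) -> float:
    """Compatibility variant of the signal statistic that substitutes the
    logistic-latent constant pi^2/3 for the residual variance.  Provided for
    comparison with analyses using that convention; the Gaussian variance
    ratio :attr:`PGLMMFit.lam` is the recommended quantity."""
    return fit.sigma2_phylo / (fit.sigma2_phylo + np.pi ** 2 / 3.0)
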