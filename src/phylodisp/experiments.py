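"""Simulation validation studies.

Batteries of seeded experiments that exercise the whole pipeline against
known ground truth: solver oracle checks, parameter-recovery and selection
studies at the reference generative condition, projection/stacking/kernel
identities, and the within- versus between-order transfer experiment.  Each
function returns a flat dict of scalar metrics; the test suite asserts on
them and the reproduction script reports them.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import crossval as cv
from . import kernels as kq
from . import pglmm
from . import selection as sel
from . import trees as ph
from .simulate import DEFAULT_BETA, SimulationConfig, simulate_dataset, simulate_tree

NONZERO_TRAITS = ("body_mass", "life_history", "breeding_latitude")
SYNDROME = NONZERO_TRAITS


def _zero_beta() -> dict:
    return {k: 0.0 for k in DEFAULT_BETA}


def gls_oracle_study(n_instances: int = 50, seed: int = 0) -> dict:
    """Profiled GLS coefficients versus a dense-inverse brute-force solve."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        n = int(rng.integers(8, 21))
        p = int(rng.integers(1, min(4, n - 4)))
        tree, _ = simulate_tree(n, 1, 1.0, seed=seed * 1000 + i)
        C = ph.phylo_vcv(tree, correlation=True).values()
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        y = rng.standard_normal(n)
        rho = float(rng.uniform(0.0, 0.95))
        beta_prof = pglmm._profile(rho, y, X, C)[1]
        W = rho * C + (1 - rho) * np.eye(n)
        Winv = np.linalg.inv(W)
        beta_dense = np.linalg.solve(X.T @ Winv @ X, X.T @ Winv @ y)
        worst = max(worst, float(np.max(np.abs(beta_prof - beta_dense))))
    return {"max_abs_beta_diff": worst, "n_instances": n_instances}


def loglik_collapse_study(n_instances: int = 20, seed: int = 0) -> dict:
    """At mixing ratio zero the PGLMM profile likelihood must equal the
    ordinary linear-model maximum log-likelihood."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        n = int(rng.integers(10, 30))
        tree, _ = simulate_tree(n, 1, 1.0, seed=seed * 500 + i)
        C = ph.phylo_vcv(tree, correlation=True).values()
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        ll0 = pglmm._profile(0.0, y, X, C)[0]
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = float(np.mean((y - X @ beta) ** 2))
        ols_ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
        worst = max(worst, abs(ll0 - ols_ll))
    return {"max_abs_loglik_diff": worst, "n_instances": n_instances}


def parameter_recovery_study(n_seeds: int = 100, seed: int = 0) -> dict:
    """Bias, interval coverage and signal recovery at the reference condition
    (n=200, lambda=0.6, beta=(0.5, -0.4, -0.2, 0, 0, 0, 0), sigma2=1)."""
    truth = dict(DEFAULT_BETA)
    betas, covers, lams = [], [], []
    names = list(truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(n_seeds):
            d = simulate_dataset(SimulationConfig(n=200, seed=seed + s + 1))
            f = pglmm.fit_pglmm(d["response"], d["traits"], d["cov"])
            betas.append([f.beta[k] for k in names])
            covers.append([f.ci_low[k] <= truth[k] <= f.ci_high[k] for k in names])
            lams.append(f.lam)
    betas = np.asarray(betas)
    covers = np.asarray(covers, dtype=float)
    bias = betas.mean(axis=0) - np.array([truth[k] for k in names])
    out = {
        "max_abs_mean_bias": float(np.max(np.abs(bias))),
        "min_coverage": float(covers.mean(axis=0).min()),
        "max_coverage": float(covers.mean(axis=0).max()),
        "lambda_mean": float(np.mean(lams)),
        "n_seeds": n_seeds,
    }
    for k, b in zip(names, bias):
        out[f"bias_{k}"] = float(b)
    return out


def selection_study(n_seeds: int = 100, seed: int = 0, k: int = 10) -> dict:
    """Forward-selection behavior: ranking of the truly informative traits
    and parsimony on pure-noise candidates."""
    top3_hits = 0
    null_zero = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(n_seeds):
            d = simulate_dataset(SimulationConfig(n=200, seed=seed + s + 1))
            ref = pglmm.fit_pglmm(d["response"], d["traits"], d["cov"])
            path = sel.forward_select(ref, list(d["traits"].columns), d["response"],
                                      d["traits"], d["cov"], k=k, seed=seed + s,
                                      orders=d["orders"])
            top3_hits += set(path.order_added[:3]) == set(NONZERO_TRAITS)

            d0 = simulate_dataset(
                SimulationConfig(n=200, seed=seed + s + 20_001, beta=_zero_beta())
            )
            ref0 = pglmm.fit_pglmm(d0["response"], d0["traits"], d0["cov"])
            p0 = sel.forward_select(ref0, list(d0["traits"].columns), d0["response"],
                                    d0["traits"], d0["cov"], k=k, seed=seed + s,
                                    orders=d0["orders"])
            null_zero += p0.chosen_size == 0
    return {
        "top3_rate": top3_hits / n_seeds,
        "null_intercept_rate": null_zero / n_seeds,
        "n_seeds": n_seeds,
    }


def projection_identity_study(n_runs: int = 10, seed: int = 0) -> dict:
    """Self-projection KL and monotonicity of the KL path across fits."""
    max_self_kl = 0.0
    violations = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(n_runs):
            d = simulate_dataset(SimulationConfig(n=100, seed=seed + s + 1))
            ref = pglmm.fit_pglmm(d["response"], d["traits"], d["cov"])
            cols = list(d["traits"].columns)
            _, _, kl_full = sel.project_submodel(ref, cols)
            max_self_kl = max(max_self_kl, kl_full)
            path = sel.forward_select(ref, cols, d["response"], d["traits"],
                                      d["cov"], k=5, seed=s)
            violations += int(np.any(np.diff(path.kl) > 1e-10))
    return {"max_self_kl": max_self_kl, "kl_monotonicity_violations": violations,
            "n_runs": n_runs}


def stacking_study(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    dominant = sel.stack_models(
        np.column_stack([np.full(60, -1.0), np.full(60, -2.5), np.full(60, -3.0)])
    )
    col = rng.normal(-1.2, 0.5, 80)
    tie = sel.stack_models(np.column_stack([col, col]))
    mixed = sel.stack_models(rng.normal(-1.5, 1.0, size=(100, 4)))
    best_single = float(max(mixed.lpd_matrix[:, j].sum() for j in range(4)))
    return {
        "dominant_weight": float(dominant.weights[0]),
        "tie_weight_gap": float(abs(tie.weights[0] - tie.weights[1])),
        "weight_sum_error": float(abs(mixed.weights.sum() - 1.0)),
        "stack_vs_best_single": float(mixed.objective - best_single),
    }


def kernel_study(seed: int = 0) -> dict:
    """CDF inversion on a 99-point grid and the simulation round trip."""
    ps = np.linspace(0.01, 0.99, 99)
    worst = 0.0
    for p in ps:
        qw = kq.weibull_quantile(1.7, 4.2, p)
        worst = max(worst, abs(kq.weibull_cdf(1.7, 4.2, qw) - p))
        qh = kq.halfcauchy_quantile(2.5, p)
        worst = max(worst, abs(kq.halfcauchy_cdf(2.5, qh) - p))
    d = simulate_dataset(SimulationConfig(n=50, seed=seed + 1))
    summary = kq.summarize_kernels(d["kernels"]).loc[d["response"].index]
    rt = float(np.max(np.abs(summary["log_median"].to_numpy() - d["response"].to_numpy())))
    return {"max_cdf_inversion_error": worst, "max_roundtrip_error": rt}


def _transfer_gap(s: int, nuisance_sd: float):
    d = simulate_dataset(SimulationConfig(n=140, seed=s, order_effect_sd=nuisance_sd))
    specs = [cv.ModelSpec("syndrome", SYNDROME)]
    try:
        w = cv.within_order_cv(d["response"], d["traits"], d["cov"], d["orders"],
                               specs, k=5, seed=s)
        b = cv.between_order_cv(d["response"], d["traits"], d["cov"], d["orders"],
                                specs, min_order_size=11, seed=s)
    except ValueError:  # too few qualifying orders under this seed's tree
        return None
    return (float(w.summary["mean_r2"].iloc[0]), float(b.summary["mean_r2"].iloc[0]))


def cv_transfer_study(n_seeds: int = 50, seed: int = 0, nuisance_sd: float = 0.4) -> dict:
    """Within- versus between-order predictive transfer, with and without
    order-level syndrome heterogeneity."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with_n = [_transfer_gap(seed + s + 1, nuisance_sd) for s in range(n_seeds)]
        without = [_transfer_gap(seed + s + 50_001, 0.0) for s in range(n_seeds)]
    with_n = np.array([g for g in with_n if g is not None])
    without = np.array([g for g in without if g is not None])
    gap0 = without[:, 0] - without[:, 1]
    return {
        "nuisance_between_lt_within_rate": float(np.mean(with_n[:, 1] < with_n[:, 0])),
        "nuisance_mean_within_r2": float(with_n[:, 0].mean()),
        "nuisance_mean_between_r2": float(with_n[:, 1].mean()),
        "null_mean_gap": float(gap0.mean()),
        "null_gap_se": float(gap0.std(ddof=1) / np.sqrt(len(gap0))),
        "n_seeds_used": int(len(with_n)),
    }


def _baseline_pair(s: int, lam: float):
    cfg = SimulationConfig(n=120, seed=s, lam=lam, beta=_zero_beta())
    d = simulate_dataset(cfg)
    # structure-matched pair: both are intercept+phylogeny models, differing
    # only in whether the training response is permuted
    specs = [cv.ModelSpec("phylogeny_only", (), "phylo_only"),
             cv.ModelSpec("random", (), "permuted")]
    try:
        w = cv.within_order_cv(d["response"], d["traits"], d["cov"], d["orders"],
                               specs, k=5, seed=s)
    except ValueError:
        return None
    su = w.summary.set_index("model")["mean_r2"]
    return float(su["phylogeny_only"]), float(su["random"])


def baseline_study(n_seeds: int = 30, seed: int = 0) -> dict:
    """Phylogeny-only conditional baseline versus the permuted-response
    baseline at strong (0.9) and absent (0) phylogenetic signal."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hi = [_baseline_pair(seed + s + 1, 0.9) for s in range(n_seeds)]
        lo = [_baseline_pair(seed + s + 30_001, 0.0) for s in range(n_seeds)]
    hi = np.array([g for g in hi if g is not None])
    lo = np.array([g for g in lo if g is not None])
    diff0 = lo[:, 0] - lo[:, 1]
    return {
        "high_lambda_win_rate": float(np.mean(hi[:, 0] > hi[:, 1])),
        "zero_lambda_mean_diff": float(diff0.mean()),
        "zero_lambda_diff_se": float(diff0.std(ddof=1) / np.sqrt(len(diff0))),
        "n_seeds_used": int(len(hi)),
    }
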