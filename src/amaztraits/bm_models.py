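"""Brownian-motion likelihood on a tree and Pagel's λ model comparison.

Under Brownian motion a continuous trait drifts along branches with variance
accruing linearly in time, so the tip values are multivariate normal with
mean μ·1 and covariance σ²C, where C is the phylogenetic covariance from
:func:`amaztraits.phylo_core.vcv_matrix`.  Pagel's λ multiplies the
off-diagonal entries of C: λ = 1 is pure Brownian covariance, λ = 0 is
complete phylogenetic independence.  Phylogenetic signal is assessed by
fitting λ by maximum likelihood and comparing three models by AIC:

* ``ml`` — λ estimated (k = 3 parameters: λ, σ², μ),
* ``fixed_zero`` — λ = 0, no phylogenetic dependence (k = 2),
* ``fixed_one`` — λ = 1, Brownian motion (k = 2).

ΔAIC is reported as AIC(best) − AIC(model): the best model scores 0 and
worse models carry increasingly negative values.

Given λ, the remaining parameters have a closed generalized-least-squares
profile: μ̂ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1) and σ̂² = (x − μ̂1)ᵀC⁻¹(x − μ̂1)/n, so the λ
search is a bounded one-dimensional optimization of the profile likelihood.
Full ML (not REML) constants are retained throughout so AIC values are
comparable across covariance structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .errors import NumericalError
from .phylo_core import Phylogeny, PhyloCovariance, lambda_transform, vcv_matrix

__all__ = [
    "LambdaFit",
    "ModelComparison",
    "bm_loglik",
    "profile_estimates",
    "fit_lambda",
    "compare_models",
]

_MODES = ("fixed_zero", "fixed_one", "ml")
_LAMBDA_XATOL = 1e-8


@dataclass
class LambdaFit:
    """One fitted trait-evolution model: λ, BM rate, root mean, fit scores."""

    lam: float
    sigma2: float
    mu: float
    loglik: float
    aic: float
    k: int
    n: int
    mode: str
    degenerate: bool = False  # constant trait: sigma2 == 0, loglik unbounded


@dataclass
class ModelComparison:
    """The three-model AIC table for one trait (best model ΔAIC = 0)."""

    fits: dict[str, LambdaFit]
    delta_aic: dict[str, float]
    best_mode: str


class ProfileResult(NamedTuple):
    mu: float
    sigma2: float
    loglik: float
    degenerate: bool


def _chol(C: np.ndarray):
    """Cholesky factorization with a single-shot jitter fallback."""
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-10 * float(np.mean(np.diag(C)))
    try:
        return cho_factor(C + jitter * np.eye(C.shape[0]), lower=True)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(C)
        raise NumericalError(
            f"covariance not positive definite after jitter (condition number {cond:.3g})"
        ) from exc


def bm_loglik(x: np.ndarray, C: PhyloCovariance, sigma2: float, mu: float) -> float:
    """Log-likelihood of tip values under BM: MVN(μ·1, σ²C) log-density."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if C.matrix.shape[0] != n:
        raise ValueError("trait vector length does not match covariance dimension")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    cf = _chol(C.matrix)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    r = x - mu
    quad = float(r @ cho_solve(cf, r))
    return -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2) + logdet_C + quad / sigma2)


def profile_estimates(x: np.ndarray, C: PhyloCovariance) -> ProfileResult:
    """Closed-form GLS profile of (μ, σ²) under BM with covariance C.

    μ̂ is the GLS mean, σ̂² the ML (divide-by-n) rate.  A constant trait gives
    σ̂² = 0 with the ``degenerate`` flag set and an undefined log-likelihood.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    cf = _chol(C.matrix)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    mu = float(Ci1 @ x) / float(Ci1 @ ones)
    r = x - mu
    sigma2 = float(r @ cho_solve(cf, r)) / n
    if sigma2 <= 0.0 or not np.isfinite(sigma2):
        return ProfileResult(mu, 0.0, math.nan, True)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    loglik = -0.5 * (n * math.log(2 * math.pi) + n * math.log(sigma2) + logdet_C + n)
    return ProfileResult(mu, sigma2, loglik, False)


def _fit_lambda_cov(C: PhyloCovariance, x: np.ndarray, mode: str) -> LambdaFit:
    n = len(x)
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")

    def profile_at(lam: float) -> ProfileResult:
        return profile_estimates(x, lambda_transform(C, lam))

    if mode == "fixed_zero":
        lam, k = 0.0, 2
        prof = profile_at(lam)
    elif mode == "fixed_one":
        lam, k = 1.0, 2
        prof = profile_at(lam)
    else:
        k = 3
        # the profile can be monotone (maximum on the boundary) or multimodal
        # with narrow interior peaks, so scan a coarse grid first and refine
        # with a bounded scalar search in the bracketing interval
        grid = np.linspace(0.0, 1.0, 21)
        grid_ll = np.array([profile_at(l).loglik for l in grid])
        candidates = [(grid_ll[0], 0.0), (grid_ll[-1], 1.0)]
        if np.any(np.isfinite(grid_ll)):
            best_i = int(np.nanargmax(grid_ll))
            lo = grid[max(best_i - 1, 0)]
            hi = grid[min(best_i + 1, len(grid) - 1)]
            res = minimize_scalar(
                lambda lam: -profile_at(lam).loglik,
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": _LAMBDA_XATOL},
            )
            if np.isfinite(res.fun):
                candidates.append((-res.fun, float(res.x)))
        candidates = [c for c in candidates if np.isfinite(c[0])]
        if not candidates:
            # constant trait: likelihood undefined at every lambda
            prof = profile_at(0.0)
            return LambdaFit(0.0, 0.0, prof.mu, math.nan, math.nan, k, n, mode, True)
        _, lam = max(candidates)
        prof = profile_at(lam)

    aic = 2 * k - 2 * prof.loglik if not prof.degenerate else math.nan
    return LambdaFit(lam, prof.sigma2, prof.mu, prof.loglik, aic, k, n, mode, prof.degenerate)


def fit_lambda(tree: Phylogeny, x: np.ndarray, mode: str = "ml") -> LambdaFit:
    """Fit one λ model to a trait vector aligned with the tree's tip order."""
    x = np.asarray(x, dtype=float)
    if tree.n_tips != len(x):
        raise ValueError("trait vector length must equal the number of tips")
    if len(x) < 3:
        raise ValueError("need at least 3 tips to fit a lambda model")
    return _fit_lambda_cov(vcv_matrix(tree), x, mode)


def compare_models(tree: Phylogeny, x: np.ndarray) -> ModelComparison:
    """Three-model AIC comparison: estimated λ, λ = 0, λ = 1.

    ΔAIC uses AIC(best) − AIC(model): 0 marks the best-supported model and
    worse models take negative values.
    """
    x = np.asarray(x, dtype=float)
    C = vcv_matrix(tree)
    fits = {mode: _fit_lambda_cov(C, x, mode) for mode in _MODES}
    best_mode = min(fits, key=lambda m: fits[m].aic)
    best_aic = fits[best_mode].aic
    delta = {m: best_aic - f.aic for m, f in fits.items()}
    return ModelComparison(fits, delta, best_mode)
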