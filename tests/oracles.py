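"""Independent brute-force oracles used to validate the fast implementations.

Nothing here shares code with the package's estimation path: likelihoods are
evaluated through an eigendecomposition of the candidate covariance, optima
are located by dense grid search with refinement, and ancestral values by
re-rooted GLS on explicitly constructed covariance matrices.
"""

import numpy as np


def mvn_loglik_eig(x, C, sigma2, mu):
    """MVN log-density via eigendecomposition (no Cholesky, no GLS)."""
    w, Q = np.linalg.eigh(C)
    y = Q.T @ (x - mu)
    return -0.5 * (
        len(x) * np.log(2 * np.pi * sigma2)
        + np.sum(np.log(w))
        + np.sum(y**2 / w) / sigma2
    )


def grid_search_lambda(x, C, n_lambda=101, n_grid=41, refinements=4, lambda_grid=None):
    """Dense grid search over (lambda, mu, sigma2) maximizing the BM
    likelihood with covariance sigma2 * C_lambda.

    Returns (lambda, mu, sigma2, loglik) at the best grid point.  For each
    lambda on a fixed grid the (mu, sigma2) plane is searched on a shrinking
    grid, which keeps the search independent of the closed-form GLS profile.
    """
    x = np.asarray(x, float)
    n = len(x)
    lambdas = (
        np.asarray(lambda_grid, float)
        if lambda_grid is not None
        else np.linspace(0.0, 1.0, n_lambda)
    )
    best = (-np.inf, None, None, None)
    mu0, mu_half = x.mean(), max(3.0 * x.std(), 1e-6)
    s20 = x.var() / np.mean(np.diag(C)) + 1e-12

    for lam in lambdas:
        Cl = C * lam
        np.fill_diagonal(Cl, np.diag(C))
        w, Q = np.linalg.eigh(Cl)
        w = np.maximum(w, 1e-12 * np.mean(np.diag(C)))
        logdet = np.sum(np.log(w))
        y = Q.T @ x
        o = Q.T @ np.ones(n)
        mu_c, mu_h = mu0, mu_half
        ls_c, ls_h = np.log(s20), 2.5
        ll_best = -np.inf
        args = None
        for _ in range(refinements):
            mus = np.linspace(mu_c - mu_h, mu_c + mu_h, n_grid)
            s2s = np.exp(np.linspace(ls_c - ls_h, ls_c + ls_h, n_grid))
            # quad[i,j] = sum_k (y_k - mus[i] o_k)^2 / w_k  evaluated densely
            resid = y[None, :] - mus[:, None] * o[None, :]
            quad = (resid**2 / w[None, :]).sum(axis=1)
            ll = (
                -0.5
                * (
                    n * np.log(2 * np.pi)
                    + n * np.log(s2s)[None, :]
                    + logdet
                    + quad[:, None] / s2s[None, :]
                )
            )
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            ll_best = ll[i, j]
            args = (mus[i], s2s[j])
            mu_c, ls_c = mus[i], np.log(s2s[j])
            mu_h *= 0.15
            ls_h *= 0.15
        if ll_best > best[0]:
            best = (ll_best, lam, args[0], args[1])
    ll, lam, mu, s2 = best
    return lam, mu, s2, ll


def rerooted_gls_estimate(tree, x, node):
    """Ancestral value at ``node`` by explicit re-rooted GLS: build the
    node-to-tip covariance from path lengths and solve the dense system."""
    tips = tree.tips
    depths = tree.node_depths()

    def path_up(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    def dist(a, b):
        anc = set(map(id, path_up(a)))
        m = b
        while id(m) not in anc:
            m = m.parent
        return depths[a] + depths[b] - 2 * depths[m]

    n = len(tips)
    Ck = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            Ck[i, j] = Ck[j, i] = 0.5 * (
                dist(node, tips[i]) + dist(node, tips[j]) - dist(tips[i], tips[j])
            )
    ones = np.ones(n)
    S = np.linalg.solve(Ck + 1e-12 * np.mean(np.diag(Ck)) * np.eye(n),
                        np.column_stack([np.asarray(x, float), ones]))
    return float(ones @ S[:, 0]) / float(ones @ S[:, 1])
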