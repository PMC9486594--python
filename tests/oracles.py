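"""Independent brute-force oracles used to validate the fast paths.

Everything here deliberately avoids the package's whitening/batching
machinery: explicit V inverses, dense normal equations, direct likelihood
evaluation.  Slow but unambiguous.
"""

import numpy as np
from scipy import stats


def gls_scan(y, dosages, K, sigma_g2, sigma_e2, covariates=None):
    """Naive per-marker generalized least squares with an explicit V solve.

    Returns (statistics, pvalues) for the one-extra-regressor F-test with
    the given (fixed) variance components.
    """
    n, m = dosages.shape
    V = sigma_g2 * K + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    cols = [np.ones((n, 1))]
    if covariates is not None:
        cols.append(covariates)
    X0 = np.hstack(cols)
    c = X0.shape[1] + 1

    def rss_of(X):
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        return float(r @ Vi @ r)

    rss0 = rss_of(X0)
    t = np.empty(m)
    for j in range(m):
        X = np.hstack([X0, dosages[:, j:j + 1]])
        t[j] = (n - c) * (rss0 - rss_of(X)) / rss_of(X)
    return t, stats.f.sf(t, 1, n - c)


def loglik_grid(y, X0, K, sigma_g2_grid, sigma_e2_grid):
    """Dense 2-D evaluation of the Gaussian likelihood of the null mixed
    model, profiling beta by GLS at each grid point.

    Returns the grid of log-likelihood values (len(g) x len(e)).
    """
    n = len(y)
    out = np.full((len(sigma_g2_grid), len(sigma_e2_grid)), -np.inf)
    for i, sg in enumerate(sigma_g2_grid):
        for j, se in enumerate(sigma_e2_grid):
            V = sg * K + se * np.eye(n)
            try:
                C = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                continue
            Vi_y = np.linalg.solve(V, y)
            Vi_X = np.linalg.solve(V, X0)
            beta = np.linalg.solve(X0.T @ Vi_X, X0.T @ Vi_y)
            r = y - X0 @ beta
            quad = float(r @ np.linalg.solve(V, r))
            logdet = 2.0 * float(np.sum(np.log(np.diag(C))))
            out[i, j] = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    return out


def ols_block(X, y):
    """Textbook normal-equations OLS for one block: (beta, rss)."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    r = y - X @ beta
    return beta, float(r @ r)


def f_upper_tail_quadrature(t, dfn, dfd):
    """Upper-tail F probability by numerical integration of the density."""
    from scipy.integrate import quad
    val, _ = quad(lambda x: stats.f.pdf(x, dfn, dfd), t, np.inf)
    return val
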