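"""Independent reference implementations used only as test oracles.

These are deliberately written straight from the definitions, with plain
loops and the statistics module where possible, so they share no code path
with the package.
"""

from statistics import median

import numpy as np


def median_polish_oracle(x, tol=0.01, max_iter=10):
    """Tukey's median polish, straight from the definition (row sweep first).

    Returns (overall, row_effects, col_effects, residuals).
    """
    resid = [list(map(float, row)) for row in x]
    nrow, ncol = len(resid), len(resid[0])
    overall = 0.0
    row_eff = [0.0] * nrow
    col_eff = [0.0] * ncol
    prev = sum(abs(v) for row in resid for v in row)
    for _ in range(max_iter):
        for i in range(nrow):
            m = median(resid[i])
            row_eff[i] += m
            for j in range(ncol):
                resid[i][j] -= m
        d = median(col_eff)
        overall += d
        for j in range(ncol):
            col_eff[j] -= d

        for j in range(ncol):
            m = median(resid[i][j] for i in range(nrow))
            col_eff[j] += m
            for i in range(nrow):
                resid[i][j] -= m
        d = median(row_eff)
        overall += d
        for i in range(nrow):
            row_eff[i] -= d

        total = sum(abs(v) for row in resid for v in row)
        if total == 0 or (prev > 0 and (prev - total) < tol * prev):
            break
        prev = total
    return overall, row_eff, col_eff, resid


def natural_spline_basis_oracle(x, knots):
    """Truncated-power natural cubic spline basis (dimension == len(knots)).

    Basis: 1, x, and d_k(x) - d_{K-1}(x) for k = 1..K-2 with
    d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k).
    """
    x = np.asarray(x, float)
    knots = np.asarray(knots, float)
    K = len(knots)

    def d(j):
        return (
            np.clip(x - knots[j], 0, None) ** 3
            - np.clip(x - knots[-1], 0, None) ** 3
        ) / (knots[-1] - knots[j])

    cols = [np.ones_like(x), x]
    d_last = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - d_last)
    return np.column_stack(cols)


def conditional_mean_by_bin(alpha, mu, sigma, n, seed, n_bins=40):
    """Monte-Carlo E[X | S in bin] for S = X + Y, X~Exp(alpha), Y~N(mu,sigma).

    Returns (bin mean of S, bin mean of X, standard error of the bin mean).
    Bins are quantile-spaced over the central 98% of S.
    """
    rng = np.random.default_rng(seed)
    x = rng.exponential(1.0 / alpha, n)
    s = x + rng.normal(mu, sigma, n)
    edges = np.quantile(s, np.linspace(0.01, 0.99, n_bins + 1))
    idx = np.digitize(s, edges)
    s_mean, x_mean, se = [], [], []
    for b in range(1, n_bins + 1):
        mask = idx == b
        nb = mask.sum()
        if nb < 100:
            continue
        s_mean.append(s[mask].mean())
        x_mean.append(x[mask].mean())
        se.append(x[mask].std(ddof=1) / np.sqrt(nb))
    return np.array(s_mean), np.array(x_mean), np.array(se)
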