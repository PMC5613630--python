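"""Independent oracles used by the test suite.

Everything here is deliberately written from scratch (plain numpy/scipy,
no imports from the package's numerical internals) so that agreement with
the package is a genuine dual-route check.
"""

import numpy as np
from scipy.stats import norm


def logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def polr_loglik(y, X, cutpoints, beta):
    """Direct cumulative-logit log-likelihood (independent implementation)."""
    y = np.asarray(y)
    X = np.asarray(X, float)
    eta = X @ np.asarray(beta, float) if X.size else np.zeros(len(y))
    cuts = np.concatenate(([-np.inf], np.asarray(cutpoints, float), [np.inf]))
    upper = logistic(cuts[y + 1] - eta)
    lower = logistic(cuts[y] - eta)
    return float(np.sum(np.log(upper - lower)))


def grid_search_polr(y, X, n_cut, span=6.0, width=41, sweeps=500):
    """Dense coordinate-wise grid search for the proportional-odds MLE.

    Cyclic per-parameter grid refinement: each sweep scans a dense grid for
    one parameter holding the others fixed; the grid width for a parameter
    shrinks only once its maximizer is interior to the current grid.  The
    cumulative-logit log-likelihood is smooth and concave in
    (cutpoints, slopes), so coordinate-wise maximization converges to the
    global ML solution without using any gradient or the package's optimizer.
    """
    y = np.asarray(y)
    X = np.asarray(X, float)
    p = X.shape[1]
    params = np.concatenate((np.linspace(-1, 1, n_cut), np.zeros(p)))
    widths = np.full(n_cut + p, span)

    def ll(params):
        cuts = params[:n_cut]
        if np.any(np.diff(cuts) <= 0):
            return -np.inf
        return polr_loglik(y, X, cuts, params[n_cut:])

    best = ll(params)
    for _ in range(sweeps):
        for j in range(n_cut + p):
            grid = params[j] + np.linspace(-widths[j], widths[j], width)
            vals = np.empty(width)
            for g_i, g in enumerate(grid):
                trial = params.copy()
                trial[j] = g
                vals[g_i] = ll(trial)
            k = int(np.argmax(vals))
            if vals[k] > best:
                best = vals[k]
                params[j] = grid[k]
            if 0 < k < width - 1:
                widths[j] *= 0.5
        if np.max(widths) < 1e-9:
            break
    return params, best


def trapezoid_marginal_loglik(y, X, cluster, cutpoints, beta, sigma_u2,
                              n_grid=4001, half_width=12.0):
    """Dense-grid marginalization of the random-intercept ordinal likelihood."""
    y = np.asarray(y)
    X = np.asarray(X, float)
    cluster = np.asarray(cluster)
    sd = np.sqrt(sigma_u2)
    ug = np.linspace(-half_width * max(sd, 0.05), half_width * max(sd, 0.05),
                     n_grid)
    phi = norm.pdf(ug, 0.0, sd)
    cuts = np.concatenate(([-np.inf], np.asarray(cutpoints, float), [np.inf]))
    eta = X @ np.asarray(beta, float) if X.size else np.zeros(len(y))
    ll = 0.0
    for j in np.unique(cluster):
        idx = np.where(cluster == j)[0]
        logL = np.zeros_like(ug)
        for i in idx:
            upper = logistic(cuts[y[i] + 1] - eta[i] - ug)
            lower = logistic(cuts[y[i]] - eta[i] - ug)
            logL += np.log(upper - lower)
        ll += np.log(np.trapezoid(np.exp(logL) * phi, ug))
    return float(ll)


def anova_icc(values, cluster):
    """One-way random-effects ANOVA estimator of the intraclass correlation."""
    values = np.asarray(values, float)
    cluster = np.asarray(cluster)
    groups = [values[cluster == j] for j in np.unique(cluster)]
    k = len(groups)
    n = np.array([len(g) for g in groups])
    grand = values.mean()
    ssb = float(np.sum(n * (np.array([g.mean() for g in groups]) - grand) ** 2))
    ssw = float(np.sum([np.sum((g - g.mean()) ** 2) for g in groups]))
    msb = ssb / (k - 1)
    msw = ssw / (len(values) - k)
    n0 = (len(values) - np.sum(n**2) / len(values)) / (k - 1)
    return (msb - msw) / (msb + (n0 - 1) * msw)


def grm_category_probs(theta, a, thresholds, dif=0.0):
    """One-line GRM oracle: adjacent differences of logistic tails."""
    tails = [1.0] + [float(logistic(a * (theta - (b + dif)))) for b in thresholds]
    tails.append(0.0)
    return np.diff(tails) * -1.0
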