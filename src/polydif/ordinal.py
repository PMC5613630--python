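"""Maximum-likelihood proportional-odds (cumulative logit) regression.

The proportional-odds model for an ordinal response :math:`Y \\in \\{0,\\dots,C-1\\}`
with predictors :math:`x` is

.. math::

    \\mathrm{logit}\\, P(Y \\le c \\mid x) = \\alpha_c - x^\\top\\beta,
    \\qquad c = 0, \\dots, C-2,

with strictly increasing cutpoints :math:`\\alpha_0 < \\dots < \\alpha_{C-2}`
and a single slope vector shared across cutpoints.  Likelihood-ratio
comparisons of nested fits of this model to a single item's responses,
conditioning on an observed ability proxy, are the classical logistic
regression approach to differential item functioning.

The sign convention above means a *positive* slope shifts probability mass
toward higher categories, matching the usual latent-variable reading
:math:`Y^* = x^\\top\\beta + \\varepsilon` with logistic error.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

__all__ = [
    "ProportionalOdds",
    "fit_proportional_odds",
    "lr_statistic",
    "LRTest",
    "NotNestedError",
]

_TINY = 1e-300


class NotNestedError(ValueError):
    """Raised when an LR test is requested for non-nested or mismatched fits."""


def _as_design(X, n_obs=None):
    """Coerce X to a 2-d float design matrix; None means no predictors."""
    if X is None:
        if n_obs is None:
            raise ValueError("X=None requires n_obs")
        return np.empty((n_obs, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("X must be 1- or 2-dimensional")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _encode_response(y):
    """Return (codes 0..C-1, original category values).

    Unobserved categories are collapsed away; both models of an LR test see
    the same response vector, hence the same collapse.
    """
    y = np.asarray(y)
    categories, codes = np.unique(y, return_inverse=True)
    if categories.size < 2:
        raise ValueError(
            f"response has {categories.size} observed category; need at least 2"
        )
    return codes.astype(np.intp), categories


def _response_hash(codes):
    return hashlib.md5(np.ascontiguousarray(codes).tobytes()).hexdigest()


def _loglik_terms(alpha, m, y_codes):
    """Pointwise cumulative-logit log-likelihood pieces.

    Parameters
    ----------
    alpha : (C-1,) increasing cutpoints
    m : linear predictor, shape (n,) or (n, Q) (broadcast against cutpoints)
    y_codes : (n,) integer codes in 0..C-1

    Returns
    -------
    logp : same shape as m
    dl_dm : d log p / d m
    wu, wl : f(z_upper)/p and f(z_lower)/p, used to assemble cutpoint
        gradients (zero where the boundary is infinite).
    """
    full = np.concatenate(([-np.inf], alpha, [np.inf]))
    hi = full[y_codes + 1]
    lo = full[y_codes]
    if m.ndim == 2:
        hi = hi[:, None]
        lo = lo[:, None]
    zu = hi - m
    zl = lo - m
    Fu = expit(zu)
    Fl = expit(zl)
    p = np.maximum(Fu - Fl, _TINY)
    logp = np.log(p)
    fu = Fu * (1.0 - Fu)
    fl = Fl * (1.0 - Fl)
    wu = fu / p
    wl = fl / p
    dl_dm = wl - wu
    return logp, dl_dm, wu, wl


def _alpha_grad(wu, wl, y_codes, n_cut, weights=None):
    """Accumulate d loglik / d alpha_c over observations.

    ``weights`` (same shape as wu) allows posterior-weighted accumulation in
    the mixed model; None means plain sum over a 1-d fit.
    """
    if weights is not None:
        wu = wu * weights
        wl = wl * weights
    if wu.ndim == 2:
        wu = wu.sum(axis=1)
        wl = wl.sum(axis=1)
    g = np.zeros(n_cut)
    top = y_codes < n_cut  # upper boundary finite
    np.add.at(g, y_codes[top], wu[top])
    bot = y_codes > 0
    np.subtract.at(g, y_codes[bot] - 1, wl[bot])
    return g


def _unpack(t, n_cut):
    """t -> (alpha, beta); alpha_0 = t_0, alpha_c = alpha_{c-1} + exp(t_c).

    Step arguments are capped at 300 so that wild line-search trial points
    stay finite; the optimum is far inside the cap.
    """
    steps = np.concatenate(([t[0]], np.exp(np.minimum(t[1:n_cut], 300.0))))
    return np.cumsum(steps), t[n_cut:]


def _pack(alpha, beta):
    d = np.diff(alpha)
    return np.concatenate(([alpha[0]], np.log(np.maximum(d, 1e-8)), beta))


def _chain_to_t(g_alpha, t, n_cut):
    """Jacobian-transpose product for the log-increment cutpoint map."""
    rev = np.cumsum(g_alpha[::-1])[::-1]  # sum_{c>=m} g_alpha[c]
    out = rev.copy()
    out[1:] *= np.exp(np.minimum(t[1:n_cut], 300.0))
    return out


def _neg_loglik_grad(t, y_codes, X, n_cut):
    alpha, beta = _unpack(t, n_cut)
    eta = X @ beta if X.shape[1] else np.zeros(X.shape[0])
    logp, dl_dm, wu, wl = _loglik_terms(alpha, eta, y_codes)
    ll = logp.sum()
    g_alpha = _alpha_grad(wu, wl, y_codes, n_cut)
    g_beta = X.T @ dl_dm
    g_t = np.concatenate((_chain_to_t(g_alpha, t, n_cut), g_beta))
    return -ll, -g_t


def _natural_grad(params, y_codes, X, n_cut):
    """Gradient of the loglik w.r.t. (alpha, beta) directly (for the Hessian)."""
    alpha, beta = params[:n_cut], params[n_cut:]
    eta = X @ beta if X.shape[1] else np.zeros(X.shape[0])
    _, dl_dm, wu, wl = _loglik_terms(alpha, eta, y_codes)
    return np.concatenate((_alpha_grad(wu, wl, y_codes, n_cut), X.T @ dl_dm))


def fd_hessian(grad_fn, params, rel_step=1e-5):
    """Central finite-difference Jacobian of an analytic gradient."""
    p = len(params)
    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * max(1.0, abs(params[j]))
        up = params.copy()
        dn = params.copy()
        up[j] += h
        dn[j] -= h
        H[:, j] = (grad_fn(up) - grad_fn(dn)) / (2 * h)
    return 0.5 * (H + H.T)


class ProportionalOdds(BaseEstimator):
    """Proportional-odds cumulative-logit regression fit by maximum likelihood.

    Parameters
    ----------
    compute_se : bool, default True
        Invert the observed information at the optimum for standard errors.
        Turn off inside simulation loops where only the log-likelihood is
        needed.
    maxiter : int
        Iteration cap for the L-BFGS-B optimizer.
    gtol : float
        Gradient infinity-norm convergence tolerance.

    Attributes
    ----------
    cutpoints_ : (C-1,) increasing cutpoint estimates
    coef_ : (p,) slope estimates
    loglik_ : maximized log-likelihood
    bse_cutpoints_, bse_coef_ : observed-information standard errors
        (None when ``compute_se=False`` or the information is singular)
    categories_ : observed response categories (collapse record)
    converged_, n_iter_, n_obs_, n_params_ : fit metadata
    """

    def __init__(self, compute_se=True, maxiter=200, gtol=1e-6):
        self.compute_se = compute_se
        self.maxiter = maxiter
        self.gtol = gtol

    # -- sklearn plumbing ---------------------------------------------------
    def fit(self, X, y, start=None):
        y_codes, categories = _encode_response(y)
        X = _as_design(X, n_obs=y_codes.size)
        if X.shape[0] != y_codes.size:
            raise ValueError("X and y have different lengths")
        n_cut = categories.size - 1

        if start is None:
            cum = np.cumsum(np.bincount(y_codes, minlength=n_cut + 1)) / y_codes.size
            alpha0 = logit(np.clip(cum[:-1], 1e-6, 1 - 1e-6))
            alpha0 = np.maximum.accumulate(alpha0)
            alpha0 += np.arange(n_cut) * 1e-6  # guard exact ties
            t0 = _pack(alpha0, np.zeros(X.shape[1]))
        else:
            t0 = _pack(*start)

        res = optimize.minimize(
            _neg_loglik_grad,
            t0,
            args=(y_codes, X, n_cut),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.maxiter, "ftol": 1e-12, "gtol": self.gtol},
        )
        alpha, beta = _unpack(res.x, n_cut)

        self.categories_ = categories
        self.cutpoints_ = alpha
        self.coef_ = beta
        self.loglik_ = -res.fun
        self.n_iter_ = res.nit
        self.converged_ = bool(res.success or np.max(np.abs(res.jac)) < 1e-3)
        self.n_obs_ = int(y_codes.size)
        self.n_params_ = int(n_cut + X.shape[1])
        self.response_hash_ = _response_hash(y_codes)
        self._y_codes = y_codes
        self._X = X

        self.bse_cutpoints_ = self.bse_coef_ = None
        if self.compute_se and self.converged_:
            params = np.concatenate((alpha, beta))
            H = -fd_hessian(
                lambda p: _natural_grad(p, y_codes, X, n_cut), params
            )
            try:
                cov = np.linalg.inv(H)
                se = np.sqrt(np.clip(np.diag(cov), 0, None))
                self.bse_cutpoints_ = se[:n_cut]
                self.bse_coef_ = se[n_cut:]
            except np.linalg.LinAlgError:
                pass
        return self

    def predict_proba(self, X):
        """Category probabilities on the observed (possibly collapsed) scale."""
        X = _as_design(X, n_obs=None if X is None else len(np.atleast_1d(X)))
        eta = X @ self.coef_ if X.shape[1] else np.zeros(X.shape[0])
        cum = expit(self.cutpoints_[None, :] - eta[:, None])
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        return np.diff(cum, axis=1)

    def predict(self, X):
        return self.categories_[np.argmax(self.predict_proba(X), axis=1)]

    def loglik_at(self, cutpoints, coef):
        """Evaluate the log-likelihood of the training data at given parameters."""
        eta = self._X @ np.asarray(coef, float) if self._X.shape[1] else np.zeros(self.n_obs_)
        logp, *_ = _loglik_terms(np.asarray(cutpoints, float), eta, self._y_codes)
        return float(logp.sum())

    def to_dict(self):
        """JSON-serializable summary of the fit."""
        return {
            "model": "proportional_odds",
            "loglik": self.loglik_,
            "cutpoints": list(self.cutpoints_),
            "coef": list(self.coef_),
            "bse_coef": None if self.bse_coef_ is None else list(self.bse_coef_),
            "categories": [int(c) for c in np.asarray(self.categories_).tolist()],
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "n_obs": self.n_obs_,
            "n_params": self.n_params_,
        }


def fit_proportional_odds(y, X=None, **kwargs):
    """Functional wrapper: fit a :class:`ProportionalOdds` model and return it."""
    return ProportionalOdds(**kwargs).fit(X, y)


@dataclass(frozen=True)
class LRTest:
    """A likelihood-ratio comparison of two nested fits."""

    chi_square: float
    df: int
    p_value: float
    valid: bool = True
    message: str = ""


def lr_statistic(fit_full, fit_reduced):
    """Likelihood-ratio test of ``fit_full`` against nested ``fit_reduced``.

    Both fits must be on the same response data (checked via length and a
    hash of the response codes).  ``df`` is the difference in parameter
    counts; for mixed fits the fixed-effect counts are compared, so the chi
    square reference distribution is standard.
    """
    n_full = getattr(fit_full, "n_fixed_params_", fit_full.n_params_)
    n_red = getattr(fit_reduced, "n_fixed_params_", fit_reduced.n_params_)
    if fit_full.n_obs_ != fit_reduced.n_obs_ or (
        fit_full.response_hash_ != fit_reduced.response_hash_
    ):
        raise NotNestedError("fits are not on the same response data")
    df = n_full - n_red
    if df < 0:
        raise NotNestedError("full model has fewer parameters than reduced model")
    if not (fit_full.converged_ and fit_reduced.converged_):
        return LRTest(np.nan, df, np.nan, valid=False, message="non-converged fit")
    if df == 0:
        return LRTest(0.0, 0, 1.0)
    chi2 = max(0.0, 2.0 * (fit_full.loglik_ - fit_reduced.loglik_))
    return LRTest(chi2, df, float(stats.chi2.sf(chi2, df)))
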