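"""Uniform and omnibus DIF tests for polytomous items, flat and hierarchical.

For each studied item, the ability proxy :math:`\\theta` is the raw total
test score (all items, including the studied one).  Three nested
proportional-odds models of the item response are compared:

* R1 (baseline): theta only
* R2: theta + group
* full: theta + group + group x theta

The *uniform* DIF test is LR(R2, R1) on 1 df (a location/group effect
constant across the trait); the *omnibus* test is LR(full, R1) on 2 df and
picks up nonuniform DIF as well.  The hierarchical (HOLR) variants fit the
same fixed effects plus a cluster random intercept; a within-cluster group
enters at the person level, a between-cluster group (constant per cluster)
enters the intercept equation — algebraically a cluster-constant column in
the same design matrix.

No multiplicity adjustment is applied by default; ``dif_scan`` offers
Benjamini–Hochberg as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mixed import RandomInterceptOrdinal, lr_statistic_mixed
from .ordinal import ProportionalOdds, lr_statistic
from .simulate import ResponseData

__all__ = ["DIFResult", "olr_dif_test", "holr_dif_test", "dif_scan"]


@dataclass
class DIFResult:
    """One item's DIF test under one method."""

    item: int
    method: str  # 'olr' or 'holr'
    test: str  # 'uniform' or 'omnibus'
    level: str  # 'within' or 'between'
    chi_square: float
    df: int
    p_value: float
    beta_group: float
    beta_group_se: float | None
    alpha: float
    flagged: bool
    valid: bool = True
    message: str = ""
    fits: dict = field(default_factory=dict, repr=False)

    def to_dict(self):
        d = {
            k: getattr(self, k)
            for k in (
                "item",
                "method",
                "test",
                "level",
                "chi_square",
                "df",
                "p_value",
                "beta_group",
                "beta_group_se",
                "alpha",
                "flagged",
                "valid",
                "message",
            )
        }
        d["fits"] = self.fits
        return d


def _coerce(responses, group=None, cluster=None, level="within"):
    if isinstance(responses, ResponseData):
        return responses
    responses = np.asarray(responses)
    return ResponseData(
        responses,
        np.zeros(len(responses), int) if cluster is None else np.asarray(cluster),
        np.asarray(group),
        level,
    )


def _check_between(group, cluster):
    for j in np.unique(cluster):
        g = group[cluster == j]
        if not np.all(g == g[0]):
            raise ValueError(
                f"between-level analysis requires a cluster-constant group; "
                f"cluster {j!r} has mixed labels"
            )


def _invalid(item, method, test, level, df, alpha, msg):
    return DIFResult(
        item, method, test, level, float("nan"), df, float("nan"),
        float("nan"), None, alpha, flagged=False, valid=False, message=msg,
    )


def olr_dif_test(
    responses,
    item,
    group=None,
    test="uniform",
    alpha=0.05,
    score="total",
    compute_se=True,
    keep_fits=False,
):
    """Flat (single-level) proportional-odds DIF test for one item.

    ``responses`` may be a :class:`ResponseData` or a persons x items array
    with ``group`` given separately.  ``score='rest'`` uses the total score
    excluding the studied item.
    """
    if test not in ("uniform", "omnibus"):
        raise ValueError("test must be 'uniform' or 'omnibus'")
    data = _coerce(responses, group)
    theta = data.rest_score(item) if score == "rest" else data.total_score()
    theta = theta.astype(float)
    g = data.group.astype(float)
    y = data.responses[:, item]

    X1 = theta[:, None]
    X2 = np.column_stack([theta, g])
    try:
        r1 = ProportionalOdds(compute_se=False).fit(X1, y)
        r2 = ProportionalOdds(compute_se=compute_se).fit(
            X2, y, start=(r1.cutpoints_, np.r_[r1.coef_, 0.0])
        )
        if test == "omnibus":
            Xf = np.column_stack([theta, g, g * theta])
            full = ProportionalOdds(compute_se=False).fit(
                Xf, y, start=(r2.cutpoints_, np.r_[r2.coef_, 0.0])
            )
            lr = lr_statistic(full, r1)
        else:
            lr = lr_statistic(r2, r1)
    except ValueError as exc:
        return _invalid(item, "olr", test, data.level, 1 if test == "uniform" else 2,
                        alpha, str(exc))
    if not lr.valid:
        return _invalid(item, "olr", test, data.level, lr.df, alpha, lr.message)
    se = None if r2.bse_coef_ is None else float(r2.bse_coef_[1])
    res = DIFResult(
        item, "olr", test, data.level, lr.chi_square, lr.df, lr.p_value,
        float(r2.coef_[1]), se, alpha, flagged=bool(lr.p_value < alpha),
    )
    if keep_fits:
        res.fits = {"r1": r1.to_dict(), "r2": r2.to_dict()}
        if test == "omnibus":
            res.fits["full"] = full.to_dict()
    return res


def holr_dif_test(
    responses,
    item,
    group=None,
    cluster=None,
    level=None,
    test="uniform",
    alpha=0.05,
    score="total",
    n_quad=21,
    compute_se=True,
    keep_fits=False,
):
    """Hierarchical (random-intercept) DIF test for one item.

    ``level`` declares where the grouping variable lives; for
    ``level='between'`` the group must be constant within every cluster (a
    varying group is a data error, never a silent answer).  The omnibus test
    is defined for within-cluster groups only.
    """
    if test not in ("uniform", "omnibus"):
        raise ValueError("test must be 'uniform' or 'omnibus'")
    data = _coerce(responses, group, cluster, level or "within")
    level = level or data.level
    if level not in ("within", "between"):
        raise ValueError("level must be 'within' or 'between'")
    if level == "between":
        _check_between(data.group, data.cluster_id)
        if test == "omnibus":
            raise ValueError("omnibus test is defined for within-cluster groups only")

    theta = data.rest_score(item) if score == "rest" else data.total_score()
    theta = theta.astype(float)
    g = data.group.astype(float)
    y = data.responses[:, item]
    cl = data.cluster_id

    try:
        base = RandomInterceptOrdinal(n_quad=n_quad, compute_se=False).fit(
            theta[:, None], y, cluster=cl
        )
        start = (base.cutpoints_, np.r_[base.coef_, 0.0], max(base.sigma_u2_, 1e-4))
        alt = RandomInterceptOrdinal(n_quad=n_quad, compute_se=compute_se).fit(
            np.column_stack([theta, g]), y, cluster=cl, start=start
        )
        if test == "omnibus":
            start_f = (alt.cutpoints_, np.r_[alt.coef_, 0.0],
                       max(alt.sigma_u2_, 1e-4))
            full = RandomInterceptOrdinal(n_quad=n_quad, compute_se=False).fit(
                np.column_stack([theta, g, g * theta]), y, cluster=cl, start=start_f
            )
            lr = lr_statistic_mixed(full, base)
        else:
            lr = lr_statistic_mixed(alt, base)
    except ValueError as exc:
        return _invalid(item, "holr", test, level, 1 if test == "uniform" else 2,
                        alpha, str(exc))
    if not lr.valid:
        return _invalid(item, "holr", test, level, lr.df, alpha, lr.message)
    se = None if alt.bse_coef_ is None else float(alt.bse_coef_[1])
    res = DIFResult(
        item, "holr", test, level, lr.chi_square, lr.df, lr.p_value,
        float(alt.coef_[1]), se, alpha, flagged=bool(lr.p_value < alpha),
    )
    if keep_fits:
        res.fits = {"baseline": base.to_dict(), "alternative": alt.to_dict()}
        if test == "omnibus":
            res.fits["full"] = full.to_dict()
    return res


def dif_scan(
    responses,
    group=None,
    cluster=None,
    method="olr",
    test="uniform",
    level="within",
    alpha=0.05,
    score="total",
    adjust=None,
    **kwargs,
):
    """Run the chosen DIF test on every item of an instrument.

    Returns a list of :class:`DIFResult`, one per item, recomputing the
    ability proxy for each studied item per the configured convention.
    ``adjust='bh'`` re-flags items by Benjamini–Hochberg adjusted p-values
    (raw p-values are kept in the results).
    """
    data = _coerce(responses, group, cluster, level)
    results = []
    for item in range(data.n_items):
        if method == "olr":
            r = olr_dif_test(data, item, test=test, alpha=alpha, score=score, **kwargs)
        elif method == "holr":
            r = holr_dif_test(
                data, item, level=level, test=test, alpha=alpha, score=score, **kwargs
            )
        else:
            raise ValueError("method must be 'olr' or 'holr'")
        results.append(r)
    if adjust == "bh":
        _bh_flag(results, alpha)
    elif adjust is not None:
        raise ValueError("adjust must be None or 'bh'")
    return results


def _bh_flag(results, alpha):
    valid = [r for r in results if r.valid and np.isfinite(r.p_value)]
    m = len(valid)
    if not m:
        return
    order = np.argsort([r.p_value for r in valid])
    p_sorted = np.array([valid[i].p_value for i in order])
    adj = np.minimum.accumulate((p_sorted * m / np.arange(1, m + 1))[::-1])[::-1]
    for rank, i in enumerate(order):
        valid[i].flagged = bool(min(adj[rank], 1.0) < alpha)
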