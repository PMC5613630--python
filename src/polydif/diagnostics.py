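"""Pre-analysis screening (ICC, design effect) and item characteristic functions.

The item characteristic function (ICF) of a graded item is its expected
score as a function of the latent trait,

.. math::

    E[X \\mid \\theta] = \\sum_{x=0}^{K-1} x \\, p_x(\\theta)
                      = \\sum_{k=1}^{K-1} P(Y \\ge k \\mid \\theta),

(the tail-sum identity).  Overlaying focal- and reference-group ICFs
visualizes uniform DIF as a vertical separation of the curves.

For clustered ordinal data, the per-item ICC is estimated on the latent
logistic scale from an intercept-only random-intercept cumulative-logit fit:
``icc = sigma_u^2 / (sigma_u^2 + pi^2 / 3)``, pi^2/3 being the logistic
residual variance.  The design effect ``1 + (m - 1) * icc`` for mean cluster
size m quantifies the variance inflation from cluster sampling; values above
2 are conventionally taken as a signal that a hierarchical analysis is
warranted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed import RandomInterceptOrdinal
from .simulate import category_probabilities

__all__ = ["ICFCurve", "icf", "icc_ordinal", "ICCResult", "design_effect",
           "diagnose", "plot_icf"]

logger = logging.getLogger(__name__)

LOGISTIC_VARIANCE = np.pi**2 / 3


@dataclass
class ICFCurve:
    """Expected-score curve of one item over a theta grid."""

    theta: np.ndarray
    expected_score: np.ndarray
    probabilities: np.ndarray  # (grid, K)
    dif_offset: float = 0.0
    group_label: str | None = None
    item: int | None = None


def icf(a, thresholds, theta_grid, dif_offset=0.0, group_label=None, item=None):
    """Item characteristic function E[X | theta] on a grid."""
    theta_grid = np.asarray(theta_grid, float)
    probs = category_probabilities(theta_grid, a, thresholds, dif_offset)
    scores = np.arange(probs.shape[-1])
    return ICFCurve(
        theta_grid,
        probs @ scores,
        probs,
        dif_offset=dif_offset,
        group_label=group_label,
        item=item,
    )


@dataclass
class ICCResult:
    icc: float
    sigma_u2: float
    boundary: bool
    converged: bool


def icc_ordinal(responses_item, cluster_id, n_quad=21):
    """Latent-scale ICC of one ordinal item from an intercept-only mixed fit."""
    fit = RandomInterceptOrdinal(n_quad=n_quad, compute_se=False).fit(
        None, responses_item, cluster=cluster_id
    )
    s2 = fit.sigma_u2_
    return ICCResult(
        icc=float(s2 / (s2 + LOGISTIC_VARIANCE)),
        sigma_u2=float(s2),
        boundary=fit.boundary_,
        converged=fit.converged_,
    )


def design_effect(icc, mean_cluster_size):
    """Variance inflation from cluster sampling: 1 + (m - 1) * icc."""
    if not 0 <= icc <= 1:
        raise ValueError("icc must be in [0, 1]")
    if mean_cluster_size < 1:
        raise ValueError("mean cluster size must be >= 1")
    return 1.0 + (mean_cluster_size - 1.0) * icc


def diagnose(data, n_quad=21):
    """Per-item ICC and design-effect table for a ResponseData.

    Flags items whose design effect exceeds the conventional threshold of 2,
    where a hierarchical analysis is recommended (guidance only).
    """
    m = data.n_persons / data.n_clusters
    rows = []
    for i in range(data.n_items):
        try:
            r = icc_ordinal(data.responses[:, i], data.cluster_id, n_quad=n_quad)
            deff = design_effect(r.icc, m)
            rows.append(
                {
                    "item": data.item_names[i],
                    "icc": r.icc,
                    "sigma_u2": r.sigma_u2,
                    "design_effect": deff,
                    "hierarchical_recommended": deff > 2.0,
                    "boundary": r.boundary,
                }
            )
        except ValueError as exc:
            logger.warning("item %s skipped: %s", data.item_names[i], exc)
            rows.append({"item": data.item_names[i], "icc": np.nan,
                         "sigma_u2": np.nan, "design_effect": np.nan,
                         "hierarchical_recommended": False, "boundary": False})
    return pd.DataFrame(rows)


def plot_icf(curves, ax=None):
    """Overlay ICF curves (e.g., focal vs reference) on one axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        label = c.group_label or (f"offset={c.dif_offset:g}" if c.dif_offset else None)
        ax.plot(c.theta, c.expected_score, label=label)
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("expected item score")
    if any(c.group_label or c.dif_offset for c in curves):
        ax.legend()
    return ax
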