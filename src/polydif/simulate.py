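"""Two-level graded-response-model simulator with injectable uniform DIF.

Responses follow a logistic graded response model (GRM): for an item with
discrimination :math:`a` and ordered thresholds :math:`b_1 < \\dots < b_{K-1}`,

.. math::

    P(Y \\ge k \\mid \\theta) = \\frac{1}{1 + e^{-a(\\theta - b_k)}},

and category probabilities are adjacent differences of these cumulative
tails.  Latent ability is two-level normal,

.. math::

    \\theta_{ij} = u_{0j} + e_{ij}, \\quad u_{0j} \\sim N(0, \\rho),
    \\quad e_{ij} \\sim N(0, 1-\\rho),

so the total latent variance is fixed at 1 and :math:`\\rho` is the
intraclass correlation.  Uniform DIF of magnitude :math:`d` shifts *all*
thresholds of one studied item upward by :math:`d` for focal-group persons
(a pure location shift: focal persons need more of the trait for the same
expected score); reference-group thresholds are untouched and core items
never receive DIF.

The grouping variable is balanced either within clusters (half of each
cluster focal, e.g. gender) or between clusters (half of the clusters focal,
e.g. school type).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ItemBank",
    "AbilitySample",
    "ResponseData",
    "LOW_DISCRIMINATION",
    "HIGH_DISCRIMINATION",
    "sample_item_bank",
    "sample_abilities",
    "assign_groups",
    "category_probabilities",
    "generate_responses",
    "simulate_dataset",
]

#: Discrimination ranges used by the study design.
LOW_DISCRIMINATION = (0.5, 0.99)
HIGH_DISCRIMINATION = (1.5, 2.0)
DISCRIMINATION_RANGES = {"low": LOW_DISCRIMINATION, "high": HIGH_DISCRIMINATION}

#: Default threshold sampling interval for item difficulty.
THRESHOLD_RANGE = (-2.5, 2.5)


@dataclass
class ItemBank:
    """GRM truth for a simulated instrument.

    ``dif_magnitude`` applies to the studied item only, as a location shift of
    its thresholds for the focal group.
    """

    discrimination: np.ndarray  # (n_items,)
    thresholds: np.ndarray  # (n_items, K-1), rows strictly increasing
    studied_item: int = -1
    dif_magnitude: float = 0.0

    def __post_init__(self):
        self.discrimination = np.asarray(self.discrimination, float)
        self.thresholds = np.atleast_2d(np.asarray(self.thresholds, float))
        if np.any(self.discrimination <= 0):
            raise ValueError("discrimination must be positive for every item")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing within items")
        if self.dif_magnitude < 0:
            raise ValueError("dif_magnitude must be >= 0")
        self.studied_item = int(range(self.n_items)[self.studied_item])

    @property
    def n_items(self):
        return self.thresholds.shape[0]

    @property
    def n_categories(self):
        return self.thresholds.shape[1] + 1

    def to_dict(self):
        return {
            "discrimination": self.discrimination.tolist(),
            "thresholds": self.thresholds.tolist(),
            "studied_item": self.studied_item,
            "dif_magnitude": self.dif_magnitude,
        }


@dataclass
class AbilitySample:
    """Latent traits for persons nested in clusters (total variance 1)."""

    theta: np.ndarray
    cluster_id: np.ndarray
    cluster_effect: np.ndarray
    icc: float

    @property
    def n_persons(self):
        return self.theta.size

    @property
    def n_clusters(self):
        return self.cluster_effect.size


@dataclass
class ResponseData:
    """Persons x items ordinal responses with cluster and group labels."""

    responses: np.ndarray  # (n, n_items) ints in 0..K-1
    cluster_id: np.ndarray  # (n,)
    group: np.ndarray  # (n,) binary; constant per cluster when level='between'
    level: str  # 'within' or 'between'
    item_names: list = field(default_factory=list)

    def __post_init__(self):
        self.responses = np.asarray(self.responses)
        self.cluster_id = np.asarray(self.cluster_id)
        self.group = np.asarray(self.group)
        if self.level not in ("within", "between"):
            raise ValueError("level must be 'within' or 'between'")
        if not self.item_names:
            self.item_names = [f"item_{i + 1}" for i in range(self.n_items)]

    @property
    def n_persons(self):
        return self.responses.shape[0]

    @property
    def n_items(self):
        return self.responses.shape[1]

    @property
    def n_clusters(self):
        return np.unique(self.cluster_id).size

    def total_score(self):
        """Raw total test score over all items (the ability proxy)."""
        return self.responses.sum(axis=1)

    def rest_score(self, item):
        """Total score excluding one item."""
        return self.total_score() - self.responses[:, item]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.responses, columns=self.item_names)
        df.insert(0, "group", self.group)
        df.insert(0, "cluster_id", self.cluster_id)
        df.insert(0, "person_id", np.arange(self.n_persons))
        return df


def _check_range(name, rng_pair):
    lo, hi = rng_pair
    if not lo < hi:
        raise ValueError(f"{name} must satisfy lo < hi, got {rng_pair}")
    return float(lo), float(hi)


def sample_item_bank(
    n_items=16,
    disc_range=LOW_DISCRIMINATION,
    threshold_range=THRESHOLD_RANGE,
    n_categories=5,
    rng=None,
    studied_item=-1,
    dif_magnitude=0.0,
):
    """Draw a fresh item bank.

    Discriminations are i.i.d. uniform on ``disc_range``.  Each item's
    ``n_categories - 1`` thresholds are drawn i.i.d. uniform on
    ``threshold_range`` and sorted ascending (rows with exact ties are
    redrawn, a probability-zero event in exact arithmetic).
    """
    rng = np.random.default_rng(rng)
    d_lo, d_hi = _check_range("disc_range", disc_range)
    t_lo, t_hi = _check_range("threshold_range", threshold_range)
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    a = rng.uniform(d_lo, d_hi, size=n_items)
    b = np.sort(rng.uniform(t_lo, t_hi, size=(n_items, n_categories - 1)), axis=1)
    while True:
        tied = np.any(np.diff(b, axis=1) <= 0, axis=1) if b.shape[1] > 1 else np.zeros(n_items, bool)
        if not tied.any():
            break
        b[tied] = np.sort(
            rng.uniform(t_lo, t_hi, size=(int(tied.sum()), n_categories - 1)), axis=1
        )
    return ItemBank(a, b, studied_item=studied_item, dif_magnitude=dif_magnitude)


def sample_abilities(n_clusters, cluster_size, icc, rng=None):
    """Draw two-level normal abilities with total variance 1 and given ICC."""
    rng = np.random.default_rng(rng)
    if not 0 <= icc < 1:
        raise ValueError("icc must be in [0, 1)")
    if n_clusters < 1 or cluster_size < 1:
        raise ValueError("n_clusters and cluster_size must be >= 1")
    u = rng.normal(0.0, np.sqrt(icc), size=n_clusters)
    e = rng.normal(0.0, np.sqrt(1.0 - icc), size=n_clusters * cluster_size)
    cluster_id = np.repeat(np.arange(n_clusters), cluster_size)
    return AbilitySample(u[cluster_id] + e, cluster_id, u, float(icc))


def assign_groups(n_clusters, cluster_size, level, rng=None):
    """Balanced binary group labels at the requested level.

    within  -> each cluster has cluster_size/2 focal persons.  For odd
    cluster sizes (the study design includes size 5) exact per-cluster
    balance is impossible; instead half the clusters get the extra focal
    person and half the extra reference person (requires even n_clusters),
    keeping the overall design exactly balanced and every cluster within one
    person of balance.

    between -> exactly n_clusters/2 focal clusters, labels constant within
    cluster (requires even n_clusters).

    Sizes that cannot be balanced raise rather than silently unbalancing.
    """
    rng = np.random.default_rng(rng)
    if level == "within":
        if cluster_size % 2 == 0:
            base = np.tile(
                np.r_[np.zeros(cluster_size // 2, int),
                      np.ones(cluster_size // 2, int)],
                (n_clusters, 1),
            )
        else:
            if n_clusters % 2:
                raise ValueError(
                    "within-level balance with odd cluster_size requires an "
                    "even n_clusters"
                )
            half = cluster_size // 2
            extra = np.r_[np.zeros(n_clusters // 2, int),
                          np.ones(n_clusters // 2, int)]
            rng.shuffle(extra)
            base = np.zeros((n_clusters, cluster_size), int)
            base[:, half:] = 1
            base[extra == 0, half] = 0  # these clusters get the extra reference
        return rng.permuted(base, axis=1).ravel()
    if level == "between":
        if n_clusters % 2:
            raise ValueError("between-level balance requires an even n_clusters")
        labels = np.r_[np.zeros(n_clusters // 2, int), np.ones(n_clusters // 2, int)]
        rng.shuffle(labels)
        return np.repeat(labels, cluster_size)
    raise ValueError("level must be 'within' or 'between'")


def category_probabilities(theta, a, thresholds, dif_offset=0.0):
    """GRM category probabilities.

    P(Y >= k | theta) = expit(a * (theta - (b_k + dif_offset))); category
    probabilities are adjacent differences of the cumulative tails.  Returns
    an array of shape ``theta.shape + (K,)``.
    """
    theta = np.asarray(theta, float)
    thresholds = np.asarray(thresholds, float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if a <= 0:
        raise ValueError("discrimination must be positive")
    tails = expit(a * (theta[..., None] - (thresholds + dif_offset)))
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    cum = np.concatenate([ones, tails, zeros], axis=-1)
    return -np.diff(cum, axis=-1)


def generate_responses(ability, bank, groups, level, rng=None):
    """Draw a ResponseData from the GRM given abilities, bank, and groups.

    Focal persons (group == 1) receive the bank's DIF offset on the studied
    item only; focal status is the person's own label (which, at
    level='between', is constant within each cluster by construction).
    """
    rng = np.random.default_rng(rng)
    groups = np.asarray(groups)
    n = ability.n_persons
    if groups.size != n:
        raise ValueError("groups and ability sizes differ")
    Y = np.empty((n, bank.n_items), dtype=np.int64)
    focal = groups == 1
    for i in range(bank.n_items):
        b = bank.thresholds[i]
        a = bank.discrimination[i]
        tails = expit(a * (ability.theta[:, None] - b))  # (n, K-1)
        if i == bank.studied_item and bank.dif_magnitude:
            tails[focal] = expit(
                a * (ability.theta[focal, None] - (b + bank.dif_magnitude))
            )
        u = rng.random((n, 1))
        Y[:, i] = (u < tails).sum(axis=1)
    return ResponseData(Y, ability.cluster_id.copy(), groups.copy(), level)


def simulate_dataset(
    n_clusters,
    cluster_size,
    icc,
    dif,
    level,
    disc="low",
    n_items=16,
    n_categories=5,
    rng=None,
):
    """One replication of the study design: bank + abilities + groups + responses.

    ``disc`` is 'low' (U(0.5, 0.99)), 'high' (U(1.5, 2.0)) or an explicit
    (lo, hi) pair.  Returns (ResponseData, ItemBank, AbilitySample).
    """
    rng = np.random.default_rng(rng)
    disc_range = DISCRIMINATION_RANGES.get(disc, disc)
    bank = sample_item_bank(
        n_items=n_items,
        disc_range=disc_range,
        n_categories=n_categories,
        rng=rng,
        dif_magnitude=dif,
    )
    ability = sample_abilities(n_clusters, cluster_size, icc, rng=rng)
    groups = assign_groups(n_clusters, cluster_size, level, rng=rng)
    data = generate_responses(ability, bank, groups, level, rng=rng)
    return data, bank, ability
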