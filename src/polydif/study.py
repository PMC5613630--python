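"""Monte-Carlo harness: Type I error and power of the OLR and HOLR DIF tests.

The study design crosses six factors: DIF magnitude (0, 0.4, 0.8), grouping
level (within / between cluster), latent ICC (0.05, 0.25, 0.45), number of
clusters (50, 100, 200), cluster size (5, 10, 20), and item discrimination
range (low: U(0.5, 0.99); high: U(1.5, 2.0)).  Each replication draws a
fresh 16-item bank, fresh two-level abilities and balanced groups, generates
graded responses, and runs the 1-df uniform DIF test on the studied item
under *both* methods on the *same* dataset (paired comparison).  Cells with
DIF = 0 estimate Type I error; cells with DIF > 0 estimate power.

Replications are seeded independently per (cell, replication) via
``numpy.random.SeedSequence`` spawn keys, so any subset of a design is
reproducible in isolation and results do not depend on execution order.
Replications whose model fits fail to converge are excluded from that
method's denominator and counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dif import holr_dif_test, olr_dif_test
from .simulate import simulate_dataset

__all__ = ["Cell", "CellResult", "run_cell", "run_design", "design_cells"]

logger = logging.getLogger(__name__)

_DESIGN_DOMAINS = {
    "icc": (0.05, 0.25, 0.45),
    "n_clusters": (50, 100, 200),
    "cluster_size": (5, 10, 20),
    "dif": (0.0, 0.4, 0.8),
    "disc": ("low", "high"),
    "level": ("within", "between"),
}


@dataclass(frozen=True)
class Cell:
    """One fully crossed combination of the manipulated factors."""

    icc: float
    n_clusters: int
    cluster_size: int
    dif: float
    disc: str = "low"
    level: str = "within"
    n_reps: int = 1000
    base_seed: int = 0

    def __post_init__(self):
        for name in ("icc", "n_clusters", "cluster_size", "dif", "disc", "level"):
            if getattr(self, name) not in _DESIGN_DOMAINS[name]:
                warnings.warn(
                    f"{name}={getattr(self, name)!r} is outside the declared "
                    f"study design domains {_DESIGN_DOMAINS[name]}",
                    stacklevel=3,
                )


@dataclass
class MethodResult:
    rejection_rate: float
    n_valid_reps: int
    n_failed_fits: int
    mc_standard_error: float


@dataclass
class CellResult:
    """Per-method rejection rates for one cell."""

    cell: Cell
    methods: dict = field(default_factory=dict)  # name -> MethodResult

    def to_rows(self):
        rows = []
        for method, m in self.methods.items():
            row = asdict(self.cell)
            row["method"] = method
            row.update(asdict(m))
            rows.append(row)
        return rows


def _rep_rng(base_seed, rep):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(rep,))
    )


def run_cell(cell, methods=("olr", "holr"), alpha=0.05, n_quad=21):
    """Run one design cell; returns a :class:`CellResult`.

    Both methods analyze the same generated dataset in every replication.
    Rejection is a 1-df uniform-DIF LR p-value below ``alpha`` for the
    studied item.
    """
    if cell.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rejects = {m: 0 for m in methods}
    valid = {m: 0 for m in methods}
    for rep in range(cell.n_reps):
        rng = _rep_rng(cell.base_seed, rep)
        data, bank, _ = simulate_dataset(
            cell.n_clusters, cell.cluster_size, cell.icc, cell.dif,
            cell.level, disc=cell.disc, rng=rng,
        )
        item = bank.studied_item
        for method in methods:
            if method == "olr":
                r = olr_dif_test(data, item, test="uniform", alpha=alpha,
                                 compute_se=False)
            elif method == "holr":
                r = holr_dif_test(data, item, level=cell.level, test="uniform",
                                  alpha=alpha, n_quad=n_quad, compute_se=False)
            else:
                raise ValueError(f"unknown method {method!r}")
            if r.valid:
                valid[method] += 1
                rejects[method] += int(r.flagged)
    result = CellResult(cell)
    for m in methods:
        if valid[m] == 0:
            raise RuntimeError(
                f"all {cell.n_reps} fits failed for method {m!r} in cell {cell}"
            )
        rate = rejects[m] / valid[m]
        result.methods[m] = MethodResult(
            rejection_rate=rate,
            n_valid_reps=valid[m],
            n_failed_fits=cell.n_reps - valid[m],
            mc_standard_error=float(np.sqrt(rate * (1 - rate) / valid[m])),
        )
        if cell.n_reps != valid[m]:
            logger.info("cell %s method %s: %d failed fits",
                        cell, m, cell.n_reps - valid[m])
    return result


def design_cells(factors, n_reps, base_seed):
    """Cross-product of factor levels -> list of Cells with derived seeds.

    ``factors`` maps any of icc / n_clusters / cluster_size / dif / disc /
    level to a list of levels; missing factors take the full design domain
    for numeric factors and 'low'/'within' defaults otherwise.
    """
    from itertools import product

    defaults = {
        "icc": _DESIGN_DOMAINS["icc"],
        "n_clusters": _DESIGN_DOMAINS["n_clusters"],
        "cluster_size": _DESIGN_DOMAINS["cluster_size"],
        "dif": _DESIGN_DOMAINS["dif"],
        "disc": ("low",),
        "level": ("within",),
    }
    levels = {k: tuple(factors.get(k, v)) for k, v in defaults.items()}
    keys = list(levels)
    cells = []
    for idx, combo in enumerate(product(*(levels[k] for k in keys))):
        seed = int(
            np.random.SeedSequence(
                entropy=base_seed, spawn_key=(idx,)
            ).generate_state(1)[0] % (2**31)
        )
        cells.append(Cell(**dict(zip(keys, combo)), n_reps=n_reps, base_seed=seed))
    return cells


def run_design(
    cells,
    methods=("olr", "holr"),
    alpha=0.05,
    n_quad=21,
    out=None,
    resume=False,
):
    """Run a list of cells; returns a tidy long-format DataFrame.

    One row per cell x method with the factors, rejection rate, Monte-Carlo
    standard error, and valid/failed counts.  With ``out`` set, rows are
    checkpointed to CSV after each cell; ``resume=True`` skips cells already
    present in that file.  A failing cell is logged and skipped rather than
    aborting the design.
    """
    factor_cols = ["icc", "n_clusters", "cluster_size", "dif", "disc", "level"]
    done = set()
    rows = []
    if resume and out is not None:
        try:
            prev = pd.read_csv(out)
            rows = prev.to_dict("records")
            done = {tuple(r[c] for c in factor_cols) for r in rows}
        except FileNotFoundError:
            pass
    for cell in cells:
        key = (cell.icc, cell.n_clusters, cell.cluster_size, cell.dif,
               cell.disc, cell.level)
        if key in done:
            continue
        try:
            res = run_cell(cell, methods=methods, alpha=alpha, n_quad=n_quad)
        except Exception:
            logger.exception("cell %s failed; continuing", cell)
            continue
        rows.extend(res.to_rows())
        if out is not None:
            pd.DataFrame(rows).to_csv(out, index=False)
    return pd.DataFrame(rows)
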