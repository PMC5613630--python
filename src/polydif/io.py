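"""Reading and writing datasets and results.

Datasets are delimited text (CSV/TSV) with one row per person: item response
columns (integer-coded 0..K-1), a cluster-id column, and one or more group
columns each declared at a level ('within' or 'between').  A
:class:`DatasetSchema` names these columns and drives validation; reading
returns the in-memory :class:`~polydif.simulate.ResponseData` consumed by
all fitters.  Rows with missing values in the analyzed columns are dropped
(listwise deletion) with a logged count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ResponseData

__all__ = ["DatasetSchema", "SchemaError", "read_dataset", "write_dataset",
           "write_results", "read_results", "results_frame"]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Dataset does not match its declared schema."""


@dataclass
class DatasetSchema:
    """Declared structure of a delimited DIF dataset.

    ``group_columns`` maps column name -> level ('within' or 'between');
    ``reverse_coded`` lists item columns to recode x -> (K-1) - x on read
    (instruments scored so that higher raw responses mean *less* of the
    construct, e.g. symptom frequency scales rescored to quality of life).
    """

    item_columns: list
    cluster_column: str
    group_columns: dict
    n_categories: int = 5
    reverse_coded: list = field(default_factory=list)

    def __post_init__(self):
        for g, level in self.group_columns.items():
            if level not in ("within", "between"):
                raise SchemaError(f"group {g!r}: level must be 'within'/'between'")
        unknown = set(self.reverse_coded) - set(self.item_columns)
        if unknown:
            raise SchemaError(f"reverse_coded names unknown items: {sorted(unknown)}")


def read_dataset(path, schema, group=None, sep=None):
    """Read and validate a delimited dataset; returns a ResponseData.

    ``group`` picks which declared group column to attach (default: the first
    declared).  Validation errors name the offending row/column.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if group is None:
        group = next(iter(schema.group_columns))
    if group not in schema.group_columns:
        raise SchemaError(f"group column {group!r} not declared in schema")
    needed = list(schema.item_columns) + [schema.cluster_column, group]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    n0 = len(df)
    df = df.dropna(subset=needed)
    if len(df) < n0:
        logger.info("%s: dropped %d rows with missing values", path, n0 - len(df))
    if not len(df):
        raise SchemaError(f"{path}: no complete rows")

    K = schema.n_categories
    resp = df[schema.item_columns].to_numpy()
    for col_i, col in enumerate(schema.item_columns):
        vals = resp[:, col_i]
        if not np.all(np.equal(np.mod(vals, 1), 0)):
            bad = df.index[np.mod(vals, 1) != 0][0]
            raise SchemaError(f"column {col!r}, row {bad}: non-integer response")
        out = (vals < 0) | (vals > K - 1)
        if out.any():
            bad = df.index[out][0]
            raise SchemaError(
                f"column {col!r}, row {bad}: value {vals[out][0]!r} outside 0..{K - 1}"
            )
    resp = resp.astype(np.int64)
    for col in schema.reverse_coded:
        j = schema.item_columns.index(col)
        resp[:, j] = (K - 1) - resp[:, j]

    gvals = df[group].to_numpy()
    uniq = np.unique(gvals)
    if uniq.size != 2:
        raise SchemaError(f"group {group!r} must be binary; found {uniq.tolist()}")
    gbin = (gvals == uniq[1]).astype(np.int64)
    cluster = df[schema.cluster_column].to_numpy()
    level = schema.group_columns[group]
    if level == "between":
        for j in np.unique(cluster):
            g = gbin[cluster == j]
            if not np.all(g == g[0]):
                raise SchemaError(
                    f"group {group!r} declared between-cluster but varies "
                    f"within cluster {j!r}"
                )
    return ResponseData(resp, cluster, gbin, level,
                        item_names=list(schema.item_columns))


def write_dataset(data, path, truth=None):
    """Write a ResponseData as long-format CSV (person_id, cluster_id, group,
    item columns) plus an optional JSON truth sidecar (bank parameters, ICC,
    DIF settings, seed) next to it."""
    path = Path(path)
    data.to_frame().to_csv(path, index=False)
    if truth is not None:
        sidecar = path.with_suffix(".truth.json")
        sidecar.write_text(json.dumps(truth, indent=2, default=_json_default))
        return sidecar
    return None


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sig6(x):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return x
    return float(f"{x:.6g}") if isinstance(x, float) else x


def results_frame(results):
    """DIFResult collection -> tidy DataFrame, ordered by (item, method)."""
    rows = []
    for r in sorted(results, key=lambda r: (r.item, r.method)):
        d = r.to_dict()
        d.pop("fits", None)
        rows.append({k: _sig6(v) for k, v in d.items()})
    cols = ["item", "method", "test", "level", "beta_group", "beta_group_se",
            "chi_square", "df", "p_value", "flagged", "alpha", "valid", "message"]
    return pd.DataFrame(rows, columns=cols)


def write_results(results, path, format=None):
    """Write DIF results to CSV (item, beta, chi-square, p layout) or JSON.

    Ordering is bit-stable (item index, then method); floats are rounded to
    6 significant digits.  JSON keeps the full fit metadata.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        results_frame(results).to_csv(path, index=False)
    elif fmt == "json":
        payload = [
            {k: _sig6(v) if isinstance(v, float) else v for k, v in r.to_dict().items()}
            for r in sorted(results, key=lambda r: (r.item, r.method))
        ]
        path.write_text(json.dumps(payload, indent=2, default=_json_default))
    else:
        raise ValueError("format must be 'csv' or 'json'")


def read_results(path):
    """Read back a results file written by :func:`write_results`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    return pd.read_csv(path)
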