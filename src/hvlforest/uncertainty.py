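"""Per-object uncertainty measures for regression forests.

Three measures are provided, all on a per-prediction basis (higher =
less certain):

* **HVL fraction** — the share of trees whose active terminal leaf is a
  *high-variance leaf* (HVL): a leaf whose member-output standard
  deviation strictly exceeds a threshold, by default half the output
  standard deviation of the dataset. Activity-cliff-like regions, where
  similar inputs carry very different outputs, inflate leaf variance, so
  a prediction drawing on many HVLs sits in an area that is hard to
  model. The fraction lies in [0, 1] by construction.
* **SDEP** — the standard deviation of the ensemble's single-tree
  predictions around their mean, the customary forest uncertainty
  baseline. Uses the population divisor ``T``: it describes the spread
  of a fixed, fully observed ensemble, not an estimate from a sample.
* **mean leaf spread** — a continuous variant of the HVL idea: the
  active leaves' standard deviations averaged over trees, with no
  cutoff to choose, at the price of an unbounded scale.

Leaf standard deviations, in contrast to SDEP, use the sample divisor
``n - 1``; leaves hold at least two member outputs precisely so that
this is defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputError
from .forest import ForestHandle, LeafTable, tree_predictions

__all__ = [
    "HvlThreshold",
    "hvl_threshold",
    "flag_hvls",
    "hvl_fraction",
    "sdep",
    "mean_leaf_std",
    "uncertainty_records",
]


@dataclass(frozen=True)
class HvlThreshold:
    """A leaf-variance cutoff: ``value = factor * reference_std``."""

    value: float
    factor: float
    reference_std: float


def hvl_threshold(y, factor: float = 0.5) -> HvlThreshold:
    """Half-sigma rule: the HVL cutoff for a dataset's output vector.

    Returns ``factor`` times the sample standard deviation of ``y``.
    A constant ``y`` yields threshold 0 (with a warning): every leaf
    with any output variation would be flagged.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.size < 2:
        raise InputError("need at least 2 outputs to form a standard deviation")
    if factor <= 0:
        raise InputError(f"factor must be positive, got {factor}")
    ref = float(np.std(y, ddof=1))
    if ref == 0.0:
        warnings.warn(
            "output vector is constant: HVL threshold is 0, so every leaf "
            "with any output variation will be flagged",
            stacklevel=2,
        )
    return HvlThreshold(value=factor * ref, factor=factor, reference_std=ref)


def flag_hvls(table: LeafTable, threshold: HvlThreshold) -> LeafTable:
    """Mark each populated leaf whose std *strictly* exceeds the threshold.

    Equality is not an HVL. Returns a new table; the input is untouched.
    """
    if threshold.value < 0:
        raise InputError("threshold value must be non-negative")
    out = table.copy()
    for t in range(out.n_trees):
        populated = out.counts[t] > 0
        with np.errstate(invalid="ignore"):
            out.is_hvl[t] = populated & (out.stds[t] > threshold.value)
    out.threshold_value = threshold.value
    return out


def _check_assignment(assignment: np.ndarray, table: LeafTable) -> None:
    if assignment.ndim != 2:
        raise InputError("leaf assignment must be a 2-D (objects x trees) matrix")
    if assignment.shape[1] != table.n_trees:
        raise InputError(
            f"assignment has {assignment.shape[1]} trees, table has {table.n_trees}"
        )
    for t in range(table.n_trees):
        col = assignment[:, t]
        n_nodes = table.counts[t].shape[0]
        bad = (col < 0) | (col >= n_nodes)
        if not bad.any():
            bad = table.counts[t][col] == 0
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ConsistencyError(tree=t, leaf=int(col[i]))


def hvl_fraction(assignment: np.ndarray, table: LeafTable) -> np.ndarray:
    """Fraction of trees whose active leaf is flagged, per object."""
    _check_assignment(assignment, table)
    flags = table.lookup(assignment, "is_hvl")
    return flags.mean(axis=1)


def mean_leaf_std(
    assignment: np.ndarray,
    table: LeafTable,
    scale: Literal["std", "variance"] = "std",
) -> np.ndarray:
    """Average spread of the active leaves, per object.

    ``scale="std"`` (default) averages the leaf standard deviations so
    the result shares units with the outputs and with the HVL
    threshold; ``scale="variance"`` averages the squared spreads.
    """
    _check_assignment(assignment, table)
    stds = table.lookup(assignment, "std")
    if scale == "variance":
        return (stds**2).mean(axis=1)
    if scale != "std":
        raise InputError(f"unknown scale {scale!r}")
    return stds.mean(axis=1)


def sdep(forest: ForestHandle, X) -> np.ndarray:
    """Population standard deviation of the single-tree predictions.

    The accompanying point prediction is the arithmetic mean of the same
    per-tree predictions (identical to the forest's ``predict``).
    """
    preds = tree_predictions(forest, X)
    return preds.std(axis=1, ddof=0)


def uncertainty_records(
    forest: ForestHandle,
    X,
    table: LeafTable,
    ids: Sequence | None = None,
) -> pd.DataFrame:
    """All measures for a query set, as a tidy per-object table.

    Columns: ``id, prediction, sdep, hvl_fraction, mean_leaf_std``. The
    table must already carry HVL flags (see :func:`flag_hvls`).
    """
    from .forest import apply_leaves

    preds = tree_predictions(forest, X)
    assignment = apply_leaves(forest, X)
    frame = pd.DataFrame(
        {
            "id": np.arange(preds.shape[0]) if ids is None else list(ids),
            "prediction": preds.mean(axis=1),
            "sdep": preds.std(axis=1, ddof=0),
            "hvl_fraction": hvl_fraction(assignment, table),
            "mean_leaf_std": mean_leaf_std(assignment, table),
        }
    )
    return frame
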