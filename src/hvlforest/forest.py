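"""Leaf-level introspection of fitted regression forests.

A random forest hides most of its internal structure behind ``predict``.
The high-variance-leaf (HVL) uncertainty measure needs two things that a
standard interface does not expose directly:

* which terminal leaf each query object reaches in every tree, and
* which training outputs populate each leaf, so the leaf's output
  standard deviation can be computed from the *raw* member outputs
  rather than from whatever value the tree stores in the leaf.

Tree induction itself is delegated to scikit-learn's
:class:`~sklearn.ensemble.RandomForestRegressor`; this module only wraps
the fitted ensemble in :class:`ForestHandle` and derives the per-leaf
statistics (:class:`LeafTable`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import InputError, LeafContractError

MembershipMode = Literal["inbag", "all_train"]

__all__ = [
    "ForestConfig",
    "ForestHandle",
    "LeafTable",
    "fit_forest",
    "apply_leaves",
    "build_leaf_table",
    "tree_predictions",
]


@dataclass(frozen=True)
class ForestConfig:
    """Settings for growing the regression forest.

    ``n_trees`` and ``min_samples_leaf`` default to the protocol used
    throughout this package: 500 trees and a minimum of two samples per
    leaf, the smallest leaf that still admits a standard deviation.
    Remaining growth parameters (feature subsetting, bootstrap draw)
    follow the scikit-learn defaults; no hyperparameter tuning is done.
    """

    n_trees: int = 500
    min_samples_leaf: int = 2
    max_features: float | int | str | None = 1.0
    n_jobs: int | None = None


@dataclass
class ForestHandle:
    """A fitted ensemble plus the bookkeeping the HVL measure needs.

    Attributes
    ----------
    model:
        The fitted ``RandomForestRegressor``.
    inbag_indices:
        Per tree, the bootstrap-drawn training-row indices *with
        multiplicity* (a multiset of size ``n_train``).
    training_features, training_outputs:
        The arrays the forest was grown on; kept so member samples can be
        re-routed through each tree when building a :class:`LeafTable`.
    """

    model: RandomForestRegressor
    inbag_indices: list[np.ndarray]
    training_features: np.ndarray
    training_outputs: np.ndarray
    config: ForestConfig
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.model.estimators_)

    @property
    def n_features(self) -> int:
        return self.model.n_features_in_


@dataclass
class LeafTable:
    """Per-(tree, leaf) sample count, output standard deviation, HVL flag.

    Stored densely as one array per tree indexed by node id; nodes that
    are not populated leaves are masked out. ``std`` uses the sample
    convention (divisor ``n - 1``), which is why every populated leaf
    must contain at least two member outputs.
    """

    counts: list[np.ndarray]     # per tree: member count per node id
    stds: list[np.ndarray]       # per tree: sample std per node id (nan if unpopulated)
    is_hvl: list[np.ndarray]     # per tree: bool per node id
    membership_mode: MembershipMode = "inbag"
    threshold_value: float | None = field(default=None)

    @property
    def n_trees(self) -> int:
        return len(self.counts)

    def copy(self) -> "LeafTable":
        return LeafTable(
            counts=[c.copy() for c in self.counts],
            stds=[s.copy() for s in self.stds],
            is_hvl=[h.copy() for h in self.is_hvl],
            membership_mode=self.membership_mode,
            threshold_value=self.threshold_value,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a tidy table with columns tree, leaf, count, std, is_hvl."""
        rows = []
        for t, counts in enumerate(self.counts):
            leaves = np.flatnonzero(counts > 0)
            rows.append(
                pd.DataFrame(
                    {
                        "tree": t,
                        "leaf": leaves,
                        "count": counts[leaves],
                        "std": self.stds[t][leaves],
                        "is_hvl": self.is_hvl[t][leaves],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def lookup(self, assignment: np.ndarray, what: Literal["std", "is_hvl", "count"]) -> np.ndarray:
        """Gather a per-leaf statistic for every entry of a leaf-assignment matrix."""
        source = {"std": self.stds, "is_hvl": self.is_hvl, "count": self.counts}[what]
        out = np.empty(assignment.shape, dtype=source[0].dtype)
        for t in range(assignment.shape[1]):
            out[:, t] = source[t][assignment[:, t]]
        return out


def _as_2d_float(X, name: str = "X") -> np.ndarray:
    arr = np.asarray(X)
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        try:
            arr = arr.astype(float)
        except (TypeError, ValueError) as exc:
            raise InputError(f"{name} must be numeric: {exc}") from exc
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise InputError(f"{name} must be a 2-D feature matrix, got ndim={arr.ndim}")
    if not np.isfinite(arr).all():
        raise InputError(f"{name} contains non-finite values")
    return arr


def fit_forest(
    X,
    y,
    config: ForestConfig | None = None,
    seed: int = 0,
) -> ForestHandle:
    """Grow a regression forest and record per-tree in-bag multisets.

    Trees are grown on bootstrap samples; identical ``(X, y, config,
    seed)`` reproduce an identical forest. Raises :class:`InputError`
    for non-numeric features or fewer than ``2 * min_samples_leaf``
    rows, which cannot populate even a single valid leaf.
    """
    config = config or ForestConfig()
    X = _as_2d_float(X)
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(y) != X.shape[0]:
        raise InputError(f"y has {len(y)} entries but X has {X.shape[0]} rows")
    if X.shape[0] < 2 * config.min_samples_leaf:
        raise InputError(
            f"need at least {2 * config.min_samples_leaf} rows to fit "
            f"(min_samples_leaf={config.min_samples_leaf}); got {X.shape[0]}"
        )
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_samples_leaf,
        max_features=config.max_features,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=config.n_jobs,
    )
    model.fit(X, y)
    inbag = [np.asarray(s, dtype=np.intp) for s in model.estimators_samples_]
    return ForestHandle(
        model=model,
        inbag_indices=inbag,
        training_features=X,
        training_outputs=y,
        config=config,
        seed=int(seed),
    )


def apply_leaves(forest: ForestHandle, X) -> np.ndarray:
    """Route objects through every tree; entry (i, t) is the leaf of tree t.

    Leaf identifiers are the node indices of the underlying trees; they
    are only meaningful relative to the forest that produced them.
    """
    X = _as_2d_float(X)
    if X.shape[1] != forest.n_features:
        raise InputError(
            f"X has {X.shape[1]} columns but the forest was trained on "
            f"{forest.n_features}"
        )
    return forest.model.apply(X)


def tree_predictions(forest: ForestHandle, X) -> np.ndarray:
    """Matrix of single-tree predictions, shape (n_objects, n_trees)."""
    X = _as_2d_float(X)
    if X.shape[1] != forest.n_features:
        raise InputError(
            f"X has {X.shape[1]} columns but the forest was trained on "
            f"{forest.n_features}"
        )
    return np.column_stack([est.predict(X) for est in forest.model.estimators_])


def _grouped_count_std(leaves: np.ndarray, outputs: np.ndarray, n_nodes: int):
    """Member count and sample std (ddof=1) per node id, two-pass for stability."""
    counts = np.bincount(leaves, minlength=n_nodes)
    sums = np.bincount(leaves, weights=outputs, minlength=n_nodes)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    dev2 = (outputs - means[leaves]) ** 2
    ss = np.bincount(leaves, weights=dev2, minlength=n_nodes)
    stds = np.full(n_nodes, np.nan)
    ok = counts >= 2
    stds[ok] = np.sqrt(ss[ok] / (counts[ok] - 1))
    return counts, stds


def build_leaf_table(
    forest: ForestHandle,
    y_train: Sequence[float] | np.ndarray | None = None,
    membership_mode: MembershipMode = "inbag",
) -> LeafTable:
    """Collect raw member outputs per (tree, leaf) and their spread.

    Under ``inbag`` (the default) a tree's members are its bootstrap
    multiset — the samples whose error that tree minimized locally —
    routed from the root; under ``all_train`` every training sample is
    routed through every tree. In both modes the statistic is the sample
    standard deviation of the raw outputs, never the value the tree
    stores in the leaf: leaf values may be post-processed by the
    learner, which would understate the local output fluctuation.

    Raises :class:`LeafContractError` if any populated leaf ends up with
    fewer than two member outputs (possible only when the forest was
    grown with ``min_samples_leaf < 2``).
    """
    if membership_mode not in ("inbag", "all_train"):
        raise InputError(f"unknown membership_mode {membership_mode!r}")
    y = (
        forest.training_outputs
        if y_train is None
        else np.asarray(y_train, dtype=np.float64).ravel()
    )
    n_train = forest.training_features.shape[0]
    if len(y) != n_train:
        raise InputError(
            f"y_train has {len(y)} entries but the forest was grown on {n_train} rows"
        )
    counts_all: list[np.ndarray] = []
    stds_all: list[np.ndarray] = []
    flags_all: list[np.ndarray] = []
    for t, est in enumerate(forest.model.estimators_):
        leaves_train = est.apply(forest.training_features)
        members = (
            forest.inbag_indices[t]
            if membership_mode == "inbag"
            else np.arange(n_train)
        )
        counts, stds = _grouped_count_std(
            leaves_train[members], y[members], est.tree_.node_count
        )
        is_leaf_node = est.tree_.children_left == -1
        bad = np.flatnonzero(is_leaf_node & (counts > 0) & (counts < 2))
        if bad.size:
            raise LeafContractError(tree=t, leaf=int(bad[0]), count=int(counts[bad[0]]))
        counts_all.append(counts)
        stds_all.append(np.where(counts > 0, stds, np.nan))
        flags_all.append(np.zeros(est.tree_.node_count, dtype=bool))
    return LeafTable(
        counts=counts_all,
        stds=stds_all,
        is_hvl=flags_all,
        membership_mode=membership_mode,
    )
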