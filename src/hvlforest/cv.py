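"""Single k-fold cross-validation producing test- and train-side statistics.

The protocol: objects are partitioned into k random folds (k = 10 by
default). Per fold, columns that are constant over the training split
are dropped (they carry no information, and binary fingerprints produce
many of them), a 500-tree forest with min-2-samples-per-leaf is fitted
on the training split, the leaf table is built and flagged, and both
splits are pushed through the forest. Each object therefore receives
exactly one test prediction and k - 1 train-side predictions; the
train-side predictions are averaged, and the train-side HVL occurrences
are summed and divided by the total ensemble size they could occur in,
``n_trees * (k - 1)`` — 500 * 9 = 4500 at the defaults.

The HVL threshold is, by default, half the output standard deviation of
the *whole* dataset (``threshold_mode="whole_dataset"``). That
convention lets the threshold see the test outputs; a leakage-free
``fold_train`` mode computing it from the training split only is
provided as the alternative. Features are never scaled — forests do not
require standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .errors import InputError
from .forest import (
    ForestConfig,
    apply_leaves,
    build_leaf_table,
    fit_forest,
    tree_predictions,
)
from .metrics import DEFAULT_FRACTIONS, EvalReport, evaluate_measures
from .uncertainty import flag_hvls, hvl_fraction, hvl_threshold, mean_leaf_std

logger = logging.getLogger(__name__)

__all__ = [
    "CvConfig",
    "CvResult",
    "drop_constant_columns",
    "run_cv",
    "evaluate_cv_result",
    "pic50_transform",
    "summarize_across_cases",
]


@dataclass(frozen=True)
class CvConfig:
    k_folds: int = 10
    n_trees: int = 500
    min_samples_leaf: int = 2
    hvl_factor: float = 0.5
    threshold_mode: Literal["whole_dataset", "fold_train"] = "whole_dataset"
    membership_mode: Literal["inbag", "all_train"] = "inbag"
    seed: int = 0
    n_jobs: int | None = None

    @property
    def train_side_denominator(self) -> int:
        """Total ensemble members an object's train-side HVLs can occur in."""
        return self.n_trees * (self.k_folds - 1)

    def forest_config(self) -> ForestConfig:
        return ForestConfig(
            n_trees=self.n_trees,
            min_samples_leaf=self.min_samples_leaf,
            n_jobs=self.n_jobs,
        )


@dataclass
class CvResult:
    """Per-object cross-validated statistics plus per-fold bookkeeping.

    ``records`` has one row per object (input order preserved):
    test_prediction, test_sdep, test_hvl_fraction, test_mean_leaf_std,
    train_prediction_mean, train_hvl_fraction. ``dropped_columns`` and
    ``thresholds`` are per-fold lists.
    """

    records: pd.DataFrame
    dropped_columns: list[list[int]]
    thresholds: list[float]
    config: CvConfig

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def drop_constant_columns(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove columns constant over the training split.

    Returns the reduced matrix and the *dropped* column indices; apply
    the same drop to the fold's test split. Surviving column order is
    preserved. A training split with no informative column at all cannot
    be fitted.
    """
    X_train = np.asarray(X_train)
    if X_train.ndim != 2:
        raise InputError("X_train must be 2-D")
    constant = (X_train == X_train[0:1, :]).all(axis=0)
    if constant.all():
        raise InputError("every feature column is constant on this training split")
    dropped = np.flatnonzero(constant)
    return X_train[:, ~constant], dropped


def pic50_transform(ic50) -> np.ndarray:
    """IC50 (molar) to pIC50: element-wise -log10."""
    arr = np.asarray(ic50, dtype=np.float64)
    if (arr <= 0).any():
        raise InputError("IC50 values must be strictly positive")
    return -np.log10(arr)


def run_cv(X, y, config: CvConfig | None = None) -> CvResult:
    """Run the full k-fold protocol; deterministic given (X, y, config)."""
    config = config or CvConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = X.shape[0]
    if len(y) != n:
        raise InputError("X and y are misaligned")
    if config.k_folds < 2 or config.k_folds > n:
        raise InputError(f"k_folds must lie in [2, {n}], got {config.k_folds}")

    test_pred = np.full(n, np.nan)
    test_sdep = np.full(n, np.nan)
    test_hvl = np.full(n, np.nan)
    test_mls = np.full(n, np.nan)
    train_pred_sum = np.zeros(n)
    train_hvl_count = np.zeros(n)
    train_models = np.zeros(n, dtype=int)

    dropped_per_fold: list[list[int]] = []
    thresholds: list[float] = []
    splitter = KFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X)):
        try:
            X_tr_red, dropped = drop_constant_columns(X[train_idx])
            keep = np.setdiff1d(np.arange(X.shape[1]), dropped)
            X_te_red = X[np.ix_(test_idx, keep)]

            forest = fit_forest(
                X_tr_red,
                y[train_idx],
                config.forest_config(),
                seed=config.seed + fold,
            )
            thr_y = y if config.threshold_mode == "whole_dataset" else y[train_idx]
            threshold = hvl_threshold(thr_y, factor=config.hvl_factor)
            table = flag_hvls(
                build_leaf_table(forest, membership_mode=config.membership_mode),
                threshold,
            )

            te_preds = tree_predictions(forest, X_te_red)
            te_assign = apply_leaves(forest, X_te_red)
            test_pred[test_idx] = te_preds.mean(axis=1)
            test_sdep[test_idx] = te_preds.std(axis=1, ddof=0)
            test_hvl[test_idx] = hvl_fraction(te_assign, table)
            test_mls[test_idx] = mean_leaf_std(te_assign, table)

            tr_preds = tree_predictions(forest, X_tr_red)
            tr_assign = apply_leaves(forest, X_tr_red)
            train_pred_sum[train_idx] += tr_preds.mean(axis=1)
            train_hvl_count[train_idx] += hvl_fraction(tr_assign, table) * config.n_trees
            train_models[train_idx] += 1
        except Exception as exc:
            exc.add_note(f"raised while processing fold {fold}")
            raise

        logger.info(
            "fold %d: train=%d test=%d dropped_columns=%d threshold=%.6g",
            fold, len(train_idx), len(test_idx), len(dropped), threshold.value,
        )
        dropped_per_fold.append([int(c) for c in dropped])
        thresholds.append(threshold.value)

    assert (train_models == config.k_folds - 1).all()
    records = pd.DataFrame(
        {
            "test_prediction": test_pred,
            "test_sdep": test_sdep,
            "test_hvl_fraction": test_hvl,
            "test_mean_leaf_std": test_mls,
            "train_prediction_mean": train_pred_sum / (config.k_folds - 1),
            "train_hvl_fraction": train_hvl_count / config.train_side_denominator,
        }
    )
    return CvResult(
        records=records,
        dropped_columns=dropped_per_fold,
        thresholds=thresholds,
        config=config,
    )


def evaluate_cv_result(
    result: CvResult,
    y,
    measures: Sequence[str] = ("test_hvl_fraction", "test_sdep"),
    coverage: float = 0.5,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> EvalReport:
    """Score the test predictions' uncertainty measures against residuals."""
    y = np.asarray(y, dtype=np.float64).ravel()
    residuals = y - result.records["test_prediction"].to_numpy()
    ums = {m: result.records[m].to_numpy() for m in measures}
    return evaluate_measures(residuals, ums, coverage=coverage, fractions=fractions)


def summarize_across_cases(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Mean and std of MSE0-normalized fraction MSEs over several cases.

    Each case's fraction MSEs are divided by that case's MSE0 before
    averaging, so datasets with different error scales contribute
    equally. Returns a table indexed by (measure, fraction) with columns
    ``mean`` and ``std`` (population convention).
    """
    if not reports:
        raise InputError("need at least one report")
    rows = []
    for rep in reports:
        if rep.mse0 == 0:
            raise InputError("a case has MSE0 = 0; normalization undefined")
        for measure, by_frac in rep.mse_at_fraction.items():
            for frac, value in by_frac.items():
                rows.append(
                    {"measure": measure, "fraction": frac, "norm_mse": value / rep.mse0}
                )
    long = pd.DataFrame(rows)
    return (
        long.groupby(["measure", "fraction"])["norm_mse"]
        .agg(mean="mean", std=lambda s: float(np.std(s, ddof=0)))
        .reset_index()
    )
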