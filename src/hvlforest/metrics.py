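"""Confidence curves and the AUCO framework for scoring uncertainty measures.

An uncertainty measure (UM) is good if discarding the predictions it
deems least certain removes the largest errors. The *confidence curve*
makes this operational: sort predictions from least to most certain,
remove them one at a time, and recompute the MSE of the remainder after
every single removal. The *oracle* curve sorts by descending absolute
residual — the best achievable removal order — and is monotone
non-increasing. The area between a measure's curve and the oracle curve
up to a coverage (50% by default: **AUCO50**, a unit-step rectangle sum)
scores the measure; smaller is better, and it is non-negative because no
ordering beats the oracle at any step. Full-coverage areas are avoided:
deep in the tail the MSE divides by very few remaining objects and the
curve turns erratic.

Also here: MSEs at fixed removal fractions (MSE5 … MSE90), the relative
AUCO (one measure's area as a percentage of another's), Pearson
correlation between measures, and the plain MSE / R² used to report
predictive quality. R² takes an explicit ``ybar`` so that train- and
test-side values can both be anchored at the whole-dataset output mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = [
    "ConfidenceCurve",
    "EvalReport",
    "confidence_curve",
    "oracle_curve",
    "auco",
    "mse_at_fractions",
    "relative_auco",
    "pearson_r",
    "mse",
    "r_squared",
    "evaluate_measures",
]

DEFAULT_FRACTIONS = (0.0, 0.05, 0.10, 0.20, 0.50, 0.90)


@dataclass(frozen=True)
class ConfidenceCurve:
    """Remaining-set MSE after removing the k most-uncertain predictions.

    ``mse_at_k[k]`` is the MSE of the ``n - k`` predictions left after
    removing ``k``; entry 0 is the MSE of all predictions (MSE0). The
    curve runs to ``k = n - 1`` internally even when only a shallower
    coverage is reported, because the deep fractions (e.g. MSE90) live
    in the tail.
    """

    label: str
    mse_at_k: np.ndarray
    n: int

    @property
    def mse0(self) -> float:
        return float(self.mse_at_k[0])


def _validate_vectors(residuals, um) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(residuals, dtype=np.float64).ravel()
    u = np.asarray(um, dtype=np.float64).ravel()
    if r.size != u.size:
        raise InputError(f"residuals ({r.size}) and um ({u.size}) differ in length")
    if r.size < 2:
        raise InputError("need at least 2 predictions to build a curve")
    if not (np.isfinite(r).all() and np.isfinite(u).all()):
        raise InputError("residuals and um must be finite")
    return r, u


def confidence_curve(
    residuals, um, label: str = "um", tie_seed: int | None = None
) -> ConfidenceCurve:
    """Curve for one measure: remove in descending-UM order (stable ties).

    The largest UM value (the least certain prediction) is removed
    first; ties keep their original input order, so results are
    reproducible for coarse measures with many equal values. Passing a
    ``tie_seed`` instead randomizes the order *within* tied UM values —
    useful for probing how much a result owes to the arbitrary
    within-tie order.
    """
    r, u = _validate_vectors(residuals, um)
    if tie_seed is None:
        order = np.argsort(-u, kind="stable")
    else:
        perm = np.random.default_rng(tie_seed).permutation(r.size)
        order = np.lexsort((perm, -u))  # primary: descending um; ties: random
    sq = r[order] ** 2
    n = r.size
    # suffix sums via a reversed running sum: no cancellation, so entries
    # that should be exactly zero (only zero residuals remain) are zero
    remaining_sum = np.cumsum(sq[::-1])[::-1]
    remaining_n = np.arange(n, 0, -1, dtype=np.float64)
    return ConfidenceCurve(label=label, mse_at_k=remaining_sum / remaining_n, n=n)


def oracle_curve(residuals) -> ConfidenceCurve:
    """Ideal curve: remove by descending absolute residual."""
    r = np.asarray(residuals, dtype=np.float64).ravel()
    return confidence_curve(r, np.abs(r), label="oracle")


def auco(
    um_curve: ConfidenceCurve,
    ideal: ConfidenceCurve,
    coverage: float = 0.5,
) -> float:
    """Area between a measure's curve and the oracle up to a coverage.

    Unit-step rectangle sum of ``um - oracle`` over ``k = 0 ..
    floor(coverage * n)``. Both curves must come from the same residual
    multiset; the area is then non-negative.
    """
    if um_curve.n != ideal.n:
        raise InputError(
            f"curves built on different sizes ({um_curve.n} vs {ideal.n})"
        )
    if not (0.0 < coverage <= 1.0):
        raise InputError(f"coverage must lie in (0, 1], got {coverage}")
    k_max = min(int(np.floor(coverage * um_curve.n)), um_curve.n - 1)
    diff = um_curve.mse_at_k[: k_max + 1] - ideal.mse_at_k[: k_max + 1]
    return float(diff.sum())


def mse_at_fractions(
    curve: ConfidenceCurve,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
) -> dict[float, float]:
    """MSE after removing a fraction f of predictions, at k = floor(f*n)."""
    out: dict[float, float] = {}
    for f in fractions:
        if not (0.0 <= f < 1.0):
            raise InputError(f"removal fraction must lie in [0, 1), got {f}")
        k = int(np.floor(f * curve.n))
        if k > curve.n - 1:
            raise InputError(f"fraction {f} removes all predictions at n={curve.n}")
        out[float(f)] = float(curve.mse_at_k[k])
    return out


def relative_auco(um_area: float, baseline_area: float) -> float:
    """One measure's area as a percentage of a baseline's (100 = parity)."""
    if baseline_area == 0:
        raise InputError(
            "baseline AUCO is 0 (the baseline matches the oracle); "
            "the relative area is undefined"
        )
    return 100.0 * um_area / baseline_area


def pearson_r(u, v) -> float:
    """Product-moment correlation between two per-object measure vectors."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.size != v.size:
        raise InputError("vectors differ in length")
    if u.size < 3:
        raise InputError("need at least 3 pairs for a correlation")
    if np.std(u) == 0 or np.std(v) == 0:
        raise InputError("correlation is undefined for a constant vector")
    return float(stats.pearsonr(u, v).statistic)


def mse(y, yhat) -> float:
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.size != yhat.size:
        raise InputError("y and yhat differ in length")
    if y.size == 0:
        raise InputError("empty input")
    return float(np.mean((y - yhat) ** 2))


def r_squared(y, yhat, ybar: float) -> float:
    """1 - SSE/SST with SST anchored at the supplied ``ybar``.

    Passing the whole-dataset output mean for ``ybar`` keeps train-side
    and test-side R² on the same footing when every object appears on
    both sides of a cross-validation.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.size != yhat.size:
        raise InputError("y and yhat differ in length")
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0:
        raise InputError("zero total sum of squares around ybar; R² undefined")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


@dataclass
class EvalReport:
    """Error-removal scores for a set of measures on one prediction set."""

    auco50: dict[str, float]
    mse_at_fraction: dict[str, dict[float, float]]
    mse0: float
    relative_auco50: float | None = None
    pearson: float | None = None
    coverage: float = 0.5
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "coverage": self.coverage,
            "mse0": self.mse0,
            "auco50": dict(self.auco50),
            "relative_auco50": self.relative_auco50,
            "pearson_r": self.pearson,
            "mse_at_fraction": {
                m: {str(f): v for f, v in d.items()}
                for m, d in self.mse_at_fraction.items()
            },
        }


def evaluate_measures(
    residuals,
    ums: Mapping[str, Sequence[float]],
    coverage: float = 0.5,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    relative_pair: tuple[str, str] | None = None,
) -> EvalReport:
    """Full report for several measures on one residual vector.

    ``relative_pair = (um, baseline)`` names the two measures compared
    by relative AUCO and Pearson correlation; with exactly two measures
    it defaults to them in mapping order (first relative to second).
    """
    residuals = np.asarray(residuals, dtype=np.float64).ravel()
    ideal = oracle_curve(residuals)
    curves = {m: confidence_curve(residuals, u, label=m) for m, u in ums.items()}
    areas = {m: auco(c, ideal, coverage) for m, c in curves.items()}
    fraction_mses = {m: mse_at_fractions(c, fractions) for m, c in curves.items()}
    rel = None
    r = None
    if relative_pair is None and len(ums) == 2:
        relative_pair = tuple(ums)  # type: ignore[assignment]
    if relative_pair is not None:
        a, b = relative_pair
        try:
            rel = relative_auco(areas[a], areas[b])
        except InputError as exc:  # perfect baseline: ratio undefined
            warnings.warn(str(exc), stacklevel=2)
        try:
            r = pearson_r(ums[a], ums[b])
        except InputError as exc:  # e.g. a measure constant on this set
            warnings.warn(str(exc), stacklevel=2)
    return EvalReport(
        auco50=areas,
        mse_at_fraction=fraction_mses,
        mse0=ideal.mse0,
        relative_auco50=rel,
        pearson=r,
        coverage=coverage,
        n=ideal.n,
    )
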