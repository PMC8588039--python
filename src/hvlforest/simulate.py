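"""Synthetic regression data with planted, spatially localized output variance.

Activity cliffs — near-identical compounds with very different
potencies — show up statistically as regions of feature space where the
output fluctuates far more than the background. This generator plants
exactly that structure: a smooth base signal over the unit hypercube
plus Gaussian noise whose standard deviation jumps from ``sigma_low``
to ``sigma_high`` inside one or more spherical "cliff" regions. The
``in_cliff`` indicator ships alongside the data so downstream tests can
ask whether an uncertainty measure recovers the planted region.

The base signals are deliberately tree-friendly (linear, or a sum of
low-frequency sinusoids) so that leaf variance reflects the planted
noise rather than approximation bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["CliffSpec", "generate_cliff_dataset", "cliff_frame"]


@dataclass(frozen=True)
class CliffSpec:
    """Parameters of one heteroscedastic 'cliff' dataset.

    ``cliff_center`` defaults to the middle of the unit hypercube;
    additional (center, radius) pairs can be planted via
    ``extra_cliffs``. ``sigma_high >= sigma_low`` is required — the
    cliff is a region of *elevated* noise; with equality the dataset is
    homoscedastic and ``in_cliff`` is purely geometric.
    """

    n: int = 2000
    d: int = 5
    cliff_center: Sequence[float] | None = None
    cliff_radius: float = 0.25
    sigma_low: float = 0.1
    sigma_high: float = 2.0
    base: Literal["linear", "additive_smooth"] = "linear"
    seed: int = 0
    extra_cliffs: tuple[tuple[tuple[float, ...], float], ...] = ()

    def centers_and_radii(self) -> list[tuple[np.ndarray, float]]:
        center = (
            np.full(self.d, 0.5)
            if self.cliff_center is None
            else np.asarray(self.cliff_center, dtype=float)
        )
        cliffs = [(center, float(self.cliff_radius))]
        cliffs += [(np.asarray(c, dtype=float), float(r)) for c, r in self.extra_cliffs]
        return cliffs

    def validate(self) -> None:
        if self.n < 1 or self.d < 1:
            raise InputError("n and d must be positive")
        if not (self.sigma_high >= self.sigma_low >= 0):
            raise InputError("need sigma_high >= sigma_low >= 0")
        for center, radius in self.centers_and_radii():
            if radius <= 0:
                raise InputError("cliff_radius must be positive")
            if center.shape != (self.d,):
                raise InputError(
                    f"cliff center has dimension {center.shape[0]}, expected {self.d}"
                )


def _base_signal(X: np.ndarray, base: str) -> np.ndarray:
    if base == "linear":
        return X.sum(axis=1)
    if base == "additive_smooth":
        j = np.arange(X.shape[1])
        return (np.sin(2 * np.pi * X) / (j + 1)).sum(axis=1)
    raise InputError(f"unknown base signal {base!r}")


def generate_cliff_dataset(
    spec: CliffSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (X, y, in_cliff) from the spec, fully determined by its seed.

    X is uniform on [0, 1]^d; y = f(X) + eps with eps drawn at
    ``sigma_high`` inside any cliff ball and ``sigma_low`` outside.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    X = rng.uniform(0.0, 1.0, size=(spec.n, spec.d))
    in_cliff = np.zeros(spec.n, dtype=bool)
    for center, radius in spec.centers_and_radii():
        in_cliff |= np.linalg.norm(X - center, axis=1) <= radius
    sigma = np.where(in_cliff, spec.sigma_high, spec.sigma_low)
    y = _base_signal(X, spec.base) + rng.standard_normal(spec.n) * sigma
    return X, y, in_cliff


def cliff_frame(spec: CliffSpec) -> pd.DataFrame:
    """Same draw as a CSV-ready table: x0..x{d-1}, y, in_cliff."""
    X, y, in_cliff = generate_cliff_dataset(spec)
    frame = pd.DataFrame(X, columns=[f"x{j}" for j in range(spec.d)])
    frame["y"] = y
    frame["in_cliff"] = in_cliff
    return frame
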