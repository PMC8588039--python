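# Methods

## Model and procedure

`hvlforest` quantifies the reliability of individual random-forest
regression predictions. The forest itself is a standard
scikit-learn `RandomForestRegressor` (bootstrap sampling, CART trees);
this package never re-implements tree induction. What it adds is a
leaf-level view of the fitted ensemble and three per-object uncertainty
measures derived from it.

**Leaf statistics.** For every tree `t` and terminal leaf `l`, the
package collects the *raw training outputs* of the samples populating
that leaf and stores their count and sample standard deviation
`s_{t,l}` (divisor `n − 1`). The statistic is always recomputed from the
member outputs rather than read off the tree, because a learner may
post-process the value stored in a leaf; only the raw member outputs
measure the output fluctuation in the subspace the leaf defines. Two
membership conventions are supported:

- `inbag` (default): the tree's bootstrap multiset, with multiplicity —
  these are the samples whose error the tree minimized locally, so
  their spread is the tree's own view of local output variance;
- `all_train`: every training sample routed from the root — a larger,
  smoother member set that also covers out-of-bag points.

Leaves are grown with `min_samples_leaf = 2`, the smallest leaf for
which the `n − 1` standard deviation exists; `build_leaf_table` raises
if any populated leaf violates this.

**High-variance leaves.** A leaf is flagged as an HVL when
`s_{t,l} > f · sd(y)` *strictly* (equality is not flagged), with
`f = 0.5` and `sd(y)` the sample standard deviation of the dataset's
output vector. The **HVL fraction** of a query object is the share of
trees whose active leaf is an HVL; it lies in `[0, 1]`, is invariant to
tree order, and is monotone non-increasing in the threshold.

**Baselines and variants.** The **SDEP** is the population standard
deviation (divisor `T`) of the `T` single-tree predictions: the
ensemble is a fixed, fully observed population, not a sample from one,
so the descriptive divisor is the right one. The divisor asymmetry with
the leaf statistic (`n − 1` there) is intentional and tested. The
**mean leaf spread** averages the active leaves' `s_{t,l}` — a
continuous alternative that needs no cutoff; it averages standard
deviations rather than variances so it shares units with the outputs
and the threshold (a variance-scale option exists).

**Cross-validation protocol.** A single k-fold split (k = 10, shuffled,
seeded). Per fold: feature columns constant on the training split are
dropped (binary fingerprints produce many), the forest (T = 500 by
default, no hyperparameter tuning, no feature scaling) is fitted on the
training split, the leaf table is built and flagged, and both splits
are scored. Every object thus receives one test-side record and
`k − 1` train-side predictions; train-side predictions are averaged and
train-side HVL occurrences are summed and divided by `T·(k − 1)`
(= 4500 at the defaults). Per-fold forests use `seed + fold_index` so
the whole run is reproducible from one integer.

**Thresholding convention.** By default the HVL threshold uses the
whole dataset's output standard deviation (`threshold_mode =
"whole_dataset"`). This deliberately mirrors the protocol the package
reproduces, but it lets test outputs leak into the threshold; the
leakage-free `fold_train` mode (training-split σ only) is provided and
is the recommended choice for honest prospective use. The two differ
only through the σ estimate, so at these sample sizes the effect is
small.

**Evaluation.** Confidence curves recompute the remaining-set MSE after
every single removal, sorting by descending measure value with *stable*
ties — essential for the coarse HVL fraction, which takes at most
`T + 1` distinct values; a seeded randomized tie-break is available to
probe tie sensitivity. The oracle curve sorts by descending absolute
residual and is provably the pointwise minimum, so every AUCO ≥ 0.
AUCO is a unit-step rectangle sum of curve differences over
`k = 0 … floor(coverage · n)`; relative AUCO (the headline comparison)
is invariant to this rule versus a trapezoid up to end effects, and to
any step-count normalization. Fraction indices use `k = floor(f · n)`.
Curves are computed to `k = n − 1` internally (MSE90 lives in the deep
tail) but areas are never reported beyond the requested coverage, where
the shrinking denominator makes the curve erratic. R² takes an explicit
`ȳ`; passing the whole-dataset output mean keeps train- and test-side
values on one footing when every object appears on both sides of the
CV.

## Numerical choices

- Remaining-set MSEs come from a reversed running (suffix) sum, not
  `total − prefix`: no cancellation, so entries that should be exactly
  zero are zero, and the incremental curve matches a from-scratch
  recomputation to 1e−9 relative at n = 1000.
- Leaf standard deviations use a two-pass (mean, then squared
  deviations) grouped computation for stability.
- Leaf identifiers are the node indices of the underlying trees; they
  are meaningful only relative to the forest that produced them, and
  `hvl_fraction` raises a consistency error naming tree and leaf if an
  assignment refers to an unpopulated node.
- Degenerate inputs: a constant output vector yields threshold 0 with a
  warning (every varying leaf becomes an HVL); a constant measure
  vector makes the Pearson correlation undefined (error at the
  operation level, a warning-and-`None` in the aggregate report); a
  baseline whose AUCO is exactly 0 makes the relative area undefined.

## The synthetic generator

`generate_cliff_dataset` emulates the statistical signature of activity
cliffs: a smooth base signal on the unit hypercube (linear, or a sum of
low-frequency sinusoids — both tree-friendly, so leaf variance reflects
noise rather than approximation bias) plus Gaussian noise whose σ jumps
from `sigma_low = 0.1` to `sigma_high = 2.0` inside one or more
spherical regions (default: one ball of radius 0.25 at the cube's
center). The σ values bracket the situation the measures target: a
20-fold local noise inflation over a background chosen well below the
signal's spread. What it does **not** emulate: discrete, sparse,
correlated fingerprint features; cliff regions defined by similarity
rather than geometry; label noise from assay heterogeneity; covariate
shift between train and test. Passing the recovery tests therefore
shows the measures detect planted local output variance through the
full pipeline — not that they rank real compounds' reliabilities at any
particular accuracy.

## Problem sizes used in the test suite

The behavioural tests run the full CV pipeline on n = 2000, d = 5,
T = 100, k = 10 over 5 generator seeds (heteroscedastic and
homoscedastic control), with smaller forests elsewhere. These sizes
give the rank-sum test on inside/outside HVL fractions p-values orders
of magnitude below the α = 0.01 gate while keeping a full run on one
CPU in the minutes range; T = 100 changes only the granularity of the
HVL fraction (steps of 1/100 rather than 1/500), not its expectation.

## Known limitations

- The half-σ threshold factor is a fixed convention, not optimized; the
  continuous mean-leaf-spread variant avoids the choice entirely.
- The HVL fraction is coarse (≤ T + 1 distinct values), so confidence
  curves built from it contain long tied runs; stable ordering makes
  them reproducible but the within-tie order is arbitrary.
- `whole_dataset` thresholding leaks test outputs (see above).
- SDEP and HVL fraction are correlated by construction (both grow in
  sparse, heterogeneous regions); the package reports their Pearson r
  but offers no consensus or calibrated-interval construction.
- Only regression forests with bootstrap sampling are supported;
  quantile-forest or conformal machinery is out of scope.
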