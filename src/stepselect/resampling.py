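"""Monte-Carlo cross-validation splits and empirical bootstrap confidence intervals.

Both stages of the consensus procedure rely on the same two resampling
primitives: a reusable plan of K random train/test partitions at a fixed
train fraction (Monte-Carlo cross-validation, MCCV), and a percentile
bootstrap confidence interval for the mean or median of a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SplitPlan",
    "BootstrapCI",
    "generate_splits",
    "bootstrap_ci",
    "derive_seeds",
]


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from one global seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


@dataclass(frozen=True)
class SplitPlan:
    """An ordered list of train/test index partitions, reusable across models.

    Every split partitions ``range(n)``: train and test are disjoint and
    their union covers all rows. ``|train| = round(train_fraction * n)``.
    """

    n: int
    K: int
    train_fraction: float
    seed: int | None
    splits: tuple[tuple[np.ndarray, np.ndarray], ...] = field(repr=False)

    def __iter__(self):
        return iter(self.splits)

    def __len__(self) -> int:
        return self.K


def generate_splits(
    n: int,
    K: int = 100,
    train_fraction: float = 0.7,
    seed: int | None = None,
    labels: Sequence[int] | None = None,
    max_redraws: int = 1000,
) -> SplitPlan:
    """Generate ``K`` uniform-random train/test partitions of ``range(n)``.

    Parameters
    ----------
    n : number of rows; must be at least 10.
    K : number of splits (100 in the reference procedure).
    train_fraction : fraction of rows in each training set (0.7 in the
        reference procedure); the train size is ``round(train_fraction*n)``.
    seed : seed for the split generator; identical seeds give identical plans.
    labels : optional binary labels. When given, any split whose *training*
        set lacks one of the classes is redrawn. With realistic cohort sizes
        this is a near-impossible event, but it keeps downstream class-weight
        fitting total.
    """
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    n_train = round(train_fraction * n)
    if n_train in (0, n):
        raise ValueError("train_fraction leaves an empty train or test set")
    y = None if labels is None else np.asarray(labels)
    if y is not None:
        classes = np.unique(y)
        # if a class has fewer members than could ever co-occur in train, fail fast
        for c in classes:
            if (y == c).sum() < 1:
                raise ValueError(f"class {c} absent from labels")
    rng = np.random.default_rng(seed)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(K):
        for _attempt in range(max_redraws):
            perm = rng.permutation(n)
            train, test = perm[:n_train], perm[n_train:]
            if y is None or len(np.unique(y[train])) == len(np.unique(y)):
                break
        else:
            raise ValueError(
                "could not draw a training set containing every class "
                f"after {max_redraws} attempts (n={n})"
            )
        splits.append((np.sort(train), np.sort(test)))
    return SplitPlan(n=n, K=K, train_fraction=train_fraction, seed=seed, splits=tuple(splits))


@dataclass(frozen=True)
class BootstrapCI:
    """Empirical percentile interval for a statistic of a sample.

    ``B`` resamples of size ``m`` are drawn with replacement; the interval is
    the pair of empirical quantiles of the ``B`` resampled statistics.
    """

    statistic: Literal["mean", "median"]
    level: float
    B: int
    m: int
    lower: float
    upper: float
    estimate: float  # the statistic of the original sample

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def excludes_zero(self) -> bool:
        return not self.contains(0.0)


_STAT_FUNCS = {"mean": np.mean, "median": np.median}


def bootstrap_ci(
    sample: Sequence[float],
    statistic: Literal["mean", "median"] = "mean",
    B: int = 1000,
    m: int = 100,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CI for the mean or median of ``sample``.

    Resampling is with replacement: ``B`` resamples of size ``m`` are drawn,
    the statistic of each is computed, and the empirical ``(1-level)/2`` and
    ``1-(1-level)/2`` quantiles (linear interpolation between order
    statistics) of the ``B`` statistics form the interval.

    The sample is sorted before resampling so the result is invariant to
    permutations of the input for a fixed seed.
    """
    values = np.sort(np.asarray(sample, dtype=float))
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if m < 1:
        raise ValueError(f"resample size m must be >= 1, got {m}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    if statistic not in _STAT_FUNCS:
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    if B < 100:
        warnings.warn(
            f"B={B} bootstrap resamples gives an unstable interval; use B >= 100",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, m))
    stats = _STAT_FUNCS[statistic](values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats, [alpha, 1.0 - alpha])
    return BootstrapCI(
        statistic=statistic,
        level=level,
        B=B,
        m=m,
        lower=float(lower),
        upper=float(upper),
        estimate=float(_STAT_FUNCS[statistic](values)),
    )
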