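"""Point-biserial feature weighting.

The w-SVM pre-scales each predictor column by a nonnegative weight derived
from its point-biserial correlation with the dichotomous response.  For
predictor x and labels y in {-1, +1},

    r = (mean(x | y=+1) - mean(x | y=-1)) / S_x * sqrt(p_+ p_- n / (n - 1))

with S_x the (n-1)-denominator sample standard deviation and p_+, p_- the
class proportions — algebraically identical to the Pearson correlation of
x against y coded 0/1.  Weights are the absolute correlations normalized
to unit sum (the diagonal weight matrix has unit trace), and the weighted
matrix is Z = X diag(w).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "WeightVector",
    "WeightedMatrix",
    "point_biserial",
    "weights_from_correlations",
    "apply_weights",
    "weight_table",
    "PointBiserialWeighter",
]

#: a summed |r| below this is treated as "no association anywhere" (error)
_ZERO_SUM_TOL = 1e-10


@dataclass(frozen=True)
class WeightVector:
    """Per-feature signed correlations, normalized weights and ranks.

    ``ranks`` assigns 1 to the largest weight; ties keep first-listed
    order.  Invariants: weights are nonnegative and sum to 1; ranks are a
    permutation of 1..p.
    """

    correlations: np.ndarray
    weights: np.ndarray
    ranks: np.ndarray
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "correlations", np.asarray(self.correlations, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "ranks", np.asarray(self.ranks, dtype=int))
        p = self.weights.shape[0]
        if self.correlations.shape != (p,) or self.ranks.shape != (p,):
            raise ValueError("correlations, weights and ranks must share one length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if sorted(self.ranks) != list(range(1, p + 1)):
            raise ValueError("ranks must be a permutation of 1..p")
        if self.names is not None and len(self.names) != p:
            raise ValueError("names length mismatch")

    @property
    def p(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class WeightedMatrix:
    """Column-scaled data matrix Z = X diag(w) with its source weights."""

    Z: np.ndarray
    source_weights: WeightVector


def point_biserial(x, y) -> float:
    """Point-biserial correlation between a numeric column and +/-1 labels.

    Requires n >= 3, both classes present and a non-constant x.  Exactly
    equals the Pearson correlation of x against y coded 0/1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if not np.all(np.isin(y, (-1, 1))):
        raise ValueError("labels must be -1 or +1")
    pos = y == 1
    n_pos = int(pos.sum())
    if n_pos == 0 or n_pos == n:
        raise ValueError("both classes must be present")
    s = x.std(ddof=1)
    if s <= 0:
        raise ValueError("x is constant; point-biserial correlation undefined")
    p_pos = n_pos / n
    r = (x[pos].mean() - x[~pos].mean()) / s * np.sqrt(p_pos * (1 - p_pos) * n / (n - 1))
    return float(r)


def weights_from_correlations(r, names=None) -> WeightVector:
    """Normalize signed correlations into unit-sum feature weights.

    w_j = |r_j| / sum_k |r_k|.  All-zero correlations are an error (the
    normalization is undefined).  Ranks are assigned by descending weight,
    ties resolved in listed order.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.shape[0] < 1:
        raise ValueError("need a 1-D vector of at least one correlation")
    total = np.abs(r).sum()
    if total < _ZERO_SUM_TOL:
        raise ValueError("all correlations are (numerically) zero; weights undefined")
    w = np.abs(r) / total
    order = np.argsort(-w, kind="stable")
    ranks = np.empty(len(w), dtype=int)
    ranks[order] = np.arange(1, len(w) + 1)
    return WeightVector(
        correlations=r,
        weights=w,
        ranks=ranks,
        names=tuple(names) if names is not None else None,
    )


def apply_weights(X, w: WeightVector) -> WeightedMatrix:
    """Scale each column of X by its weight: z_ij = x_ij * w_j."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[1] != w.p:
        raise ValueError(f"X has {X.shape[1]} columns but weight vector has {w.p}")
    return WeightedMatrix(Z=X * w.weights, source_weights=w)


def weight_table(w: WeightVector) -> pd.DataFrame:
    """Weight report as a tidy table: variable, correlation, weight, rank."""
    names = w.names if w.names is not None else tuple(f"X{j + 1}" for j in range(w.p))
    return pd.DataFrame(
        {
            "variable": list(names),
            "correlation": w.correlations,
            "weight": w.weights,
            "rank": w.ranks,
        }
    )


class PointBiserialWeighter(TransformerMixin, BaseEstimator):
    """Supervised column scaler: weights columns by |point-biserial r|.

    ``fit`` computes per-column point-biserial correlations with the
    binary response and normalizes their absolute values to unit sum;
    ``transform`` multiplies each column by its weight.

    Parameters
    ----------
    constant_policy : {"error", "zero"}
        What to do with a constant training column, for which the
        correlation is undefined.  ``"zero"`` assigns it zero correlation
        (hence zero weight), which is the pragmatic choice inside
        resampling loops where a rare category may vanish from a split.

    Attributes
    ----------
    weight_vector_ : WeightVector
        Correlations, weights and ranks computed on the training data.
    """

    def __init__(self, constant_policy: str = "error"):
        self.constant_policy = constant_policy

    def fit(self, X, y):
        if self.constant_policy not in ("error", "zero"):
            raise ValueError("constant_policy must be 'error' or 'zero'")
        X, y = validate_data(self, X, y)
        y = np.asarray(y)
        r = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            try:
                r[j] = point_biserial(X[:, j], y)
            except ValueError as exc:
                if self.constant_policy == "zero" and "constant" in str(exc):
                    r[j] = 0.0
                else:
                    raise
        self.weight_vector_ = weights_from_correlations(r)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return apply_weights(X, self.weight_vector_).Z
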