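"""RBF-kernel soft-margin SVM solved in the dual, plus the weighted variant.

The classifier solves the standard soft-margin dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(z_i, z_j)
    s.t.   0 <= a_i <= C,   sum_i a_i y_i = 0

with K the radial basis function kernel exp(-gamma ||u - v||^2), using a
sequential-minimal-optimization (SMO) solver with maximal-violating-pair
working-set selection, the approach used by libsvm.  The weighted variant
first z-scores continuous columns with training statistics, scales every
column by its normalized |point-biserial| weight, and then trains the same
dual on the weighted matrix.

An exact algebraic identity worth knowing: uniform weights w_j = 1/p with
RBF width gamma give the same kernel matrix — hence the same fit — as the
unweighted problem with width gamma / p**2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .weighting import WeightVector, point_biserial, weights_from_correlations

__all__ = [
    "rbf_kernel",
    "rbf_kernel_matrix",
    "SMOSVC",
    "WeightedSVMClassifier",
    "TuningResult",
    "tune",
    "DEFAULT_GRID",
    "SolverError",
]

#: default (C, gamma) search ladder: C in 2^{-3..9 step 2}, gamma in 2^{-9..1 step 2}
DEFAULT_GRID: tuple[tuple[float, float], ...] = tuple(
    (2.0**lc, 2.0**lg) for lc in range(-3, 10, 2) for lg in range(-9, 2, 2)
)


class SolverError(RuntimeError):
    """The dual optimizer failed to reach the requested KKT tolerance."""


def rbf_kernel(u, v, gamma: float) -> float:
    """Radial basis function kernel exp(-gamma * ||u - v||^2) of two vectors."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u and v must have equal length")
    d = u - v
    return float(np.exp(-gamma * np.dot(d, d)))


def rbf_kernel_matrix(A, B, gamma: float) -> np.ndarray:
    """Pairwise RBF kernel matrix between the rows of A and of B."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    return np.exp(-gamma * cdist(A, B, metric="sqeuclidean"))


def _smo_solve(K: np.ndarray, y: np.ndarray, C: float, tol: float, max_iter: int):
    """Maximal-violating-pair SMO on a precomputed kernel matrix.

    Returns (alpha, bias, n_iter, kkt_gap).  The stopping rule is the
    standard violating-pair gap m(alpha) - M(alpha) <= tol, which bounds
    the KKT residual of the iterate.
    """
    n = K.shape[0]
    yf = y.astype(float)
    Q = (yf[:, None] * yf[None, :]) * K
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of 1/2 a'Qa - 1'a at a = 0
    tau = 1e-12

    for it in range(max_iter):
        yg = -yf * grad
        up = (alpha < C - 1e-12 * C) & (yf > 0) | (alpha > 1e-12 * C) & (yf < 0)
        low = (alpha < C - 1e-12 * C) & (yf < 0) | (alpha > 1e-12 * C) & (yf > 0)
        if not up.any() or not low.any():
            gap = 0.0
            break
        i = np.flatnonzero(up)[np.argmax(yg[up])]
        j = np.flatnonzero(low)[np.argmin(yg[low])]
        gap = yg[i] - yg[j]
        if gap <= tol:
            break

        s = yf[i] * yf[j]
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta < tau:
            eta = tau
        # E_k = (decision without bias at k) - y_k equals y_k * grad_k
        delta = yf[j] * (yf[i] * grad[i] - yf[j] * grad[j]) / eta
        aj_old, ai_old = alpha[j], alpha[i]
        if s < 0:
            L = max(0.0, aj_old - ai_old)
            H = min(C, C + aj_old - ai_old)
        else:
            L = max(0.0, ai_old + aj_old - C)
            H = min(C, ai_old + aj_old)
        aj_new = min(max(aj_old + delta, L), H)
        ai_new = ai_old + s * (aj_old - aj_new)
        alpha[j] = aj_new
        alpha[i] = ai_new
        grad += Q[:, i] * (ai_new - ai_old) + Q[:, j] * (aj_new - aj_old)
    else:
        raise SolverError(
            f"SMO did not converge in {max_iter} iterations "
            f"(violating-pair gap {gap:.3e} > tol {tol:.1e}, n={n}, C={C})"
        )

    # bias from free (unbounded) support vectors; fall back to the gap midpoint
    sv_tol = 1e-8 * C
    free = (alpha > sv_tol) & (alpha < C - sv_tol)
    yg = -yf * grad
    if free.any():
        bias = float(np.mean(yg[free]))
    else:
        up = (alpha < C - 1e-12 * C) & (yf > 0) | (alpha > 1e-12 * C) & (yf < 0)
        low = (alpha < C - 1e-12 * C) & (yf < 0) | (alpha > 1e-12 * C) & (yf > 0)
        hi = yg[up].max() if up.any() else yg[low].min()
        lo = yg[low].min() if low.any() else yg[up].max()
        bias = float((hi + lo) / 2.0)
    return alpha, bias, it + 1, float(max(gap, 0.0))


class SMOSVC(ClassifierMixin, BaseEstimator):
    """Soft-margin RBF support vector classifier solved by SMO.

    Parameters
    ----------
    C : float
        Box constraint on the dual coefficients (cost of margin violation).
    gamma : float
        RBF width; the kernel is exp(-gamma ||u - v||^2).
    tol : float
        KKT (violating-pair gap) tolerance of the dual solver.
    max_iter : int
        Hard cap on SMO pair updates; exceeded -> :class:`SolverError`.

    Attributes
    ----------
    support_ : ndarray — indices of training rows with alpha above threshold
    support_vectors_ : ndarray — the corresponding rows
    dual_coef_ : ndarray — alpha_i * y_i for the support vectors
    intercept_ : float — bias of the decision function
    dual_objective_ : float — value of sum a - 1/2 a'Qa at the solution
    kkt_gap_ : float — final violating-pair gap (KKT residual bound)
    """

    def __init__(self, C: float = 1.0, gamma: float = 1.0, tol: float = 1e-4,
                 max_iter: int = 200_000):
        self.C = C
        self.gamma = gamma
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly two classes required, got {len(self.classes_)}"
            )
        ypm = np.where(y == self.classes_[1], 1, -1)

        K = rbf_kernel_matrix(X, X, self.gamma)
        alpha, bias, n_iter, gap = _smo_solve(
            K, ypm, float(self.C), self.tol, self.max_iter
        )
        Q = np.outer(ypm, ypm) * K
        self.dual_objective_ = float(alpha.sum() - 0.5 * alpha @ Q @ alpha)
        self.kkt_gap_ = gap
        self.n_iter_ = n_iter

        sv = alpha > 1e-8 * self.C
        self.support_ = np.flatnonzero(sv)
        self.support_vectors_ = X[sv]
        self.dual_coef_ = alpha[sv] * ypm[sv]
        self.intercept_ = bias
        self._alpha = alpha
        self._ypm = ypm
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        K = rbf_kernel_matrix(X, self.support_vectors_, self.gamma)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X):
        # sign(0) -> +1 by convention (>= 0 maps to the positive class)
        dec = self.decision_function(X)
        return np.where(dec >= 0, self.classes_[1], self.classes_[0])


class WeightedSVMClassifier(ClassifierMixin, BaseEstimator):
    """w-SVM: point-biserial feature weighting followed by an RBF SVM.

    ``fit`` (i) z-scores the designated continuous columns using training
    statistics, (ii) computes per-column point-biserial correlations with
    the response and normalizes their absolute values into unit-sum
    weights, (iii) scales every column by its weight and (iv) trains the
    soft-margin RBF dual on the weighted matrix.  Prediction applies the
    stored standardization and weights to new rows before the kernel
    expansion.

    Parameters
    ----------
    C, gamma, tol, max_iter : dual-solver parameters, as in :class:`SMOSVC`.
    weights : "auto" | "uniform" | array-like | WeightVector
        "auto" learns weights from the training split; "uniform" fixes
        w_j = 1/p; an explicit vector (or WeightVector) freezes externally
        computed weights, e.g. full-data weights inside a resampling loop.
    standardize : bool
        Whether to z-score continuous columns before weighting.
    continuous_mask : array-like of bool or None
        Which columns are continuous (None = all of them).  Categorical
        columns keep their integer codes un-centred.

    Attributes
    ----------
    weight_vector_ : WeightVector used for the fit
    center_, scale_ : per-feature standardization statistics
    support_vectors_, dual_coef_, intercept_ : the fitted kernel expansion
        (support vectors live in the weighted coordinate system)
    """

    def __init__(self, C: float = 1.0, gamma: float = 1.0, weights="auto",
                 standardize: bool = True, continuous_mask=None,
                 tol: float = 1e-4, max_iter: int = 200_000):
        self.C = C
        self.gamma = gamma
        self.weights = weights
        self.standardize = standardize
        self.continuous_mask = continuous_mask
        self.tol = tol
        self.max_iter = max_iter

    def _resolve_weights(self, X, ypm) -> WeightVector:
        w = self.weights
        if isinstance(w, WeightVector):
            if w.p != X.shape[1]:
                raise ValueError("weight vector length does not match X")
            return w
        if isinstance(w, str):
            if w == "uniform":
                p = X.shape[1]
                return weights_from_correlations(np.ones(p))
            if w == "auto":
                r = np.empty(X.shape[1])
                for j in range(X.shape[1]):
                    col = X[:, j]
                    # a split may strand a constant column; it carries no
                    # class information there, so it gets zero weight
                    r[j] = 0.0 if col.std(ddof=1) == 0 else point_biserial(col, ypm)
                return weights_from_correlations(r)
            raise ValueError(f"unknown weights mode {w!r}")
        arr = np.asarray(w, dtype=float)
        return weights_from_correlations(arr)

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly two classes required, got {len(self.classes_)}"
            )
        ypm = np.where(y == self.classes_[1], 1, -1)

        p = X.shape[1]
        mask = (np.ones(p, dtype=bool) if self.continuous_mask is None
                else np.asarray(self.continuous_mask, dtype=bool))
        if mask.shape != (p,):
            raise ValueError("continuous_mask length does not match X")
        center = np.zeros(p)
        scale = np.ones(p)
        if self.standardize:
            center[mask] = X[:, mask].mean(axis=0)
            sd = X[:, mask].std(axis=0, ddof=1)
            scale[mask] = np.where(sd > 0, sd, 1.0)
        self.center_ = center
        self.scale_ = scale

        Xs = (X - center) / scale
        self.weight_vector_ = self._resolve_weights(Xs, ypm)
        Z = Xs * self.weight_vector_.weights

        self._svc = SMOSVC(C=self.C, gamma=self.gamma, tol=self.tol,
                           max_iter=self.max_iter).fit(Z, ypm)
        self.support_ = self._svc.support_
        self.support_vectors_ = self._svc.support_vectors_
        self.dual_coef_ = self._svc.dual_coef_
        self.intercept_ = self._svc.intercept_
        self.dual_objective_ = self._svc.dual_objective_
        self.kkt_gap_ = self._svc.kkt_gap_
        return self

    def _transform(self, X):
        return (X - self.center_) / self.scale_ * self.weight_vector_.weights

    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self._svc.decision_function(self._transform(X))

    def predict(self, X):
        dec = self.decision_function(X)
        return np.where(dec >= 0, self.classes_[1], self.classes_[0])

    # --- serialization ---------------------------------------------------
    def to_json(self) -> str:
        """Serialize the fitted model to a documented JSON container."""
        check_is_fitted(self)
        wv = self.weight_vector_
        payload = {
            "format": "wsvm-model/1",
            "C": self.C,
            "gamma": self.gamma,
            "classes": self.classes_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "weights": {
                "correlations": wv.correlations.tolist(),
                "weights": wv.weights.tolist(),
                "ranks": wv.ranks.tolist(),
                "names": list(wv.names) if wv.names is not None else None,
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "WeightedSVMClassifier":
        d = json.loads(text)
        if d.get("format") != "wsvm-model/1":
            raise ValueError("not a wsvm model container")
        wv = WeightVector(
            correlations=np.array(d["weights"]["correlations"]),
            weights=np.array(d["weights"]["weights"]),
            ranks=np.array(d["weights"]["ranks"]),
            names=tuple(d["weights"]["names"]) if d["weights"]["names"] else None,
        )
        model = cls(C=d["C"], gamma=d["gamma"], weights=wv)
        model.classes_ = np.array(d["classes"])
        model.center_ = np.array(d["center"])
        model.scale_ = np.array(d["scale"])
        model.weight_vector_ = wv
        model.support_vectors_ = np.array(d["support_vectors"])
        model.dual_coef_ = np.array(d["dual_coef"])
        model.intercept_ = float(d["intercept"])
        model.n_features_in_ = model.center_.shape[0]
        svc = SMOSVC(C=d["C"], gamma=d["gamma"])
        svc.classes_ = np.array([-1, 1])
        svc.support_vectors_ = model.support_vectors_
        svc.dual_coef_ = model.dual_coef_
        svc.intercept_ = model.intercept_
        svc.n_features_in_ = model.support_vectors_.shape[1]
        model._svc = svc
        return model


@dataclass(frozen=True)
class TuningResult:
    """Outcome of a k-fold grid search over (C, gamma)."""

    grid: tuple[tuple[float, float], ...]
    cv_error: tuple[float, ...]  # mean validation misclassification rate
    best: tuple[float, float]
    folds_seed: int
    k: int = 10


def tune(Z, y, grid=None, k: int = 10, seed: int = 0) -> TuningResult:
    """Select (C, gamma) by stratified k-fold cross-validated error.

    Folds are stratified on the labels and deterministic given ``seed``.
    The candidate with minimal mean validation misclassification wins;
    ties prefer the smallest C, then the smallest gamma (smoother models).
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y)
    n = Z.shape[0]
    if grid is None:
        grid = DEFAULT_GRID
    grid = tuple((float(c), float(g)) for c, g in grid)
    if not grid:
        raise ValueError("empty tuning grid")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(Z, y))
    for tr, _ in folds:
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                "a training fold lost one class entirely; use a smaller k"
            )

    errors = []
    for C, gamma in grid:
        errs = []
        for tr, va in folds:
            model = SMOSVC(C=C, gamma=gamma).fit(Z[tr], y[tr])
            errs.append(float(np.mean(model.predict(Z[va]) != y[va])))
        errors.append(float(np.mean(errs)))
    errors_arr = np.array(errors)
    # stable tie-break: minimal error, then smallest C, then smallest gamma
    best_idx = min(
        range(len(grid)),
        key=lambda i: (errors_arr[i], grid[i][0], grid[i][1]),
    )
    return TuningResult(
        grid=grid,
        cv_error=tuple(errors),
        best=grid[best_idx],
        folds_seed=seed,
        k=k,
    )
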