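"""Monte-Carlo cross-validation and the seven performance indices.

One MCCV run repeatedly partitions a dataset into stratified train/test
sets at a fixed splitting ratio, re-fits the whole w-SVM pipeline on each
training portion (weights, optional tuning, dual solve) and scores the
held-out portion with seven indices derived from the 2x2 confusion
matrix: accuracy, misclassification error rate, sensitivity, specificity,
positive and negative predictive value, and the Jaccard index.  Reported
means are arithmetic means over iterations; a pooled-count mode (one
confusion matrix summed over iterations) is also available.

An index whose denominator is zero in some iteration (possible with very
small test sets) is recorded as NaN — "undefined", never silently 0 — and
excluded from that index's mean with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import Dataset
from .svm import DEFAULT_GRID, SMOSVC, tune
from .weighting import point_biserial, weights_from_correlations, WeightVector

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "SplitPlan",
    "MCCVReport",
    "PipelineConfig",
    "make_split",
    "confusion",
    "indices",
    "compute_weight_vector",
    "mccv",
    "compare_classifiers",
    "INDEX_NAMES",
]

INDEX_NAMES = ("acc", "mer", "se", "sp", "p_plus", "p_minus", "ji")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts for a +/-1 prediction task."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class PerformanceReport:
    """The seven indices on the [0, 1] scale; NaN marks an undefined value."""

    acc: float
    mer: float
    se: float
    sp: float
    p_plus: float
    p_minus: float
    ji: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in INDEX_NAMES}

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * getattr(self, k) for k in INDEX_NAMES}


@dataclass(frozen=True)
class SplitPlan:
    """One reproducible train/test partition."""

    ratio: float
    stratified: bool
    seed: int
    train_ids: np.ndarray
    test_ids: np.ndarray


def _largest_remainder_counts(sizes: np.ndarray, ratio: float) -> np.ndarray:
    """Per-class training counts: floors plus largest-remainder top-up.

    The total training size is the nearest integer to n * ratio (half
    rounds up); remaining seats go to the classes with the largest
    fractional parts, ties resolved toward the larger class, then by
    class order.
    """
    exact = sizes * ratio
    base = np.floor(exact).astype(int)
    total = int(np.floor(sizes.sum() * ratio + 0.5))
    short = total - base.sum()
    remainders = exact - base
    order = sorted(
        range(len(sizes)),
        key=lambda c: (-remainders[c], -sizes[c], c),
    )
    counts = base.copy()
    for c in order[:short]:
        counts[c] += 1
    return counts


def make_split(dataset: Dataset, ratio: float, seed: int,
               stratified: bool = True) -> SplitPlan:
    """Draw a reproducible train/test partition at the given train fraction.

    Stratified mode keeps the class mix: each class contributes a number
    of training rows computed by largest-remainder rounding, so the split
    sizes are identical across seeds.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    n = dataset.n
    if stratified:
        train_idx = []
        classes, sizes = np.unique(dataset.y, return_counts=True)
        counts = _largest_remainder_counts(sizes.astype(float), ratio)
        for cls, k in zip(classes, counts):
            members = np.flatnonzero(dataset.y == cls)
            if k < 1:
                raise ValueError(
                    f"ratio {ratio} leaves class {cls} empty in training"
                )
            if k >= len(members) and len(classes) > 1:
                # class fully consumed by training; test would miss it
                k = len(members)
            train_idx.append(rng.permutation(members)[:k])
        train = np.sort(np.concatenate(train_idx))
    else:
        k = int(np.floor(n * ratio + 0.5))
        perm = rng.permutation(n)
        train = np.sort(perm[:k])
    test = np.setdiff1d(np.arange(n), train)
    if len(test) == 0:
        raise ValueError(f"ratio {ratio} leaves an empty test set (n={n})")
    return SplitPlan(ratio=ratio, stratified=stratified, seed=seed,
                     train_ids=train, test_ids=test)


def confusion(pred, truth) -> ConfusionMatrix:
    """Count the four cells of the 2x2 table for +/-1 labels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 1:
        raise ValueError("pred and truth must be equal-length 1-D, n >= 1")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.all(np.isin(arr, (-1, 1))):
            raise ValueError(f"{name} contains labels outside {{-1, +1}}")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == -1))),
        fn=int(np.sum((pred == -1) & (truth == 1))),
        tn=int(np.sum((pred == -1) & (truth == -1))),
    )


def _ratio_or_nan(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def indices(cm: ConfusionMatrix) -> PerformanceReport:
    """The seven performance indices of a confusion matrix.

    Acc=(TP+TN)/N, MER=(FP+FN)/N, Se=TP/(TP+FN), Sp=TN/(FP+TN),
    P+=TP/(TP+FP), P-=TN/(TN+FN), JI=TP/(TP+FP+FN).  A zero denominator
    yields NaN for that index.
    """
    if cm.n < 1:
        raise ValueError("empty confusion matrix")
    return PerformanceReport(
        acc=(cm.tp + cm.tn) / cm.n,
        mer=(cm.fp + cm.fn) / cm.n,
        se=_ratio_or_nan(cm.tp, cm.tp + cm.fn),
        sp=_ratio_or_nan(cm.tn, cm.fp + cm.tn),
        p_plus=_ratio_or_nan(cm.tp, cm.tp + cm.fp),
        p_minus=_ratio_or_nan(cm.tn, cm.tn + cm.fn),
        ji=_ratio_or_nan(cm.tp, cm.tp + cm.fp + cm.fn),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """How each MCCV iteration trains the classifier.

    weights_mode : "per-split" recomputes point-biserial weights on each
        training portion (no test leakage); "full-data" computes them once
        on the whole dataset, mirroring a single-table analysis.
    tune_mode : "nested" re-tunes (C, gamma) by k-fold CV inside every
        training portion; "once" tunes a single time on the full data;
        "fixed" uses the given C and gamma unchanged.
    """

    weights_mode: str = "per-split"
    standardize: bool = True
    tune_mode: str = "nested"
    C: float = 1.0
    gamma: float = 0.5
    grid: tuple[tuple[float, float], ...] = DEFAULT_GRID
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.weights_mode not in ("per-split", "full-data"):
            raise ValueError(f"unknown weights_mode {self.weights_mode!r}")
        if self.tune_mode not in ("nested", "once", "fixed"):
            raise ValueError(f"unknown tune_mode {self.tune_mode!r}")


@dataclass
class MCCVReport:
    """Per-iteration and aggregated indices for one splitting ratio."""

    ratio: float
    n_iter: int
    per_iteration: list[PerformanceReport]
    mean_report: PerformanceReport
    master_seed: int
    pooled_report: PerformanceReport | None = None
    undefined_counts: dict[str, int] = field(default_factory=dict)
    failures: list[tuple[int, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.per_iteration]
        return pd.DataFrame(rows)


def iteration_seed(master_seed: int, iteration: int) -> int:
    """Deterministic per-iteration seed: counter-derived, reproducible alone."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(iteration,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def compute_weight_vector(dataset: Dataset, standardize: bool = True) -> WeightVector:
    """Point-biserial weight vector of a dataset (full-data, single table).

    Standardization does not change the correlations (they are affine
    invariant); it is accepted for interface symmetry with the pipeline.
    """
    r = np.empty(dataset.p)
    for j in range(dataset.p):
        col = dataset.X[:, j]
        r[j] = 0.0 if col.std(ddof=1) == 0 else point_biserial(col, dataset.y)
    return weights_from_correlations(r, names=dataset.feature_names)


def _prepare_train_test(dataset, plan, config, fixed_weights):
    """Standardize on train stats, weight, and return (Ztr, ytr, Zte, yte, wv)."""
    Xtr = dataset.X[plan.train_ids]
    Xte = dataset.X[plan.test_ids]
    ytr = dataset.y[plan.train_ids]
    yte = dataset.y[plan.test_ids]

    p = dataset.p
    center = np.zeros(p)
    scale = np.ones(p)
    if config.standardize:
        mask = dataset.continuous_mask()
        center[mask] = Xtr[:, mask].mean(axis=0)
        sd = Xtr[:, mask].std(axis=0, ddof=1)
        scale[mask] = np.where(sd > 0, sd, 1.0)
    Xtr_s = (Xtr - center) / scale
    Xte_s = (Xte - center) / scale

    if fixed_weights is not None:
        wv = fixed_weights
    else:
        r = np.empty(p)
        for j in range(p):
            col = Xtr_s[:, j]
            r[j] = 0.0 if col.std(ddof=1) == 0 else point_biserial(col, ytr)
        wv = weights_from_correlations(r, names=dataset.feature_names)
    return Xtr_s * wv.weights, ytr, Xte_s * wv.weights, yte, wv


def _nanmean_report(reports: list[PerformanceReport]):
    """Arithmetic means per index, skipping undefined values; count them."""
    frame = pd.DataFrame([r.as_dict() for r in reports])
    undefined = {k: int(frame[k].isna().sum()) for k in INDEX_NAMES
                 if frame[k].isna().any()}
    means = {k: float(frame[k].mean()) for k in INDEX_NAMES}  # pandas skips NaN
    return PerformanceReport(**means), undefined


def mccv(dataset: Dataset, ratio: float, n_iter: int, master_seed: int,
         config: PipelineConfig | None = None) -> MCCVReport:
    """Monte-Carlo cross-validation of the w-SVM at one splitting ratio.

    Each iteration derives its own seed from ``master_seed``, draws a
    stratified split, fits the pipeline on the training portion per
    ``config`` and scores the test portion.  Fully reproducible from
    ``master_seed``; iteration errors are recorded, not fatal.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if config is None:
        config = PipelineConfig()

    fixed_weights = None
    if config.weights_mode == "full-data":
        fixed_weights = compute_weight_vector(dataset, config.standardize)

    fixed_params = (config.C, config.gamma)
    if config.tune_mode == "once":
        plan_all = SplitPlan(1.0, True, master_seed,
                             np.arange(dataset.n), np.arange(0))
        Z_all, y_all, _, _, _ = _prepare_train_test(
            dataset,
            replace(plan_all, test_ids=np.arange(dataset.n)),
            config, fixed_weights,
        )
        result = tune(Z_all, y_all, grid=config.grid, k=config.cv_folds,
                      seed=iteration_seed(master_seed, 0) % (2**31))
        fixed_params = result.best
        logger.info("tuned once on full data: C=%g gamma=%g", *fixed_params)

    reports: list[PerformanceReport] = []
    pooled = ConfusionMatrix(0, 0, 0, 0)
    failures: list[tuple[int, str]] = []
    for it in range(n_iter):
        seed_it = iteration_seed(master_seed, it)
        try:
            plan = make_split(dataset, ratio, seed_it, stratified=True)
            Ztr, ytr, Zte, yte, _ = _prepare_train_test(
                dataset, plan, config, fixed_weights
            )
            if config.tune_mode == "nested":
                res = tune(Ztr, ytr, grid=config.grid, k=config.cv_folds,
                           seed=seed_it % (2**31))
                C, gamma = res.best
            else:
                C, gamma = fixed_params
            model = SMOSVC(C=C, gamma=gamma).fit(Ztr, ytr)
            cm = confusion(model.predict(Zte), yte)
            reports.append(indices(cm))
            pooled = pooled + cm
        except (ValueError, RuntimeError) as exc:
            logger.warning("iteration %d failed: %s", it, exc)
            failures.append((it, str(exc)))
    if not reports:
        raise RuntimeError(
            f"all {n_iter} MCCV iterations failed; first error: {failures[0][1]}"
        )
    mean_report, undefined = _nanmean_report(reports)
    if undefined:
        logger.info("undefined index values excluded from means: %s", undefined)
    return MCCVReport(
        ratio=ratio,
        n_iter=n_iter,
        per_iteration=reports,
        mean_report=mean_report,
        master_seed=master_seed,
        pooled_report=indices(pooled),
        undefined_counts=undefined,
        failures=failures,
    )


def _baseline_factory(name: str, seed: int):
    if name == "svm":
        from sklearn.svm import SVC
        return SVC(kernel="rbf")  # library defaults: C=1, gamma="scale"
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "nb":
        from sklearn.naive_bayes import GaussianNB
        return GaussianNB()
    raise ValueError(f"unknown method {name!r}")


def compare_classifiers(dataset: Dataset, ratios, methods, n_iter: int,
                        master_seed: int,
                        config: PipelineConfig | None = None):
    """Paired mean-MER comparison of w-SVM against reference classifiers.

    All methods see the identical split sequence at each ratio (paired
    design), so per-iteration MER differences are directly comparable.
    Baselines come from scikit-learn: ``svm`` (unweighted RBF SVC),
    ``rf`` (random forest), ``nb`` (Gaussian naive Bayes); they receive
    the standardized but unweighted feature matrix.

    Returns
    -------
    table : DataFrame of mean MER, rows = methods, columns = ratios.
    per_iteration : dict (method, ratio) -> list of per-iteration MER.
    """
    methods = list(methods)
    known = {"wsvm", "svm", "rf", "nb"}
    bad = set(methods) - known
    if bad:
        raise ValueError(f"unknown methods {sorted(bad)}; choose from {sorted(known)}")
    if config is None:
        config = PipelineConfig()

    fixed_weights = None
    if config.weights_mode == "full-data":
        fixed_weights = compute_weight_vector(dataset, config.standardize)

    table = pd.DataFrame(index=methods, columns=[float(r) for r in ratios],
                         dtype=float)
    per_iteration: dict[tuple[str, float], list[float]] = {
        (m, float(r)): [] for m in methods for r in ratios
    }
    for ratio in ratios:
        ratio = float(ratio)
        for it in range(n_iter):
            seed_it = iteration_seed(master_seed, it)
            plan = make_split(dataset, ratio, seed_it, stratified=True)
            Ztr, ytr, Zte, yte, _ = _prepare_train_test(
                dataset, plan, config, fixed_weights
            )
            for method in methods:
                if method == "wsvm":
                    if config.tune_mode == "nested":
                        res = tune(Ztr, ytr, grid=config.grid,
                                   k=config.cv_folds, seed=seed_it % (2**31))
                        C, gamma = res.best
                    else:
                        C, gamma = config.C, config.gamma
                    model = SMOSVC(C=C, gamma=gamma).fit(Ztr, ytr)
                    pred = model.predict(Zte)
                else:
                    # baselines see standardized, unweighted features
                    Xtr = dataset.X[plan.train_ids]
                    Xte = dataset.X[plan.test_ids]
                    if config.standardize:
                        mask = dataset.continuous_mask()
                        center = np.zeros(dataset.p)
                        scale = np.ones(dataset.p)
                        center[mask] = Xtr[:, mask].mean(axis=0)
                        sd = Xtr[:, mask].std(axis=0, ddof=1)
                        scale[mask] = np.where(sd > 0, sd, 1.0)
                        Xtr = (Xtr - center) / scale
                        Xte = (Xte - center) / scale
                    try:
                        clf = _baseline_factory(method, seed_it)
                    except ImportError as exc:  # pragma: no cover
                        logger.warning("baseline %s unavailable: %s", method, exc)
                        continue
                    clf.fit(Xtr, ytr)
                    pred = clf.predict(Xte)
                mer = float(np.mean(pred != yte))
                per_iteration[(method, ratio)].append(mer)
        for method in methods:
            vals = per_iteration[(method, ratio)]
            table.loc[method, ratio] = float(np.mean(vals)) if vals else np.nan
    return table, per_iteration
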