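"""Classifiers, validation protocol and diagnostic metrics.

The study protocol splits subjects 60/40 into an optimization set (feature
selection, hyperparameter tuning via 10-fold stratified CV) and a
cross-validation set on which performance is estimated by stratified
5-fold CV.  Anything estimated from data -- standardization statistics,
ROC cutoffs, hyperparameters -- is computed on training-side data only.

Three classifiers are supported: unpenalized logistic regression fitted by
maximum likelihood, a soft-margin linear-kernel SVM with regularization
parameter C, and a one-hidden-layer MLP (hyperbolic-tangent hidden units,
logistic outputs, weight-decay regularization alpha).  Single features are
evaluated through an optimal ROC cutoff (Youden's J) estimated per fold on
the training folds.

Diagnostic metrics follow the usual screening conventions: Se, Sp, PPV,
NPV and Acc in percent; LR+ = Se/(1-Sp) and LR- = (1-Se)/Sp on the
proportion scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

K_FOLDS = 5
TUNING_FOLDS = 10
TUNING_RUNS = 10

#: Default hyperparameter grids: C over decades, N_H and alpha sampling the
#: assessed ranges [2, 50] and [0, 10].
C_GRID = tuple(10.0**k for k in range(-5, 6))
NH_GRID = (2, 3, 5, 8, 12, 20, 30, 50)
ALPHA_GRID = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0)


# ---------------------------------------------------------------------------
# split plan


@dataclass
class SplitPlan:
    """60/40 stratified split plus stratified K folds of the 40% portion.

    All index arrays refer to row positions in the full cohort.
    """

    optimization_idx: np.ndarray
    crossval_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int | None = None

    @property
    def k(self) -> int:
        return len(self.folds)


def make_split(
    y,
    seed: int | None = None,
    *,
    k: int = K_FOLDS,
    crossval_fraction: float = 0.40,
) -> SplitPlan:
    """Random stratified 60/40 split and K=5 stratified folds of the
    cross-validation portion; reproducible by seed."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    idx = np.arange(y.size)
    rs = None if seed is None else int(seed) % (2**32)
    opt_idx, cv_idx = train_test_split(
        idx, test_size=crossval_fraction, stratify=y, random_state=rs
    )
    counts = np.array([(y[cv_idx] == c).sum() for c in classes])
    if counts.min() < k:
        raise ValueError(
            f"need at least {k} cross-validation subjects per class, got {counts}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
    folds = [
        (np.sort(cv_idx[tr]), np.sort(cv_idx[te]))
        for tr, te in skf.split(cv_idx, y[cv_idx])
    ]
    return SplitPlan(np.sort(opt_idx), np.sort(cv_idx), folds, seed)


# ---------------------------------------------------------------------------
# models


@dataclass(frozen=True)
class ModelSpec:
    """Classifier kind plus its hyperparameters.

    ``c`` applies to the SVM; ``n_hidden`` and ``alpha`` to the MLP; the
    seed fixes the MLP's random weight initialization.
    """

    kind: str = "lr"
    c: float = 1.0
    n_hidden: int = 5
    alpha: float = 1.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lr", "svm", "mlp"):
            raise ValueError(f"unknown model kind {self.kind!r}")


def make_classifier(spec: ModelSpec) -> Pipeline:
    """Build an unfitted pipeline: per-feature z-scoring (training
    statistics) followed by the requested classifier."""
    if spec.kind == "lr":
        # C=inf disables the penalty: plain maximum-likelihood fit, and
        # newton-cholesky is the IRLS algorithm
        est = LogisticRegression(
            C=np.inf, solver="newton-cholesky", tol=1e-10, max_iter=200
        )
    elif spec.kind == "svm":
        est = SVC(kernel="linear", C=spec.c)
    else:
        rs = None if spec.seed is None else int(spec.seed) % (2**32)
        est = MLPClassifier(
            hidden_layer_sizes=(spec.n_hidden,),
            activation="tanh",
            alpha=spec.alpha,
            solver="lbfgs",
            max_iter=500,
            tol=1e-6,
            random_state=rs,
        )
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def train_model(spec: ModelSpec, X, y) -> Pipeline:
    """Fit the classifier described by ``spec``; raises on single-class y."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("cannot train on a single-class target")
    return make_classifier(spec).fit(np.asarray(X, dtype=float), y)


class SingleFeatureClassifier(BaseEstimator, ClassifierMixin):
    """Threshold rule on one feature with a ROC-optimal (Youden) cutoff.

    ``fit`` estimates both the cutoff and the direction (whether high
    values indicate the positive class) from the training data only.
    """

    def __init__(self, column: int = 0):
        self.column = column

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        scores = X[:, self.column]
        # direction: positives should score higher; flip if they do not
        self.flip_ = scores[y == 1].mean() < scores[y == 0].mean()
        s = -scores if self.flip_ else scores
        self.threshold_ = roc_optimal_cutoff(s, y)
        return self

    def predict(self, X):
        s = np.asarray(X, dtype=float)[:, self.column]
        if self.flip_:
            s = -s
        return (s >= self.threshold_).astype(int)


# ---------------------------------------------------------------------------
# hyperparameter tuning


def _cv_accuracy(model, X, y, seed, n_folds):
    rs = None if seed is None else int(seed) % (2**32)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
    accs = []
    for tr, te in skf.split(X, y):
        m = clone(model).fit(X[tr], y[tr])
        accs.append(float(np.mean(m.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def tune_hyperparams(
    kind: str,
    X,
    y,
    seed: int | None = 0,
    *,
    c_grid=C_GRID,
    nh_grid=NH_GRID,
    alpha_grid=ALPHA_GRID,
    n_folds: int = TUNING_FOLDS,
    n_runs: int = TUNING_RUNS,
) -> dict:
    """Grid search by 10-fold stratified CV accuracy on the optimization
    set.

    For the MLP each grid point is averaged over ``n_runs`` random weight
    initializations.  Ties resolve to the smallest C (SVM) or the smallest
    N_H then alpha (MLP) because grids are scanned in ascending order and
    only strictly better accuracy replaces the incumbent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("optimization set must contain both classes")
    if kind == "lr":
        return {}
    if kind == "svm":
        if len(c_grid) == 0:
            raise ValueError("empty grid")
        best, best_acc = None, -np.inf
        for c in sorted(c_grid):
            acc = _cv_accuracy(
                make_classifier(ModelSpec("svm", c=c)), X, y, seed, n_folds
            )
            if acc > best_acc:
                best, best_acc = c, acc
        return {"c": best}
    if kind == "mlp":
        if len(nh_grid) == 0 or len(alpha_grid) == 0:
            raise ValueError("empty grid")
        base = 0 if seed is None else int(seed)
        best, best_acc = None, -np.inf
        for nh in sorted(nh_grid):
            for alpha in sorted(alpha_grid):
                accs = [
                    _cv_accuracy(
                        make_classifier(
                            ModelSpec("mlp", n_hidden=nh, alpha=alpha, seed=base + r)
                        ),
                        X,
                        y,
                        seed,
                        n_folds,
                    )
                    for r in range(n_runs)
                ]
                acc = float(np.mean(accs))
                if acc > best_acc:
                    best, best_acc = (nh, alpha), acc
        return {"n_hidden": best[0], "alpha": best[1]}
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# metrics


def roc_optimal_cutoff(scores, labels) -> float:
    """Threshold maximizing Youden's J = Se + Sp - 1 for the rule
    ``score >= threshold -> positive``.

    Candidates are the midpoints between consecutive distinct scores;
    ties resolve to the lowest threshold.  If all scores coincide the
    rule is degenerate (J = 0): a warning is emitted and the common score
    returned.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    distinct = np.unique(s)
    if distinct.size == 1:
        warnings.warn("all scores identical: degenerate ROC cutoff", RuntimeWarning)
        return float(distinct[0])
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    best_t, best_j = None, -np.inf
    for t in mids:
        pred = s >= t
        se = (pred & (y == 1)).sum() / n_pos
        sp = (~pred & (y == 0)).sum() / n_neg
        j = se + sp - 1.0
        if j > best_j:
            best_t, best_j = float(t), j
    return best_t


def _ratio(num: float, den: float) -> float:
    if den == 0.0:
        return float("inf") if num > 0 else float("nan")
    return num / den


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Se/Sp/PPV/NPV/Acc in percent; LR+ and LR- on the proportion scale.

    Undefined ratios (zero denominator) are inf or NaN; ``degenerate``
    reports whether any occurred.
    """

    se: float
    sp: float
    ppv: float
    npv: float
    lr_plus: float
    lr_minus: float
    acc: float

    @property
    def degenerate(self) -> bool:
        vals = [self.se, self.sp, self.ppv, self.npv, self.lr_plus, self.lr_minus]
        return any(not np.isfinite(v) for v in vals)

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def diagnostic_metrics(predicted, labels) -> DiagnosticMetrics:
    """Compute the 2x2-table screening metrics."""
    pred = np.asarray(predicted).astype(bool)
    y = np.asarray(labels).astype(bool)
    if y.size == 0:
        raise ValueError("empty input")
    tp = float((pred & y).sum())
    fn = float((~pred & y).sum())
    tn = float((~pred & ~y).sum())
    fp = float((pred & ~y).sum())
    se = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    return DiagnosticMetrics(
        se=100.0 * se,
        sp=100.0 * sp,
        ppv=100.0 * _ratio(tp, tp + fp),
        npv=100.0 * _ratio(tn, tn + fn),
        lr_plus=_ratio(se, 1.0 - sp),
        lr_minus=_ratio(1.0 - se, sp),
        acc=100.0 * (tp + tn) / y.size,
    )


@dataclass
class EvaluationReport:
    """Per-fold diagnostic metrics with across-fold mean and SD."""

    per_fold: list[DiagnosticMetrics]
    models: list | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.per_fold)

    def _table(self) -> pd.DataFrame:
        return pd.DataFrame([m.as_dict() for m in self.per_fold])

    def mean(self) -> dict[str, float]:
        return self._table().mean().to_dict()

    def std(self) -> dict[str, float]:
        """Across-fold standard deviation (the dispersion reported with
        every averaged metric)."""
        return self._table().std(ddof=1).to_dict()

    def summary(self) -> pd.DataFrame:
        t = self._table()
        return pd.DataFrame({"mean": t.mean(), "sd": t.std(ddof=1)})


def kfold_evaluate(
    plan: SplitPlan, model, X, y, *, return_models: bool = False
) -> EvaluationReport:
    """Train on K-1 folds, test on the held-out fold, for each fold of the
    plan's cross-validation portion.

    ``model`` is an unfitted sklearn-style estimator (a pipeline from
    :func:`make_classifier`, or :class:`SingleFeatureClassifier`); it is
    cloned and refitted per fold, so every data-driven quantity -- scaler
    statistics, ROC cutoffs -- is re-estimated from training folds only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    per_fold = []
    models = []
    for tr, te in plan.folds:
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError("a fold contains a single class")
        m = clone(model).fit(X[tr], y[tr])
        per_fold.append(diagnostic_metrics(m.predict(X[te]), y[te]))
        models.append(m)
    return EvaluationReport(per_fold, models=models if return_models else None)


def mannwhitney_compare(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (tie-corrected); returns (U, p) with
    U the statistic of the first group."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
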