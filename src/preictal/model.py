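"""RF-initialized gradient-boosted trees, cross-validation and metrics.

The classifier is a logistic-loss gradient-boosting machine whose initial
score is not the usual constant: a random forest is fitted first and its
class-1 probability ``p_hat`` for each sample becomes the boosting start
``H_0``.  Probabilities live in (0, 1) while boosting scores live on the
logit scale, so by default ``H_0 = logit(clip(p_hat, eps, 1 - eps))``; the
literal reading (feed the probability straight in as a score) is kept
behind ``init_mode="raw"``.

Each boosting round fits a regression tree to the negative gradient of the
logistic loss, ``r_i = y_i - sigmoid(H(x_i))``, and assigns each leaf a
single Newton step ``sum(r) / sum(p (1 - p))``; scores update as
``H <- H + phi * f_t(x)`` with shrinkage ``phi``.  ``T = 0`` rounds therefore
reproduces the random forest exactly (through the sigmoid).

Evaluation is stratified k-fold cross-validation at the window level;
out-of-fold predictions are kept in row order so the alarm stage can
reassemble per-segment decision sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeRegressor

from .entropy import FeatureMatrix

__all__ = ["ModelParams", "BoostingState", "ConfusionMatrix", "CVReport",
           "fit_rf_init", "fit_gbdt", "predict", "cross_validate", "metrics",
           "sigmoid"]

_EPS = 1e-6


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    from scipy.special import expit
    return expit(z)


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


@dataclass(frozen=True)
class ModelParams:
    n_rounds: int = 100          # T
    shrinkage: float = 0.1       # phi
    max_depth: int = 3
    rf_trees: int = 100
    init_mode: str = "logit"     # or "raw": feed the RF probability as-is

    def __post_init__(self) -> None:
        if self.n_rounds < 0:
            raise ValueError("n_rounds >= 0")
        if not (0 < self.shrinkage <= 1):
            raise ValueError("shrinkage in (0, 1]")
        if self.init_mode not in ("logit", "raw"):
            raise ValueError("init_mode must be 'logit' or 'raw'")


@dataclass
class BoostingState:
    """Fitted RF + boosted trees; enough to score new samples."""

    rf: RandomForestClassifier | None
    trees: list[DecisionTreeRegressor]
    leaf_values: list[dict[int, float]]
    params: ModelParams
    n_features: int
    train_loss: list[float] = field(default_factory=list)
    residuals: list[np.ndarray] = field(default_factory=list)

    def initial_scores(self, X: np.ndarray) -> np.ndarray:
        if self.rf is None:
            return np.zeros(len(X))
        p = self.rf.predict_proba(X)[:, list(self.rf.classes_).index(1)]
        return _logit(p) if self.params.init_mode == "logit" else p.copy()

    def partial_scores(self, X: np.ndarray, n_trees: int,
                       h0: np.ndarray | None = None) -> np.ndarray:
        """Cumulative score H_t after the first ``n_trees`` boosting rounds."""
        h = self.initial_scores(X) if h0 is None else np.asarray(h0, float).copy()
        for tree, values in zip(self.trees[:n_trees], self.leaf_values[:n_trees]):
            leaves = tree.apply(X)
            h = h + self.params.shrinkage * np.array(
                [values[int(l)] for l in leaves])
        return h


def _rf_initial_scores(rf: RandomForestClassifier, X: np.ndarray,
                       init_mode: str, training: bool) -> np.ndarray:
    """Class-1 probability -> score.  On training data prefer out-of-bag
    probabilities (less optimistic than refit probabilities); samples never
    left out of a bootstrap fall back to the in-fit estimate."""
    cls1 = list(rf.classes_).index(1)
    p_fit = rf.predict_proba(X)[:, cls1]
    if training and getattr(rf, "oob_decision_function_", None) is not None:
        p_oob = rf.oob_decision_function_[:, cls1]
        p = np.where(np.isnan(p_oob), p_fit, p_oob)
    else:
        p = p_fit
    return _logit(p) if init_mode == "logit" else p.copy()


def fit_rf_init(X: np.ndarray, y: np.ndarray,
                params: ModelParams = ModelParams(), seed: int = 0
                ) -> tuple[RandomForestClassifier, np.ndarray]:
    """Fit the random forest and return it with per-sample initial scores."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    rf = RandomForestClassifier(n_estimators=params.rf_trees,
                                oob_score=True, random_state=seed)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small folds can starve OOB
        rf.fit(X, y)
    h0 = _rf_initial_scores(rf, X, params.init_mode, training=True)
    return rf, h0


def fit_gbdt(X: np.ndarray, y: np.ndarray, h0: np.ndarray | None = None,
             params: ModelParams = ModelParams(), seed: int = 0,
             rf: RandomForestClassifier | None = None,
             keep_residuals: bool = False) -> BoostingState:
    """Boost ``params.n_rounds`` logistic-loss regression trees from ``h0``.

    With ``keep_residuals`` the per-round negative gradients are retained on
    the state so the identity ``r_t + sigmoid(H_{t-1}) == y`` can be audited
    externally.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    h = np.zeros(len(X)) if h0 is None else np.asarray(h0, dtype=np.float64).copy()

    state = BoostingState(rf=rf, trees=[], leaf_values=[], params=params,
                          n_features=X.shape[1])
    state.train_loss.append(_log_loss(y, sigmoid(h)))
    rng = np.random.SeedSequence(seed)
    tree_seeds = rng.generate_state(max(params.n_rounds, 1)) % (2 ** 31)
    for t in range(params.n_rounds):
        p = sigmoid(h)
        residual = y - p            # negative gradient of the logistic loss
        if keep_residuals:
            state.residuals.append(residual.copy())
        tree = DecisionTreeRegressor(max_depth=params.max_depth,
                                     random_state=int(tree_seeds[t]))
        tree.fit(X, residual)
        leaves = tree.apply(X)
        hess = np.maximum(p * (1.0 - p), 1e-12)
        values: dict[int, float] = {}
        for leaf in np.unique(leaves):
            sel = leaves == leaf
            values[int(leaf)] = float(residual[sel].sum() / hess[sel].sum())
        h = h + params.shrinkage * np.array([values[int(l)] for l in leaves])
        state.trees.append(tree)
        state.leaf_values.append(values)
        state.train_loss.append(_log_loss(y, sigmoid(h)))
    return state


def _log_loss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def predict(state: BoostingState, X: np.ndarray,
            h0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(labels, probabilities); label 1 iff p >= 0.5 (alarm-favoring tie)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != state.n_features:
        raise ValueError(f"expected {state.n_features} features, got {X.shape[1]}")
    h = state.partial_scores(X, len(state.trees), h0=h0)
    proba = sigmoid(h)
    return (proba >= 0.5).astype(np.int64), proba


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray
                         ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, FPR, F1; NaN where the denominator is zero."""
    def safe(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    return {
        "accuracy": safe(cm.tp + cm.tn, cm.total),
        "sensitivity": safe(cm.tp, cm.tp + cm.fn),
        "fpr": safe(cm.fp, cm.fp + cm.tn),
        "f1": safe(2 * cm.tp, 2 * cm.tp + cm.fn + cm.fp),
    }


@dataclass
class CVReport:
    """Per-fold and averaged metrics plus row-aligned out-of-fold outputs."""

    fold_metrics: list[dict[str, float]]
    mean_metrics: dict[str, float]
    oof_pred: np.ndarray
    oof_proba: np.ndarray
    k: int
    seed: int

    def to_dict(self) -> dict:
        return {"k": self.k, "seed": self.seed,
                "fold_metrics": self.fold_metrics,
                "mean_metrics": self.mean_metrics}


def cross_validate(fm: FeatureMatrix, k: int = 10,
                   params: ModelParams = ModelParams(),
                   seed: int = 0, group_by_segment: bool = False) -> CVReport:
    """Stratified k-fold CV of the RF+GBDT classifier.

    ``group_by_segment`` assigns whole 10-min segments to folds (no window
    of one epoch in both train and test); the default matches the pooled
    window-level protocol.
    """
    if k < 2:
        raise ValueError("k >= 2")
    X, y = fm.X, fm.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(f"stratification impossible: a class has fewer than "
                         f"{k} samples")

    if group_by_segment:
        folds = _segment_folds(fm, k, seed)
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))

    oof_pred = np.full(len(y), -1, dtype=np.int64)
    oof_proba = np.full(len(y), np.nan)
    fold_metrics = []
    fold_seeds = np.random.SeedSequence(seed).generate_state(k) % (2 ** 31)
    for f, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {f}: a class is absent from the training split")
        rf, h0 = fit_rf_init(X[tr], y[tr], params, seed=int(fold_seeds[f]))
        state = fit_gbdt(X[tr], y[tr], h0, params,
                         seed=int(fold_seeds[f]), rf=rf)
        pred, proba = predict(state, X[te])
        oof_pred[te] = pred
        oof_proba[te] = proba
        fold_metrics.append(metrics(ConfusionMatrix.from_predictions(y[te], pred)))

    mean_metrics = {key: float(np.nanmean([fm_[key] for fm_ in fold_metrics]))
                    for key in fold_metrics[0]}
    return CVReport(fold_metrics=fold_metrics, mean_metrics=mean_metrics,
                    oof_pred=oof_pred, oof_proba=oof_proba, k=k, seed=seed)


def _segment_folds(fm: FeatureMatrix, k: int, seed: int):
    """Group-stratified folds: whole segments assigned round-robin per class."""
    meta = fm.meta
    rng = np.random.default_rng(seed)
    folds_tr, assignments = [], {}
    for label in (0, 1):
        segs = meta.loc[meta["label"] == label, "segment_index"].unique()
        segs = rng.permutation(segs)
        for i, s in enumerate(segs):
            assignments[int(s)] = i % k
    seg_fold = meta["segment_index"].map(assignments).to_numpy()
    idx = np.arange(len(meta))
    for f in range(k):
        te = idx[seg_fold == f]
        tr = idx[seg_fold != f]
        if len(te):
            folds_tr.append((tr, te))
    return folds_tr
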