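"""Condition classification from the 17 screened features.

Five standard algorithms (SVM with RBF and polynomial kernels, k-NN, a
single-hidden-layer MLP and a random forest) are evaluated under two
schemes: leave-one-out over trials, and leave-one-gesture-type-out, where
all trials of one action type form the test set of a fold (seven folds),
probing generalization to unseen gestures.  Features are z-scored with
statistics fit on each training partition only; SVM hyperparameters are
tuned by grid search over consecutive powers of two.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from vitalkin.errors import ConfigurationError, DataError
from vitalkin.stats import SIGNIFICANT_FEATURES
from vitalkin.synthetic import CONDITIONS

log = logging.getLogger(__name__)

ALGORITHMS = ("svm_rbf", "svm_poly", "knn", "mlp", "rf")

#: class order of every confusion matrix
CLASS_ORDER = tuple(CONDITIONS)

#: feature subsets with published reference results, plus the
#: factor-representative set (one feature per retained component)
BUILTIN_SUBSETS = {
    "Amx+SMsd": ["Amx", "SMsd"],
    "Amx+Vmx": ["Amx", "Vmx"],
    "Amx+SMa": ["Amx", "SMa"],
    "Amx+VWsd": ["Amx", "VWsd"],
    "Amx+SMsd+VWsd": ["Amx", "SMsd", "VWsd"],
    "Amx+Vmx+SMsd": ["Amx", "Vmx", "SMsd"],
    "Amx+SMmx+SMa+SMsd+VWsd": ["Amx", "SMmx", "SMa", "SMsd", "VWsd"],
    "Amx+Vmx+SMsd+VWsd": ["Amx", "Vmx", "SMsd", "VWsd"],
    "factor_representatives": ["Jmx", "SMmx", "AACsd", "AEsd", "AACmx", "S"],
}


@dataclass
class ClassifierSpec:
    """Algorithm choice plus hyperparameters; ``None`` means tune/default."""

    algorithm: str
    C: float | None = None
    gamma: float | None = None
    k: int | None = None
    hidden: int = 32
    max_epochs: int = 300
    n_trees: int = 300
    degree: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        for name in ("C", "gamma"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigurationError(f"{name} must be positive")


def make_estimator(spec: ClassifierSpec):
    if spec.algorithm == "svm_rbf":
        return SVC(kernel="rbf", C=spec.C or 1.0, gamma=spec.gamma or "scale")
    if spec.algorithm == "svm_poly":
        return SVC(kernel="poly", degree=spec.degree, C=spec.C or 1.0, gamma=spec.gamma or "scale")
    if spec.algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=spec.k or 5)
    if spec.algorithm == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(spec.hidden,),
            max_iter=spec.max_epochs,
            random_state=spec.seed,
        )
    return RandomForestClassifier(
        n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
    )


def normalize_features(
    train: np.ndarray, test: np.ndarray | None = None, method: str = "minmax"
):
    """Per-feature scaling with statistics fit on the training partition only.

    ``minmax`` (default) maps each feature's training range to [0, 1] —
    the scaling under which the power-of-two SVM hyperparameter grid is
    meaningful; ``zscore`` centers to mean 0, SD 1.  Zero-variance features
    are centered but not scaled (with a warning).  Held-out rows may fall
    outside the training range (no clipping).  Returns
    ``(train_scaled, test_scaled)``.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise DataError("empty training partition")
    if method == "zscore":
        mu = train.mean(axis=0)
        sd = train.std(axis=0, ddof=0)
        flat = sd == 0
        scale = np.where(flat, 1.0, sd)
    elif method == "minmax":
        mu = train.min(axis=0)
        rng = train.max(axis=0) - mu
        flat = rng == 0
        scale = np.where(flat, 1.0, rng)
    else:
        raise ConfigurationError(f"unknown normalization method {method!r}")
    if flat.any():
        log.warning("%d zero-variance feature(s) centered but not scaled", int(flat.sum()))
    ts = None if test is None else (np.asarray(test, dtype=float) - mu) / scale
    return (train - mu) / scale, ts


def chance_level(labels) -> float:
    """Majority-class share in percent."""
    counts = pd.Series(list(labels)).value_counts()
    return float(100.0 * counts.iloc[0] / counts.sum())


# ---------------------------------------------------------------------------
# evaluation reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Classification results of one (scheme, algorithm) combination."""

    scheme: str
    algorithm: str
    accuracy: float  # percent
    f_score: float
    precision: float
    recall: float
    confusion: pd.DataFrame  # rows true, cols predicted, CLASS_ORDER
    per_fold: pd.DataFrame | None = None  # logo: one row per withheld action
    sd: dict = field(default_factory=dict)  # logo: sd of metrics across folds

    def to_dict(self) -> dict:
        out = {
            "scheme": self.scheme,
            "algorithm": self.algorithm,
            "accuracy": self.accuracy,
            "f_score": self.f_score,
            "precision": self.precision,
            "recall": self.recall,
            "confusion": self.confusion.to_dict(),
        }
        if self.per_fold is not None:
            out["per_fold"] = self.per_fold.to_dict(orient="records")
        if self.sd:
            out["sd"] = self.sd
        return out


def _metrics(y_true, y_pred) -> dict:
    """Support-weighted metrics, in percent."""
    return {
        "accuracy": 100.0 * float(np.mean(np.asarray(y_true) == np.asarray(y_pred))),
        "f_score": 100.0 * f1_score(y_true, y_pred, average="weighted", zero_division=0),
        "precision": 100.0 * precision_score(y_true, y_pred, average="weighted", zero_division=0),
        "recall": 100.0 * recall_score(y_true, y_pred, average="weighted", zero_division=0),
    }


def _confusion(y_true, y_pred) -> pd.DataFrame:
    labels = [c for c in CLASS_ORDER if c in set(y_true) | set(y_pred)]
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return pd.DataFrame(cm, index=labels, columns=labels)


def report_from_predictions(scheme, algorithm, y_true, y_pred, per_fold=None, sd=None):
    m = _metrics(y_true, y_pred)
    return EvalReport(
        scheme=scheme,
        algorithm=algorithm,
        confusion=_confusion(y_true, y_pred),
        per_fold=per_fold,
        sd=sd or {},
        **m,
    )


def metrics_from_confusion(cm: pd.DataFrame) -> dict:
    """Recompute the weighted metrics from a stored confusion matrix."""
    M = cm.to_numpy(dtype=float)
    support = M.sum(axis=1)
    total = M.sum()
    acc = np.trace(M) / total
    prec_c = np.divide(np.diag(M), M.sum(axis=0), out=np.zeros(len(M)), where=M.sum(axis=0) > 0)
    rec_c = np.divide(np.diag(M), support, out=np.zeros(len(M)), where=support > 0)
    f1_c = np.divide(
        2 * prec_c * rec_c, prec_c + rec_c, out=np.zeros(len(M)), where=(prec_c + rec_c) > 0
    )
    w = support / total
    return {
        "accuracy": 100.0 * float(acc),
        "f_score": 100.0 * float((f1_c * w).sum()),
        "precision": 100.0 * float((prec_c * w).sum()),
        "recall": 100.0 * float((rec_c * w).sum()),
    }


# ---------------------------------------------------------------------------
# hyperparameter tuning
# ---------------------------------------------------------------------------

def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbf",
    exponent_range: tuple = (1, 9),
    cv: int = 5,
    seed: int = 0,
    degree: int = 3,
):
    """Tune (C, gamma) over consecutive powers of 2 in ``exponent_range``.

    Selection is by mean cross-validated weighted F-score; ties break
    toward smaller C, then smaller gamma.  Normalization is refit inside
    each inner fold.  Returns ``(C, gamma)``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DataError("grid search needs >= 2 classes")
    lo, hi = exponent_range
    cands = [(2.0**i, 2.0**j) for i in range(lo, hi + 1) for j in range(lo, hi + 1)]
    n_splits = min(cv, int(pd.Series(y).value_counts().min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = None
    for C, gamma in cands:  # ordered ascending: first max wins ties
        scores = []
        for tr, te in folds:
            Xtr, Xte = normalize_features(X[tr], X[te])
            clf = SVC(kernel=kernel, C=C, gamma=gamma, degree=degree)
            clf.fit(Xtr, y[tr])
            scores.append(f1_score(y[te], clf.predict(Xte), average="weighted", zero_division=0))
        score = float(np.mean(scores))
        if best is None or score > best[0] + 1e-12:
            best = (score, C, gamma)
    return best[1], best[2]


def _tune_knn(X, y, ks=tuple(range(1, 16, 2)), cv: int = 5, seed: int = 0) -> int:
    n_splits = max(min(cv, int(pd.Series(y).value_counts().min())), 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = None
    for k in ks:
        if k >= len(y) * (1 - 1 / n_splits):
            continue
        scores = []
        for tr, te in folds:
            Xtr, Xte = normalize_features(X[tr], X[te])
            clf = KNeighborsClassifier(n_neighbors=k).fit(Xtr, y[tr])
            scores.append(f1_score(y[te], clf.predict(Xte), average="weighted", zero_division=0))
        score = float(np.mean(scores))
        if best is None or score > best[0] + 1e-12:
            best = (score, k)
    return best[1]


def _resolve_spec(spec: ClassifierSpec, X, y, exponent_range=(1, 9)) -> ClassifierSpec:
    """Fill unset hyperparameters by tuning on the given training data."""
    if spec.algorithm in ("svm_rbf", "svm_poly") and (spec.C is None or spec.gamma is None):
        kernel = "rbf" if spec.algorithm == "svm_rbf" else "poly"
        C, gamma = grid_search_svm(
            X, y, kernel, exponent_range, seed=spec.seed, degree=spec.degree
        )
        return replace(spec, C=C, gamma=gamma)
    if spec.algorithm == "knn" and spec.k is None:
        return replace(spec, k=_tune_knn(X, y, seed=spec.seed))
    return spec


# ---------------------------------------------------------------------------
# validation schemes
# ---------------------------------------------------------------------------

def _design(table: pd.DataFrame, feature_subset):
    feats = list(feature_subset) if feature_subset is not None else list(SIGNIFICANT_FEATURES)
    missing = [f for f in feats if f not in table.columns]
    if missing:
        raise DataError(f"features absent from table: {missing}")
    return table[feats].to_numpy(dtype=float), table["condition"].to_numpy()


def loocv_evaluate(table: pd.DataFrame, spec: ClassifierSpec, feature_subset=None) -> EvalReport:
    """Leave-one-trial-out evaluation; normalization refit per fold.

    Unset SVM/k-NN hyperparameters are tuned once on the full table before
    the folds are run (mirroring a single preliminary grid search).
    """
    X, y = _design(table, feature_subset)
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise DataError(f"every class needs >= 2 trials, got {counts.to_dict()}")
    spec = _resolve_spec(spec, X, y)
    n = len(y)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, Xte = normalize_features(X[tr], X[[i]])
        clf = make_estimator(spec)
        clf.fit(Xtr, y[tr])
        preds[i] = clf.predict(Xte)[0]
    return report_from_predictions("loocv", spec.algorithm, y, preds)


def logo_evaluate(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    feature_subset=None,
    exponent_range: tuple = (1, 9),
) -> EvalReport:
    """Leave-one-gesture-type-out evaluation: one fold per action type.

    SVM hyperparameters are re-tuned independently within each fold's
    training partition.  Metrics are reported as the mean (SD) across
    folds; the confusion matrix pools all folds.
    """
    actions = sorted(table["action"].unique())
    if len(actions) < 2:
        raise DataError("leave-one-gesture-type-out needs >= 2 action types")
    X, y = _design(table, feature_subset)
    fold_rows = []
    y_all, p_all = [], []
    for action in actions:
        te = (table["action"] == action).to_numpy()
        tr = ~te
        spec_f = _resolve_spec(spec, X[tr], y[tr], exponent_range)
        Xtr, Xte = normalize_features(X[tr], X[te])
        clf = make_estimator(spec_f)
        clf.fit(Xtr, y[tr])
        pred = clf.predict(Xte)
        m = _metrics(y[te], pred)
        fold_rows.append({"action": action, "n_test": int(te.sum()), **m})
        y_all.extend(y[te])
        p_all.extend(pred)
    per_fold = pd.DataFrame(fold_rows)
    means = per_fold[["accuracy", "f_score", "precision", "recall"]].mean()
    sds = per_fold[["accuracy", "f_score", "precision", "recall"]].std(ddof=1)
    return EvalReport(
        scheme="logo",
        algorithm=spec.algorithm,
        accuracy=float(means["accuracy"]),
        f_score=float(means["f_score"]),
        precision=float(means["precision"]),
        recall=float(means["recall"]),
        confusion=_confusion(y_all, p_all),
        per_fold=per_fold,
        sd={k: float(sds[k]) for k in sds.index},
    )


def compare_fold_scores(scores_by_group: dict):
    """One-way ANOVA + Tukey HSD over per-fold F-scores grouped by algorithm
    (or by action type).  Returns ``(F, p, tukey_frame)``."""
    groups = {k: np.asarray(v, dtype=float) for k, v in scores_by_group.items()}
    if len(groups) < 2:
        raise DataError("need >= 2 groups")
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1:
        raise DataError(f"unequal fold counts across groups: { {k: len(v) for k, v in groups.items()} }")
    if min(sizes) < 2:
        raise DataError("need >= 2 folds per group")
    arrays = list(groups.values())
    if all(np.allclose(a, arrays[0]) for a in arrays[1:]) and all(
        np.allclose(a, a.mean()) for a in arrays
    ):
        F, p = 0.0, 1.0
    else:
        F, p = sps.f_oneway(*arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = np.concatenate(arrays)
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    tk = pairwise_tukeyhsd(data, labels)
    frame = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return float(F), float(p), frame


def single_feature_ranking(
    table: pd.DataFrame, features=None, spec: ClassifierSpec | None = None
) -> pd.DataFrame:
    """Leave-one-out random-forest evaluation of each feature alone;
    returns a frame sorted by descending F-score."""
    feats = list(features) if features is not None else list(SIGNIFICANT_FEATURES)
    if spec is None:
        spec = ClassifierSpec("rf")
    rows = []
    for feat in feats:
        rep = loocv_evaluate(table, spec, [feat])
        rows.append({"feature": feat, "accuracy": rep.accuracy, "f_score": rep.f_score})
    return (
        pd.DataFrame(rows)
        .sort_values("f_score", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


def subset_evaluation(
    table: pd.DataFrame, subsets: dict | None = None, spec: ClassifierSpec | None = None
) -> pd.DataFrame:
    """Leave-one-out random-forest metrics for named feature subsets."""
    if subsets is None:
        subsets = BUILTIN_SUBSETS
    if spec is None:
        spec = ClassifierSpec("rf")
    rows = []
    for name, feats in subsets.items():
        if not feats:
            raise ConfigurationError(f"subset {name!r} is empty")
        rep = loocv_evaluate(table, spec, feats)
        rows.append(
            {
                "subset": name,
                "n_features": len(feats),
                "accuracy": rep.accuracy,
                "f_score": rep.f_score,
                "precision": rep.precision,
                "recall": rep.recall,
            }
        )
    return pd.DataFrame(rows)
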