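"""Severity classification: six classifiers, repeated stratified k-fold CV
and seven evaluation metrics.

The classifier zoo covers ECOC-SVM (one-vs-one coding over binary SVMs),
Gaussian naive Bayes, k-NN, a 100-tree random forest, AdaBoost over decision
stumps, and a four-layer fully connected network (hidden 256-128-64, Adam,
learning rate 0.001, batch 32, cross-entropy, 200 epochs).  Features are
z-scored inside each training fold.  Aggregate metrics are the overall
accuracy, macro-averaged one-vs-rest sensitivity / specificity / precision /
F1, the generalized multiclass Matthews correlation coefficient and Cohen's
kappa, reported as mean ± sd over all folds of all repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.multiclass import OneVsOneClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .selection import select_features

__all__ = ["ClassifierSpec", "CVConfig", "EvalReport", "CLASSIFIER_KINDS",
           "make_classifier", "train", "predict", "compute_metrics",
           "cross_validate", "run_experiment"]

CLASSIFIER_KINDS = ("ecoc_svm", "nb", "knn", "rf", "adaboost", "dnn")

METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1",
           "mcc", "kappa")


@dataclass
class ClassifierSpec:
    kind: str = "rf"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class CVConfig:
    k_folds: int = 5
    repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2 or self.repeats < 1:
            raise ValueError("need k_folds >= 2 and repeats >= 1")


@dataclass
class EvalReport:
    confusions: list[np.ndarray]
    summary: pd.DataFrame  # index = metric, columns = mean, sd
    classes: list


def make_classifier(spec: ClassifierSpec) -> Pipeline:
    """Build the (scaler -> estimator) pipeline for one classifier kind."""
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.kind == "ecoc_svm":
        est = OneVsOneClassifier(SVC(kernel=hp.get("kernel", "rbf"),
                                     random_state=seed))
    elif spec.kind == "nb":
        est = GaussianNB()
    elif spec.kind == "knn":
        est = KNeighborsClassifier(n_neighbors=hp.get("k", 5))
    elif spec.kind == "rf":
        est = RandomForestClassifier(n_estimators=hp.get("n_trees", 100),
                                     random_state=seed)
    elif spec.kind == "adaboost":
        est = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
            n_estimators=hp.get("n_estimators", 100), random_state=seed)
    else:  # dnn
        est = MLPClassifier(hidden_layer_sizes=hp.get("layers", (256, 128, 64)),
                            solver="adam",
                            learning_rate_init=hp.get("lr", 0.001),
                            batch_size=hp.get("batch", 32),
                            max_iter=hp.get("epochs", 200),
                            random_state=seed)
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def train(spec: ClassifierSpec, X, y) -> Pipeline:
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    model = make_classifier(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        model.fit(X, np.asarray(y))
    return model


def predict(model: Pipeline, X) -> np.ndarray:
    return model.predict(np.asarray(X, dtype=float))


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def compute_metrics(cm: np.ndarray) -> dict:
    """Seven metrics from a confusion matrix (rows = truth, cols = predicted).

    Sensitivity, specificity, precision and F1 are macro-averaged over
    one-vs-rest decompositions; a per-class table is returned alongside.
    MCC uses the generalized multiclass correlation form.
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError("confusion matrix must be square with >= 2 classes")
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = n - tp - fn - fp

    def _safe(num, den):
        den = np.asarray(den, dtype=float)
        out = np.zeros_like(den)
        ok = den > 0
        out[ok] = np.asarray(num, dtype=float)[ok] / den[ok]
        return out

    sens = _safe(tp, tp + fn)
    spec = _safe(tn, tn + fp)
    prec = _safe(tp, tp + fp)
    f1 = _safe(2 * prec * sens, prec + sens)

    # generalized multiclass MCC
    t_k = cm.sum(axis=1)
    p_k = cm.sum(axis=0)
    c = tp.sum()
    num = c * n - (t_k * p_k).sum()
    den = np.sqrt(n ** 2 - (p_k ** 2).sum()) * np.sqrt(n ** 2 - (t_k ** 2).sum())
    mcc = float(num / den) if den > 0 else 0.0

    po = c / n
    pe = (t_k * p_k).sum() / n ** 2
    kappa = float((po - pe) / (1 - pe)) if pe < 1 else 0.0

    per_class = pd.DataFrame({"sensitivity": sens, "specificity": spec,
                              "precision": prec, "f1": f1})
    return {"accuracy": float(po), "sensitivity": float(sens.mean()),
            "specificity": float(spec.mean()), "precision": float(prec.mean()),
            "f1": float(f1.mean()), "mcc": mcc, "kappa": kappa,
            "per_class": per_class}


def cross_validate(spec: ClassifierSpec, X, y, cv: CVConfig | None = None,
                   select_in_fold: bool = False,
                   selection_fraction: float = 2 / 3) -> EvalReport:
    """Repeated stratified k-fold evaluation with fold-internal scaling.

    With ``select_in_fold`` the three-filter consensus selection runs inside
    each training fold and the test fold is restricted to the chosen columns
    (avoids selection leakage).
    """
    cv = cv or CVConfig()
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    counts = pd.Series(y).value_counts()
    if counts.min() < cv.k_folds:
        raise ValueError("every class needs at least k_folds members")
    splitter = RepeatedStratifiedKFold(n_splits=cv.k_folds,
                                       n_repeats=cv.repeats,
                                       random_state=cv.seed)
    confusions = []
    per_fold = {m: [] for m in METRICS}
    for tr, te in splitter.split(Xdf, y):
        Xtr, Xte = Xdf.iloc[tr], Xdf.iloc[te]
        if select_in_fold and Xtr.shape[1] > 1:
            try:
                sel = select_features(Xtr, y[tr], fraction=selection_fraction)
                Xtr, Xte = Xtr[sel.selected], Xte[sel.selected]
            except ValueError:
                pass  # empty consensus: keep all columns for this fold
        model = train(spec, Xtr.to_numpy(float), y[tr])
        pred = predict(model, Xte.to_numpy(float))
        cm = _confusion(y[te], pred, classes)
        confusions.append(cm)
        m = compute_metrics(cm)
        for name in METRICS:
            per_fold[name].append(m[name])
    summary = pd.DataFrame({
        "mean": {k: float(np.mean(v)) for k, v in per_fold.items()},
        "sd": {k: float(np.std(v)) for k, v in per_fold.items()},
    })
    return EvalReport(confusions=confusions, summary=summary, classes=classes)


# the seven feature combinations used in the classification experiments
FEATURE_COMBOS = {
    "texture": ("texture",),
    "color": ("color",),
    "spectrum": ("spectrum",),
    "texture+color": ("texture", "color"),
    "texture+spectrum": ("texture", "spectrum"),
    "color+spectrum": ("color", "spectrum"),
    "full": ("texture", "color", "spectrum"),
}


def run_experiment(features: pd.DataFrame, combos: list[str],
                   classifier_kinds: list[str], cv: CVConfig | None = None,
                   metric: str = "f1", seed: int = 0) -> pd.DataFrame:
    """Grid of classifier x feature-combination results (headline metric F1).

    ``features`` is an extract_matrix frame (filename/label/is_patch plus
    prefixed feature columns).  A failed cell is recorded as NaN.
    """
    cv = cv or CVConfig()
    prefix = {"texture": "tex.", "color": "col.", "spectrum": "spec."}
    y = features["label"].to_numpy()
    results = pd.DataFrame(index=classifier_kinds, columns=combos, dtype=float)
    for combo in combos:
        groups = FEATURE_COMBOS[combo]
        cols = [c for c in features.columns
                if any(c.startswith(prefix[g]) for g in groups)]
        X = features[cols]
        for kind in classifier_kinds:
            try:
                rep = cross_validate(ClassifierSpec(kind=kind, seed=seed),
                                     X, y, cv)
                results.loc[kind, combo] = rep.summary.loc[metric, "mean"]
            except ValueError:
                results.loc[kind, combo] = np.nan
    return results
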