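"""Classifier training and evaluation on strip term vectors.

Strips are split 70/15/15 into train/validation/test, stratified by
label.  The main classifier is a one-hidden-layer MLP (10 neurons by
default) whose early stopping is driven by the validation split;
Gaussian-kernel SVM, linear SVM, KNN and Gaussian naive Bayes serve as
baselines, and a PCA feature path (flattened dense descriptors reduced
by PCA instead of the visual-word histogram) provides the ablation.

Metrics use MA as the positive class: accuracy, sensitivity
(= recall of MA), specificity (= recall of normal) and precision, in
percent.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

POSITIVE_LABEL = "MA"
NEGATIVE_LABEL = "normal"
SPLIT_NAMES = ("train", "validation", "test")

BASELINE_KINDS = ("gaussian_svm", "linear_svm", "knn", "naive_bayes")


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def ids(self, split: str) -> list[str]:
        return [sid for sid, s in self.assignment.items() if s == split]


@dataclass
class MLPSpec:
    hidden_neurons: int = 10
    activation: str = "tanh"
    learning_rate: float = 0.01
    max_epochs: int = 200
    steps_per_epoch: int = 20  # full-batch Adam steps between validations
    patience: int = 20
    n_restarts: int = 3  # random initializations; best validation loss wins
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_neurons < 1:
            raise ValueError("hidden_neurons must be >= 1")


@dataclass
class EvalMetrics:
    """Confusion counts with MA positive, plus the four derived rates
    in percent (NaN where the denominator is zero)."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    precision: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracy = _rate(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn, "accuracy")
        self.sensitivity = _rate(self.tp, self.tp + self.fn, "sensitivity")
        self.specificity = _rate(self.tn, self.tn + self.fp, "specificity")
        self.precision = _rate(self.tp, self.tp + self.fp, "precision")

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.tn, self.fn)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
        }


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> EvalMetrics:
    return EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def make_splits(strip_ids: list[str], labels: list[str], spec: SplitSpec) -> SplitSpec:
    """Stratified random train/validation/test assignment.

    Global split sizes are fixed by largest-remainder rounding of the
    fractions; per-label quotas are rounded the same way and then
    adjusted minimally so each split reaches its global size, keeping
    every per-label count within one strip of exact proportionality.
    """
    if len(strip_ids) != len(labels):
        raise ValueError("one label per strip id required")
    n = len(strip_ids)
    if n == 0:
        raise ValueError("no strips to split")
    fr = np.asarray(spec.fractions)

    def largest_remainder(total: int, fracs: np.ndarray) -> np.ndarray:
        exact = total * fracs
        out = np.floor(exact).astype(int)
        order = np.argsort(-(exact - out), kind="stable")
        for i in order[: total - out.sum()]:
            out[i] += 1
        return out

    global_sizes = largest_remainder(n, fr)
    by_label: dict[str, list[str]] = {}
    for sid, lab in zip(strip_ids, labels):
        by_label.setdefault(lab, []).append(sid)
    quotas = {lab: largest_remainder(len(ids), fr) for lab, ids in by_label.items()}

    # fix column sums to the global sizes, moving single strips between
    # the splits whose per-label rounding error is smallest
    cols = np.sum(list(quotas.values()), axis=0)
    labs = sorted(by_label)
    while not np.array_equal(cols, global_sizes):
        surplus = int(np.argmax(cols - global_sizes))
        deficit = int(np.argmin(cols - global_sizes))
        best_lab = min(
            (lab for lab in labs if quotas[lab][surplus] > 0),
            key=lambda lab: quotas[lab][surplus] - len(by_label[lab]) * fr[surplus],
        )
        quotas[best_lab][surplus] -= 1
        quotas[best_lab][deficit] += 1
        cols = np.sum(list(quotas.values()), axis=0)

    for lab, q in quotas.items():
        if any(len(by_label[lab]) > 0 and qi == 0 and fr[i] > 0 for i, qi in enumerate(q)):
            # a populated label would miss a requested split entirely
            if min(q[fr > 0]) == 0:
                raise ValueError(f"infeasible stratification for label {lab!r}")

    rng = np.random.default_rng(spec.seed)
    assignment: dict[str, str] = {}
    for lab in labs:
        ids = list(by_label[lab])
        rng.shuffle(ids)
        start = 0
        for split_name, count in zip(SPLIT_NAMES, quotas[lab]):
            for sid in ids[start : start + count]:
                assignment[sid] = split_name
            start += count
    return SplitSpec(fractions=spec.fractions, seed=spec.seed, assignment=assignment)


@dataclass
class MLPModel:
    """A trained one-hidden-layer network with its input scaler and
    training curve."""

    clf: MLPClassifier
    scaler: StandardScaler
    spec: MLPSpec
    n_epochs: int
    best_epoch: int
    val_history: list[float]

    def predict(self, X) -> np.ndarray:
        return self.clf.predict(self.scaler.transform(np.asarray(X)))

    def predict_proba_positive(self, X) -> np.ndarray:
        proba = self.clf.predict_proba(self.scaler.transform(np.asarray(X)))
        pos = list(self.clf.classes_).index(POSITIVE_LABEL)
        return proba[:, pos]


def train_mlp(
    train_vectors,
    train_labels,
    val_vectors,
    val_labels,
    spec: MLPSpec = MLPSpec(),
) -> MLPModel:
    """Train the MLP with early stopping on the provided validation set.

    ``spec.n_restarts`` networks are trained from different random
    initializations and the one with the lowest validation log-loss is
    kept — a small 10-neuron net is sensitive to its starting point.
    Inputs are standardized (zero mean, unit variance per feature, fit
    on the training split) before entering the network.
    """
    Xtr = np.asarray(train_vectors, dtype=np.float64)
    ytr = np.asarray(train_labels)
    Xval = np.asarray(val_vectors, dtype=np.float64)
    yval = np.asarray(val_labels)
    classes = np.unique(ytr)
    if classes.size < 2:
        raise ValueError("single-class training set")
    scaler = StandardScaler().fit(Xtr)
    Xtr = scaler.transform(Xtr)
    Xval = scaler.transform(Xval)

    best_model: MLPModel | None = None
    for restart in range(max(1, spec.n_restarts)):
        model = _train_mlp_once(Xtr, ytr, Xval, yval, spec, scaler, spec.seed + 1000 * restart)
        if best_model is None or min(model.val_history) < min(best_model.val_history):
            best_model = model
    return best_model


def _train_mlp_once(Xtr, ytr, Xval, yval, spec: MLPSpec, scaler, init_seed: int) -> MLPModel:
    """One training run with chunked full-batch Adam and early stopping.

    The network advances ``spec.steps_per_epoch`` steps at a time; after
    each chunk the validation log-loss is measured, training stops when
    it has not improved for ``spec.patience`` chunks, and the
    best-validation weights are restored.
    """
    clf = MLPClassifier(
        hidden_layer_sizes=(spec.hidden_neurons,),
        activation=spec.activation,
        solver="adam",
        batch_size=max(1, Xtr.shape[0]),
        learning_rate_init=spec.learning_rate,
        random_state=init_seed,
        max_iter=spec.steps_per_epoch,
        warm_start=True,
        tol=0.0,
        n_iter_no_change=np.inf,
    )
    best_loss = np.inf
    best_state = None
    best_epoch = 0
    history: list[float] = []
    epoch = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # chunked fits never "converge" per sklearn
        for epoch in range(1, spec.max_epochs + 1):
            clf.fit(Xtr, ytr)
            val_loss = _log_loss(yval, clf.predict_proba(Xval), clf.classes_)
            history.append(val_loss)
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best_state = (copy.deepcopy(clf.coefs_), copy.deepcopy(clf.intercepts_))
                best_epoch = epoch
            elif epoch - best_epoch >= spec.patience:
                break
    if best_state is not None:
        clf.coefs_, clf.intercepts_ = best_state
    return MLPModel(
        clf=clf, scaler=scaler, spec=spec, n_epochs=epoch, best_epoch=best_epoch, val_history=history
    )


def _log_loss(y, proba, classes) -> float:
    idx = np.searchsorted(classes, y)
    p = np.clip(proba[np.arange(len(y)), idx], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


def train_baseline(kind: str, train_vectors, train_labels, seed: int = 0, **params):
    """Fit one of the baseline classifiers.

    SVMs and KNN see standardized inputs (scaler fit on the training
    split); Gaussian naive Bayes is per-feature scale-equivariant and
    takes the raw vectors.  Hyperparameter defaults: Gaussian SVM with
    the variance-adaptive kernel width gamma = 1/(dim * Var(X)), C = 1;
    linear SVM C = 1; KNN k = 5.
    """
    X = np.asarray(train_vectors, dtype=np.float64)
    y = np.asarray(train_labels)
    if np.unique(y).size < 2:
        raise ValueError("single-class training set")
    if kind == "gaussian_svm":
        model = make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", gamma=params.pop("gamma", "scale"), C=params.pop("C", 1.0), random_state=seed),
        )
    elif kind == "linear_svm":
        model = make_pipeline(
            StandardScaler(), SVC(kernel="linear", C=params.pop("C", 1.0), random_state=seed)
        )
    elif kind == "knn":
        model = make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=params.pop("k", 5)))
    elif kind == "naive_bayes":
        model = GaussianNB()
    else:
        raise ValueError(f"unknown baseline classifier kind {kind!r}")
    model.fit(X, y)
    return model


def pca_feature_path(descriptor_sets, n_components: int = 50, train_mask=None):
    """Ablation features: flattened dense descriptors reduced by PCA.

    Each strip's 64 grid descriptors are concatenated in fixed grid
    order into a 4096-d vector; PCA is fitted on training strips only
    and all strips are projected to ``n_components``.

    Returns ``(projected_vectors, fitted_pca)``.
    """
    flat = np.stack([np.asarray(ds.matrix).ravel() for ds in descriptor_sets])
    if train_mask is None:
        train_mask = np.ones(flat.shape[0], dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    Xtr = flat[train_mask]
    max_rank = min(Xtr.shape[0], Xtr.shape[1])
    if n_components > max_rank:
        raise ValueError(f"n_components {n_components} exceeds data rank bound {max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    pca.fit(Xtr)
    return pca.transform(flat), pca


def evaluate(model, test_vectors, test_labels) -> EvalMetrics:
    """Confusion matrix and the four rates on a held-out set."""
    X = np.asarray(test_vectors, dtype=np.float64)
    y = np.asarray(test_labels)
    if y.size == 0:
        raise ValueError("empty test set")
    pred = model.predict(X)
    tp = int(np.sum((pred == POSITIVE_LABEL) & (y == POSITIVE_LABEL)))
    fp = int(np.sum((pred == POSITIVE_LABEL) & (y != POSITIVE_LABEL)))
    tn = int(np.sum((pred != POSITIVE_LABEL) & (y != POSITIVE_LABEL)))
    fn = int(np.sum((pred != POSITIVE_LABEL) & (y == POSITIVE_LABEL)))
    return metrics_from_confusion(tp, fp, tn, fn)


def hidden_neuron_sweep(
    train_vectors,
    train_labels,
    val_vectors,
    val_labels,
    test_vectors,
    test_labels,
    neuron_range=range(1, 21),
    seeds=(0,),
) -> list[dict]:
    """Mean test accuracy per hidden-layer size, over seeds."""
    neuron_range = list(neuron_range)
    if not neuron_range:
        raise ValueError("empty neuron range")
    rows = []
    for n_neurons in neuron_range:
        accs = []
        for seed in seeds:
            model = train_mlp(
                train_vectors, train_labels, val_vectors, val_labels,
                MLPSpec(hidden_neurons=n_neurons, seed=seed),
            )
            accs.append(evaluate(model, test_vectors, test_labels).accuracy)
        rows.append(
            {"hidden_neurons": n_neurons, "mean_accuracy": float(np.mean(accs)), "accuracies": accs}
        )
    return rows
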