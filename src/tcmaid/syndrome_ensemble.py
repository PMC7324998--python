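"""Per-disease syndrome prediction by majority vote over four base learners.

One integrated model is trained per disease over that disease's syndrome
label set.  Each model holds four heterogeneous learners — a
back-propagation multilayer perceptron, a support-vector classifier, a
random forest and an extreme-gradient-boosting classifier — fitted on the
same class-balanced feature vectors.  Prediction is majority rule over the
four votes; ties among top vote counts are broken by the highest mean
confidence of the tied label's voters, then lexicographically.  The
disease prediction gates which integrated model is consulted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .preprocess import balance_classes

logger = logging.getLogger(__name__)

__all__ = [
    "BASE_KINDS",
    "BaseLearnerSpec",
    "IntegratedModel",
    "Registry",
    "default_specs",
    "fit_integrated",
    "majority_vote",
    "predict_syndrome",
    "evaluate_models",
]

BASE_KINDS = ("backprop-mlp", "support-vector-classifier", "random-forest", "extreme-gradient-boosting")


@dataclass
class BaseLearnerSpec:
    kind: str
    hyperparams: dict = field(default_factory=dict)
    #: candidate hyperparameter dicts for the resampling search (may be empty)
    grid: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BASE_KINDS:
            raise ValueError(f"unknown base learner kind {self.kind!r}")


def default_specs(seed: int = 0) -> list[BaseLearnerSpec]:
    """One spec per kind with a small documented search grid."""
    return [
        BaseLearnerSpec("backprop-mlp", {"hidden_layer_sizes": (64,), "max_iter": 400}, seed=seed),
        BaseLearnerSpec(
            "support-vector-classifier", {"C": 1.0, "kernel": "linear"},
            grid=[{"C": 1.0, "kernel": "linear"}, {"C": 10.0, "kernel": "linear"}], seed=seed,
        ),
        BaseLearnerSpec(
            "random-forest", {"n_estimators": 100},
            grid=[{"n_estimators": 100}, {"n_estimators": 50}], seed=seed,
        ),
        BaseLearnerSpec("extreme-gradient-boosting", {"n_estimators": 50, "max_depth": 4}, seed=seed),
    ]


def _make_learner(kind: str, hyperparams: dict, seed: int):
    hp = dict(hyperparams)
    if kind == "backprop-mlp":
        return MLPClassifier(random_state=seed, **hp)
    if kind == "support-vector-classifier":
        return SVC(random_state=seed, **hp)  # confidences from decision_function
    if kind == "random-forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if kind == "extreme-gradient-boosting":
        hp.setdefault("n_jobs", 1)
        return XGBClassifier(random_state=seed, eval_metric="mlogloss", **hp)
    raise ValueError(f"unknown base learner kind {kind!r}")


class _Wrapped:
    """Uniform fit/predict-with-confidence facade over the four learners."""

    def __init__(self, kind: str, hyperparams: dict, seed: int):
        self.kind = kind
        self.hyperparams = dict(hyperparams)
        self.seed = seed
        self.classes_: np.ndarray | None = None
        self._clf = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Wrapped":
        self.classes_ = np.array(sorted(np.unique(y).tolist()))
        self._clf = _make_learner(self.kind, self.hyperparams, self.seed)
        if self.kind == "extreme-gradient-boosting":
            enc = {c: i for i, c in enumerate(self.classes_)}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._clf.fit(X, np.array([enc[v] for v in y]))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._clf.fit(X, y)
        return self

    def _proba(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "support-vector-classifier":
            # min-max scale decision values per row, normalize to sum 1
            dec = self._clf.decision_function(X)
            if dec.ndim == 1:
                dec = np.stack([-dec, dec], axis=1)
            lo = dec.min(axis=1, keepdims=True)
            hi = dec.max(axis=1, keepdims=True)
            span = np.where(hi - lo > 0, hi - lo, 1.0)
            scaled = (dec - lo) / span
            tot = scaled.sum(axis=1, keepdims=True)
            return np.where(tot > 0, scaled / tot, 1.0 / dec.shape[1])
        return self._clf.predict_proba(X)

    def predict_with_confidence(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (labels, confidence of the predicted label) per row."""
        proba = self._proba(np.atleast_2d(X))
        best = np.argmax(proba, axis=1)
        labels = self.classes_[best]
        conf = proba[np.arange(len(proba)), best]
        return labels, conf


@dataclass
class IntegratedModel:
    disease: str
    labels: tuple[str, ...]
    learners: dict[str, _Wrapped]  # kind -> fitted learner; empty if degenerate
    constant: str | None = None  # set for single-syndrome diseases
    meta: dict = field(default_factory=dict)

    def base_predictions(self, X: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {k: l.predict_with_confidence(X) for k, l in self.learners.items()}


@dataclass
class Registry:
    models: dict[str, IntegratedModel]

    def __contains__(self, disease: str) -> bool:
        return disease in self.models

    def __getitem__(self, disease: str) -> IntegratedModel:
        try:
            return self.models[disease]
        except KeyError:
            raise KeyError(f"no syndrome model for disease {disease!r}") from None


def _resample_score(kind: str, hp: dict, X, y, folds: int, seed: int) -> float:
    """k-fold accuracy on a bootstrap resample of the train/val pool."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    boot = rng.integers(len(X), size=len(X))
    Xb, yb = X[boot], y[boot]
    # the bootstrap may drop a class; retry a few times, else use the originals
    for _ in range(5):
        if len(np.unique(yb)) == len(classes) and np.unique(yb, return_counts=True)[1].min() >= 2:
            break
        boot = rng.integers(len(X), size=len(X))
        Xb, yb = X[boot], y[boot]
    else:
        Xb, yb = X, y
    k = int(min(folds, np.unique(yb, return_counts=True)[1].min()))
    if k < 2:
        return 0.0
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(Xb, yb):
        clf = _Wrapped(kind, hp, seed).fit(Xb[tr], yb[tr])
        pred, _ = clf.predict_with_confidence(Xb[te])
        accs.append(float(np.mean(pred == yb[te])))
    return float(np.mean(accs))


def fit_integrated(
    disease: str,
    X: np.ndarray,
    y: list[str] | np.ndarray,
    specs: list[BaseLearnerSpec] | None = None,
    seed: int = 0,
    tune_folds: int = 3,
    balance: bool = True,
) -> IntegratedModel:
    """Fit the four base learners for one disease on balanced records.

    A single-syndrome disease yields a degenerate constant model (logged).
    Each learner with a non-trivial grid has its hyperparameters selected
    by k-fold accuracy on a bootstrap resample of the training pool.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = tuple(sorted(np.unique(y).tolist()))
    if len(labels) == 1:
        logger.info("disease %s has a single syndrome %s; constant model", disease, labels[0])
        return IntegratedModel(disease, labels, {}, constant=labels[0])
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError(f"disease {disease}: every represented syndrome needs >= 2 records")
    if balance:
        X, y = balance_classes(X, y, target_per_class=int(counts.max()), seed=seed)
    specs = specs if specs is not None else default_specs(seed)
    learners: dict[str, _Wrapped] = {}
    meta: dict = {"chosen": {}}
    for spec in specs:
        hp = dict(spec.hyperparams)
        if spec.grid and len(spec.grid) > 1:
            scores = [
                (_resample_score(spec.kind, cand, X, y, tune_folds, seed), -i, cand)
                for i, cand in enumerate(spec.grid)
            ]
            scores.sort(key=lambda t: (t[0], t[1]), reverse=True)
            hp = dict(scores[0][2])
        meta["chosen"][spec.kind] = hp
        learners[spec.kind] = _Wrapped(spec.kind, hp, seed).fit(X, y)
    return IntegratedModel(disease, labels, learners, meta=meta)


def majority_vote(labels: list[str], confidences: list[float]) -> str:
    """Plurality over the votes; documented deterministic tie-breaks.

    Ties among top vote counts go to the label whose voters have the
    highest mean confidence; residual ties resolve lexicographically.
    """
    ranked = rank_votes(labels, confidences)
    return ranked[0][0]


def rank_votes(labels: list[str], confidences: list[float]) -> list[tuple[str, int, float]]:
    """All voted labels ranked by (votes desc, mean confidence desc, label asc)."""
    if len(labels) != len(confidences):
        raise ValueError("labels and confidences must align")
    votes: dict[str, list[float]] = {}
    for lab, conf in zip(labels, confidences):
        votes.setdefault(lab, []).append(float(conf))
    ranked = [(lab, len(cs), float(np.mean(cs))) for lab, cs in votes.items()]
    ranked.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return ranked


def predict_syndrome(
    features: np.ndarray,
    disease: str,
    registry: Registry,
) -> list[tuple[str, int, float]]:
    """Ranked syndrome list for one feature vector via the disease's model.

    The top entry is the majority vote; entries are (label, vote count,
    mean confidence).  Labels of the disease that received no vote follow
    with vote count 0.  Raises KeyError if the disease has no model.
    """
    model = registry[disease]
    if model.constant is not None:
        return [(model.constant, 4, 1.0)]
    x = np.atleast_2d(np.asarray(features, dtype=float))
    labels = []
    confs = []
    for kind in BASE_KINDS:
        lab, conf = model.learners[kind].predict_with_confidence(x)
        labels.append(str(lab[0]))
        confs.append(float(conf[0]))
    ranked = rank_votes(labels, confs)
    voted = {lab for lab, _, _ in ranked}
    ranked.extend((lab, 0, 0.0) for lab in model.labels if lab not in voted)
    return ranked


def evaluate_models(
    X: np.ndarray,
    y: list[str] | np.ndarray,
    specs: list[BaseLearnerSpec] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Stratified k-fold CV accuracy per base kind plus the integrated vote.

    Returns {kind: accuracy, ..., "integration": accuracy}.  If some class
    has fewer records than ``folds``, the fold count is reduced with a
    warning; constant-label data scores 1.0 throughout.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    specs = specs if specs is not None else default_specs(seed)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) == 1:
        return {**{s.kind: 1.0 for s in specs}, "integration": 1.0}
    k = int(min(folds, counts.min()))
    if k < folds:
        logger.warning("reducing folds from %d to %d (smallest class has %d records)", folds, k, counts.min())
    if k < 2:
        raise ValueError("need at least 2 records per class for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    hits = {s.kind: 0 for s in specs}
    hits["integration"] = 0
    n = 0
    for tr, te in skf.split(X, y):
        fitted = {s.kind: _Wrapped(s.kind, s.hyperparams, seed).fit(X[tr], y[tr]) for s in specs}
        fold_labels = []
        fold_confs = []
        for s in specs:
            lab, conf = fitted[s.kind].predict_with_confidence(X[te])
            hits[s.kind] += int(np.sum(lab == y[te]))
            fold_labels.append(lab)
            fold_confs.append(conf)
        for i in range(len(te)):
            vote = majority_vote([fl[i] for fl in fold_labels], [fc[i] for fc in fold_confs])
            hits["integration"] += int(vote == y[te][i])
        n += len(te)
    return {kind: h / n for kind, h in hits.items()}
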