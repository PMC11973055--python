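"""Cross-validated multi-classifier discrimination stage.

A fixed roster of 15 scikit-learn classifiers (library defaults, except the
support-vector machine which uses ``gamma="auto"``) is evaluated with
stratified 7-fold cross-validation on each pairwise dataset.  Predictions
are pooled across folds into a single confusion matrix per
(pair, classifier) entry, from which accuracy, recall, precision, F1 and
specificity are computed; AUC comes from the pooled continuous scores
(predict_proba or decision_function), falling back to 0.5 with a diagnostic
when a classifier exposes neither.

Pooling (rather than fold-averaging) keeps the metrics on the k/n grid of
the dataset size — on 14 subjects the achievable accuracies are multiples
of 1/14, e.g. 13/14 ~= 92.86%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier, BaggingClassifier, ExtraTreesClassifier,
    GradientBoostingClassifier, RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV, SGDClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import PairwiseDataset

logger = logging.getLogger(__name__)

#: Canonical roster order of the 15 classifiers.
ROSTER_NAMES: tuple[str, ...] = (
    "AdaBoostClassifier",
    "BaggingClassifier",
    "DecisionTreeClassifier",
    "ExtraTreesClassifier",
    "GaussianNB",
    "GaussianProcessClassifier",
    "GradientBoostingClassifier",
    "KNearestNeighborsClassifier",
    "LinearDiscriminantAnalysis",
    "LogisticRegression",
    "LogisticRegressionCV",
    "MLPClassifier",
    "RandomForestClassifier",
    "SGDClassifier",
    "SupportVectorMachine",
)

#: Classifiers whose fitting is stochastic and therefore receive a seed.
_SEEDED = {
    "AdaBoostClassifier", "BaggingClassifier", "DecisionTreeClassifier",
    "ExtraTreesClassifier", "GaussianProcessClassifier",
    "GradientBoostingClassifier", "LogisticRegressionCV", "MLPClassifier",
    "RandomForestClassifier", "SGDClassifier",
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One roster entry: a canonical name plus hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ROSTER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings: fold count, stratification, shuffle seed."""

    n_folds: int = 7
    stratified: bool = True
    shuffle_seed: int = 0
    normalize_within_folds: bool = False
    positive_class: int = 1


def default_roster() -> list[ClassifierSpec]:
    """The canonical 15-classifier roster (defaults; SVM with gamma='auto')."""
    return [ClassifierSpec(name) for name in ROSTER_NAMES]


def build_estimator(spec: ClassifierSpec, seed: int = 0) -> BaseEstimator:
    """Instantiate the scikit-learn estimator behind a roster name."""
    factories = {
        "AdaBoostClassifier": AdaBoostClassifier,
        "BaggingClassifier": BaggingClassifier,
        "DecisionTreeClassifier": DecisionTreeClassifier,
        "ExtraTreesClassifier": ExtraTreesClassifier,
        "GaussianNB": GaussianNB,
        "GaussianProcessClassifier": GaussianProcessClassifier,
        "GradientBoostingClassifier": GradientBoostingClassifier,
        "KNearestNeighborsClassifier": KNeighborsClassifier,
        "LinearDiscriminantAnalysis": LinearDiscriminantAnalysis,
        "LogisticRegression": LogisticRegression,
        "LogisticRegressionCV": LogisticRegressionCV,
        "MLPClassifier": MLPClassifier,
        "RandomForestClassifier": RandomForestClassifier,
        "SGDClassifier": SGDClassifier,
        "SupportVectorMachine": lambda **kw: SVC(gamma="auto", **kw),
    }
    kwargs = dict(spec.hyperparameters)
    if spec.name in _SEEDED:
        kwargs.setdefault("random_state", seed)
    return factories[spec.name](**kwargs)


@dataclass
class ReportEntry:
    """Pooled cross-validation result for one (pair, classifier) cell."""

    pair: tuple[str, str]
    classifier: str
    tp: int
    tn: int
    fp: int
    fn: int
    auc: float
    fold_details: list[dict] = field(default_factory=list)
    failure: str | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else 0.0


@dataclass
class ClassificationReport:
    """All (pair, classifier) entries plus helpers for tabulation and ranking."""

    entries: list[ReportEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "pair": f"{e.pair[0]}_vs_{e.pair[1]}", "classifier": e.classifier,
            "accuracy": e.accuracy, "recall": e.recall, "precision": e.precision,
            "f1": e.f1, "auc": e.auc, "specificity": e.specificity,
            "tp": e.tp, "tn": e.tn, "fp": e.fp, "fn": e.fn,
            "failure": e.failure or "",
        } for e in self.entries]
        return pd.DataFrame(rows)

    def best_per_pair(self) -> dict[tuple[str, str], ReportEntry]:
        """Best classifier per pair by accuracy; ties by AUC, then roster order."""
        best: dict[tuple[str, str], ReportEntry] = {}
        for e in self.entries:
            cur = best.get(e.pair)
            if cur is None or (e.accuracy, e.auc) > (cur.accuracy, cur.auc):
                best[e.pair] = e
        return best

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_folds(ds: PairwiseDataset, cfg: CVConfig | None = None
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, shuffled, seed-deterministic train/test index pairs.

    With 7 + 7 subjects and 7 folds each test fold holds exactly one subject
    per class.
    """
    cfg = cfg or CVConfig()
    counts = np.bincount(ds.y)
    if cfg.n_folds > counts.min():
        raise ValueError(
            f"n_folds={cfg.n_folds} exceeds the smaller class size {counts.min()}")
    splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                               random_state=cfg.shuffle_seed)
    return [(tr, te) for tr, te in splitter.split(ds.X, ds.y)]


def _scores_for_auc(est: BaseEstimator, X: np.ndarray) -> np.ndarray | None:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    if hasattr(est, "decision_function"):
        return est.decision_function(X)
    return None


def _fold_normalize(X_train: np.ndarray, X_test: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    mins = X_train.min(axis=0)
    span = X_train.max(axis=0) - mins
    safe = np.where(span == 0, 1.0, span)
    return (X_train - mins) / safe, (X_test - mins) / safe


def run_cv(ds: PairwiseDataset, spec: ClassifierSpec,
           cfg: CVConfig | None = None) -> ReportEntry:
    """Fit/predict over all folds and pool the predictions.

    The positive class is label 1 (by convention the more-affected group of
    the pair).  A classifier failure on any fold is recorded on the entry
    (zero counts, AUC 0.5) rather than raised, so one fragile model cannot
    abort a full comparison run.
    """
    cfg = cfg or CVConfig()
    folds = make_folds(ds, cfg)
    y_true = np.empty(ds.n_subjects, dtype=int)
    y_pred = np.empty(ds.n_subjects, dtype=int)
    scores = np.empty(ds.n_subjects, dtype=float)
    have_scores = True
    fold_details: list[dict] = []
    try:
        for k, (tr, te) in enumerate(folds):
            X_tr, X_te = ds.X[tr], ds.X[te]
            if cfg.normalize_within_folds:
                X_tr, X_te = _fold_normalize(X_tr, X_te)
            est = build_estimator(spec, seed=cfg.shuffle_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X_tr, ds.y[tr])
                pred = est.predict(X_te)
                s = _scores_for_auc(est, X_te)
            y_true[te] = ds.y[te]
            y_pred[te] = pred
            if s is None:
                have_scores = False
            else:
                scores[te] = s
            fold_details.append({
                "fold": k, "test_subjects": [ds.subject_ids[i] for i in te],
                "y_true": ds.y[te].tolist(), "y_pred": pred.tolist(),
            })
    except Exception as exc:  # pragma: no cover - defensive path
        logger.warning("classifier %s failed: %s", spec.name, exc)
        return ReportEntry(pair=ds.pair, classifier=spec.name,
                           tp=0, tn=0, fp=0, fn=0, auc=0.5, failure=str(exc))

    pos = cfg.positive_class
    tp = int(np.sum((y_pred == pos) & (y_true == pos)))
    tn = int(np.sum((y_pred != pos) & (y_true != pos)))
    fp = int(np.sum((y_pred == pos) & (y_true != pos)))
    fn = int(np.sum((y_pred != pos) & (y_true == pos)))
    if have_scores:
        auc = float(roc_auc_score((y_true == pos).astype(int), scores))
    else:
        logger.info("%s exposes no continuous score; AUC set to 0.5", spec.name)
        auc = 0.5
    return ReportEntry(pair=ds.pair, classifier=spec.name, tp=tp, tn=tn,
                       fp=fp, fn=fn, auc=auc, fold_details=fold_details)


def run_all(datasets: list[PairwiseDataset],
            roster: list[ClassifierSpec] | None = None,
            cfg: CVConfig | None = None) -> ClassificationReport:
    """Evaluate the full roster on every pairwise dataset."""
    roster = roster if roster is not None else default_roster()
    if not roster:
        raise ValueError("classifier roster is empty")
    cfg = cfg or CVConfig()
    report = ClassificationReport()
    for ds in datasets:
        for spec in roster:
            report.entries.append(run_cv(ds, spec, cfg))
    return report
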