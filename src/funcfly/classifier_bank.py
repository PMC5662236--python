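"""Per-term classifier training and selection.

Four candidate algorithms are trained for every GO term -- Random Forests,
AdaBoost with decision stumps, k-nearest neighbours and linear discriminant
analysis -- and the best one (the *Opt-Classifier*) is chosen by stratified
cross-validation on the training split, ranked by mean MCC with mean AUROC
and then a fixed algorithm order (RF > AdaBoost > KNN > LDA) as tie-breaks.
The winner is refitted on the full training split.

All algorithms see z-scored features (mean/SD fitted on training data only);
this is required by KNN and LDA and harmless for the tree ensembles. Each
model exposes a confidence score in [0, 1]: the fraction of trees voting
positive (RF), the fraction of positive neighbours (KNN), a logistic
transform 1/(1+exp(-2*margin)) of the boosting margin (AdaBoost), or the
class posterior (LDA). The number of cross-validation folds follows the
size of the positive class: 10 folds for >= 100 training positives, 5 for
20-99, otherwise 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .containers import FeatureMatrix
from .dataset_builder import GoTermDataset
from .errors import DatasetError, ParameterError, ValidationError
from .evaluation import auroc, confusion_at_threshold, mcc

logger = logging.getLogger(__name__)

#: Fixed tie-break priority of the candidate algorithms.
ALGORITHM_ORDER = ("RF", "AdaBoost", "KNN", "LDA")

#: Decision threshold on the confidence score used for MCC.
MCC_THRESHOLD = 0.5


@dataclass(frozen=True)
class ClassifierSpec:
    """One candidate algorithm with fixed hyperparameters.

    Defaults: RF with 500 Gini trees and sqrt-feature subsampling; AdaBoost
    with 200 depth-1 learners; KNN with k = 5 and Euclidean distance; LDA
    without shrinkage. All are overridable through ``params``.
    """

    algorithm: str
    params: tuple = ()

    def __post_init__(self):
        if self.algorithm not in ALGORITHM_ORDER:
            raise ParameterError(
                f"algorithm must be one of {ALGORITHM_ORDER}: {self.algorithm!r}"
            )
        object.__setattr__(self, "params", tuple(sorted(dict(self.params).items())))

    def param(self, name, default):
        return dict(self.params).get(name, default)

    def build(self, seed: int = 0):
        """Instantiate the underlying scikit-learn estimator."""
        if self.algorithm == "RF":
            return RandomForestClassifier(
                n_estimators=self.param("n_estimators", 500),
                criterion="gini",
                max_features="sqrt",
                random_state=seed,
                n_jobs=1,
            )
        if self.algorithm == "AdaBoost":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=self.param("n_estimators", 200),
                random_state=seed,
            )
        if self.algorithm == "KNN":
            return KNeighborsClassifier(
                n_neighbors=self.param("n_neighbors", 5), metric="euclidean"
            )
        return LinearDiscriminantAnalysis()


def default_specs(
    rf_trees: int = 500, ada_learners: int = 200, knn_k: int = 5
) -> tuple:
    """The four candidate specifications in tie-break order."""
    return (
        ClassifierSpec("RF", (("n_estimators", rf_trees),)),
        ClassifierSpec("AdaBoost", (("n_estimators", ada_learners),)),
        ClassifierSpec("KNN", (("n_neighbors", knn_k),)),
        ClassifierSpec("LDA"),
    )


def choose_n_folds(
    n_positives_train: int, breakpoints: tuple = (100, 20), folds: tuple = (10, 5, 2)
) -> int:
    """Cross-validation fold count from the training positive count."""
    if n_positives_train < 2:
        raise ParameterError("need at least 2 training positives")
    hi, lo = breakpoints
    if n_positives_train >= hi:
        return folds[0]
    if n_positives_train >= lo:
        return folds[1]
    return folds[2]


# ---------------------------------------------------------------------------
# standardization + confidence scores
# ---------------------------------------------------------------------------

def _fit_standardizer(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale == 0.0, 1.0, scale)
    return mean, scale


def _apply_standardizer(X: np.ndarray, mean: np.ndarray, scale: np.ndarray):
    return (X - mean) / scale


def confidence_scores(estimator, algorithm: str, X: np.ndarray) -> np.ndarray:
    """Posterior-probability-like confidence of the positive class, in [0, 1]."""
    if algorithm == "RF":
        votes = np.zeros(len(X), dtype=float)
        for tree in estimator.estimators_:
            votes += tree.predict(X) == 1
        conf = votes / len(estimator.estimators_)
    elif algorithm == "AdaBoost":
        margin = estimator.decision_function(X)
        conf = 1.0 / (1.0 + np.exp(-2.0 * margin))
    else:  # KNN, LDA expose calibatable posteriors directly
        pos = int(np.flatnonzero(estimator.classes_ == 1)[0])
        conf = estimator.predict_proba(X)[:, pos]
    return np.clip(conf, 0.0, 1.0)


# ---------------------------------------------------------------------------
# cross-validation and model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CvScores:
    """Per-fold MCC/AUROC of one candidate algorithm."""

    algorithm: str
    mcc_per_fold: tuple
    auroc_per_fold: tuple

    @property
    def n_folds(self) -> int:
        return len(self.mcc_per_fold)

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.mcc_per_fold))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.auroc_per_fold))


def _train_arrays(dataset: GoTermDataset):
    if dataset.is_split:
        return dataset.X_train, dataset.y_train
    return dataset.X, dataset.labels


def cross_validate(
    dataset: GoTermDataset,
    spec: ClassifierSpec,
    seed: int = 0,
    n_folds: Optional[int] = None,
) -> CvScores:
    """Stratified k-fold cross-validation of one candidate on the train split.

    Standardization is refitted on each fold's training part. A held-out
    fold containing a single class scores AUROC 0.5 and MCC 0 (logged).
    Deterministic under a fixed seed.
    """
    X, y = _train_arrays(dataset)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos < 2 or n_neg < 2:
        raise DatasetError(
            f"{dataset.term_id}: cross-validation needs >= 2 of each class"
        )
    if n_folds is None:
        n_folds = choose_n_folds(n_pos)
    clamped = min(n_folds, n_pos, n_neg)
    if clamped != n_folds:
        logger.info(
            "%s: clamping %d folds to %d (minority class size)",
            dataset.term_id, n_folds, clamped,
        )
        n_folds = clamped

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    mccs, aurocs = [], []
    for fold, (tr, ho) in enumerate(skf.split(X, y)):
        mean, scale = _fit_standardizer(X[tr])
        Xtr = _apply_standardizer(X[tr], mean, scale)
        Xho = _apply_standardizer(X[ho], mean, scale)
        est = spec.build(seed=(seed + 1009 * (fold + 1)) % (2**31))
        est.fit(Xtr, y[tr])
        if len(np.unique(y[ho])) < 2:
            logger.info("%s fold %d: single-class held-out set", dataset.term_id, fold)
            mccs.append(0.0)
            aurocs.append(0.5)
            continue
        conf = confidence_scores(est, spec.algorithm, Xho)
        mccs.append(mcc(confusion_at_threshold(conf, y[ho], MCC_THRESHOLD)))
        aurocs.append(auroc(conf, y[ho]))
    return CvScores(spec.algorithm, tuple(mccs), tuple(aurocs))


@dataclass
class TrainedTermModel:
    """The selected, refitted classifier of one GO term."""

    term_id: str
    spec: ClassifierSpec
    model: object
    feature_names: tuple
    mean: np.ndarray
    scale: np.ndarray
    cv: Mapping          # algorithm -> CvScores for every candidate

    @property
    def algorithm(self) -> str:
        return self.spec.algorithm

    def predict_confidence(self, features) -> np.ndarray:
        """Confidence scores for a FeatureMatrix / DataFrame / ndarray whose
        columns match the training features."""
        if isinstance(features, FeatureMatrix):
            frame = features.values
        elif isinstance(features, pd.DataFrame):
            frame = features
        else:
            X = np.asarray(features, dtype=float)
            if X.shape[1] != len(self.feature_names):
                raise ValidationError(
                    f"{self.term_id}: expected {len(self.feature_names)} feature "
                    f"columns, got {X.shape[1]}"
                )
            return confidence_scores(
                self.model, self.algorithm,
                _apply_standardizer(X, self.mean, self.scale),
            )
        missing = [c for c in self.feature_names if c not in frame.columns]
        extra = [c for c in frame.columns if c not in self.feature_names]
        if missing or extra:
            raise ValidationError(
                f"{self.term_id}: feature columns do not match training columns "
                f"(missing: {missing[:5]}, extra: {extra[:5]})"
            )
        X = frame.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        return confidence_scores(
            self.model, self.algorithm, _apply_standardizer(X, self.mean, self.scale)
        )


def select_opt_classifier(
    dataset: GoTermDataset,
    specs: Optional[Sequence[ClassifierSpec]] = None,
    seed: int = 0,
    n_folds: Optional[int] = None,
) -> TrainedTermModel:
    """Cross-validate all candidates, pick the best and refit it on the full
    training split.

    Ranking: highest mean CV MCC; ties broken by mean CV AUROC, then by the
    fixed order RF > AdaBoost > KNN > LDA. The returned model's mean CV MCC
    is therefore >= every candidate's.
    """
    if specs is None:
        specs = default_specs()
    cv = {s.algorithm: cross_validate(dataset, s, seed=seed, n_folds=n_folds)
          for s in specs}
    priority = {a: i for i, a in enumerate(ALGORITHM_ORDER)}
    winner = min(
        specs,
        key=lambda s: (
            -cv[s.algorithm].mean_mcc,
            -cv[s.algorithm].mean_auroc,
            priority[s.algorithm],
        ),
    )
    X, y = _train_arrays(dataset)
    mean, scale = _fit_standardizer(X)
    est = winner.build(seed=seed)
    est.fit(_apply_standardizer(X, mean, scale), y)
    return TrainedTermModel(
        term_id=dataset.term_id,
        spec=winner,
        model=est,
        feature_names=tuple(dataset.features.feature_names),
        mean=mean,
        scale=scale,
        cv=cv,
    )


def predict_with_confidence(model: TrainedTermModel, features) -> np.ndarray:
    """Confidence scores of a trained term model on new feature rows."""
    return model.predict_confidence(features)
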