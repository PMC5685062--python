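"""Random-forest AUC ranking of pathway pairs.

Each pair's per-sample features (the two pathway activities, by default)
are fed to a random-forest classifier — 500 trees, mtry = floor(sqrt(p))
features per split — and scored by the area under the ROC curve of
out-of-fold case-probabilities from a stratified 10-fold cross-validation.
The AUC is computed once on the pooled out-of-fold probabilities (the
Mann-Whitney rank form, ties counted 1/2), which is stable when folds
contain only a couple of samples.  Pairs are ranked by CV AUC and the
top k retained; an optional held-out set gives a validation AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFConfig:
    """Random-forest and cross-validation settings.

    ``mtry=None`` resolves to floor(sqrt(p)) with p the number of feature
    columns (minimum 1), the standard forest heuristic.
    """

    ntree: int = 500
    mtry: int | None = None
    n_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1 when given")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is not None:
            if self.mtry > p:
                raise ValueError(f"mtry={self.mtry} exceeds feature count {p}")
            return self.mtry
        return max(1, int(math.floor(math.sqrt(p))))


@dataclass(frozen=True)
class PairScore:
    """AUC scores for one canonical pathway pair."""

    pair: tuple[str, str]
    cv_auc: float
    validation_auc: float | None = None
    ds: float | None = None


class FoldConstructionError(ValueError):
    """Stratified folds cannot be built with both classes per training part."""


def auc_score(y_true: np.ndarray, prob_case: np.ndarray) -> float:
    """Rank-based AUC of case-probabilities (ties counted 1/2)."""
    return float(roc_auc_score(np.asarray(y_true, dtype=int), prob_case))


def _forest(config: RFConfig, p: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=config.resolve_mtry(p),
        random_state=seed,
        n_jobs=1,
    )


def cv_auc(X: np.ndarray, y: np.ndarray, config: RFConfig) -> float:
    """Stratified k-fold cross-validated AUC for one pair's feature matrix.

    Per fold a forest is trained on the remaining samples and out-of-fold
    case-probabilities collected; the AUC is computed once on the pooled
    probabilities.  When ``n_folds`` exceeds the minority-class count the
    fold count is lowered to it (logged); fewer than two possible folds is
    a :class:`FoldConstructionError`.  Deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if X.shape[0] != y.size:
        raise ValueError("feature matrix and labels disagree on sample count")
    minority = int(min(y.sum(), (~y).sum()))
    if minority == 0:
        raise FoldConstructionError("both classes must be present")
    n_folds = config.n_folds
    if n_folds > minority:
        logger.warning(
            "reducing n_folds from %d to minority-class count %d", n_folds, minority
        )
        n_folds = minority
    if n_folds < 2:
        raise FoldConstructionError(
            f"cannot build >= 2 stratified folds with minority count {minority}"
        )
    if X.shape[0] < n_folds:
        raise FoldConstructionError("fewer samples than folds")

    rng = np.random.SeedSequence(config.seed)
    fold_seed, *tree_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng.spawn(n_folds + 1)
    ]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
    prob = np.empty(X.shape[0])
    for k, (train_idx, test_idx) in enumerate(skf.split(X, y.astype(int))):
        y_train = y[train_idx]
        if y_train.all() or not y_train.any():
            raise FoldConstructionError(
                f"fold {k} training partition contains a single class"
            )
        forest = _forest(config, X.shape[1], tree_seeds[k])
        forest.fit(X[train_idx], y_train.astype(int))
        case_col = list(forest.classes_).index(1)
        prob[test_idx] = forest.predict_proba(X[test_idx])[:, case_col]
    return auc_score(y, prob)


def holdout_auc(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    config: RFConfig,
) -> float:
    """AUC on a held-out set of a forest trained on the full training portion."""
    y_train = np.asarray(y_train, dtype=bool)
    y_test = np.asarray(y_test, dtype=bool)
    if y_test.all() or not y_test.any():
        raise ValueError("test set contains a single class")
    if y_train.all() or not y_train.any():
        raise ValueError("training set contains a single class")
    seed = int(
        np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31 - 1)
    )
    forest = _forest(config, np.asarray(X_train).shape[1], seed)
    forest.fit(np.asarray(X_train, dtype=float), y_train.astype(int))
    case_col = list(forest.classes_).index(1)
    prob = forest.predict_proba(np.asarray(X_test, dtype=float))[:, case_col]
    return auc_score(y_test, prob)


def rank_pairs(scores: Sequence[PairScore], k: int = 10) -> list[PairScore]:
    """Top-k pairs by CV AUC descending.

    Ties are broken by validation AUC descending (absent treated as lowest)
    then canonical pair name ascending.
    """
    if not scores:
        raise ValueError("no pair scores to rank")
    def key(s: PairScore):
        v = s.validation_auc if s.validation_auc is not None else -math.inf
        return (-s.cv_auc, -v, s.pair)
    return sorted(scores, key=key)[: min(k, len(scores))]
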