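"""Confounding-patient detection by multi-classifier consensus.

A *confounding patient* is a training sample that four heterogeneous
classifiers (gradient-boosted trees, random forest, Gaussian naive Bayes and
a support-vector machine) all fail to classify correctly under repeated
stratified cross-validation: such a patient sits in opposite-class territory
of feature space, so no model family can separate it.  Removing these
patients yields the "clean" training set; the removed ones form the
confounder set used to train the arbiter model.

Each classifier produces a score in [0, 1]; a patient is predicted IDE when
its score reaches the training-set IDE prevalence, mirroring the prevalence
thresholds used by the base models.  "Misclassified" aggregates over rounds
as a strict majority: a classifier marks a patient when it got it wrong in
more than half of the repeated-CV rounds.

Inter-classifier agreement is quantified with Cohen's kappa, averaged over
rounds, before and after cleaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .endpoints import EndpointDataset
from .utils import DegenerateDataError, child_seed

log = logging.getLogger(__name__)

CLASSIFIERS = ("XGB", "RF", "NB", "SVM")


def _make_classifiers(seed: int, n_estimators: int = 100) -> dict:
    return {
        "XGB": XGBClassifier(
            n_estimators=n_estimators, tree_method="hist", eval_metric="logloss",
            verbosity=0, random_state=seed, n_jobs=1,
        ),
        "RF": RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1),
        # variance floor at 0.1 x the largest feature variance: without it the
        # tiny class-conditional variances of rare one-hot indicators dominate
        # the log-likelihood and the model degenerates to noise
        "NB": GaussianNB(var_smoothing=0.1),
        "SVM": SVC(kernel="rbf", random_state=seed),
    }


def _scores_01(name: str, clf, X: np.ndarray) -> np.ndarray:
    """Positive-class score in [0, 1]; SVM margins are min-max scaled per fold."""
    if name == "SVM":
        d = clf.decision_function(X)
        span = d.max() - d.min()
        return (d - d.min()) / span if span > 0 else np.full(len(X), 0.5)
    return clf.predict_proba(X)[:, 1]


def _oof_predictions(
    X: np.ndarray,
    y: np.ndarray,
    rounds: int,
    inner_k: int,
    seed: int,
    n_estimators: int = 100,
) -> np.ndarray:
    """Out-of-fold class predictions, shape (rounds, 4 classifiers, n).

    Every round draws a fresh stratified ``inner_k``-fold split, so each
    patient gets exactly one held-out prediction per classifier per round.
    Scores convert to classes at the inner training set's IDE prevalence.
    """
    n = len(y)
    preds = np.zeros((rounds, len(CLASSIFIERS), n), dtype=np.int8)
    for r in range(rounds):
        split = None
        for attempt in range(10):
            skf = StratifiedKFold(
                n_splits=inner_k, shuffle=True,
                random_state=child_seed(seed, r, attempt),
            )
            candidate = list(skf.split(X, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in candidate):
                split = candidate
                break
            log.warning("round %d: single-class inner fold, re-drawing split", r)
        if split is None:
            raise DegenerateDataError("could not draw a two-class inner split in 10 tries")
        for tr, te in split:
            thr = y[tr].mean()
            clfs = _make_classifiers(child_seed(seed, r, 997), n_estimators)
            for ci, name in enumerate(CLASSIFIERS):
                clf = clfs[name]
                clf.fit(X[tr], y[tr])
                s = _scores_01(name, clf, X[te])
                preds[r, ci, te] = (s >= thr).astype(np.int8)
    return preds


@dataclass
class MisclassificationTally:
    """Per (patient, classifier) count of rounds with a wrong prediction."""

    patient_ids: np.ndarray
    counts: np.ndarray  # shape (n, 4)
    rounds: int
    predictions: np.ndarray | None = None  # (rounds, 4, n), kept for kappa maps

    def __post_init__(self) -> None:
        if self.counts.min() < 0 or self.counts.max() > self.rounds:
            raise ValueError("tally outside [0, rounds]")


@dataclass
class ConfounderPartition:
    """Training ids split into clean patients and confounders."""

    clean_ids: np.ndarray
    confounder_ids: np.ndarray

    def __post_init__(self) -> None:
        overlap = np.intersect1d(self.clean_ids, self.confounder_ids)
        if overlap.size:
            raise ValueError("clean and confounder sets overlap")


def tally_misclassifications(
    train: EndpointDataset,
    rounds: int = 20,
    inner_k: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
) -> MisclassificationTally:
    """Count, per patient and classifier, the rounds with a wrong
    out-of-fold prediction under a ``rounds`` x ``inner_k``-fold scheme."""
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if len(np.unique(train.y)) < 2:
        raise DegenerateDataError("training set must contain both classes")
    preds = _oof_predictions(train.X, train.y, rounds, inner_k, seed, n_estimators)
    wrong = preds != train.y[None, None, :]
    counts = wrong.sum(axis=0).T.astype(int)  # (n, 4)
    return MisclassificationTally(train.patient_ids.copy(), counts, rounds, preds)


def identify_confounders(tally: MisclassificationTally, rounds: int | None = None) -> ConfounderPartition:
    """A patient is a confounder iff *every* classifier misclassified it in a
    strict majority (> rounds/2) of the repeated-CV rounds."""
    rounds = tally.rounds if rounds is None else rounds
    is_conf = (tally.counts > rounds / 2).all(axis=1)
    return ConfounderPartition(
        clean_ids=np.sort(tally.patient_ids[~is_conf]),
        confounder_ids=np.sort(tally.patient_ids[is_conf]),
    )


def cohens_kappa(pred_a, pred_b) -> float:
    """Chance-corrected agreement between two binary prediction vectors.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and chance
    agreement p_e from the marginal prediction frequencies.  When both
    vectors are constant and identical, chance agreement is 1 and kappa is
    defined as 1 (perfect, trivially).
    """
    a = np.asarray(pred_a).astype(int)
    b = np.asarray(pred_b).astype(int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("predictions must be equal-length vectors of length >= 2")
    p_o = float(np.mean(a == b))
    pa = a.mean()
    pb = b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


@dataclass
class KappaMatrix:
    """Symmetric 4x4 Cohen's-kappa agreement matrix, averaged over rounds."""

    classifiers: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("kappa matrix must be symmetric")
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("kappa outside [-1, 1]")

    def mean_off_diagonal(self) -> float:
        m = ~np.eye(len(self.classifiers), dtype=bool)
        return float(self.values[m].mean())


def _kappa_map(preds: np.ndarray) -> KappaMatrix:
    """Average pairwise kappa of per-round predictions, shape (R, 4, n)."""
    rounds, k, _ = preds.shape
    vals = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ks = [cohens_kappa(preds[r, i], preds[r, j]) for r in range(rounds)]
            vals[i, j] = vals[j, i] = float(np.mean(ks))
    return KappaMatrix(CLASSIFIERS, vals)


def consensus_maps(
    train: EndpointDataset,
    partition: ConfounderPartition,
    rounds: int = 20,
    inner_k: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
    tally: MisclassificationTally | None = None,
) -> tuple[KappaMatrix, KappaMatrix]:
    """Pairwise agreement maps before and after the cleaning-up procedure.

    "Before" uses out-of-fold predictions on the full training set (reused
    from ``tally`` when provided); "after" refits on the clean patients only.
    """
    if tally is not None and tally.predictions is not None:
        before_preds = tally.predictions
    else:
        before_preds = _oof_predictions(train.X, train.y, rounds, inner_k, seed, n_estimators)

    clean_mask = np.isin(train.patient_ids, partition.clean_ids)
    clean = train.subset(clean_mask)
    n_min = min(int(clean.y.sum()), int(len(clean) - clean.y.sum()))
    if n_min < inner_k:
        raise DegenerateDataError("clean set too small for the inner fold count")
    after_preds = _oof_predictions(
        clean.X, clean.y, rounds, inner_k, child_seed(seed, 1), n_estimators
    )
    return _kappa_map(before_preds), _kappa_map(after_preds)
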