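"""The three baseline scorers feeding the voting ensemble.

Model 1 trains on the raw outer-training set; Model 2 on the clean patients
left by the cleaning-up procedure; Model 3 on the confounding patients only.
Each model runs a nested shadow-feature selection (repeated stratified
cross-validation; a feature is kept when confirmed in at least half of the
round x fold runs), then fits a gradient-boosted tree classifier on the
selected features.  A model's decision threshold is exactly the IDE
prevalence of its own training set.

Degenerate confounder sets degrade gracefully: with too few patients per
class, feature selection is skipped (all features used); with a single
class, Model 3 emits a constant score equal to its class indicator and is
flagged so the rule engine treats it as never decisive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .endpoints import EndpointDataset
from .selection import shadow_feature_select
from .utils import DegenerateDataError, child_seed

log = logging.getLogger(__name__)


@dataclass
class SelectionFrequency:
    """Per-feature confirmation percentage over the nested selection runs."""

    feature_names: list[str]
    percent: np.ndarray  # in [0, 100]

    def as_series(self) -> pd.Series:
        return pd.Series(self.percent, index=self.feature_names)


def select_features(
    train: EndpointDataset,
    rounds: int = 20,
    inner_k: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
    max_iter: int = 100,
    cutoff_percent: float = 50.0,
) -> tuple[list[str], SelectionFrequency]:
    """Nested shadow-feature selection over ``rounds`` x ``inner_k`` runs.

    Returns the features confirmed in at least ``cutoff_percent`` of runs and
    the full confirmation-frequency profile.  If nothing clears the cutoff,
    all features are retained with a logged warning.
    """
    names = train.schema.names
    n_feat = len(names)
    counts = np.zeros(n_feat)
    n_runs = 0
    for r in range(rounds):
        skf = StratifiedKFold(n_splits=inner_k, shuffle=True,
                              random_state=child_seed(seed, r))
        for fi, (tr, _) in enumerate(skf.split(train.X, train.y)):
            confirmed = shadow_feature_select(
                train.X[tr], train.y[tr], train.column_owner, n_feat,
                seed=child_seed(seed, r, fi),
                n_estimators=n_estimators, max_iter=max_iter,
            )
            counts += confirmed
            n_runs += 1
    percent = 100.0 * counts / n_runs
    freq = SelectionFrequency(list(names), percent)
    selected = [names[i] for i in np.flatnonzero(percent >= cutoff_percent)]
    if not selected:
        log.warning("no feature cleared the %.0f%% cutoff; keeping all features",
                    cutoff_percent)
        selected = list(names)
    return selected, freq


@dataclass
class BaseModelBundle:
    """A fitted baseline scorer restricted to its selected features."""

    model_id: int
    selected_features: list[str]
    threshold: float
    clf: XGBClassifier | None = None
    feature_cols: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    constant_score: float | None = None  # set for single-class degenerate fits
    train_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def degenerate(self) -> bool:
        return self.constant_score is not None

    def score(self, X: np.ndarray) -> np.ndarray:
        if self.degenerate:
            return np.full(len(X), float(self.constant_score))
        return self.clf.predict_proba(X[:, self.feature_cols])[:, 1]


def train_scorer(
    train: EndpointDataset,
    features: list[str],
    model_id: int = 1,
    seed: int = 0,
    n_estimators: int = 100,
) -> BaseModelBundle:
    """Fit the gradient-boosted tree scorer on the given feature subset.

    The bundle threshold equals the training set's IDE fraction exactly.
    """
    unknown = set(features) - set(train.schema.names)
    if unknown:
        raise ValueError(f"features outside the schema: {sorted(unknown)}")
    classes = np.unique(train.y)
    if len(classes) < 2:
        raise DegenerateDataError("single-class training set")
    names = train.schema.names
    sel_idx = [names.index(f) for f in features]
    cols = np.flatnonzero(np.isin(train.column_owner, sel_idx))
    clf = XGBClassifier(
        n_estimators=n_estimators, tree_method="hist", eval_metric="logloss",
        verbosity=0, random_state=seed, n_jobs=1,
    )
    clf.fit(train.X[:, cols], train.y)
    threshold = int(train.y.sum()) / len(train.y)
    return BaseModelBundle(
        model_id=model_id,
        selected_features=list(features),
        threshold=threshold,
        clf=clf,
        feature_cols=cols,
        train_ids=train.patient_ids.copy(),
    )


def fit_model(
    train: EndpointDataset,
    model_id: int,
    rounds: int = 20,
    inner_k: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
    selection_max_iter: int = 100,
) -> tuple[BaseModelBundle, SelectionFrequency | None]:
    """Nested feature selection + scorer fit, with the degenerate fallbacks."""
    n_pos = int(train.y.sum())
    n_neg = len(train) - n_pos
    if min(n_pos, n_neg) == 0:
        # single class: constant score equal to its class indicator
        score = 1.0 if n_pos > 0 else 0.0
        log.warning("model %d training set is single-class; constant score %.0f",
                    model_id, score)
        bundle = BaseModelBundle(
            model_id=model_id, selected_features=list(train.schema.names),
            threshold=0.5, constant_score=score, train_ids=train.patient_ids.copy(),
        )
        return bundle, None
    if min(n_pos, n_neg) < inner_k:
        log.warning("model %d: < %d patients per class; skipping feature selection",
                    model_id, inner_k)
        features = list(train.schema.names)
        freq = None
    else:
        features, freq = select_features(
            train, rounds=rounds, inner_k=inner_k, seed=seed,
            n_estimators=n_estimators, max_iter=selection_max_iter,
        )
    bundle = train_scorer(train, features, model_id=model_id,
                          seed=child_seed(seed, 77), n_estimators=n_estimators)
    return bundle, freq


def score_patients(
    bundles: dict[int, BaseModelBundle],
    test: EndpointDataset,
) -> pd.DataFrame:
    """Score every test patient with the three models.

    Returns a frame with columns ``patient_id, s1, s2, s3, y`` whose scores
    all lie in [0, 1]; thresholds live on the bundles.  Training/test id
    disjointness is asserted for every model.
    """
    for m, b in bundles.items():
        overlap = np.intersect1d(b.train_ids, test.patient_ids)
        if overlap.size:
            raise ValueError(f"model {m} was trained on {overlap.size} test patients")
    out = {"patient_id": test.patient_ids}
    for m in (1, 2, 3):
        out[f"s{m}"] = bundles[m].score(test.X)
    out["y"] = test.y
    return pd.DataFrame(out)
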