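"""Per-horizon endpoint labeling and the outer cross-validation plan.

Two binary tasks are supported: IDE within 60 months and IDE within 120
months.  A patient is an IDE case when an event is recorded at or before the
horizon.  Controls must have a definitively negative status at the horizon:
either an event observed *after* the horizon, or no event with at least 120
(5-year task) / 168 (10-year task) months of follow-up.  Event-free patients
with shorter follow-up are excluded -- they could still develop an event
shortly after the horizon -- and land in a reason-coded exclusion log.

The outer evaluation uses a stratified 10-fold split on the IDE label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable
from .schema import FeatureSchema, encode_features
from .utils import DegenerateDataError

#: minimum event-free follow-up (months) for control status, per horizon
CONTROL_FOLLOWUP = {60: 120, 120: 168}

REASON_SHORT_FOLLOWUP = "insufficient follow-up"


@dataclass
class EndpointDataset:
    """Binary-labeled, encoded feature matrix for one prediction horizon."""

    horizon_months: int
    patient_ids: np.ndarray
    X: np.ndarray
    y: np.ndarray  # 1 = IDE, 0 = non-IDE
    feature_names: list[str]
    column_owner: np.ndarray  # encoded column -> schema feature position
    schema: FeatureSchema
    exclusion_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    event_type_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patient_ids)

    @property
    def n_ide(self) -> int:
        return int(self.y.sum())

    def subset(self, mask_or_idx) -> "EndpointDataset":
        idx = np.asarray(mask_or_idx)
        return EndpointDataset(
            self.horizon_months,
            self.patient_ids[idx],
            self.X[idx],
            self.y[idx],
            self.feature_names,
            self.column_owner,
            self.schema,
            self.exclusion_log,
            self.event_type_counts,
        )


def label_endpoint(cohort: CohortTable, horizon: int) -> EndpointDataset:
    """Build the binary IDE / non-IDE dataset for a 60- or 120-month horizon.

    The cohort must be imputed (no missing values).  Excluded patients are
    reported in ``exclusion_log`` with a reason code; the per-event-type
    composition of the IDE class is tallied in ``event_type_counts``.
    """
    if horizon not in CONTROL_FOLLOWUP:
        raise ValueError(f"horizon must be 60 or 120 months, got {horizon}")
    if cohort.has_missing():
        raise ValueError("cohort must be imputed before endpoint labeling")
    df = cohort.data
    event_m = df["event_months"].astype(float).fillna(np.inf).to_numpy()
    followup = df["followup_months"].to_numpy(float)
    has_event = (df["event_type"] != "none").to_numpy()

    is_ide = has_event & (event_m <= horizon)
    later_event = has_event & (event_m > horizon)
    long_followup = ~has_event & (followup >= CONTROL_FOLLOWUP[horizon])
    is_control = later_event | long_followup
    excluded = ~(is_ide | is_control)

    log = pd.DataFrame(
        {
            "patient_id": df.loc[excluded, "patient_id"].to_numpy(),
            "reason": REASON_SHORT_FOLLOWUP,
        }
    )
    keep = is_ide | is_control
    if is_ide.sum() == 0:
        raise DegenerateDataError(f"IDE class empty at horizon {horizon}")
    if is_control.sum() == 0:
        raise DegenerateDataError(f"non-IDE class empty at horizon {horizon}")

    X, names, owner, _ = encode_features(df.loc[keep, cohort.schema.names], cohort.schema)
    counts = (
        df.loc[is_ide, "event_type"].value_counts().to_dict()
    )
    return EndpointDataset(
        horizon_months=horizon,
        patient_ids=df.loc[keep, "patient_id"].to_numpy(int),
        X=X,
        y=is_ide[keep].astype(int),
        feature_names=names,
        column_owner=owner,
        schema=cohort.schema,
        exclusion_log=log,
        event_type_counts={k: int(v) for k, v in counts.items()},
    )


@dataclass
class SplitPlan:
    """Stratified outer k-fold plan, stored by patient id."""

    seed: int
    k: int
    fold_of: dict[int, int]  # patient_id -> fold index

    def test_ids(self, fold: int) -> np.ndarray:
        return np.array(sorted(pid for pid, f in self.fold_of.items() if f == fold))

    def train_ids(self, fold: int) -> np.ndarray:
        return np.array(sorted(pid for pid, f in self.fold_of.items() if f != fold))

    def fold_masks(self, patient_ids: np.ndarray):
        """Yield (fold, train_mask, test_mask) aligned with ``patient_ids``."""
        folds = np.array([self.fold_of[int(p)] for p in patient_ids])
        for f in range(self.k):
            yield f, folds != f, folds == f

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"seed": self.seed, "k": self.k,
                        "fold_of": {str(k): v for k, v in self.fold_of.items()}})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(d["seed"], d["k"], {int(k): v for k, v in d["fold_of"].items()})


def make_split_plan(dataset: EndpointDataset, k: int = 10, seed: int = 0) -> SplitPlan:
    """Stratified k-fold partition of the endpoint dataset.

    Each test fold holds ~1/k of the patients (sizes differing by at most 1)
    with the IDE fraction preserved within one patient per fold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    n_ide = int(dataset.y.sum())
    n_non = len(dataset) - n_ide
    if min(n_ide, n_non) < k:
        raise DegenerateDataError(
            f"both classes need >= {k} members (IDE {n_ide}, non-IDE {n_non})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[int, int] = {}
    for f, (_, test_idx) in enumerate(skf.split(dataset.X, dataset.y)):
        for i in test_idx:
            fold_of[int(dataset.patient_ids[i])] = f
    return SplitPlan(seed=seed, k=k, fold_of=fold_of)
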