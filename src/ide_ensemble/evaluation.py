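"""Abstention-aware performance metrics and fold summaries.

AUC is the Mann-Whitney probability that a random IDE patient outscores a
random non-IDE patient (ties counted 1/2).  The operating threshold for
accuracy / sensitivity / specificity maximizes Youden's J = sensitivity +
specificity - 1 over the distinct score cutpoints (a patient is predicted
IDE when its score reaches the threshold; ties in J resolve to the smallest
cutpoint).  Patients the ensemble abstained on are excluded from the
confusion counts; the abstention percentage is reported against the full
fold size.  Fold metrics are summarized by median and quartiles with linear
interpolation of order statistics (NumPy's default, quantile type 7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted 1/2.

    Raises on single-class input; callers treat that fold as undefined.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def youden_threshold(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J over distinct score cutpoints.

    Returns ``(threshold, sensitivity, specificity)`` at that cutpoint,
    where predicted-IDE means score >= threshold.  Ties in J break toward
    the smallest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("Youden threshold undefined: both classes must be present")
    best = None
    for t in np.unique(s):
        pred = s >= t
        sens = float(np.mean(pred[y == 1]))
        spec = float(np.mean(~pred[y == 0]))
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, t, sens, spec = best
    return float(t), sens, spec


def confusion_metrics(
    decisions: pd.DataFrame,
    labels: pd.Series | dict | pd.DataFrame,
    threshold: float | None = None,
) -> dict:
    """Accuracy / sensitivity / specificity on answered patients only.

    ``decisions`` is a decision table (patient_id, verdict, final_score);
    ``labels`` maps patient_id -> 1 (IDE) / 0.  When ``threshold`` is given,
    answered patients are re-classified from ``final_score`` at that
    threshold; otherwise the categorical verdicts are scored as-is.
    Abstentions enter no confusion cell; ``abstain_pct`` is relative to the
    full fold.  With zero answered patients the rates are NaN.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels.set_index("patient_id")["y"]
    lab = pd.Series(labels)
    y = lab.reindex(decisions["patient_id"]).to_numpy(int)
    answered = (decisions["verdict"] != "abstain").to_numpy()
    n = len(decisions)
    n_abs = int(n - answered.sum())
    if threshold is not None:
        pred = decisions["final_score"].to_numpy(float) >= threshold
    else:
        pred = (decisions["verdict"] == "IDE").to_numpy()
    pred = pred[answered]
    ya = y[answered]
    tp = int(np.sum(pred & (ya == 1)))
    tn = int(np.sum(~pred & (ya == 0)))
    fp = int(np.sum(pred & (ya == 0)))
    fn = int(np.sum(~pred & (ya == 1)))

    def _rate(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": _rate(tp + tn, tp + tn + fp + fn),
        "sensitivity": _rate(tp, tp + fn),
        "specificity": _rate(tn, tn + fp),
        "abstain_pct": 100.0 * n_abs / n if n else float("nan"),
        "n_answered": int(answered.sum()),
        "n_abstained": n_abs,
    }


@dataclass
class EvaluationReport:
    """Per-fold metric lines plus median / quartile summary."""

    per_fold: pd.DataFrame
    summary: pd.DataFrame  # rows: metrics; columns: median, q1, q3

    def to_json_dict(self) -> dict:
        return {
            "per_fold": self.per_fold.to_dict(orient="records"),
            "summary": self.summary.to_dict(orient="index"),
            "quartile_convention": "linear interpolation (type 7)",
        }


METRICS = ("auc", "accuracy", "sensitivity", "specificity", "abstain_pct")


def summarize(per_fold: pd.DataFrame, metrics: tuple[str, ...] = METRICS) -> EvaluationReport:
    """Median and first/third quartiles of each metric over defined folds."""
    rows = {}
    any_defined = False
    for m in metrics:
        if m not in per_fold.columns:
            continue
        vals = per_fold[m].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            rows[m] = {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
            continue
        any_defined = True
        rows[m] = {
            "median": float(np.median(vals)),
            "q1": float(np.quantile(vals, 0.25)),
            "q3": float(np.quantile(vals, 0.75)),
        }
    if not any_defined:
        raise ValueError("no fold has defined metrics")
    return EvaluationReport(per_fold.copy(), pd.DataFrame(rows).T[["median", "q1", "q3"]])
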