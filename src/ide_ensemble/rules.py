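"""Quantile-anchored voting rules with a reject option, and their grid search.

Each test patient carries three scores (s1, s2, s3) from the raw-data model,
the clean-data model and the confounder model, with per-fold prevalence
thresholds (th1, th2, th3).  Eight searched parameters shape the vote:

* ``lo_m``/``hi_m`` (m = 1, 2, 3): the uncertainty band of model m.  The
  model casts a *non-IDE vote* when its score falls at or below ``lo_m`` and
  an *IDE vote* when it exceeds ``hi_m``; scores inside the band are
  uncertain and cast no vote.
* ``d_agree``: maximum |s1 - s2| still counting as agreement between the two
  main models.
* ``d_conf``: margin by which s3 must clear th3 (in its vote's direction)
  before the confounder model may arbitrate.

The decision cascade (first branch that fires wins; the branch id is kept for
per-patient explainability):

* R1 *strong consensus* -- models 1 and 2 cast the same vote and agree within
  ``d_agree``: verdict by that vote, final score mean(s1, s2).
* R2 *confounder arbitration* -- model 3 casts a decisive vote and at least
  one main model votes the same way: verdict by model 3's vote, final score
  the mean of the agreeing scores (including s3).
* R3 *weak consensus* -- model 3 casts a decisive vote and both main scores
  sit on that same side of their thresholds (though inside their bands):
  verdict by that side, final score mean(s1, s2, s3).
* R4 -- abstain ("no answer").

Every branch condition is a conjunction of band-vote predicates (which only
shrink when bands widen or ``d_conf`` grows) and band-independent threshold
comparisons, so the abstention count is monotone non-decreasing under band
enlargement -- and with zero-width bands at the thresholds, ``d_agree = 1``
and ``d_conf = 0`` no patient abstains.

This rule schema is a faithful-in-spirit reconstruction: it keeps the
published constraints (8 searched parameters anchored to training-score
quantiles averaged over the ten training sets, consensus => decision, no
consensus => "no answer", automatic prevalence thresholds) without claiming
to be the original authors' verbatim cascade.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

PARAM_NAMES = ("lo1", "hi1", "lo2", "hi2", "lo3", "hi3", "d_agree", "d_conf")

RULE_LABELS = {0: "abstain", 1: "strong_consensus", 2: "confounder_arbitration",
               3: "weak_consensus"}


@dataclass(frozen=True)
class RuleParameters:
    """The eight searched rule parameters (thresholds stay with the scores)."""

    lo1: float
    hi1: float
    lo2: float
    hi2: float
    lo3: float
    hi3: float
    d_agree: float
    d_conf: float

    def __post_init__(self) -> None:
        for m in (1, 2, 3):
            lo, hi = getattr(self, f"lo{m}"), getattr(self, f"hi{m}")
            if lo > hi:
                raise ValueError(f"lo{m} > hi{m}")
            if not (0 <= lo <= 1 and 0 <= hi <= 1):
                raise ValueError(f"band {m} outside [0, 1]")
        if self.d_agree < 0 or self.d_conf < 0:
            raise ValueError("d_agree and d_conf must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


@dataclass
class EnsembleDecision:
    """Verdict for one patient: IDE / non-IDE / abstain plus explanation."""

    patient_id: int
    verdict: str  # "IDE" | "non-IDE" | "abstain"
    final_score: float | None
    rule_fired: str


def _evaluate_batch(
    scores: np.ndarray,
    thresholds: np.ndarray,
    params: np.ndarray,
    model3_decisive: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized cascade over C parameter combinations and n patients.

    ``scores``: (n, 3); ``thresholds``: (3,); ``params``: (C, 8) in
    PARAM_NAMES order.  Returns ``(verdict, final_score, rule)`` each of
    shape (C, n): verdict is +1 (IDE) / -1 (non-IDE) / 0 (abstain), rule is
    the fired branch id (0 = abstain).
    """
    s1, s2, s3 = scores[:, 0][None, :], scores[:, 1][None, :], scores[:, 2][None, :]
    th1, th2, th3 = thresholds
    p = params
    lo1, hi1 = p[:, 0][:, None], p[:, 1][:, None]
    lo2, hi2 = p[:, 2][:, None], p[:, 3][:, None]
    lo3, hi3 = p[:, 4][:, None], p[:, 5][:, None]
    d_agree, d_conf = p[:, 6][:, None], p[:, 7][:, None]

    # band votes; with an inverted band (lo > hi) the IDE vote takes precedence
    v1_ide = s1 > hi1
    v1_non = ~v1_ide & (s1 <= lo1)
    v2_ide = s2 > hi2
    v2_non = ~v2_ide & (s2 <= lo2)
    if model3_decisive:
        v3_ide = (s3 > hi3) & ((s3 - th3) >= d_conf)
        v3_non = ~v3_ide & (s3 <= lo3) & ((th3 - s3) >= d_conf)
    else:
        v3_ide = np.zeros(np.broadcast_shapes(s3.shape, hi3.shape), dtype=bool)
        v3_non = v3_ide

    close12 = np.abs(s1 - s2) <= d_agree
    side1 = s1 > th1
    side2 = s2 > th2

    r1_ide = v1_ide & v2_ide & close12
    r1_non = v1_non & v2_non & close12
    r2_ide = v3_ide & (v1_ide | v2_ide)
    r2_non = v3_non & (v1_non | v2_non)
    r3_ide = v3_ide & side1 & side2
    r3_non = v3_non & ~side1 & ~side2

    r1 = r1_ide | r1_non
    r2 = ~r1 & (r2_ide | r2_non)
    r3 = ~r1 & ~r2 & (r3_ide | r3_non)

    verdict = np.zeros(r1.shape, dtype=np.int8)
    verdict[r1_ide | (r2 & r2_ide) | (r3 & r3_ide)] = 1
    verdict[r1_non | (r2 & r2_non) | (r3 & r3_non)] = -1

    rule = np.zeros(r1.shape, dtype=np.int8)
    rule[r3] = 3
    rule[r2] = 2
    rule[r1] = 1

    # final scores: mean of the scores that voted for the verdict
    mean12 = np.broadcast_to((s1 + s2) / 2.0, r1.shape)
    mean123 = np.broadcast_to((s1 + s2 + s3) / 3.0, r1.shape)
    m1_agree = (r2_ide & v1_ide) | (r2_non & v1_non)
    m2_agree = (r2_ide & v2_ide) | (r2_non & v2_non)
    r2_sum = (np.where(m1_agree, s1, 0.0) + np.where(m2_agree, s2, 0.0)
              + np.broadcast_to(s3, r1.shape))
    r2_cnt = 1 + m1_agree.astype(int) + m2_agree.astype(int)
    mean_r2 = r2_sum / r2_cnt

    final = np.full(r1.shape, np.nan)
    final[r1] = mean12[r1]
    final[r2] = mean_r2[r2]
    final[r3] = mean123[r3]
    return verdict, final, rule


def apply_rules(triple, params: RuleParameters, model3_decisive: bool = True) -> EnsembleDecision:
    """Apply the cascade to one patient's score triple.

    ``triple`` needs attributes ``s1, s2, s3, th1, th2, th3`` (and optionally
    ``patient_id``).
    """
    scores = np.array([[triple.s1, triple.s2, triple.s3]], dtype=float)
    th = np.array([triple.th1, triple.th2, triple.th3], dtype=float)
    verdict, final, rule = _evaluate_batch(
        scores, th, params.as_array()[None, :], model3_decisive
    )
    v = int(verdict[0, 0])
    return EnsembleDecision(
        patient_id=getattr(triple, "patient_id", 0),
        verdict={1: "IDE", -1: "non-IDE", 0: "abstain"}[v],
        final_score=None if v == 0 else float(final[0, 0]),
        rule_fired=RULE_LABELS[int(rule[0, 0])],
    )


def decide_fold(
    score_frame: pd.DataFrame,
    thresholds: tuple[float, float, float],
    params: RuleParameters,
    model3_decisive: bool = True,
) -> pd.DataFrame:
    """Decision table for one fold's score frame (columns patient_id, s1..s3)."""
    scores = score_frame[["s1", "s2", "s3"]].to_numpy(float)
    verdict, final, rule = _evaluate_batch(
        scores, np.asarray(thresholds, float), params.as_array()[None, :], model3_decisive
    )
    v = verdict[0]
    return pd.DataFrame(
        {
            "patient_id": score_frame["patient_id"].to_numpy(),
            "verdict": np.select([v == 1, v == -1], ["IDE", "non-IDE"], "abstain"),
            "final_score": np.where(v == 0, np.nan, final[0]),
            "rule_fired": [RULE_LABELS[int(r)] for r in rule[0]],
        }
    )


# ---------------------------------------------------------------------------
# parameter grid


@dataclass
class ParameterGrid:
    """Per-parameter candidate values, evenly spaced between quantile anchors."""

    candidates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.candidates)
        if missing:
            raise ValueError(f"grid missing parameters: {sorted(missing)}")
        for name, vals in self.candidates.items():
            vals = np.asarray(vals, dtype=float)
            if np.any(np.diff(vals) < 0):
                raise ValueError(f"candidates for {name} must be sorted ascending")
            self.candidates[name] = vals

    @property
    def n_combinations(self) -> int:
        out = 1
        for name in PARAM_NAMES:
            out *= len(self.candidates[name])
        return out

    def combo_matrix(self) -> np.ndarray:
        """All combinations, shape (n_combinations, 8), lexicographic order."""
        grids = [self.candidates[name] for name in PARAM_NAMES]
        return np.array(list(itertools.product(*grids)), dtype=float)


def _anchor(values: np.ndarray, q: float, fallback: float) -> float:
    values = np.asarray(values, dtype=float)
    return float(np.quantile(values, q)) if values.size else fallback


def derive_parameter_grid(
    training_scores: list[pd.DataFrame],
    thresholds: list[tuple[float, float, float]],
    grid_size: int = 5,
) -> ParameterGrid:
    """Anchor the candidate grid to training-score quantiles.

    ``training_scores``: one frame per outer training set with columns
    ``s1, s2, s3, y``; ``thresholds``: the matching (th1, th2, th3).

    For each model m, ``lo_m`` ranges from the mean (over training sets)
    0.25 quantile of the correctly-classified non-IDE scores (strict: a
    non-IDE vote demands a clearly low score) up to the mean prevalence
    threshold th_m (permissive: the band's lower edge reaches the decision
    threshold, the zero-width limit where every score votes); ``hi_m``
    symmetrically from th_m up to the mean 0.75 quantile of the
    correctly-classified IDE scores.  ``d_agree`` and ``d_conf`` range from
    0 to the mean 0.75 quantile of |s1 - s2| and |s3 - th3| respectively.
    The candidate grids therefore always bracket the no-abstention corner
    (bands collapsed onto the thresholds) and the strictest quantile corner,
    so the constrained search can trade abstention against AUC across the
    whole spectrum.  ``grid_size`` evenly spaced candidates per parameter,
    endpoints included.
    """
    if not training_scores:
        raise ValueError("no training-score distributions supplied")
    if len(training_scores) != len(thresholds):
        raise ValueError("training_scores and thresholds length mismatch")
    lo_anchors = {m: ([], []) for m in (1, 2, 3)}
    hi_anchors = {m: ([], []) for m in (1, 2, 3)}
    agree_q75, conf_q75 = [], []
    for frame, (th1, th2, th3) in zip(training_scores, thresholds):
        y = frame["y"].to_numpy()
        ths = {1: th1, 2: th2, 3: th3}
        for m in (1, 2, 3):
            s = frame[f"s{m}"].to_numpy(float)
            ok_non = s[(y == 0) & (s < ths[m])]
            ok_ide = s[(y == 1) & (s >= ths[m])]
            if ok_non.size == 0:
                ok_non = s[y == 0]
            if ok_ide.size == 0:
                ok_ide = s[y == 1]
            lo_anchors[m][0].append(_anchor(ok_non, 0.25, 0.0))
            lo_anchors[m][1].append(ths[m])
            hi_anchors[m][0].append(ths[m])
            hi_anchors[m][1].append(_anchor(ok_ide, 0.75, 1.0))
        gap12 = np.abs(frame["s1"].to_numpy(float) - frame["s2"].to_numpy(float))
        gap3 = np.abs(frame["s3"].to_numpy(float) - th3)
        agree_q75.append(_anchor(gap12, 0.75, 0.2))
        conf_q75.append(_anchor(gap3, 0.75, 0.2))

    def span(lower: float, upper: float) -> np.ndarray:
        lower, upper = float(np.clip(lower, 0, 1)), float(np.clip(upper, 0, 1))
        if upper < lower:
            lower, upper = upper, lower
        return np.linspace(lower, upper, grid_size)

    cand: dict[str, np.ndarray] = {}
    for m in (1, 2, 3):
        cand[f"lo{m}"] = span(np.mean(lo_anchors[m][0]), np.mean(lo_anchors[m][1]))
        cand[f"hi{m}"] = span(np.mean(hi_anchors[m][0]), np.mean(hi_anchors[m][1]))
    cand["d_agree"] = span(0.0, float(np.mean(agree_q75)))
    cand["d_conf"] = span(0.0, float(np.mean(conf_q75)))
    return ParameterGrid(cand)


# ---------------------------------------------------------------------------
# constrained grid search


class InfeasibleBudgetError(RuntimeError):
    """No parameter combination satisfies the abstention budget."""

    def __init__(self, message: str, best_combo: np.ndarray, best_abstain: float):
        super().__init__(message)
        self.best_combo = best_combo
        self.best_abstain = best_abstain


@dataclass
class GridSearchReport:
    """Feasibility / objective trace of the constrained search."""

    combos: np.ndarray           # (C, 8)
    median_abstain_pct: np.ndarray
    median_auc: np.ndarray
    feasible: np.ndarray
    best_index: int | None
    per_fold_abstain_pct: np.ndarray  # (C, k)
    per_fold_auc: np.ndarray          # (C, k)

    @property
    def n_combinations(self) -> int:
        return len(self.combos)

    def trace_frame(self, top: int = 20) -> pd.DataFrame:
        order = np.argsort(-np.nan_to_num(self.median_auc, nan=-np.inf))
        order = [i for i in order if self.feasible[i]][:top]
        return pd.DataFrame(
            np.column_stack([self.combos[order],
                             self.median_abstain_pct[order],
                             self.median_auc[order]]),
            columns=list(PARAM_NAMES) + ["median_abstain_pct", "median_auc"],
        )


def _fold_metrics(
    scores: np.ndarray,
    y: np.ndarray,
    thresholds: np.ndarray,
    combos: np.ndarray,
    model3_decisive: bool,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-combo abstention % and answered-only AUC for one fold."""
    C = len(combos)
    n = len(y)
    abstain = np.empty(C)
    auc = np.full(C, np.nan)
    pos = y == 1
    neg = ~pos
    for start in range(0, C, chunk):
        p = combos[start:start + chunk]
        verdict, final, _ = _evaluate_batch(scores, thresholds, p, model3_decisive)
        answered = verdict != 0
        abstain[start:start + chunk] = 100.0 * (n - answered.sum(axis=1)) / n
        a_pos = answered & pos[None, :]
        a_neg = answered & neg[None, :]
        n_pos = a_pos.sum(axis=1)
        n_neg = a_neg.sum(axis=1)
        fs = np.nan_to_num(final, nan=0.0)
        diff = fs[:, :, None] - fs[:, None, :]
        concord = (diff > 0) + 0.5 * (diff == 0)
        pair = a_pos[:, :, None] & a_neg[:, None, :]
        numer = np.where(pair, concord, 0.0).sum(axis=(1, 2))
        denom = (n_pos * n_neg).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            chunk_auc = np.where(denom > 0, numer / denom, np.nan)
        auc[start:start + chunk] = chunk_auc
    return abstain, auc


def grid_search(
    fold_scores: list[pd.DataFrame],
    fold_thresholds: list[tuple[float, float, float]],
    grid: ParameterGrid,
    max_median_abstain: float = 25.0,
    model3_decisive: list[bool] | None = None,
) -> tuple[RuleParameters, GridSearchReport]:
    """Exhaustively evaluate every parameter combination on the test folds.

    ``fold_scores``: per outer fold, a frame with columns ``patient_id, s1,
    s2, s3, y`` of *test* patients.  The feasible set holds combinations
    whose median abstention percentage over folds is at most
    ``max_median_abstain`` (and with coherent bands, lo_m <= hi_m); the
    winner maximizes the median answered-only AUC, ties broken by lower
    median abstention, then by the lexicographically smallest parameter
    vector.
    """
    combos = grid.combo_matrix()
    C = len(combos)
    k = len(fold_scores)
    if model3_decisive is None:
        model3_decisive = [True] * k
    ab = np.empty((C, k))
    au = np.empty((C, k))
    for f, (frame, th) in enumerate(zip(fold_scores, fold_thresholds)):
        scores = frame[["s1", "s2", "s3"]].to_numpy(float)
        y = frame["y"].to_numpy(int)
        ab[:, f], au[:, f] = _fold_metrics(
            scores, y, np.asarray(th, float), combos, model3_decisive[f]
        )
    median_ab = np.median(ab, axis=1)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN fold rows
        median_au = np.nanmedian(au, axis=1)
    valid_bands = (combos[:, 0] <= combos[:, 1]) & (combos[:, 2] <= combos[:, 3]) \
        & (combos[:, 4] <= combos[:, 5])
    feasible = valid_bands & (median_ab <= max_median_abstain) & ~np.isnan(median_au)

    report = GridSearchReport(combos, median_ab, median_au, feasible, None, ab, au)
    if not feasible.any():
        i = int(np.argmin(median_ab))
        raise InfeasibleBudgetError(
            f"infeasible abstention budget {max_median_abstain}%: best median "
            f"abstention is {median_ab[i]:.1f}%",
            best_combo=combos[i], best_abstain=float(median_ab[i]),
        )
    # maximize median AUC; ties -> lower abstention -> lexicographically smallest
    idx = np.flatnonzero(feasible)
    best_auc = median_au[idx].max()
    tied = idx[np.isclose(median_au[idx], best_auc)]
    best_ab = median_ab[tied].min()
    tied = tied[np.isclose(median_ab[tied], best_ab)]
    if len(tied) > 1:
        order = np.lexsort(combos[tied].T[::-1])
        best = int(tied[order[0]])
    else:
        best = int(tied[0])
    report.best_index = best
    params = RuleParameters(**dict(zip(PARAM_NAMES, combos[best])))
    return params, report
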