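"""Voting cascade, parameter grid derivation and the constrained search.

``_oracle_decide`` re-implements the decision cascade as plain per-patient
branch logic, independent of the vectorized engine, and the two are compared
on large random batches.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ide_ensemble import (
    InfeasibleBudgetError,
    ParameterGrid,
    RuleParameters,
    apply_rules,
    decide_fold,
    derive_parameter_grid,
    grid_search,
)
from ide_ensemble.rules import PARAM_NAMES, _evaluate_batch


def _oracle_decide(s1, s2, s3, th, p, model3_decisive=True):
    """Explicit branch-table evaluation of the cascade for one patient."""
    th1, th2, th3 = th

    def band_vote(s, lo, hi):
        if s > hi:
            return "IDE"
        if s <= lo:
            return "non-IDE"
        return None

    v1 = band_vote(s1, p.lo1, p.hi1)
    v2 = band_vote(s2, p.lo2, p.hi2)
    v3 = None
    if model3_decisive:
        if s3 > p.hi3 and (s3 - th3) >= p.d_conf:
            v3 = "IDE"
        elif s3 <= p.lo3 and (th3 - s3) >= p.d_conf:
            v3 = "non-IDE"

    if v1 is not None and v1 == v2 and abs(s1 - s2) <= p.d_agree:
        return v1, (s1 + s2) / 2, "strong_consensus"
    if v3 is not None and (v1 == v3 or v2 == v3):
        voters = [s3] + [s for s, v in ((s1, v1), (s2, v2)) if v == v3]
        return v3, sum(voters) / len(voters), "confounder_arbitration"
    if v3 is not None:
        side1 = "IDE" if s1 > th1 else "non-IDE"
        side2 = "IDE" if s2 > th2 else "non-IDE"
        if side1 == side2 == v3:
            return v3, (s1 + s2 + s3) / 3, "weak_consensus"
    return "abstain", None, "abstain"


def _random_params(rng) -> RuleParameters:
    lo = rng.uniform(0, 1, size=3)
    hi = np.minimum(1, lo + rng.uniform(0, 1 - lo))
    return RuleParameters(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2],
                          rng.uniform(0, 0.5), rng.uniform(0, 0.3))


def _triple(s1, s2, s3, th=(0.3, 0.3, 0.3), pid=1):
    return SimpleNamespace(patient_id=pid, s1=s1, s2=s2, s3=s3,
                           th1=th[0], th2=th[1], th3=th[2])


class TestApplyRules:
    def test_unanimous_high_confidence_is_ide(self):
        params = RuleParameters(0.2, 0.9, 0.2, 0.9, 0.2, 0.9, 0.05, 0.0)
        dec = apply_rules(_triple(0.95, 0.92, 0.90), params)
        assert dec.verdict == "IDE"
        assert dec.final_score == pytest.approx(0.935)
        assert dec.rule_fired == "strong_consensus"

    def test_unanimous_low_confidence_is_non_ide(self):
        params = RuleParameters(0.1, 0.8, 0.1, 0.8, 0.1, 0.8, 0.05, 0.0)
        dec = apply_rules(_triple(0.02, 0.05, 0.10), params)
        assert dec.verdict == "non-IDE"
        assert dec.final_score == pytest.approx(0.035)

    def test_uncertain_and_opposed_main_models_abstain(self):
        # both inside their bands, opposite threshold sides: no branch fires
        params = RuleParameters(0.1, 0.9, 0.1, 0.9, 0.0, 1.0, 1.0, 0.0)
        for s3 in (0.0, 0.5, 1.0):
            dec = apply_rules(_triple(0.2, 0.6, s3, th=(0.3, 0.3, 0.3)), params)
            assert dec.verdict == "abstain"
            assert dec.final_score is None

    def test_matches_branch_table_oracle_on_random_draws(self):
        rng = np.random.default_rng(12345)
        n = 10_000
        scores = rng.uniform(0, 1, size=(n, 3))
        th = (0.28, 0.31, 0.44)
        for _ in range(8):
            params = _random_params(rng)
            verdict, final, rule = _evaluate_batch(
                scores, np.array(th), params.as_array()[None, :]
            )
            for i in range(0, n, 7):  # dense but not exhaustive sampling
                ov, of, orule = _oracle_decide(*scores[i], th, params)
                got = {1: "IDE", -1: "non-IDE", 0: "abstain"}[int(verdict[0, i])]
                assert got == ov, (scores[i], params)
                assert orule == {0: "abstain", 1: "strong_consensus",
                                 2: "confounder_arbitration",
                                 3: "weak_consensus"}[int(rule[0, i])]
                if of is not None:
                    assert final[0, i] == pytest.approx(of)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_abstention_monotone_under_band_enlargement(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(0, 1, size=(200, 3))
        th = np.array([0.3, 0.3, 0.3])
        p = _random_params(rng)
        grow = rng.uniform(0, 0.3, size=7)
        wider = RuleParameters(
            max(0, p.lo1 - grow[0]), min(1, p.hi1 + grow[1]),
            max(0, p.lo2 - grow[2]), min(1, p.hi2 + grow[3]),
            max(0, p.lo3 - grow[4]), min(1, p.hi3 + grow[5]),
            p.d_agree, p.d_conf + grow[6],
        )
        v_narrow, _, _ = _evaluate_batch(scores, th, p.as_array()[None, :])
        v_wide, _, _ = _evaluate_batch(scores, th, wider.as_array()[None, :])
        assert (v_wide[0] == 0).sum() >= (v_narrow[0] == 0).sum()

    def test_collapsed_bands_never_abstain(self):
        rng = np.random.default_rng(0)
        th = (0.27, 0.35, 0.41)
        params = RuleParameters(th[0], th[0], th[1], th[1], th[2], th[2],
                                d_agree=1.0, d_conf=0.0)
        scores = rng.uniform(0, 1, size=(500, 3))
        verdict, final, _ = _evaluate_batch(scores, np.array(th),
                                            params.as_array()[None, :])
        assert (verdict[0] != 0).all()
        assert np.isfinite(final[0]).all()

    def test_non_decisive_model3_disables_arbitration(self):
        params = RuleParameters(0.3, 0.3, 0.3, 0.3, 0.3, 0.3, 0.0, 0.0)
        t = _triple(0.9, 0.1, 0.95)  # main models disagree, s3 extreme
        assert apply_rules(t, params).verdict == "IDE"
        assert apply_rules(t, params, model3_decisive=False).verdict == "abstain"

    def test_decision_table_coverage(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame({
            "patient_id": np.arange(50),
            "s1": rng.uniform(size=50), "s2": rng.uniform(size=50),
            "s3": rng.uniform(size=50),
        })
        params = _random_params(rng)
        dec = decide_fold(frame, (0.3, 0.3, 0.3), params)
        answered = (dec["verdict"] != "abstain").sum()
        assert answered + (dec["verdict"] == "abstain").sum() == 50
        assert dec.loc[dec["verdict"] == "abstain", "final_score"].isna().all()
        assert dec.loc[dec["verdict"] != "abstain", "final_score"].notna().all()


class TestParameterGrid:
    def test_even_spacing_between_anchors(self):
        grid = ParameterGrid({name: np.linspace(0.2, 0.6, 5) for name in PARAM_NAMES})
        np.testing.assert_allclose(grid.candidates["lo1"],
                                   [0.2, 0.3, 0.4, 0.5, 0.6])

    def test_full_grid_cardinality(self):
        grid = ParameterGrid({name: np.linspace(0, 1, 5) for name in PARAM_NAMES})
        assert grid.n_combinations == 5**8 == 390625

    def test_degenerate_anchor_grid_is_enumerable(self):
        grid = ParameterGrid({name: np.full(5, 0.4) for name in PARAM_NAMES})
        assert grid.n_combinations == 5**8
        combos = ParameterGrid(
            {name: (np.full(1, 0.4) if name != "lo1" else np.full(5, 0.4))
             for name in PARAM_NAMES}
        ).combo_matrix()
        assert np.allclose(combos, 0.4)

    def test_derivation_from_training_scores(self):
        rng = np.random.default_rng(2)
        frames, ths = [], []
        for _ in range(10):
            y = np.repeat([0, 1], 50)
            s = np.clip(rng.normal(0.3 + 0.3 * y[:, None], 0.15, size=(100, 3)), 0, 1)
            frames.append(pd.DataFrame(
                {"s1": s[:, 0], "s2": s[:, 1], "s3": s[:, 2], "y": y}))
            ths.append((0.5, 0.5, 0.5))
        grid = derive_parameter_grid(frames, ths, grid_size=5)
        for name in PARAM_NAMES:
            assert len(grid.candidates[name]) == 5
            assert np.all(np.diff(grid.candidates[name]) >= 0)
        # bands bracket the threshold: lo up to th, hi from th
        assert grid.candidates["lo1"][-1] == pytest.approx(0.5)
        assert grid.candidates["hi1"][0] == pytest.approx(0.5)
        assert grid.candidates["d_agree"][0] == 0.0

    def test_derivation_requires_scores(self):
        with pytest.raises(ValueError):
            derive_parameter_grid([], [])


def _score_folds(rng, k=10, n=40, informative=True):
    frames, ths = [], []
    for _ in range(k):
        y = rng.integers(0, 2, size=n)
        if informative:
            mu = 0.25 + 0.45 * y[:, None]
        else:
            mu = np.full((n, 1), 0.5)
        s = np.clip(rng.normal(mu, 0.12, size=(n, 3)), 0, 1)
        frames.append(pd.DataFrame({
            "patient_id": np.arange(n), "s1": s[:, 0], "s2": s[:, 1],
            "s3": s[:, 2], "y": y,
        }))
        ths.append((0.5, 0.5, 0.5))
    return frames, ths


class TestGridSearch:
    def test_singleton_grid_evaluates_one_combination(self):
        rng = np.random.default_rng(7)
        frames, ths = _score_folds(rng)
        grid = ParameterGrid({
            "lo1": [0.5], "hi1": [0.5], "lo2": [0.5], "hi2": [0.5],
            "lo3": [0.5], "hi3": [0.5], "d_agree": [1.0], "d_conf": [0.0],
        })
        params, report = grid_search(frames, ths, grid)
        assert report.n_combinations == 1
        assert report.median_abstain_pct[0] == 0.0  # collapsed-band limit

    def test_two_free_parameters_give_25_combinations(self):
        rng = np.random.default_rng(8)
        frames, ths = _score_folds(rng)
        cand = {name: [0.5] for name in PARAM_NAMES}
        cand["d_agree"] = np.linspace(0, 1, 5)
        cand["d_conf"] = np.linspace(0, 0.2, 5)
        params, report = grid_search(frames, ths, ParameterGrid(cand))
        assert report.n_combinations == 25

    def test_budget_constraint_is_respected(self):
        rng = np.random.default_rng(9)
        frames, ths = _score_folds(rng)
        grid = derive_parameter_grid(
            [f.drop(columns="patient_id") for f in frames], ths, grid_size=3)
        params, report = grid_search(frames, ths, grid, max_median_abstain=25.0)
        assert report.median_abstain_pct[report.best_index] <= 25.0
        feas = report.feasible
        assert report.median_auc[report.best_index] == pytest.approx(
            np.nanmax(report.median_auc[feas]))

    def test_infeasible_budget_raises_with_best_combo(self):
        rng = np.random.default_rng(10)
        frames, ths = _score_folds(rng)
        # full-width bands cast no votes: every patient abstains
        grid = ParameterGrid({
            "lo1": [0.0], "hi1": [1.0], "lo2": [0.0], "hi2": [1.0],
            "lo3": [0.0], "hi3": [1.0], "d_agree": [1.0], "d_conf": [0.0],
        })
        with pytest.raises(InfeasibleBudgetError) as err:
            grid_search(frames, ths, grid, max_median_abstain=25.0)
        assert err.value.best_abstain == 100.0

    def test_ties_break_to_smallest_parameter_vector(self):
        rng = np.random.default_rng(11)
        # extreme scores: identical decisions for every candidate band
        frames, ths = [], []
        for _ in range(3):
            y = rng.integers(0, 2, size=30)
            s = np.broadcast_to(np.where(y[:, None] == 1, 0.99, 0.01), (30, 3))
            frames.append(pd.DataFrame({
                "patient_id": np.arange(30), "s1": s[:, 0], "s2": s[:, 1],
                "s3": s[:, 2], "y": y,
            }))
            ths.append((0.5, 0.5, 0.5))
        cand = {name: [0.5] for name in PARAM_NAMES}
        cand["d_agree"] = [0.3, 0.6, 0.9]
        cand["d_conf"] = [0.0, 0.1]
        params, report = grid_search(frames, ths, ParameterGrid(cand))
        assert params.d_agree == 0.3 and params.d_conf == 0.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            RuleParameters(0.8, 0.2, 0.1, 0.9, 0.1, 0.9, 0.1, 0.1)
        with pytest.raises(ValueError):
            RuleParameters(0.1, 0.9, 0.1, 0.9, 0.1, 0.9, -0.1, 0.1)
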