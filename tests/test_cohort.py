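"""Generator and imputation behaviour: marginals, planted signal, donors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ide_ensemble import GeneratorConfig, default_schema, generate_cohort, impute_missing
from ide_ensemble.cohort import CohortTable
from ide_ensemble.schema import CONTINUOUS, MISSING
from ide_ensemble.utils import ConfigurationError, ImputationError


def toy_cohort(n_rows: int) -> CohortTable:
    """Small complete cohort whose rows tests can then edit freely."""
    return generate_cohort(
        GeneratorConfig(n_patients=n_rows, seed=3, noise_rate=0.0, missingness_scale=0.0)
    )


class TestGenerator:
    def test_shape_and_reproducibility(self):
        cfg = GeneratorConfig(n_patients=529, seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(GeneratorConfig(n_patients=529, seed=7))
        assert len(a) == 529
        assert len(a.schema) == 28
        assert set(a.schema.names) <= set(a.data.columns)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = generate_cohort(GeneratorConfig(n_patients=529, seed=8))
        assert not a.data.equals(c.data)

    def test_zero_missing_rates_leave_no_gaps(self):
        cohort = generate_cohort(
            GeneratorConfig(n_patients=10, seed=1, missingness_scale=0.0)
        )
        assert not cohort.has_missing()

    def test_prevalences_match_without_noise(self):
        cfg = GeneratorConfig(n_patients=4000, seed=2, noise_rate=0.0)
        d = generate_cohort(cfg).data
        em = d["event_months"].astype(float).fillna(np.inf)
        assert abs((em <= 60).mean() - cfg.prevalence_5y) < 0.01
        assert abs((em <= 120).mean() - cfg.prevalence_10y) < 0.01

    def test_marginal_fidelity_three_standard_errors(self):
        n = 5000
        cohort = generate_cohort(GeneratorConfig(n_patients=n, seed=4, noise_rate=0.0))
        for feat in cohort.schema:
            if feat.kind == CONTINUOUS:
                continue
            col = cohort.data[feat.name].astype(str)
            obs = col[col != MISSING]
            for cat, p in zip(feat.categories, feat.marginal):
                if p in (0.0, 1.0):
                    continue
                se = np.sqrt(p * (1 - p) / len(obs))
                assert abs((obs == cat).mean() - p) <= 3 * se + 1e-12, (feat.name, cat)

    def test_zero_signal_has_no_feature_label_association(self):
        import statsmodels.api as sm

        d = generate_cohort(
            GeneratorConfig(n_patients=2000, seed=9, signal_strength=0.0,
                            noise_rate=0.0, missingness_scale=0.0)
        ).data
        y = (d["event_months"].astype(float).fillna(np.inf) <= 120).astype(int)
        x = pd.to_numeric(d["Ki67"]).astype(float)
        x = (x - x.mean()) / x.std()
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        lo, hi = fit.conf_int().iloc[1]
        assert lo <= 0.0 <= hi

    def test_planted_flips_are_recorded(self):
        cfg = GeneratorConfig(n_patients=600, seed=6, noise_rate=0.1)
        cohort = generate_cohort(cfg)
        gt = cohort.ground_truth
        assert len(gt.flipped_ids) == 60
        assert set(gt.signal_features) == {"Ki67", "ER", "grading", "metastatic l."}
        assert set(gt.flipped_ids) <= set(cohort.data["patient_id"])

    def test_therapy_fields_are_logically_consistent(self):
        d = toy_cohort(400).data
        no_ct = d["CT"] == "No"
        assert (d.loc[no_ct, "CT scheme"] == "absent").all()
        assert (d.loc[no_ct, "CT months"].astype(float) == 0).all()
        assert (d.loc[no_ct, "trastuzumab"] == "No").all()
        assert (d.loc[d["HT"] == "No", "HT scheme"] == "absent").all()

    @pytest.mark.parametrize(
        "field, value",
        [("n_patients", 0), ("prevalence_5y", 1.5), ("noise_rate", 0.6),
         ("signal_strength", -1.0), ("missingness_scale", -0.1)],
    )
    def test_invalid_config_names_the_field(self, field, value):
        cfg = GeneratorConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            cfg.validate()


class TestImputation:
    def test_identity_on_complete_cohort(self):
        cohort = toy_cohort(12)
        out = impute_missing(cohort)
        pd.testing.assert_frame_equal(out.data, cohort.data)

    def test_nearest_complete_donor_supplies_all_gaps(self):
        cohort = toy_cohort(3)
        df = cohort.data
        # P3 mirrors P1 exactly except for the gaps; P2 is left different
        for col in cohort.schema.names:
            df.loc[2, col] = df.loc[0, col]
        df.loc[0, "Ki67"] = 22.0
        df.loc[1, "Ki67"] = 80.0
        df.loc[2, "Ki67"] = MISSING
        df.loc[2, "grading"] = MISSING
        out = impute_missing(CohortTable(df, cohort.schema)).data
        assert out.loc[2, "Ki67"] == 22.0
        assert out.loc[2, "grading"] == df.loc[0, "grading"]
        # complete patients untouched
        assert out.loc[1, "Ki67"] == 80.0

    def test_equidistant_donors_resolve_to_smallest_patient_id(self):
        cohort = toy_cohort(3)
        df = cohort.data
        for col in cohort.schema.names:  # P1 == P2 except Ki67; P3 mirrors both
            df.loc[1, col] = df.loc[0, col]
            df.loc[2, col] = df.loc[0, col]
        df.loc[0, "Ki67"] = 30.0
        df.loc[1, "Ki67"] = 70.0
        df.loc[2, "Ki67"] = MISSING
        out = impute_missing(CohortTable(df, cohort.schema)).data
        assert out.loc[2, "Ki67"] == 30.0  # donor with patient_id 1, not 2

    def test_idempotence_and_donor_realism(self, small_cohort):
        once = impute_missing(small_cohort)
        twice = impute_missing(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        # every imputed categorical value appears in some complete record
        complete = ~small_cohort.feature_frame().astype(str).eq(MISSING).any(axis=1)
        for feat in small_cohort.schema:
            if feat.kind == CONTINUOUS:
                continue
            was_missing = small_cohort.data[feat.name].astype(str) == MISSING
            imputed_vals = set(once.data.loc[was_missing, feat.name])
            donor_vals = set(small_cohort.data.loc[complete, feat.name])
            assert imputed_vals <= donor_vals

    def test_errors_without_donors(self):
        cohort = toy_cohort(2)
        df = cohort.data
        df.loc[0, "Ki67"] = MISSING
        df.loc[1, "ER"] = MISSING
        with pytest.raises(ImputationError):
            impute_missing(CohortTable(df, cohort.schema))
        with pytest.raises(ImputationError):
            impute_missing(CohortTable(df.iloc[:0], cohort.schema))


def test_csv_round_trip(tmp_path, small_cohort):
    path = tmp_path / "cohort.csv"
    small_cohort.to_csv(path)
    back = CohortTable.from_csv(path)
    a = small_cohort.data.reset_index(drop=True)
    b = back.data[a.columns]
    for col in a.columns:
        assert list(a[col].astype(str)) == list(b[col].astype(str)), col
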