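"""Shared fixtures: small seeded cohorts and one reduced full pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ide_ensemble import (
    GeneratorConfig,
    PipelineConfig,
    default_schema,
    generate_cohort,
    impute_missing,
    label_endpoint,
    run_pipeline,
)
from ide_ensemble.cohort import CohortTable


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohort():
    """200 patients, no planted noise, default missingness."""
    return generate_cohort(GeneratorConfig(n_patients=200, seed=11, noise_rate=0.0))


@pytest.fixture(scope="session")
def imputed_cohort(small_cohort):
    return impute_missing(small_cohort)


@pytest.fixture(scope="session")
def endpoint60(imputed_cohort):
    return label_endpoint(imputed_cohort, 60)


def build_composition_cohort() -> CohortTable:
    """A 529-patient cohort replicating the reference endpoint composition.

    111 recurrences, 21 contralateral and 10 second tumors within 60 months;
    46/11/8 more in (60, 120]; 309 event-free patients with long (200-month)
    follow-up; 13 event-free patients followed only 96 months.  Features come
    from the generator with missingness disabled; only the outcome columns
    are overridden.
    """
    base = generate_cohort(
        GeneratorConfig(n_patients=529, seed=5, noise_rate=0.0, missingness_scale=0.0)
    )
    df = base.data.copy()
    rows = (
        [("recurrence", 30)] * 111 + [("contralateral", 30)] * 21
        + [("second_tumor", 30)] * 10
        + [("recurrence", 90)] * 46 + [("contralateral", 90)] * 11
        + [("second_tumor", 90)] * 8
        + [("none", None)] * 309
        + [("none", None)] * 13
    )
    assert len(rows) == 529
    ev_type = [r[0] for r in rows]
    ev_months = pd.array([r[1] for r in rows], dtype="Int64")
    followup = np.full(529, 200)
    followup[-13:] = 96
    df["event_type"] = ev_type
    df["event_months"] = ev_months
    df["followup_months"] = followup
    table = CohortTable(df, base.schema)
    table.validate()
    return table


@pytest.fixture(scope="session")
def composition_cohort():
    return build_composition_cohort()


@pytest.fixture(scope="session")
def pipeline_result():
    """One reduced-size full run (5-year horizon, 529 patients, 3-value grid).

    Session-scoped: the heavyweight acceptance-style checks all share it.
    """
    config = PipelineConfig.desk(seed=1, horizons=(60,))
    results, manifest = run_pipeline(config)
    return config, results[60], manifest
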