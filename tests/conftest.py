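"""Shared fixtures: toy matrices/cohorts and one session-scoped synthetic run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import twinclock as tc


def make_matrix(values, probes=None, samples=None, symbols=None) -> tc.ExpressionMatrix:
    values = np.asarray(values, float)
    probes = probes or [f"P{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j:03d}" for j in range(values.shape[1])]
    ann = None
    if symbols is not None:
        ann = pd.Series(symbols, index=probes)
    return tc.ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), ann)


def make_cohort(ages, sexes=None) -> tc.TwinCohort:
    """Paired cohort with one couple per age; sample ids C{i}M{1,2}."""
    rows = []
    for i, age in enumerate(ages):
        cid = f"C{i + 1:02d}"
        sex = (sexes or ["F"] * len(ages))[i]
        rows.append((f"{cid}M1", cid, 1, age, sex))
        rows.append((f"{cid}M2", cid, 2, age, sex))
    df = pd.DataFrame(
        rows, columns=["sample_id", "couple_id", "member", "age", "sex"]
    ).set_index("sample_id")
    return tc.TwinCohort(df)


@pytest.fixture(scope="session")
def default_run():
    """Default synthetic cohort (seed 0) with its extracted signature.

    Session-scoped because extraction runs 27 leave-one-couple-out folds.
    """
    config = tc.SyntheticConfig(seed=0)
    matrix, cohort, truth = tc.generate_twin_cohort(config)
    pipeline = tc.PipelineConfig(seed=0)
    signature = tc.extract_signature(matrix, cohort, pipeline)
    return {
        "config": config,
        "matrix": matrix,
        "cohort": cohort,
        "truth": truth,
        "pipeline": pipeline,
        "signature": signature,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
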