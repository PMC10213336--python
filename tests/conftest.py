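import numpy as np
import pandas as pd
import pytest

from symptomnet.cohort import ALL_COLUMNS, GAD7_COLS, PHQ9_COLS
from symptomnet.synthetic import GeneratorConfig, generate_cohort
from symptomnet import score_cohort


def make_cohort_df(n: int = 5, seed: int = 0) -> pd.DataFrame:
    """Small hand-buildable cohort frame covering every schema column."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({c: rng.integers(0, 4, n) for c in PHQ9_COLS})
    for c in GAD7_COLS:
        df[c] = rng.integers(0, 4, n)
    df["fatigue"] = rng.integers(0, 11, n)
    df["qol_1"] = rng.integers(1, 6, n)
    df["qol_2"] = rng.integers(1, 6, n)
    df["age"] = rng.integers(20, 70, n).astype(float)
    df["sex"] = rng.choice(["male", "female"], n)
    for c in ["married", "employed", "rural", "physical_disease",
              "visit_difficulty", "medication_compliance_good"]:
        df[c] = rng.integers(0, 2, n)
    df["education"] = rng.choice(["below_senior", "senior_or_above"], n)
    df["financial_status"] = rng.choice(["poor", "fair", "good"], n)
    df["social_media_freq"] = rng.choice(["none_minimal", "sometimes", "often"], n)
    df["diagnosis"] = rng.choice(["mdd", "bipolar", "schizophrenia", "other"], n)
    df["respondent_id"] = [f"R{i + 1:06d}" for i in range(n)]
    return df[ALL_COLUMNS]


@pytest.fixture
def cohort_df():
    return make_cohort_df()


@pytest.fixture(scope="session")
def default_scored():
    """One default synthetic cohort of the study's size, scored."""
    return score_cohort(generate_cohort(GeneratorConfig(n=1101, seed=7)))


@pytest.fixture(scope="session")
def phq_items(default_scored):
    return default_scored.data[PHQ9_COLS]
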