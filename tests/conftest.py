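import numpy as np
import pandas as pd
import pytest

from genelife.config import FOOD_ITEMS, SNP_IDS, AnalysisConfig, SimulationConfig
from genelife.simulate import generate_cohort, genotype_labels


def make_subject(subject_id="S1", **overrides):
    """One fully-specified, internally consistent cohort row."""
    row = {
        "subject_id": subject_id,
        "age": 50.0,
        "sex": "female",
        "education": "junior",
        "marital": "married_cohabit",
        "income": "lt1000",
        "family_history_htn": False,
        "antihypertensive_med": False,
        "baseline_sbp": 118.0,
        "baseline_dbp": 75.0,
        "followup_sbp": 120.0,
        "followup_dbp": 78.0,
        "hypertension": False,
        **{f"ff_{item}": "weekly" for item in FOOD_ITEMS},
        "bmi": 22.0,
        "smoking": "never",
        "years_since_quit": np.nan,
        "ipaq_level": "moderate",
        "drinks_per_year": 0,
        **{snp: genotype_labels(snp)[0] for snp in SNP_IDS},
    }
    row.update(overrides)
    return row


def make_cohort(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_cohort():
    """Four hand-written valid subjects spanning outcome states."""
    return make_cohort(
        [
            make_subject("S1"),
            make_subject(
                "S2",
                followup_sbp=145.0,
                followup_dbp=88.0,
                hypertension=True,
                bmi=27.0,
                smoking="current",
            ),
            make_subject(
                "S3",
                antihypertensive_med=True,
                followup_sbp=130.0,
                followup_dbp=82.0,
                hypertension=True,
                sex="male",
            ),
            make_subject("S4", ipaq_level="low", drinks_per_year=60),
        ]
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """Default stated-world synthetic cohort (n=4592, seed 1)."""
    return generate_cohort(SimulationConfig(n_subjects=4592, seed=1))


@pytest.fixture(scope="session")
def scored_cohort(sim_cohort):
    from genelife.scoring import score_cohort

    scored, model = score_cohort(sim_cohort, AnalysisConfig(seed=1))
    return scored, model
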