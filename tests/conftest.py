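import numpy as np
import pandas as pd
import pytest

from moltmark import (
    CohortDesign,
    DayGroupingRules,
    ExpressionMatrix,
    default_paper_profiles,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_profiles():
    return default_paper_profiles()


@pytest.fixture(scope="session")
def default_cohort(default_profiles):
    """One simulated cohort under the default study design."""
    return simulate_cohort(CohortDesign(), default_profiles, seed=7)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Pool-of-1, zero-noise cohort: pooled values equal the trends exactly."""
    profiles = {
        g: p.__class__(**{**vars(p), "noise_sd": 0.0, "phase_locked": False})
        for g, p in default_paper_profiles().items()
    }
    design = CohortDesign(copepods_per_pool=1, apolysis_day_sd=0.0)
    return simulate_cohort(design, profiles, seed=0)


@pytest.fixture
def tiny_matrix():
    """Hand-built 4-sample x 3-gene un-normalized matrix (2 targets + 1 hk)."""
    values = pd.DataFrame(
        {
            "A": [5.0, 6.0, 1.0, 2.0],
            "B": [3.0, 3.5, 4.0, 4.5],
            "HK": [2.0, 2.0, 2.0, 2.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    samples = pd.DataFrame(
        {
            "day": [1.0, 1.0, 10.0, 10.0],
            "replicate": [1, 2, 1, 2],
            "molt_phase": ["pre", "pre", "post", "post"],
        },
        index=values.index,
    )
    return ExpressionMatrix(values=values, samples=samples, housekeeping_genes=("HK",))


@pytest.fixture(scope="session")
def grouping_rules():
    return DayGroupingRules()
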