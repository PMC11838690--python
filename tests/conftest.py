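import numpy as np
import pandas as pd
import pytest

from mddpredict.cohort_prep import encode_features, screen_participants
from mddpredict.mice_rf import ImputationConfig, ImputedStack, impute
from mddpredict.synthetic_data import SimConfig, generate_cohort


def zero_missing_config(**overrides) -> SimConfig:
    base = dict(
        block_missing_rate=0.0,
        item_missing_rate=0.0,
        income_missing_rate=0.0,
        followup_missing_rates={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
    )
    base.update(overrides)
    return SimConfig(**base)


def stack_from_frames(frames, outcome_week: int = 4) -> ImputedStack:
    """Build an ImputedStack directly from completed data frames (no
    missingness; mask all-False) for constructed test instances."""
    mask = pd.DataFrame(
        False, index=frames[0].index, columns=[c for c in frames[0].columns if c != "arm"]
    )
    return ImputedStack(
        [f.copy() for f in frames],
        mask,
        ImputationConfig(m_imputations=len(frames)),
        outcome_week,
    )


@pytest.fixture(scope="session")
def big_complete_cohort():
    """n=20,000 cohort with zero missingness: marginal-calibration checks."""
    return generate_cohort(zero_missing_config(n_participants=20_000, rng_seed=11))


@pytest.fixture(scope="session")
def signal_table():
    """n=300 complete cohort with the default threshold effect, encoded."""
    cohort = generate_cohort(zero_missing_config(n_participants=300, rng_seed=7))
    screened, _ = screen_participants(cohort)
    return encode_features(screened)


@pytest.fixture(scope="session")
def signal_stack(signal_table):
    """Three identical completed copies of the complete signal table."""
    return impute(signal_table, ImputationConfig(m_imputations=3, rng_seed=1))


@pytest.fixture(scope="session")
def missing_table():
    """n=300 cohort with the default (trial-like) missingness profile."""
    cohort = generate_cohort(SimConfig(n_participants=300, rng_seed=19))
    screened, _ = screen_participants(cohort)
    return encode_features(screened)


@pytest.fixture(scope="session")
def missing_stack(missing_table):
    cfg = ImputationConfig(
        m_imputations=10, trees_per_forest=10, chain_iterations=3, rng_seed=3
    )
    return impute(missing_table, cfg)
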