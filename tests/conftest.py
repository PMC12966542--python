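import numpy as np
import pytest

from audema import (TruthConfig, add_decomposition, score_table,
                    simulate_study)
from audema.config import OutcomeParams


def small_config(seed: int = 5, **overrides) -> TruthConfig:
    """A quick 3-day, 30-participant study for unit tests."""
    base = dict(
        n_participants=30,
        n_days=3,
        final_day_prompts=3,
        compliance_by_day=(0.9, 0.8, 0.8),
        seed=seed,
    )
    base.update(overrides)
    return TruthConfig(**base)


def noise_free_config(seed: int = 5, residual_sd: float = 0.0,
                      random_intercept_sd: float = 0.0,
                      **overrides) -> TruthConfig:
    """Deterministic outcomes: (near-)zero residual noise, no random
    intercepts, censoring off so outcomes equal their linear predictors."""
    quiet = dict(random_intercept_sd=random_intercept_sd,
                 residual_sd=residual_sd)
    base = dict(
        effort=OutcomeParams(intercept=3.5, sleep_quality=-0.1, **quiet),
        affect=OutcomeParams(intercept=4.0, sleep_quality=0.2, **quiet),
        fatigue=OutcomeParams(intercept=3.0, time_of_day=0.1, **quiet),
        compliance_by_day=(1.0, 1.0, 1.0),
        keep_latent=True,
        clip_outcomes=False,
    )
    base.update(overrides)
    return small_config(seed=seed, **base)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def scored_frame(small_study):
    """Scored + decomposed analysis table for the small study."""
    scored, cuts = score_table(small_study.ema)
    scored = scored.merge(small_study.participants, on="participant_id")
    return add_decomposition(scored), cuts


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
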