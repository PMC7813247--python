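import numpy as np
import pandas as pd
import pytest

from ewasoc import (
    ExperimentConfig,
    LearningParams,
    build_migration_schedule,
    build_phase_schedule,
    simulate_session,
)


HEAVY_TESTS = {
    # long-running MCMC recoveries run after everything else so the fast
    # checks report first
    "test_baseline_recovers_population_means",
    "test_shipped_fit_meets_diagnostics_contract",
    "test_monotonic_model_separates_subgroups",
    "test_contrast_recovers_spatial_elevation",
}


def pytest_collection_modifyitems(items):
    items.sort(key=lambda item: item.name.split("[")[0] in HEAVY_TESTS)


@pytest.fixture(scope="session")
def default_config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def phase_schedule(default_config):
    return build_phase_schedule(default_config, seed=3)


@pytest.fixture(scope="session")
def migration_schedule(default_config):
    return build_migration_schedule(default_config)


@pytest.fixture(scope="session")
def homogeneous_agents():
    return [LearningParams(0.3, 0.2, 3.0, 0.5, 0.15, 0.7)] * 8


@pytest.fixture(scope="session")
def one_session(default_config, phase_schedule, migration_schedule, homogeneous_agents):
    """One simulated session with homogeneous, moderately social agents."""
    return simulate_session(
        default_config, phase_schedule, migration_schedule,
        homogeneous_agents, seed=7,
    )


def toy_session(n_rounds=3):
    """Hand-built two-participant mini-session used by the likelihood oracle tests.

    Participant 1 sees participant 2 as neighbour slot 1 (and vice
    versa); slots 2-3 are empty.  Values are chosen so every social
    branch (conformity, experience weighting, masking) is exercised.
    """
    rows = []
    # (round, participant, choice, payoff, nb_choice, nb_exp, cview, eview)
    script = [
        (1, 1, 2, 14.0, 0, 0, False, False),
        (1, 2, 3, 11.0, 0, 0, False, False),
        (2, 1, 3, 16.5, 3, 2, True, True),
        (2, 2, 3, 15.0, 2, 1, True, False),
        (3, 1, 3, 17.0, 3, 2, True, False),
        (3, 2, 3, 16.0, 3, 1, False, True),
    ]
    for rnd, pid, choice, payoff, nbc, nbe, cv, ev in script[: 2 * n_rounds]:
        row = dict(
            session=1, participant=pid, id=pid, round=rnd, region=1,
            phase=1, hard=False, choice=choice, payoff=payoff, optimal=3,
            experience=rnd, lag_spatial=rnd, lag_temporal=rnd,
            spatial_window=False, temporal_window=False,
        )
        for k, vals in ((1, (nbc, nbe, cv, ev)), (2, (0, 0, False, False)),
                        (3, (0, 0, False, False))):
            ch, ex, c_v, e_v = vals
            row[f"nb{k}_choice"] = ch
            row[f"nb{k}_experience"] = ex
            row[f"nb{k}_choice_viewed"] = c_v
            row[f"nb{k}_experience_viewed"] = e_v
        rows.append(row)
    return pd.DataFrame(rows)
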