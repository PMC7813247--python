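"""Lag curves and post hoc simulation comparison."""

import numpy as np
import pandas as pd
import pytest

from ewasoc import (
    DataError,
    ExperimentConfig,
    LearningParams,
    boxes_viewed_by_lag,
    posthoc_compare,
    prop_optimal_by_lag,
    simulate_session,
)
from ewasoc.summaries import PosteriorResult


def tiny_table():
    """12 observations across 3 lags with known per-lag proportions."""
    rows = []
    # lag 1: 4 obs, 2 optimal; lag 2: 4 obs, 3 optimal; lag 3: 4 obs, 4 optimal
    spec = {1: [1, 1, 2, 3], 2: [1, 1, 1, 4], 3: [1, 1, 1, 1]}
    for lag, choices in spec.items():
        for c in choices:
            rows.append(dict(lag_spatial=lag, lag_temporal=lag, choice=c,
                             optimal=1, hard=False))
    return pd.DataFrame(rows)


class TestPropOptimal:
    def test_hand_built_table(self):
        curve = prop_optimal_by_lag(tiny_table(), event="spatial")
        means = dict(zip(curve.table["lag"], curve.table["mean"]))
        assert means == {1: pytest.approx(0.5), 2: pytest.approx(0.75), 3: pytest.approx(1.0)}
        # s.e.m. = s / sqrt(n) with the sample s.d. (ddof = 1)
        sem1 = np.std([1, 1, 0, 0], ddof=1) / np.sqrt(4)
        assert curve.at(1)["sem"] == pytest.approx(sem1)
        assert curve.at(3)["sem"] == 0.0
        assert (curve.table["low_n"]).all()  # 4 < 5 observations per lag

    def test_all_optimal_curve_is_one(self):
        df = tiny_table()
        df["choice"] = 1
        curve = prop_optimal_by_lag(df, event="temporal")
        assert (curve.table["mean"] == 1.0).all()
        assert (curve.table["sem"] == 0.0).all()

    def test_random_agents_flat_at_chance(self, default_config, phase_schedule,
                                          migration_schedule):
        agents = [LearningParams(0.0, 0.5, 1.0, 0.0, 0.0, 0.5)] * 8
        frames = [
            simulate_session(default_config, phase_schedule, migration_schedule,
                             agents, seed=s) for s in range(4)
        ]
        curve = prop_optimal_by_lag(pd.concat(frames), event="spatial")
        good = curve.table[curve.table["n"] >= 100]
        assert np.abs(good["mean"] - 0.25).max() < 0.08

    def test_empty_stratum_is_absent_not_zero(self):
        df = tiny_table()  # all phases easy
        curve = prop_optimal_by_lag(df, event="spatial", strata="hard")
        assert len(curve.table) == 0

    def test_unknown_event_or_stratum(self):
        with pytest.raises(DataError):
            prop_optimal_by_lag(tiny_table(), event="sideways")
        with pytest.raises(DataError):
            prop_optimal_by_lag(tiny_table(), strata="medium")


class TestBoxesViewed:
    def test_configured_view_rates_recovered(self, one_session):
        choice_curve = boxes_viewed_by_lag(one_session, "choice", "spatial")
        exp_curve = boxes_viewed_by_lag(one_session, "experience", "spatial")
        w_choice = np.average(choice_curve.table["mean"], weights=choice_curve.table["n"])
        w_exp = np.average(exp_curve.table["mean"], weights=exp_curve.table["n"])
        assert w_choice == pytest.approx(0.85, abs=0.03)
        assert w_exp == pytest.approx(0.55, abs=0.03)

    def test_all_or_nothing_masks(self, one_session):
        df = one_session.copy()
        for k in (1, 2, 3):
            df[f"nb{k}_choice_viewed"] = True
            df[f"nb{k}_experience_viewed"] = False
        assert (boxes_viewed_by_lag(df, "choice").table["mean"] == 1.0).all()
        assert (boxes_viewed_by_lag(df, "experience").table["mean"] == 0.0).all()

    def test_individual_control_yields_absent_curve(self, one_session):
        df = one_session.drop(columns=[c for c in one_session.columns
                                       if c.startswith("nb")])
        curve = boxes_viewed_by_lag(df, "choice")
        assert len(curve.table) == 0


def test_sem_halves_when_n_quadruples():
    rng = np.random.default_rng(0)
    base = rng.binomial(1, 0.3, 4000).astype(float)
    small = pd.DataFrame(dict(lag_spatial=1, lag_temporal=1, hard=False,
                              choice=base[:1000] + 1, optimal=2))
    big = pd.DataFrame(dict(lag_spatial=1, lag_temporal=1, hard=False,
                            choice=base + 1, optimal=2))
    s_small = prop_optimal_by_lag(small).at(1)["sem"]
    s_big = prop_optimal_by_lag(big).at(1)["sem"]
    assert s_big == pytest.approx(s_small / 2, rel=0.1)


def fake_posterior(nat_means, sds=None):
    """Minimal baseline PosteriorResult for simulation-only consumers."""
    from ewasoc.transforms import PARAM_NAMES, PARAM_TRANSFORMS, to_unconstrained
    mu = np.array([float(to_unconstrained(nat_means[n], k))
                   for n, k in zip(PARAM_NAMES, PARAM_TRANSFORMS)])
    tau = np.zeros(6) if sds is None else np.asarray(sds, float)
    draws = {
        "mu_trans": np.tile(mu, (2, 3, 1)),
        "tau": np.tile(tau, (2, 3, 1)),
        "Rho": np.tile(np.eye(6), (2, 3, 1, 1)),
    }
    return PosteriorResult(
        kind="baseline", draws=draws, summary=pd.DataFrame(),
        diagnostics_table=pd.DataFrame(dict(rhat_ok=[True])),
        indiv_draws=np.zeros((2, 3, 8, 6)), ids=np.arange(8),
        payoff_totals=np.zeros(8),
        entries=[(p, "const") for p in range(6)],
    )


def fake_monotonic_posterior():
    """Minimal monotonic-fit PosteriorResult: sigma declines from 0.7 to 0.1."""
    from ewasoc.transforms import logit
    mu = np.array([float(logit(0.7)), float(logit(0.1)),  # sigma tmin/tmax
                   float(logit(0.5)), np.log(1.0), 0.0, np.log(0.2),
                   float(logit(0.6))])
    Pv = 7
    delta = np.concatenate([[0.0], np.full(19, 1 / 19)])[1:]
    draws = {
        "mu_trans": np.tile(mu, (2, 3, 1)),
        "tau": np.zeros((2, 3, Pv)),
        "Rho": np.tile(np.eye(Pv), (2, 3, 1, 1)),
        "sigma_delta": np.tile(delta, (2, 3, 1)),
    }
    entries = [(0, "tmin"), (0, "tmax")] + [(p, "const") for p in range(1, 6)]
    return PosteriorResult(
        kind="monotonic", draws=draws, summary=pd.DataFrame(),
        diagnostics_table=pd.DataFrame(dict(rhat_ok=[True])),
        indiv_draws=np.zeros((2, 3, 8, 6)), ids=np.arange(8),
        payoff_totals=np.zeros(8), entries=entries,
    )


class TestPosthocCompare:
    def test_random_population_stays_at_chance(self, one_session):
        post = fake_posterior(dict(sigma=1e-9, kappa=0.5, f=1.0, beta=0.0,
                                   phi=0.5, **{"lambda": 1e-9}))
        out = posthoc_compare(one_session, post, ExperimentConfig(), seed=0,
                              n_agents=32)
        sim = out["spatial"]["simulated"].table
        good = sim[sim["n"] >= 100]
        assert np.abs(good["mean"] - 0.25).max() < 0.09
        assert {"reference", "simulated"} <= set(out["spatial"])

    def test_time_varying_posterior_simulates(self, one_session):
        """A monotonic-fit population (endpoint pairs + shared step simplex)
        drives the post hoc simulation without error."""
        out = posthoc_compare(one_session, fake_monotonic_posterior(),
                              ExperimentConfig(), seed=2, n_agents=16)
        sim = out["spatial"]["simulated"].table
        assert len(sim) > 0 and sim["mean"].between(0, 1).all()

    def test_learning_steepens_with_payoff_gap(self, one_session):
        """A larger payoff gap makes softmax learners more reliably optimal."""
        post = fake_posterior(dict(sigma=1e-9, kappa=0.5, f=1.0, beta=0.0,
                                   phi=0.7, **{"lambda": 0.3}))
        overall = []
        for mult in (1.0, 5.0):
            out = posthoc_compare(one_session, post, ExperimentConfig(), seed=1,
                                  n_agents=32, payoff_gap_multiplier=mult)
            tab = out["spatial"]["simulated"].table
            overall.append(np.average(tab["mean"], weights=tab["n"]))
        assert overall[1] > overall[0] + 0.1
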