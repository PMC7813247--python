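"""Behavioural summaries and post hoc simulation comparison.

Learning curves (proportion of optimal choices) and information-search
curves (proportion of social-information boxes viewed) as a function of
rounds since a spatial change (migration) or a temporal change (phase
boundary), with standard errors of the means; and simulation of new
participants from a fitted population of varying effects for
side-by-side comparison with reference data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .environment import DataError, ExperimentConfig
from .ewa import LearningParams, MonotonicSpec
from .simulate import N_NEIGHBOURS, PopulationSpec, simulate_sessions
from .transforms import PARAM_NAMES

LOW_N = 5  # lags with fewer observations are reported but flagged


@dataclass(frozen=True)
class LagCurve:
    """Per-lag means with standard errors, stratified by event type.

    ``table`` has one row per lag with columns ``lag``, ``mean``,
    ``sem``, ``n`` and ``low_n``; lags with no observations are absent,
    not zero.
    """

    table: pd.DataFrame
    event: str
    measure: str
    stratum: str | None = None

    def at(self, lag: int) -> pd.Series:
        row = self.table.loc[self.table["lag"] == lag]
        if row.empty:
            raise DataError(f"no observations at lag {lag}")
        return row.iloc[0]


def _lag_column(event: str) -> str:
    if event == "spatial":
        return "lag_spatial"
    if event == "temporal":
        return "lag_temporal"
    raise DataError(f"unknown event type {event!r}")


def _curve(values: pd.Series, lags: pd.Series, event: str, measure: str,
           stratum: str | None) -> LagCurve:
    df = pd.DataFrame({"lag": lags.to_numpy(), "value": values.to_numpy(dtype=float)})
    grouped = df.groupby("lag")["value"]
    agg = grouped.agg(["mean", "std", "count"]).reset_index()
    agg["sem"] = (agg["std"] / np.sqrt(agg["count"])).fillna(0.0)
    table = pd.DataFrame({
        "lag": agg["lag"].astype(int),
        "mean": agg["mean"],
        "sem": agg["sem"],
        "n": agg["count"].astype(int),
    })
    table["low_n"] = table["n"] < LOW_N
    return LagCurve(table=table, event=event, measure=measure, stratum=stratum)


def prop_optimal_by_lag(records: pd.DataFrame, event: str = "spatial",
                        strata: str | None = None) -> LagCurve:
    """Mean proportion of optimal choices per lag with s.e.m. = s / sqrt(n).

    ``strata`` restricts to ``"hard"`` or ``"easy"`` phases.  Empty
    strata yield an empty curve, not zeros.
    """
    col = _lag_column(event)
    for needed in (col, "choice", "optimal", "hard"):
        if needed not in records.columns:
            raise DataError(f"records lack column {needed!r}")
    sub = records
    if strata == "hard":
        sub = records[records["hard"].astype(bool)]
    elif strata == "easy":
        sub = records[~records["hard"].astype(bool)]
    elif strata is not None:
        raise DataError(f"unknown stratum {strata!r}")
    indicator = (sub["choice"] == sub["optimal"]).astype(float)
    return _curve(indicator, sub[col], event, "prop_optimal", strata)


def boxes_viewed_by_lag(records: pd.DataFrame, box_kind: str = "choice",
                        event: str = "spatial") -> LagCurve:
    """Mean proportion of available social-information boxes viewed per lag."""
    if box_kind not in ("choice", "experience"):
        raise DataError(f"unknown box kind {box_kind!r}")
    col = _lag_column(event)
    mask_cols = [f"nb{k}_{box_kind}_viewed" for k in range(1, N_NEIGHBOURS + 1)]
    if not all(c in records.columns for c in mask_cols):
        # individual-learning control: no boxes, hence no curve
        empty = pd.DataFrame(columns=["lag", "mean", "sem", "n", "low_n"])
        return LagCurve(table=empty, event=event, measure=f"{box_kind}_boxes")
    viewed = records[mask_cols].astype(float).mean(axis=1)
    return _curve(viewed, records[col], event, f"{box_kind}_boxes", None)


def population_from_posterior(posterior, view_rate_choice: float = 0.85,
                              view_rate_experience: float = 0.55):
    """Posterior-mean population of varying effects (means, scales, correlations).

    Returns ``(spec_like, entries)`` where ``spec_like`` carries the
    posterior-mean ``mu``/``tau``/``Rho`` over the model's
    individual-level entries (endpoint pairs included for monotonic
    fits, preserving their correlations).
    """
    mu = posterior.flat("mu_trans").mean(axis=0)
    tau = posterior.flat("tau").mean(axis=0)
    rho = posterior.flat("Rho").mean(axis=0)
    # symmetrize against draw-averaging noise
    rho = 0.5 * (rho + rho.T)
    np.fill_diagonal(rho, 1.0)
    return (mu, tau, rho), list(posterior.entries)


def _agents_from_population(mu, tau, rho, entries, posterior, n_agents, rng):
    cov = np.outer(tau, tau) * rho
    draws = rng.multivariate_normal(mu, cov, size=n_agents, method="svd")
    tv_names = sorted({PARAM_NAMES[p] for p, role in entries if role != "const"})
    deltas = {name: posterior.flat(f"{name}_delta").mean(axis=0) for name in tv_names}
    agents, tv_specs = [], []
    for vec in draws:
        nat = np.zeros(6)
        tv = {}
        for e, (p, role) in enumerate(entries):
            name = PARAM_NAMES[p]
            if role == "const":
                nat[p] = vec[e]
            elif role == "tmin":
                e1 = [i for i, (pp, rr) in enumerate(entries)
                      if pp == p and rr == "tmax"][0]
                x = deltas[name]
                delta = np.concatenate([[0.0], x])
                tv[name] = MonotonicSpec(vec[e], vec[e1], delta)
                nat[p] = vec[e]  # placeholder; overridden per lag
        agents.append(LearningParams.from_unconstrained(nat))
        tv_specs.append(tv)
    return agents, tv_specs


def posthoc_compare(records: pd.DataFrame, posterior, config: ExperimentConfig,
                    seed, n_agents: int = 200, payoff_gap_multiplier: float = 1.0,
                    events=("spatial", "temporal")) -> dict:
    """Simulate new participants from a fitted population and pair the curves.

    Samples ``n_agents`` agents from the posterior-mean population of
    varying effects (correlation structure preserved), simulates whole
    sessions (optionally with the payoff gap scaled by
    ``payoff_gap_multiplier``), and returns reference-vs-simulated
    learning curves per event type.
    """
    (mu, tau, rho), entries = population_from_posterior(posterior)
    rng = np.random.default_rng(seed)
    sim_config = replace(
        config, payoff_gap=config.payoff_gap * payoff_gap_multiplier
    ) if payoff_gap_multiplier != 1.0 else config
    n_sessions = int(np.ceil(n_agents / sim_config.n_agents))

    def populations(s, session_rng):
        agents, tv = _agents_from_population(
            mu, tau, rho, entries, posterior, sim_config.n_agents, session_rng)
        populations.tv_by_session[s] = tv
        return agents

    populations.tv_by_session = {}

    def tv_builder(s, agents, session_rng):
        tv = populations.tv_by_session[s]
        return tv if any(tv) else None

    has_tv = any(role != "const" for _, role in entries)
    sim, _ = simulate_sessions(
        sim_config, populations, n_sessions, seed=int(rng.integers(2**31)),
        tv_builder=tv_builder if has_tv else None,
    )
    out = {}
    for event in events:
        out[event] = dict(
            reference=prop_optimal_by_lag(records, event=event),
            simulated=prop_optimal_by_lag(sim, event=event),
        )
    return out
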