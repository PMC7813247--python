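"""Agent-based generator of microsociety sessions.

Simulates full sessions of EWA agents playing the migration-structured
four-armed bandit: two regional groups of four agents, 100 rounds, four
payoff phases with region-distinct optima, a cyclic migration schedule,
and partial-information viewing (per-round Bernoulli masks over choice
and experience boxes).  Agents choose by the same learning rules the
inference module assumes, so likelihoods evaluated on generated data
are exact.

Output is a long-format :class:`pandas.DataFrame`, one row per
participant-round (see :data:`OBSERVATION_COLUMNS`), plus a ground-truth
sidecar of the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import (
    ConfigurationError,
    ExperimentConfig,
    MigrationSchedule,
    PhaseSchedule,
    build_migration_schedule,
    build_phase_schedule,
)
from .ewa import (
    LearningParams,
    MonotonicSpec,
    monotonic_trajectory,
)
from .transforms import PARAM_NAMES, PARAM_TRANSFORMS, to_natural, to_unconstrained

N_NEIGHBOURS = 3  # group_size - 1 under the default design

#: canonical long-format column order (choices and options are 1-based;
#: a neighbour choice of 0 means "hidden from group mates this round")
OBSERVATION_COLUMNS = (
    ["session", "participant", "id", "round", "region", "phase", "hard",
     "choice", "payoff", "optimal", "experience", "lag_spatial",
     "lag_temporal", "spatial_window", "temporal_window"]
    + [f"nb{k}_{fld}" for k in range(1, N_NEIGHBOURS + 1)
       for fld in ("choice", "experience", "choice_viewed", "experience_viewed")]
)

#: extra generator-bookkeeping columns appended after the canonical schema
BOOKKEEPING_COLUMNS = ["sigma_round", "social_available"]


@dataclass(frozen=True)
class PopulationSpec:
    """Population of varying effects on the transformed parameter scales.

    ``means`` and ``sds`` are length-6 vectors in canonical
    (sigma, kappa, f, beta, lambda, phi) order on the logit/log/identity
    scales; ``corr`` the 6x6 correlation matrix among them.  View rates
    give the per-box probability that a participant opens a neighbour's
    choice or experience box in a round.
    """

    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray = field(default_factory=lambda: np.eye(6))
    view_rate_choice: float = 0.85
    view_rate_experience: float = 0.55

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        object.__setattr__(self, "corr", np.asarray(self.corr, dtype=float))
        if self.means.shape != (6,) or self.sds.shape != (6,):
            raise ConfigurationError("means and sds must be length-6 vectors")
        if (self.sds < 0).any():
            raise ConfigurationError("sds must be nonnegative")
        if self.corr.shape != (6, 6) or not np.allclose(self.corr, self.corr.T):
            raise ConfigurationError("corr must be a symmetric 6x6 matrix")
        if not np.allclose(np.diag(self.corr), 1.0):
            raise ConfigurationError("corr must have unit diagonal")
        w = np.linalg.eigvalsh(self.corr)
        if w.min() < -1e-10:
            raise ConfigurationError("corr must be positive semidefinite")
        if not (0.0 <= self.view_rate_choice <= 1.0
                and 0.0 <= self.view_rate_experience <= 1.0):
            raise ConfigurationError("view rates must lie in [0, 1]")

    @classmethod
    def from_natural(cls, natural_means: dict, sds=None, **kw) -> "PopulationSpec":
        """Build from natural-scale mean parameters (sds on transformed scales)."""
        mu = np.array(
            [float(to_unconstrained(natural_means[n], k))
             for n, k in zip(PARAM_NAMES, PARAM_TRANSFORMS)]
        )
        sds = np.zeros(6) if sds is None else np.asarray(sds, dtype=float)
        return cls(means=mu, sds=sds, **kw)


def sample_population(spec: PopulationSpec, n: int, seed) -> list:
    """Draw ``n`` agents from the multivariate-normal population of varying effects.

    Sampling happens on the transformed scales (preserving the
    correlation structure) and is back-transformed to natural scales.
    """
    rng = np.random.default_rng(seed)
    cov = np.outer(spec.sds, spec.sds) * spec.corr
    draws = rng.multivariate_normal(spec.means, cov, size=n, method="svd")
    return [LearningParams.from_unconstrained(v) for v in draws]


def _tv_natural_trajectories(tv_spec: dict, n_lags: int) -> dict:
    """Per-lag natural-scale values for each time-varying parameter."""
    out = {}
    for name, spec in tv_spec.items():
        if spec.n_lags != n_lags:
            raise ConfigurationError(
                f"time-varying spec for {name!r} has {spec.n_lags} lags, "
                f"schedule attains {n_lags}"
            )
        kind = PARAM_TRANSFORMS[PARAM_NAMES.index(name)]
        out[name] = np.asarray(to_natural(monotonic_trajectory(spec), kind))
    return out


def simulate_session(
    config: ExperimentConfig,
    phase_schedule: PhaseSchedule,
    migration_schedule: MigrationSchedule,
    agents: list,
    seed,
    tv_specs: list | None = None,
    view_rate_choice: float = 0.85,
    view_rate_experience: float = 0.55,
    session_id: int = 1,
) -> pd.DataFrame:
    """Simulate one full session and return its long-format observations.

    ``agents`` holds one :class:`LearningParams` per participant
    (founders of region 1 first).  ``tv_specs``, if given, holds one
    ``{param_name: MonotonicSpec}`` dict per agent (transformed-scale
    endpoints); parameters absent from the dict stay constant.  New
    arrivals' previous-round choices are hidden from their group mates,
    and every neighbour box is viewed with the configured rate.
    """
    n_agents = config.n_agents
    if len(agents) != n_agents:
        raise ConfigurationError(f"need {n_agents} agents, got {len(agents)}")
    if config.group_size - 1 > N_NEIGHBOURS:
        raise ConfigurationError(
            f"schema supports at most {N_NEIGHBOURS + 1} members per group"
        )
    if tv_specs is not None and len(tv_specs) != n_agents:
        raise ConfigurationError("tv_specs must match the number of agents")

    rng = np.random.default_rng(seed)
    n_lags = config.group_size * config.migration_interval
    trajectories = [
        _tv_natural_trajectories(tv_specs[j], n_lags) if tv_specs else {}
        for j in range(n_agents)
    ]
    base = np.stack([a.as_array() for a in agents])  # (n_agents, 6)

    event_by_round = dict(migration_schedule.events)
    g = config.group_size
    region = np.array([0] * g + [1] * g)
    last_move = np.zeros(n_agents, dtype=int)  # event round of last migration
    A = np.zeros((n_agents, 4))
    prev_choice = np.full(n_agents, -1)

    rows = []
    for rnd in range(1, config.n_rounds + 1):
        phase = phase_schedule.phase_of_round(rnd)
        lag_temporal = (rnd - 1) % config.phase_length + 1
        lag_spatial = rnd - last_move  # vector
        arrived = last_move == rnd - 1  # migrated at the immediately preceding boundary
        arrived &= rnd > 1

        choices = np.empty(n_agents, dtype=int)
        payoffs = np.empty(n_agents)
        for j in range(n_agents):
            ell = int(lag_spatial[j])
            par = base[j].copy()
            for name, traj in trajectories[j].items():
                par[PARAM_NAMES.index(name)] = traj[min(ell, n_lags) - 1]
            sigma, kappa, f, beta, lam, phi = par

            # asocial branch
            x = lam * A[j]
            x = x - x.max()
            e = np.exp(x)
            pa = e / e.sum()

            nb_fields = []
            counts = np.zeros(4)
            ew = np.zeros(4)  # exp(beta * E) mass per option
            if config.social_condition and rnd > 1:
                neighbours = [k for k in range(n_agents) if k != j and region[k] == region[j]]
                for k in neighbours:
                    hidden = bool(arrived[k])
                    cview = bool(rng.random() < view_rate_choice)
                    eview = bool(rng.random() < view_rate_experience)
                    nb_choice = 0 if hidden else int(prev_choice[k]) + 1
                    nb_exp = int(lag_spatial[k])
                    nb_fields.append((nb_choice, nb_exp, cview, eview))
                    if not hidden and cview:
                        opt = int(prev_choice[k])
                        counts[opt] += 1.0
                        ew[opt] += np.exp(beta * (nb_exp if eview else 0.0))

            total = counts.sum()
            if total > 0:
                pc = counts ** f
                pc /= pc.sum()
                pe = ew / ew.sum()
                ps = (1.0 - kappa) * pc + kappa * pe
                p = (1.0 - sigma) * pa + sigma * ps
            else:
                p = pa

            c = int(rng.choice(4, p=p))
            pay = float(rng.normal(
                phase_schedule.tier_mean[phase]
                if c == phase_schedule.optimal_option[phase, region[j]]
                else phase_schedule.tier_mean[phase] - config.payoff_gap,
                phase_schedule.payoff_sd[phase],
            ))
            choices[j] = c
            payoffs[j] = pay

            row = dict(
                session=session_id,
                participant=j + 1,
                id=(session_id - 1) * n_agents + j + 1,
                round=rnd,
                region=int(region[j]) + 1,
                phase=phase + 1,
                hard=bool(phase_schedule.hard_flag[phase]),
                choice=c + 1,
                payoff=pay,
                optimal=int(phase_schedule.optimal_option[phase, region[j]]) + 1,
                experience=ell,
                lag_spatial=ell,
                lag_temporal=lag_temporal,
                spatial_window=bool(ell <= 5 and last_move[j] > 0),
                temporal_window=bool(lag_temporal <= 5 and phase > 0),
                sigma_round=float(sigma) if total > 0 else 0.0,
                social_available=bool(total > 0),
            )
            if config.social_condition:
                for k in range(N_NEIGHBOURS):
                    if k < len(nb_fields):
                        ch, ex, cv, ev = nb_fields[k]
                    else:  # smaller group sizes leave trailing slots empty
                        ch, ex, cv, ev = 0, 0, False, False
                    row[f"nb{k + 1}_choice"] = ch
                    row[f"nb{k + 1}_experience"] = ex
                    row[f"nb{k + 1}_choice_viewed"] = cv
                    row[f"nb{k + 1}_experience_viewed"] = ev
            rows.append(row)

        # learn, then apply any end-of-round migration event
        for j in range(n_agents):
            phi_j = base[j][5]
            if "phi" in trajectories[j]:
                phi_j = trajectories[j]["phi"][min(int(lag_spatial[j]), n_lags) - 1]
            A[j, choices[j]] = (1.0 - phi_j) * A[j, choices[j]] + phi_j * payoffs[j]
        prev_choice = choices.copy()
        if rnd in event_by_round:
            pair = event_by_round[rnd]
            a, b = pair, g + pair
            region[a], region[b] = region[b], region[a]
            last_move[a] = rnd
            last_move[b] = rnd

    frame = pd.DataFrame(rows)
    cols = [c for c in OBSERVATION_COLUMNS if c in frame.columns] + BOOKKEEPING_COLUMNS
    return frame[cols]


def simulate_sessions(
    config: ExperimentConfig,
    populations,
    n_sessions: int,
    seed,
    tv_builder=None,
    view_rate_choice: float = 0.85,
    view_rate_experience: float = 0.55,
    with_schedules: bool = False,
) -> tuple:
    """Simulate several sessions with per-session seed streams.

    ``populations`` is either a :class:`PopulationSpec` (agents drawn
    per session) or a callable ``(session_index, rng) -> list[LearningParams]``.
    ``tv_builder``, if given, maps ``(session_index, agents, rng)`` to a
    per-agent list of time-varying spec dicts.  Returns
    ``(observations, truth)`` DataFrames, plus a third
    ``(phase_schedules, migration_events)`` pair of tidy frames when
    ``with_schedules`` is set.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sessions)
    frames, truth_rows = [], []
    phase_frames, event_frames = [], []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        sched_seed = int(rng.integers(2**31))
        phase_schedule = build_phase_schedule(config, sched_seed)
        migration_schedule = build_migration_schedule(config)
        if with_schedules:
            pf = phase_schedule.to_frame()
            pf.insert(0, "session", s + 1)
            phase_frames.append(pf)
            ef = migration_schedule.to_frame()
            ef.insert(0, "session", s + 1)
            event_frames.append(ef)
        if isinstance(populations, PopulationSpec):
            agents = sample_population(populations, config.n_agents, rng)
        else:
            agents = populations(s, rng)
        tv = tv_builder(s, agents, rng) if tv_builder is not None else None
        frames.append(
            simulate_session(
                config, phase_schedule, migration_schedule, agents,
                seed=rng, tv_specs=tv, session_id=s + 1,
                view_rate_choice=view_rate_choice,
                view_rate_experience=view_rate_experience,
            )
        )
        for j, a in enumerate(agents):
            rec = dict(session=s + 1, participant=j + 1,
                       id=s * config.n_agents + j + 1, **a.to_dict())
            if tv is not None:
                for name, spec in tv[j].items():
                    rec[f"{name}_tmin"] = spec.theta_tmin
                    rec[f"{name}_tmax"] = spec.theta_tmax
                rec["subgroup"] = "time-varying" if tv[j] else "constant"
            truth_rows.append(rec)
    obs = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    if with_schedules:
        return obs, truth, (pd.concat(phase_frames, ignore_index=True),
                            pd.concat(event_frames, ignore_index=True))
    return obs, truth


# ---------------------------------------------------------------------------
# the parameter-recovery scenario
# ---------------------------------------------------------------------------

#: population means used by the recovery scenario (natural scale);
#: chosen as plausible microsociety values: moderate experience bias,
#: clear conformity, prompt updating.
RECOVERY_BASE_MEANS = dict(sigma=0.3, kappa=0.2, f=3.0, beta=0.5, **{"lambda": 0.15}, phi=0.7)

RECOVERY_SIGMA_TMIN = 0.8   # declining subgroup: heavy social learning on arrival
RECOVERY_SIGMA_TMAX = 0.02  # ... then essentially none
RECOVERY_SD = 0.3           # individual s.d. on transformed scales


def recovery_delta(n_lags: int = 20, decay: float = 0.8) -> np.ndarray:
    """Step vector of the declining subgroup: geometric steps, ~60% of the
    total change inside the first five lags."""
    steps = decay ** np.arange(1, n_lags)
    return np.concatenate([[0.0], steps / steps.sum()])


def recovery_scenario(seed, n_sessions: int = 25, config: ExperimentConfig | None = None):
    """Two-subgroup scenario for validating the monotonic-effects model.

    Half of the agents in every session rely heavily on social learning
    right after migration and then switch to individual learning
    (monotonic sigma from ~0.8 down to ~0.02); the other half use an
    intermediate, constant amount (sigma ~ 0.3).  All other parameters
    are constant across lags.  Returns ``(observations, truth)``; the
    truth sidecar records each agent's parameters, subgroup and sigma
    endpoints.
    """
    config = config or ExperimentConfig()
    n_lags = config.group_size * config.migration_interval
    delta = recovery_delta(n_lags)
    mu = np.array([
        float(to_unconstrained(RECOVERY_BASE_MEANS[n], k))
        for n, k in zip(PARAM_NAMES, PARAM_TRANSFORMS)
    ])
    spec = PopulationSpec(means=mu, sds=np.full(6, RECOVERY_SD))
    tmin_mu = float(to_unconstrained(RECOVERY_SIGMA_TMIN, "logit"))
    tmax_mu = float(to_unconstrained(RECOVERY_SIGMA_TMAX, "logit"))

    def tv_builder(s, agents, rng):
        specs = []
        for j in range(len(agents)):
            if j % 2 == 0:  # declining subgroup
                specs.append({
                    "sigma": MonotonicSpec(
                        theta_tmin=tmin_mu + RECOVERY_SD * rng.standard_normal(),
                        theta_tmax=tmax_mu + RECOVERY_SD * rng.standard_normal(),
                        delta=delta,
                    )
                })
            else:
                specs.append({})
        return specs

    return simulate_sessions(config, spec, n_sessions, seed, tv_builder=tv_builder)
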