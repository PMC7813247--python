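"""Experimental design of the migration-structured bandit microsociety.

A session consists of two regional groups of four participants playing a
four-armed bandit for 100 rounds.  The session is divided into four
25-round phases; within each phase and region exactly one option is
optimal, paying ``tier_mean`` on average while the other three pay
``tier_mean - payoff_gap``.  Payoffs are Gaussian with a phase-specific
standard deviation ("hard" phases overlap strongly, "easy" phases
little).  Every ``migration_interval`` rounds one fixed cross-region
pair of participants swaps regions, cycling through the pairs in founder
order, so that each group is fully exchanged after
``group_size * migration_interval`` rounds and restored after twice
that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when an experiment configuration violates its invariants."""


class DataError(ValueError):
    """Raised when observations are inconsistent with the design."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Generative design of one session (defaults reproduce the experiment)."""

    n_rounds: int = 100
    n_phases: int = 4
    phase_length: int = 25
    migration_interval: int = 5
    group_size: int = 4
    n_regions: int = 2
    n_options: int = 4
    payoff_tier_means: tuple = (13.0, 15.0, 17.0, 19.0)
    payoff_gap: float = 3.0
    sd_hard: float = 3.0
    sd_easy: float = 1.5
    n_hard_phases: int = 2
    social_condition: bool = True

    def __post_init__(self):
        if self.n_phases * self.phase_length != self.n_rounds:
            raise ConfigurationError(
                f"n_phases * phase_length = {self.n_phases * self.phase_length} "
                f"must equal n_rounds = {self.n_rounds}"
            )
        if self.n_hard_phases > self.n_phases:
            raise ConfigurationError("n_hard_phases exceeds n_phases")
        if self.payoff_gap <= 0:
            raise ConfigurationError("payoff_gap must be positive")
        if self.sd_hard < 0 or self.sd_easy < 0:
            raise ConfigurationError("payoff standard deviations must be nonnegative")
        if len(self.payoff_tier_means) != self.n_phases:
            raise ConfigurationError("need one payoff tier mean per phase")
        if self.n_regions != 2:
            raise ConfigurationError("the design is defined for exactly two regions")

    @property
    def n_agents(self) -> int:
        return self.n_regions * self.group_size

    def to_dict(self) -> dict:
        d = asdict(self)
        d["payoff_tier_means"] = list(self.payoff_tier_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "payoff_tier_means" in d:
            d["payoff_tier_means"] = tuple(float(x) for x in d["payoff_tier_means"])
        return cls(**d)


@dataclass(frozen=True)
class PhaseSchedule:
    """Realized per-phase design: optima per region, tier means, noise levels.

    ``optimal_option[phase, region]`` is a 0-based option index;
    ``tier_mean[phase]`` the optimal option's mean payoff;
    ``payoff_sd[phase]`` the Gaussian payoff noise; ``hard_flag[phase]``
    marks high-uncertainty phases.
    """

    optimal_option: np.ndarray
    tier_mean: np.ndarray
    payoff_sd: np.ndarray
    hard_flag: np.ndarray
    config: ExperimentConfig = field(default_factory=ExperimentConfig)

    def phase_of_round(self, rnd: int) -> int:
        """0-based phase of a 1-based round index."""
        if not 1 <= rnd <= self.config.n_rounds:
            raise DataError(f"round {rnd} outside session")
        return (rnd - 1) // self.config.phase_length

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in range(self.config.n_phases):
            for r in range(self.config.n_regions):
                rows.append(
                    dict(
                        phase=p + 1,
                        region=r + 1,
                        optimal_option=int(self.optimal_option[p, r]) + 1,
                        tier_mean=float(self.tier_mean[p]),
                        payoff_sd=float(self.payoff_sd[p]),
                        hard=bool(self.hard_flag[p]),
                    )
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MigrationSchedule:
    """Ordered swap events and the fixed cross-region pairing.

    ``events`` is a list of ``(round, pair_index)``: at the end of that
    round the pair's two members exchange regions (taking effect from
    the next round).  ``pair_assignment`` maps each participant id to
    their fixed partner.  Participants ``0..group_size-1`` found region
    0; ``group_size..2*group_size-1`` found region 1; pair ``k`` links
    founders ``k`` and ``group_size + k``.
    """

    events: tuple
    pair_assignment: dict
    config: ExperimentConfig = field(default_factory=ExperimentConfig)

    def membership_at(self, rnd: int) -> np.ndarray:
        """Region (0/1) of every participant during 1-based round ``rnd``."""
        g = self.config.group_size
        region = np.array([0] * g + [1] * g)
        for ev_round, pair in self.events:
            if ev_round < rnd:
                a, b = pair, g + pair
                region[a], region[b] = region[b], region[a]
        return region

    def migration_rounds(self) -> list:
        """Rounds whose end carries a swap event."""
        return [ev for ev, _ in self.events]

    def to_frame(self) -> pd.DataFrame:
        g = self.config.group_size
        return pd.DataFrame(
            [
                dict(round=ev, pair=p + 1, participant_a=p + 1, participant_b=g + p + 1)
                for ev, p in self.events
            ]
        )


def build_phase_schedule(config: ExperimentConfig, seed: int) -> PhaseSchedule:
    """Randomize the per-phase design subject to the design invariants.

    Per phase, the two regions' optimal options are drawn uniformly
    among ordered pairs of distinct options; the tier means are a
    uniformly random permutation of ``payoff_tier_means``; exactly
    ``n_hard_phases`` uniformly chosen phases carry ``sd_hard``.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    P, R, O = config.n_phases, config.n_regions, config.n_options
    optimal = np.empty((P, R), dtype=int)
    for p in range(P):
        o1 = rng.integers(O)
        o2 = rng.integers(O - 1)
        if o2 >= o1:
            o2 += 1
        optimal[p] = (o1, o2)
    tier = np.asarray(config.payoff_tier_means, dtype=float)[rng.permutation(P)]
    hard = np.zeros(P, dtype=bool)
    hard[rng.choice(P, size=config.n_hard_phases, replace=False)] = True
    sd = np.where(hard, config.sd_hard, config.sd_easy)
    return PhaseSchedule(optimal, tier, sd, hard, config)


def build_migration_schedule(config: ExperimentConfig) -> MigrationSchedule:
    """Deterministic swap schedule: pairs cycle in founder order.

    Events sit at the end of rounds ``migration_interval, 2*migration_interval, ...``
    within the session (the last round carries no event since it cannot
    take effect).
    """
    events = []
    pair_cycle = itertools.cycle(range(config.group_size))
    rnd = config.migration_interval
    while rnd < config.n_rounds:
        events.append((rnd, next(pair_cycle)))
        rnd += config.migration_interval
    g = config.group_size
    pairs = {}
    for k in range(g):
        pairs[k] = g + k
        pairs[g + k] = k
    return MigrationSchedule(tuple(events), pairs, config)


def full_swap_round(schedule: MigrationSchedule) -> int:
    """Event round after which each group holds only the other group's founders."""
    g = schedule.config.group_size
    founders0 = set(range(g))
    for ev_round, _ in schedule.events:
        region = schedule.membership_at(ev_round + 1)
        group0 = {i for i in range(2 * g) if region[i] == 0}
        if group0 == set(range(g, 2 * g)):
            return ev_round
    raise DataError("schedule never reaches a complete swap")


def restoration_round(schedule: MigrationSchedule) -> int:
    """Event round after which both founding memberships are restored."""
    g = schedule.config.group_size
    for ev_round, _ in schedule.events:
        region = schedule.membership_at(ev_round + 1)
        group0 = {i for i in range(2 * g) if region[i] == 0}
        if ev_round > schedule.config.migration_interval and group0 == set(range(g)):
            return ev_round
    raise DataError("schedule never restores the founders")


def draw_payoff(option, region, phase, schedule: PhaseSchedule, rng, size=None):
    """Gaussian payoff draw(s) for an option in a region-phase cell.

    Mean is the phase tier mean if the option is the region's current
    optimum, else ``tier_mean - payoff_gap``; payoffs are real-valued,
    untruncated and unrounded.
    """
    cfg = schedule.config
    mean = np.where(
        np.asarray(option) == schedule.optimal_option[phase, region],
        schedule.tier_mean[phase],
        schedule.tier_mean[phase] - cfg.payoff_gap,
    )
    draws = rng.normal(mean, schedule.payoff_sd[phase], size=size)
    return draws if size is not None else float(draws)


def lag_counters(schedule: MigrationSchedule, participant: int, rnd: int):
    """(rounds since migration, rounds since temporal change), both 1-based.

    The spatial lag is 1 on a participant's first round in a region and
    increments each round until their next migration; the temporal lag
    resets to 1 on the first round of each phase.
    """
    cfg = schedule.config
    if not 0 <= participant < cfg.n_agents:
        raise DataError(f"unknown participant {participant}")
    if not 1 <= rnd <= cfg.n_rounds:
        raise DataError(f"round {rnd} outside session")
    g = cfg.group_size
    pair = participant if participant < g else participant - g
    # last event round < rnd that moved this participant
    last_move = 0
    for ev_round, ev_pair in schedule.events:
        if ev_round < rnd and ev_pair == pair:
            last_move = ev_round
    spatial = rnd - last_move
    temporal = (rnd - 1) % cfg.phase_length + 1
    return spatial, temporal


def max_spatial_lag(config: ExperimentConfig) -> int:
    """Longest attainable residence time under the cyclic pair schedule."""
    return config.group_size * config.migration_interval
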