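"""Experience-weighted attraction (EWA) learning with social cues.

Pure, side-effect-free functions implementing the learning model:
attraction updating, the softmax asocial choice rule, frequency-
dependent (conformist) and experience-biased social choice
probabilities, their mixtures, and the two constructors for
time-varying parameters (monotonic effects over a step simplex, and a
Gaussian-process covariance over residence-time lags).

Choice probabilities for individual j mix asocial and social cues,

    P(i) = (1 - sigma_j) * P_A(i) + sigma_j * P_S(i),

where P_A is a softmax of lambda_j * attractions, and the social term
mixes conformist and experience-directed probabilities,

    P_S(i) = (1 - kappa_j) * P_C(i) + kappa_j * P_E(i),
    P_C(i) prop. to n_i ** f_j,
    P_E(i) prop. to sum_k exp(beta_j * E_k)  over observed choosers k of i.

Attractions update by A <- (1 - phi_j) * A + phi_j * payoff for the
chosen option only; unchosen attractions persist unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import (
    PARAM_NAMES,
    PARAM_TRANSFORMS,
    to_natural,
    to_unconstrained,
)
from .environment import DataError


@dataclass(frozen=True)
class LearningParams:
    """One individual's EWA parameters on the natural scale.

    sigma : weight of social vs asocial cues, in [0, 1]
    kappa : weight of experience vs frequency cues, in [0, 1]
    f     : conformity exponent, > 0 (1 = unbiased frequency copying)
    beta  : experience-bias strength, real (0 = experience-blind)
    lam   : softmax sensitivity (inverse exploration rate), >= 0
    phi   : attraction updating rate, in [0, 1]
    """

    sigma: float
    kappa: float
    f: float
    beta: float
    lam: float
    phi: float

    def __post_init__(self):
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must lie in [0, 1]")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if self.f <= 0.0:
            raise ValueError("f must be positive")
        if self.lam < 0.0:
            raise ValueError("lambda must be nonnegative")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        """Natural-scale values in canonical (sigma, kappa, f, beta, lambda, phi) order."""
        return np.array([self.sigma, self.kappa, self.f, self.beta, self.lam, self.phi])

    def to_unconstrained(self) -> np.ndarray:
        """Values on the model's transformed scales (logit/log/identity)."""
        nat = self.as_array()
        return np.array(
            [float(to_unconstrained(v, k)) for v, k in zip(nat, PARAM_TRANSFORMS)]
        )

    @classmethod
    def from_unconstrained(cls, vec) -> "LearningParams":
        vec = np.asarray(vec, dtype=float)
        nat = [float(to_natural(v, k)) for v, k in zip(vec, PARAM_TRANSFORMS)]
        return cls(*nat)

    @classmethod
    def from_dict(cls, d) -> "LearningParams":
        return cls(
            sigma=d["sigma"], kappa=d["kappa"], f=d["f"],
            beta=d["beta"], lam=d["lambda"], phi=d["phi"],
        )

    def to_dict(self) -> dict:
        return dict(zip(PARAM_NAMES, self.as_array()))


@dataclass(frozen=True)
class SocialContext:
    """Visible social information for one participant-round.

    Per neighbour: previous-round choice (0-based index, or -1 when
    hidden because the neighbour just migrated in), experience in the
    current region (rounds, >= 1), and the two viewing masks from mouse
    tracking.  A neighbour's choice enters the frequency counts only if
    its choice box was viewed; their experience enters the experience
    weights only if that box was viewed (otherwise it contributes at
    E = 0, i.e. a unit weight).
    """

    choices: np.ndarray          # (n_neighbours,) int, -1 = hidden
    experiences: np.ndarray      # (n_neighbours,) int
    choice_viewed: np.ndarray    # (n_neighbours,) bool
    experience_viewed: np.ndarray  # (n_neighbours,) bool
    n_options: int = 4

    def visible(self) -> np.ndarray:
        """Neighbours whose previous choice is usable as social information."""
        return (np.asarray(self.choices) >= 0) & np.asarray(self.choice_viewed, dtype=bool)

    def counts(self) -> np.ndarray:
        """n_i: visible choosers per option."""
        vis = self.visible()
        return np.bincount(
            np.asarray(self.choices)[vis], minlength=self.n_options
        ).astype(float)

    def effective_experiences(self) -> np.ndarray:
        """Experience values as used by the model (0 where the box went unviewed)."""
        return np.where(
            np.asarray(self.experience_viewed, dtype=bool),
            np.asarray(self.experiences, dtype=float),
            0.0,
        )


class NoSocialInformation(ValueError):
    """No visible neighbour choices: the caller must fall back to asocial cues."""


def update_attractions(attractions, chosen: int, payoff: float, phi: float):
    """One attraction-learning step; returns a new array.

    Only the chosen option moves: A_c <- (1 - phi) * A_c + phi * payoff.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    A = np.array(attractions, dtype=float)
    A[chosen] = (1.0 - phi) * A[chosen] + phi * payoff
    return A


def asocial_probs(attractions, lam: float) -> np.ndarray:
    """Softmax choice probabilities, numerically stabilized by max subtraction."""
    if lam < 0.0:
        raise ValueError("lambda must be nonnegative")
    x = lam * np.asarray(attractions, dtype=float)
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def conformity_probs(context: SocialContext, f: float) -> np.ndarray:
    """Frequency-dependent copying probabilities, prop. to n_i ** f."""
    if f <= 0.0:
        raise ValueError("f must be positive")
    n = context.counts()
    if n.sum() == 0:
        raise NoSocialInformation("no visible neighbour choices")
    w = n ** f
    return w / w.sum()


def experience_probs(context: SocialContext, beta: float) -> np.ndarray:
    """Experience-directed copying: choosers weighted by exp(beta * E_k)."""
    vis = context.visible()
    if not vis.any():
        raise NoSocialInformation("no visible neighbour choices")
    choices = np.asarray(context.choices)[vis]
    E = context.effective_experiences()[vis]
    x = beta * E
    w = np.exp(x - x.max())  # max-subtracted: stable for any beta
    per_option = np.bincount(choices, weights=w, minlength=context.n_options)
    return per_option / per_option.sum()


def social_probs(pc, pe, kappa: float) -> np.ndarray:
    """Mixture of conformist and experience-directed cues."""
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    return (1.0 - kappa) * np.asarray(pc, dtype=float) + kappa * np.asarray(pe, dtype=float)


def choice_probs(pa, ps, sigma: float) -> np.ndarray:
    """Mixture of asocial and social cues; falls back to asocial when ps is None."""
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("sigma must lie in [0, 1]")
    pa = np.asarray(pa, dtype=float)
    if ps is None:
        return pa.copy()
    return (1.0 - sigma) * pa + sigma * np.asarray(ps, dtype=float)


# ---------------------------------------------------------------------------
# time-varying parameter constructors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonotonicSpec:
    """Monotonic trajectory of a (transformed-scale) parameter over lags.

    theta_tmin / theta_tmax are the values at the shortest and longest
    residence lag; ``delta`` is the step-size vector with delta[0] = 0
    and the remaining entries a simplex, so the trajectory moves from
    theta_tmin at lag 1 to theta_tmax at the last lag, monotonically.
    """

    theta_tmin: float
    theta_tmax: float
    delta: np.ndarray

    def __post_init__(self):
        delta = np.asarray(self.delta, dtype=float)
        object.__setattr__(self, "delta", delta)
        if delta[0] != 0.0:
            raise ValueError("delta[0] must be 0")
        if (delta[1:] < 0).any() or abs(delta[1:].sum() - 1.0) > 1e-8:
            raise ValueError("delta[1:] must be a simplex")

    @property
    def n_lags(self) -> int:
        return self.delta.shape[0]


def monotonic_value(spec: MonotonicSpec, lag: int) -> float:
    """Parameter value after ``lag`` rounds in a region (transformed scale).

    theta(lag) = theta_tmin - (theta_tmin - theta_tmax) * sum_{m=0}^{lag-1} delta_m.
    """
    if not 1 <= lag <= spec.n_lags:
        raise DataError(f"lag {lag} outside 1..{spec.n_lags}")
    partial = float(spec.delta[:lag].sum())
    return spec.theta_tmin - (spec.theta_tmin - spec.theta_tmax) * partial


def monotonic_trajectory(spec: MonotonicSpec) -> np.ndarray:
    """Values at every lag 1..n_lags (transformed scale)."""
    cum = np.concatenate([[0.0], np.cumsum(spec.delta[1:])])
    return spec.theta_tmin - (spec.theta_tmin - spec.theta_tmax) * cum


@dataclass(frozen=True)
class GPSpec:
    """Gaussian-process description of per-lag parameter offsets.

    The covariance between lags x and y is
    ``eta2 * exp(-rho2 * D(x, y)^2) + sigma2_same * [x == y]``; the
    parameter trajectory is ``mean_value + offsets`` on the transformed
    scale.
    """

    eta2: float
    rho2: float
    sigma2_same: float
    mean_value: float = 0.0
    offsets: np.ndarray = field(default_factory=lambda: np.zeros(20))

    def __post_init__(self):
        if self.eta2 < 0 or self.rho2 < 0 or self.sigma2_same < 0:
            raise ValueError("GP hyperparameters must be nonnegative")
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))

    def trajectory(self) -> np.ndarray:
        return self.mean_value + self.offsets


def gp_covariance(lags, spec: GPSpec, jitter: float = 0.0) -> np.ndarray:
    """Squared-exponential covariance over lag values, plus same-lag variance."""
    lags = np.asarray(lags, dtype=float)
    D2 = (lags[:, None] - lags[None, :]) ** 2
    K = spec.eta2 * np.exp(-spec.rho2 * D2)
    K[np.diag_indices_from(K)] += spec.sigma2_same + jitter
    return K
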