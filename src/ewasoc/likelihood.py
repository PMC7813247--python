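"""Choice-probability likelihood of observed sessions.

Two routes compute the same quantity:

* a readable reference path (:func:`observation_probability`,
  :func:`session_log_likelihood`) built from the pure functions in
  :mod:`ewasoc.ewa`, propagating attraction states round by round; and
* a numba-compiled kernel (:func:`loglik_and_grad`) over packed arrays
  that additionally returns analytic gradients of the log-likelihood
  with respect to every observation's six natural-scale parameters.
  The phi gradient is propagated through the attraction recursion by a
  reverse (adjoint) sweep.

The kernel is what the hierarchical models differentiate through; the
reference path is the oracle it is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .environment import DataError
from .ewa import (
    LearningParams,
    NoSocialInformation,
    SocialContext,
    asocial_probs,
    choice_probs,
    conformity_probs,
    experience_probs,
    social_probs,
    update_attractions,
)
from .simulate import N_NEIGHBOURS


def _context_from_record(obs) -> SocialContext | None:
    """Build a SocialContext from a long-format record; None without neighbour fields."""
    if f"nb1_choice" not in obs:
        return None
    choices, exps, cview, eview = [], [], [], []
    for k in range(1, N_NEIGHBOURS + 1):
        choices.append(int(obs[f"nb{k}_choice"]) - 1)  # 0 (hidden) -> -1
        exps.append(int(obs[f"nb{k}_experience"]))
        cview.append(bool(obs[f"nb{k}_choice_viewed"]))
        eview.append(bool(obs[f"nb{k}_experience_viewed"]))
    return SocialContext(
        np.array(choices), np.array(exps), np.array(cview), np.array(eview)
    )


def observation_probability(obs, params: LearningParams, state) -> float:
    """Probability of the realized choice in one participant-round.

    ``state`` holds the participant's four attractions entering this
    round.  Social cues are used only when at least one neighbour choice
    is visible; otherwise the asocial branch stands alone.
    """
    pa = asocial_probs(state, params.lam)
    context = _context_from_record(obs)
    ps = None
    if context is not None:
        try:
            pc = conformity_probs(context, params.f)
            pe = experience_probs(context, params.beta)
            ps = social_probs(pc, pe, params.kappa)
        except NoSocialInformation:
            ps = None
    p = choice_probs(pa, ps, params.sigma)
    return float(p[int(obs["choice"]) - 1])


def session_log_likelihood(records: pd.DataFrame, all_params) -> float:
    """Log-probability of one session's observations.

    ``all_params`` maps the ``participant`` column to
    :class:`LearningParams` (a dict, or a sequence indexed by
    ``participant - 1``).  Attractions start at zero and are propagated
    in round order by the chosen option's payoff.
    """
    total = 0.0
    for pid, sub in records.groupby("participant", sort=True):
        sub = sub.sort_values("round")
        rounds = sub["round"].to_numpy()
        if not np.array_equal(rounds, np.arange(rounds[0], rounds[0] + len(rounds))):
            raise DataError(f"participant {pid} has missing rounds")
        params = all_params[pid] if isinstance(all_params, dict) else all_params[pid - 1]
        state = np.zeros(4)
        for _, obs in sub.iterrows():
            total += np.log(observation_probability(obs, params, state))
            state = update_attractions(
                state, int(obs["choice"]) - 1, float(obs["payoff"]), params.phi
            )
    return float(total)


# ---------------------------------------------------------------------------
# packed representation + numba kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PackedData:
    """Array view of a long-format dataset, sorted by individual then round.

    ``starts`` delimits each individual's observation block;
    ``nb_option``/``nb_experience`` carry each visible neighbour's
    0-based previous choice (-1 when hidden or unviewed) and effective
    experience (0 where the experience box went unviewed).
    """

    starts: np.ndarray        # (N+1,) int64
    ind: np.ndarray           # (n_obs,) int64 individual index
    choice: np.ndarray        # (n_obs,) int64, 0-based
    payoff: np.ndarray        # (n_obs,) float64
    nb_option: np.ndarray     # (n_obs, 3) int64
    nb_experience: np.ndarray  # (n_obs, 3) float64
    lag_spatial: np.ndarray   # (n_obs,) int64
    spatial_window: np.ndarray   # (n_obs,) float64 0/1
    temporal_window: np.ndarray  # (n_obs,) float64 0/1
    ids: np.ndarray           # (N,) original ``id`` values
    payoff_totals: np.ndarray  # (N,) summed payoffs per individual

    @property
    def n_individuals(self) -> int:
        return len(self.starts) - 1

    @property
    def n_obs(self) -> int:
        return len(self.choice)


def pack_data(df: pd.DataFrame) -> PackedData:
    """Pack a long-format dataset for the likelihood kernel."""
    required = {"id", "round", "choice", "payoff"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"dataset lacks required columns: {sorted(missing)}")
    df = df.sort_values(["id", "round"], kind="mergesort").reset_index(drop=True)
    ids, ind = np.unique(df["id"].to_numpy(), return_inverse=True)
    counts = np.bincount(ind)
    starts = np.concatenate([[0], np.cumsum(counts)])
    for i in range(len(ids)):
        rounds = df["round"].to_numpy()[starts[i]:starts[i + 1]]
        if not np.array_equal(rounds, np.arange(rounds[0], rounds[0] + len(rounds))):
            raise DataError(f"individual id={ids[i]} has missing rounds")

    n_obs = len(df)
    nb_option = np.full((n_obs, N_NEIGHBOURS), -1, dtype=np.int64)
    nb_exp = np.zeros((n_obs, N_NEIGHBOURS), dtype=np.float64)
    if "nb1_choice" in df.columns:
        for k in range(N_NEIGHBOURS):
            ch = df[f"nb{k + 1}_choice"].to_numpy(dtype=np.int64) - 1
            cv = df[f"nb{k + 1}_choice_viewed"].to_numpy(dtype=bool)
            ev = df[f"nb{k + 1}_experience_viewed"].to_numpy(dtype=bool)
            ex = df[f"nb{k + 1}_experience"].to_numpy(dtype=np.float64)
            visible = (ch >= 0) & cv
            nb_option[:, k] = np.where(visible, ch, -1)
            nb_exp[:, k] = np.where(visible & ev, ex, 0.0)

    if "lag_spatial" in df.columns:
        lag = df["lag_spatial"].to_numpy(dtype=np.int64)
    else:
        lag = np.ones(n_obs, dtype=np.int64)
    sw = (df["spatial_window"].to_numpy(dtype=np.float64)
          if "spatial_window" in df.columns else np.zeros(n_obs))
    tw = (df["temporal_window"].to_numpy(dtype=np.float64)
          if "temporal_window" in df.columns else np.zeros(n_obs))
    payoff = df["payoff"].to_numpy(dtype=np.float64)
    totals = np.bincount(ind, weights=payoff)
    return PackedData(
        starts=starts.astype(np.int64),
        ind=ind.astype(np.int64),
        choice=(df["choice"].to_numpy(dtype=np.int64) - 1),
        payoff=payoff,
        nb_option=nb_option,
        nb_experience=nb_exp,
        lag_spatial=lag,
        spatial_window=sw,
        temporal_window=tw,
        ids=ids,
        payoff_totals=totals,
    )


@njit(cache=True, fastmath=False, error_model="numpy")
def _kernel(starts, choice, payoff, nb_option, nb_experience, nat, grad_out):
    """Log-likelihood and per-observation natural-scale gradients.

    ``nat`` is (n_obs, 6): sigma, kappa, f, beta, lambda, phi for every
    observation (already evaluated at the observation's lag for
    time-varying models).  Writes d log L / d nat into ``grad_out`` and
    returns the total log-likelihood.
    """
    n_ind = starts.shape[0] - 1
    total = 0.0
    max_T = 0
    for i in range(n_ind):
        T = starts[i + 1] - starts[i]
        if T > max_T:
            max_T = T
    A_hist = np.empty((max_T, 4))
    v_hist = np.empty((max_T, 4))
    # scratch vectors reused across observations (no per-round allocation)
    A = np.empty(4)
    pa = np.empty(4)
    n = np.empty(4)
    W = np.empty(4)
    S = np.empty(4)
    pc = np.empty(4)
    pe = np.empty(4)
    adj = np.empty(4)
    log_int = np.array([0.0, 0.0, np.log(2.0), np.log(3.0)])

    for i in range(n_ind):
        s, e = starts[i], starts[i + 1]
        for o in range(4):
            A[o] = 0.0
        for t in range(s, e):
            sig = nat[t, 0]
            kap = nat[t, 1]
            f = nat[t, 2]
            beta = nat[t, 3]
            lam = nat[t, 4]

            # asocial softmax
            m = lam * A[0]
            for o in range(1, 4):
                if lam * A[o] > m:
                    m = lam * A[o]
            Z = 0.0
            for o in range(4):
                pa[o] = np.exp(lam * A[o] - m)
                Z += pa[o]
            for o in range(4):
                pa[o] /= Z

            # social counts and experience weights; exponents are
            # max-subtracted so extreme f or beta cannot overflow
            ntot = 0.0
            m_e = -np.inf
            for o in range(4):
                n[o] = 0.0
                W[o] = 0.0
                S[o] = 0.0
            for k in range(nb_option.shape[1]):
                o = nb_option[t, k]
                if o >= 0:
                    n[o] += 1.0
                    ntot += 1.0
                    if beta * nb_experience[t, k] > m_e:
                        m_e = beta * nb_experience[t, k]
            if ntot > 0.0:
                for k in range(nb_option.shape[1]):
                    o = nb_option[t, k]
                    if o >= 0:
                        E = nb_experience[t, k]
                        w = np.exp(beta * E - m_e)
                        W[o] += w
                        S[o] += E * w

            c = choice[t]
            if ntot > 0.0:
                ln_max = 0.0
                for o in range(4):
                    if log_int[int(n[o])] > ln_max:
                        ln_max = log_int[int(n[o])]
                Zc = 0.0
                for o in range(4):
                    if n[o] > 0.0:
                        pc[o] = np.exp(f * (log_int[int(n[o])] - ln_max))
                        Zc += pc[o]
                    else:
                        pc[o] = 0.0
                sum_pc_logn = 0.0
                for o in range(4):
                    if n[o] > 0.0:
                        pc[o] /= Zc
                        sum_pc_logn += pc[o] * log_int[int(n[o])]
                ZW = 0.0
                ZS = 0.0
                for o in range(4):
                    ZW += W[o]
                    ZS += S[o]
                for o in range(4):
                    pe[o] = W[o] / ZW
                ps_c = (1.0 - kap) * pc[c] + kap * pe[c]
                pch = (1.0 - sig) * pa[c] + sig * ps_c
                if pch < 1e-300:  # floor against underflow far out in the tails
                    pch = 1e-300
                aw = 1.0 - sig
                grad_out[t, 0] = (ps_c - pa[c]) / pch
                grad_out[t, 1] = sig * (pe[c] - pc[c]) / pch
                if n[c] > 0.0:
                    dpc = pc[c] * (log_int[int(n[c])] - sum_pc_logn)
                else:
                    dpc = 0.0
                grad_out[t, 2] = (1.0 - kap) * sig * dpc / pch
                dpe = (S[c] - pe[c] * ZS) / ZW
                grad_out[t, 3] = kap * sig * dpe / pch
            else:
                pch = pa[c]
                if pch < 1e-300:
                    pch = 1e-300
                aw = 1.0
                grad_out[t, 0] = 0.0
                grad_out[t, 1] = 0.0
                grad_out[t, 2] = 0.0
                grad_out[t, 3] = 0.0

            total += np.log(pch)

            Abar = 0.0
            for o in range(4):
                Abar += pa[o] * A[o]
            grad_out[t, 4] = aw * pa[c] * (A[c] - Abar) / pch

            coef = aw * pa[c] * lam / pch
            for o in range(4):
                v_hist[t - s, o] = -coef * pa[o]
                A_hist[t - s, o] = A[o]
            v_hist[t - s, c] += coef

            phi = nat[t, 5]
            A[c] = (1.0 - phi) * A[c] + phi * payoff[t]

        # reverse sweep for phi
        for o in range(4):
            adj[o] = 0.0
        for t in range(e - 1, s - 1, -1):
            c = choice[t]
            phi = nat[t, 5]
            grad_out[t, 5] = adj[c] * (payoff[t] - A_hist[t - s, c])
            adj[c] *= (1.0 - phi)
            for o in range(4):
                adj[o] += v_hist[t - s, o]
    return total


def loglik_and_grad(data: PackedData, nat: np.ndarray):
    """Total log-likelihood and (n_obs, 6) gradient w.r.t. natural parameters."""
    grad = np.empty_like(nat)
    lp = _kernel(
        data.starts, data.choice, data.payoff,
        data.nb_option, data.nb_experience, nat, grad,
    )
    return float(lp), grad


def loglik(data: PackedData, nat: np.ndarray) -> float:
    lp, _ = loglik_and_grad(data, nat)
    return lp


def nat_from_params(data: PackedData, params_by_id) -> np.ndarray:
    """Constant per-individual natural parameters expanded to per-observation rows."""
    nat = np.empty((data.n_obs, 6))
    for i, id_ in enumerate(data.ids):
        p = params_by_id[id_] if isinstance(params_by_id, dict) else params_by_id[i]
        nat[data.starts[i]:data.starts[i + 1]] = p.as_array()
    return nat
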