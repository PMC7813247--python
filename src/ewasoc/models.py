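"""Hierarchical Bayesian EWA models on the unconstrained scale.

One posterior class covers the four model kinds:

baseline
    Six learning parameters per individual, drawn (on logit/log/identity
    scales) from a multivariate-normal population with means ``mu``,
    scales ``tau`` and an LKJ-distributed correlation matrix, in the
    non-centred parametrization ``theta_i = mu + tau * (L @ z_i)``.
contrast
    Baseline plus additive population-level offsets on the transformed
    scales, switched on inside the first-five-round windows after
    spatial (migration) and temporal (phase-boundary) changes; both
    windows may be active at once.
monotonic
    Selected parameters get per-individual endpoint pairs (value at the
    shortest and longest residence lag) joined by a shared
    Dirichlet-simplex step vector; endpoints join the varying-effects
    block, so their correlations with other parameters are estimated.
gp
    Baseline plus population-level per-lag offsets under a
    squared-exponential Gaussian-process prior over residence lags
    (individual-specific GP covariances are deliberately out of scope).

The class exposes ``logp_and_grad`` for the sampler; every gradient is
analytic except the small constrained-bijection Jacobians, which use
complex-step differentiation (exact to machine precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .environment import ConfigurationError
from .likelihood import PackedData, loglik_and_grad
from .transforms import (
    PARAM_NAMES,
    PARAM_TRANSFORMS,
    corr_chol_from_unconstrained,
    corr_chol_value_jac,
    inv_logit,
    simplex_from_unconstrained,
    simplex_value_jac,
    to_natural,
)

MODEL_KINDS = ("baseline", "contrast", "monotonic", "gp")


@dataclass(frozen=True)
class ModelConfig:
    """Sampler and prior settings for a hierarchical EWA fit."""

    kind: str = "baseline"
    chains: int = 4
    iterations: int = 500          # post-warmup draws per chain
    warmup: int = 500
    seed: int | None = None
    prior_mu_sd: float = 1.0       # normal prior s.d. on transformed population means
    prior_tau_rate: float = 1.0    # exponential prior rate for scale parameters
    lkj_eta: float = 2.0
    dirichlet_alpha: float = 2.0   # concentration for monotonic step simplexes
    contrast_params: tuple = ("sigma", "kappa", "f", "beta")
    time_varying: tuple = PARAM_NAMES  # monotonic/gp: which parameters vary over lags
    n_lags: int = 20
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ConfigurationError(
                f"unknown model kind {self.kind!r}; expected one of {MODEL_KINDS}"
            )
        if self.chains < 1 or self.iterations < 1 or self.warmup < 0:
            raise ConfigurationError("chains/iterations/warmup must be positive")
        if self.dirichlet_alpha <= 0:
            raise ConfigurationError("dirichlet_alpha must be positive")
        for p in self.contrast_params + tuple(self.time_varying):
            if p not in PARAM_NAMES:
                raise ConfigurationError(f"unknown parameter name {p!r}")


class HierarchicalEWA:
    """Unconstrained-space posterior for one model kind over packed data."""

    def __init__(self, data: PackedData, config: ModelConfig):
        self.data = data
        self.config = config
        self.N = data.n_individuals
        kind = config.kind

        # individual-level entries: (param index, role); monotonic models
        # replace a varying parameter's single entry by an endpoint pair
        entries = []
        for p, name in enumerate(PARAM_NAMES):
            if kind == "monotonic" and name in config.time_varying:
                entries.append((p, "tmin"))
                entries.append((p, "tmax"))
            else:
                entries.append((p, "const"))
        self.entries = entries
        self.Pv = len(entries)
        self.n_corr = self.Pv * (self.Pv - 1) // 2
        self.entry_of = {}
        for e, (p, role) in enumerate(entries):
            self.entry_of[(p, role)] = e

        self.tv_params = (
            [PARAM_NAMES.index(n) for n in config.time_varying]
            if kind in ("monotonic", "gp") else []
        )
        self.cp = ([PARAM_NAMES.index(n) for n in config.contrast_params]
                   if kind == "contrast" else [])
        L = config.n_lags
        self.lag_idx = np.clip(data.lag_spatial, 1, L) - 1  # 0-based lag bin

        # layout
        ofs = 0
        self.s_mu = slice(ofs, ofs + self.Pv); ofs += self.Pv
        self.s_ltau = slice(ofs, ofs + self.Pv); ofs += self.Pv
        self.s_corr = slice(ofs, ofs + self.n_corr); ofs += self.n_corr
        self.s_z = slice(ofs, ofs + self.N * self.Pv); ofs += self.N * self.Pv
        if kind == "contrast":
            nc = len(self.cp)
            self.s_off_s = slice(ofs, ofs + nc); ofs += nc
            self.s_off_t = slice(ofs, ofs + nc); ofs += nc
        if kind == "monotonic":
            self.s_delta = {}
            for p in self.tv_params:
                self.s_delta[p] = slice(ofs, ofs + L - 2)
                ofs += L - 2
        if kind == "gp":
            self.s_d, self.s_hyp = {}, {}
            for p in self.tv_params:
                self.s_d[p] = slice(ofs, ofs + L); ofs += L
                self.s_hyp[p] = slice(ofs, ofs + 3); ofs += 3  # log eta2, rho2, sig2
        self.dim = ofs
        self._D2 = (np.arange(L)[:, None] - np.arange(L)[None, :]) ** 2.0

    # -- helpers ------------------------------------------------------------

    def _natural_and_jac(self, theta):
        """Map transformed-scale (n_obs, 6) values to natural scale + Jacobian."""
        nat = np.empty_like(theta)
        jac = np.empty_like(theta)
        logit_cols = [0, 1, 5]   # sigma, kappa, phi
        log_cols = [2, 4]        # f, lambda
        v = expit(theta[:, logit_cols])
        nat[:, logit_cols] = v
        jac[:, logit_cols] = v * (1.0 - v)
        # clip far outside the prior's reach so extreme warmup excursions
        # cannot overflow to inf
        w = np.exp(np.clip(theta[:, log_cols], -60.0, 60.0))
        nat[:, log_cols] = w
        jac[:, log_cols] = w
        nat[:, 3] = theta[:, 3]
        jac[:, 3] = 1.0
        return nat, jac

    def initial_point(self, rng) -> np.ndarray:
        q = 0.1 * rng.standard_normal(self.dim)
        q[self.s_ltau] = np.log(0.5) + 0.05 * rng.standard_normal(self.Pv)
        return q

    # -- posterior ----------------------------------------------------------

    def logp_and_grad(self, q):
        # non-finite intermediate values (e.g. partial correlations hitting
        # +-1 in warmup excursions) surface as -inf/NaN log densities and are
        # rejected by the sampler's energy check; silence the noise here
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            return self._logp_and_grad(q)

    def _logp_and_grad(self, q):
        cfg = self.config
        data = self.data
        N, Pv = self.N, self.Pv
        mu = q[self.s_mu]
        ltau = q[self.s_ltau]
        tau = np.exp(ltau)
        y_corr = q[self.s_corr]
        Z = q[self.s_z].reshape(N, Pv)
        Lmat, corr_prior_val, J_L, g_corr_prior = corr_chol_value_jac(
            y_corr, Pv, cfg.lkj_eta)
        M = Z @ Lmat.T                      # (N, Pv)
        V = mu[None, :] + tau[None, :] * M  # individual transformed values

        ind = data.ind
        mono = {}  # per tv param: (cum, diff_obs) for the backward pass
        delta_tr = {}  # per tv param: (x, prior_val, J, g_prior)
        if cfg.kind != "monotonic":
            # entries coincide with the six parameters: one gather
            theta = V[ind]
            if cfg.kind == "gp":
                for p in self.tv_params:
                    theta[:, p] += q[self.s_d[p]][self.lag_idx]
        else:
            theta = np.empty((data.n_obs, 6))
            for p in range(6):
                if p in self.tv_params:
                    delta_tr[p] = simplex_value_jac(
                        q[self.s_delta[p]], cfg.dirichlet_alpha)
                    x = delta_tr[p][0]
                    cum = np.concatenate([[0.0], np.cumsum(x)])  # length n_lags
                    tmin = V[ind, self.entry_of[(p, "tmin")]]
                    tmax = V[ind, self.entry_of[(p, "tmax")]]
                    C = cum[self.lag_idx]
                    theta[:, p] = tmin - (tmin - tmax) * C
                    mono[p] = (cum, C, tmin, tmax)
                else:
                    theta[:, p] = V[ind, self.entry_of[(p, "const")]]
        if cfg.kind == "contrast":
            off_s = q[self.s_off_s]
            off_t = q[self.s_off_t]
            for j, p in enumerate(self.cp):
                theta[:, p] += (data.spatial_window * off_s[j]
                                + data.temporal_window * off_t[j])

        nat, jac = self._natural_and_jac(theta)
        lp, g_nat = loglik_and_grad(data, nat)
        g_theta = g_nat * jac

        grad = np.zeros(self.dim)
        G_V = np.zeros((N, Pv))
        for p in range(6):
            if cfg.kind == "monotonic" and p in self.tv_params:
                cum, C, tmin, tmax = mono[p]
                g = g_theta[:, p]
                G_V[:, self.entry_of[(p, "tmin")]] += np.bincount(
                    ind, weights=g * (1.0 - C), minlength=N)
                G_V[:, self.entry_of[(p, "tmax")]] += np.bincount(
                    ind, weights=g * C, minlength=N)
                gC_lag = np.bincount(
                    self.lag_idx, weights=-g * (tmin - tmax),
                    minlength=cfg.n_lags)
                suffix = np.cumsum(gC_lag[::-1])[::-1]
                g_simplex = suffix[1:]  # d logp / d delta_m, m = 1..L-1
                _, prior_val, J, g_prior = delta_tr[p]
                lp += prior_val
                grad[self.s_delta[p]] += J.T @ g_simplex + g_prior
            else:
                G_V[:, self.entry_of[(p, "const")]] += np.bincount(
                    ind, weights=g_theta[:, p], minlength=N)
                if cfg.kind == "gp" and p in self.tv_params:
                    grad[self.s_d[p]] += np.bincount(
                        self.lag_idx, weights=g_theta[:, p], minlength=cfg.n_lags)

        if cfg.kind == "contrast":
            for j, p in enumerate(self.cp):
                grad[self.s_off_s][j] += np.sum(g_theta[:, p] * data.spatial_window)
                grad[self.s_off_t][j] += np.sum(g_theta[:, p] * data.temporal_window)
            lp += -0.5 * np.sum((off_s / cfg.prior_mu_sd) ** 2)
            lp += -0.5 * np.sum((off_t / cfg.prior_mu_sd) ** 2)
            grad[self.s_off_s] += -off_s / cfg.prior_mu_sd**2
            grad[self.s_off_t] += -off_t / cfg.prior_mu_sd**2

        if cfg.kind == "gp":
            for p in self.tv_params:
                d = q[self.s_d[p]]
                le2, lr2, ls2 = q[self.s_hyp[p]]
                eta2, rho2, sig2 = np.exp(le2), np.exp(lr2), np.exp(ls2)
                Kse = eta2 * np.exp(-rho2 * self._D2)
                K = Kse + (sig2 + 1e-8) * np.eye(cfg.n_lags)
                cf = cho_factor(K, lower=True)
                alpha = cho_solve(cf, d)
                logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
                lp += -0.5 * float(d @ alpha) - 0.5 * logdet
                grad[self.s_d[p]] += -alpha
                Kinv = cho_solve(cf, np.eye(cfg.n_lags))
                for h, dK in enumerate((
                    Kse,                                   # d K / d log eta2
                    -rho2 * self._D2 * Kse,                # d K / d log rho2 (pre-chain)
                    sig2 * np.eye(cfg.n_lags),             # d K / d log sig2
                )):
                    gh = 0.5 * float(alpha @ dK @ alpha) - 0.5 * float(np.trace(Kinv @ dK))
                    grad[self.s_hyp[p]][h] += gh
                # exponential priors on the variance-scale hyperparameters
                for h, val in enumerate((eta2, rho2, sig2)):
                    lp += -cfg.prior_tau_rate * val + np.log(val)
                    grad[self.s_hyp[p]][h] += -cfg.prior_tau_rate * val + 1.0

        # hierarchy: V = mu + tau * (Z L^T)
        grad[self.s_mu] += G_V.sum(axis=0)
        grad[self.s_ltau] += (G_V * M).sum(axis=0) * tau
        GZ = (G_V * tau[None, :]) @ Lmat
        grad[self.s_z] += GZ.ravel()
        G_L = (G_V * tau[None, :]).T @ Z  # (Pv, Pv), lower triangle relevant

        # priors: mu, tau, z, correlation
        lp += -0.5 * np.sum((mu / cfg.prior_mu_sd) ** 2)
        grad[self.s_mu] += -mu / cfg.prior_mu_sd**2
        lp += np.sum(-cfg.prior_tau_rate * tau + ltau)
        grad[self.s_ltau] += -cfg.prior_tau_rate * tau + 1.0
        lp += -0.5 * np.sum(Z * Z)
        grad[self.s_z] += -Z.ravel()

        # correlation block: LKJ prior + transform Jacobian (one batched
        # complex-step pass computed alongside the transform above)
        lp += corr_prior_val
        grad[self.s_corr] += J_L.T @ G_L.ravel() + g_corr_prior

        return float(lp), grad

    # -- draw unpacking ------------------------------------------------------

    def unpack(self, q) -> dict:
        """Constrained, interpretable quantities of one draw."""
        cfg = self.config
        N, Pv = self.N, self.Pv
        mu = q[self.s_mu]
        tau = np.exp(q[self.s_ltau])
        Lmat, _ = corr_chol_from_unconstrained(q[self.s_corr], Pv)
        Z = q[self.s_z].reshape(N, Pv)
        V = mu[None, :] + tau[None, :] * (Z @ Lmat.T)
        Rho = Lmat @ Lmat.T

        out = {"mu_trans": mu, "tau": tau, "Rho": Rho}
        indiv = np.empty((N, 6))
        for p, name in enumerate(PARAM_NAMES):
            kind = PARAM_TRANSFORMS[p]
            if cfg.kind == "monotonic" and p in self.tv_params:
                x, _ = simplex_from_unconstrained(q[self.s_delta[p]])
                cum = np.concatenate([[0.0], np.cumsum(x)])
                e0 = self.entry_of[(p, "tmin")]
                e1 = self.entry_of[(p, "tmax")]
                traj = mu[e0] - (mu[e0] - mu[e1]) * cum
                out[f"{name}_traj"] = np.asarray(to_natural(traj, kind))
                out[f"{name}_tmin"] = float(to_natural(mu[e0], kind))
                out[f"{name}_tmax"] = float(to_natural(mu[e1], kind))
                out[f"{name}_tmin_ind"] = np.asarray(to_natural(V[:, e0], kind))
                out[f"{name}_tmax_ind"] = np.asarray(to_natural(V[:, e1], kind))
                out[f"{name}_delta"] = x
                # individual value averaged over the lag trajectory
                cum_mean = float(cum.mean())
                indiv[:, p] = to_natural(
                    V[:, e0] - (V[:, e0] - V[:, e1]) * cum_mean, kind)
            else:
                e = self.entry_of[(p, "const")]
                out[f"{name}_mean"] = float(to_natural(mu[e], kind))
                indiv[:, p] = to_natural(V[:, e], kind)
                if cfg.kind == "gp" and p in self.tv_params:
                    d = q[self.s_d[p]]
                    out[f"{name}_traj"] = np.asarray(to_natural(mu[e] + d, kind))
                    out[f"{name}_offsets"] = d
                    out[f"{name}_gp_hyp"] = np.exp(q[self.s_hyp[p]])
        if cfg.kind == "contrast":
            off_s = q[self.s_off_s]
            off_t = q[self.s_off_t]
            for j, p in enumerate(self.cp):
                name = PARAM_NAMES[p]
                kind = PARAM_TRANSFORMS[p]
                e = self.entry_of[(p, "const")]
                sp = float(to_natural(mu[e] + off_s[j], kind))
                te = float(to_natural(mu[e] + off_t[j], kind))
                out[f"{name}_spatial"] = sp
                out[f"{name}_temporal"] = te
                out[f"{name}_contrast"] = sp - te
        out["indiv"] = indiv
        return out
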