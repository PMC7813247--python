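"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained gradient-based MCMC engine over a target supplying
``logp_and_grad(q) -> (float, ndarray)`` on an unconstrained space.
Implements multinomial NUTS (recursive doubling, no-U-turn termination,
multinomial sampling of the proposal within the trajectory), dual
averaging of the step size towards a target acceptance statistic, and
windowed estimation of a diagonal inverse metric during warmup,
following the scheme popularized by Stan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_nuts", "NUTSStats"]

_MAX_DELTA_H = 1000.0  # divergence threshold on energy error


@dataclass
class NUTSStats:
    """Per-draw sampler statistics for one chain."""

    accept_stat: np.ndarray
    step_size: float
    n_divergent: int
    tree_depth: np.ndarray


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0, target=0.8, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat):
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1.0 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1.0 - w) * self.log_eps_bar

    @property
    def eps(self):
        return float(np.exp(self.log_eps))

    @property
    def eps_final(self):
        return float(np.exp(self.log_eps_bar))


class _Welford:
    """Online mean/variance accumulator."""

    def __init__(self, dim):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def add(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self):
        return self.m2 / max(self.n - 1, 1)


def _find_reasonable_eps(logp_grad, q, inv_mass, rng):
    eps = 1.0
    lp, grad = logp_grad(q)
    p = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(p * p * inv_mass)
    q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
    h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return max(eps, 1e-8)


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p_half = p + 0.5 * eps * grad
    q_new = q + eps * inv_mass * p_half
    lp, grad_new = logp_grad(q_new)
    p_new = p_half + 0.5 * eps * grad_new
    return q_new, p_new, lp, grad_new


class _Tree:
    __slots__ = ("q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
                 "q_prop", "log_w", "sum_accept", "n_leapfrog", "divergent", "turning")


def _build_tree(logp_grad, q, p, grad, depth, direction, eps, inv_mass, h0, rng):
    if depth == 0:
        q1, p1, lp1, g1 = _leapfrog(logp_grad, q, p, grad, direction * eps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
        t = _Tree()
        t.q_minus = t.q_plus = q1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = g1
        t.q_prop = q1
        delta_h = h1 - h0 if np.isfinite(h1) else -np.inf
        t.log_w = delta_h
        t.sum_accept = min(1.0, np.exp(delta_h)) if np.isfinite(delta_h) else 0.0
        t.n_leapfrog = 1
        t.divergent = delta_h < -_MAX_DELTA_H
        t.turning = False
        return t

    inner = _build_tree(logp_grad, q, p, grad, depth - 1, direction, eps, inv_mass, h0, rng)
    if inner.divergent or inner.turning:
        return inner
    if direction == 1:
        q_e, p_e, g_e = inner.q_plus, inner.p_plus, inner.g_plus
    else:
        q_e, p_e, g_e = inner.q_minus, inner.p_minus, inner.g_minus
    outer = _build_tree(logp_grad, q_e, p_e, g_e, depth - 1, direction, eps, inv_mass, h0, rng)

    t = _Tree()
    if direction == 1:
        t.q_minus, t.p_minus, t.g_minus = inner.q_minus, inner.p_minus, inner.g_minus
        t.q_plus, t.p_plus, t.g_plus = outer.q_plus, outer.p_plus, outer.g_plus
    else:
        t.q_minus, t.p_minus, t.g_minus = outer.q_minus, outer.p_minus, outer.g_minus
        t.q_plus, t.p_plus, t.g_plus = inner.q_plus, inner.p_plus, inner.g_plus
    t.log_w = np.logaddexp(inner.log_w, outer.log_w)
    t.sum_accept = inner.sum_accept + outer.sum_accept
    t.n_leapfrog = inner.n_leapfrog + outer.n_leapfrog
    t.divergent = outer.divergent
    dq = t.q_plus - t.q_minus
    t.turning = (outer.turning
                 or np.dot(dq, inv_mass * t.p_minus) < 0
                 or np.dot(dq, inv_mass * t.p_plus) < 0)
    # multinomial choice between subtrees
    if (not t.divergent and not t.turning
            and np.log(rng.random()) < outer.log_w - t.log_w):
        t.q_prop = outer.q_prop
    else:
        t.q_prop = inner.q_prop
    return t


def _nuts_step(logp_grad, q, lp, grad, eps, inv_mass, max_depth, rng):
    p0 = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * np.sum(p0 * p0 * inv_mass)
    q_minus = q_plus = q
    p_minus = p_plus = p0
    g_minus = g_plus = grad
    q_curr = q
    log_w = 0.0  # weight of the initial point relative to exp(h0)
    sum_accept = 0.0
    n_leapfrog = 0
    divergent = False
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(logp_grad, q_plus, p_plus, g_plus, depth, 1,
                              eps, inv_mass, h0, rng)
            q_plus, p_plus, g_plus = sub.q_plus, sub.p_plus, sub.g_plus
        else:
            sub = _build_tree(logp_grad, q_minus, p_minus, g_minus, depth, -1,
                              eps, inv_mass, h0, rng)
            q_minus, p_minus, g_minus = sub.q_minus, sub.p_minus, sub.g_minus
        sum_accept += sub.sum_accept
        n_leapfrog += sub.n_leapfrog
        if sub.divergent:
            divergent = True
            break
        if sub.turning:
            break
        # biased progressive sampling towards the new subtree
        if np.log(rng.random()) < sub.log_w - log_w:
            q_curr = sub.q_prop
        log_w = np.logaddexp(log_w, sub.log_w)
        dq = q_plus - q_minus
        if (np.dot(dq, inv_mass * p_minus) < 0
                or np.dot(dq, inv_mass * p_plus) < 0):
            break
        depth += 1
    accept_stat = sum_accept / max(n_leapfrog, 1)
    return q_curr, depth, accept_stat, divergent


def sample_nuts(
    logp_grad,
    q0,
    n_warmup: int,
    n_draws: int,
    rng,
    max_treedepth: int = 10,
    target_accept: float = 0.8,
    adapt_mass: bool = True,
):
    """Run one NUTS chain; returns (draws, NUTSStats).

    ``draws`` has shape (n_draws, dim) and excludes warmup.  Mass-matrix
    adaptation uses expanding covariance-estimation windows inside
    warmup, bracketed by step-size-only phases.
    """
    rng = np.random.default_rng(rng)
    q = np.asarray(q0, dtype=float).copy()
    dim = q.shape[0]
    # trees are capped low while the step size is still far from tuned
    # (the opening fast phase), where deep doublings buy nothing
    fast_treedepth = min(6, max_treedepth)
    inv_mass = np.ones(dim)
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_eps(logp_grad, q, inv_mass, rng)
    da = _DualAveraging(eps, target=target_accept)

    # warmup windows (Stan-like): fast, expanding slow, fast
    fast1 = min(75, int(0.15 * n_warmup))
    fast2 = min(50, int(0.1 * n_warmup))
    slow_start, slow_end = fast1, n_warmup - fast2
    window_ends = []
    if adapt_mass and slow_end - slow_start >= 20:
        w = 25
        pos = slow_start
        while True:
            end = pos + w
            if end + 2 * w > slow_end:
                end = slow_end
                window_ends.append(end)
                break
            window_ends.append(end)
            pos = end
            w *= 2
    welford = _Welford(dim)

    draws = np.empty((n_draws, dim))
    accept_stats = np.empty(n_draws)
    depths = np.empty(n_draws, dtype=int)
    n_div = 0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        depth_cap = fast_treedepth if (warming and it < fast1) else max_treedepth
        q, depth, accept_stat, divergent = _nuts_step(
            logp_grad, q, lp, grad, eps, inv_mass, depth_cap, rng
        )
        lp, grad = logp_grad(q)
        if warming:
            da.update(accept_stat)
            eps = da.eps
            if window_ends and slow_start <= it < slow_end:
                welford.add(q)
                if it + 1 == window_ends[0]:
                    n = welford.n
                    var = welford.variance()
                    inv_mass = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                    inv_mass = np.maximum(inv_mass, 1e-10)
                    welford = _Welford(dim)
                    window_ends.pop(0)
                    eps = _find_reasonable_eps(logp_grad, q, inv_mass, rng)
                    da = _DualAveraging(eps, target=target_accept)
            if it + 1 == n_warmup:
                eps = da.eps_final
        else:
            j = it - n_warmup
            draws[j] = q
            accept_stats[j] = accept_stat
            depths[j] = depth
            if divergent:
                n_div += 1

    stats = NUTSStats(
        accept_stat=accept_stats,
        step_size=eps,
        n_divergent=n_div,
        tree_depth=depths,
    )
    return draws, stats
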