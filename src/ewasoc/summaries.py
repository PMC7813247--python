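"""Posterior summaries: HPDI, convergence diagnostics, payoff correlations."""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .environment import ConfigurationError, DataError

RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 1000.0


def hpdi(draws, mass: float = 0.89):
    """Narrowest contiguous interval containing ``mass`` of the draws.

    Sliding-window over the sorted sample: the interval spans
    ``ceil(mass * n)`` consecutive order statistics; ties in width are
    broken towards the lowest lower bound.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 2:
        raise DataError("hpdi needs at least 2 draws")
    if not 0.0 < mass < 1.0:
        raise DataError("mass must lie in (0, 1)")
    s = np.sort(draws)
    n = s.size
    k = int(np.ceil(mass * n))
    widths = s[k - 1:] - s[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first (lowest) minimizer
    return float(s[i]), float(s[i + k - 1])


def diagnostics(draws_by_chain) -> pd.DataFrame:
    """Split R-hat and effective sample size per quantity.

    ``draws_by_chain`` maps quantity names to (chains, draws) arrays.
    Returns a frame with pass/fail flags against the conventional
    thresholds (R-hat <= 1.01, ESS > 1000).
    """
    rows = []
    for name, arr in draws_by_chain.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2:
            raise DataError(f"{name}: expected (chains, draws), got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise ConfigurationError("split R-hat requires at least 2 chains")
        ds = az.convert_to_dataset(arr)
        rhat = float(az.rhat(ds)["x"].values)
        ess = float(az.ess(ds)["x"].values)
        rows.append(dict(
            quantity=name, rhat=rhat, ess=ess,
            rhat_ok=bool(rhat <= RHAT_THRESHOLD),
            ess_ok=bool(ess > ESS_THRESHOLD),
        ))
    return pd.DataFrame(rows)


def payoff_correlations(param_draws, payoffs, mass: float = 0.89) -> pd.DataFrame:
    """Cross-individual correlation between parameters and payoff totals.

    ``param_draws`` is (n_draws, n_individuals, n_params); for each
    posterior draw the Pearson correlation across individuals between
    each parameter and the per-individual payoff statistic is computed,
    then summarized by mean and HPDI.  Zero-variance inputs yield an
    absent (NaN) correlation.
    """
    param_draws = np.asarray(param_draws, dtype=float)
    payoffs = np.asarray(payoffs, dtype=float)
    if param_draws.ndim != 3:
        raise DataError("param_draws must be (draws, individuals, params)")
    n_ind = param_draws.shape[1]
    if n_ind < 3 or payoffs.shape[0] != n_ind:
        raise DataError("need one payoff per individual and at least 3 individuals")
    pay_c = payoffs - payoffs.mean()
    pay_ss = float(pay_c @ pay_c)
    rows = []
    for p in range(param_draws.shape[2]):
        x = param_draws[:, :, p]
        xc = x - x.mean(axis=1, keepdims=True)
        xss = np.einsum("di,di->d", xc, xc)
        if pay_ss <= 0.0 or np.all(xss <= 0.0):
            rows.append(dict(param=p, mean=np.nan, hpdi_low=np.nan, hpdi_high=np.nan))
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ pay_c) / np.sqrt(xss * pay_ss)
        r = r[np.isfinite(r)]
        if r.size < 2:
            rows.append(dict(param=p, mean=np.nan, hpdi_low=np.nan, hpdi_high=np.nan))
            continue
        lo, hi = hpdi(r, mass)
        rows.append(dict(param=p, mean=float(r.mean()), hpdi_low=lo, hpdi_high=hi))
    return pd.DataFrame(rows)


@dataclass
class PosteriorResult:
    """Draws, summaries and diagnostics of one hierarchical fit.

    ``draws`` maps quantity names to arrays with leading (chain, draw)
    axes.  ``summary`` mirrors the columns of the baseline results
    table: posterior mean, 89% HPDI, and (for learning parameters) the
    across-individual s.d. of varying effects with its HPDI.
    ``indiv_draws`` is (chain, draw, n_individuals, 6) on natural
    scales, used for payoff correlations.
    """

    kind: str
    draws: dict
    summary: pd.DataFrame
    diagnostics_table: pd.DataFrame
    indiv_draws: np.ndarray
    ids: np.ndarray
    payoff_totals: np.ndarray
    entries: list = field(default_factory=list)  # (param index, role) per varying effect
    sampler_stats: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics_table["rhat_ok"].all())

    def flat(self, name: str) -> np.ndarray:
        """Draws of a quantity with chain/draw axes flattened."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def payoff_correlations(self, payoff_stat=None, mass: float = 0.89) -> pd.DataFrame:
        """Table-1-style correlations between parameters and overall success.

        By default the per-individual payoff totals are used; pass
        ``payoff_stat`` (one value per individual, e.g. a geometric mean
        of per-round payoffs) for the multiplicative-fitness variant.
        """
        from .transforms import PARAM_NAMES
        pay = self.payoff_totals if payoff_stat is None else np.asarray(payoff_stat)
        flat = self.indiv_draws.reshape(-1, *self.indiv_draws.shape[2:])
        tab = payoff_correlations(flat, pay, mass=mass)
        tab["param"] = [PARAM_NAMES[p] for p in tab["param"]]
        return tab
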