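"""Model fitting: NUTS over the hierarchical EWA posteriors."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .likelihood import PackedData, pack_data
from .models import HierarchicalEWA, ModelConfig
from .nuts import sample_nuts
from .summaries import PosteriorResult, diagnostics, hpdi
from .transforms import PARAM_NAMES

log = logging.getLogger(__name__)


def fit_model(data, config: ModelConfig) -> PosteriorResult:
    """Fit a hierarchical EWA model by NUTS and summarize the posterior.

    ``data`` is a long-format observations DataFrame (or an already
    packed dataset).  Chains run sequentially with seeds fanned out from
    ``config.seed``.  Non-convergence (R-hat above 1.01 for any
    population-level quantity, or divergent transitions) is reported in
    ``result.warnings`` and ``result.converged`` — never silently
    dropped.
    """
    packed = data if isinstance(data, PackedData) else pack_data(data)
    model = HierarchicalEWA(packed, config)
    ss = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    chain_rngs = [np.random.default_rng(c) for c in ss.spawn(config.chains)]

    qdraws = np.empty((config.chains, config.iterations, model.dim))
    stats = []
    for c, rng in enumerate(chain_rngs):
        q0 = model.initial_point(rng)
        log.info("chain %d/%d: %d warmup + %d draws, dim=%d",
                 c + 1, config.chains, config.warmup, config.iterations, model.dim)
        qdraws[c], st = sample_nuts(
            model.logp_and_grad, q0, config.warmup, config.iterations, rng,
            max_treedepth=config.max_treedepth, target_accept=config.target_accept,
        )
        stats.append(st)

    # unpack every draw into constrained quantities
    first = model.unpack(qdraws[0, 0])
    draws = {}
    for name, val in first.items():
        shape = np.shape(val)
        draws[name] = np.empty((config.chains, config.iterations) + shape)
    for c in range(config.chains):
        for d in range(config.iterations):
            for name, val in model.unpack(qdraws[c, d]).items():
                draws[name][c, d] = val

    # population-level scalar quantities for diagnostics
    diag_quants = {}
    for name, arr in draws.items():
        if arr.ndim == 2:  # scalar per draw
            diag_quants[name] = arr
    for e in range(model.Pv):
        diag_quants[f"tau[{e}]"] = draws["tau"][:, :, e]
    diag = diagnostics(diag_quants)

    summary_rows = []
    for name, arr in draws.items():
        if arr.ndim == 2:
            flat = arr.reshape(-1)
            lo, hi = hpdi(flat)
            summary_rows.append(dict(quantity=name, mean=float(flat.mean()),
                                     hpdi_low=lo, hpdi_high=hi))
    for e, (p, role) in enumerate(model.entries):
        flat = draws["tau"][:, :, e].reshape(-1)
        lo, hi = hpdi(flat)
        suffix = "" if role == "const" else f"_{role}"
        summary_rows.append(dict(quantity=f"{PARAM_NAMES[p]}{suffix}_sd_indiv",
                                 mean=float(flat.mean()), hpdi_low=lo, hpdi_high=hi))
    summary = pd.DataFrame(summary_rows)

    warnings = []
    n_div = sum(st.n_divergent for st in stats)
    if n_div:
        warnings.append(f"{n_div} divergent transitions after warmup")
    bad = diag.loc[~diag["rhat_ok"], "quantity"].tolist()
    if bad:
        warnings.append(f"R-hat above 1.01 for: {', '.join(bad)}")
    low_ess = diag.loc[~diag["ess_ok"], "quantity"].tolist()
    if low_ess:
        warnings.append(f"ESS at or below 1000 for: {', '.join(low_ess)}")
    for w in warnings:
        log.warning("%s", w)

    return PosteriorResult(
        kind=config.kind,
        draws=draws,
        summary=summary,
        diagnostics_table=diag,
        indiv_draws=draws["indiv"],
        ids=packed.ids,
        payoff_totals=packed.payoff_totals,
        entries=list(model.entries),
        sampler_stats=stats,
        warnings=warnings,
    )


def table1(result: PosteriorResult, mass: float = 0.89) -> pd.DataFrame:
    """Baseline-results table: posterior means, HPDIs, varying-effect s.d.s
    and correlations with overall payoffs, one row per learning parameter."""
    corr = result.payoff_correlations(mass=mass).set_index("param")
    rows = []
    for p, name in enumerate(PARAM_NAMES):
        mean_name = f"{name}_mean" if f"{name}_mean" in result.draws else f"{name}_tmin"
        flat = result.flat(mean_name)
        lo, hi = hpdi(flat, mass)
        tau_flat = result.flat("tau")[:, p] if result.flat("tau").shape[1] == 6 else None
        row = dict(parameter=name, post_mean=float(flat.mean()),
                   hpdi_low=lo, hpdi_high=hi)
        if tau_flat is not None:
            tlo, thi = hpdi(tau_flat, mass)
            row.update(sd_indiv=float(tau_flat.mean()), sd_hpdi_low=tlo, sd_hpdi_high=thi)
        row.update(
            corr_payoff=float(corr.loc[name, "mean"]),
            corr_hpdi_low=float(corr.loc[name, "hpdi_low"]),
            corr_hpdi_high=float(corr.loc[name, "hpdi_high"]),
        )
        rows.append(row)
    return pd.DataFrame(rows)
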