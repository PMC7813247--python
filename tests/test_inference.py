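"""Posterior summaries, diagnostics, and model-structure checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ewasoc import (
    ConfigurationError,
    DataError,
    ExperimentConfig,
    LearningParams,
    diagnostics,
    hpdi,
    payoff_correlations,
    simulate_session,
)
from ewasoc.likelihood import pack_data
from ewasoc.models import HierarchicalEWA, ModelConfig
from ewasoc.nuts import sample_nuts
from ewasoc.transforms import PARAM_NAMES, PARAM_TRANSFORMS, to_natural


class TestHPDI:
    def test_constant_draws_zero_width(self):
        lo, hi = hpdi(np.full(100, 3.2))
        assert lo == hi == 3.2

    def test_standard_normal_interval(self):
        rng = np.random.default_rng(0)
        lo, hi = hpdi(rng.standard_normal(1_000_000), 0.89)
        z = stats.norm.ppf(0.945)  # symmetric 89% interval of the normal
        # the narrowest-window estimator jitters by ~n^(-1/3) around +-z
        assert lo == pytest.approx(-z, abs=0.04)
        assert hi == pytest.approx(z, abs=0.04)

    def test_uniform_width(self):
        rng = np.random.default_rng(1)
        lo, hi = hpdi(rng.uniform(0, 1, 500_000), 0.89)
        assert hi - lo == pytest.approx(0.89, abs=0.01)

    def test_matches_arviz_on_skewed_sample(self):
        import arviz as az
        rng = np.random.default_rng(2)
        draws = rng.gamma(2.0, 1.0, 20_000)
        lo, hi = hpdi(draws, 0.89)
        ref = az.hdi(draws, hdi_prob=0.89)
        assert lo == pytest.approx(float(ref[0]), abs=0.02)
        assert hi == pytest.approx(float(ref[1]), abs=0.02)

    def test_errors(self):
        with pytest.raises(DataError):
            hpdi(np.array([1.0]))
        with pytest.raises(DataError):
            hpdi(np.arange(10), mass=1.5)


class TestDiagnostics:
    def test_identical_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        arr = rng.standard_normal((4, 2000))
        d = diagnostics({"x": arr})
        assert d.loc[0, "rhat"] == pytest.approx(1.0, abs=0.01)
        assert d.loc[0, "rhat_ok"] and d.loc[0, "ess_ok"]

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        arr = rng.standard_normal((2, 500)) + np.array([[0.0], [10.0]])
        d = diagnostics({"x": arr})
        assert d.loc[0, "rhat"] > 1.5
        assert not d.loc[0, "rhat_ok"]

    def test_single_chain_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            diagnostics({"x": np.random.default_rng(0).standard_normal((1, 100))})

    def test_ar1_ess_matches_analytic_rate(self):
        """For an AR(1) chain with coefficient a, ESS/n -> (1-a)/(1+a)."""
        a = 0.6
        rng = np.random.default_rng(3)
        n, chains = 5000, 4
        arr = np.empty((chains, n))
        for c in range(chains):
            x = 0.0
            eps = rng.standard_normal(n + 200)
            xs = []
            for t in range(n + 200):
                x = a * x + eps[t]
                xs.append(x)
            arr[c] = xs[200:]
        d = diagnostics({"x": arr})
        expected = chains * n * (1 - a) / (1 + a)
        assert d.loc[0, "ess"] == pytest.approx(expected, rel=0.25)


class TestPayoffCorrelations:
    def test_recovers_generating_correlation(self):
        rng = np.random.default_rng(0)
        n_ind, n_draws = 120, 400
        pay = rng.normal(1500, 120, n_ind)
        r_true = 0.6
        z = (pay - pay.mean()) / pay.std()
        draws = np.empty((n_draws, n_ind, 1))
        for d in range(n_draws):
            draws[d, :, 0] = r_true * z + np.sqrt(1 - r_true**2) * rng.standard_normal(n_ind)
        tab = payoff_correlations(draws, pay)
        assert tab.loc[0, "mean"] == pytest.approx(r_true, abs=0.08)

    def test_degenerate_inputs_reported_absent(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((50, 10, 1))
        tab = payoff_correlations(draws, np.full(10, 7.0))
        assert np.isnan(tab.loc[0, "mean"])
        flat = np.ones((50, 10, 1))
        tab = payoff_correlations(flat, rng.normal(size=10))
        assert np.isnan(tab.loc[0, "mean"])

    def test_too_few_individuals(self):
        with pytest.raises(DataError):
            payoff_correlations(np.ones((10, 2, 1)), np.array([1.0, 2.0]))


class TestModelStructure:
    def test_contrast_reduces_to_baseline_without_windows(self, one_session):
        """With every window flag off and zero offsets, the contrast model's
        posterior density equals the baseline model's."""
        df = one_session.copy()
        df["spatial_window"] = False
        df["temporal_window"] = False
        packed = pack_data(df)
        base = HierarchicalEWA(packed, ModelConfig(kind="baseline"))
        cont = HierarchicalEWA(packed, ModelConfig(kind="contrast"))
        rng = np.random.default_rng(0)
        q = base.initial_point(rng) + 0.1 * rng.standard_normal(base.dim)
        q_ext = np.zeros(cont.dim)
        q_ext[: base.dim] = q  # shared layout prefix; offsets stay zero
        lp_b, _ = base.logp_and_grad(q)
        lp_c, _ = cont.logp_and_grad(q_ext)
        assert lp_c == pytest.approx(lp_b, rel=1e-12)

    def test_unknown_model_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(kind="mystery")

    def test_prior_predictive_choices_are_option_symmetric(self):
        """Simulating from prior-mean parameter draws favours no option id."""
        rng = np.random.default_rng(7)
        cfg = ExperimentConfig()
        counts = np.zeros(4)
        for rep in range(8):
            trans = rng.normal(0.0, 1.0, 6)
            nat = [float(to_natural(v, k)) for v, k in zip(trans, PARAM_TRANSFORMS)]
            agents = [LearningParams(*nat)] * 8
            from ewasoc import build_migration_schedule, build_phase_schedule
            sched = build_phase_schedule(cfg, seed=int(rng.integers(2**31)))
            mig = build_migration_schedule(cfg)
            df = simulate_session(cfg, sched, mig, agents,
                                  seed=int(rng.integers(2**31)))
            counts += np.bincount(df["choice"] - 1, minlength=4)
        freq = counts / counts.sum()
        assert np.abs(freq - 0.25).max() < 0.1


class TestFitSmoke:
    """Tiny end-to-end fits of every model kind (sampling quality not at
    stake here, only that the pipeline runs and reports coherently)."""

    @pytest.fixture(scope="class")
    def tiny_obs(self):
        from ewasoc import PopulationSpec, simulate_sessions
        from ewasoc.simulate import RECOVERY_BASE_MEANS
        cfg = ExperimentConfig(n_rounds=20, n_phases=4, phase_length=5)
        spec = PopulationSpec.from_natural(RECOVERY_BASE_MEANS,
                                           sds=np.full(6, 0.2))
        obs, _ = simulate_sessions(cfg, spec, 2, seed=31)
        return obs

    @pytest.mark.parametrize("kind,kw", [
        ("baseline", {}),
        ("contrast", {}),
        ("monotonic", dict(time_varying=("sigma",), n_lags=20)),
        ("gp", dict(time_varying=("sigma",), n_lags=20)),
    ])
    def test_fit_runs_and_reports(self, tiny_obs, kind, kw):
        from ewasoc.fit import fit_model
        cfg = ModelConfig(kind=kind, chains=2, iterations=30, warmup=30,
                          seed=9, max_treedepth=6, **kw)
        res = fit_model(tiny_obs, cfg)
        assert res.kind == kind
        assert {"quantity", "mean", "hpdi_low", "hpdi_high"} <= set(res.summary.columns)
        assert (res.summary["hpdi_low"] <= res.summary["hpdi_high"]).all()
        assert res.indiv_draws.shape == (2, 30, 16, 6)
        assert np.isfinite(res.indiv_draws).all()
        # every sampled population quantity carries diagnostics
        assert {"rhat", "ess"} <= set(res.diagnostics_table.columns)
        if kind == "contrast":
            assert "sigma_contrast" in res.draws
        if kind == "monotonic":
            assert res.draws["sigma_traj"].shape == (2, 30, 20)
            deltas = res.draws["sigma_delta"]
            np.testing.assert_allclose(deltas.sum(axis=-1), 1.0, atol=1e-9)
        if kind == "gp":
            assert res.draws["sigma_traj"].shape == (2, 30, 20)
            assert (res.draws["sigma_gp_hyp"] > 0).all()


class TestNUTS:
    def test_recovers_correlated_gaussian(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((5, 5))
        cov = A @ A.T + 5 * np.eye(5)
        prec = np.linalg.inv(cov)

        def lg(x):
            return float(-0.5 * x @ prec @ x), -prec @ x

        chains = []
        for _ in range(4):
            d, st = sample_nuts(lg, rng.standard_normal(5), 300, 500, rng)
            assert st.n_divergent == 0
            chains.append(d)
        d = np.stack(chains)
        flat = d.reshape(-1, 5)
        assert np.abs(flat.mean(axis=0)).max() < 0.15
        np.testing.assert_allclose(flat.var(axis=0), np.diag(cov), rtol=0.15)
        diag = diagnostics({f"q{i}": d[:, :, i] for i in range(5)})
        assert diag["rhat_ok"].all()
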