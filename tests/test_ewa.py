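"""Hand-checked values and invariants of the EWA learning rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewasoc import (
    DataError,
    GPSpec,
    MonotonicSpec,
    NoSocialInformation,
    SocialContext,
    asocial_probs,
    choice_probs,
    conformity_probs,
    experience_probs,
    gp_covariance,
    monotonic_trajectory,
    monotonic_value,
    social_probs,
    update_attractions,
)


def context(choices, experiences=None, cview=None, eview=None):
    choices = np.asarray(choices)
    n = len(choices)
    return SocialContext(
        choices=choices,
        experiences=np.ones(n, dtype=int) if experiences is None else np.asarray(experiences),
        choice_viewed=np.ones(n, dtype=bool) if cview is None else np.asarray(cview),
        experience_viewed=np.ones(n, dtype=bool) if eview is None else np.asarray(eview),
    )


class TestAttractionUpdate:
    def test_limits_and_hand_value(self):
        A = np.array([10.0, 1.0, 2.0, 3.0])
        np.testing.assert_array_equal(update_attractions(A, 0, 20.0, 0.0), A)
        assert update_attractions(A, 0, 20.0, 1.0)[0] == 20.0
        assert update_attractions(A, 0, 20.0, 0.5)[0] == 15.0

    def test_unchosen_options_unchanged(self):
        A = np.array([1.0, 2.0, 3.0, 4.0])
        out = update_attractions(A, 2, 100.0, 0.9)
        np.testing.assert_array_equal(out[[0, 1, 3]], A[[0, 1, 3]])


class TestAsocialProbs:
    def test_zero_lambda_is_uniform(self):
        np.testing.assert_allclose(
            asocial_probs([5.0, -3.0, 100.0, 0.0], 0.0), np.full(4, 0.25))

    def test_equal_attractions_uniform(self):
        np.testing.assert_allclose(asocial_probs([2.0] * 4, 3.7), np.full(4, 0.25))

    def test_hand_value(self):
        p = asocial_probs([1.0, 0.0, 0.0, 0.0], 1.0)
        e = np.e
        np.testing.assert_allclose(p, [e / (e + 3), 1 / (e + 3), 1 / (e + 3), 1 / (e + 3)])

    def test_large_scores_stable(self):
        p = asocial_probs([1000.0, 0.0, 0.0, 0.0], 50.0)
        assert np.isfinite(p).all() and abs(p[0] - 1.0) < 1e-12


class TestSocialProbs:
    def test_conformity_unanimity_and_hand_values(self):
        ctx = context([0, 0, 0])
        np.testing.assert_allclose(conformity_probs(ctx, 2.5), [1, 0, 0, 0])
        ctx = context([0, 0, 1])
        np.testing.assert_allclose(conformity_probs(ctx, 1.0), [2 / 3, 1 / 3, 0, 0])
        np.testing.assert_allclose(conformity_probs(ctx, 3.0), [8 / 9, 1 / 9, 0, 0])

    def test_conformity_needs_visible_choices(self):
        ctx = context([-1, -1, -1])
        with pytest.raises(NoSocialInformation):
            conformity_probs(ctx, 1.0)
        ctx = context([0, 1, 2], cview=[False, False, False])
        with pytest.raises(NoSocialInformation):
            experience_probs(ctx, 0.5)

    def test_experience_beta_zero_is_count_based(self):
        ctx = context([0, 0, 1], experiences=[20, 3, 1])
        np.testing.assert_allclose(experience_probs(ctx, 0.0), [2 / 3, 1 / 3, 0, 0])

    def test_experience_hand_value(self):
        # weights 2^2 = 4 and 2^1 = 2 under beta = ln 2
        ctx = context([0, 1], experiences=[2, 1])
        np.testing.assert_allclose(experience_probs(ctx, np.log(2.0)), [2 / 3, 1 / 3, 0, 0])

    def test_experience_strong_bias_limit(self):
        ctx = context([0, 0, 1], experiences=[20, 20, 1])
        p = experience_probs(ctx, 50.0)
        assert p[0] > 1 - 1e-12

    def test_unviewed_experience_boxes_degrade_to_counts(self):
        ctx = context([0, 0, 1], experiences=[20, 5, 1], eview=[False, False, False])
        np.testing.assert_allclose(experience_probs(ctx, 3.0), [2 / 3, 1 / 3, 0, 0])

    def test_mixtures(self):
        pc = np.array([1.0, 0, 0, 0])
        pe = np.array([0, 1.0, 0, 0])
        np.testing.assert_allclose(social_probs(pc, pe, 0.0), pc)
        np.testing.assert_allclose(social_probs(pc, pe, 1.0), pe)
        np.testing.assert_allclose(social_probs(pc, pe, 0.25), [0.75, 0.25, 0, 0])
        pa = np.full(4, 0.25)
        np.testing.assert_allclose(choice_probs(pa, pc, 0.0), pa)
        np.testing.assert_allclose(choice_probs(pa, pc, 1.0), pc)
        np.testing.assert_allclose(choice_probs(pa, None, 0.9), pa)

    @given(
        choices=st.lists(st.integers(-1, 3), min_size=1, max_size=3),
        f=st.floats(0.2, 5.0),
        beta=st.floats(-2.0, 2.0),
        kappa=st.floats(0.0, 1.0),
        sigma=st.floats(0.0, 1.0),
        lam=st.floats(0.0, 5.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_probability_vectors_are_simplex(self, choices, f, beta, kappa, sigma, lam):
        ctx = context(choices, experiences=[(c + 2) for c in choices])
        pa = asocial_probs([1.0, -2.0, 0.5, 3.0], lam)
        try:
            pc = conformity_probs(ctx, f)
            pe = experience_probs(ctx, beta)
            ps = social_probs(pc, pe, kappa)
        except NoSocialInformation:
            ps = None
        p = choice_probs(pa, ps, sigma)
        assert (p >= 0).all()
        assert abs(p.sum() - 1.0) < 1e-12

    @given(choices=st.lists(st.integers(0, 3), min_size=1, max_size=3),
           experiences=st.lists(st.integers(1, 20), min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_three_way_agreement_of_unbiased_rules(self, choices, experiences):
        """f = 1 conformity, beta = 0 experience weighting, and raw counts agree."""
        ctx = context(choices, experiences=experiences[: len(choices)])
        counts = ctx.counts()
        expected = counts / counts.sum()
        np.testing.assert_allclose(conformity_probs(ctx, 1.0), expected, atol=1e-12)
        np.testing.assert_allclose(experience_probs(ctx, 0.0), expected, atol=1e-12)


class TestMonotonicEffects:
    def test_endpoints(self):
        delta = np.concatenate([[0.0], np.full(19, 1 / 19)])
        spec = MonotonicSpec(2.0, -1.0, delta)
        assert monotonic_value(spec, 1) == pytest.approx(2.0)
        assert monotonic_value(spec, 20) == pytest.approx(-1.0)

    def test_uniform_steps_hand_value(self):
        delta = np.concatenate([[0.0], np.full(19, 1 / 19)])
        spec = MonotonicSpec(0.0, 1.0, delta)
        assert monotonic_value(spec, 11) == pytest.approx(10 / 19)

    def test_lag_out_of_range(self):
        spec = MonotonicSpec(0.0, 1.0, np.concatenate([[0.0], np.full(19, 1 / 19)]))
        with pytest.raises(DataError):
            monotonic_value(spec, 0)
        with pytest.raises(DataError):
            monotonic_value(spec, 21)

    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=19),
           st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_trajectory_is_weakly_monotone(self, raw, tmin, tmax):
        steps = np.asarray(raw) / np.sum(raw)
        spec = MonotonicSpec(tmin, tmax, np.concatenate([[0.0], steps]))
        traj = monotonic_trajectory(spec)
        diffs = np.diff(traj)
        assert (diffs >= -1e-12).all() or (diffs <= 1e-12).all()


class TestGPCovariance:
    def test_hand_values(self):
        spec = GPSpec(eta2=1.0, rho2=1.0, sigma2_same=0.5)
        K = gp_covariance([1, 2], spec)
        assert K[0, 0] == pytest.approx(1.5)
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_long_distance_decay(self):
        spec = GPSpec(eta2=2.0, rho2=0.5, sigma2_same=0.0)
        K = gp_covariance([1, 100], spec)
        assert K[0, 1] < 1e-12

    def test_matches_bruteforce_double_loop(self):
        lags = np.arange(1, 21)
        spec = GPSpec(eta2=0.7, rho2=0.12, sigma2_same=0.2)
        K = gp_covariance(lags, spec)
        brute = np.empty((20, 20))
        for i, x in enumerate(lags):
            for j, y in enumerate(lags):
                brute[i, j] = 0.7 * np.exp(-0.12 * (x - y) ** 2) + (0.2 if x == y else 0.0)
        np.testing.assert_allclose(K, brute, rtol=1e-12)
        assert np.all(np.linalg.eigvalsh(K + 1e-9 * np.eye(20)) > 0)
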