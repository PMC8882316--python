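"""Millen and Bayesianized Gail-Simon interaction probabilities.

Each probability is checked against an independent brute-force loop over
draws; the loops deliberately avoid the vectorized implementation path.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bayesenrich.interaction import (
    EmptyConditioningWarning,
    gail_simon_draws,
    millen_probability,
    quali_probability,
    quanti_probability,
)
from bayesenrich.posterior import SubsetArmCounts, sample_posterior

from conftest import draws_from_theta, make_draws


def brute_millen(theta_k, theta_t, eta):
    num = den = 0
    for tk, tt in zip(theta_k, theta_t):
        if tt >= tk:
            den += 1
            if tt / tk > eta:
                num += 1
    return num / den if den else 0.0


def brute_quali(beta, sigma, c1):
    hits = 0
    for row in beta:
        qm = sum((b / s) ** 2 for b, s in zip(row, sigma) if b < 0)
        qp = sum((b / s) ** 2 for b, s in zip(row, sigma) if b > 0)
        hits += min(qm, qp) > c1
    return hits / len(beta)


def brute_quanti(theta, theta_global, c2):
    hits = 0
    for row, tg in zip(theta, theta_global):
        hits += sum(t - tg for t in row) > c2
    return hits / len(theta)


class TestMillen:
    def test_identical_draws_eta_one(self):
        theta = np.tile(np.linspace(0.5, 1.5, 50), (2, 1)).T
        d = draws_from_theta(theta)
        p, frac = millen_probability(d, "A", "B", 1.0)
        assert p == 0.0 and frac == 1.0  # ratio exactly 1, never > 1

    def test_doubled_draws(self):
        base = np.linspace(0.4, 1.2, 40)
        d = draws_from_theta(np.column_stack([base, 2 * base]))
        p, frac = millen_probability(d, "A", "B", 1.5)
        assert p == 1.0 and frac == 1.0

    def test_matches_brute_force(self, rng):
        theta = rng.lognormal(0, 0.4, size=(500, 2))
        d = draws_from_theta(theta)
        for eta in (1.0, 1.1, 1.3, 2.0):
            p, _ = millen_probability(d, "A", "B", eta)
            assert p == brute_millen(theta[:, 0], theta[:, 1], eta)

    def test_monotone_in_eta(self, rng):
        d = draws_from_theta(rng.lognormal(0, 0.5, size=(400, 2)))
        etas = np.linspace(1.0, 2.5, 10)
        vals = [millen_probability(d, "A", "B", e)[0] for e in etas]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_label_exchange_conditioning(self, rng):
        theta = rng.lognormal(0, 0.3, size=(300, 2))
        d = draws_from_theta(theta)
        _, f_ab = millen_probability(d, "A", "B", 1.2)
        _, f_ba = millen_probability(d, "B", "A", 1.2)
        assert f_ab + f_ba >= 1.0  # ties counted in both conditioning events

    def test_empty_conditioning_warns_and_returns_zero(self):
        theta = np.column_stack([np.full(20, 2.0), np.full(20, 0.5)])
        d = draws_from_theta(theta)
        with pytest.warns(EmptyConditioningWarning):
            p, frac = millen_probability(d, "A", "B", 1.0)
        assert p == 0.0 and frac == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**20), eta=st.floats(1.0, 3.0))
    def test_brute_force_agreement_property(self, seed, eta):
        theta = np.random.default_rng(seed).lognormal(0, 0.5, size=(120, 2))
        d = draws_from_theta(theta)
        p, _ = millen_probability(d, "A", "B", eta)
        assert p == brute_millen(theta[:, 0], theta[:, 1], eta)

    def test_requires_two_subsets(self, rng):
        d = draws_from_theta(rng.lognormal(0, 0.3, size=(50, 3)))
        with pytest.raises(ValueError):
            millen_probability(d, "A", "B", 1.1)


class TestGailSimon:
    def test_all_negative_betas_zero_qplus(self):
        theta = np.full((30, 3), 0.5)  # log theta < 0 everywhere
        theta += np.linspace(0, 0.1, 30)[:, None]  # non-degenerate sd
        d = draws_from_theta(theta)
        gs = gail_simon_draws(d)
        assert np.all(gs.q_plus == 0)
        assert np.all(np.minimum(gs.q_minus, gs.q_plus) == 0)

    def test_sum_identity(self, rng):
        d = draws_from_theta(rng.lognormal(0, 0.5, size=(400, 3)))
        gs = gail_simon_draws(d)
        z2 = (gs.beta / gs.sigma) ** 2
        np.testing.assert_allclose(gs.q_minus + gs.q_plus, z2.sum(axis=1), rtol=1e-12)

    def test_degenerate_draws_rejected(self):
        d = draws_from_theta(np.ones((50, 2)))
        with pytest.raises(ValueError):
            gail_simon_draws(d)

    def test_plugin_sigma_mode(self, rng):
        counts = SubsetArmCounts(("A", "B"), np.array([[30, 25], [20, 28]]),
                                 np.array([[100, 90], [100, 95]]))
        d = sample_posterior(counts, n_draws=20_000, seed=14)
        gs_post = gail_simon_draws(d)
        gs_plug = gail_simon_draws(d, sigma_mode="plugin", counts=counts)
        # delta-method and posterior sd agree to first order at this n
        np.testing.assert_allclose(gs_plug.sigma, gs_post.sigma, rtol=0.15)
        zero_cell = SubsetArmCounts(("A", "B"), np.array([[0, 25], [20, 28]]),
                                    np.array([[100, 90], [100, 95]]))
        d0 = sample_posterior(zero_cell, n_draws=100, seed=15)
        with pytest.raises(ValueError):
            gail_simon_draws(d0, sigma_mode="plugin", counts=zero_cell)

    def test_quali_trivial_cases(self, rng):
        all_benefit = draws_from_theta(0.5 + 0.1 * rng.random((100, 2)))
        gs = gail_simon_draws(all_benefit)
        assert quali_probability(gs, 0.5) == 0.0
        mixed = draws_from_theta(
            np.column_stack([0.5 + 0.1 * rng.random(100), 1.5 + 0.1 * rng.random(100)])
        )
        assert quali_probability(gail_simon_draws(mixed), 0.0) == 1.0

    def test_quali_matches_brute_force(self, rng):
        d = draws_from_theta(rng.lognormal(0, 0.6, size=(300, 3)))
        gs = gail_simon_draws(d)
        for c1 in (0.2, 1.0, 2.5):
            assert quali_probability(gs, c1) == pytest.approx(
                brute_quali(gs.beta, gs.sigma, c1), abs=1e-12
            )

    def test_quali_monotone_in_c1(self, rng):
        gs = gail_simon_draws(draws_from_theta(rng.lognormal(0, 0.5, size=(300, 2))))
        vals = [quali_probability(gs, c) for c in np.linspace(0, 4, 9)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestQuanti:
    def test_low_cutoff_certain(self, rng):
        d = draws_from_theta(rng.lognormal(0, 0.3, size=(200, 2)))
        sums = d.theta.sum(axis=1) - 2 * d.theta_global
        assert quanti_probability(d, float(sums.min()) - 1.0) == 1.0

    def test_matches_brute_force(self, rng):
        theta = rng.lognormal(0, 0.4, size=(300, 3))
        d = draws_from_theta(theta, theta_global=rng.lognormal(0, 0.2, size=300))
        for c2 in (-0.5, 0.0, 0.2):
            assert quanti_probability(d, c2) == pytest.approx(
                brute_quanti(theta, d.theta_global, c2), abs=1e-12
            )

    def test_balanced_configuration_symmetric(self):
        # identical counts in every cell; pooled global built from the same
        # data: the per-draw sum of deviations is symmetric about ~0
        counts = SubsetArmCounts(("A", "B"), np.full((2, 2), 40), np.full((2, 2), 100))
        d = sample_posterior(counts, n_draws=100_000, seed=16)
        assert quanti_probability(d, 0.0) == pytest.approx(0.5, abs=0.02)

    def test_monotone_in_c2(self, rng):
        d = draws_from_theta(rng.lognormal(0, 0.4, size=(300, 2)))
        vals = [quanti_probability(d, c) for c in np.linspace(-1, 1, 9)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
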