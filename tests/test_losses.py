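"""Loss terms: closed forms, composition identities and the ELBO bound."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from cellmatch.losses import (LossBreakdown, batch_loss, bernoulli_recon_loss,
                              categorical_entropy, kl_standard_normal,
                              supervised_loss, unsupervised_loss)
from cellmatch.model import ModelConfig, SemiSupervisedVAE


class TestBernoulliRecon:
    def test_uniform_probabilities_give_two_log_two(self):
        assert bernoulli_recon_loss(np.array([1.0, 0.0]),
                                    np.array([0.5, 0.5])) \
            == pytest.approx(2 * np.log(2))

    def test_loss_vanishes_as_p_approaches_binary_x(self):
        x = np.array([1.0, 0.0, 1.0])
        p = np.array([1 - 1e-9, 1e-9, 1 - 1e-9])
        assert bernoulli_recon_loss(x, p) < 1e-7

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=6),
           st.lists(st.floats(0.01, 0.99), min_size=6, max_size=6))
    def test_nonnegative_for_binary_x(self, xs, ps):
        x = np.array(xs, dtype=float)
        p = np.array(ps[:len(xs)])
        assert bernoulli_recon_loss(x, p) >= 0.0


class TestKL:
    def test_prior_equals_posterior_gives_zero(self):
        assert kl_standard_normal(np.zeros(3), np.ones(3)) == pytest.approx(0)

    def test_unit_mean_shift_gives_half(self):
        assert kl_standard_normal(np.array([1.0]), np.array([1.0])) \
            == pytest.approx(0.5)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=4),
           st.lists(st.floats(0.1, 3), min_size=4, max_size=4))
    def test_nonnegative(self, mus, sigmas):
        mu = np.array(mus)
        sigma = np.array(sigmas[:len(mus)])
        assert kl_standard_normal(mu, sigma) >= -1e-12

    def test_matches_monte_carlo_estimate(self):
        # KL = E_q[log q(z) - log p(z)] estimated with 1e5 draws
        rng = np.random.default_rng(6)
        for _ in range(5):
            d = int(rng.integers(1, 4))
            mu = rng.uniform(-1, 1, d)
            sigma = rng.uniform(0.5, 1.5, d)
            z = mu + sigma * rng.standard_normal((100_000, d))
            log_q = (-0.5 * ((z - mu) / sigma) ** 2
                     - np.log(sigma) - 0.5 * np.log(2 * np.pi)).sum(axis=1)
            log_p = (-0.5 * z ** 2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
            mc = (log_q - log_p).mean()
            assert kl_standard_normal(mu, sigma) == pytest.approx(mc,
                                                                  abs=0.02)


class TestEntropy:
    def test_one_hot_gives_zero(self):
        assert categorical_entropy(np.array([0.0, 1.0, 0.0])) == 0.0

    def test_uniform_over_four_gives_log_four(self):
        assert categorical_entropy(np.full(4, 0.25)) \
            == pytest.approx(np.log(4))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_bounded_by_log_h(self, raw):
        pi = np.array(raw) / np.sum(raw)
        assert -1e-12 <= categorical_entropy(pi) <= np.log(len(pi)) + 1e-12


@pytest.fixture
def small_model():
    return SemiSupervisedVAE(ModelConfig(n_features=6, n_subtypes=3,
                                         encoder_hidden=(5,), seed=7))


class TestCompositeLosses:
    def test_unsupervised_matches_manual_composition(self, small_model, rng):
        x = rng.random(6)
        u = unsupervised_loss(x, small_model, np.random.default_rng(5))
        mu, sigma = small_model.encode(x)
        z = small_model.reparameterize(mu, sigma, np.random.default_rng(5))
        manual = (bernoulli_recon_loss(np.atleast_2d(x),
                                       small_model.decode(z)).sum()
                  + kl_standard_normal(mu, sigma).sum()
                  + categorical_entropy(small_model.classify(z)).sum())
        assert u.total == pytest.approx(manual, abs=1e-12)

    def test_supervised_minus_unsupervised_is_classification_term(
            self, small_model, rng):
        # S(x,y) - U(x) = -ln pi_y(z) under a shared latent draw
        x = rng.random(6)
        for y in range(3):
            u = unsupervised_loss(x, small_model, np.random.default_rng(8))
            s = supervised_loss(x, y, small_model, np.random.default_rng(8))
            mu, sigma = small_model.encode(x)
            z = small_model.reparameterize(mu, sigma,
                                           np.random.default_rng(8))
            expected = -np.log(small_model.classify(z)[0, y])
            assert s.total - u.total == pytest.approx(expected, abs=1e-6)
            assert s.cls >= 0.0

    def test_label_out_of_range_rejected(self, small_model, rng):
        with pytest.raises(ValueError, match="label"):
            supervised_loss(rng.random(6), 3, small_model,
                            np.random.default_rng(0))

    def test_breakdown_total_is_sum_of_terms(self):
        bd = LossBreakdown(recon=1.0, kl=0.5, entropy=0.25, cls=2.0)
        assert bd.total == 3.75


class TestBatchLoss:
    def test_empty_cell_batch_reduces_to_supervised(self, small_model, rng):
        X = rng.random((3, 6))
        y = np.array([0, 1, 2])
        total, bd = batch_loss(None, X, y, small_model,
                               np.random.default_rng(2))
        s = supervised_loss(X, y, small_model, np.random.default_rng(2))
        assert total == pytest.approx(s.total)

    def test_single_labelled_sample(self, small_model, rng):
        x = rng.random((1, 6))
        total, _ = batch_loss(None, x, [1], small_model,
                              np.random.default_rng(3))
        s = supervised_loss(x, [1], small_model, np.random.default_rng(3))
        assert total == pytest.approx(s.total)

    def test_both_empty_rejected(self, small_model):
        with pytest.raises(ValueError, match="empty"):
            batch_loss(None, None, None, small_model,
                       np.random.default_rng(0))

    def test_additive_over_concatenation(self, small_model, rng):
        # per-sample draws make the summed loss additive over a batch split
        X = rng.random((4, 6))
        rng_a = np.random.default_rng(9)
        full = unsupervised_loss(X, small_model, rng_a).total
        rng_b = np.random.default_rng(9)
        parts = (unsupervised_loss(X[:2], small_model, rng_b).total
                 + unsupervised_loss(X[2:], small_model, rng_b).total)
        assert full == pytest.approx(parts, abs=1e-9)


def test_negative_unsupervised_loss_is_evidence_lower_bound(small_model, rng):
    """-U(x) + H = L(x) must not exceed log p(x) (importance-sampling oracle)."""
    x = rng.random(6)
    mu, sigma = small_model.encode(x)
    mu, sigma = mu[0], sigma[0]
    K = 10_000
    z = mu + sigma * np.random.default_rng(10).standard_normal((K, len(mu)))
    p = small_model.decode(z)
    log_px_z = (x * np.log(p) + (1 - x) * np.log1p(-p)).sum(axis=1)
    log_pz = (-0.5 * z ** 2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
    log_qz = (-0.5 * ((z - mu) / sigma) ** 2 - np.log(sigma)
              - 0.5 * np.log(2 * np.pi)).sum(axis=1)
    log_px = logsumexp(log_px_z + log_pz - log_qz) - np.log(K)
    # the expected ELBO: E_q[log p(x|z)] (Monte Carlo) minus closed-form KL
    elbo = log_px_z.mean() - kl_standard_normal(mu, sigma)
    assert elbo <= log_px + 0.02
    # and a single-draw U is built from the same three terms
    u = unsupervised_loss(x, small_model, np.random.default_rng(11))
    assert np.isfinite(u.total) and u.kl >= 0
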