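"""Evidential losses against closed forms, quadrature and Monte Carlo."""

import numpy as np
import pytest
from scipy import integrate, special, stats

from trustomics import objective
from trustomics.nn import Tensor


class TestEvidentialCe:
    @pytest.mark.parametrize("alpha, y, expected", [
        # digamma recurrence psi(x + 1) = psi(x) + 1/x:
        ((2.0, 1.0), (1, 0), 0.5),       # psi(3) - psi(2) = 1/2
        ((1.0, 1.0), (1, 0), 1.0),       # psi(2) - psi(1) = 1
    ])
    def test_digamma_recurrence_values(self, alpha, y, expected):
        out = objective.evidential_ce(np.array(alpha), np.array(y))
        assert out == pytest.approx(expected, abs=1e-12)

    def test_limit_vanishes_with_overwhelming_evidence(self):
        big = objective.evidential_ce(np.array([1e8, 1.0]), np.array([1, 0]))
        assert 0 <= big < 1e-6

    def test_quadrature_oracle_binary(self):
        """Matches the exact expectation E_Dir[-log p_true] by integration."""
        for a, b in [(2.0, 1.0), (3.5, 1.2), (1.1, 4.0)]:
            exact, _ = integrate.quad(
                lambda p: -np.log(p) * stats.beta.pdf(p, a, b), 0, 1)
            ours = objective.evidential_ce(np.array([a, b]), np.array([1, 0]))
            assert ours == pytest.approx(exact, abs=1e-4)

    def test_monte_carlo_oracle_three_classes(self):
        rng = np.random.default_rng(0)
        alpha = np.array([2.5, 1.3, 4.0])
        samples = rng.dirichlet(alpha, size=2_000_000)
        mc = -np.log(samples[:, 1]).mean()
        ours = objective.evidential_ce(alpha, np.array([0, 1, 0]))
        assert ours == pytest.approx(mc, abs=1e-2)

    def test_non_one_hot_rejected(self):
        with pytest.raises(ValueError):
            objective.evidential_ce(np.array([2.0, 1.0]),
                                    np.array([0.5, 0.5]))


class TestAdjustedAlpha:
    @pytest.mark.parametrize("alpha, y, expected", [
        ((5.0, 2.0), (1, 0), (1.0, 2.0)),
        ((1.0, 1.0), (1, 0), (1.0, 1.0)),
        ((4.0, 3.0, 2.0), (0, 1, 0), (4.0, 1.0, 2.0)),
    ])
    def test_true_class_reset_to_one(self, alpha, y, expected):
        out = objective.adjusted_alpha(np.array(alpha), np.array(y))
        np.testing.assert_allclose(out, expected)


class TestKlToUniform:
    def test_uniform_is_zero(self):
        assert objective.kl_to_uniform(np.ones(3)) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_closed_form_example(self):
        # ln 2 + psi(2) - psi(3) = 0.6931 - 0.5 = 0.1931
        out = objective.kl_to_uniform(np.array([1.0, 2.0]))
        assert out == pytest.approx(np.log(2) - 0.5, abs=1e-12)
        assert out == pytest.approx(0.1931, abs=1e-4)

    def test_quadrature_oracle_binary(self):
        a, b = 1.7, 3.2
        kl_num, _ = integrate.quad(
            lambda p: stats.beta.pdf(p, a, b)
            * np.log(stats.beta.pdf(p, a, b)), 1e-12, 1 - 1e-12)
        out = objective.kl_to_uniform(np.array([a, b]))
        assert out == pytest.approx(kl_num, abs=1e-4)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(1)
        alpha = np.array([1.5, 2.5, 0.8])
        samples = rng.dirichlet(alpha, size=1_000_000)
        log_pdf = (special.gammaln(alpha.sum())
                   - special.gammaln(alpha).sum()
                   + ((alpha - 1) * np.log(samples)).sum(axis=1))
        log_uniform = special.gammaln(3.0)
        mc = (log_pdf - log_uniform).mean()
        assert objective.kl_to_uniform(alpha) == pytest.approx(mc, abs=1e-2)

    def test_non_negative(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            alpha = rng.uniform(0.2, 8.0, size=4)
            assert objective.kl_to_uniform(alpha) >= -1e-12


class TestSampleLoss:
    def test_lambda_zero_is_pure_ce(self):
        alpha, y = np.array([3.0, 2.0]), np.array([1, 0])
        assert objective.sample_loss(alpha, y, 0.0) == pytest.approx(
            objective.evidential_ce(alpha, y))

    def test_composed_example(self):
        # adjusted alpha (1, 1) has zero KL, so loss = psi(3) - psi(2) = 0.5
        out = objective.sample_loss(np.array([2.0, 1.0]), np.array([1, 0]),
                                    1.0)
        assert out == pytest.approx(0.5, abs=1e-12)

    def test_kl_term_is_strictly_additive(self):
        alpha, y = np.array([5.0, 2.0]), np.array([1, 0])
        assert objective.sample_loss(alpha, y, 1.0) > \
            objective.sample_loss(alpha, y, 0.0)

    def test_gradient_of_true_class_evidence_is_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            e = rng.uniform(0.5, 5.0, size=3)
            y = np.array([1, 0, 0])
            t = Tensor(e, requires_grad=True)
            objective.sample_loss(t + 1.0, y, 0.5).backward()
            assert t.grad[0] < 0


class TestLambdaSchedule:
    @pytest.mark.parametrize("epoch, expected", [
        (0, 0.0), (25, 0.5), (50, 1.0), (500, 1.0)])
    def test_linear_warmup(self, epoch, expected):
        assert objective.lambda_schedule(epoch, 50) == pytest.approx(expected)


class TestGlobalLoss:
    def setup_method(self):
        rng = np.random.default_rng(4)
        self.k = 3
        self.labels = np.array([0, 1, 2, 0])
        self.fused = rng.uniform(1.0, 4.0, size=(4, self.k))
        self.per_omics = [rng.uniform(1.0, 4.0, size=(4, self.k))
                          for _ in range(2)]
        self.logits = [rng.standard_normal((4, self.k)) for _ in range(2)]

    def test_breakdown_resums_to_total(self):
        cfg = objective.LossConfig(n_classes=self.k, gamma=1.0)
        bd = objective.global_loss(self.fused, self.per_omics, self.logits,
                                   self.labels, cfg, epoch=10)
        resum = (bd.fused_loss + sum(bd.per_omics_losses)
                 + bd.gamma * sum(bd.gat_ce))
        assert bd.total == pytest.approx(resum, abs=1e-9)
        assert all(v >= 0 for v in
                   [bd.fused_loss, *bd.per_omics_losses, *bd.gat_ce])

    def test_gamma_zero_drops_gat_terms(self):
        cfg = objective.LossConfig(n_classes=self.k, gamma=0.0)
        bd = objective.global_loss(self.fused, self.per_omics, self.logits,
                                   self.labels, cfg, epoch=10)
        assert bd.total == pytest.approx(bd.fused_loss
                                         + sum(bd.per_omics_losses))

    def test_single_modality_degeneracy(self):
        cfg = objective.LossConfig(n_classes=self.k, gamma=1.0)
        bd = objective.global_loss(self.fused, [self.fused],
                                   [self.logits[0]], self.labels, cfg,
                                   epoch=10)
        assert bd.total == pytest.approx(2 * bd.fused_loss + bd.gat_ce[0])

    def test_tensor_path_matches_numpy_path(self):
        cfg = objective.LossConfig(n_classes=self.k)
        bd_np = objective.global_loss(self.fused, self.per_omics,
                                      self.logits, self.labels, cfg, epoch=5)
        bd_t = objective.global_loss(
            Tensor(self.fused), [Tensor(a) for a in self.per_omics],
            [Tensor(lg) for lg in self.logits], self.labels, cfg, epoch=5)
        assert bd_t.total == pytest.approx(bd_np.total, abs=1e-12)
        assert bd_t.node is not None
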