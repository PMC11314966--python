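"""Objectives, latent-parameter updates, and the training loop."""

import numpy as np
import pytest

from protogan import autodiff as ad
from protogan.model import LatentGMM, init_latent_gmm, sample_latent
from protogan.training import (
    TrainConfig,
    adversarial_loss,
    discriminator_loss,
    gradient_penalty,
    latent_gradients,
    project_simplex_with_floor,
    total_objective,
    train,
    u2c_loss,
    u2c_loss_per_sample,
    update_latent_parameters,
)


def u2c_double_loop(e, assignments, mu):
    """Independent double-loop evaluation of the contrastive loss."""
    e, mu = np.asarray(e, float), np.asarray(mu, float)
    ks = np.asarray(assignments) - 1
    B = e.shape[0]
    losses = []
    for i in range(B):
        def cos(i_, j_):
            a = e[i_]
            b = mu[ks[j_]]
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

        denom = np.mean([np.exp(cos(i, j)) for j in range(B)])
        losses.append(-np.log(np.exp(cos(i, i)) / denom))
    return float(np.mean(losses))


class TestGradientPenalty:
    def test_constant_critic_gives_lambda1(self, rng):
        critic = lambda x: x.sum(axis=(1, 2, 3)) * 0.0 + 3.0
        x = rng.normal(size=(4, 5, 5, 3)).astype(np.float32)
        gp = gradient_penalty(critic, x, x[::-1].copy(), lambda1=10.0, seed=rng)
        assert gp.item() == pytest.approx(10.0, rel=1e-4)

    def test_unit_norm_linear_critic_gives_zero(self, rng):
        d = 5 * 5 * 3
        w = np.full((1, 5, 5, 3), 1.0 / np.sqrt(d), dtype=np.float32)
        critic = lambda x: (x * w).sum(axis=(1, 2, 3))
        x = rng.normal(size=(4, 5, 5, 3)).astype(np.float32)
        gp = gradient_penalty(critic, x, x[::-1].copy(), lambda1=10.0, seed=rng)
        assert gp.item() == pytest.approx(0.0, abs=1e-6)

    def test_analytic_norm_of_scaled_sum_critic(self, rng):
        critic = lambda x: (x * 2.0).sum(axis=(1, 2, 3))
        x = rng.normal(size=(3, 4, 4, 3)).astype(np.float32)
        d = 4 * 4 * 3
        expected = 10.0 * (2.0 * np.sqrt(d) - 1.0) ** 2
        gp = gradient_penalty(critic, x, x[::-1].copy(), lambda1=10.0, seed=rng)
        assert gp.item() == pytest.approx(expected, rel=1e-5)

    def test_shape_mismatch_rejected(self, rng):
        critic = lambda x: x.sum(axis=(1, 2, 3))
        with pytest.raises(ValueError, match="mismatch"):
            gradient_penalty(critic, np.zeros((2, 4, 4, 3)),
                             np.zeros((3, 4, 4, 3)))


class TestDiscriminatorLoss:
    def test_zero_critic_reduces_to_penalty(self, tiny_bundle, tiny_gmm, rng):
        # zero out the critic head: D(x) = 0 everywhere
        saved = tiny_bundle.D.fc.W.data.copy(), tiny_bundle.D.fc.b.data.copy()
        tiny_bundle.D.fc.W.data = np.zeros_like(saved[0])
        tiny_bundle.D.fc.b.data = np.zeros_like(saved[1])
        try:
            x = rng.normal(size=(4, 16, 16, 3)).astype(np.float32) * 0.5
            z = sample_latent(tiny_gmm, 4, seed=0)
            loss = discriminator_loss(tiny_bundle, x, z, lambda1=10.0, seed=rng)
            assert loss.item() == pytest.approx(10.0, rel=1e-4)
        finally:
            tiny_bundle.D.fc.W.data, tiny_bundle.D.fc.b.data = saved

    @staticmethod
    def _stub_bundle(real_scores, fake_scores):
        """Identity generator plus a critic replaying fixed scores."""
        from types import SimpleNamespace

        scores = [np.asarray(real_scores, float), np.asarray(fake_scores, float)]

        def D(x):
            return ad.tensor(scores.pop(0))

        return SimpleNamespace(G=lambda z: z, D=D)

    def test_two_sample_hand_arithmetic(self):
        stub = self._stub_bundle([3.0, -1.0], [0.5, 0.5])
        x = np.zeros((2, 2, 2, 3), dtype=np.float32)
        loss = discriminator_loss(stub, x, np.zeros((2, 2, 2, 3)), lambda1=0.0)
        assert loss.item() == pytest.approx(-1.0 + 0.5)

    def test_raising_real_scores_lowers_loss(self):
        x = np.zeros((2, 2, 2, 3), dtype=np.float32)
        z = np.zeros((2, 2, 2, 3))
        base = discriminator_loss(
            self._stub_bundle([1.0, 1.0], [0.0, 0.0]), x, z, lambda1=0.0
        ).item()
        raised = discriminator_loss(
            self._stub_bundle([3.0, 3.0], [0.0, 0.0]), x, z, lambda1=0.0
        ).item()
        assert raised == pytest.approx(base - 2.0)

    def test_adversarial_loss_sign(self, tiny_bundle, rng):
        z = rng.normal(size=(3, 8))
        la = adversarial_loss(tiny_bundle, z)
        with ad.no_grad():
            d = tiny_bundle.D(tiny_bundle.G(ad.Tensor(z.astype(np.float32)))).data
        assert np.allclose(la.data, -d, atol=1e-6)


class TestU2C:
    def test_single_sample_is_zero(self, rng):
        gmm = init_latent_gmm(3, dz=4, seed=0)
        e = rng.normal(size=(1, 4))
        assert u2c_loss(e, [2], gmm).item() == pytest.approx(0.0, abs=1e-12)

    def test_orthonormal_prototypes_closed_form(self):
        mu = np.eye(4)[:2]
        gmm = LatentGMM(np.array([0.5, 0.5]), mu, np.ones((2, 4)))
        e = mu.copy()  # e_i = mu_{K_i}
        expected = np.log((np.e + 1.0) / 2.0) - 1.0
        assert u2c_loss(e, [1, 2], gmm).item() == pytest.approx(expected, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        gmm = init_latent_gmm(4, dz=8, seed=1)
        for _ in range(10):
            e = rng.normal(size=(4, 8))
            ks = rng.integers(1, 5, size=4)
            assert u2c_loss(e, ks, gmm).item() == pytest.approx(
                u2c_double_loop(e, ks, gmm.mu), abs=1e-6
            )

    def test_invariant_to_positive_rescaling(self, rng):
        gmm = init_latent_gmm(3, dz=6, seed=2)
        e = rng.normal(size=(5, 6))
        ks = rng.integers(1, 4, size=5)
        a = u2c_loss(e, ks, gmm).item()
        b = u2c_loss(37.5 * e, ks, gmm).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_zero_norm_rejected(self):
        gmm = init_latent_gmm(2, dz=3, seed=0)
        with pytest.raises(ValueError, match="zero-norm"):
            u2c_loss(np.zeros((2, 3)), [1, 2], gmm)


class TestTotalObjective:
    def test_lambda2_zero_equals_mean_adversarial(self, tiny_bundle, tiny_gmm,
                                                  rng):
        z = sample_latent(tiny_gmm, 4, seed=0)
        tot = total_objective(tiny_bundle, tiny_gmm, z, lambda2=0.0)
        adv = adversarial_loss(tiny_bundle, z.z)
        assert tot.item() == pytest.approx(float(np.mean(adv.data)), abs=1e-6)

    def test_decomposes_into_adv_plus_u2c(self, tiny_bundle, tiny_gmm):
        tiny_bundle.eval()  # frozen normalization so both paths coincide
        z = sample_latent(tiny_gmm, 3, seed=1)
        tot = total_objective(tiny_bundle, tiny_gmm, z, lambda2=1.0)
        tot0 = total_objective(tiny_bundle, tiny_gmm, z, lambda2=0.0)
        from protogan.model import assign_component, encode, generate

        e = encode(tiny_bundle, generate(tiny_bundle, z.z))
        ks = assign_component(z.z, tiny_gmm)
        u2c = u2c_loss(e, ks, tiny_gmm).item()
        assert tot.item() == pytest.approx(tot0.item() + u2c, abs=1e-5)


class TestLatentUpdates:
    @staticmethod
    def toy_objective(targets, eps_grid):
        """Deterministic expected loss of a frozen dz=2 toy.

        L = sum_k p_k * mean_m || mu_k + sqrt(sigma_k) eps_m - t_k ||^2,
        an exact expectation over a frozen noise grid.
        """

        def objective(gmm):
            total = None
            for k in range(targets.shape[0]):
                mu_k = ad.take_rows(gmm.mu, [k])
                sig_k = ad.take_rows(gmm.sigma, [k])
                p_k = ad.take_rows(gmm.p, [k]).reshape((1, 1))
                z = mu_k + ad.sqrt(sig_k) * eps_grid
                d = z - targets[k]
                term = (p_k * (d * d)).sum() / eps_grid.shape[0]
                total = term if total is None else total + term
            return total.reshape(())

        return objective

    def test_mu_gradient_matches_central_finite_differences(self, rng):
        targets = rng.normal(size=(2, 2))
        eps_grid = rng.normal(size=(16, 2))
        objective = self.toy_objective(targets, eps_grid)
        gmm = init_latent_gmm(2, dz=2, seed=0)
        _, (g_p, g_mu, g_sig) = latent_gradients(gmm, objective)

        h = 1e-5
        for k in range(2):
            for d in range(2):
                gp = gmm.copy()
                gp.mu[k, d] += h
                gm = gmm.copy()
                gm.mu[k, d] -= h
                fd = (objective(gp).item() - objective(gm).item()) / (2 * h)
                assert abs(g_mu[k, d] - fd) <= 0.05 * max(abs(fd), 1e-8)

    def test_p_and_sigma_gradients_match_finite_differences(self, rng):
        targets = rng.normal(size=(2, 2))
        eps_grid = rng.normal(size=(16, 2))
        objective = self.toy_objective(targets, eps_grid)
        gmm = init_latent_gmm(2, dz=2, seed=3)
        _, (g_p, g_mu, g_sig) = latent_gradients(gmm, objective)
        h = 1e-5
        for k in range(2):
            gp = gmm.copy()
            gp.p = gp.p.copy()
            gp.p[k] += h
            gm = gmm.copy()
            gm.p = gm.p.copy()
            gm.p[k] -= h
            fd = (objective(gp).item() - objective(gm).item()) / (2 * h)
            assert g_p[k] == pytest.approx(fd, rel=1e-4)
            gp2 = gmm.copy()
            gp2.sigma[k, 0] += h
            gm2 = gmm.copy()
            gm2.sigma[k, 0] -= h
            fd2 = (objective(gp2).item() - objective(gm2).item()) / (2 * h)
            assert g_sig[k, 0] == pytest.approx(fd2, rel=1e-3)

    def test_zero_gradient_leaves_gmm_unchanged(self):
        gmm = init_latent_gmm(3, dz=2, seed=1)
        out = update_latent_parameters(gmm, lambda g: (g.mu * 0.0).sum(), 0.004)
        assert np.allclose(out.p, gmm.p)
        assert np.allclose(out.mu, gmm.mu)
        assert np.allclose(out.sigma, gmm.sigma)

    def test_invariants_hold_after_many_random_updates(self, rng):
        gmm = init_latent_gmm(3, dz=2, seed=2)
        for _ in range(300):
            w = rng.normal(size=3)
            v = rng.normal(size=(3, 2))

            def objective(g, w=w, v=v):
                return (g.p * w).sum() + (g.mu * v).sum() + (
                    g.sigma * rng.normal(size=(3, 2))
                ).sum()

            gmm = update_latent_parameters(gmm, objective, gamma=0.05)
            assert abs(gmm.p.sum() - 1.0) < 1e-9
            assert np.all(gmm.p >= 1e-4 - 1e-12)
            assert np.all(gmm.sigma > 0)

    def test_prototype_learning_decreases_frozen_objective(self, rng):
        targets = rng.normal(size=(3, 2)) * 3.0

        def objective(g):
            d = g.mu - targets
            return (d * d).sum() / 3.0  # no p or sigma dependence

        gmm = init_latent_gmm(3, dz=2, seed=4)
        values = [objective(gmm).item()]
        for _ in range(50):
            gmm = update_latent_parameters(gmm, objective, gamma=0.004)
            values.append(objective(gmm).item())
        assert values[-1] < values[0]
        assert np.allclose(gmm.p, 1 / 3)  # p untouched by this objective
        assert np.allclose(gmm.sigma, 1.0)

    def test_non_finite_objective_aborts(self):
        gmm = init_latent_gmm(2, dz=2, seed=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            update_latent_parameters(gmm, lambda g: (g.p * np.nan).sum(), 0.004)

    def test_simplex_projection_with_floor(self, rng):
        for _ in range(100):
            v = rng.normal(size=4) * 3
            p = project_simplex_with_floor(v, floor=1e-4)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 1e-4 - 1e-15)
        # a valid point projects to itself
        p0 = np.array([0.5, 0.3, 0.2])
        assert np.allclose(project_simplex_with_floor(p0), p0)


class TestTrainConfig:
    def test_paper_rates(self):
        cfg = TrainConfig()
        assert cfg.eta == 1e-4
        assert cfg.lr_discriminator == pytest.approx(4e-4)
        assert cfg.gamma == 0.004
        assert cfg.lr_mu == pytest.approx(0.04)
        assert cfg.lambda1 == 10.0 and cfg.lambda2 == 1.0
        assert cfg.B == 64 and cfg.iterations == 18000 and cfg.b_D == 5

    def test_from_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("eta: 0.0002\ngamma: 0.01\nB: 8\niterations: 5\n")
        cfg = TrainConfig.from_file(path)
        assert cfg.eta == 2e-4 and cfg.B == 8 and cfg.iterations == 5

    def test_invalid_batch_rejected(self):
        with pytest.raises(ValueError, match="batch"):
            TrainConfig(B=1)


class TestTrainLoop:
    def test_short_run_keeps_invariants_and_logs(self, small_scalograms,
                                                 tmp_path):
        cfg = TrainConfig(B=4, b_D=1, iterations=6, seed=0)
        bundle, gmm, report = train(
            small_scalograms, cfg, n_components=2, image_size=16,
            width_scale=0.125, log_every=2,
        )
        gmm.validate()
        assert np.all(np.isfinite(report.to_dataframe().to_numpy()[:, :5].astype(float)))
        csv = tmp_path / "losses.csv"
        report.save_csv(csv)
        header = csv.read_text().splitlines()[0]
        assert header.startswith("step,d_loss,adv,u2c,total,p1")

    def test_dataset_smaller_than_batch_rejected(self, small_scalograms):
        cfg = TrainConfig(B=512, iterations=1, seed=0)
        with pytest.raises(ValueError, match="smaller"):
            train(small_scalograms, cfg, image_size=16)
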