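"""Mixture prior, component assignment, and network geometry."""

import numpy as np
import pytest

from protogan.model import (
    GanBundle,
    LatentGMM,
    assign_component,
    build_networks,
    deep_feature_map,
    encode,
    generate,
    init_latent_gmm,
    load_checkpoint,
    log_component_posteriors,
    sample_latent,
    save_checkpoint,
)


class TestLatentGMM:
    def test_uniform_init(self):
        gmm = init_latent_gmm(3, dz=100, seed=0)
        assert np.allclose(gmm.p, 1 / 3)
        assert np.allclose(gmm.sigma, 1.0)
        assert gmm.mu.shape == (3, 100)

    def test_seeded_determinism(self):
        a = init_latent_gmm(4, dz=10, seed=42)
        b = init_latent_gmm(4, dz=10, seed=42)
        assert np.array_equal(a.mu, b.mu)

    def test_single_component_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            init_latent_gmm(1, dz=10, seed=0)

    def test_invariants_validated(self):
        with pytest.raises(ValueError, match="sum"):
            LatentGMM(np.array([0.6, 0.6]), np.zeros((2, 2)),
                      np.ones((2, 2))).validate()
        with pytest.raises(ValueError, match="positive"):
            LatentGMM(np.array([0.5, 0.5]), np.zeros((2, 2)),
                      np.zeros((2, 2))).validate()


class TestSampling:
    def test_degenerate_mixture_uses_single_component(self):
        gmm = LatentGMM(np.array([1.0 - 1e-4, 1e-4]),
                        np.zeros((2, 3)), np.ones((2, 3)))
        batch = sample_latent(gmm, 200, seed=0)
        assert np.sum(batch.component == 1) >= 195

    def test_single_component_mean_clt_bound(self):
        mu = np.array([[2.0, -1.0, 0.5]])
        gmm = LatentGMM(np.array([0.9998, 0.0002]),
                        np.vstack([mu, mu * 100]), np.ones((2, 3)))
        batch = sample_latent(gmm, 10_000, seed=1)
        sel = batch.z[batch.component == 1]
        assert np.all(np.abs(sel.mean(axis=0) - mu[0]) < 4 / np.sqrt(len(sel)))

    def test_component_frequencies_within_multinomial_bounds(self):
        p = np.array([0.4, 0.4, 0.2])
        gmm = LatentGMM(p, np.zeros((3, 2)), np.ones((3, 2)))
        B = 10_000
        batch = sample_latent(gmm, B, seed=2)
        freq = np.bincount(batch.component - 1, minlength=3) / B
        bound = 3 * np.sqrt(p * (1 - p) / B)
        assert np.all(np.abs(freq - p) < bound)


class TestAssignment:
    def test_nearest_mean_wins_under_symmetry(self):
        gmm = LatentGMM(np.array([0.5, 0.5]),
                        np.array([[-2.0, 0.0], [2.0, 0.0]]), np.ones((2, 2)))
        assert assign_component(np.array([-1.9, 0.0]), gmm) == 1

    def test_prior_breaks_equidistant_tie(self):
        gmm = LatentGMM(np.array([0.9, 0.1]),
                        np.array([[-1.0, 0.0], [1.0, 0.0]]), np.ones((2, 2)))
        assert assign_component(np.array([0.0, 0.0]), gmm) == 1

    def test_hand_computed_log_densities(self):
        # N=2, mu1=(0,0), mu2=(3,0), p=(0.2,0.8), Sigma=I, z=(1.2,0)
        gmm = LatentGMM(np.array([0.2, 0.8]),
                        np.array([[0.0, 0.0], [3.0, 0.0]]), np.ones((2, 2)))
        z = np.array([1.2, 0.0])
        log1 = np.log(0.2) - 0.5 * (1.2**2) - np.log(2 * np.pi)
        log2 = np.log(0.8) - 0.5 * (1.8**2) - np.log(2 * np.pi)
        expected = 1 if log1 > log2 else 2
        assert assign_component(z, gmm) == expected
        got = log_component_posteriors(z, gmm)[0]
        assert got[0] == pytest.approx(log1)
        assert got[1] == pytest.approx(log2)

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        for _ in range(1000):
            N, dz = int(rng.integers(2, 6)), int(rng.integers(1, 5))
            p = rng.dirichlet(np.ones(N)) * (1 - N * 1e-4) + 1e-4
            gmm = LatentGMM(p, rng.normal(size=(N, dz)),
                            rng.uniform(0.2, 3.0, (N, dz)))
            z = rng.normal(size=dz)
            dens = [
                p[k]
                * np.prod(
                    np.exp(-0.5 * (z - gmm.mu[k]) ** 2 / gmm.sigma[k])
                    / np.sqrt(2 * np.pi * gmm.sigma[k])
                )
                for k in range(N)
            ]
            assert assign_component(z, gmm) == int(np.argmax(dens)) + 1

    def test_sampling_recovers_component_at_high_separation(self):
        # prototypes 10 standard deviations apart
        mu = np.zeros((3, 8))
        mu[1, 0], mu[2, 1] = 10.0, 10.0
        gmm = LatentGMM(np.full(3, 1 / 3), mu, np.ones((3, 8)))
        batch = sample_latent(gmm, 2000, seed=3)
        recovered = assign_component(batch.z, gmm)
        assert np.mean(recovered == batch.component) >= 0.99


class TestNetworks:
    def test_full_scale_layer_map(self):
        bundle = build_networks(image_size=64, dz=100, width_scale=1.0, seed=0)
        assert bundle.D.fc.W.shape == (8192, 1)  # flatten width 8192
        x = generate(bundle, np.zeros((2, 100)))
        assert x.shape == (2, 64, 64, 3)
        e = encode(bundle, x)
        assert e.shape == (2, 100)
        dfm = deep_feature_map(bundle, x)
        assert dfm.shape == (2, 8192)  # 4*4*512

    def test_generated_values_inside_unit_range(self, tiny_bundle, rng):
        x = generate(tiny_bundle, rng.normal(size=(4, 8)))
        assert np.all(np.abs(x) < 1.0)

    def test_inference_is_deterministic(self, tiny_bundle, rng):
        z = rng.normal(size=(3, 8))
        assert np.array_equal(generate(tiny_bundle, z), generate(tiny_bundle, z))
        x = rng.normal(size=(3, 16, 16, 3)).astype(np.float32) * 0.5
        assert np.array_equal(encode(tiny_bundle, x), encode(tiny_bundle, x))
        assert np.array_equal(
            deep_feature_map(tiny_bundle, x), deep_feature_map(tiny_bundle, x)
        )

    def test_batch_order_preserved(self, tiny_bundle, rng):
        z = rng.normal(size=(4, 8))
        full = generate(tiny_bundle, z)
        for i in range(4):
            assert np.allclose(generate(tiny_bundle, z[i : i + 1])[0], full[i],
                               atol=1e-6)

    def test_unsupported_size_rejected(self):
        with pytest.raises(ValueError, match="image size"):
            build_networks(image_size=48)

    def test_dimension_mismatch_rejected(self, tiny_bundle):
        with pytest.raises(ValueError, match="latent dimension"):
            generate(tiny_bundle, np.zeros((2, 9)))
        with pytest.raises(ValueError, match="images"):
            encode(tiny_bundle, np.zeros((2, 8, 8, 3)))

    def test_baseline_scalogram_is_generated_from_prototype(
        self, tiny_bundle, tiny_gmm
    ):
        baselines = generate(tiny_bundle, tiny_gmm.mu)
        dfms = deep_feature_map(tiny_bundle, baselines)
        assert baselines.shape == (3, 16, 16, 3)
        assert np.array_equal(
            dfms[1], deep_feature_map(tiny_bundle, generate(tiny_bundle,
                                                            tiny_gmm.mu[1]))[0]
        )


class TestCheckpoint:
    def test_round_trip_reproduces_inference(self, tmp_path, tiny_bundle,
                                             tiny_gmm, rng):
        path = tmp_path / "model.npz"
        save_checkpoint(path, tiny_bundle, tiny_gmm)
        bundle2, gmm2 = load_checkpoint(path)
        z = rng.normal(size=(3, 8))
        assert np.array_equal(generate(tiny_bundle, z), generate(bundle2, z))
        x = generate(tiny_bundle, z)
        assert np.array_equal(encode(tiny_bundle, x), encode(bundle2, x))
        assert np.array_equal(gmm2.p, tiny_gmm.p)
        assert np.array_equal(gmm2.mu, tiny_gmm.mu)
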