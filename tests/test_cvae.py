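import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import methgen as mg
from methgen.cvae import CVAEError, ModelIOError

from .oracles import kl_quadrature


class TestKL:
    def test_prior_gives_zero(self):
        q = mg.GaussianPosterior(np.zeros(5), np.zeros(5))
        assert mg.kl_gaussian_vs_standard_normal(q) == 0.0

    def test_unit_mean_closed_form(self):
        q = mg.GaussianPosterior(np.array([1.0]), np.array([0.0]))
        assert mg.kl_gaussian_vs_standard_normal(q) == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-3, max_value=3),
                st.floats(min_value=-3, max_value=3),
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_matches_quadrature(self, pairs):
        mu = np.array([p[0] for p in pairs])
        lv = np.array([p[1] for p in pairs])
        closed = mg.kl_gaussian_vs_standard_normal(mg.GaussianPosterior(mu, lv))
        assert closed >= 0.0
        assert closed == pytest.approx(kl_quadrature(mu, lv), abs=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(CVAEError):
            mg.GaussianPosterior(np.array([np.inf]), np.array([0.0]))


class TestElboLoss:
    def test_half_probabilities_give_n_ln2(self):
        n = 7
        x = np.full(n, 0.5)
        q = mg.GaussianPosterior(np.zeros(3), np.zeros(3))
        total, recon, kl = mg.elbo_loss(x, x, q)
        assert kl == 0.0
        assert recon == pytest.approx(n * np.log(2.0))
        assert total == pytest.approx(recon + kl)

    def test_mse_perfect_reconstruction(self):
        x = np.array([0.2, 0.8])
        q = mg.GaussianPosterior(np.array([1.0]), np.array([0.5]))
        total, recon, kl = mg.elbo_loss(x, x, q, reconstruction_loss="mse")
        assert recon == 0.0
        assert kl == mg.kl_gaussian_vs_standard_normal(q)

    def test_shape_mismatch(self):
        q = mg.GaussianPosterior(np.zeros(2), np.zeros(2))
        with pytest.raises(CVAEError, match="shape"):
            mg.elbo_loss(np.zeros(3), np.zeros(4), q)


class TestReparameterize:
    def test_zero_variance_returns_mean(self):
        q = mg.GaussianPosterior(np.array([2.0, -1.0]), np.full(2, -745.0))
        z = mg.reparameterize(q, np.random.default_rng(0))
        np.testing.assert_allclose(z.z, q.mu)

    def test_seeded_draws_identical(self):
        q = mg.GaussianPosterior(np.zeros(4), np.zeros(4))
        z1 = mg.reparameterize(q, np.random.default_rng(42))
        z2 = mg.reparameterize(q, np.random.default_rng(42))
        np.testing.assert_array_equal(z1.z, z2.z)

    def test_sample_mean_concentrates_on_mu(self):
        mu = np.array([0.3, -0.7])
        lv = np.array([0.2, -0.5])
        q = mg.GaussianPosterior(mu, lv)
        rng = np.random.default_rng(1)
        draws = np.stack([mg.reparameterize(q, rng).z for _ in range(10000)])
        sd = np.exp(0.5 * lv)
        assert (np.abs(draws.mean(axis=0) - mu) < 4 * sd / np.sqrt(10000)).all()


class TestEncodeDecode:
    def test_posterior_lengths_match_latent_dim(self, trained_small_cvae):
        st_ = trained_small_cvae
        x = np.full(len(st_.chunk_cpg_ids[0]), 0.5)
        q = mg.encode(x, st_.vocabulary[0], st_)
        assert q.mu.shape == (st_.config.latent_dim,)
        assert q.logvar.shape == (st_.config.latent_dim,)

    def test_encode_deterministic(self, trained_small_cvae):
        st_ = trained_small_cvae
        x = np.linspace(0.1, 0.9, len(st_.chunk_cpg_ids[0]))
        q1 = mg.encode(x, st_.vocabulary[0], st_)
        q2 = mg.encode(x, st_.vocabulary[0], st_)
        np.testing.assert_array_equal(q1.mu, q2.mu)

    def test_condition_shifts_posterior(self, trained_small_cvae, separable_fixture):
        st_ = trained_small_cvae
        matrix, labels, _ = separable_fixture
        x = matrix.values[0]
        qa = mg.encode(x, st_.vocabulary[0], st_)
        qb = mg.encode(x, st_.vocabulary[1], st_)
        assert not np.allclose(qa.mu, qb.mu)

    def test_unknown_condition_lists_vocabulary(self, trained_small_cvae):
        with pytest.raises(CVAEError, match="vocabulary"):
            mg.encode(np.full(20, 0.5), "NOPE", trained_small_cvae)

    def test_decode_output_open_interval(self, trained_small_cvae):
        st_ = trained_small_cvae
        z = np.full(st_.config.latent_dim, 50.0)  # extreme latent
        out = mg.decode(z, st_.vocabulary[0], st_)
        assert out.shape == (len(st_.chunk_cpg_ids[0]),)
        assert (out > 0).all() and (out < 1).all()

    def test_decoder_mirrors_encoder_widths(self):
        cfg = mg.CVAEConfig(encoder_hidden=(500, 250))
        assert cfg.decoder_layers == (250, 500)
        assert cfg.decoder_activations == tuple(reversed(cfg.activation_plan))


class TestTraining:
    def test_paper_defaults(self):
        cfg = mg.CVAEConfig()
        assert cfg.encoder_hidden == (500, 250)
        assert cfg.latent_dim == 125
        assert cfg.learning_rate == 1e-3
        assert cfg.epochs == 10000

    def test_loss_decreases(self, trained_small_cvae):
        trace = trained_small_cvae.loss_traces[0]
        assert trace[-1] < trace[0]

    def test_training_deterministic(self, separable_fixture):
        matrix, labels, _ = separable_fixture
        chunked = mg.chunk_cpgs(matrix, chunk_size=1000)
        cfg = mg.CVAEConfig(
            encoder_hidden=(8, 4), latent_dim=2, epochs=20, batch_size=30, seed=7
        )
        s1 = mg.train_cvae(chunked, labels, cfg)
        s2 = mg.train_cvae(chunked, labels, cfg)
        for k1, k2 in zip(s1.weights, s2.weights):
            for name in k1:
                np.testing.assert_array_equal(k1[name], k2[name])
        assert s1.loss_traces == s2.loss_traces

    def test_missing_values_rejected(self):
        vals = np.array([[0.5, np.nan], [0.2, 0.3]])
        m = mg.BetaMatrix(["s1", "s2"], ["cg1", "cg2"], vals)
        chunked = mg.chunk_cpgs(m, 10)
        lab = mg.ConditionVector(["A", "B"])
        with pytest.raises(CVAEError, match="preprocess"):
            mg.train_cvae(chunked, lab, mg.CVAEConfig(epochs=1))

    def test_absent_condition_warned(self):
        rng = np.random.default_rng(0)
        m = mg.BetaMatrix(
            ["s1", "s2", "s3"], ["cg1", "cg2"], rng.uniform(0.2, 0.8, (3, 2))
        )
        lab = mg.ConditionVector(["A", "A", "A"], vocabulary=["A", "B"])
        cfg = mg.CVAEConfig(encoder_hidden=(4,), activation_plan=("elu",),
                            latent_dim=2, epochs=2, batch_size=3)
        state = mg.train_cvae(mg.chunk_cpgs(m, 10), lab, cfg)
        assert any("'B'" in w for w in state.warnings)


class TestGeneration:
    def test_shape_and_ids(self, trained_small_cvae):
        st_ = trained_small_cvae
        out = mg.generate(st_, st_.vocabulary[0], 10, seed=3)
        assert out.values.shape == (10, len(st_.cpg_ids))
        assert out.sample_ids[0] == f"{st_.vocabulary[0]}_sim_0"

    def test_values_strictly_inside_unit_interval(self, trained_small_cvae):
        out = mg.generate(trained_small_cvae, trained_small_cvae.vocabulary[0],
                          20, seed=1)
        assert (out.values > 0).all() and (out.values < 1).all()

    def test_seeded_generation_bit_identical(self, trained_small_cvae):
        a = mg.generate(trained_small_cvae, trained_small_cvae.vocabulary[1],
                        5, seed=7)
        b = mg.generate(trained_small_cvae, trained_small_cvae.vocabulary[1],
                        5, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_conditional_means_recovered(self, trained_small_cvae,
                                         separable_fixture):
        """Generation under each condition tracks that condition's mean profile."""
        _, labels, truth = separable_fixture
        st_ = trained_small_cvae
        true_means = {}
        for cond in labels.vocabulary:
            p = truth.params_for(cond)
            true_means[cond] = (p["alpha"] / (p["alpha"] + p["beta"])).to_numpy()
        sep = np.abs(true_means[labels.vocabulary[0]]
                     - true_means[labels.vocabulary[1]])
        informative = sep >= 0.2
        for cond in labels.vocabulary:
            other = [c for c in labels.vocabulary if c != cond][0]
            gen = mg.generate(st_, cond, 100, seed=13)
            gmean = gen.values.mean(axis=0)
            closer = (np.abs(gmean - true_means[cond])
                      < np.abs(gmean - true_means[other]))
            assert closer[informative].mean() >= 0.9

    def test_unknown_condition(self, trained_small_cvae):
        with pytest.raises(CVAEError, match="vocabulary"):
            mg.generate(trained_small_cvae, "XXX", 3)


class TestSerialization:
    def test_roundtrip_generation_bit_identical(self, trained_small_cvae, tmp_path):
        mg.save_state(trained_small_cvae, tmp_path / "model")
        loaded = mg.load_state(tmp_path / "model")
        a = mg.generate(trained_small_cvae, trained_small_cvae.vocabulary[0],
                        8, seed=7)
        b = mg.generate(loaded, loaded.vocabulary[0], 8, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        assert loaded.vocabulary == trained_small_cvae.vocabulary
        assert loaded.chunk_cpg_ids == trained_small_cvae.chunk_cpg_ids

    def test_truncated_file_raises_corruption_error(self, trained_small_cvae,
                                                    tmp_path):
        mg.save_state(trained_small_cvae, tmp_path / "model")
        wpath = tmp_path / "model" / "weights.npz"
        wpath.write_bytes(wpath.read_bytes()[:40])
        with pytest.raises(ModelIOError, match="corrupt"):
            mg.load_state(tmp_path / "model")

    def test_version_mismatch(self, trained_small_cvae, tmp_path):
        import json
        mg.save_state(trained_small_cvae, tmp_path / "model")
        meta = json.loads((tmp_path / "model" / "meta.json").read_text())
        meta["version"] = 999
        (tmp_path / "model" / "meta.json").write_text(json.dumps(meta))
        with pytest.raises(ModelIOError, match="version"):
            mg.load_state(tmp_path / "model")
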