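"""Collapsed variational inference: E-step oracle, statistics, hyperparameter
fixed points, single-type collapse, fold-in."""

import numpy as np
import pytest
import scipy.sparse as sp

from typedlda import (
    CorpusMode,
    FittedModel,
    ModelConfig,
    TypedCorpus,
    e_step,
    fit,
    infer_heldout_theta,
    init_state,
    m_step,
    simulate_corpus,
    update_alpha,
    update_beta,
)
from reference import (
    PlainLdaCvb0,
    cvb0_sweep_transcription,
    dm_loglik_alpha,
    make_small_instance,
    match_topics,
    maximize_alpha,
    maximize_beta,
    penalized_loglik_beta,
)


def _one_doc_corpus(counts_row, label="physician"):
    counts_row = np.atleast_2d(counts_row)
    W = counts_row.shape[1]
    return TypedCorpus([label], [[f"w{i}" for i in range(W)]],
                       [sp.csr_matrix(counts_row)], ["g0"])


class TestInitState:
    def test_gamma_rows_normalized_and_deterministic(self, small_sim):
        corpus, _ = small_sim
        cfg = ModelConfig(n_topics=3, seed=5)
        s1 = init_state(corpus, cfg)
        s2 = init_state(corpus, cfg)
        assert np.allclose(s1.gamma.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(s1.gamma > 0)
        assert np.array_equal(s1.gamma, s2.gamma)
        s3 = init_state(corpus, ModelConfig(n_topics=3, seed=6))
        assert not np.array_equal(s1.gamma, s3.gamma)

    def test_initial_statistics_aggregate_gamma(self, small_sim):
        """n_jk row sums equal document token totals; statistics match a
        brute-force summation of the responsibilities."""
        corpus, _ = small_sim
        state = init_state(corpus, ModelConfig(n_topics=3, seed=0))
        totals = corpus.doc_token_totals().sum(axis=1)
        assert np.allclose(state.n_jk.sum(axis=1), totals, atol=1e-9)
        expect = np.zeros_like(state.n_jk)
        for g in range(state.n_groups):
            expect[state.doc_idx[g]] += state.counts[g] * state.gamma[g]
        assert np.allclose(state.n_jk, expect, atol=1e-12)


class TestEStep:
    @pytest.mark.parametrize("seed", range(8))
    def test_sweep_matches_straightline_transcription(self, seed):
        """One vectorized sweep equals the from-scratch transcription of the
        collapsed update with explicit exclusion counts, to 1e-10."""
        corpus = make_small_instance(seed)
        cfg = ModelConfig(n_topics=2 + seed % 2, seed=seed)
        state = init_state(corpus, cfg)
        alpha = np.linspace(0.2, 0.7, cfg.n_topics)
        beta = np.linspace(0.05, 0.2, corpus.num_types)
        expected = cvb0_sweep_transcription(
            state.doc_idx, state.type_idx, state.word_idx, state.counts,
            state.gamma.copy(), alpha, beta, state.vocab_sizes)
        e_step(state, alpha, beta)
        assert np.max(np.abs(state.gamma - expected)) < 1e-10

    def test_single_topic_gives_unit_gamma(self):
        corpus = _one_doc_corpus([[2, 1, 1]])
        state = init_state(corpus, ModelConfig(n_topics=1, seed=0))
        e_step(state, np.array([0.5]), np.array([0.1]))
        assert np.array_equal(state.gamma, np.ones_like(state.gamma))

    def test_symmetric_instance_stays_uniform(self):
        """Uniform alpha, symmetric beta, all-distinct words and a uniform
        start: the collapsed update preserves the symmetry."""
        corpus = _one_doc_corpus([[1, 1, 1, 1]])
        cfg = ModelConfig(n_topics=3, seed=0, init_noise=0.0)
        state = init_state(corpus, cfg)
        e_step(state, np.full(3, 0.4), np.array([0.1]))
        assert np.allclose(state.gamma, 1.0 / 3.0, atol=1e-12)

    def test_conservation_after_incremental_sweeps(self, small_sim):
        corpus, _ = small_sim
        state = init_state(corpus, ModelConfig(n_topics=3, seed=2))
        alpha, beta = np.full(3, 1 / 3), np.array([0.1, 0.1])
        for _ in range(5):
            e_step(state, alpha, beta)
        totals = corpus.doc_token_totals().sum(axis=1)
        assert np.max(np.abs(state.n_jk.sum(axis=1) - totals)) < 1e-8
        assert np.allclose(state.gamma.sum(axis=1), 1.0, atol=1e-9)


class TestMStep:
    def test_uniform_gamma_splits_tokens_evenly(self):
        corpus = _one_doc_corpus([[4, 2, 2]])  # N = 8
        state = init_state(corpus, ModelConfig(n_topics=4, seed=0, init_noise=0.0))
        m_step(state)
        assert np.allclose(state.n_jk, 8 / 4, atol=1e-12)

    def test_statistics_match_triple_loop(self, rng, small_sim):
        corpus, _ = small_sim
        state = init_state(corpus, ModelConfig(n_topics=3, seed=0))
        g = rng.dirichlet(np.ones(3), size=state.n_groups)
        state.gamma = g
        m_step(state)
        n_jk = np.zeros_like(state.n_jk)
        n_wk = np.zeros_like(state.n_wk)
        n_tk = np.zeros_like(state.n_tk)
        for i in range(state.n_groups):
            c = state.counts[i]
            n_jk[state.doc_idx[i]] += c * g[i]
            n_wk[state.word_idx[i]] += c * g[i]
            n_tk[state.type_idx[i]] += c * g[i]
        assert np.allclose(state.n_jk, n_jk, atol=1e-10)
        assert np.allclose(state.n_wk, n_wk, atol=1e-10)
        assert np.allclose(state.n_tk, n_tk, atol=1e-10)
        # conservation per type
        type_totals = corpus.doc_token_totals().sum(axis=0)
        assert np.allclose(state.n_tk.sum(axis=1), type_totals, atol=1e-9)


class TestHyperparameterUpdates:
    def test_alpha_fixed_point_maximizes_marginal_likelihood(self, rng):
        """Iterating the alpha update converges to the numerical maximizer of
        the Dirichlet-multinomial marginal log-likelihood (4 sig. figures)."""
        # counts drawn from a genuine Dirichlet-multinomial so the marginal
        # likelihood has a finite interior maximum
        true_alpha = np.array([2.0, 1.0, 0.5])
        theta = rng.dirichlet(true_alpha, size=20)
        n_jk = np.array([rng.multinomial(30, p) for p in theta], dtype=float)
        alpha = np.ones(3)
        for _ in range(20000):
            new = update_alpha(alpha, n_jk)
            if np.max(np.abs(new - alpha)) < 1e-13:
                alpha = new
                break
            alpha = new
        opt = maximize_alpha(n_jk, 3)
        assert np.allclose(alpha, opt, rtol=5e-4)
        assert dm_loglik_alpha(alpha, n_jk) >= dm_loglik_alpha(opt, n_jk) - 1e-6

    def test_beta_fixed_point_maximizes_penalized_likelihood(self, rng):
        """The symmetric per-type update converges to the maximizer of the
        Gamma(1, 100)-penalized symmetric Dirichlet-multinomial likelihood."""
        n_wk = rng.poisson(6.0, size=(5, 3)).astype(float)
        beta = np.array([0.1])
        for _ in range(20000):
            new = update_beta(beta, [n_wk])
            if np.max(np.abs(new - beta)) < 1e-14:
                beta = new
                break
            beta = new
        opt = maximize_beta(n_wk, a=1.0, b=100.0)
        assert np.isclose(beta[0], opt, rtol=5e-4)
        assert penalized_loglik_beta(beta[0], n_wk) >= \
            penalized_loglik_beta(opt, n_wk) - 1e-6

    def test_empty_statistics_do_not_crash(self):
        # alpha: zero counts make the denominator vanish -> update skipped
        alpha = np.array([0.3, 0.6])
        out = update_alpha(alpha, np.zeros((4, 2)))
        assert np.array_equal(out, alpha)
        # beta: numerator (a-1) = 0 -> floored at the positivity bound
        out = update_beta(np.array([0.5]), [np.zeros((6, 2))])
        assert out[0] == pytest.approx(1e-10)
        assert out[0] > 0


class TestFit:
    def test_single_topic_single_doc_closed_form(self):
        counts = np.array([[3, 1]])
        corpus = _one_doc_corpus(counts)
        cfg = ModelConfig(n_topics=1, max_iter=5, min_iter=1, seed=0,
                          hyper_update="off")
        model = fit(corpus, cfg)
        assert np.allclose(model.theta_hat, [[1.0]])
        beta = model.beta[0]
        expected = (beta + counts[0]) / (2 * beta + 4)
        assert np.allclose(model.phi_hat[0].ravel(), expected, atol=1e-12)

    def test_same_seed_reproduces_fit_exactly(self, small_sim):
        corpus, _ = small_sim
        cfg = ModelConfig(n_topics=3, seed=9, max_iter=40)
        a = fit(corpus, cfg)
        b = fit(corpus, cfg)
        assert np.array_equal(a.theta_hat, b.theta_hat)
        assert all(np.array_equal(x, y) for x, y in zip(a.phi_hat, b.phi_hat))
        assert a.objective_trace == b.objective_trace

    def test_single_type_corpus_collapses_to_plain_lda(self):
        """With one note type the model is standard LDA: the multi-type fit
        equals the flattened fit exactly, and both match an independently
        written plain CVB0 implementation after identical initialization."""
        corpus, _ = simulate_corpus(
            n_topics=3, type_sizes={"physician": 30}, n_docs=20,
            doc_length=50, seed=13)
        cfg = dict(n_topics=3, seed=13, max_iter=15, min_iter=15,
                   tol=1e-15, hyper_update="off")
        multi = fit(corpus, ModelConfig(mode=CorpusMode.MULTI_TYPE, **cfg))
        same = fit(corpus, ModelConfig(mode=CorpusMode.SINGLE_SAME_WORD, **cfg))
        assert np.max(np.abs(multi.theta_hat - same.theta_hat)) < 1e-12
        assert np.max(np.abs(multi.phi_hat[0] - same.phi_hat[0])) < 1e-12

        state0 = init_state(corpus, ModelConfig(mode=CorpusMode.MULTI_TYPE, **cfg))
        ref = PlainLdaCvb0(corpus.counts[0], 3, alpha=np.full(3, 1 / 3),
                           beta=0.1, gamma0=state0.gamma)
        theta_ref, phi_ref = ref.run(15)
        assert np.max(np.abs(multi.theta_hat - theta_ref)) < 1e-8
        assert np.max(np.abs(multi.phi_hat[0] - phi_ref)) < 1e-8

    def test_objective_trend_is_nondecreasing(self, small_fit):
        """No sustained decrease of the monitored objective: never 5
        consecutive iterations each dropping by more than 1e-6."""
        diffs = np.diff(small_fit.objective_trace)
        sustained = [
            all(d < -1e-6 for d in diffs[i:i + 5])
            for i in range(max(len(diffs) - 4, 0))
        ]
        assert not any(sustained)

    def test_normalizations_hold(self, small_fit):
        assert np.allclose(small_fit.theta_hat.sum(axis=1), 1.0, atol=1e-9)
        for p in small_fit.phi_hat:
            assert np.allclose(p.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(small_fit.alpha > 0) and np.all(small_fit.beta > 0)

    def test_posterior_means_recompute_from_final_stats(self, small_fit):
        m = small_fit
        theta = (m.alpha + m.n_jk)
        theta /= theta.sum(axis=1, keepdims=True)
        assert np.allclose(theta, m.theta_hat, atol=1e-12)
        for t in range(len(m.phi_hat)):
            n = m.n_wk_for_type(t)
            W = n.shape[0]
            phi = (m.beta[t] + n) / (W * m.beta[t] + n.sum(axis=0))
            assert np.allclose(phi, m.phi_hat[t], atol=1e-12)

    def test_model_round_trip(self, small_fit, tmp_path):
        small_fit.save(tmp_path / "model")
        back = FittedModel.load(tmp_path / "model")
        assert np.array_equal(back.theta_hat, small_fit.theta_hat)
        assert np.array_equal(back.alpha, small_fit.alpha)
        assert np.array_equal(back.n_wk, small_fit.n_wk)
        for a, b in zip(back.phi_hat, small_fit.phi_hat):
            assert np.array_equal(a, b)
        assert back.config.to_dict() == small_fit.config.to_dict()
        assert back.vocabs == small_fit.vocabs


class TestFoldIn:
    def test_empty_document_gets_prior_mean(self, small_fit):
        oov = TypedCorpus(
            ["physician", "nursing"], [["zzz"], ["zzz"]],
            [sp.csr_matrix(np.array([[2]])), sp.csr_matrix(np.array([[1]]))],
            ["new0"],
        )
        with pytest.warns(UserWarning):
            theta = infer_heldout_theta(small_fit, oov)
        assert np.allclose(theta[0], small_fit.alpha / small_fit.alpha.sum(),
                           atol=1e-12)

    def test_folding_in_training_documents_recovers_theta(self, small_sim,
                                                          small_fit):
        """Fold-in re-infers the training mixtures closely; exact agreement
        is impossible because fold-in cannot exclude a token's own
        contribution from the frozen topic-word statistics (an O(1/n)
        perturbation)."""
        corpus, _ = small_sim
        theta = infer_heldout_theta(small_fit, corpus)
        assert np.max(np.abs(theta - small_fit.theta_hat)) < 0.02
        rs = [np.corrcoef(theta[j], small_fit.theta_hat[j])[0, 1]
              for j in range(corpus.num_docs)]
        assert np.mean(rs) > 0.999

    def test_heldout_mixtures_track_the_truth(self):
        """Mixtures of unseen documents correlate with the simulating truth
        (mean per-document Pearson r >= 0.8 at 300 tokens/doc/type)."""
        corpus, truth = simulate_corpus(
            n_topics=5, type_sizes={"physician": 60, "nursing": 60},
            n_docs=150, doc_length=300, seed=17)
        train, held = corpus.subset(range(100)), corpus.subset(range(100, 150))
        model = fit(train, ModelConfig(n_topics=5, seed=17))
        perm, _ = match_topics(np.vstack(model.phi_hat), np.vstack(truth.phi))
        theta = infer_heldout_theta(model, held)[:, perm]
        rs = [np.corrcoef(theta[i], truth.theta[100 + i])[0, 1]
              for i in range(50)]
        assert np.mean(rs) >= 0.8
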