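import math

import numpy as np
import pytest

from kanosat import lda
from kanosat.lda import (
    Corpus,
    LdaConfig,
    _elbow,
    best_topic,
    build_corpus,
    fit_lda,
    fold_in,
    perplexity,
    select_k,
    top_keyword_tokens,
    top_keywords,
)
from kanosat.simulate import GeneratorConfig, generate_corpus

from conftest import make_dataset, make_review


def corpus_from_token_lists(token_lists):
    ds = make_dataset(
        [make_review(f"r{i}", text=" ".join(t), tokens=tuple(t))
         for i, t in enumerate(token_lists)]
    )
    return build_corpus(ds)


# ---------------------------------------------------------------------------
# corpus construction

def test_build_corpus_document_frequency_pruning():
    docs = [["a", "b"], ["a", "c"], ["a", "d"]]
    c1 = corpus_from_token_lists(docs)
    assert "a" in c1.vocabulary
    # token in every doc excluded at max_doc_fraction=0.5
    ds = make_dataset(
        [make_review(f"r{i}", tokens=tuple(t)) for i, t in enumerate(docs)]
    )
    c2 = build_corpus(ds, max_doc_fraction=0.5)
    assert "a" not in c2.vocabulary and "b" in c2.vocabulary
    # unique token excluded at min_doc_freq=2
    c3 = build_corpus(ds, min_doc_freq=2)
    assert c3.vocabulary == ["a"]


def test_build_corpus_drops_emptied_documents_and_reports():
    ds = make_dataset([
        make_review("r0", tokens=("a", "b")),
        make_review("r1", tokens=("unique",)),
        make_review("r2", tokens=("a",)),
    ])
    c = build_corpus(ds, min_doc_freq=2)
    assert c.doc_ids == ["r0", "r2"] and c.dropped_doc_ids == ["r1"]
    with pytest.raises(ValueError, match="every document"):
        build_corpus(ds, min_doc_freq=10)


# ---------------------------------------------------------------------------
# fitting

def test_single_topic_point_mass():
    c = corpus_from_token_lists([["w"], ["w"], ["w"]])
    fit = fit_lda(c, LdaConfig(k=1, n_iterations=10, burn_in=5, seed=0))
    assert fit.phi.shape == (1, 1)
    assert fit.phi[0, 0] == pytest.approx(1.0)
    assert np.allclose(fit.theta, 1.0)


def test_same_seed_gives_bit_identical_fit():
    cfg = GeneratorConfig(k_true=3, vocab_size=60, n_docs=50, doc_length_mean=20,
                          beta_pd_true=[0, 0, 0], beta_nd_true=[0, 0, 0], n_apps=3, seed=4)
    ds, _ = generate_corpus(cfg)
    corpus = build_corpus(ds)
    f1 = fit_lda(corpus, LdaConfig(k=3, n_iterations=50, burn_in=25, seed=7))
    f2 = fit_lda(corpus, LdaConfig(k=3, n_iterations=50, burn_in=25, seed=7))
    assert np.array_equal(f1.theta, f2.theta) and np.array_equal(f1.phi, f2.phi)
    f3 = fit_lda(corpus, LdaConfig(k=3, n_iterations=50, burn_in=25, seed=8))
    assert not np.array_equal(f1.theta, f3.theta)


def test_rows_normalize_after_any_fit():
    cfg = GeneratorConfig(k_true=4, vocab_size=80, n_docs=60, doc_length_mean=15,
                          beta_pd_true=np.zeros(4), beta_nd_true=np.zeros(4), n_apps=3, seed=1)
    ds, _ = generate_corpus(cfg)
    corpus = build_corpus(ds)
    for avg in (False, True):
        fit = fit_lda(corpus, LdaConfig(k=4, n_iterations=40, burn_in=20, seed=0,
                                        average_over_samples=avg))
        assert np.allclose(fit.phi.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(fit.theta.sum(axis=1), 1.0, atol=1e-8)
        assert (fit.phi >= 0).all() and (fit.theta >= 0).all()


def test_disjoint_planted_topics_recovered():
    """Two topics with disjoint vocabularies are recovered almost exactly."""
    cfg = GeneratorConfig(k_true=2, vocab_size=20, n_docs=200, doc_length_mean=50,
                          topic_separation=1.0, beta_pd_true=[0, 0], beta_nd_true=[0, 0],
                          n_apps=5, seed=1)
    ds, truth = generate_corpus(cfg)
    corpus = build_corpus(ds)
    gen_idx = np.array([int(t[1:]) for t in corpus.vocabulary])
    truth_phi = truth.phi[:, gen_idx]
    truth_phi = truth_phi / truth_phi.sum(axis=1, keepdims=True)
    fit = fit_lda(corpus, LdaConfig(k=2, n_iterations=200, burn_in=100, seed=0))

    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    sims = np.array([[cos(fit.phi[i], truth_phi[j]) for j in range(2)] for i in range(2)])
    best = max(sims[0, 0] + sims[1, 1], sims[0, 1] + sims[1, 0]) / 2
    assert best > 0.95


def test_degenerate_k_warns_but_fits():
    c = corpus_from_token_lists([["a"], ["b"]])
    with pytest.warns(RuntimeWarning, match="degenerate"):
        fit = fit_lda(c, LdaConfig(k=5, n_iterations=5, burn_in=1, seed=0))
    assert fit.phi.shape[0] == 5


# ---------------------------------------------------------------------------
# perplexity

def test_uniform_phi_perplexity_equals_vocab_size():
    c = corpus_from_token_lists([["a", "b"], ["c", "d", "a"]])
    fit = fit_lda(c, LdaConfig(k=2, n_iterations=5, burn_in=1, seed=0))
    V = c.vocab_size
    fit.phi = np.full((2, V), 1.0 / V)
    assert perplexity(fit, c) == pytest.approx(V, abs=1e-9)


def test_point_mass_phi_perplexity_equals_one():
    c = corpus_from_token_lists([["w"], ["w"]])
    fit = fit_lda(c, LdaConfig(k=1, n_iterations=5, burn_in=1, seed=0))
    assert perplexity(fit, c) == pytest.approx(1.0, abs=1e-9)


def test_perplexity_matches_term_by_term_evaluation():
    """Direct evaluation of exp(-sum log sum_k theta*phi / N) on a 5-doc fixture."""
    rng = np.random.default_rng(3)
    V, K = 7, 3
    docs = [rng.integers(0, V, size=n).astype(np.int32) for n in (4, 2, 6, 3, 5)]
    c = Corpus(vocabulary=[f"t{v}" for v in range(V)], documents=docs,
               doc_ids=[f"d{i}" for i in range(5)])
    phi = rng.dirichlet(np.ones(V), size=K)
    theta = rng.dirichlet(np.ones(K), size=5)
    fit = fit_lda(c, LdaConfig(k=K, n_iterations=2, burn_in=1, seed=0))
    fit.phi, fit.theta = phi, theta
    # independent brute-force evaluation, one token at a time
    total, n_tokens = 0.0, 0
    for d, words in enumerate(docs):
        for w in words:
            p = sum(theta[d, k] * phi[k, w] for k in range(K))
            total += math.log(p)
            n_tokens += 1
    expected = math.exp(-total / n_tokens)
    assert perplexity(fit, c) == pytest.approx(expected, rel=1e-12)


def test_perplexity_rejects_unknown_token_ids():
    c = corpus_from_token_lists([["a", "b"]])
    fit = fit_lda(c, LdaConfig(k=1, n_iterations=3, burn_in=1, seed=0))
    alien = Corpus(vocabulary=c.vocabulary + ["zz"],
                   documents=[np.array([2], dtype=np.int32)], doc_ids=["x"])
    with pytest.raises(ValueError, match="outside"):
        perplexity(fit, alien)


def test_heldout_agreement_with_established_library():
    """Held-out perplexity of our Gibbs fit is within 15% of a variational
    LDA fit from scikit-learn with matching hyperparameters."""
    from sklearn.decomposition import LatentDirichletAllocation

    cfg = GeneratorConfig(k_true=3, vocab_size=60, n_docs=50, doc_length_mean=40,
                          topic_separation=0.9, beta_pd_true=np.zeros(3),
                          beta_nd_true=np.zeros(3), n_apps=3, seed=6)
    ds, _ = generate_corpus(cfg)
    corpus = build_corpus(ds)
    train_idx = list(range(45))
    held_idx = list(range(45, corpus.n_docs))
    train, held = corpus.subset(train_idx), corpus.subset(held_idx)
    K, alpha, eta = 3, 0.5, 0.1
    ours = fit_lda(train, LdaConfig(k=K, alpha=alpha, eta=eta, n_iterations=300,
                                    burn_in=150, seed=0))
    counts = np.zeros((train.n_docs, corpus.vocab_size))
    for d, words in enumerate(train.documents):
        np.add.at(counts[d], words, 1)
    sk = LatentDirichletAllocation(n_components=K, doc_topic_prior=alpha,
                                   topic_word_prior=eta, max_iter=50, random_state=0)
    sk.fit(counts)
    sk_phi = sk.components_ / sk.components_.sum(axis=1, keepdims=True)

    def heldout_perp(phi):
        theta_h = fold_in(phi, held.documents, alpha, seed=0)
        ll = sum(float(np.log(theta_h[i] @ phi[:, w]).sum())
                 for i, w in enumerate(held.documents))
        n = sum(len(w) for w in held.documents)
        return math.exp(-ll / n)

    p_ours, p_sk = heldout_perp(ours.phi), heldout_perp(sk_phi)
    assert abs(p_ours - p_sk) / p_sk < 0.15


# ---------------------------------------------------------------------------
# model selection

def test_elbow_rule_picks_maximum_slowdown():
    assert _elbow([5, 10, 15, 20], [1000, 500, 480, 470]) == 10


def test_elbow_tie_breaks_to_first_interior_point():
    # perfectly linear decline: every interior second difference is 0
    assert _elbow([2, 4, 6, 8], [300, 200, 100, 0]) == 4


def test_select_k_validates_grid():
    c = corpus_from_token_lists([["a", "b"]] * 20)
    with pytest.raises(ValueError, match="ascending"):
        select_k(c, [4, 4, 8], seed=0)
    with pytest.raises(ValueError, match="at least 3"):
        select_k(c, [4, 8], seed=0)


def test_select_k_override_must_be_on_grid():
    cfg = GeneratorConfig(k_true=2, vocab_size=30, n_docs=40, doc_length_mean=15,
                          beta_pd_true=[0, 0], beta_nd_true=[0, 0], n_apps=2, seed=0)
    ds, _ = generate_corpus(cfg)
    c = build_corpus(ds)
    tmpl = LdaConfig(k=2, n_iterations=20, burn_in=10, seed=0)
    curve = select_k(c, [2, 3, 4], tmpl, seed=0, k_override=3)
    assert curve.chosen_k == 3
    with pytest.raises(ValueError, match="not on the grid"):
        select_k(c, [2, 3, 4], tmpl, seed=0, k_override=7)


# ---------------------------------------------------------------------------
# summaries

def test_top_keywords_orders_by_probability_then_id():
    c = corpus_from_token_lists([["a", "b", "c"]])
    fit = fit_lda(c, LdaConfig(k=1, n_iterations=3, burn_in=1, seed=0))
    fit.phi = np.array([[0.5, 0.3, 0.2]])
    assert top_keywords(fit, 0, 2) == [0, 1]
    assert top_keyword_tokens(fit, c, 0, 2) == ["a", "b"]
    fit.phi = np.array([[1 / 3, 1 / 3, 1 / 3]])  # uniform: tie-break by id
    assert top_keywords(fit, 0, 3) == [0, 1, 2]
    assert top_keywords(fit, 0, 99) == [0, 1, 2]  # n > V returns V tokens


def test_best_topic_argmax_with_low_index_ties():
    assert best_topic(np.array([0.1, 0.7, 0.2])) == 1
    assert best_topic(np.array([0.5, 0.5])) == 0
    assert best_topic(np.full(12, 1 / 12)) == 0
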