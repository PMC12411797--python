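"""Fit LDA by collapsed Gibbs sampling and choose the number of topics.

Held-out perplexity is computed over a grid of topic counts; the chosen k
is the point where the decline of the curve slows down the most.  With 6
well-separated planted topics, the elbow lands on 6.
"""

from kanosat.lda import LdaConfig, build_corpus, fit_lda, select_k, top_keyword_tokens
from kanosat.preprocess import run_preprocess
from kanosat.simulate import GeneratorConfig, generate_full_study

config = GeneratorConfig(k_true=6, vocab_size=300, n_docs=1200, doc_length_mean=40,
                         topic_separation=1.0,
                         beta_pd_true=[0.3] * 6, beta_nd_true=[-1.0] * 6,
                         n_apps=10, seed=3)
dataset, truth = generate_full_study(config)
clean, _ = run_preprocess(dataset)
corpus = build_corpus(clean, min_doc_freq=2)

template = LdaConfig(k=2, n_iterations=150, burn_in=75, seed=0)
curve = select_k(corpus, [2, 4, 6, 8, 10], template, seed=0)
print("k grid      :", curve.k_grid)
print("perplexity  :", [round(p, 1) for p in curve.perplexities])
print("chosen k    :", curve.chosen_k)

fit = fit_lda(corpus, LdaConfig(k=curve.chosen_k, n_iterations=300, burn_in=150, seed=0))
for topic in range(fit.k):
    words = top_keyword_tokens(fit, corpus, topic, 5)
    print(f"topic {topic}: {words}")
# Lower perplexity = better held-out fit; keywords are each topic's
# highest-probability vocabulary items (abstract symbols here).
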