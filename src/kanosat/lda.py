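"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The review corpus is modeled as the standard LDA generative process: each
document draws a topic mixture theta_d ~ Dirichlet(alpha), each token a
topic from theta_d and a word from that topic's distribution phi_k ~
Dirichlet(eta).  Inference integrates theta and phi out and Gibbs-samples
the token-topic assignments; point estimates are the smoothed posterior
means from the final assignment counts,

    phi_kw   ∝ n_kw + eta,      theta_dk ∝ n_dk + alpha.

Model size is chosen by held-out perplexity over a grid of topic counts:
fit on a train split, fold held-out documents in against the fixed phi,
and take the grid point where the decline of the perplexity curve slows
down the most (the largest second difference), with a manual override for
when human judgment disagrees with the elbow.

Defaults follow the common Gibbs-LDA practice: alpha = 50/K, eta = 0.01,
1,000 sweeps with 500 burn-in.  All randomness flows from an explicit
integer seed; identical (corpus, config) gives an identical fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .io import ReviewDataset

__all__ = [
    "Corpus",
    "LdaConfig",
    "LdaFit",
    "PerplexityCurve",
    "build_corpus",
    "fit_lda",
    "perplexity",
    "fold_in",
    "select_k",
    "top_keywords",
    "best_topic",
]


@dataclass
class Corpus:
    """Bag-of-words view of the tokenized reviews.

    ``vocabulary`` maps token id -> token string (ids are dense in [0, V));
    ``documents`` holds one int32 id array per document, all non-empty;
    ``doc_ids`` carries the originating review id per document.
    """

    vocabulary: list[str]
    documents: list[np.ndarray]
    doc_ids: list[str]
    dropped_doc_ids: list[str] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    @property
    def vocab_size(self) -> int:
        return len(self.vocabulary)

    @property
    def n_tokens(self) -> int:
        return int(sum(len(d) for d in self.documents))

    def token_id(self, token: str) -> int:
        return self.vocabulary.index(token)

    def subset(self, indices: Sequence[int]) -> "Corpus":
        return Corpus(
            vocabulary=self.vocabulary,
            documents=[self.documents[i] for i in indices],
            doc_ids=[self.doc_ids[i] for i in indices],
        )


@dataclass(frozen=True)
class LdaConfig:
    k: int
    alpha: float | None = None  # None -> 50/k
    eta: float = 0.01
    n_iterations: int = 1000
    burn_in: int = 500
    seed: int = 0
    average_over_samples: bool = False  # posterior mean over post-burn-in sweeps

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")

    @property
    def effective_alpha(self) -> float:
        return 50.0 / self.k if self.alpha is None else self.alpha


@dataclass
class LdaFit:
    phi: np.ndarray  # K x V, rows sum to 1
    theta: np.ndarray  # D x K, rows sum to 1
    assignment_counts: np.ndarray  # K x V integer tallies behind phi
    topic_token_counts: np.ndarray  # length-K token tallies per topic
    config: LdaConfig
    train_loglik_trace: np.ndarray  # collapsed joint log p(w, z) per sweep

    @property
    def k(self) -> int:
        return self.phi.shape[0]


@dataclass
class PerplexityCurve:
    k_grid: list[int]
    perplexities: list[float]
    chosen_k: int

    def as_dict(self) -> dict:
        return {
            "k_grid": self.k_grid,
            "perplexity": self.perplexities,
            "chosen_k": self.chosen_k,
        }


# ---------------------------------------------------------------------------
# corpus construction

def build_corpus(
    dataset: ReviewDataset, min_doc_freq: int = 1, max_doc_fraction: float = 1.0
) -> Corpus:
    """Build the id corpus from tokenized reviews, pruning the vocabulary.

    Tokens kept appear in at least ``min_doc_freq`` documents and in at
    most ``max_doc_fraction`` of them.  Reviews with no tokens (or emptied
    by pruning) are dropped and reported via ``dropped_doc_ids``.
    """
    if min_doc_freq < 1:
        raise ValueError("min_doc_freq must be >= 1")
    if not (0 < max_doc_fraction <= 1):
        raise ValueError("max_doc_fraction must lie in (0, 1]")
    docs = [(r.review_id, r.tokens) for r in dataset.reviews]
    for rid, tokens in docs:
        if tokens is None:
            raise ValueError(f"review {rid!r} is not tokenized; run the preprocess stage first")
    n_docs_with_tokens = sum(1 for _, t in docs if t)
    doc_freq: dict[str, int] = {}
    for _, tokens in docs:
        for tok in set(tokens):
            doc_freq[tok] = doc_freq.get(tok, 0) + 1
    max_df = max_doc_fraction * n_docs_with_tokens
    # first-appearance order keeps ids deterministic
    vocab: list[str] = []
    token2id: dict[str, int] = {}
    for _, tokens in docs:
        for tok in tokens:
            if tok in token2id:
                continue
            if min_doc_freq <= doc_freq[tok] and doc_freq[tok] <= max_df:
                token2id[tok] = len(vocab)
                vocab.append(tok)
    documents: list[np.ndarray] = []
    doc_ids: list[str] = []
    dropped: list[str] = []
    for rid, tokens in docs:
        ids = [token2id[t] for t in tokens if t in token2id]
        if ids:
            documents.append(np.asarray(ids, dtype=np.int32))
            doc_ids.append(rid)
        else:
            dropped.append(rid)
    if not documents:
        raise ValueError("vocabulary pruning removed every document; relax the thresholds")
    return Corpus(vocabulary=vocab, documents=documents, doc_ids=doc_ids, dropped_doc_ids=dropped)


# ---------------------------------------------------------------------------
# collapsed Gibbs kernels (numba)

@njit(cache=True)
def _gibbs_kernel(words, doc_of, z, ndk, nkw, nk, doc_totals, alpha, eta,
                  n_iterations, burn_in, average, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    n_tokens = words.shape[0]
    K = nkw.shape[0]
    V = nkw.shape[1]
    D = ndk.shape[0]
    cum = np.empty(K, dtype=np.float64)
    trace = np.empty(n_iterations, dtype=np.float64)
    theta_acc = np.zeros((D, K), dtype=np.float64)
    phi_acc = np.zeros((K, V), dtype=np.float64)
    n_samples = 0
    eta_v = eta * V
    for it in range(n_iterations):
        for n in range(n_tokens):
            w = words[n]
            d = doc_of[n]
            k = z[n]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            total = 0.0
            for kk in range(K):
                total += (ndk[d, kk] + alpha) * (nkw[kk, w] + eta) / (nk[kk] + eta_v)
                cum[kk] = total
            u = np.random.random() * total
            knew = 0
            while cum[knew] < u and knew < K - 1:
                knew += 1
            z[n] = knew
            ndk[d, knew] += 1
            nkw[knew, w] += 1
            nk[knew] += 1
        # collapsed joint log p(w, z) up to constants: the Dirichlet-multinomial
        # score of the current count tables; cheap convergence diagnostic
        score = 0.0
        for kk in range(K):
            for vv in range(V):
                score += math.lgamma(nkw[kk, vv] + eta)
            score -= math.lgamma(nk[kk] + eta_v)
        for dd in range(D):
            for kk in range(K):
                score += math.lgamma(ndk[dd, kk] + alpha)
            score -= math.lgamma(doc_totals[dd] + alpha * K)
        trace[it] = score
        if average and it >= burn_in:
            n_samples += 1
            for dd in range(D):
                tot = doc_totals[dd] + alpha * K
                for kk in range(K):
                    theta_acc[dd, kk] += (ndk[dd, kk] + alpha) / tot
            for kk in range(K):
                tot = nk[kk] + eta_v
                for vv in range(V):
                    phi_acc[kk, vv] += (nkw[kk, vv] + eta) / tot
    return trace, theta_acc, phi_acc, n_samples


@njit(cache=True)
def _fold_in_kernel(words, phi, alpha, n_iterations, seed):  # pragma: no cover - jit
    np.random.seed(seed)
    K = phi.shape[0]
    n = words.shape[0]
    z = np.empty(n, dtype=np.int32)
    nd = np.zeros(K, dtype=np.int64)
    cum = np.empty(K, dtype=np.float64)
    for i in range(n):
        k = np.random.randint(0, K)
        z[i] = k
        nd[k] += 1
    for it in range(n_iterations):
        for i in range(n):
            w = words[i]
            k = z[i]
            nd[k] -= 1
            total = 0.0
            for kk in range(K):
                total += (nd[kk] + alpha) * phi[kk, w]
                cum[kk] = total
            u = np.random.random() * total
            knew = 0
            while cum[knew] < u and knew < K - 1:
                knew += 1
            z[i] = knew
            nd[knew] += 1
    theta = np.empty(K, dtype=np.float64)
    tot = n + alpha * K
    for kk in range(K):
        theta[kk] = (nd[kk] + alpha) / tot
    return theta


def fit_lda(corpus: Corpus, config: LdaConfig) -> LdaFit:
    """Run the collapsed Gibbs sampler and return smoothed point estimates.

    With ``average_over_samples`` off (the default) phi and theta come from
    the final sweep's assignment counts; on, they are averaged over every
    post-burn-in sweep.  A ``k`` exceeding the corpus token count is
    allowed (some topics simply stay empty) but warned about.
    """
    if corpus.n_docs == 0:
        raise ValueError("corpus is empty")
    K, V, D = config.k, corpus.vocab_size, corpus.n_docs
    words = np.concatenate(corpus.documents).astype(np.int32)
    if words.size and (words.min() < 0 or words.max() >= V):
        raise ValueError("corpus contains token ids outside the vocabulary")
    doc_of = np.concatenate(
        [np.full(len(d), i, dtype=np.int32) for i, d in enumerate(corpus.documents)]
    )
    if K > words.size:
        import warnings

        warnings.warn(
            f"k={K} exceeds the corpus token count {words.size}; the model is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    alpha = config.effective_alpha
    rng = np.random.default_rng(config.seed)
    z = rng.integers(0, K, size=words.size).astype(np.int32)
    ndk = np.zeros((D, K), dtype=np.int64)
    nkw = np.zeros((K, V), dtype=np.int64)
    nk = np.zeros(K, dtype=np.int64)
    np.add.at(ndk, (doc_of, z), 1)
    np.add.at(nkw, (z, words), 1)
    np.add.at(nk, z, 1)
    doc_totals = np.asarray([len(d) for d in corpus.documents], dtype=np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    trace, theta_acc, phi_acc, n_samples = _gibbs_kernel(
        words, doc_of, z, ndk, nkw, nk, doc_totals,
        float(alpha), float(config.eta),
        int(config.n_iterations), int(config.burn_in),
        config.average_over_samples, kernel_seed,
    )
    if config.average_over_samples and n_samples > 0:
        theta = theta_acc / n_samples
        phi = phi_acc / n_samples
    else:
        theta = (ndk + alpha) / (doc_totals[:, None] + alpha * K)
        phi = (nkw + config.eta) / (nk[:, None] + config.eta * V)
    return LdaFit(
        phi=phi,
        theta=theta,
        assignment_counts=nkw,
        topic_token_counts=nk,
        config=config,
        train_loglik_trace=trace,
    )


# ---------------------------------------------------------------------------
# evaluation

def _token_loglik(phi: np.ndarray, theta: np.ndarray, documents: list[np.ndarray]) -> tuple[float, int]:
    total_ll = 0.0
    total_n = 0
    for d, words in enumerate(documents):
        p = theta[d] @ phi[:, words]
        total_ll += float(np.log(p).sum())
        total_n += len(words)
    return total_ll, total_n


def fold_in(
    phi: np.ndarray, documents: list[np.ndarray], alpha: float,
    n_iterations: int = 100, seed: int = 0,
) -> np.ndarray:
    """Infer document-topic mixtures for new documents with phi held fixed."""
    V = phi.shape[1]
    thetas = np.empty((len(documents), phi.shape[0]))
    for i, words in enumerate(documents):
        if words.min() < 0 or words.max() >= V:
            raise ValueError(f"document {i} contains token ids outside the fitted vocabulary")
        thetas[i] = _fold_in_kernel(
            words.astype(np.int32), phi, float(alpha), int(n_iterations), int(seed + i)
        )
    return thetas


def perplexity(
    fit: LdaFit, corpus: Corpus, theta: np.ndarray | None = None,
    fold_in_iterations: int = 100, seed: int = 0,
) -> float:
    """exp(− mean per-token log-likelihood) of ``corpus`` under the fit.

    If ``theta`` is omitted it is taken from the fit when the corpus is the
    training corpus (matching document count), and obtained by folding in
    otherwise — the held-out evaluation used by ``select_k``.
    """
    V = fit.phi.shape[1]
    for i, words in enumerate(corpus.documents):
        if words.min() < 0 or words.max() >= V:
            raise ValueError(f"document {i} contains token ids outside the fitted vocabulary")
    if theta is None:
        if corpus.n_docs == fit.theta.shape[0]:
            theta = fit.theta
        else:
            theta = fold_in(
                fit.phi, corpus.documents, fit.config.effective_alpha,
                n_iterations=fold_in_iterations, seed=seed,
            )
    ll, n = _token_loglik(fit.phi, theta, corpus.documents)
    return float(np.exp(-ll / n))


def _elbow(k_grid: Sequence[int], perp: Sequence[float]) -> int:
    """Grid point where the perplexity decline slows down the most.

    chosen_k = argmax over interior points of the second difference
    (p_prev − p_k) − (p_k − p_next); ties break toward smaller k.
    """
    best_k = None
    best_val = -np.inf
    for j in range(1, len(k_grid) - 1):
        val = (perp[j - 1] - perp[j]) - (perp[j] - perp[j + 1])
        if val > best_val + 1e-12:
            best_val = val
            best_k = k_grid[j]
    return int(best_k)


def select_k(
    corpus: Corpus,
    k_grid: Sequence[int],
    config_template: LdaConfig | None = None,
    heldout_fraction: float = 0.1,
    seed: int = 0,
    k_override: int | None = None,
) -> PerplexityCurve:
    """Held-out perplexity over a grid of topic counts, with elbow selection.

    Documents are split 90/10 (by default) into train/held-out; each k is
    fit on the train split and scored by fold-in perplexity on the held-out
    split.  ``k_override`` bypasses the elbow rule (it must be on the grid),
    for when the automatic rule disagrees with human reading of the curve.
    """
    k_grid = [int(k) for k in k_grid]
    if len(k_grid) < 3:
        raise ValueError("k_grid needs at least 3 points for elbow selection")
    if any(b <= a for a, b in zip(k_grid, k_grid[1:])):
        raise ValueError("k_grid must be strictly ascending")
    if not (0 < heldout_fraction < 1):
        raise ValueError("heldout_fraction must lie in (0, 1)")
    if config_template is None:
        config_template = LdaConfig(k=k_grid[0])
    rng = np.random.default_rng(seed)
    order = rng.permutation(corpus.n_docs)
    n_held = max(1, int(round(heldout_fraction * corpus.n_docs)))
    if n_held >= corpus.n_docs:
        raise ValueError("held-out split would consume the whole corpus")
    held_idx = order[:n_held]
    train_idx = order[n_held:]
    train = corpus.subset(train_idx)
    held = corpus.subset(held_idx)
    perps: list[float] = []
    for k in k_grid:
        cfg = replace(config_template, k=k, alpha=config_template.alpha,
                      seed=int(rng.integers(0, 2**31 - 1)))
        fit = fit_lda(train, cfg)
        theta_h = fold_in(
            fit.phi, held.documents, cfg.effective_alpha,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ll, n = _token_loglik(fit.phi, theta_h, held.documents)
        perps.append(float(np.exp(-ll / n)))
    if k_override is not None:
        if k_override not in k_grid:
            raise ValueError(f"k_override {k_override} is not on the grid {k_grid}")
        chosen = k_override
    else:
        chosen = _elbow(k_grid, perps)
    return PerplexityCurve(k_grid=k_grid, perplexities=perps, chosen_k=chosen)


# ---------------------------------------------------------------------------
# summaries

def top_keywords(fit: LdaFit, topic: int, n: int = 30) -> list[int]:
    """Ids of the n highest-probability words of a topic; ties break by vocab id."""
    if not (0 <= topic < fit.k):
        raise ValueError(f"topic must lie in [0, {fit.k})")
    row = fit.phi[topic]
    n = min(n, row.shape[0])
    # stable sort on (-p, id): equal probabilities yield ascending ids
    order = np.lexsort((np.arange(row.shape[0]), -row))
    return [int(i) for i in order[:n]]


def top_keyword_tokens(fit: LdaFit, corpus: Corpus, topic: int, n: int = 30) -> list[str]:
    """Same as :func:`top_keywords` but resolved to token strings."""
    return [corpus.vocabulary[i] for i in top_keywords(fit, topic, n)]


def best_topic(theta_row: np.ndarray) -> int:
    """Argmax topic of a document-topic row; ties break toward the lowest index."""
    return int(np.argmax(theta_row))
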