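"""Synthetic review studies with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
that every stage of the pipeline can be exercised and checked against
planted parameters without any scraped data:

* documents follow the LDA generative process (Dirichlet topic mixtures
  over an abstract vocabulary, optionally block-separated topics),
* ratings follow the censored-linear deviation model: per-review latent
  positive/negative deviations are linear in min-max-normalized topic
  attention with normal noise, censored to [0, 4], and folded back into
  1..5-star ratings around each app's comprehensive rating,
* contamination (duplicates, bot reviews, sentiment-rating conflicts) is
  planted at controllable rates and fully recorded.

Token strings are abstract symbols ("w0042"); no attempt is made at
language-realistic text.  All randomness flows from the config seed.

The default configuration mirrors a large published app-review study
shrunk about tenfold: 18,000 reviews over 86 apps, 12 topics with effect
sizes spanning roughly −3.7 to +2.8, a vocabulary of 2,000, mean document
length 50, and an overall satisfaction probability near 72%.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .io import AppRecord, Review, ReviewDataset
from .tobit import DeviationOutcome, minmax_normalize

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "default_effects",
    "generate_corpus",
    "generate_outcomes",
    "inject_noise",
    "generate_full_study",
]

ANDROID_STORES = ("huawei", "xiaomi", "vivo", "oppo")


def default_effects() -> tuple[np.ndarray, np.ndarray]:
    """The default planted effect pattern: 2 "basic" themes whose discussion
    drives dissatisfaction (negative satisfaction effect, large positive
    dissatisfaction effect) and 10 "attractive" themes with the mirror
    pattern, with magnitudes shaped like published pregnancy-app estimates.
    """
    beta_pd = np.array(
        [-0.474, -0.232, 0.220, 0.223, 0.023, 0.222, 0.356, 0.209, 0.306, 0.238, 0.401, 0.307]
    )
    beta_nd = np.array(
        [2.829, 1.955, -2.796, -2.032, -0.420, -3.587, -3.665, -0.501, -2.570, -1.168, -3.109,
         -2.416]
    )
    return beta_pd, beta_nd


@dataclass
class GeneratorConfig:
    k_true: int = 12
    vocab_size: int = 2000
    n_docs: int = 18000
    doc_length_mean: float = 50.0
    doc_length_dispersion: float | None = None  # None: Poisson; else neg. binomial size
    dirichlet_alpha_doc: float = 0.03
    dirichlet_eta_topic: float = 0.05
    topic_separation: float = 0.8  # 0 shared vocabulary .. 1 disjoint blocks
    beta_pd_true: np.ndarray | None = None  # None -> default_effects()
    beta_nd_true: np.ndarray | None = None
    sigma_true: float = 1.0
    n_apps: int = 86
    comprehensive_ratings: Sequence[float] | None = None  # None -> drawn U[3.2, 4.8]
    app_weight_zipf: float = 2.0  # review volume concentration across apps (top-heavy market)
    platform_ios_share: float = 0.6  # review-level iOS share (roughly 3:2)
    satisfaction_prob: float | Sequence[float] = 0.7234  # scalar or per-topic
    platform_satisfaction: Mapping[str, float] | None = None  # overrides the above
    polarity_conflict_rate: float = 0.05
    duplicate_rate: float = 0.02
    bot_rate: float = 0.03
    window: tuple[_dt.date, _dt.date] = (_dt.date(2019, 1, 1), _dt.date(2024, 12, 31))
    seed: int = 0

    def __post_init__(self):
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        for name in ("polarity_conflict_rate", "duplicate_rate", "bot_rate",
                     "platform_ios_share", "topic_separation"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.topic_separation == 1 and self.vocab_size < self.k_true:
            raise ValueError("disjoint topic blocks need vocab_size >= k_true")
        if self.k_true == 12:
            d_pd, d_nd = default_effects()
            if self.beta_pd_true is None:
                self.beta_pd_true = d_pd
            if self.beta_nd_true is None:
                self.beta_nd_true = d_nd
        if self.beta_pd_true is None or self.beta_nd_true is None:
            raise ValueError("beta_pd_true and beta_nd_true are required when k_true != 12")
        self.beta_pd_true = np.asarray(self.beta_pd_true, dtype=float)
        self.beta_nd_true = np.asarray(self.beta_nd_true, dtype=float)
        if self.beta_pd_true.shape != (self.k_true,) or self.beta_nd_true.shape != (self.k_true,):
            raise ValueError("effect vectors must have length k_true")


@dataclass
class GroundTruth:
    phi: np.ndarray  # k_true x V
    theta: np.ndarray  # D x k_true
    beta_pd: np.ndarray
    beta_nd: np.ndarray
    sigma: float
    app_of_doc: np.ndarray | None = None  # app index per review
    comprehensive: np.ndarray | None = None  # per app
    pd_star: np.ndarray | None = None  # censored latent deviations
    nd_star: np.ndarray | None = None
    satisfied: np.ndarray | None = None  # Bernoulli branch per review
    duplicate_ids: set[str] = field(default_factory=set)
    bot_ids: set[str] = field(default_factory=set)
    conflict_ids: set[str] = field(default_factory=set)


def _draw_phi(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    """Topic-word rows: Dirichlet draws blended toward disjoint word blocks."""
    K, V, s = cfg.k_true, cfg.vocab_size, cfg.topic_separation
    base = rng.dirichlet(np.full(V, cfg.dirichlet_eta_topic), size=K)
    if s == 0:
        return base
    bounds = np.linspace(0, V, K + 1).astype(int)
    block = np.zeros((K, V))
    for k in range(K):
        lo, hi = bounds[k], bounds[k + 1]
        block[k, lo:hi] = rng.dirichlet(np.full(hi - lo, 1.0))
    return (1 - s) * base + s * block


def generate_corpus(config: GeneratorConfig) -> tuple[ReviewDataset, GroundTruth]:
    """Draw the LDA corpus plus app/platform/date structure.

    Ratings are initialized to a placeholder (5) and are meant to be
    overwritten by :func:`generate_outcomes`; use :func:`generate_full_study`
    for the composed version.
    """
    rng = np.random.default_rng(config.seed)
    K, V, D = config.k_true, config.vocab_size, config.n_docs
    phi = _draw_phi(rng, config)
    theta = rng.dirichlet(np.full(K, config.dirichlet_alpha_doc), size=D)
    if config.doc_length_dispersion is None:
        lengths = np.maximum(rng.poisson(config.doc_length_mean, size=D), 1)
    else:
        size = config.doc_length_dispersion
        p = size / (size + config.doc_length_mean)
        lengths = np.maximum(rng.negative_binomial(size, p, size=D), 1)
    # token topics per document, then words pooled per topic for speed
    ndk = np.empty((D, K), dtype=np.int64)
    for d in range(D):
        ndk[d] = rng.multinomial(lengths[d], theta[d])
    total_per_topic = ndk.sum(axis=0)
    words_per_topic = [
        rng.choice(V, size=int(total_per_topic[k]), p=phi[k]) for k in range(K)
    ]
    cursors = np.zeros(K, dtype=np.int64)
    documents: list[np.ndarray] = []
    for d in range(D):
        parts = []
        for k in range(K):
            c = ndk[d, k]
            if c:
                parts.append(words_per_topic[k][cursors[k]: cursors[k] + c])
                cursors[k] += c
        doc = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        rng.shuffle(doc)
        documents.append(doc)

    # apps, stores, comprehensive ratings, review->app assignment (top-heavy)
    if config.comprehensive_ratings is None:
        comprehensive = np.round(rng.uniform(3.2, 4.8, size=config.n_apps), 1)
    else:
        comprehensive = np.asarray(config.comprehensive_ratings, dtype=float)
        if comprehensive.shape != (config.n_apps,):
            raise ValueError("comprehensive_ratings must have one entry per app")
    store_of_app = np.where(
        rng.random(config.n_apps) < config.platform_ios_share,
        "apple",
        rng.choice(ANDROID_STORES, size=config.n_apps),
    )
    weights = 1.0 / np.arange(1, config.n_apps + 1) ** config.app_weight_zipf
    weights /= weights.sum()
    app_of_doc = rng.choice(config.n_apps, size=D, p=weights)

    start, end = config.window
    day_span = (end - start).days
    offsets = rng.integers(0, day_span + 1, size=D)

    reviews = []
    digits = len(str(D))
    for d in range(D):
        tokens = tuple(f"w{int(w):04d}" for w in documents[d])
        reviews.append(
            Review(
                review_id=f"r{d:0{digits}d}",
                app_id=f"app{int(app_of_doc[d]):03d}",
                store=str(store_of_app[app_of_doc[d]]),
                date=start + _dt.timedelta(days=int(offsets[d])),
                rating=5,  # placeholder until outcomes are generated
                text=" ".join(tokens),
                tokens=tokens,
            )
        )
    apps = {
        f"app{a:03d}": AppRecord(
            app_id=f"app{a:03d}",
            name=f"App {a}",
            store=str(store_of_app[a]),
            comprehensive_rating=float(comprehensive[a]),
            downloads=int(1e7 * weights[a] * config.n_docs / max(config.n_docs, 1)) + 100,
        )
        for a in range(config.n_apps)
    }
    dataset = ReviewDataset(reviews=reviews, apps=apps)
    truth = GroundTruth(
        phi=phi, theta=theta,
        beta_pd=config.beta_pd_true, beta_nd=config.beta_nd_true, sigma=config.sigma_true,
        app_of_doc=app_of_doc, comprehensive=comprehensive,
    )
    return dataset, truth


def generate_outcomes(
    theta: np.ndarray,
    config: GeneratorConfig,
    comprehensive_per_review: np.ndarray | None = None,
    platform_per_review: Sequence[str] | None = None,
    mode: Literal["rating", "direct"] = "rating",
    seed: int | None = None,
) -> tuple[np.ndarray | None, DeviationOutcome, dict]:
    """Simulate the censored deviation model on given topic mixtures.

    Latent deviations are  pd* = clip(x·beta_pd + eps, 0, 4)  and
    nd* = clip(x·beta_nd + eps', 0, 4)  with x the min-max-normalized theta
    row and independent Normal(0, sigma²) errors.

    In ``direct`` mode the censored latents are returned as outcomes with
    no ratings — the clean setting for estimator testing.  In ``rating``
    mode each review is satisfied with probability p_sat (a scalar, the
    per-topic propensity of its dominant theme, or a per-platform rate) and
    its star rating is the app's comprehensive rating shifted by the
    relevant deviation, rounded and clamped to 1..5.

    Returns (ratings or None, censored DeviationOutcome, extras) where
    extras records x, the satisfaction branch, and the draw seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[0]
    x, _ = minmax_normalize(theta)
    eps = rng.normal(0.0, config.sigma_true, size=n)
    eps2 = rng.normal(0.0, config.sigma_true, size=n)
    pd_star = np.clip(x @ config.beta_pd_true + eps, 0.0, 4.0)
    nd_star = np.clip(x @ config.beta_nd_true + eps2, 0.0, 4.0)
    extras = {"x": x, "pd_star": pd_star, "nd_star": nd_star}
    if mode == "direct":
        return None, DeviationOutcome(pd=pd_star, nd=nd_star), extras
    if comprehensive_per_review is None:
        raise ValueError("rating mode needs each review's app comprehensive rating")
    c = np.asarray(comprehensive_per_review, dtype=float)
    if config.platform_satisfaction is not None:
        if platform_per_review is None:
            raise ValueError("platform_satisfaction needs per-review platforms")
        p_sat = np.asarray(
            [config.platform_satisfaction[p] for p in platform_per_review], dtype=float
        )
    elif np.ndim(config.satisfaction_prob) == 0:
        p_sat = np.full(n, float(config.satisfaction_prob))
    else:
        vec = np.asarray(config.satisfaction_prob, dtype=float)
        if vec.shape != (theta.shape[1],):
            raise ValueError("per-topic satisfaction_prob must have length k_true")
        p_sat = vec[theta.argmax(axis=1)]  # propensity of the review's dominant theme
    satisfied = rng.random(n) < p_sat
    ratings = np.where(
        satisfied,
        np.clip(np.round(c + pd_star), 1, 5),
        np.clip(np.round(c - nd_star), 1, 5),
    ).astype(int)
    extras["satisfied"] = satisfied
    return ratings, DeviationOutcome(pd=pd_star, nd=nd_star), extras


def _consistent_polarity(rating: int) -> str:
    return "positive" if rating >= 4 else ("neutral" if rating == 3 else "negative")


def _conflicting_polarity(rating: int) -> str:
    # a polarity the default alignment matrix drops for this rating
    return "negative" if rating >= 3 else "positive"


def inject_noise(
    dataset: ReviewDataset, config: GeneratorConfig, seed: int | None = None
) -> tuple[ReviewDataset, GroundTruth]:
    """Plant duplicates, bot flags, and polarity-rating conflicts.

    Duplicates are copies with fresh ids dated one day later (so the
    original is the one deduplication keeps); bot flags are set on a random
    fraction; polarity labels are consistent with the rating except for a
    conflict-rate fraction flipped to a contradicting polarity.  Every
    planted artifact is recorded in the returned flags.
    """
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    n = len(dataset)
    flags = GroundTruth(
        phi=np.empty(0), theta=np.empty(0),
        beta_pd=config.beta_pd_true, beta_nd=config.beta_nd_true, sigma=config.sigma_true,
    )
    reviews: list[Review] = []
    for i, r in enumerate(dataset.reviews):
        conflict = rng.random() < config.polarity_conflict_rate
        polarity = _conflicting_polarity(r.rating) if conflict else _consistent_polarity(r.rating)
        bot = bool(rng.random() < config.bot_rate)
        rid = r.review_id
        if conflict:
            flags.conflict_ids.add(rid)
        if bot:
            flags.bot_ids.add(rid)
        reviews.append(
            Review(
                review_id=rid, app_id=r.app_id, store=r.store, date=r.date,
                rating=r.rating, text=r.text, tokens=r.tokens,
                polarity=polarity, bot_flag=bot,
            )
        )
    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        end = config.window[1]
        dup_sources = rng.choice(n, size=n_dup, replace=False)
        for j, src in enumerate(dup_sources):
            orig = reviews[int(src)]
            rid = f"{orig.review_id}_dup{j}"
            flags.duplicate_ids.add(rid)
            # the copy inherits the original's contamination status
            if orig.bot_flag:
                flags.bot_ids.add(rid)
            if orig.review_id in flags.conflict_ids:
                flags.conflict_ids.add(rid)
            reviews.append(
                Review(
                    review_id=rid, app_id=orig.app_id, store=orig.store,
                    date=min(orig.date + _dt.timedelta(days=1), end),
                    rating=orig.rating, text=orig.text, tokens=orig.tokens,
                    polarity=orig.polarity, bot_flag=orig.bot_flag,
                )
            )
    out = ReviewDataset(reviews=reviews, apps=dataset.apps)
    return out, flags


def generate_full_study(config: GeneratorConfig) -> tuple[ReviewDataset, GroundTruth]:
    """Corpus + outcomes + contamination: the full end-to-end study fixture."""
    dataset, truth = generate_corpus(config)
    comp_per_review = truth.comprehensive[truth.app_of_doc]
    platforms = [r.platform for r in dataset.reviews]
    ratings, dev, extras = generate_outcomes(
        truth.theta, config,
        comprehensive_per_review=comp_per_review,
        platform_per_review=platforms,
        mode="rating",
        seed=config.seed + 1_000_003,
    )
    reviews = [
        Review(
            review_id=r.review_id, app_id=r.app_id, store=r.store, date=r.date,
            rating=int(ratings[i]), text=r.text, tokens=r.tokens,
        )
        for i, r in enumerate(dataset.reviews)
    ]
    dataset = ReviewDataset(reviews=reviews, apps=dataset.apps)
    truth.pd_star, truth.nd_star = dev.pd, dev.nd
    truth.satisfied = extras["satisfied"]
    dataset, flags = inject_noise(dataset, config, seed=config.seed + 2_000_003)
    truth.duplicate_ids = flags.duplicate_ids
    truth.bot_ids = flags.bot_ids
    truth.conflict_ids = flags.conflict_ids
    return dataset, truth
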