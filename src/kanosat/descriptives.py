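"""Descriptive surfaces: satisfaction rates, topic share tables,
market-concentration shares, and screening agreement.

All percentages are reported rounded half-up to 2 decimals (the convention
of published summary tables) with the raw unrounded value alongside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ReviewDataset
from .kano import DEFAULT_SATISFACTION_THRESHOLD
from .lda import Corpus, LdaFit

__all__ = [
    "Percentage",
    "satisfaction_rate",
    "group_rates",
    "share_table",
    "share_table_from_counts",
    "concentration",
    "cohen_kappa",
]


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Percentage:
    """A percentage as reported (2 decimals, half-up) plus its raw value."""

    value: float
    raw: float

    def __float__(self) -> float:
        return self.value


def satisfaction_rate(
    ratings: Sequence[int] | None = None,
    threshold: int = DEFAULT_SATISFACTION_THRESHOLD,
    as_counts: tuple[int, int] | None = None,
) -> Percentage:
    """Share of ratings at or above ``threshold`` stars, as a percentage.

    ``as_counts=(satisfied, total)`` bypasses the rating list, which also
    makes this the generic printed-proportion helper (e.g. apps retained
    out of apps screened).
    """
    if as_counts is not None:
        satisfied, total = as_counts
    else:
        if ratings is None or len(ratings) == 0:
            raise ValueError("no ratings given")
        arr = np.asarray(ratings)
        satisfied, total = int(np.sum(arr >= threshold)), arr.size
    if total <= 0:
        raise ValueError("total must be positive")
    raw = 100.0 * satisfied / total
    return Percentage(value=_round2(raw), raw=raw)


def group_rates(
    dataset: ReviewDataset,
    by: str = "platform",
    threshold: int = DEFAULT_SATISFACTION_THRESHOLD,
) -> pd.DataFrame:
    """Per-group satisfaction rate and review count.

    ``by`` is one of platform, year, platform_year.  Empty groups simply do
    not appear.  Returns a DataFrame indexed by group key with columns
    n_reviews and satisfaction_rate (2-decimal percentage).
    """
    if by not in ("platform", "year", "platform_year"):
        raise ValueError("by must be 'platform', 'year' or 'platform_year'")

    def key(r):
        if by == "platform":
            return r.platform
        if by == "year":
            return r.date.year
        return (r.platform, r.date.year)

    groups: dict = {}
    for r in dataset.reviews:
        groups.setdefault(key(r), []).append(r.rating)
    rows = []
    for g in sorted(groups, key=str):
        rate = satisfaction_rate(groups[g], threshold)
        rows.append({"group": g, "n_reviews": len(groups[g]),
                     "satisfaction_rate": rate.value, "satisfaction_rate_raw": rate.raw})
    return pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame(
        columns=["n_reviews", "satisfaction_rate", "satisfaction_rate_raw"]
    )


def share_table_from_counts(
    token_counts: Sequence[int],
    review_counts: Sequence[int],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Topic share table from per-topic token and review tallies.

    corpus_share is each topic's percentage of all token assignments,
    review_share its percentage of all reviews (by best topic); both
    rounded half-up to 2 decimals, raw values alongside.
    """
    token_counts = np.asarray(token_counts, dtype=np.int64)
    review_counts = np.asarray(review_counts, dtype=np.int64)
    if token_counts.shape != review_counts.shape:
        raise ValueError("token and review counts must be aligned")
    if labels is None:
        labels = [f"topic_{k}" for k in range(len(token_counts))]
    tok_total = token_counts.sum()
    rev_total = review_counts.sum()
    if tok_total <= 0 or rev_total <= 0:
        raise ValueError("counts must not all be zero")
    rows = []
    for lab, tok, rev in zip(labels, token_counts, review_counts):
        rows.append(
            {
                "topic": lab,
                "corpus_tokens": int(tok),
                "corpus_share": _round2(100.0 * tok / tok_total),
                "corpus_share_raw": 100.0 * tok / tok_total,
                "n_reviews": int(rev),
                "review_share": _round2(100.0 * rev / rev_total),
                "review_share_raw": 100.0 * rev / rev_total,
            }
        )
    return pd.DataFrame(rows).set_index("topic")


def share_table(
    fit: LdaFit, corpus: Corpus, best_topics: Sequence[int],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Topic share table from a fitted model.

    Token mass per topic is the final Gibbs assignment tally; review counts
    come from each review's best topic, so the review column always sums to
    the number of topic-modeled reviews.
    """
    best = np.asarray(best_topics)
    if best.shape[0] != corpus.n_docs:
        raise ValueError("best_topics must have one entry per document")
    review_counts = np.bincount(best, minlength=fit.k)
    return share_table_from_counts(fit.topic_token_counts, review_counts, labels)


def concentration(values: Iterable[float], top_n: int) -> Percentage:
    """Share of the total held by the ``top_n`` largest values (market concentration)."""
    arr = np.sort(np.asarray(list(values), dtype=float))[::-1]
    if np.any(arr < 0):
        raise ValueError("values must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("values must not all be zero")
    if not (0 < top_n <= arr.size):
        raise ValueError("top_n must lie in 1..len(values)")
    raw = 100.0 * arr[:top_n].sum() / total
    return Percentage(value=_round2(raw), raw=raw)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two raters' categorical decisions.

    kappa = (p_o − p_e) / (1 − p_e) with p_e from the marginal products.
    When both raters are constant and identical (p_e = 1) agreement is
    perfect by convention: kappa = 1.
    """
    if len(labels_a) != len(labels_b) or len(labels_a) == 0:
        raise ValueError("label vectors must be non-empty and of equal length")
    n = len(labels_a)
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    p_e = sum(ca[c] * cb.get(c, 0) for c in ca) / (n * n)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)
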