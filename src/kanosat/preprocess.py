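"""Cleaning the review stream before topic modeling.

The pipeline order is fixed and auditable: study-window filter, bot filter,
duplicate removal, blank/invalid removal, sentiment–rating consistency
filter, tokenization with stopword removal.  Each stage returns a report
whose removal counts reconcile exactly with the input size, and every
filter is idempotent.

The sentiment–rating consistency filter drops reviews whose precomputed
sentiment polarity contradicts the star rating (e.g. a "negative" 5-star
review), on the view that such reviews are noise for a satisfaction
analysis.  Which (polarity, stars) cells count as aligned is a 15-cell
alignment matrix, fully configurable; the shipped default keeps positive
polarity only at 4–5 stars, negative only at 1–2, and neutral only at 3.
"""

from __future__ import annotations

import datetime as _dt
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping

from .io import POLARITIES, Review, ReviewDataset

__all__ = [
    "AlignmentMatrix",
    "PreprocessReport",
    "default_alignment_matrix",
    "default_stopwords",
    "whitespace_tokenizer",
    "filter_window",
    "filter_bots",
    "deduplicate",
    "filter_invalid",
    "sentiment_consistency_filter",
    "tokenize",
    "run_preprocess",
]

Tokenizer = Callable[[str], list[str]]

#: study window used throughout: 2019-01-01 .. 2024-12-31
DEFAULT_WINDOW = (_dt.date(2019, 1, 1), _dt.date(2024, 12, 31))

RATINGS = (1, 2, 3, 4, 5)


class AlignmentMatrix:
    """Mapping (polarity, star rating) -> keep/drop; all 15 cells must be set."""

    def __init__(self, keep: Mapping[tuple[str, int], bool]):
        cells = {(p, r) for p in POLARITIES for r in RATINGS}
        missing = cells - set(keep)
        extra = set(keep) - cells
        if missing or extra:
            raise ValueError(
                f"alignment matrix must define exactly the 15 (polarity, rating) cells; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for r in RATINGS:
            if not any(keep[(p, r)] for p in POLARITIES):
                raise ValueError(f"rating {r} has no keep cell; every rating needs at least one")
        self._keep = dict(keep)

    def keeps(self, polarity: str, rating: int) -> bool:
        return self._keep[(polarity, rating)]

    def as_dict(self) -> dict[tuple[str, int], bool]:
        return dict(self._keep)

    @classmethod
    def from_config(cls, spec: Mapping[str, Iterable[int]]) -> "AlignmentMatrix":
        """Build from {"positive": [4,5], "neutral": [3], "negative": [1,2]}."""
        keep = {(p, r): False for p in POLARITIES for r in RATINGS}
        for polarity, ratings in spec.items():
            for r in ratings:
                keep[(polarity, int(r))] = True
        return cls(keep)


def default_alignment_matrix() -> AlignmentMatrix:
    return AlignmentMatrix.from_config(
        {"positive": [4, 5], "neutral": [3], "negative": [1, 2]}
    )


@dataclass
class PreprocessReport:
    """Removal tallies per reason; ``retained + sum(removed) == input``."""

    input_size: int = 0
    retained: int = 0
    out_of_window: int = 0
    bot: int = 0
    duplicate: int = 0
    blank_or_invalid: int = 0
    polarity_conflict: int = 0
    unlabeled_polarity: int = 0  # informational: passed through, not removed
    zero_token: int = 0  # informational: flagged for topic-model exclusion
    stages: list[str] = field(default_factory=list)

    @property
    def removed_total(self) -> int:
        return (
            self.out_of_window
            + self.bot
            + self.duplicate
            + self.blank_or_invalid
            + self.polarity_conflict
        )

    def check(self) -> None:
        assert self.retained + self.removed_total == self.input_size, (
            f"report does not reconcile: {self.retained} + {self.removed_total} "
            f"!= {self.input_size}"
        )

    def merge(self, other: "PreprocessReport") -> "PreprocessReport":
        out = PreprocessReport(input_size=self.input_size, retained=other.retained)
        for reason in (
            "out_of_window",
            "bot",
            "duplicate",
            "blank_or_invalid",
            "polarity_conflict",
            "unlabeled_polarity",
            "zero_token",
        ):
            setattr(out, reason, getattr(self, reason) + getattr(other, reason))
        out.stages = self.stages + other.stages
        return out

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "retained": self.retained,
            "removed": {
                "out_of_window": self.out_of_window,
                "bot": self.bot,
                "duplicate": self.duplicate,
                "blank_or_invalid": self.blank_or_invalid,
                "polarity_conflict": self.polarity_conflict,
            },
            "unlabeled_polarity": self.unlabeled_polarity,
            "zero_token": self.zero_token,
            "stages": self.stages,
        }


def _subset(dataset: ReviewDataset, reviews: list[Review]) -> ReviewDataset:
    return ReviewDataset(reviews=reviews, apps=dataset.apps)


def filter_window(
    dataset: ReviewDataset,
    start: _dt.date = DEFAULT_WINDOW[0],
    end: _dt.date = DEFAULT_WINDOW[1],
) -> tuple[ReviewDataset, PreprocessReport]:
    """Drop reviews dated outside [start, end] (inclusive)."""
    kept = [r for r in dataset.reviews if start <= r.date <= end]
    report = PreprocessReport(
        input_size=len(dataset),
        retained=len(kept),
        out_of_window=len(dataset) - len(kept),
        stages=["window"],
    )
    report.check()
    return _subset(dataset, kept), report


def filter_bots(dataset: ReviewDataset) -> tuple[ReviewDataset, PreprocessReport]:
    """Remove reviews with ``bot_flag`` true; unflagged reviews pass through."""
    kept = [r for r in dataset.reviews if not r.bot_flag]
    report = PreprocessReport(
        input_size=len(dataset), retained=len(kept), bot=len(dataset) - len(kept),
        stages=["bots"],
    )
    report.check()
    return _subset(dataset, kept), report


_WS = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """NFKC + whitespace collapse: the duplicate-detection normal form."""
    return _WS.sub(" ", unicodedata.normalize("NFKC", text)).strip()


def deduplicate(dataset: ReviewDataset) -> tuple[ReviewDataset, PreprocessReport]:
    """Keep one review per (app_id, rating, normalized text) key.

    The earliest-dated copy survives; date ties go to the lexicographically
    smallest review_id, so the outcome is order-independent.
    """
    best: dict[tuple[str, int, str], Review] = {}
    for r in dataset.reviews:
        key = (r.app_id, r.rating, normalize_text(r.text))
        cur = best.get(key)
        if cur is None or (r.date, r.review_id) < (cur.date, cur.review_id):
            best[key] = r
    keep_ids = {r.review_id for r in best.values()}
    kept = [r for r in dataset.reviews if r.review_id in keep_ids]
    report = PreprocessReport(
        input_size=len(dataset), retained=len(kept), duplicate=len(dataset) - len(kept),
        stages=["dedup"],
    )
    report.check()
    return _subset(dataset, kept), report


def _word_chars(text: str) -> int:
    # letters and digits in any script; emoji, punctuation, symbols excluded
    return sum(1 for ch in text if unicodedata.category(ch)[0] in ("L", "N"))


def filter_invalid(
    dataset: ReviewDataset, min_chars: int = 2
) -> tuple[ReviewDataset, PreprocessReport]:
    """Remove blank reviews and those made only of emojis/punctuation.

    A review survives iff its text contains at least ``min_chars`` word
    characters (Unicode letters or digits) after stripping everything else.
    """
    if min_chars < 1:
        raise ValueError("min_chars must be >= 1")
    kept = [r for r in dataset.reviews if _word_chars(r.text) >= min_chars]
    report = PreprocessReport(
        input_size=len(dataset),
        retained=len(kept),
        blank_or_invalid=len(dataset) - len(kept),
        stages=["invalid"],
    )
    report.check()
    return _subset(dataset, kept), report


def sentiment_consistency_filter(
    dataset: ReviewDataset, matrix: AlignmentMatrix | None = None
) -> tuple[ReviewDataset, PreprocessReport]:
    """Drop reviews whose polarity label contradicts their star rating.

    Reviews without a polarity label pass through untouched and are counted
    separately in the report.
    """
    matrix = matrix or default_alignment_matrix()
    kept: list[Review] = []
    unlabeled = 0
    for r in dataset.reviews:
        if r.polarity is None:
            unlabeled += 1
            kept.append(r)
        elif matrix.keeps(r.polarity, r.rating):
            kept.append(r)
    report = PreprocessReport(
        input_size=len(dataset),
        retained=len(kept),
        polarity_conflict=len(dataset) - len(kept),
        unlabeled_polarity=unlabeled,
        stages=["polarity"],
    )
    report.check()
    return _subset(dataset, kept), report


def whitespace_tokenizer(text: str) -> list[str]:
    return text.split()


def default_stopwords() -> frozenset[str]:
    """The small shipped stopword list (one token per line, '#' comments)."""
    raw = resources.files("kanosat.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in raw.splitlines() if line.strip() and not line.startswith("#")
    )


def load_stopwords(path) -> frozenset[str]:
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )


def tokenize(
    dataset: ReviewDataset,
    tokenizer: Tokenizer = whitespace_tokenizer,
    stopwords: Iterable[str] = frozenset(),
) -> tuple[ReviewDataset, PreprocessReport]:
    """Attach a token list (stopwords removed) to every review.

    Reviews left with zero tokens keep an empty tuple — the flag telling
    the corpus builder to exclude them from topic modeling.
    """
    stop = frozenset(stopwords)
    out: list[Review] = []
    zero = 0
    for r in dataset.reviews:
        tokens = [t for t in tokenizer(r.text) if t not in stop]
        if not tokens:
            zero += 1
        out.append(r.with_tokens(tokens))
    report = PreprocessReport(
        input_size=len(dataset), retained=len(out), zero_token=zero, stages=["tokenize"]
    )
    report.check()
    return _subset(dataset, out), report


def run_preprocess(
    dataset: ReviewDataset,
    *,
    window: tuple[_dt.date, _dt.date] | None = DEFAULT_WINDOW,
    matrix: AlignmentMatrix | None = None,
    min_chars: int = 2,
    tokenizer: Tokenizer = whitespace_tokenizer,
    stopwords: Iterable[str] | None = None,
) -> tuple[ReviewDataset, PreprocessReport]:
    """Run the full fixed-order cleaning pipeline and reconcile the report."""
    report = PreprocessReport(input_size=len(dataset), retained=len(dataset))
    if window is not None:
        dataset, r = filter_window(dataset, *window)
        report = report.merge(r)
    dataset, r = filter_bots(dataset)
    report = report.merge(r)
    dataset, r = deduplicate(dataset)
    report = report.merge(r)
    dataset, r = filter_invalid(dataset, min_chars=min_chars)
    report = report.merge(r)
    dataset, r = sentiment_consistency_filter(dataset, matrix)
    report = report.merge(r)
    dataset, r = tokenize(
        dataset, tokenizer, default_stopwords() if stopwords is None else stopwords
    )
    report = report.merge(r)
    report.check()
    return dataset, report
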