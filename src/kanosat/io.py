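"""Review and app records: the shared data model and its JSONL/CSV round trip.

The study unit is a dated, star-rated app-store review attached to an app
with a store-level comprehensive rating.  JSONL (one review object per
line, UTF-8) is the canonical on-disk format because review text freely
contains commas and newlines; CSV is an alias with a documented column
order.  ``platform`` is always derived from ``store`` and never stored, so
the two can never disagree.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Review",
    "AppRecord",
    "ReviewDataset",
    "SchemaError",
    "STORES",
    "store_platform",
    "read_reviews",
    "write_reviews",
    "read_apps",
    "write_apps",
    "attach_apps",
]

STORES = ("apple", "huawei", "xiaomi", "vivo", "oppo", "other")

#: mainland-China store -> operating system. Only Apple distributes iOS
#: apps; every other store (including the catch-all "other") is Android,
#: since Google Play is not a data source here.
_STORE_PLATFORM = {
    "apple": "ios",
    "huawei": "android",
    "xiaomi": "android",
    "vivo": "android",
    "oppo": "android",
    "other": "android",
}

POLARITIES = ("positive", "neutral", "negative")

REVIEW_COLUMNS = (
    "review_id",
    "app_id",
    "store",
    "date",
    "rating",
    "text",
    "tokens",
    "polarity",
    "bot_flag",
)

APP_COLUMNS = ("app_id", "name", "store", "comprehensive_rating", "downloads", "category")


class SchemaError(ValueError):
    """A record violated the documented schema; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


def store_platform(store: str) -> str:
    """Operating system implied by the store a review was posted in."""
    try:
        return _STORE_PLATFORM[store]
    except KeyError:
        raise SchemaError(f"unknown store {store!r}; expected one of {STORES}") from None


@dataclass(frozen=True)
class Review:
    review_id: str
    app_id: str
    store: str
    date: _dt.date
    rating: int
    text: str
    tokens: tuple[str, ...] | None = None
    polarity: str | None = None
    bot_flag: bool | None = None

    @property
    def platform(self) -> str:
        return store_platform(self.store)

    def validate(self, row: int | None = None) -> None:
        if self.store not in STORES:
            raise SchemaError(f"unknown store {self.store!r}", row)
        if not isinstance(self.rating, int) or self.rating not in (1, 2, 3, 4, 5):
            raise SchemaError(f"rating must be an integer in 1..5, got {self.rating!r}", row)
        if not isinstance(self.date, _dt.date):
            raise SchemaError(f"date must be a calendar date, got {self.date!r}", row)
        if self.polarity is not None and self.polarity not in POLARITIES:
            raise SchemaError(f"unknown polarity {self.polarity!r}", row)

    def with_tokens(self, tokens: Sequence[str]) -> "Review":
        return replace(self, tokens=tuple(tokens))


@dataclass(frozen=True)
class AppRecord:
    app_id: str
    name: str
    store: str
    comprehensive_rating: float
    downloads: int
    category: str | None = None

    def validate(self, row: int | None = None) -> None:
        if self.store not in STORES:
            raise SchemaError(f"unknown store {self.store!r}", row)
        if not (1.0 <= float(self.comprehensive_rating) <= 5.0):
            raise SchemaError(
                f"comprehensive_rating must lie in [1, 5], got {self.comprehensive_rating!r}", row
            )
        if int(self.downloads) < 0:
            raise SchemaError(f"downloads must be non-negative, got {self.downloads!r}", row)


@dataclass
class ReviewDataset:
    """Reviews plus the app registry they resolve against.

    The registry may be empty (reviews-only workflows); when present every
    ``review.app_id`` must resolve and review ids must be unique.
    """

    reviews: list[Review] = field(default_factory=list)
    apps: dict[str, AppRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reviews)

    def validate(self) -> None:
        seen: set[str] = set()
        for i, r in enumerate(self.reviews):
            r.validate(row=i)
            if r.review_id in seen:
                raise SchemaError(f"duplicate review_id {r.review_id!r}", i)
            seen.add(r.review_id)
            if self.apps and r.app_id not in self.apps:
                raise SchemaError(f"review {r.review_id!r} references unknown app {r.app_id!r}", i)

    def comprehensive_for(self, review: Review) -> float:
        return self.apps[review.app_id].comprehensive_rating


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_date(value, row: int) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError:
        raise SchemaError(f"date {value!r} is not ISO-8601", row) from None


def _parse_rating(value, row: int) -> int:
    # no silent coercion: "4.5" or 4.5 is a schema error, "4" is accepted
    if isinstance(value, bool):
        raise SchemaError(f"rating must be an integer in 1..5, got {value!r}", row)
    if isinstance(value, float) and not value.is_integer():
        raise SchemaError(f"rating must be an integer in 1..5, got {value!r}", row)
    try:
        as_int = int(str(value))
    except ValueError:
        raise SchemaError(f"rating must be an integer in 1..5, got {value!r}", row) from None
    if as_int not in (1, 2, 3, 4, 5):
        raise SchemaError(f"rating must be an integer in 1..5, got {value!r}", row)
    return as_int


def _parse_bool(value, row: int) -> bool | None:
    if value is None or value == "":
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1"):
        return True
    if text in ("false", "0"):
        return False
    raise SchemaError(f"bot_flag {value!r} is not a boolean", row)


def _review_from_mapping(obj: dict, row: int) -> Review:
    for fieldname in ("review_id", "app_id", "store", "date", "rating", "text"):
        if fieldname not in obj or obj[fieldname] is None:
            raise SchemaError(f"missing required field {fieldname!r}", row)
    tokens = obj.get("tokens")
    if tokens is not None and not isinstance(tokens, (list, tuple)):
        raise SchemaError(f"tokens must be a list, got {tokens!r}", row)
    polarity = obj.get("polarity") or None
    review = Review(
        review_id=str(obj["review_id"]),
        app_id=str(obj["app_id"]),
        store=str(obj["store"]),
        date=_parse_date(obj["date"], row),
        rating=_parse_rating(obj["rating"], row),
        text=str(obj["text"]),
        tokens=tuple(tokens) if tokens is not None else None,
        polarity=polarity,
        bot_flag=_parse_bool(obj.get("bot_flag"), row),
    )
    review.validate(row)
    return review


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("jsonl", "csv"):
            raise ValueError(f"format must be 'jsonl' or 'csv', got {format!r}")
        return format
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def read_reviews(path, format: str | None = None) -> ReviewDataset:
    """Read reviews from JSONL (canonical) or CSV into a validated dataset.

    Any row violating the schema raises :class:`SchemaError` naming the
    offending row; nothing is silently coerced or dropped.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    reviews: list[Review] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"invalid JSON: {exc}", i) from None
                reviews.append(_review_from_mapping(obj, i))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return ReviewDataset()
            for i, rec in enumerate(reader):
                # empty string means absent, except text (a required field
                # that may legitimately be empty) and the JSON tokens column
                obj = {k: v for k, v in rec.items() if v not in (None, "")}
                if "text" in rec and rec["text"] is not None:
                    obj["text"] = rec["text"]
                if "tokens" in obj:
                    try:
                        obj["tokens"] = json.loads(obj["tokens"])
                    except json.JSONDecodeError:
                        raise SchemaError("tokens column is not a JSON list", i) from None
                reviews.append(_review_from_mapping(obj, i))
    dataset = ReviewDataset(reviews=reviews)
    dataset.validate()
    return dataset


def write_reviews(dataset: ReviewDataset, path, format: str | None = None) -> None:
    """Write reviews so that ``read_reviews`` reproduces them field-for-field."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in dataset.reviews:
                obj = {
                    "review_id": r.review_id,
                    "app_id": r.app_id,
                    "store": r.store,
                    "date": r.date.isoformat(),
                    "rating": r.rating,
                    "text": r.text,
                }
                if r.tokens is not None:
                    obj["tokens"] = list(r.tokens)
                if r.polarity is not None:
                    obj["polarity"] = r.polarity
                if r.bot_flag is not None:
                    obj["bot_flag"] = r.bot_flag
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=REVIEW_COLUMNS)
            writer.writeheader()
            for r in dataset.reviews:
                writer.writerow(
                    {
                        "review_id": r.review_id,
                        "app_id": r.app_id,
                        "store": r.store,
                        "date": r.date.isoformat(),
                        "rating": r.rating,
                        "text": r.text,
                        "tokens": json.dumps(list(r.tokens), ensure_ascii=False)
                        if r.tokens is not None else "",
                        "polarity": r.polarity or "",
                        "bot_flag": "" if r.bot_flag is None else str(r.bot_flag).lower(),
                    }
                )


def read_apps(path) -> list[AppRecord]:
    """Read the app registry CSV: app_id,name,store,comprehensive_rating,downloads,category."""
    path = Path(path)
    apps: list[AppRecord] = []
    with path.open(encoding="utf-8", newline="") as fh:
        for i, rec in enumerate(csv.DictReader(fh)):
            for fieldname in ("app_id", "name", "store", "comprehensive_rating", "downloads"):
                if not rec.get(fieldname):
                    raise SchemaError(f"missing required field {fieldname!r}", i)
            try:
                rating = float(rec["comprehensive_rating"])
                downloads = int(rec["downloads"])
            except ValueError as exc:
                raise SchemaError(str(exc), i) from None
            app = AppRecord(
                app_id=rec["app_id"],
                name=rec["name"],
                store=rec["store"],
                comprehensive_rating=rating,
                downloads=downloads,
                category=rec.get("category") or None,
            )
            app.validate(i)
            apps.append(app)
    return apps


def write_apps(apps: Iterable[AppRecord], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=APP_COLUMNS)
        writer.writeheader()
        for a in apps:
            writer.writerow(
                {
                    "app_id": a.app_id,
                    "name": a.name,
                    "store": a.store,
                    "comprehensive_rating": repr(a.comprehensive_rating),
                    "downloads": a.downloads,
                    "category": a.category or "",
                }
            )


def attach_apps(
    reviews: Sequence[Review], apps: Sequence[AppRecord]
) -> tuple[ReviewDataset, list[Review]]:
    """Join reviews to the app registry.

    Returns the validated dataset plus the orphan reviews whose ``app_id``
    did not resolve (reported, not silently dropped into the dataset).
    Duplicate app ids in the registry are an error.
    """
    registry: dict[str, AppRecord] = {}
    for a in apps:
        if a.app_id in registry:
            raise SchemaError(f"duplicate app_id {a.app_id!r} in app registry")
        a.validate()
        registry[a.app_id] = a
    matched = [r for r in reviews if r.app_id in registry]
    orphans = [r for r in reviews if r.app_id not in registry]
    dataset = ReviewDataset(reviews=matched, apps=registry)
    dataset.validate()
    return dataset, orphans
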