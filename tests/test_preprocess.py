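import datetime as dt

import numpy as np
import pytest

from kanosat import preprocess
from kanosat.preprocess import (
    AlignmentMatrix,
    default_alignment_matrix,
    deduplicate,
    filter_bots,
    filter_invalid,
    filter_window,
    run_preprocess,
    sentiment_consistency_filter,
    tokenize,
)
from kanosat.simulate import GeneratorConfig, generate_full_study

from conftest import make_dataset, make_review


def test_filter_bots_removes_flagged_keeps_unflagged():
    reviews = [make_review(f"r{i}", bot_flag=(i < 3)) for i in range(10)]
    ds, report = filter_bots(make_dataset(reviews))
    assert len(ds) == 7 and report.bot == 3
    # no flags present -> identity; all flagged -> empty
    ds2, rep2 = filter_bots(make_dataset([make_review("x")]))
    assert len(ds2) == 1 and rep2.bot == 0
    ds3, rep3 = filter_bots(make_dataset([make_review("y", bot_flag=True)]))
    assert len(ds3) == 0 and rep3.bot == 1


def test_deduplicate_keeps_earliest_and_distinguishes_apps():
    a = make_review("rA", date=dt.date(2020, 1, 5), text="same  text")
    b = make_review("rB", date=dt.date(2020, 1, 1), text="same text")  # earlier, ws differs
    c = make_review("rC", app_id="other_app", store="huawei", text="same text")
    ds, report = deduplicate(make_dataset([a, b, c]))
    kept = {r.review_id for r in ds.reviews}
    assert kept == {"rB", "rC"} and report.duplicate == 1


def test_deduplicate_tie_breaks_by_review_id():
    d = dt.date(2020, 1, 1)
    a = make_review("r2", date=d, text="t")
    b = make_review("r1", date=d, text="t")
    ds, _ = deduplicate(make_dataset([a, b]))
    assert [r.review_id for r in ds.reviews] == ["r1"]


@pytest.mark.parametrize(
    "text,min_chars,kept",
    [
        ("!!!😊😊", 2, False),  # emojis/punctuation only
        ("好用", 1, True),
        ("", 1, False),
        ("a", 2, False),
        ("ab!", 2, True),
    ],
)
def test_filter_invalid_counts_word_characters(text, min_chars, kept):
    ds, _ = filter_invalid(make_dataset([make_review(text=text)]), min_chars=min_chars)
    assert (len(ds) == 1) is kept


def test_alignment_matrix_must_cover_all_cells():
    with pytest.raises(ValueError, match="15"):
        AlignmentMatrix({("positive", 5): True})
    with pytest.raises(ValueError, match="no keep cell"):
        AlignmentMatrix.from_config({"positive": [4, 5], "neutral": [3], "negative": [1]})


def test_sentiment_filter_default_matrix():
    keep = make_review("k", rating=5, polarity="positive")
    drop = make_review("d", rating=5, polarity="negative")
    unlabeled = make_review("u", rating=5)
    ds, report = sentiment_consistency_filter(make_dataset([keep, drop, unlabeled]))
    assert {r.review_id for r in ds.reviews} == {"k", "u"}
    assert report.polarity_conflict == 1 and report.unlabeled_polarity == 1


def test_tokenize_removes_stopwords_and_flags_empty():
    ds0 = make_dataset(
        [make_review("r0", text="good app good"), make_review("r1", text="app app")]
    )
    ds, report = tokenize(ds0, stopwords={"app"})
    assert ds.reviews[0].tokens == ("good", "good")
    assert ds.reviews[1].tokens == ()
    assert report.zero_token == 1


def test_window_filter_inclusive_bounds():
    inside = make_review("in", date=dt.date(2019, 1, 1))
    outside = make_review("out", date=dt.date(2018, 12, 31))
    ds, report = filter_window(make_dataset([inside, outside]))
    assert [r.review_id for r in ds.reviews] == ["in"] and report.out_of_window == 1


@pytest.mark.parametrize(
    "stage",
    [filter_bots, deduplicate, lambda d: filter_invalid(d, 2),
     sentiment_consistency_filter, filter_window],
)
def test_filters_are_idempotent(stage):
    reviews = [
        make_review("r0", rating=5, polarity="negative", bot_flag=True,
                    date=dt.date(2018, 1, 1), text="!!"),
        make_review("r1", rating=5, polarity="positive", text="fine app"),
        make_review("r2", rating=5, polarity="positive", text="fine app",
                    date=dt.date(2021, 1, 1)),
        make_review("r3", rating=2, polarity="negative", text="bad login"),
    ]
    once, _ = stage(make_dataset(reviews))
    twice, rep = stage(once)
    assert [r.review_id for r in twice.reviews] == [r.review_id for r in once.reviews]
    assert rep.removed_total == 0


def test_full_pipeline_reconciles_counts():
    cfg = GeneratorConfig(n_docs=400, vocab_size=100, doc_length_mean=10, n_apps=5,
                          duplicate_rate=0.1, bot_rate=0.1, polarity_conflict_rate=0.2, seed=3)
    ds, truth = generate_full_study(cfg)
    clean, report = run_preprocess(ds)
    report.check()
    assert report.input_size == len(ds)
    assert report.retained == len(clean)
    assert report.bot > 0 and report.duplicate > 0 and report.polarity_conflict > 0


def test_planted_bots_and_duplicates_removed_exactly():
    """The flag ground truth and the filters agree review-for-review."""
    cfg = GeneratorConfig(n_docs=1000, vocab_size=200, doc_length_mean=15, n_apps=10,
                          duplicate_rate=0.10, bot_rate=0.12, polarity_conflict_rate=0.0,
                          seed=9)
    ds, truth = generate_full_study(cfg)
    no_bots, rep_b = filter_bots(ds)
    removed = {r.review_id for r in ds.reviews} - {r.review_id for r in no_bots.reviews}
    assert removed == truth.bot_ids
    deduped, rep_d = deduplicate(ds)
    surviving = {r.review_id for r in deduped.reviews}
    # every planted copy loses to its earlier-dated original
    assert truth.duplicate_ids & surviving == set()
    assert rep_d.duplicate >= len(truth.duplicate_ids)


def test_planted_conflict_fraction_is_binomial_consistent():
    rate = 0.2
    n = 4000
    cfg = GeneratorConfig(n_docs=n, vocab_size=200, doc_length_mean=15, n_apps=10,
                          duplicate_rate=0.0, bot_rate=0.0, polarity_conflict_rate=rate,
                          seed=21)
    ds, truth = generate_full_study(cfg)
    _, report = sentiment_consistency_filter(ds)
    se = np.sqrt(rate * (1 - rate) / n)
    assert abs(report.polarity_conflict / n - rate) < 2 * se
    # conflict-labelled reviews are exactly the removed set
    assert report.polarity_conflict == len(truth.conflict_ids)


def test_conflict_rate_one_removes_every_labeled_review():
    cfg = GeneratorConfig(n_docs=200, vocab_size=100, doc_length_mean=10, n_apps=4,
                          duplicate_rate=0.0, bot_rate=0.0, polarity_conflict_rate=1.0,
                          seed=2)
    ds, _ = generate_full_study(cfg)
    out, report = sentiment_consistency_filter(ds)
    assert len(out) == 0 and report.polarity_conflict == len(ds)
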