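import datetime as dt

import numpy as np
import pytest

from kanosat.io import AppRecord, Review, ReviewDataset


def make_review(
    review_id="r0",
    app_id="a0",
    store="apple",
    date=dt.date(2020, 6, 1),
    rating=5,
    text="good app",
    tokens=None,
    polarity=None,
    bot_flag=None,
):
    return Review(
        review_id=review_id, app_id=app_id, store=store, date=date, rating=rating,
        text=text, tokens=tokens, polarity=polarity, bot_flag=bot_flag,
    )


def make_dataset(reviews, apps=None):
    if apps is None:
        apps = {}
        for r in reviews:
            apps[r.app_id] = AppRecord(
                app_id=r.app_id, name=r.app_id, store=r.store,
                comprehensive_rating=4.0, downloads=1000,
            )
    return ReviewDataset(reviews=list(reviews), apps=apps)


@pytest.fixture
def tiny_dataset():
    reviews = [
        make_review("r0", rating=5, text="great tracker calendar"),
        make_review("r1", rating=1, text="crashes on login always"),
        make_review("r2", rating=3, text="okay but ads everywhere"),
    ]
    return make_dataset(reviews)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
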