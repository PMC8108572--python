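from datetime import date

import pandas as pd
import pytest

from tweetphases.io_ingest import TweetRecord


def make_record(
    rec_id="t1",
    day="2020-01-01",
    hour=12,
    text="corona update",
    user="u1",
    is_retweet=False,
    retweet_count=0,
):
    return TweetRecord(
        id=rec_id,
        timestamp=pd.Timestamp(day) + pd.Timedelta(hours=hour),
        text=text,
        user_id=user,
        is_retweet=is_retweet,
        retweet_count=retweet_count,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def jan_window():
    return (date(2020, 1, 1), date(2020, 1, 31))
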