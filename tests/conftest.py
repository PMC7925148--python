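import datetime as dt
import logging

import pytest

from sentits import CodedComment, Comment

logging.getLogger("sentits").setLevel(logging.ERROR)


def make_comment(i, date=None, text="some words", case="C1", flags=()):
    return Comment(
        comment_id=f"c{i:05d}",
        case_id=case,
        media_source="Sina News",
        date=date or dt.date(2014, 1, 1) + dt.timedelta(days=i % 365),
        text=text,
        flags=frozenset(flags),
    )


@pytest.fixture
def comment_factory():
    return make_comment


@pytest.fixture
def coded_factory():
    def make(i, labels, rater=None):
        return CodedComment(f"c{i:05d}", frozenset(labels), rater_id=rater)

    return make
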