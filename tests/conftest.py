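import datetime as dt

import pytest

from forumminer import ForumCorpus, LexiconModel, Post, classify_corpus


def make_post(pid, tid, author, day, body, cites=(), urls=None):
    """Build a post dated *day* (ISO string) with optional explicit URLs."""
    kwargs = {}
    if urls is not None:
        kwargs["urls"] = tuple(urls)
    else:
        from forumminer import extract_urls

        kwargs["urls"] = tuple(extract_urls(body))
    return Post(
        post_id=pid,
        thread_id=tid,
        author=author,
        timestamp=dt.date.fromisoformat(day),
        body=body,
        cited_post_ids=tuple(cites),
        **kwargs,
    )


WINDOW_2010 = (dt.date(2010, 1, 1), dt.date(2010, 12, 31))


@pytest.fixture
def topic_lexicon():
    return LexiconModel(terms={"ccsvi": 1.0}, threshold=0.5)


@pytest.fixture
def feature_corpus():
    """Hand-built 12-post, 4-user corpus exercising every behavior feature.

    Three threads; posts containing "ccsvi" are on-topic.  All expected
    feature values in the tests were computed by hand from this layout.
    """
    posts = [
        # thread T1
        make_post("p01", "T1", "A", "2010-01-01", "ccsvi start",
                  urls=["http://www.youtube.com/a"]),
        make_post("p02", "T1", "B", "2010-01-02", "ccsvi reply", cites=["p01"]),
        make_post("p03", "T1", "A", "2010-01-03", "ccsvi more",
                  urls=["http://www.youtube.com/b", "http://www.dmsg.de/x"]),
        make_post("p04", "T1", "C", "2010-01-04", "offtopic hello"),
        make_post("p05", "T1", "D", "2010-01-05", "ccsvi again",
                  urls=["http://www.dmsg.de/y", "http://www.dmsg.de/y"]),
        # thread T2
        make_post("p06", "T2", "B", "2010-02-01", "ccsvi topic"),
        make_post("p07", "T2", "C", "2010-02-02", "ccsvi too", cites=["p06"]),
        make_post("p08", "T2", "A", "2010-02-10", "nothing here"),
        # thread T3
        make_post("p09", "T3", "D", "2010-03-01", "hello all"),
        make_post("p10", "T3", "A", "2010-03-05", "ccsvi link www.wikipedia.org/wiki/x"),
        make_post("p11", "T3", "B", "2010-03-06", "plain chat"),
        make_post("p12", "T3", "A", "2010-03-07", "bye"),
    ]
    return ForumCorpus(posts, WINDOW_2010)


@pytest.fixture
def feature_labels(feature_corpus, topic_lexicon):
    return classify_corpus(feature_corpus, topic_lexicon)
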