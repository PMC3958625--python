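"""Data model and I/O for forum corpora.

A corpus is a set of threads, each an ordered sequence of posts.  Posts
carry free text, hyperlinks and structural citations of earlier posts.
The on-disk dialect is UTF-8 JSON-lines: one post object per line with
fields ``post_id``, ``thread_id``, ``author``, ``timestamp`` (ISO-8601
date), ``body``, ``cited_post_ids`` and optionally ``urls`` (pre-extracted
hyperlinks; extracted from the body when absent).

An alias is treated as a user.  Forum software often lets different people
post under one alias, and one person may use several aliases; no identity
resolution is attempted and downstream "user" statistics inherit this
caveat.

Timestamps have day resolution: every per-day quantity downstream is
defined on calendar days, so finer precision would add nothing.  Ordering
inside a thread is by (timestamp, post_id) which makes thread order and
the thread initiator deterministic.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field

__all__ = [
    "Post",
    "Thread",
    "ForumCorpus",
    "LoadReport",
    "CorpusError",
    "extract_urls",
    "load_corpus",
    "write_corpus",
    "user_index",
]


class CorpusError(ValueError):
    """Raised on malformed corpus files or invariant violations."""


# URL grammar: scheme-prefixed URLs plus bare www.-prefixed hosts.  Trailing
# sentence punctuation is not part of the URL.
_URL_RE = re.compile(r"(?:https?://|www\.)[^\s<>\"'‘’“”]+", re.IGNORECASE)
_TRAILING_PUNCT = ".,;:!?)]}>"


def extract_urls(body: str) -> list[str]:
    """Return every hyperlink in *body*, in order, duplicates preserved.

    Matches ``http(s)://...`` and bare ``www....`` substrings.  Duplicate
    URLs are kept: whether repeats within one post count once is a
    downstream, per-post decision.
    """
    out = []
    for m in _URL_RE.finditer(body):
        url = m.group(0).rstrip(_TRAILING_PUNCT)
        if url:
            out.append(url)
    return out


@dataclass(frozen=True)
class Post:
    post_id: str
    thread_id: str
    author: str
    timestamp: _dt.date
    body: str
    cited_post_ids: tuple[str, ...] = ()
    urls: tuple[str, ...] = ()

    def sort_key(self) -> tuple:
        return (self.timestamp, self.post_id)


@dataclass(frozen=True)
class Thread:
    """An ordered conversation.  ``post_ids`` are sorted by (timestamp, post_id)."""

    thread_id: str
    post_ids: tuple[str, ...]
    initiator: str

    def __post_init__(self):
        if not self.post_ids:
            raise CorpusError(f"thread {self.thread_id!r} is empty")


@dataclass
class LoadReport:
    n_posts: int = 0
    n_threads: int = 0
    n_users: int = 0
    n_dropped_outside_window: int = 0
    warnings: list[str] = field(default_factory=list)


class ForumCorpus:
    """In-memory corpus: posts, threads, and a consistent user index."""

    def __init__(
        self,
        posts: list[Post],
        window: tuple[_dt.date, _dt.date],
    ) -> None:
        start, end = window
        if start > end:
            raise CorpusError("window start after end")
        seen: dict[str, Post] = {}
        for p in posts:
            if p.post_id in seen:
                raise CorpusError(f"duplicate post_id {p.post_id!r}")
            if not (start <= p.timestamp <= end):
                raise CorpusError(
                    f"post {p.post_id!r} timestamp {p.timestamp} outside window"
                )
            seen[p.post_id] = p
        self.posts: dict[str, Post] = seen
        self.window = (start, end)
        self.threads: dict[str, Thread] = {}
        by_thread: dict[str, list[Post]] = {}
        for p in seen.values():
            by_thread.setdefault(p.thread_id, []).append(p)
        for tid in sorted(by_thread):
            ordered = sorted(by_thread[tid], key=Post.sort_key)
            self.threads[tid] = Thread(
                thread_id=tid,
                post_ids=tuple(p.post_id for p in ordered),
                initiator=ordered[0].author,
            )
        self._validate_citations()

    def _validate_citations(self) -> None:
        self.citation_warnings: list[str] = []
        for p in self.posts.values():
            for cid in p.cited_post_ids:
                target = self.posts.get(cid)
                if target is None:
                    self.citation_warnings.append(
                        f"post {p.post_id!r} cites unknown post {cid!r}"
                    )
                elif target.timestamp > p.timestamp:
                    self.citation_warnings.append(
                        f"post {p.post_id!r} cites later post {cid!r}"
                    )

    # -- container conveniences -------------------------------------------
    def __len__(self) -> int:
        return len(self.posts)

    def iter_posts(self):
        """Posts in deterministic (thread, in-thread) order."""
        for t in self.threads.values():
            for pid in t.post_ids:
                yield self.posts[pid]

    def thread_posts(self, thread_id: str) -> list[Post]:
        return [self.posts[pid] for pid in self.threads[thread_id].post_ids]

    def users(self) -> list[str]:
        return sorted({p.author for p in self.posts.values()})


def _parse_record(line: str, lineno: int) -> Post:
    try:
        rec = json.loads(line)
    except json.JSONDecodeError as e:
        raise CorpusError(f"line {lineno}: malformed JSON ({e})") from e
    try:
        ts = _dt.date.fromisoformat(str(rec["timestamp"])[:10])
        body = rec["body"]
        urls = rec.get("urls")
        return Post(
            post_id=str(rec["post_id"]),
            thread_id=str(rec["thread_id"]),
            author=str(rec["author"]),
            timestamp=ts,
            body=body,
            cited_post_ids=tuple(str(c) for c in rec.get("cited_post_ids", [])),
            urls=tuple(urls) if urls is not None else tuple(extract_urls(body)),
        )
    except KeyError as e:
        raise CorpusError(f"line {lineno}: missing field {e}") from e
    except (TypeError, ValueError) as e:
        raise CorpusError(f"line {lineno}: bad field value ({e})") from e


def load_corpus(
    path,
    window: tuple[_dt.date, _dt.date],
) -> tuple[ForumCorpus, LoadReport]:
    """Load a JSON-lines corpus, dropping posts outside *window*.

    Returns the corpus and a load report (counts plus validation
    warnings).  Duplicate post ids and malformed lines are hard errors;
    citations of unknown posts are kept but flagged as warnings.
    """
    start, end = window
    posts: list[Post] = []
    report = LoadReport()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            p = _parse_record(line, lineno)
            if not (start <= p.timestamp <= end):
                report.n_dropped_outside_window += 1
                continue
            posts.append(p)
    corpus = ForumCorpus(posts, window)
    report.n_posts = len(corpus)
    report.n_threads = len(corpus.threads)
    report.n_users = len(corpus.users())
    report.warnings = list(corpus.citation_warnings)
    return corpus, report


def write_corpus(corpus: ForumCorpus, path) -> None:
    """Write the corpus back to JSON-lines (deterministic order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in corpus.iter_posts():
            rec = {
                "post_id": p.post_id,
                "thread_id": p.thread_id,
                "author": p.author,
                "timestamp": p.timestamp.isoformat(),
                "body": p.body,
                "cited_post_ids": list(p.cited_post_ids),
                "urls": list(p.urls),
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def user_index(corpus: ForumCorpus) -> dict[str, dict[str, set]]:
    """Map alias -> {'posts', 'threads', 'initiated'} id sets.

    Covers exactly the aliases that authored at least one post; the
    initiated set holds threads whose earliest post the alias authored.
    """
    idx: dict[str, dict[str, set]] = {}
    for p in corpus.posts.values():
        d = idx.setdefault(p.author, {"posts": set(), "threads": set(), "initiated": set()})
        d["posts"].add(p.post_id)
        d["threads"].add(p.thread_id)
    for t in corpus.threads.values():
        idx[t.initiator]["initiated"].add(t.thread_id)
    return idx
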