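"""Per-user source-preference vectors and behavioral features.

Two views of a user are computed from a labeled corpus:

* an 8-dimensional *preference vector* counting posted hyperlinks per
  domain class (unit-normalized before clustering so it expresses taste,
  not activity), and
* nine *behavior features* over the user's whole contribution period:
  average message length (characters, references stripped), posts per
  day, unique references per post, distinct threads per day, days
  active (last minus first post date), fraction of posts cited at least
  once, fraction of relevant posts, fraction of contributed threads the
  user initiated, and discussion-partner coverage per post.

Per-day denominators use ``days_active + 1`` so a single-day user is
well defined.  A *relevant run* is a maximal uninterrupted sequence of
relevant posts inside one thread; everyone who posted in a run is a
discussion partner of everyone else in it, and the coverage feature is
the size of a user's partner union over all their runs divided by their
total post count.
"""

from __future__ import annotations

import re
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forum_model import ForumCorpus, Post, _URL_RE
from .references import DomainClass, DomainMap, URLError, classify_domain, reduce_url
from .relevance import RelevanceLabels

__all__ = [
    "FEATURE_NAMES",
    "PREFERENCE_NAMES",
    "PreferenceVector",
    "BehaviorFeatures",
    "FeatureMatrix",
    "preference_vector",
    "behavior_features",
    "behavior_matrix",
    "preference_matrix",
    "eligible_users",
    "normalize",
    "relevant_runs",
]

FEATURE_NAMES = (
    "avg_message_length",
    "posts_per_day",
    "refs_per_post",
    "threads_per_day",
    "days_active",
    "fraction_cited",
    "fraction_relevant",
    "fraction_initiated",
    "coverage_per_post",
)

PREFERENCE_NAMES = tuple(c.value for c in DomainClass)


@dataclass(frozen=True)
class PreferenceVector:
    """Hyperlink counts per domain class, in :data:`PREFERENCE_NAMES` order."""

    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) != len(DomainClass):
            raise ValueError("preference vector must have 8 dimensions")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative hyperlink count")

    @property
    def total(self) -> int:
        return sum(self.counts)

    def normalized(self) -> np.ndarray:
        v = np.asarray(self.counts, dtype=float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("zero preference vector cannot be unit-normalized")
        return v / n


@dataclass(frozen=True)
class BehaviorFeatures:
    avg_message_length: float
    posts_per_day: float
    refs_per_post: float
    threads_per_day: float
    days_active: float
    fraction_cited: float
    fraction_relevant: float
    fraction_initiated: float
    coverage_per_post: float

    def __post_init__(self):
        for name in ("fraction_cited", "fraction_relevant", "fraction_initiated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in FEATURE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


@dataclass
class FeatureMatrix:
    """User-by-feature table with an explicit normalization state."""

    data: pd.DataFrame
    normalization_state: str = "raw"  # raw | unit | zscore

    def __post_init__(self):
        if self.data.isna().any().any():
            raise ValueError("feature matrix has missing cells")

    @property
    def users(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Preference vectors


def _post_unique_domains(post: Post) -> list[str]:
    """Reduced domains of the post's unique URLs (unreducible ones skipped)."""
    seen: set[str] = set()
    out = []
    for url in post.urls:
        if url in seen:
            continue
        seen.add(url)
        try:
            out.append(reduce_url(url))
        except URLError:
            continue
    return out


def preference_vector(
    user: str,
    corpus: ForumCorpus,
    labels: RelevanceLabels,
    domain_map: DomainMap,
    relevant_only: bool = True,
) -> PreferenceVector:
    """Count the user's posted hyperlinks per domain class.

    URLs repeated within one post count once; across posts they count
    each time.  By default only links in relevant posts count, matching
    the "at least 5 relevant hyperlinks" eligibility scope;
    ``relevant_only=False`` counts links in every post.
    """
    idx = {c: i for i, c in enumerate(DomainClass)}
    counts = [0] * len(DomainClass)
    for p in corpus.posts.values():
        if p.author != user:
            continue
        if relevant_only and not labels.is_relevant(p.post_id):
            continue
        for dom in _post_unique_domains(p):
            counts[idx[classify_domain(dom, domain_map)]] += 1
    return PreferenceVector(counts=tuple(counts))


# ---------------------------------------------------------------------------
# Behavior features


def relevant_runs(corpus: ForumCorpus, labels: RelevanceLabels) -> list[list[Post]]:
    """Maximal uninterrupted sequences of relevant posts, per thread."""
    runs: list[list[Post]] = []
    for tid in corpus.threads:
        current: list[Post] = []
        for p in corpus.thread_posts(tid):
            if labels.is_relevant(p.post_id):
                current.append(p)
            elif current:
                runs.append(current)
                current = []
        if current:
            runs.append(current)
    return runs


def _strip_references(body: str) -> str:
    """Remove hyperlink substrings so length measures prose, not references."""
    return _URL_RE.sub("", body)


def discussion_partners(
    corpus: ForumCorpus, labels: RelevanceLabels
) -> dict[str, set[str]]:
    """alias → union of co-authors over all relevant runs the alias posted in."""
    partners: dict[str, set[str]] = {}
    for run in relevant_runs(corpus, labels):
        authors = {p.author for p in run}
        for a in authors:
            partners.setdefault(a, set()).update(authors - {a})
    return partners


def _cited_post_ids(corpus: ForumCorpus) -> set[str]:
    cited: set[str] = set()
    for p in corpus.posts.values():
        cited.update(p.cited_post_ids)
    return cited


def behavior_features(
    user: str,
    corpus: ForumCorpus,
    labels: RelevanceLabels,
    *,
    _partners: dict[str, set[str]] | None = None,
    _cited: set[str] | None = None,
    _posts: list[Post] | None = None,
) -> BehaviorFeatures:
    """Compute the nine behavior features for one user.

    The private ``_partners`` / ``_cited`` / ``_posts`` arguments let
    :func:`behavior_matrix` share corpus-wide precomputations.
    """
    posts = (
        _posts
        if _posts is not None
        else [p for p in corpus.posts.values() if p.author == user]
    )
    if not posts:
        raise ValueError(f"user {user!r} has no posts")
    n = len(posts)
    first = min(p.timestamp for p in posts)
    last = max(p.timestamp for p in posts)
    days_active = (last - first).days
    span = days_active + 1

    threads = {p.thread_id for p in posts}
    initiated = sum(1 for t in threads if corpus.threads[t].initiator == user)

    cited = _cited if _cited is not None else _cited_post_ids(corpus)
    partners = (
        _partners if _partners is not None else discussion_partners(corpus, labels)
    )

    return BehaviorFeatures(
        avg_message_length=float(
            np.mean([len(_strip_references(p.body)) for p in posts])
        ),
        posts_per_day=n / span,
        refs_per_post=float(np.mean([len(set(p.urls)) for p in posts])),
        threads_per_day=len(threads) / span,
        days_active=float(days_active),
        fraction_cited=sum(1 for p in posts if p.post_id in cited) / n,
        fraction_relevant=sum(1 for p in posts if labels.is_relevant(p.post_id)) / n,
        fraction_initiated=initiated / len(threads),
        coverage_per_post=len(partners.get(user, set())) / n,
    )


def behavior_matrix(
    corpus: ForumCorpus,
    labels: RelevanceLabels,
    users: list[str] | None = None,
) -> FeatureMatrix:
    if users is None:
        users = corpus.users()
    partners = discussion_partners(corpus, labels)
    cited = _cited_post_ids(corpus)
    by_author: dict[str, list[Post]] = {}
    for p in corpus.posts.values():
        by_author.setdefault(p.author, []).append(p)
    rows = {
        u: behavior_features(
            u, corpus, labels, _partners=partners, _cited=cited, _posts=by_author.get(u)
        ).as_array()
        for u in users
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df = df.loc[sorted(rows)]
    df.index.name = "user"
    return FeatureMatrix(data=df, normalization_state="raw")


def preference_matrix(
    corpus: ForumCorpus,
    labels: RelevanceLabels,
    domain_map: DomainMap,
    users: list[str] | None = None,
    relevant_only: bool = True,
) -> FeatureMatrix:
    if users is None:
        users = corpus.users()
    rows = {
        u: np.asarray(
            preference_vector(u, corpus, labels, domain_map, relevant_only).counts,
            dtype=float,
        )
        for u in users
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(PREFERENCE_NAMES))
    df = df.loc[sorted(rows)]
    df.index.name = "user"
    return FeatureMatrix(data=df, normalization_state="raw")


# ---------------------------------------------------------------------------
# Eligibility and normalization


def eligible_users(
    corpus: ForumCorpus,
    labels: RelevanceLabels,
    mode: str,
    threshold: int = 5,
    domain_map: DomainMap | None = None,
) -> set[str]:
    """Users admitted to a clustering.

    ``mode="links"``: at least *threshold* hyperlinks (per-post unique)
    in relevant posts.  ``mode="posts"``: at least *threshold* relevant
    posts.  Thresholds are inclusive.
    """
    if mode not in ("links", "posts"):
        raise ValueError(f"bad eligibility mode {mode!r}")
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    totals: dict[str, int] = {}
    for p in corpus.posts.values():
        if not labels.is_relevant(p.post_id):
            continue
        if mode == "posts":
            totals[p.author] = totals.get(p.author, 0) + 1
        else:
            totals[p.author] = totals.get(p.author, 0) + len(_post_unique_domains(p))
    return {u for u, t in totals.items() if t >= threshold}


def normalize(matrix: FeatureMatrix, method: str) -> FeatureMatrix:
    """Unit-norm rows or z-score columns (population sd).

    Unit normalization preserves direction only; a zero row is an error
    naming the user.  Z-scoring centers each column and scales by the
    population standard deviation; a constant column becomes all zeros
    with a warning.  Both transforms are idempotent.
    """
    X = matrix.values().copy()
    if method == "unit":
        norms = np.linalg.norm(X, axis=1)
        zero = np.flatnonzero(norms == 0)
        if zero.size:
            raise ValueError(
                f"zero vector cannot be unit-normalized: user {matrix.users[zero[0]]!r}"
            )
        X = X / norms[:, None]
        state = "unit"
    elif method == "zscore":
        if X.shape[0] < 2:
            raise ValueError("z-score normalization needs at least 2 rows")
        mu = X.mean(axis=0)
        sd = X.std(axis=0)  # population sd
        const = sd == 0
        if const.any():
            names = [matrix.data.columns[i] for i in np.flatnonzero(const)]
            _warnings.warn(f"constant feature(s) zeroed under z-score: {names}")
        sd = np.where(const, 1.0, sd)
        X = (X - mu) / sd
        X[:, const] = 0.0
        state = "zscore"
    else:
        raise ValueError(f"unknown normalization {method!r}")
    df = pd.DataFrame(X, index=matrix.data.index, columns=matrix.data.columns)
    return FeatureMatrix(data=df, normalization_state=state)
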