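"""Synthetic forum generator with planted archetypes and ground truth.

Real health-forum corpora are rarely redistributable, so every pipeline
stage here is exercised against generated corpora whose properties are
known by construction: per-user behavior archetypes (posting rate, days
active, thread initiation, topic affinity, reference rate, post length),
per-user source-preference distributions over the eight domain classes,
heavy participation inequality (a configurable share of users posts
exactly once), and within-thread topic drift.

Mechanism, in posting order: each post's author draws a desired topic
state from their archetype's ``relevance_prob`` and either initiates a
new thread in that state (with their ``initiation_prob``) or joins an
existing thread currently in that state.  The post's relevance equals
the thread's state at posting time, and the state flips with the
configured drift probability afterwards — with zero drift every thread
stays uniformly on- or off-topic.  Relevant posts embed tokens from the
emitted topic lexicon; irrelevant posts never do, so the lexicon
classifier recovers the planted labels (boundary ambiguity is off by
default).  Hyperlinks are drawn from the author's preference
distribution over a fixed per-class domain pool.

Bodies are token streams, not natural language: length, link and token
statistics are realistic, prose is not.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .forum_model import ForumCorpus, Post
from .references import DEFAULT_DOMAIN_MAP, DomainClass, DomainMap
from .relevance import LexiconModel

__all__ = [
    "ArchetypeSpec",
    "SynthConfig",
    "GroundTruth",
    "generate",
    "validate_statistics",
    "default_behavior_config",
    "default_preference_config",
    "TOPIC_TOKENS",
]

#: Planted on-topic markers; the emitted lexicon scores exactly these.
TOPIC_TOKENS = ("ccsvi", "zamboni", "liberation", "venenverengung", "stenose")

_FILLER = (
    "hallo danke heute morgen gruppe treffen wetter familie arbeit musik "
    "garten urlaub essen schlafen freunde spazieren lesen kaffee montag "
    "dienstag sommer winter fahrrad schwimmen termin woche monat abend "
    "frage antwort meinung erfahrung bericht alltag hoffnung geduld kraft "
    "pause rezept buch film nachbarn besuch"
).split()

#: Fixed pinned domain pool per class (all present in the default map).
CLASS_POOLS: dict[DomainClass, tuple[str, ...]] = {}
for _dom, _cls in DEFAULT_DOMAIN_MAP.items():
    CLASS_POOLS.setdefault(_cls, tuple())
    CLASS_POOLS[_cls] = CLASS_POOLS[_cls] + (_dom,)

_CLASS_ORDER = tuple(DomainClass)


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted user role."""

    name: str
    weight: float
    posts_per_day_mean: float
    days_active_range: tuple[int, int]
    initiation_prob: float
    relevance_prob: float
    refs_per_post_mean: float
    body_length_mean: float
    preference_distribution: tuple[float, ...]  # over DomainClass order

    def __post_init__(self):
        probs = (self.initiation_prob, self.relevance_prob, self.weight)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError(f"archetype {self.name}: probability outside [0,1]")
        if len(self.preference_distribution) != len(DomainClass):
            raise ValueError(f"archetype {self.name}: preference must have 8 entries")
        if abs(sum(self.preference_distribution) - 1.0) > 1e-9:
            raise ValueError(f"archetype {self.name}: preference must sum to 1")
        lo, hi = self.days_active_range
        if not (0 <= lo <= hi):
            raise ValueError(f"archetype {self.name}: bad days_active_range")


_UNIFORM8 = tuple([1.0 / 8] * 8)


def _conc(cls: DomainClass, mass: float = 0.8) -> tuple[float, ...]:
    rest = (1.0 - mass) / 7
    return tuple(mass if c is cls else rest for c in _CLASS_ORDER)


#: Behavior roles around an "average" baseline: a focused responder with a
#: long low-key on-topic presence, a highly active relational poster
#: (~4 posts/day), an activator (thread starter, 3x the references), a
#: sophisticated contributor (3x length, 5x references), and a short-lived
#: spammer (a few days, many short on-topic posts).
DEFAULT_BEHAVIOR_ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec("average", 0.40, 0.3, (60, 100), 0.10, 0.30, 0.5, 200.0, _UNIFORM8),
    ArchetypeSpec("focused_responder", 0.15, 0.3, (150, 200), 0.03, 0.95, 0.5, 200.0, _UNIFORM8),
    ArchetypeSpec("highly_active_relational", 0.12, 4.0, (60, 100), 0.05, 0.30, 0.3, 100.0, _UNIFORM8),
    ArchetypeSpec("activator", 0.12, 0.4, (60, 100), 0.70, 0.95, 1.5, 200.0, _UNIFORM8),
    ArchetypeSpec("sophisticated", 0.11, 0.3, (60, 100), 0.10, 0.50, 2.5, 600.0, _UNIFORM8),
    ArchetypeSpec("short_lived_spammer", 0.10, 6.0, (2, 4), 0.30, 0.95, 0.1, 60.0, _UNIFORM8),
)

#: Source-preference roles: one concentrated profile per salient class plus
#: a balanced profile, over a shared moderate behavior baseline.
_PREF_BASE = dict(
    posts_per_day_mean=0.3,
    days_active_range=(60, 100),
    initiation_prob=0.15,
    relevance_prob=0.8,
    refs_per_post_mean=1.5,
    body_length_mean=200.0,
)
DEFAULT_PREFERENCE_ARCHETYPES: tuple[ArchetypeSpec, ...] = (
    ArchetypeSpec("social_media_fan", 0.17, preference_distribution=_conc(DomainClass.SOCIAL), **_PREF_BASE),
    ArchetypeSpec("organization_follower", 0.17, preference_distribution=_conc(DomainClass.ORGANIZATION), **_PREF_BASE),
    ArchetypeSpec("balanced_source_user", 0.17, preference_distribution=_UNIFORM8, **_PREF_BASE),
    ArchetypeSpec("homepage_promoter", 0.17, preference_distribution=_conc(DomainClass.PERSONAL), **_PREF_BASE),
    ArchetypeSpec("healthcare_seeker", 0.16, preference_distribution=_conc(DomainClass.HEALTHCARE), **_PREF_BASE),
    ArchetypeSpec("uncommon_sources", 0.16, preference_distribution=_conc(DomainClass.OTHER), **_PREF_BASE),
)


@dataclass(frozen=True)
class SynthConfig:
    n_users: int = 300
    window: tuple[_dt.date, _dt.date] = (_dt.date(2009, 1, 1), _dt.date(2011, 12, 31))
    single_post_share: float = 0.65
    drift_prob: float = 0.05
    citation_prob: float = 0.3
    archetypes: tuple[ArchetypeSpec, ...] = DEFAULT_BEHAVIOR_ARCHETYPES
    single_post_relevance: float = 0.3
    single_post_refs_mean: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_users < 1:
            raise ValueError("n_users must be positive")
        if not 0.0 <= self.single_post_share <= 1.0:
            raise ValueError("single_post_share outside [0,1]")
        if not self.archetypes:
            raise ValueError("at least one archetype required")
        total = sum(a.weight for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype weights sum to {total}, not 1")
        if self.window[0] > self.window[1]:
            raise ValueError("window start after end")
        span = (self.window[1] - self.window[0]).days
        if any(a.days_active_range[1] > span for a in self.archetypes):
            raise ValueError("days_active_range exceeds the corpus window")


def default_behavior_config(n_users: int = 300, seed: int = 0) -> SynthConfig:
    return SynthConfig(n_users=n_users, seed=seed)


def default_preference_config(n_users: int = 300, seed: int = 0) -> SynthConfig:
    return SynthConfig(
        n_users=n_users, seed=seed, archetypes=DEFAULT_PREFERENCE_ARCHETYPES
    )


@dataclass
class GroundTruth:
    """Planted labels consistent with the emitted corpus."""

    user_archetype: dict[str, str]
    post_relevance: dict[str, bool]
    link_classes: dict[tuple[str, str], str]  # (post_id, url) -> class value
    config: SynthConfig = None

    def archetype_users(self, name: str) -> list[str]:
        return sorted(u for u, a in self.user_archetype.items() if a == name)


def _make_body(
    rng: np.random.Generator,
    target_len: float,
    relevant: bool,
    urls: list[str],
) -> str:
    n_words = max(3, int(round(target_len / 7.0)))
    words = [_FILLER[i] for i in rng.integers(0, len(_FILLER), size=n_words)]
    if relevant:
        n_topic = 1 + int(rng.poisson(1.0))
        for _ in range(n_topic):
            tok = TOPIC_TOKENS[int(rng.integers(len(TOPIC_TOKENS)))]
            words.insert(int(rng.integers(len(words) + 1)), tok)
    body = " ".join(words)
    if urls:
        body = body + " " + " ".join(urls)
    return body


def generate(
    config: SynthConfig,
) -> tuple[ForumCorpus, GroundTruth, LexiconModel]:
    """Emit a corpus, its ground truth and the matching topic lexicon.

    Deterministic for a given config (the seed lives in the config).
    """
    rng = np.random.default_rng(config.seed)
    start, end = config.window
    span = (end - start).days

    weights = np.array([a.weight for a in config.archetypes])
    weights = weights / weights.sum()

    # -- per-user plans: (user, day) post stubs --------------------------
    stubs: list[tuple[int, str, ArchetypeSpec | None]] = []  # (day, user, spec)
    user_archetype: dict[str, str] = {}
    for ui in range(config.n_users):
        user = f"u{ui:05d}"
        if rng.random() < config.single_post_share:
            user_archetype[user] = "single_post"
            stubs.append((int(rng.integers(0, span + 1)), user, None))
            continue
        spec = config.archetypes[int(rng.choice(len(config.archetypes), p=weights))]
        user_archetype[user] = spec.name
        lo, hi = spec.days_active_range
        days_active = int(rng.integers(lo, hi + 1))
        start_day = int(rng.integers(0, span - days_active + 1))
        n_posts = max(2, int(rng.poisson(spec.posts_per_day_mean * (days_active + 1))))
        days = [start_day, start_day + days_active]
        if n_posts > 2:
            days += [
                int(d)
                for d in rng.integers(start_day, start_day + days_active + 1, size=n_posts - 2)
            ]
        for d in days:
            stubs.append((d, user, spec))

    stubs.sort(key=lambda s: s[0])  # stable: same-day posts keep draw order

    # -- thread assignment with topic state and drift --------------------
    spec_by_name = {a.name: a for a in config.archetypes}
    threads_by_state: dict[bool, list[str]] = {True: [], False: []}
    thread_state: dict[str, bool] = {}
    thread_posts: dict[str, list[str]] = {}
    n_threads = 0

    posts: list[Post] = []
    post_relevance: dict[str, bool] = {}
    link_classes: dict[tuple[str, str], str] = {}
    link_counter = 0

    for i, (day, user, spec) in enumerate(stubs):
        pid = f"p{i:06d}"
        if spec is None:
            init_p, rel_p = 0.3, config.single_post_relevance
            refs_mean, body_len = config.single_post_refs_mean, 150.0
            pref = _UNIFORM8
        else:
            init_p, rel_p = spec.initiation_prob, spec.relevance_prob
            refs_mean, body_len = spec.refs_per_post_mean, spec.body_length_mean
            pref = spec.preference_distribution

        desired = bool(rng.random() < rel_p)
        pool = threads_by_state[desired]
        if rng.random() < init_p or not pool:
            tid = f"t{n_threads:05d}"
            n_threads += 1
            thread_state[tid] = desired
            thread_posts[tid] = []
            threads_by_state[desired].append(tid)
        else:
            tid = pool[int(rng.integers(len(pool)))]

        relevant = thread_state[tid]
        post_relevance[pid] = relevant

        # citations of earlier posts in the thread
        cited: tuple[str, ...] = ()
        earlier = thread_posts[tid]
        if earlier and rng.random() < config.citation_prob:
            cited = (earlier[int(rng.integers(len(earlier)))],)

        # hyperlinks from the author's class preference
        n_refs = int(rng.poisson(refs_mean))
        urls: list[str] = []
        for _ in range(n_refs):
            cls = _CLASS_ORDER[int(rng.choice(len(_CLASS_ORDER), p=np.asarray(pref)))]
            dom = CLASS_POOLS[cls][int(rng.integers(len(CLASS_POOLS[cls])))]
            url = f"http://www.{dom}/ref{link_counter}"
            link_counter += 1
            urls.append(url)
            link_classes[(pid, url)] = cls.value

        body = _make_body(rng, body_len, relevant, urls)
        posts.append(
            Post(
                post_id=pid,
                thread_id=tid,
                author=user,
                timestamp=start + _dt.timedelta(days=day),
                body=body,
                cited_post_ids=cited,
                urls=tuple(urls),
            )
        )
        thread_posts[tid].append(pid)

        # topic drift for subsequent posts in this thread
        if rng.random() < config.drift_prob:
            old = thread_state[tid]
            thread_state[tid] = not old
            threads_by_state[old].remove(tid)
            threads_by_state[not old].append(tid)

    corpus = ForumCorpus(posts, config.window)
    truth = GroundTruth(
        user_archetype=user_archetype,
        post_relevance=post_relevance,
        link_classes=link_classes,
        config=config,
    )
    lexicon = LexiconModel(terms={t: 1.0 for t in TOPIC_TOKENS}, threshold=0.5)
    return corpus, truth, lexicon


# ---------------------------------------------------------------------------
# Self-validation


def validate_statistics(
    corpus: ForumCorpus,
    truth: GroundTruth,
    config: SynthConfig,
    rel_tol: float = 0.15,
    min_users: int = 20,
    min_links: int = 100,
) -> dict:
    """Check the emitted corpus against its own archetype specification.

    For every archetype with at least *min_users* members, empirical
    means of posting rate, reference rate, body length and relevance
    fraction must sit within ``rel_tol`` (relative; absolute 0.1 floor
    for fractions) of the planted value; each sufficiently-linked
    archetype's modal domain-class share must reach its planted mass
    minus 0.1; and topic tokens must occur in exactly the relevant
    posts.  Returns ``{"checks": [...], "all_ok": bool}``.
    """
    from .forum_model import _URL_RE
    from .relevance import tokenize

    by_user: dict[str, list[Post]] = {}
    for p in corpus.posts.values():
        by_user.setdefault(p.author, []).append(p)

    checks: list[dict] = []

    def add(name, ok, observed, expected):
        checks.append(
            {"name": name, "ok": bool(ok), "observed": observed, "expected": expected}
        )

    for spec in config.archetypes:
        users = [u for u in truth.archetype_users(spec.name) if u in by_user]
        if len(users) < min_users:
            continue
        ppd, refs, lens, rel = [], [], [], []
        cls_counts: dict[str, int] = {}
        for u in users:
            ps = by_user[u]
            first = min(p.timestamp for p in ps)
            last = max(p.timestamp for p in ps)
            spn = (last - first).days + 1
            ppd.append(len(ps) / spn)
            refs.append(np.mean([len(p.urls) for p in ps]))
            lens.append(np.mean([len(_URL_RE.sub("", p.body)) for p in ps]))
            rel.append(np.mean([truth.post_relevance[p.post_id] for p in ps]))
            for p in ps:
                for url in p.urls:
                    c = truth.link_classes[(p.post_id, url)]
                    cls_counts[c] = cls_counts.get(c, 0) + 1

        def close(obs, exp, frac=rel_tol, floor=0.0):
            return abs(obs - exp) <= max(frac * exp, floor)

        add(f"{spec.name}.posts_per_day", close(np.mean(ppd), spec.posts_per_day_mean),
            float(np.mean(ppd)), spec.posts_per_day_mean)
        add(f"{spec.name}.refs_per_post", close(np.mean(refs), spec.refs_per_post_mean, floor=0.1),
            float(np.mean(refs)), spec.refs_per_post_mean)
        add(f"{spec.name}.body_length", close(np.mean(lens), spec.body_length_mean),
            float(np.mean(lens)), spec.body_length_mean)
        add(f"{spec.name}.fraction_relevant", close(np.mean(rel), spec.relevance_prob, floor=0.1),
            float(np.mean(rel)), spec.relevance_prob)
        total_links = sum(cls_counts.values())
        if total_links >= min_links:
            mass = max(spec.preference_distribution)
            modal_cls = _CLASS_ORDER[
                int(np.argmax(spec.preference_distribution))
            ].value
            share = cls_counts.get(modal_cls, 0) / total_links
            add(f"{spec.name}.modal_class_share", share >= mass - 0.1, share, mass)

    # relevance-token consistency: topic tokens iff planted relevant
    token_set = set(TOPIC_TOKENS)
    consistent = True
    for p in corpus.posts.values():
        has = bool(token_set & set(tokenize(_URL_RE.sub("", p.body))))
        if has != truth.post_relevance[p.post_id]:
            consistent = False
            break
    add("relevance_token_consistency", consistent, consistent, True)

    return {"checks": checks, "all_ok": all(c["ok"] for c in checks)}


# ---------------------------------------------------------------------------
# File emission (CLI support)


def write_truth(truth: GroundTruth, directory) -> None:
    import pathlib

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "user_archetypes.csv", "w", encoding="utf-8") as fh:
        fh.write("user,archetype\n")
        for u in sorted(truth.user_archetype):
            fh.write(f"{u},{truth.user_archetype[u]}\n")
    with open(d / "post_relevance.csv", "w", encoding="utf-8") as fh:
        fh.write("post_id,relevant\n")
        for pid in sorted(truth.post_relevance):
            fh.write(f"{pid},{int(truth.post_relevance[pid])}\n")
    with open(d / "link_classes.csv", "w", encoding="utf-8") as fh:
        fh.write("post_id,url,domain_class\n")
        for (pid, url), cls in sorted(truth.link_classes.items()):
            fh.write(f"{pid},{url},{cls}\n")


def emit(config: SynthConfig, directory) -> None:
    """Generate and write corpus JSONL, truth CSVs, lexicon and domain map."""
    import pathlib

    from .forum_model import write_corpus
    from .relevance import write_lexicon

    corpus, truth, lexicon = generate(config)
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_corpus(corpus, d / "corpus.jsonl")
    write_truth(truth, d)
    write_lexicon(lexicon, d / "lexicon.tsv")
    DomainMap.default().to_tsv(d / "domain_map.tsv")
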