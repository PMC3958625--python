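"""Hyperlink reduction, domain classification and publication matching.

Every posted URL is reduced to its *basic domain* — the registrable part
of the host, one label plus the public suffix (``blogs.example.co.uk`` →
``example.co.uk``) — and the basic domain is mapped to one of eight
source classes describing who authors the content behind it:
Organization, Commerce, News, Other, Personal, Scientific (which
includes Wikipedia), Social, and Healthcare providers.

Publication use is detected offline: a catalog of candidate scientific
publications is built as the PMID-deduplicated union of a citation
network (reachability closure from a seed publication) and a keyword
search result list; linked documents, supplied by an offline document
store (URL → fetched text), are then scanned for catalog titles or
identifiers.  Matches start as ``unverified``; upgrading them to
``direct`` (the publication itself) or ``indirect`` (a resource solely
discussing it) is a human annotation step, mirroring practice where that
distinction needs judgment.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
import urllib.parse
from dataclasses import dataclass, field

import pandas as pd

from .forum_model import ForumCorpus
from .relevance import RelevanceLabels

__all__ = [
    "DomainClass",
    "DomainMap",
    "PublicationRecord",
    "ReferenceMatch",
    "URLError",
    "reduce_url",
    "classify_domain",
    "build_publication_catalog",
    "match_publications",
    "monthly_domain_counts",
    "DEFAULT_DOMAIN_MAP",
    "PUBLIC_SUFFIXES",
]


class URLError(ValueError):
    """Raised when a URL cannot be reduced to a registrable domain."""


class DomainClass(enum.Enum):
    """Eight-way source taxonomy for basic domains."""

    ORGANIZATION = "Organization"
    COMMERCE = "Commerce"
    NEWS = "News"
    OTHER = "Other"
    PERSONAL = "Personal"
    SCIENTIFIC = "Scientific"
    SOCIAL = "Social"
    HEALTHCARE = "HealthcareProviders"


# ---------------------------------------------------------------------------
# URL reduction over a pinned public-suffix subset.
#
# A frozen subset of the public-suffix list covering the generic TLDs and the
# multi-label country suffixes a European health-forum corpus realistically
# hits.  Hosts under an unknown TLD fall back to treating the last label as
# the suffix (the wildcard rule).
PUBLIC_SUFFIXES: frozenset[str] = frozenset(
    """
    com org net edu gov mil int info biz name mobi io tv cc me eu
    uk de at ch fr it nl be dk se no fi pl cz es pt ie gr hu ru ua
    ca us mx br ar cl jp cn kr in au nz za il tr
    co.uk org.uk ac.uk gov.uk me.uk net.uk
    com.au org.au net.au edu.au gov.au
    co.nz org.nz net.nz ac.nz
    co.jp ne.jp or.jp ac.jp go.jp
    com.cn org.cn net.cn edu.cn
    com.br org.br net.br
    co.za org.za web.za
    co.at or.at ac.at
    co.il org.il ac.il
    com.tr org.tr edu.tr
    com.mx org.mx
    com.ar org.ar
    """.split()
)


def reduce_url(url: str, suffixes: frozenset[str] = PUBLIC_SUFFIXES) -> str:
    """Reduce *url* to its lower-cased registrable domain.

    Scheme, port, path, query and fragment are discarded; the registrable
    domain is the longest matching public suffix plus one preceding
    label.  Bare ``www.``-prefixed strings are accepted.  Raises
    :class:`URLError` on strings without a usable host.
    """
    raw = url.strip()
    if not raw:
        raise URLError("empty URL")
    if "://" not in raw:
        raw = "http://" + raw
    parsed = urllib.parse.urlparse(raw)
    host = parsed.hostname
    if not host or "." not in host:
        raise URLError(f"no host in URL: {url!r}")
    host = host.strip(".").lower()
    labels = host.split(".")
    if any(not lab for lab in labels):
        raise URLError(f"malformed host in URL: {url!r}")
    if host in suffixes:
        raise URLError(f"host {host!r} is a public suffix")
    # longest public suffix that is a proper suffix of the host
    suffix_len = 1  # wildcard rule: unknown TLD acts as a suffix
    for i in range(len(labels) - 1, 0, -1):
        cand = ".".join(labels[i:])
        if cand in suffixes:
            suffix_len = len(labels) - i
    if suffix_len >= len(labels):
        # the host IS a bare suffix (e.g. "co.uk"); nothing registrable
        raise URLError(f"host {host!r} is a public suffix")
    return ".".join(labels[-(suffix_len + 1):])


# ---------------------------------------------------------------------------
# Domain classification

#: Built-in map: the domains named by the taxonomy (YouTube, Facebook,
#: Wikipedia) plus a representative pinned pool per class; extend via TSV.
DEFAULT_DOMAIN_MAP: dict[str, DomainClass] = {
    # Social: communication and user-generated content
    "youtube.com": DomainClass.SOCIAL,
    "facebook.com": DomainClass.SOCIAL,
    "twitter.com": DomainClass.SOCIAL,
    "msforum-connect.de": DomainClass.SOCIAL,
    # Organization: foundations, associations, unions
    "dmsg.de": DomainClass.ORGANIZATION,
    "msif.org": DomainClass.ORGANIZATION,
    "ms-stiftung.org": DomainClass.ORGANIZATION,
    "patienten-allianz.org": DomainClass.ORGANIZATION,
    # News: commercial news providers
    "spiegel.de": DomainClass.NEWS,
    "zeit.de": DomainClass.NEWS,
    "ms-nachrichten.de": DomainClass.NEWS,
    # Scientific: scientific work and knowledge, incl. Wikipedia
    "wikipedia.org": DomainClass.SCIENTIFIC,
    "nih.gov": DomainClass.SCIENTIFIC,
    "sciencedirect.com": DomainClass.SCIENTIFIC,
    "jvir-journal.org": DomainClass.SCIENTIFIC,
    # Personal: static content from a single person
    "ms-tagebuch.de": DomainClass.PERSONAL,
    "meine-ms-seite.de": DomainClass.PERSONAL,
    "privat-homepage.de": DomainClass.PERSONAL,
    # Commerce: businesses not selling treatment
    "amazon.de": DomainClass.COMMERCE,
    "sanitaetshaus-shop.de": DomainClass.COMMERCE,
    "hilfsmittel-versand.de": DomainClass.COMMERCE,
    # Healthcare providers: doctors' offices, clinics, professional Q&A
    "venenklinik.de": DomainClass.HEALTHCARE,
    "ms-ambulanz.at": DomainClass.HEALTHCARE,
    "gefaesspraxis.ch": DomainClass.HEALTHCARE,
    # Other
    "esoterik-portal.de": DomainClass.OTHER,
    "wunderheilung.info": DomainClass.OTHER,
    "sonstiges-archiv.net": DomainClass.OTHER,
}


@dataclass(frozen=True)
class DomainMap:
    """Mapping of already-reduced domains to classes.

    ``strict=False`` (default) sends unmapped domains to Other;
    ``strict=True`` raises instead.
    """

    entries: dict[str, DomainClass]
    strict: bool = False

    @classmethod
    def default(cls, strict: bool = False) -> "DomainMap":
        return cls(entries=dict(DEFAULT_DOMAIN_MAP), strict=strict)

    @classmethod
    def from_tsv(cls, path, strict: bool = False) -> "DomainMap":
        entries: dict[str, DomainClass] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                domain, cls_name = line.split("\t")
                entries[domain.lower()] = DomainClass(cls_name)
        return cls(entries=entries, strict=strict)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for domain in sorted(self.entries):
                fh.write(f"{domain}\t{self.entries[domain].value}\n")


def classify_domain(domain: str, domain_map: DomainMap) -> DomainClass:
    cls = domain_map.entries.get(domain.lower())
    if cls is None:
        if domain_map.strict:
            raise KeyError(f"unmapped domain: {domain!r}")
        return DomainClass.OTHER
    return cls


# ---------------------------------------------------------------------------
# Publication catalog and matching


@dataclass(frozen=True)
class PublicationRecord:
    pmid: str
    title: str
    alt_ids: tuple[str, ...] = ()
    pub_date: _dt.date | None = None
    annotation: str = ""


@dataclass(frozen=True)
class ReferenceMatch:
    post_id: str
    url: str
    pmid: str
    kind: str = "unverified"  # unverified | direct | indirect

    def __post_init__(self):
        if self.kind not in ("unverified", "direct", "indirect"):
            raise ValueError(f"bad reference kind {self.kind!r}")


def build_publication_catalog(
    seed: PublicationRecord,
    citation_records: list[tuple[str, str]],
    search_results: list[PublicationRecord],
    records_by_pmid: dict[str, PublicationRecord] | None = None,
    max_depth: int | None = None,
) -> tuple[list[PublicationRecord], list[str]]:
    """Catalog = citation closure from *seed* ∪ *search_results*, PMID-deduplicated.

    ``citation_records`` are (citing, cited) PMID pairs; traversal follows
    both directions (papers citing and cited by a known paper) to the full
    closure, or to ``max_depth`` hops when given.  ``records_by_pmid``
    supplies metadata for PMIDs discovered through the network; a PMID
    without any record is rejected with a warning.  Output order is the
    PMID sort, which makes the catalog independent of input order.
    """
    warnings: list[str] = []
    adj: dict[str, set[str]] = {}
    for citing, cited in citation_records:
        adj.setdefault(str(citing), set()).add(str(cited))
        adj.setdefault(str(cited), set()).add(str(citing))
    # breadth-first closure with a visited set; cycles terminate naturally
    reached = {seed.pmid}
    frontier = [seed.pmid]
    depth = 0
    while frontier and (max_depth is None or depth < max_depth):
        nxt = []
        for pmid in frontier:
            for nb in adj.get(pmid, ()):
                if nb not in reached:
                    reached.add(nb)
                    nxt.append(nb)
        frontier = nxt
        depth += 1
    records: dict[str, PublicationRecord] = {seed.pmid: seed}
    lookup = records_by_pmid or {}
    for pmid in sorted(reached):
        if pmid in records:
            continue
        rec = lookup.get(pmid)
        if rec is None:
            warnings.append(f"PMID {pmid} reached in citation network but has no record")
        else:
            records[pmid] = rec
    for rec in search_results:
        if not rec.pmid:
            warnings.append(f"search result without PMID rejected: {rec.title[:40]!r}")
            continue
        records.setdefault(rec.pmid, rec)
    catalog = [records[p] for p in sorted(records)]
    return catalog, warnings


def _squash_ws(text: str) -> str:
    return " ".join(text.split()).casefold()


def match_publications(
    document_text: str, catalog: list[PublicationRecord]
) -> list[str]:
    """PMIDs whose title or any identifier occurs in *document_text*.

    Title matching is case-insensitive on whitespace-normalized text and
    requires the full title as a substring — shared single words never
    match.  Identifier matching checks the PMID and every alternate id as
    a literal substring.
    """
    squashed = _squash_ws(document_text)
    hits = []
    for rec in catalog:
        if rec.title and _squash_ws(rec.title) in squashed:
            hits.append(rec.pmid)
            continue
        ids = (rec.pmid, *rec.alt_ids)
        if any(i and i.casefold() in squashed for i in ids):
            hits.append(rec.pmid)
    return hits


def load_catalog_tsv(path) -> list[PublicationRecord]:
    """Read a catalog TSV: pmid, title, alt_ids (;-separated), date."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pmid, title, alt_ids, date = (line.split("\t") + ["", ""])[:4]
            records.append(
                PublicationRecord(
                    pmid=pmid,
                    title=title,
                    alt_ids=tuple(a for a in alt_ids.split(";") if a),
                    pub_date=_dt.date.fromisoformat(date) if date else None,
                )
            )
    return records


def write_catalog_tsv(catalog: list[PublicationRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in catalog:
            date = rec.pub_date.isoformat() if rec.pub_date else ""
            fh.write(f"{rec.pmid}\t{rec.title}\t{';'.join(rec.alt_ids)}\t{date}\n")


class DocumentStore:
    """Offline URL → fetched-text store: a directory plus a JSON index."""

    def __init__(self, directory, index: dict[str, str]):
        self.directory = directory
        self.index = index

    @classmethod
    def open(cls, directory) -> "DocumentStore":
        import pathlib

        d = pathlib.Path(directory)
        with open(d / "index.json", encoding="utf-8") as fh:
            return cls(d, json.load(fh))

    def get(self, url: str) -> str | None:
        import pathlib

        fname = self.index.get(url)
        if fname is None:
            return None
        return (pathlib.Path(self.directory) / fname).read_text(encoding="utf-8")


def scan_corpus_for_publications(
    corpus: ForumCorpus,
    catalog: list[PublicationRecord],
    store: DocumentStore,
) -> list[ReferenceMatch]:
    """Run publication matching over every linked document in the corpus."""
    matches: list[ReferenceMatch] = []
    for post in corpus.iter_posts():
        for url in post.urls:
            text = store.get(url)
            if text is None:
                continue
            for pmid in match_publications(text, catalog):
                matches.append(ReferenceMatch(post.post_id, url, pmid))
    return matches


# ---------------------------------------------------------------------------
# Monthly domain-class timeline


def monthly_domain_counts(
    corpus: ForumCorpus,
    labels: RelevanceLabels | None,
    domain_map: DomainMap,
    scope: str = "all",
) -> pd.DataFrame:
    """Count posted hyperlinks per (calendar month, domain class).

    Each post contributes its *unique* URLs once (repeats of one URL
    inside a post collapse; repeats across posts count each time).
    ``scope="relevant-only"`` restricts to relevant posts and requires
    *labels*.  Months inside the corpus window with no links appear as
    zero rows; unreducible URLs are skipped and reported via the second
    element of the result's ``attrs['rejected']`` list.
    """
    if scope not in ("all", "relevant-only"):
        raise ValueError(f"bad scope {scope!r}")
    if scope == "relevant-only" and labels is None:
        raise ValueError("relevant-only scope requires relevance labels")
    rows = []
    rejected: list[str] = []
    for post in corpus.iter_posts():
        if scope == "relevant-only" and not labels.is_relevant(post.post_id):
            continue
        seen: set[str] = set()
        for url in post.urls:
            if url in seen:
                continue
            seen.add(url)
            try:
                dom = reduce_url(url)
            except URLError:
                rejected.append(url)
                continue
            cls = classify_domain(dom, domain_map)
            rows.append((pd.Period(post.timestamp, freq="M"), cls.value))
    start, end = corpus.window
    months = pd.period_range(pd.Period(start, freq="M"), pd.Period(end, freq="M"))
    classes = [c.value for c in DomainClass]
    table = pd.DataFrame(0, index=months, columns=classes, dtype=int)
    for month, cls in rows:
        table.loc[month, cls] += 1
    table.index.name = "month"
    table.attrs["rejected"] = rejected
    return table
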