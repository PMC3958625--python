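import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forumminer import (
    DomainClass,
    DomainMap,
    ForumCorpus,
    PublicationRecord,
    URLError,
    build_publication_catalog,
    classify_domain,
    match_publications,
    monthly_domain_counts,
    reduce_url,
)

from conftest import WINDOW_2010, make_post


class TestReduceUrl:
    @pytest.mark.parametrize(
        "url,expected",
        [
            ("http://www.youtube.com/watch?v=abc", "youtube.com"),
            ("https://blogs.example.co.uk/x/y.pdf", "example.co.uk"),
            ("HTTP://Example.COM:8080", "example.com"),
            ("www.dmsg.de/forum/thread?id=1", "dmsg.de"),
            ("http://a.b.c.wikipedia.org", "wikipedia.org"),
            ("http://shop.amazon.com.br/item", "amazon.com.br"),
            ("http://unknowntld.zz", "unknowntld.zz"),  # wildcard rule
        ],
    )
    def test_reduction(self, url, expected):
        assert reduce_url(url) == expected

    @pytest.mark.parametrize("bad", ["", "no spaces here", "http://", "co.uk"])
    def test_unreducible_raises(self, bad):
        with pytest.raises(URLError):
            reduce_url(bad)

    @settings(max_examples=100, deadline=None)
    @given(
        sub=st.sampled_from(["", "www.", "blogs.", "a.b."]),
        dom=st.sampled_from(["example", "dmsg", "you-tube"]),
        suffix=st.sampled_from(["com", "de", "co.uk", "org.au", "zz"]),
        path=st.sampled_from(["", "/x", "/x/y?q=1#f"]),
    )
    def test_idempotent(self, sub, dom, suffix, path):
        url = f"http://{sub}{dom}.{suffix}{path}"
        once = reduce_url(url)
        assert reduce_url(once) == once
        assert once == f"{dom}.{suffix}"

    def test_path_and_query_do_not_affect_domain(self):
        assert reduce_url("http://dmsg.de/a") == reduce_url("https://dmsg.de/b?q=2")


class TestClassifyDomain:
    def test_shipped_map_known_domains(self):
        m = DomainMap.default()
        assert classify_domain("youtube.com", m) is DomainClass.SOCIAL
        assert classify_domain("wikipedia.org", m) is DomainClass.SCIENTIFIC

    def test_unmapped_defaults_to_other(self):
        assert (
            classify_domain("zzz-unknown.example", DomainMap.default())
            is DomainClass.OTHER
        )

    def test_unmapped_strict_raises(self):
        with pytest.raises(KeyError, match="zzz-unknown"):
            classify_domain("zzz-unknown.example", DomainMap.default(strict=True))

    def test_tsv_round_trip(self, tmp_path):
        m = DomainMap.default()
        m.to_tsv(tmp_path / "map.tsv")
        m2 = DomainMap.from_tsv(tmp_path / "map.tsv")
        assert m2.entries == m.entries

    def test_eight_classes(self):
        assert len(DomainClass) == 8


SEED = PublicationRecord(pmid="100", title="Seed venous insufficiency paper")
REC_A = PublicationRecord(pmid="200", title="Follow-up A")
REC_B = PublicationRecord(pmid="300", title="Study B")
REC_C = PublicationRecord(pmid="400", title="Search hit C")


class TestPublicationCatalog:
    def test_union_and_dedup(self):
        catalog, warnings = build_publication_catalog(
            SEED,
            [("200", "100"), ("300", "100")],
            [REC_B, REC_C],
            records_by_pmid={"200": REC_A, "300": REC_B},
        )
        assert [r.pmid for r in catalog] == ["100", "200", "300", "400"]
        assert not warnings

    def test_empty_inputs_yield_seed_only(self):
        catalog, _ = build_publication_catalog(SEED, [], [])
        assert [r.pmid for r in catalog] == ["100"]

    def test_cyclic_citations_terminate(self):
        catalog, _ = build_publication_catalog(
            SEED,
            [("100", "200"), ("200", "300"), ("300", "100")],
            [],
            records_by_pmid={"200": REC_A, "300": REC_B},
        )
        assert [r.pmid for r in catalog] == ["100", "200", "300"]

    def test_order_independence(self):
        cites = [("200", "100"), ("300", "200")]
        recs = {"200": REC_A, "300": REC_B}
        c1, _ = build_publication_catalog(SEED, cites, [REC_C], records_by_pmid=recs)
        c2, _ = build_publication_catalog(
            SEED, cites[::-1], [REC_C], records_by_pmid=recs
        )
        assert c1 == c2

    def test_missing_record_warns(self):
        catalog, warnings = build_publication_catalog(SEED, [("999", "100")], [])
        assert [r.pmid for r in catalog] == ["100"]
        assert any("999" in w for w in warnings)

    def test_depth_limit(self):
        catalog, _ = build_publication_catalog(
            SEED,
            [("200", "100"), ("300", "200")],
            [],
            records_by_pmid={"200": REC_A, "300": REC_B},
            max_depth=1,
        )
        assert [r.pmid for r in catalog] == ["100", "200"]


class TestMatchPublications:
    CATALOG = [
        PublicationRecord(
            pmid="19060024",
            title="Chronic cerebrospinal venous insufficiency in patients",
            alt_ids=("10.1136/jnnp.2008.157164",),
        )
    ]

    def test_verbatim_title_matches(self):
        text = "We read Chronic  cerebrospinal\nvenous insufficiency in patients today."
        assert match_publications(text, self.CATALOG) == ["19060024"]

    def test_identifier_channel(self):
        assert match_publications("see PMID: 19060024 for details", self.CATALOG) == [
            "19060024"
        ]
        assert match_publications(
            "doi:10.1136/jnnp.2008.157164", self.CATALOG
        ) == ["19060024"]

    def test_shared_words_do_not_match(self):
        assert match_publications("venous patients were chronic", self.CATALOG) == []


class TestDocumentStore:
    def test_scan_corpus_against_offline_store(self, tmp_path):
        import json

        from forumminer import ForumCorpus
        from forumminer.references import (
            DocumentStore,
            load_catalog_tsv,
            scan_corpus_for_publications,
            write_catalog_tsv,
        )

        catalog = [
            PublicationRecord(pmid="19060024", title="Venous insufficiency study",
                              alt_ids=("10.1000/x",), pub_date=dt.date(2008, 12, 5))
        ]
        write_catalog_tsv(catalog, tmp_path / "catalog.tsv")
        assert load_catalog_tsv(tmp_path / "catalog.tsv") == catalog

        (tmp_path / "doc1.txt").write_text(
            "A page citing the Venous insufficiency study in full.", encoding="utf-8"
        )
        (tmp_path / "doc2.txt").write_text("Nothing of note.", encoding="utf-8")
        url1, url2 = "http://www.dmsg.de/a", "http://www.dmsg.de/b"
        (tmp_path / "index.json").write_text(
            json.dumps({url1: "doc1.txt", url2: "doc2.txt"}), encoding="utf-8"
        )
        store = DocumentStore.open(tmp_path)

        posts = [
            make_post("p1", "t", "a", "2010-01-01", "x", urls=[url1]),
            make_post("p2", "t", "b", "2010-01-02", "y", urls=[url2]),
            make_post("p3", "t", "c", "2010-01-03", "z",
                      urls=["http://www.unfetched.de/q"]),
        ]
        matches = scan_corpus_for_publications(
            ForumCorpus(posts, WINDOW_2010), catalog, store
        )
        assert [(m.post_id, m.pmid, m.kind) for m in matches] == [
            ("p1", "19060024", "unverified")
        ]


class TestMonthlyDomainCounts:
    def _corpus(self):
        posts = [
            make_post("p1", "t1", "a", "2010-03-01", "x",
                      urls=["http://www.youtube.com/1"]),
            make_post("p2", "t1", "a", "2010-03-02", "x",
                      urls=["http://www.youtube.com/2", "http://www.youtube.com/2"]),
            make_post("p3", "t1", "b", "2010-03-03", "ccsvi",
                      urls=["http://www.youtube.com/3"]),
            make_post("p4", "t1", "b", "2010-04-01", "ccsvi",
                      urls=["http://www.dmsg.de/a"]),
            make_post("p5", "t2", "c", "2010-04-02", "x", urls=[]),
            make_post("p6", "t2", "c", "2010-05-01", "x",
                      urls=["http://www.wikipedia.org/w"]),
        ]
        return ForumCorpus(posts, WINDOW_2010)

    def test_three_social_links_in_march(self, topic_lexicon):
        from forumminer import classify_corpus

        corpus = self._corpus()
        labels = classify_corpus(corpus, topic_lexicon)
        table = monthly_domain_counts(corpus, labels, DomainMap.default(), "all")
        # p2's duplicate URL collapses within the post
        assert table.loc["2010-03", "Social"] == 3

    def test_conservation(self, topic_lexicon):
        from forumminer import classify_corpus

        corpus = self._corpus()
        labels = classify_corpus(corpus, topic_lexicon)
        table = monthly_domain_counts(corpus, labels, DomainMap.default(), "all")
        # 5 unique URLs over the corpus (p2 collapses)
        assert int(table.to_numpy().sum()) == 5
        # all window months present even when empty
        assert len(table) == 12

    def test_relevant_only_differs_by_irrelevant_links(self, topic_lexicon):
        from forumminer import classify_corpus

        corpus = self._corpus()
        labels = classify_corpus(corpus, topic_lexicon)
        all_scope = monthly_domain_counts(corpus, labels, DomainMap.default(), "all")
        rel_scope = monthly_domain_counts(
            corpus, labels, DomainMap.default(), "relevant-only"
        )
        # relevant posts: p3 (Social), p4 (Organization) — hand count
        assert int(rel_scope.to_numpy().sum()) == 2
        diff = all_scope - rel_scope
        assert int(diff.to_numpy().sum()) == 3  # links in irrelevant posts
        assert (diff.to_numpy() >= 0).all()
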