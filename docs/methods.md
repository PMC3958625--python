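# Methods

## Scope and data model

The observational unit is a forum corpus: threads containing
time-ordered posts, each post carrying free text, zero or more
hyperlinks and structural citations of earlier posts. Aliases are
treated as users; forum software of the era allowed free alias choice,
so an alias is not guaranteed to be one person and no identity
resolution is attempted — every per-user statistic inherits that
caveat. Timestamps are handled at day resolution because all per-day
behavior features are defined on calendar days. Within a thread, posts
are ordered by (timestamp, post id); the tie-break makes the thread
initiator and run boundaries deterministic, which no coarser convention
would.

## Relevance classification

Threads drift off topic, so relevance is decided per post. The
classifier is a weighted lexicon: Unicode-NFC + casefold both the post
body and the lexicon terms, tokenize on non-letter boundaries, score
`Σ w_t·n_t`, optionally divide by token count, threshold at θ. A
trainer fits weights as additive-smoothed log-odds (smoothing 1) of
term document frequency in relevant vs. irrelevant training posts,
keeping only positive-evidence terms; the default decision threshold
after training is 0.5 so that a zero-evidence post is never labeled
relevant. Precision/recall/F1 use the standard confusion-table
definitions with NaN as the explicit undefined marker for 0/0.

This is deliberately a transparent, deterministic classifier: the
binary per-post contract ("discusses the topic at least partially") is
what downstream stages consume, and on synthetic corpora — where
relevance markers are planted — it is exact by construction. Its
accuracy on real, un-planted text is *not* established by these tests.

## URL reduction and domain classes

Every URL is reduced to its registrable domain: longest matching
public suffix plus one label, lower-cased, scheme/port/path/query
dropped. The public-suffix table is a pinned offline subset
(generic TLDs plus the multi-label country suffixes a European corpus
plausibly hits, e.g. `co.uk`, `com.au`, `com.br`); unknown TLDs fall
back to the wildcard rule (last label acts as the suffix), and a host
that *is* a bare suffix is rejected. Reduction is idempotent, so
classification is invariant under path/query changes.

Basic domains map to 8 closed classes — Organization, Commerce, News,
Other, Personal, Scientific (Wikipedia included as a factual source),
Social, Healthcare providers. The shipped map covers the canonical
examples (youtube.com → Social, facebook.com → Social, wikipedia.org →
Scientific) plus the generator's pinned domain pool; analysts extend it
via a two-column TSV. Unmapped domains go to Other by default, or raise
under the strict policy.

Within one post, repeated identical URLs count once; across posts they
count each time. This keeps the timeline counts and the per-user
"unique references per post" feature on one convention.

## Publication catalog and matching

The candidate-publication catalog is the union of (a) the citation
network reachable from a seed publication (breadth-first closure over
undirected citation pairs; a depth parameter can truncate it) and (b) a
keyword-search result list, de-duplicated by PMID and sorted by PMID so
the catalog is independent of input order. Linked documents come from
an offline URL → text store; a document matches a publication when the
whitespace-normalized, case-insensitive full title or any identifier
occurs as a substring — shared single words never match. Matches are
emitted as `unverified`; promoting them to `direct` (the publication
itself) vs. `indirect` (a resource solely discussing it) is a human
annotation step by design, since that judgment is not mechanizable from
text alone.

## Behavior features

Nine per-user features over the whole contribution period:

| feature | definition | unit |
|---|---|---|
| avg_message_length | mean body length with hyperlink substrings removed | characters |
| posts_per_day | posts ÷ (days_active + 1) | posts/day |
| refs_per_post | mean per-post unique URL count | links/post |
| threads_per_day | distinct threads ÷ (days_active + 1) | threads/day |
| days_active | last − first post date | days |
| fraction_cited | share of own posts cited ≥ 1 time | [0,1] |
| fraction_relevant | share of own posts labeled relevant | [0,1] |
| fraction_initiated | initiated ÷ contributed threads | [0,1] |
| coverage_per_post | distinct discussion partners ÷ posts | users/post |

Conventions that were genuinely open and are pinned here:

- **+1 day denominator.** "Days active" is the difference of dates, 0
  for a single-day user, so per-day rates divide by `days_active + 1`.
- **Reference stripping.** Only hyperlink substrings are removed before
  character counting; citations are structural in this dialect and
  contribute no body text.
- **Threads per day** is distinct threads ÷ (days_active + 1); a
  per-calendar-day average of daily distinct-thread counts is the
  plausible alternative and is not implemented.
- **Discussion partners.** A *relevant run* is a maximal uninterrupted
  sequence of relevant posts within one thread; a user's partners are
  the union of co-authors over all runs they posted in, each partner
  counted once, never the user themself.
- **Preference vectors count links in relevant posts only** (matching
  the "≥ 5 relevant hyperlinks" eligibility scope); `relevant_only=False`
  switches to all posts.

## Normalization and clustering

Preference vectors are unit-normalized (direction = taste, magnitude =
activity is discarded; zero vectors are an error naming the user).
Behavior features are z-scored with the **population** standard
deviation — a determinism pin; with cohort sizes near 100 the
sample/population difference is ~0.5% and irrelevant next to
clustering variability. Constant columns become zeros with a warning.
Both transforms are idempotent.

K-means is a from-scratch Lloyd iteration: assign to the nearest
centroid by squared Euclidean distance (ties to the lowest index),
recompute centroids as means, stop when no membership changes
(`max_iter` 300 is a safeguard only — SSE strictly decreases on any
membership change, so termination is guaranteed). Initialization is a
deterministic farthest-point heuristic: first centroid = the point
nearest the grand mean, each next = the point with maximal minimum
distance to the chosen set. Because that heuristic is deterministic,
restart 0 uses it and the remaining `n_restarts − 1` (default 19) use
seeded random row draws; the best run by within-cluster SSE wins. A
cluster emptied during iteration is reseeded to the point farthest from
its current centroid, keeping k fixed. Default k = 6 for both
clusterings; internal metrics (within-SSE and a from-scratch mean
silhouette, cross-checked against scikit-learn in tests) support manual
k inspection but no automatic selection.

Recovery of planted labels is scored two ways: best-permutation
agreement (exhaustive over injections of the smaller label set into the
larger, k ≤ 8) and the adjusted Rand index computed from the
contingency table (also cross-checked against scikit-learn).

## Synthetic forum generator

The generator emulates the features of real forum data the pipeline
depends on, with full ground truth:

- **Participation inequality**: each user is a single-post "lurker"
  with probability 0.65 (the typical two-thirds share of online
  communities); engaged users draw an archetype by weight.
- **Archetypes** specify posting rate (posts/day, Poisson counts over a
  uniformly drawn active span), days-active range, thread-initiation
  probability, topic affinity, references per post (Poisson), body
  length and an 8-class source-preference distribution.
- **Topic dynamics**: a poster draws a desired topic state from their
  archetype's relevance probability and initiates a thread in that
  state or joins one currently in it; the post's relevance is the
  thread's state at posting time, and the state flips with the drift
  probability (default 0.05) after each post. Zero drift therefore
  yields uniformly on- or off-topic threads; the author-side choice
  plants per-user relevance fractions. Relevant posts embed topic
  tokens from the emitted lexicon; off-topic posts never do.
- **Hyperlinks** are drawn from the archetype's class distribution over
  a fixed pinned domain pool (all pool domains are in the default
  domain map); every generated URL is unique, so link counts are exact.
- **Citations**: each non-initial thread post cites one earlier post of
  its thread with probability 0.3 (corpus-level, since the archetype
  spec carries no citation field); this feeds `fraction_cited` without
  separating archetypes.

Two default archetype sets are shipped. The six **behavior** roles are
set from relative descriptions around an "average" baseline (0.3
posts/day, 200-character posts, 0.5 refs/post, 60–100 days active,
initiation 0.10, topic affinity 0.30): a focused responder (affinity
0.95, initiation 0.03, 150–200 days), a highly active relational poster
(4 posts/day, short posts, initiation 0.05), an activator (initiation
0.70, affinity 0.95, 3× the references), a sophisticated contributor
(3× length, 5× references) and a short-lived spammer (2–4 days, 6
posts/day, short on-topic posts, few references). The absolute baseline
is a free modeling choice — only the relative structure is meaningful —
and it is chosen so that every archetype pair differs by ≥ 3 pooled
standard deviations on at least two features, a condition asserted by a
test rather than assumed. The six **preference** roles are one
0.8-concentrated profile per salient class (Social, Organization,
Personal, Healthcare, Other) plus a balanced uniform profile, over a
shared moderate behavior baseline.

Default problem sizes: 300 users per corpus (≈ 6 × 10³ posts, ≥ 60
eligible users) for recovery studies, 500 users for classifier
self-consistency, 1000 users for the participation-inequality check, 20
seeds per protocol; these sizes give binomial/CLT tolerances of a few
percent on every checked rate while a full protocol completes in tens
of seconds.

**What passing recovery does and does not show.** Bodies are token
streams, not prose; relevance markers are planted, so classifier
perfection here says nothing about accuracy on real text. Archetypes
are homogeneous and well separated; real roles are fuzzier, overlap,
and need not be linearly separable — recovery here validates the
pipeline's correctness (features measure what they claim; normalization
and clustering find structure that is present), not the discoverability
of roles in any real forum.

## Numerical choices and degenerate inputs

- Assignment and argmax ties break to the lowest index everywhere;
  catalogs and user tables sort by identifier — all outputs are
  deterministic given a seed.
- Unit-normalizing a zero vector, z-scoring fewer than 2 rows, k > n,
  non-finite features, empty lexicons and empty gold standards are
  errors; constant features and all-zero radar profiles warn and
  continue.
- 0/0 evaluation ratios return NaN, never a silent 0 or 1.
- Silhouette with one cluster is NaN; singleton clusters score 0.

## Known limitations

- The lexicon classifier is a linear bag-of-terms model; negation,
  quoting and sarcasm are invisible to it.
- The public-suffix subset is pinned and partial; exotic suffixes fall
  back to the wildcard rule, which can over-reduce (e.g. treat a
  registrable second-level domain as a suffix's registrant).
- Direct/indirect reference classification requires human annotation;
  the pipeline only proposes `unverified` matches.
- Alias ≠ person: all per-user statistics are per-alias.
- The generator does not model reply networks beyond citations, burst
  dynamics within a day, or realistic text.
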