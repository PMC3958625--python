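# forumminer

Mining **information sources and behavioral roles** from online
health-forum corpora.

Patient communities debate contested medical hypotheses — such as the
chronic cerebrospinal venous insufficiency (CCSVI) hypothesis in
multiple sclerosis — largely outside the scientific literature. Given a
forum corpus (threads of posts carrying hyperlinks and citations),
`forumminer` answers two questions: *which kinds of sources do users
point to?* and *what roles do users play in the discussion?* It is
aimed at health-informatics researchers who study information
dissemination in online communities.

The pipeline:

1. **Relevance** — every post is labeled on- or off-topic by a weighted
   lexicon classifier (threads drift, so classification is per post,
   never per thread). A post's score is
   `s(p) = Σ_t w_t · n_t(p)` over lexicon terms `t` with `n_t(p)` the
   case-folded match count; `p` is relevant iff `s(p) ≥ θ`.
2. **References** — each posted URL is reduced to its registrable
   ("basic") domain via a pinned public-suffix table and mapped to one
   of 8 source classes (Organization, Commerce, News, Other, Personal,
   Scientific incl. Wikipedia, Social, Healthcare providers). Linked
   documents can be scanned offline for titles/identifiers from a
   PMID-deduplicated publication catalog built as a citation-network
   closure plus keyword-search union.
3. **Features** — each user is an 8-dim preference vector (hyperlink
   counts per class) and a 9-dim behavior vector: mean post length
   (references stripped), posts/day, unique references/post,
   threads/day, days active, fraction of posts cited, fraction
   relevant, fraction of contributed threads initiated, and
   discussion-partner coverage per post (partners co-occur in maximal
   uninterrupted runs of relevant posts).
4. **Clustering** — a from-scratch Lloyd k-means (default k = 6) with
   deterministic farthest-point initialization and
   membership-stability termination groups eligible users (≥ 5
   relevant hyperlinks for the preference clustering, ≥ 5 relevant
   posts for the behavior clustering). Preference vectors are
   unit-normalized (`x/‖x‖₂`, taste not activity); behavior features
   are z-scored (`(x−μ)/σ`, population σ).
5. **Report** — monthly link timelines, radar-chart profiles (min-max
   normalized cluster means; summed-then-unit preference vectors) and
   sampling-flow summaries, each paired with a CSV of the exact
   plotted values.

A **synthetic forum generator** plants user archetypes (posting rate,
topic affinity, initiation, reference habits, source preferences),
participation inequality (~two-thirds single-post users) and
within-thread topic drift, with full ground truth — so every stage is
validated end to end by recovering what was planted.

## Worked example

```python
from forumminer import (classify_corpus, eligible_users, behavior_matrix,
                        normalize, kmeans, match_clusters,
                        ClusteringConfig, summarize_flow)
from forumminer.synthforum import default_behavior_config, generate

corpus, truth, lexicon = generate(default_behavior_config(n_users=300, seed=42))
labels = classify_corpus(corpus, lexicon)
flow = summarize_flow(corpus, labels)
print(f"posts: {flow['n_posts']}  relevant: {flow['n_relevant_posts']}  "
      f"users: {flow['n_users']}  single-post share: {flow['single_post_share']:.3f}")

users = sorted(eligible_users(corpus, labels, "posts", 5))
print(f"eligible users (>=5 relevant posts): {len(users)}")

raw = behavior_matrix(corpus, labels, users)
result = kmeans(normalize(raw, "zscore"), ClusteringConfig(k=6, seed=42))
agreement, ari = match_clusters([truth.user_archetype[u] for u in users],
                                result.assignments)
print(f"cluster sizes: {sorted(result.sizes().tolist(), reverse=True)}")
print(f"planted-role recovery: agreement {agreement:.3f}, ARI {ari:.3f}")
```

prints

```
posts: 6280  relevant: 2987  users: 300  single-post share: 0.663
eligible users (>=5 relevant posts): 97
cluster sizes: [34, 19, 13, 11, 10, 10]
planted-role recovery: agreement 0.990, ARI 0.982
```

The generated community has 300 aliases, two-thirds of whom posted
once; of the 97 users active enough to cluster, k-means on the z-scored
behavior features recovers the six planted roles almost perfectly
(agreement is the best-permutation match between planted and recovered
labels; ARI is the adjusted Rand index).

The same workflow is available from the shell:

```sh
forumminer synth --n-users 300 --seed 42 --out demo/
forumminer validate demo/corpus.jsonl --start 2009-01-01 --end 2011-12-31
forumminer cluster demo/corpus.jsonl --lexicon demo/lexicon.tsv \
    --mode behavior --k 6 --seed 42 --out demo/reports \
    --start 2009-01-01 --end 2011-12-31
forumminer report demo/corpus.jsonl --lexicon demo/lexicon.tsv \
    --out demo/reports --start 2009-01-01 --end 2011-12-31
```

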