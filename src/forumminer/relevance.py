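"""Per-post topic-relevance classification.

A post is *relevant* when it discusses the target topic at least
partially.  Because forum threads drift off their original topic,
classification is strictly per post, never per thread.

The classifier is a weighted-lexicon scorer: the score of a post is the
sum over lexicon terms of ``weight * count(term in body)`` after Unicode
NFC normalization and case folding, optionally divided by the post's
token count (length normalization).  A post is relevant iff its score
reaches the threshold.  ``train_lexicon`` fits term weights from labeled
posts as smoothed log-odds of term occurrence in relevant vs. irrelevant
posts, which keeps the classifier trainable, deterministic and
inspectable.
"""

from __future__ import annotations

import math
import re
import unicodedata
from dataclasses import dataclass, field

from .forum_model import ForumCorpus, Post

__all__ = [
    "LexiconModel",
    "RelevanceLabels",
    "score_post",
    "classify_corpus",
    "train_lexicon",
    "evaluate_classifier",
    "load_lexicon",
    "write_lexicon",
]

_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Case-folded NFC tokens split on non-letter boundaries."""
    return _TOKEN_RE.findall(unicodedata.normalize("NFC", text).casefold())


@dataclass(frozen=True)
class LexiconModel:
    """Term weights plus decision threshold."""

    terms: dict[str, float]
    threshold: float
    length_normalized: bool = False

    def __post_init__(self):
        if not self.terms:
            raise ValueError("lexicon must contain at least one term")
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        # terms and post tokens must share one normal form
        normalized = {
            unicodedata.normalize("NFC", t).casefold(): w
            for t, w in self.terms.items()
        }
        object.__setattr__(self, "terms", normalized)


@dataclass
class RelevanceLabels:
    """Per-post decision and raw score; label is relevant iff score >= threshold."""

    labels: dict[str, bool]
    scores: dict[str, float] = field(default_factory=dict)

    def n_relevant(self) -> int:
        return sum(self.labels.values())

    def is_relevant(self, post_id: str) -> bool:
        return self.labels[post_id]


def score_post(post: Post, model: LexiconModel) -> float:
    tokens = tokenize(post.body)
    score = 0.0
    if not tokens:
        return 0.0
    counts: dict[str, int] = {}
    for t in tokens:
        counts[t] = counts.get(t, 0) + 1
    for term, w in model.terms.items():
        n = counts.get(term, 0)
        if n:
            score += w * n
    if model.length_normalized:
        score /= len(tokens)
    return score


def classify_corpus(corpus: ForumCorpus, model: LexiconModel) -> RelevanceLabels:
    labels: dict[str, bool] = {}
    scores: dict[str, float] = {}
    for p in corpus.posts.values():
        s = score_post(p, model)
        scores[p.post_id] = s
        labels[p.post_id] = s >= model.threshold
    return RelevanceLabels(labels=labels, scores=scores)


def train_lexicon(
    posts: list[Post],
    gold: dict[str, bool],
    threshold: float = 0.5,
    smoothing: float = 1.0,
    min_weight: float = 0.0,
) -> LexiconModel:
    """Fit term weights as additive-smoothed log-odds.

    ``weight(t) = log[(rel_t + a)/(rel + 2a)] - log[(irr_t + a)/(irr + 2a)]``
    where rel_t / irr_t count relevant / irrelevant training posts
    containing *t*.  Terms with weight <= ``min_weight`` are dropped so the
    lexicon stays focused on positive evidence.
    """
    if not gold:
        raise ValueError("empty training set")
    rel_docs = irr_docs = 0
    rel_df: dict[str, int] = {}
    irr_df: dict[str, int] = {}
    for p in posts:
        if p.post_id not in gold:
            continue
        toks = set(tokenize(p.body))
        if gold[p.post_id]:
            rel_docs += 1
            for t in toks:
                rel_df[t] = rel_df.get(t, 0) + 1
        else:
            irr_docs += 1
            for t in toks:
                irr_df[t] = irr_df.get(t, 0) + 1
    a = smoothing
    terms: dict[str, float] = {}
    for t in set(rel_df) | set(irr_df):
        lo = math.log((rel_df.get(t, 0) + a) / (rel_docs + 2 * a)) - math.log(
            (irr_df.get(t, 0) + a) / (irr_docs + 2 * a)
        )
        if lo > min_weight:
            terms[t] = lo
    if not terms:
        raise ValueError("training produced an empty lexicon")
    return LexiconModel(terms=terms, threshold=threshold)


#: Marker returned when a ratio metric is 0/0.
UNDEFINED = float("nan")


def evaluate_classifier(
    labels: RelevanceLabels, gold: dict[str, bool]
) -> tuple[float, float, float]:
    """Precision, recall and F1 of *labels* against *gold*.

    0/0 ratios return NaN (undefined-marker) rather than a silent 0 or 1.
    """
    if not gold:
        raise ValueError("empty gold standard")
    missing = set(gold) - set(labels.labels)
    if missing:
        raise ValueError(f"gold references unlabeled posts: {sorted(missing)[:5]}")
    tp = fp = fn = 0
    for pid, g in gold.items():
        pred = labels.labels[pid]
        if pred and g:
            tp += 1
        elif pred and not g:
            fp += 1
        elif not pred and g:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else UNDEFINED
    recall = tp / (tp + fn) if tp + fn else UNDEFINED
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = UNDEFINED if math.isnan(precision) or math.isnan(recall) else 0.0
    return precision, recall, f1


def load_lexicon(path, threshold: float, length_normalized: bool = False) -> LexiconModel:
    """Read a two-column TSV (term, weight)."""
    terms: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term, weight = line.split("\t")
            terms[term] = float(weight)
    return LexiconModel(terms=terms, threshold=threshold, length_normalized=length_normalized)


def write_lexicon(model: LexiconModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(model.terms):
            fh.write(f"{term}\t{model.terms[term]!r}\n")
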