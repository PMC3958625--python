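"""Figure-analog outputs: timelines, radar charts and sampling summaries.

Every chart is paired with a machine-readable CSV holding exactly the
plotted values, so rendered output is a view over data that can always
be read back and checked; nothing is filtered silently at render time.
"""

from __future__ import annotations

import pathlib
import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterProfile
from .features import eligible_users
from .forum_model import ForumCorpus
from .references import DomainMap, monthly_domain_counts
from .relevance import RelevanceLabels

__all__ = [
    "TimelineTable",
    "CitationTimeline",
    "timeline_table",
    "render_radar",
    "render_timeline",
    "summarize_flow",
]


@dataclass
class TimelineTable:
    """Month-by-domain-class link counts over a contiguous month range."""

    table: pd.DataFrame

    def __post_init__(self):
        idx = self.table.index
        if len(idx) and not (idx == pd.period_range(idx[0], idx[-1])).all():
            raise ValueError("timeline months are not contiguous")
        if (self.table.to_numpy() < 0).any():
            raise ValueError("negative counts in timeline")

    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


@dataclass
class CitationTimeline:
    """Per-publication posting dates of direct/indirect references."""

    pub_dates: dict[str, object]  # pmid -> date
    reference_dates: dict[str, list[tuple[object, str]]]  # pmid -> [(date, kind)]

    def to_csv(self, path) -> None:
        rows = []
        for pmid, refs in sorted(self.reference_dates.items()):
            for date, kind in refs:
                rows.append((pmid, self.pub_dates.get(pmid), date, kind))
        pd.DataFrame(
            rows, columns=["pmid", "pub_date", "reference_date", "kind"]
        ).to_csv(path, index=False)


def timeline_table(
    corpus: ForumCorpus,
    labels: RelevanceLabels | None,
    domain_map: DomainMap,
    scope: str = "all",
) -> TimelineTable:
    return TimelineTable(monthly_domain_counts(corpus, labels, domain_map, scope))


def render_timeline(tl: TimelineTable, out_prefix) -> tuple[pathlib.Path, pathlib.Path]:
    """Write <prefix>.csv and <prefix>.png (monthly stacked link counts)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    prefix = pathlib.Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    png_path = prefix.with_suffix(".png")
    tl.to_csv(csv_path)
    fig, ax = plt.subplots(figsize=(10, 4))
    x = tl.table.index.astype(str)
    bottom = np.zeros(len(tl.table))
    for col in tl.table.columns:
        ax.bar(x, tl.table[col].to_numpy(), bottom=bottom, label=col)
        bottom += tl.table[col].to_numpy()
    ax.set_ylabel("posted hyperlinks")
    step = max(1, len(x) // 12)
    ax.set_xticks(range(0, len(x), step))
    ax.set_xticklabels(x[::step], rotation=45, ha="right")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return csv_path, png_path


def render_radar(
    profile: ClusterProfile, out_prefix, which: str = "minmax"
) -> tuple[pathlib.Path, pathlib.Path]:
    """Render one radar chart per cluster; spoke length ∝ normalized value.

    ``which`` selects ``minmax`` feature means or the preference
    clustering's ``unit_sums``.  Writes <prefix>.csv (the exact plotted
    values, byte-deterministic) and <prefix>.png.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if which == "minmax":
        data = profile.minmax_means
    elif which == "unit_sums":
        if profile.unit_sums is None:
            raise ValueError("profile has no unit sums (not a preference clustering)")
        data = profile.unit_sums
    else:
        raise ValueError(f"unknown radar source {which!r}")
    if np.allclose(data.to_numpy(), 0):
        _warnings.warn("all-zero profile: radar chart is degenerate")
    prefix = pathlib.Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    png_path = prefix.with_suffix(".png")
    data.to_csv(csv_path, float_format="%.10g")

    k, m = data.shape
    angles = np.linspace(0, 2 * np.pi, m, endpoint=False)
    ncols = min(3, k)
    nrows = int(np.ceil(k / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 3.5 * nrows), subplot_kw={"polar": True}
    )
    axes = np.atleast_1d(axes).ravel()
    vmax = max(float(data.to_numpy().max()), 1e-12)
    for c in range(k):
        ax = axes[c]
        vals = data.iloc[c].to_numpy()
        closed = np.append(vals, vals[0])
        ang = np.append(angles, angles[0])
        ax.plot(ang, closed)
        ax.fill(ang, closed, alpha=0.25)
        ax.set_ylim(0, vmax)
        ax.set_xticks(angles)
        ax.set_xticklabels(data.columns, fontsize=6)
        ax.set_yticklabels([])
        ax.set_title(f"cluster {c} (n={profile.sizes[c]})", fontsize=9)
    for ax in axes[k:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return csv_path, png_path


def summarize_flow(
    corpus: ForumCorpus,
    labels: RelevanceLabels,
    domain_map: DomainMap | None = None,
    link_threshold: int = 5,
    post_threshold: int = 5,
) -> dict:
    """Sampling-funnel counts for the two clusterings.

    Reports corpus totals, the single-post-user share, both eligible
    sets and their overlap — the flow from "all posts" down to "users we
    may cluster".
    """
    users = corpus.users()
    posts_per_user: dict[str, int] = {}
    for p in corpus.posts.values():
        posts_per_user[p.author] = posts_per_user.get(p.author, 0) + 1
    single = sum(1 for c in posts_per_user.values() if c == 1)
    elig_links = eligible_users(corpus, labels, "links", link_threshold)
    elig_posts = eligible_users(corpus, labels, "posts", post_threshold)
    return {
        "n_posts": len(corpus),
        "n_threads": len(corpus.threads),
        "n_relevant_posts": labels.n_relevant(),
        "n_users": len(users),
        "n_single_post_users": single,
        "single_post_share": single / len(users) if users else 0.0,
        "n_eligible_links": len(elig_links),
        "n_eligible_posts": len(elig_posts),
        "n_eligible_overlap": len(elig_links & elig_posts),
    }
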