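"""Aggregation of posterior source contributions into pollution categories.

Nitrate sources are conventionally split into non-point sources (NPS:
atmospheric deposition, chemical fertilizer, soil nitrogen — diffuse inputs
via erosion and leaching) and point sources (PS: manure & sewage,
discharged through pipe networks).  Because category contributions are sums
of member-source draws, aggregation commutes with posterior summarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, DomainError
from .mixing import MixingPosterior

__all__ = ["SourceGrouping", "AggregatedPosterior", "aggregate_sources", "contribution_table"]


@dataclass(frozen=True)
class SourceGrouping:
    """Disjoint mapping of category name → member source names."""

    categories: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"NPS": ("AP", "CF", "SN"), "PS": ("MS",)}
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cat, members in self.categories.items():
            if not members:
                raise DomainError(f"category {cat!r} has no members")
            overlap = seen & set(members)
            if overlap:
                raise DomainError(f"sources {sorted(overlap)} appear in two categories")
            seen |= set(members)

    def all_sources(self) -> set[str]:
        return {s for members in self.categories.values() for s in members}

    def check_covers(self, sources: list[str]) -> None:
        missing = set(sources) - self.all_sources()
        if missing:
            raise CoverageError(
                f"grouping does not cover source(s): {sorted(missing)}"
            )
        extra = self.all_sources() - set(sources)
        if extra:
            raise CoverageError(
                f"grouping names unknown source(s): {sorted(extra)}"
            )


@dataclass
class AggregatedPosterior:
    """Category-level draws and equal-tailed summaries."""

    categories: list[str]
    draws: np.ndarray  # (n_draws, n_categories)
    summary: pd.DataFrame  # category, mean, lo, hi


def aggregate_sources(
    posterior: MixingPosterior,
    grouping: SourceGrouping | None = None,
    cred_level: float = 0.95,
) -> AggregatedPosterior:
    """Sum member-source draws into category draws.

    Categories preserve the simplex: each aggregated draw sums to 1 because
    the grouping partitions the posterior's sources.
    """
    grouping = grouping or SourceGrouping()
    grouping.check_covers(posterior.sources)
    cats = list(grouping.categories)
    idx = {s: k for k, s in enumerate(posterior.sources)}
    draws = np.column_stack(
        [
            posterior.draws_p[:, [idx[s] for s in grouping.categories[c]]].sum(axis=1)
            for c in cats
        ]
    )
    lo_q, hi_q = (1 - cred_level) / 2, 1 - (1 - cred_level) / 2
    summary = pd.DataFrame(
        {
            "category": cats,
            "mean": draws.mean(axis=0),
            "lo": np.quantile(draws, lo_q, axis=0),
            "hi": np.quantile(draws, hi_q, axis=0),
        }
    )
    return AggregatedPosterior(categories=cats, draws=draws, summary=summary)


def contribution_table(
    strata: list[tuple[str, MixingPosterior]],
    grouping: SourceGrouping | None = None,
    cred_level: float = 0.95,
) -> pd.DataFrame:
    """Long-format stratum × source/category contribution table (percent).

    One row per stratum × source plus one per stratum × category; source
    percentages conserve 100 per stratum.
    """
    if not strata:
        raise DomainError("need at least one stratum")
    labels = [label for label, _ in strata]
    if len(set(labels)) != len(labels):
        raise DomainError("duplicate stratum labels")
    grouping = grouping or SourceGrouping()
    lo_q, hi_q = (1 - cred_level) / 2, 1 - (1 - cred_level) / 2
    rows = []
    for label, post in strata:
        for k, s in enumerate(post.sources):
            d = post.draws_p[:, k] * 100.0
            rows.append(
                {
                    "stratum": label,
                    "name": s,
                    "kind": "source",
                    "mean_pct": d.mean(),
                    "lo_pct": float(np.quantile(d, lo_q)),
                    "hi_pct": float(np.quantile(d, hi_q)),
                }
            )
        agg = aggregate_sources(post, grouping, cred_level)
        for c, cat in enumerate(agg.categories):
            d = agg.draws[:, c] * 100.0
            rows.append(
                {
                    "stratum": label,
                    "name": cat,
                    "kind": "category",
                    "mean_pct": d.mean(),
                    "lo_pct": float(np.quantile(d, lo_q)),
                    "hi_pct": float(np.quantile(d, hi_q)),
                }
            )
    return pd.DataFrame(rows)
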