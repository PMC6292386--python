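"""Functional marker gene survey across metagenomes.

Unassembled metagenomic ORFs are searched against a curated marker protein
database; this module takes the tabular hits from there. Hits are filtered
at a 30% identity cutoff and reduced to the best hit per ORF, counted per
(metagenome, function category), normalized by metagenome size to hits per
million reads, and compared between sites with a two-sided Wilcoxon
rank-sum test under a Bonferroni correction.

Only two site contrasts are tested — the two epilimnia against each other,
and the epilimnion against the hypolimnion of the humic lake. The eutrophic
epilimnion vs. humic hypolimnion contrast confounds too many factors to be
informative and is deliberately not run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import HitRecord, MarkerCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "TESTED_PAIRS",
    "MetagenomeInfo",
    "SiteComparison",
    "filter_hits",
    "abundance_table",
    "rank_sum_test",
    "compare_sites",
]

#: Site pairs actually compared (epilimnion vs epilimnion; epi vs hypo
#: within the humic lake).
TESTED_PAIRS = (
    ("mendota_epi", "troutbog_epi"),
    ("troutbog_epi", "troutbog_hypo"),
)


@dataclass(frozen=True)
class MetagenomeInfo:
    """One metagenome: where and when it was sampled, and its size."""

    metagenome_id: str
    site: str
    sample_date: date
    read_count: int
    base_count: int | None = None

    def __post_init__(self) -> None:
        if self.read_count <= 0:
            raise ValueError("read_count must be positive")

    def size_bases(self, read_length: int = 150) -> int:
        """Metagenome size in bases (read_count x read length if no base count)."""
        return self.base_count if self.base_count is not None else self.read_count * read_length


@dataclass(frozen=True)
class SiteComparison:
    function_category: str
    site_a: str
    site_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    higher_site: str  # a site name, or "ns" when not significant


def filter_hits(
    hits: Sequence[HitRecord],
    min_identity: float = 30.0,
    best_hit_only: bool = True,
) -> list[HitRecord]:
    """Apply the identity cutoff, then keep the best hit per ORF.

    The cutoff is inclusive (percent_identity >= min_identity). With
    best_hit_only (the default) each query keeps only its highest-bitscore
    hit, ties broken by lexicographic subject_id, so one ORF cannot be
    counted against several related markers. Setting best_hit_only=False
    keeps every passing hit.
    """
    passing = [h for h in hits if h.percent_identity >= min_identity]
    if not best_hit_only:
        return passing
    best: dict[tuple[str, str], HitRecord] = {}
    for h in passing:
        key = (h.metagenome_id, h.query_id)
        prev = best.get(key)
        if prev is None or (-h.bitscore, h.subject_id) < (-prev.bitscore, prev.subject_id):
            best[key] = h
    # preserve input order among winners
    winners = set(map(id, best.values()))
    return [h for h in passing if id(h) in winners]


def abundance_table(
    hits: Sequence[HitRecord],
    catalog: MarkerCatalog,
    metas: Sequence[MetagenomeInfo],
    lenient: bool = False,
) -> pd.DataFrame:
    """Count retained hits per (metagenome, function category) and normalize.

    Every (metagenome, category) pair appears, zero-filled. hits_per_million
    = raw_hits x 1e6 / read_count. Subject ids that do not resolve in the
    catalog raise, or are skipped with a logged warning when lenient=True.
    """
    by_meta = {m.metagenome_id: m for m in metas}
    unresolved = sorted({h.subject_id for h in hits if h.subject_id not in catalog})
    if unresolved:
        if not lenient:
            raise KeyError(f"subject id(s) not in marker catalog: {unresolved}")
        logger.warning("skipping unresolved subject id(s): %s", unresolved)

    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        if h.subject_id not in catalog:
            continue
        if h.metagenome_id not in by_meta:
            raise KeyError(f"hit references unknown metagenome {h.metagenome_id!r}")
        key = (h.metagenome_id, catalog.category_of(h.subject_id))
        counts[key] = counts.get(key, 0) + 1

    rows = []
    for m in metas:
        for category in catalog.categories:
            raw = counts.get((m.metagenome_id, category), 0)
            rows.append(
                {
                    "metagenome_id": m.metagenome_id,
                    "function_category": category,
                    "raw_hits": raw,
                    "hits_per_million": raw * 1e6 / m.read_count,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["metagenome_id", "function_category", "raw_hits", "hits_per_million"],
    )


#: Largest per-group size at which the exact null distribution is enumerated.
EXACT_N_MAX = 8


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum statistic of `x` (sum of the
    ranks of x in the pooled sample). The exact null distribution is used
    when min(len(x), len(y)) <= 8 and the pooled sample has no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two nonempty groups")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = min(x.size, y.size) <= EXACT_N_MAX and not has_ties
    res = stats.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    w_statistic = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return w_statistic, float(res.pvalue)


def compare_sites(
    abund: pd.DataFrame,
    metas: Sequence[MetagenomeInfo],
    alpha: float = 0.05,
) -> list[SiteComparison]:
    """Run every (function category, site pair) rank-sum comparison.

    The Bonferroni family is the full grid actually tested: n_tests =
    (#categories) x (#pairs). higher_site is the site with the larger
    median hits_per_million when p_adjusted < alpha, else "ns". A pair with
    an empty site group yields an NA comparison (NaN statistic and
    p-values) with a logged reason.
    """
    site_of = {m.metagenome_id: m.site for m in metas}
    abund = abund.assign(site=abund["metagenome_id"].map(site_of))
    if abund["site"].isna().any():
        missing = sorted(abund.loc[abund["site"].isna(), "metagenome_id"].unique())
        raise KeyError(f"abundance rows for unknown metagenome(s): {missing}")

    categories = sorted(abund["function_category"].unique())
    n_tests = len(categories) * len(TESTED_PAIRS)

    results: list[SiteComparison] = []
    for category in categories:
        sub = abund[abund["function_category"] == category]
        for site_a, site_b in TESTED_PAIRS:
            va = sub.loc[sub["site"] == site_a, "hits_per_million"].to_numpy()
            vb = sub.loc[sub["site"] == site_b, "hits_per_million"].to_numpy()
            if va.size == 0 or vb.size == 0:
                logger.warning(
                    "no %s abundances for %s in pair (%s, %s); reported as NA",
                    category, site_a if va.size == 0 else site_b, site_a, site_b,
                )
                results.append(
                    SiteComparison(category, site_a, site_b,
                                   math.nan, math.nan, math.nan, "ns")
                )
                continue
            statistic, p_raw = rank_sum_test(va, vb)
            p_adj = min(1.0, p_raw * n_tests)
            if p_adj < alpha:
                higher = site_a if np.median(va) > np.median(vb) else site_b
            else:
                higher = "ns"
            results.append(
                SiteComparison(category, site_a, site_b, statistic, p_raw, p_adj, higher)
            )
    return results
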