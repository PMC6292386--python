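"""Glycoside hydrolase (GH) content of MAGs.

GHs are the CAZyme class that cleaves glycosidic bonds; their abundance in
a genome proxies the ability to degrade complex carbohydrates. Two per-MAG
metrics are computed from dbCAN2-style CAZyme annotations:

* GH coding density — the percentage of a MAG's coding regions (genes)
  annotated as a GH; a gene with several GH domains counts once.
* GH family diversity — the number of distinct GH families (GH13, GH29,
  ...), an indicator of the range of substrates a population can attack.
  Subfamilies (GH13_10) collapse to the parent family by default.

Density and diversity are correlated (Pearson) and averaged by
(site, taxonomic order) for cross-lake comparison. Non-GH CAZyme classes
(GT/PL/CE/CBM/AA) are parsed, ignored and logged.
"""

from __future__ import annotations

import logging
import re
from typing import Sequence

import pandas as pd
from scipy import stats

from .mag_catalog import MagRecord, effective_phylum

logger = logging.getLogger(__name__)

__all__ = [
    "gh_profile",
    "density_diversity_correlation",
    "aggregate_by_order",
]

_GH_RE = re.compile(r"^GH(\d+)(_\d+)?$")
_OTHER_CLASS_RE = re.compile(r"^(GT|PL|CE|CBM|AA)\d")


def _gh_family(family: str, collapse_subfamilies: bool) -> str | None:
    """Return the GH family name, or None for non-GH CAZyme classes."""
    m = _GH_RE.match(family)
    if m:
        return f"GH{m.group(1)}" if collapse_subfamilies else family
    if _OTHER_CLASS_RE.match(family):
        return None
    raise ValueError(f"unparseable CAZyme family {family!r}")


def gh_profile(
    cazyme_annotations: pd.DataFrame,
    mags: Sequence[MagRecord],
    collapse_subfamilies: bool = True,
) -> pd.DataFrame:
    """Per-MAG GH gene count, family diversity and coding density.

    `cazyme_annotations` has columns (mag_id, gene_id, cazyme_family).
    Every MAG in `mags` gets a row (zero profile if it has no GH genes);
    annotation rows for MAGs missing from `mags` are a keying error, as is
    a MAG with gene_count 0.
    """
    by_id = {m.mag_id: m for m in mags}
    unknown = sorted(set(cazyme_annotations["mag_id"]) - set(by_id))
    if unknown:
        raise KeyError(f"CAZyme annotations for unknown MAG(s): {unknown}")
    for m in mags:
        if m.gene_count <= 0:
            raise ValueError(f"MAG {m.mag_id!r} has gene_count 0")

    gh_genes: dict[str, set[str]] = {m.mag_id: set() for m in mags}
    gh_families: dict[str, set[str]] = {m.mag_id: set() for m in mags}
    n_other = 0
    for row in cazyme_annotations.itertuples(index=False):
        fam = _gh_family(row.cazyme_family, collapse_subfamilies)
        if fam is None:
            n_other += 1
            continue
        gh_genes[row.mag_id].add(row.gene_id)
        gh_families[row.mag_id].add(fam)
    if n_other:
        logger.info("ignored %d non-GH CAZyme annotation row(s)", n_other)

    rows = []
    for m in mags:
        n_genes = len(gh_genes[m.mag_id])
        rows.append(
            {
                "mag_id": m.mag_id,
                "gh_gene_count": n_genes,
                "gh_family_count": len(gh_families[m.mag_id]),
                "coding_density": 100.0 * n_genes / m.gene_count,
            }
        )
    return pd.DataFrame(
        rows, columns=["mag_id", "gh_gene_count", "gh_family_count", "coding_density"]
    )


def density_diversity_correlation(
    profiles: pd.DataFrame,
) -> tuple[float, float, int]:
    """Pearson correlation between GH coding density and family diversity.

    Returns (r_squared, p_value, n); p is two-sided from the t transform
    with n - 2 degrees of freedom. Requires at least 3 profiles and
    non-constant density and diversity vectors.
    """
    x = profiles["coding_density"].to_numpy(dtype=float)
    y = profiles["gh_family_count"].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 profiles, got {n}")
    if x.min() == x.max() or y.min() == y.max():
        raise ValueError("degenerate input: a metric is constant across MAGs")
    res = stats.pearsonr(x, y)
    return float(res.statistic) ** 2, float(res.pvalue), n


def aggregate_by_order(
    profiles: pd.DataFrame, mags: Sequence[MagRecord]
) -> pd.DataFrame:
    """Mean GH density and family count per (site, taxonomic order).

    MAGs without an order rank group as "Unclassified-<effective phylum>".
    """
    by_id = {m.mag_id: m for m in mags}
    unknown = sorted(set(profiles["mag_id"]) - set(by_id))
    if unknown:
        raise KeyError(f"profiles for unknown MAG(s): {unknown}")

    groups: dict[tuple[str, str], list[int]] = {}
    for i, mag_id in enumerate(profiles["mag_id"]):
        rec = by_id[mag_id]
        order = rec.lineage.order or f"Unclassified-{effective_phylum(rec)}"
        groups.setdefault((rec.site, order), []).append(i)

    rows = []
    for (site, order), idx in sorted(groups.items()):
        sub = profiles.iloc[idx]
        rows.append(
            {
                "site": site,
                "order": order,
                "mean_density": float(sub["coding_density"].mean()),
                "mean_family_count": float(sub["gh_family_count"].mean()),
                "n_mags": len(idx),
            }
        )
    return pd.DataFrame(
        rows, columns=["site", "order", "mean_density", "mean_family_count", "n_mags"]
    )
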