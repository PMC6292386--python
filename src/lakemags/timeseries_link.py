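"""Linking MAG population dynamics to functional marker dynamics.

Within a multi-year metagenomic time series, a MAG's abundance in each
sample is approximated by read coverage normalized by genome length and
metagenome size:

    normalized_coverage = (mapped bases / genome length) / (metagenome Gb)

i.e. the mean depth the population would reach in a one-gigabase
metagenome. Each year the most abundant member of a taxon group (here,
Cyanobacteria) is selected as that year's dominant population, and its
coverage trajectory is correlated (Pearson, by default) against the
per-sample abundance of a functional marker category — nitrogenase
subunits (nifH/nifD/nifK) for nitrogen fixation. A significant correlation
in years whose dominant MAG carries the pathway, and none in years where
it does not, ties the function's seasonal dynamics to a specific
population.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mag_catalog import MagRecord
from .marker_survey import MetagenomeInfo

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageSeries",
    "DominantMag",
    "normalize_coverage",
    "dominant_mag_per_year",
    "marker_series",
    "correlate_series",
]

#: Assumed read length (bp) when a metagenome's base count is not given.
DEFAULT_READ_LENGTH = 150


@dataclass(frozen=True)
class CoverageSeries:
    """One MAG's normalized coverage over dated samples (dates increasing)."""

    mag_id: str
    points: tuple[tuple[date, str, float], ...]  # (date, metagenome_id, coverage)

    def __post_init__(self) -> None:
        dates = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"dates not strictly increasing for {self.mag_id!r}")
        if any(p[2] < 0 for p in self.points):
            raise ValueError(f"negative coverage for {self.mag_id!r}")

    def as_series(self) -> pd.Series:
        return pd.Series(
            [p[2] for p in self.points],
            index=pd.Index([p[0] for p in self.points], name="sample_date"),
            name=self.mag_id,
        )

    def year_values(self, year: int) -> list[float]:
        return [p[2] for p in self.points if p[0].year == year]


@dataclass(frozen=True)
class DominantMag:
    """The year's most abundant group member and how dominant it was."""

    mag_id: str
    year: int
    mean_coverage: float
    dominance_ratio: float  # top mean / runner-up mean (inf for singletons)


def normalize_coverage(
    raw: pd.DataFrame,
    mags: Sequence[MagRecord],
    metas: Sequence[MetagenomeInfo],
    read_length: int = DEFAULT_READ_LENGTH,
) -> dict[str, CoverageSeries]:
    """Turn mapped-base counts into normalized coverage series.

    `raw` has columns (mag_id, metagenome_id, mapped_bases). Pairs absent
    from `raw` are zero coverage; every MAG gets a point for every
    metagenome in `metas`. Metagenome size in gigabases comes from
    base_count when present, else read_count x read_length.
    """
    by_mag = {m.mag_id: m for m in mags}
    by_meta = {m.metagenome_id: m for m in metas}
    unknown_mag = sorted(set(raw["mag_id"]) - set(by_mag))
    if unknown_mag:
        raise KeyError(f"coverage rows for unknown MAG(s): {unknown_mag}")
    unknown_meta = sorted(set(raw["metagenome_id"]) - set(by_meta))
    if unknown_meta:
        raise KeyError(f"coverage rows for unknown metagenome(s): {unknown_meta}")

    mapped: dict[tuple[str, str], float] = {
        (r.mag_id, r.metagenome_id): float(r.mapped_bases)
        for r in raw.itertuples(index=False)
    }
    metas_sorted = sorted(metas, key=lambda m: (m.sample_date, m.metagenome_id))
    out: dict[str, CoverageSeries] = {}
    for mag in mags:
        points = []
        for meta in metas_sorted:
            gigabases = meta.size_bases(read_length) / 1e9
            depth = mapped.get((mag.mag_id, meta.metagenome_id), 0.0) / mag.genome_length
            points.append((meta.sample_date, meta.metagenome_id, depth / gigabases))
        out[mag.mag_id] = CoverageSeries(mag_id=mag.mag_id, points=tuple(points))
    return out


def dominant_mag_per_year(
    series: Mapping[str, CoverageSeries] | Iterable[CoverageSeries],
    group: set[str],
    year: int,
) -> DominantMag:
    """Pick the group member with the highest mean coverage in a year.

    Ties break lexicographically by mag_id (and are logged). The dominance
    ratio (top mean over runner-up mean) quantifies how clear-cut the call
    is; it is inf when the group has one member or the runner-up mean is 0.
    """
    if isinstance(series, Mapping):
        candidates = [series[m] for m in sorted(group & set(series))]
    else:
        candidates = sorted((s for s in series if s.mag_id in group),
                            key=lambda s: s.mag_id)
    means = [
        (s.mag_id, float(np.mean(vals)))
        for s in candidates
        if (vals := s.year_values(year))
    ]
    if not means:
        raise ValueError(f"no group member has samples in year {year}")
    means.sort(key=lambda t: (-t[1], t[0]))
    top_id, top_mean = means[0]
    if len(means) > 1:
        runner_mean = means[1][1]
        if runner_mean == top_mean:
            logger.info("dominance tie in %d between %s and %s; picked %s",
                        year, top_id, means[1][0], top_id)
        ratio = top_mean / runner_mean if runner_mean > 0 else math.inf
    else:
        ratio = math.inf
    return DominantMag(mag_id=top_id, year=year,
                       mean_coverage=top_mean, dominance_ratio=ratio)


def marker_series(
    abund: pd.DataFrame,
    metas: Sequence[MetagenomeInfo],
    category: str,
) -> pd.Series:
    """Date-ordered hits-per-million series for one function category.

    Samples without the category (zero-filled upstream) contribute 0;
    samples sharing a date are summed.
    """
    if category not in set(abund["function_category"]):
        raise KeyError(f"unknown function category {category!r}")
    date_of = {m.metagenome_id: m.sample_date for m in metas}
    sub = abund[abund["function_category"] == category]
    s = (
        sub.assign(sample_date=sub["metagenome_id"].map(date_of))
        .groupby("sample_date")["hits_per_million"]
        .sum()
        .sort_index()
    )
    s.name = category
    return s


def correlate_series(
    a: pd.Series,
    b: pd.Series,
    method: str = "pearson",
    log1p: bool = False,
) -> tuple[float, float, int]:
    """Correlate two dated series on their shared dates.

    Inner-joins on the date index, then Pearson (default) or Spearman
    correlation; log1p=True transforms both series first. Returns
    (r, p, n); requires at least 3 shared dates.
    """
    joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"only {n} shared date(s); need >= 3 for a correlation")
    x = joined["a"].to_numpy(dtype=float)
    y = joined["b"].to_numpy(dtype=float)
    if log1p:
        x, y = np.log1p(x), np.log1p(y)
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue), n
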