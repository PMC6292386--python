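"""Marker hit filtering, abundance normalization, rank-sum site contrasts."""

import itertools
import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

from lakemags import (
    HitRecord,
    MarkerCatalog,
    MetagenomeInfo,
    SimConfig,
    abundance_table,
    compare_sites,
    filter_hits,
    rank_sum_test,
    simulate_marker_hits,
)


def _hit(query="orf1", subject="TIGR1287", pident=50.0, bitscore=100.0, meta="M1"):
    return HitRecord(meta, query, subject, pident, bitscore)


def rank_sum_enumeration(x, y):
    """Oracle: exact two-sided p by enumerating every rank assignment."""
    nx, ny = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    mean_w = nx * (nx + ny + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, nx + ny + 1), nx):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return w_obs, count / total


class TestFilterHits:
    def test_identity_cutoff_inclusive(self):
        kept = filter_hits([_hit(pident=30.0), _hit(query="orf2", pident=29.9)])
        assert [h.query_id for h in kept] == ["orf1"]

    def test_best_hit_per_query_by_bitscore(self):
        hits = [
            _hit(subject="A", bitscore=80.0),
            _hit(subject="B", bitscore=90.0),
            _hit(query="orf2", subject="C", bitscore=70.0),
        ]
        kept = filter_hits(hits)
        assert {(h.query_id, h.subject_id) for h in kept} == {("orf1", "B"), ("orf2", "C")}

    def test_bitscore_tie_broken_lexicographically(self):
        hits = [_hit(subject="Z", bitscore=90.0), _hit(subject="A", bitscore=90.0)]
        (kept,) = filter_hits(hits)
        assert kept.subject_id == "A"

    def test_all_hits_mode(self):
        hits = [_hit(subject="A"), _hit(subject="B")]
        assert len(filter_hits(hits, best_hit_only=False)) == 2

    def test_planted_count_on_decoy_laden_simulation(self):
        """Retained best hits equal the generator's above-threshold hits."""
        config = SimConfig(seed=31, decoy_fraction=0.5)
        catalog = MarkerCatalog([("TIGR1287", "nitrogen fixation"),
                                 ("PF00016", "carbon fixation")])
        hits = simulate_marker_hits(
            config, catalog, [("M1", "mendota_epi", 3_000_000)]
        )
        planted_above = [h for h in hits if h.percent_identity >= 30]
        assert len(planted_above) < len(hits)  # decoys were generated
        assert sorted(h.query_id for h in filter_hits(hits)) == sorted(
            h.query_id for h in planted_above
        )

    def test_no_decoys_means_everything_passes(self):
        config = SimConfig(seed=32, decoy_fraction=0.0)
        catalog = MarkerCatalog([("TIGR1287", "nitrogen fixation")])
        hits = simulate_marker_hits(config, catalog, [("M1", "mendota_epi", 3_000_000)])
        assert all(h.percent_identity >= 30 for h in hits)


class TestAbundanceTable:
    def test_hits_per_million(self, two_site_metas):
        catalog = MarkerCatalog([("TIGR1287", "nitrogen fixation")])
        hits = [_hit(query=f"orf{i}", meta="M1") for i in range(10)]
        ab = abundance_table(hits, catalog, two_site_metas)
        row = ab[(ab.metagenome_id == "M1")].iloc[0]
        assert row.raw_hits == 10
        assert row.hits_per_million == pytest.approx(5.0)

    def test_zero_fill_every_pair(self, two_site_metas):
        catalog = MarkerCatalog([("TIGR1287", "nitrogen fixation"),
                                 ("PF00016", "carbon fixation")])
        ab = abundance_table([_hit(meta="M1")], catalog, two_site_metas)
        assert len(ab) == len(two_site_metas) * 2
        assert (ab.raw_hits >= 0).all()
        zero = ab[(ab.metagenome_id == "T2") & (ab.function_category == "carbon fixation")]
        assert zero.iloc[0].raw_hits == 0

    def test_normalization_invariant_to_joint_scaling(self):
        catalog = MarkerCatalog([("TIGR1287", "nitrogen fixation")])
        k = 3
        base = [_hit(query=f"orf{i}") for i in range(4)]
        scaled = [_hit(query=f"orf{i}") for i in range(4 * k)]
        meta1 = [MetagenomeInfo("M1", "mendota_epi", date(2008, 6, 1), 2_000_000)]
        metak = [MetagenomeInfo("M1", "mendota_epi", date(2008, 6, 1), 2_000_000 * k)]
        hpm1 = abundance_table(base, catalog, meta1).iloc[0].hits_per_million
        hpmk = abundance_table(scaled, catalog, metak).iloc[0].hits_per_million
        assert hpm1 == pytest.approx(hpmk)

    def test_unresolvable_subject_listed(self, two_site_metas):
        catalog = MarkerCatalog([("TIGR1287", "nitrogen fixation")])
        with pytest.raises(KeyError, match="UNKNOWN1"):
            abundance_table([_hit(subject="UNKNOWN1")], catalog, two_site_metas)
        ab = abundance_table(
            [_hit(subject="UNKNOWN1")], catalog, two_site_metas, lenient=True
        )
        assert (ab.raw_hits == 0).all()

    def test_raw_hits_conserve_retained_best_hits(self):
        """Sum of category counts per metagenome equals retained hits."""
        config = SimConfig(seed=33)
        from lakemags import demo_marker_catalog

        catalog = demo_marker_catalog()
        design = [("M1", "mendota_epi", 2_000_000), ("T1", "troutbog_hypo", 2_500_000)]
        hits = simulate_marker_hits(config, catalog, design)
        kept = filter_hits(hits)
        metas = [
            MetagenomeInfo(mid, site, date(2008, 6, 1), rc) for mid, site, rc in design
        ]
        ab = abundance_table(kept, catalog, metas)
        per_meta = ab.groupby("metagenome_id")["raw_hits"].sum()
        for mid, _, _ in design:
            assert per_meta[mid] == sum(1 for h in kept if h.metagenome_id == mid)


class TestRankSumTest:
    def test_complete_separation_exact_p(self):
        w, p = rank_sum_test([1, 2, 3, 4], [5, 6, 7, 8])
        assert w == 10  # ranks 1+2+3+4
        assert p == pytest.approx(2 / 70)

    def test_identical_groups_no_evidence(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_exact_branch_matches_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(77)
        for nx in range(1, 7):
            for ny in range(1, 7):
                for _ in range(3):
                    x = list(rng.permutation(np.arange(1, nx + ny + 1))[:nx].astype(float))
                    pooled = set(x)
                    y = [float(v) for v in range(1, nx + ny + 1) if float(v) not in pooled]
                    w, p = rank_sum_test(x, y)
                    w_oracle, p_oracle = rank_sum_enumeration(x, y)
                    assert w == pytest.approx(w_oracle)
                    assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_type_one_error_calibrated(self):
        """~5% of null comparisons at alpha=0.05 (normal-approximation branch)."""
        rng = np.random.default_rng(2024)
        n_reps = 500
        rejections = 0
        for _ in range(n_reps):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            _, p = rank_sum_test(x, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestCompareSites:
    def _abundance(self, values_by_meta, category="nitrogen fixation"):
        rows = [
            {
                "metagenome_id": mid,
                "function_category": category,
                "raw_hits": 0,
                "hits_per_million": v,
            }
            for mid, v in values_by_meta.items()
        ]
        return pd.DataFrame(rows)

    def _metas(self, n_per_site, sites=("mendota_epi", "troutbog_epi")):
        metas = []
        for site in sites:
            for i in range(n_per_site):
                metas.append(
                    MetagenomeInfo(f"{site}.{i}", site, date(2008, 6, 1), 1_000_000)
                )
        return metas

    def test_bonferroni_arithmetic_and_ns(self):
        # one category, two pairs tested -> n_tests = 2; an effect giving
        # p_raw ~ 0.03 is not significant after correction
        rng = np.random.default_rng(5)
        metas = self._metas(8, sites=("mendota_epi", "troutbog_epi", "troutbog_hypo"))
        values = {m.metagenome_id: float(v) for m, v in zip(metas, rng.normal(10, 1, 24))}
        ab = self._abundance(values)
        comps = compare_sites(ab, metas)
        assert len(comps) == 2
        for c in comps:
            assert c.p_adjusted == pytest.approx(min(1.0, c.p_raw * 2))
            if not math.isnan(c.p_adjusted) and c.p_adjusted >= 0.05:
                assert c.higher_site == "ns"

    def test_planted_difference_detected_with_direction(self):
        metas = self._metas(20, sites=("troutbog_epi", "troutbog_hypo"))
        values = {
            m.metagenome_id: (50.0 + i if m.site == "troutbog_hypo" else 5.0 + i * 0.1)
            for i, m in enumerate(metas)
        }
        ab = self._abundance(values)
        (c,) = [c for c in compare_sites(ab, metas)
                if c.site_a == "troutbog_epi" and not math.isnan(c.p_raw)]
        assert c.p_adjusted < 0.05
        assert c.higher_site == "troutbog_hypo"

    def test_empty_site_group_reported_na(self, caplog):
        metas = self._metas(4, sites=("mendota_epi", "troutbog_epi"))
        values = {m.metagenome_id: 1.0 * i for i, m in enumerate(metas)}
        ab = self._abundance(values)
        with caplog.at_level("WARNING"):
            comps = compare_sites(ab, metas)
        na = [c for c in comps if c.site_b == "troutbog_hypo"]
        assert len(na) == 1 and math.isnan(na[0].p_raw) and na[0].higher_site == "ns"

    def test_results_invariant_to_row_order(self):
        rng = np.random.default_rng(8)
        metas = self._metas(10)
        values = {m.metagenome_id: float(v) for m, v in zip(metas, rng.gamma(2, 3, 20))}
        ab = self._abundance(values)
        shuffled = ab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = [c for c in compare_sites(ab, metas) if not math.isnan(c.p_raw)]
        b = [c for c in compare_sites(shuffled, metas) if not math.isnan(c.p_raw)]
        assert a == b and len(a) == 1
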