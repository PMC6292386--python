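"""Coverage normalization, dominant-MAG selection, marker-series coupling."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

from lakemags import (
    CoverageSeries,
    MarkerCatalog,
    Lineage,
    MagRecord,
    MetagenomeInfo,
    SimConfig,
    correlate_series,
    demo_marker_catalog,
    dominant_mag_per_year,
    filter_hits,
    abundance_table,
    marker_series,
    normalize_coverage,
    simulate_timeseries,
)


def _mag(mag_id, genome_length=2_000_000):
    return MagRecord(
        mag_id, "mendota_epi", Lineage(phylum="Cyanobacteria"),
        completeness=90.0, contamination=1.0,
        genome_length=genome_length, gene_count=2000,
    )


def _meta(mid, d, read_count=2_000_000, base_count=None):
    return MetagenomeInfo(mid, "mendota_epi", d, read_count, base_count)


class TestNormalizeCoverage:
    def test_unit_definition(self):
        """mapped bases == genome length in a 1 Gb metagenome -> coverage 1."""
        mag = _mag("A", genome_length=2_000_000)
        meta = _meta("M1", date(2008, 6, 1), base_count=1_000_000_000)
        raw = pd.DataFrame(
            {"mag_id": ["A"], "metagenome_id": ["M1"], "mapped_bases": [2_000_000.0]}
        )
        series = normalize_coverage(raw, [mag], [meta])
        assert series["A"].points[0][2] == pytest.approx(1.0)

    def test_read_count_fallback_uses_150bp(self):
        mag = _mag("A", genome_length=1_000_000)
        meta = _meta("M1", date(2008, 6, 1), read_count=2_000_000)  # 0.3 Gb
        raw = pd.DataFrame(
            {"mag_id": ["A"], "metagenome_id": ["M1"], "mapped_bases": [1_000_000.0]}
        )
        series = normalize_coverage(raw, [mag], [meta])
        assert series["A"].points[0][2] == pytest.approx(1 / 0.3)

    def test_missing_pairs_are_zero(self):
        mag = _mag("A")
        metas = [_meta("M1", date(2008, 6, 1)), _meta("M2", date(2008, 6, 8))]
        raw = pd.DataFrame(
            {"mag_id": ["A"], "metagenome_id": ["M1"], "mapped_bases": [5000.0]}
        )
        series = normalize_coverage(raw, [mag], metas)
        assert len(series["A"].points) == 2
        assert series["A"].points[1][2] == 0.0

    def test_joint_scaling_invariance(self):
        mag = _mag("A")
        raw1 = pd.DataFrame(
            {"mag_id": ["A"], "metagenome_id": ["M1"], "mapped_bases": [7000.0]}
        )
        raw2 = raw1.assign(mapped_bases=[14000.0])
        v1 = normalize_coverage(raw1, [mag], [_meta("M1", date(2008, 6, 1), 2_000_000)])
        v2 = normalize_coverage(raw2, [mag], [_meta("M1", date(2008, 6, 1), 4_000_000)])
        assert v1["A"].points[0][2] == pytest.approx(v2["A"].points[0][2])

    def test_unknown_ids_are_keying_errors(self):
        raw = pd.DataFrame(
            {"mag_id": ["ghost"], "metagenome_id": ["M1"], "mapped_bases": [1.0]}
        )
        with pytest.raises(KeyError, match="ghost"):
            normalize_coverage(raw, [_mag("A")], [_meta("M1", date(2008, 6, 1))])


class TestDominantMag:
    def _series(self, mag_id, values, year=2008):
        points = tuple(
            (date(year, 6, 1 + i), f"M{i}", v) for i, v in enumerate(values)
        )
        return CoverageSeries(mag_id=mag_id, points=points)

    def test_highest_mean_wins_with_ratio(self):
        series = {"A": self._series("A", [10, 10]), "B": self._series("B", [2, 2])}
        dom = dominant_mag_per_year(series, {"A", "B"}, 2008)
        assert dom.mag_id == "A"
        assert dom.dominance_ratio == pytest.approx(5.0)

    def test_exact_tie_lexicographic(self):
        series = {"B": self._series("B", [3, 3]), "A": self._series("A", [3, 3])}
        dom = dominant_mag_per_year(series, {"A", "B"}, 2008)
        assert dom.mag_id == "A"
        assert dom.dominance_ratio == pytest.approx(1.0)

    def test_empty_year_is_error(self):
        series = {"A": self._series("A", [1.0])}
        with pytest.raises(ValueError, match="2011"):
            dominant_mag_per_year(series, {"A"}, 2011)

    def test_invariant_to_sample_order_within_year(self):
        rng = np.random.default_rng(3)
        vals = list(rng.uniform(0, 5, 8))
        perm = list(reversed(vals))
        s1 = {"A": self._series("A", vals), "B": self._series("B", [1] * 8)}
        s2 = {"A": self._series("A", perm), "B": self._series("B", [1] * 8)}
        assert (
            dominant_mag_per_year(s1, {"A", "B"}, 2008).mag_id
            == dominant_mag_per_year(s2, {"A", "B"}, 2008).mag_id
        )

    def test_planted_dominant_recovered_across_seeds(self):
        catalog = demo_marker_catalog()
        for seed in range(10):
            ts = simulate_timeseries(SimConfig(seed=seed, n_years=3,
                                               dominant_is_diazotroph=(True, False, True)))
            series = normalize_coverage(ts.coverage, ts.mags, ts.metas)
            group = {m.mag_id for m in ts.mags}
            for year, planted in ts.dominant_by_year.items():
                assert dominant_mag_per_year(series, group, year).mag_id == planted


class TestMarkerSeries:
    def _setup(self, seed=41):
        ts = simulate_timeseries(SimConfig(seed=seed, n_years=2,
                                           dominant_is_diazotroph=(True, False)))
        catalog = demo_marker_catalog()
        ab = abundance_table(filter_hits(ts.hits), catalog, ts.metas)
        return ts, ab

    def test_category_series_dated_and_complete(self):
        ts, ab = self._setup()
        nif = marker_series(ab, ts.metas, "nitrogen fixation")
        assert len(nif) == len(ts.metas)
        assert list(nif.index) == sorted(nif.index)

    def test_per_marker_series_sum_to_category_series(self):
        ts, ab = self._setup()
        catalog = demo_marker_catalog()
        kept = filter_hits(ts.hits)
        nif = marker_series(ab, ts.metas, "nitrogen fixation")
        total = None
        for marker in catalog.markers_in("nitrogen fixation"):
            sub = [h for h in kept if h.subject_id == marker]
            single = abundance_table(
                sub, MarkerCatalog([(marker, "nitrogen fixation")]), ts.metas
            )
            s = marker_series(single, ts.metas, "nitrogen fixation")
            total = s if total is None else total.add(s)
        pd.testing.assert_series_equal(total, nif, check_names=False)

    def test_unknown_category_rejected(self):
        ts, ab = self._setup()
        with pytest.raises(KeyError, match="bioluminescence"):
            marker_series(ab, ts.metas, "bioluminescence")


class TestCorrelateSeries:
    def _dated(self, values, start=date(2008, 6, 1)):
        idx = pd.Index(
            [date(2008, 6, 1 + i) for i in range(len(values))], name="sample_date"
        )
        return pd.Series(values, index=idx)

    def test_proportional_series_r_one(self):
        a = self._dated([1.0, 2.0, 5.0, 3.0])
        r, p, n = correlate_series(a, 2 * a)
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(10)
        a = self._dated(list(rng.uniform(0, 5, 10)))
        b = self._dated(list(rng.uniform(0, 5, 10)))
        r_ab, p_ab, _ = correlate_series(a, b)
        r_ba, p_ba, _ = correlate_series(b, a)
        r_scaled, _, _ = correlate_series(3.5 * a, b)
        assert r_ab == pytest.approx(r_ba)
        assert p_ab == pytest.approx(p_ba)
        assert r_scaled == pytest.approx(r_ab)

    def test_insufficient_shared_dates(self):
        a = self._dated([1.0, 2.0])
        with pytest.raises(ValueError, match="need >= 3"):
            correlate_series(a, a)

    def test_noise_free_single_diazotroph_exactly_proportional(self):
        """With coupling noise off and a single planted diazotroph, the
        nitrogenase series is proportional to that MAG's coverage."""
        cfg = SimConfig(seed=51, n_years=1, dominant_is_diazotroph=(True,),
                        minor_diazotroph=False, timeseries_nb_dispersion=None)
        ts = simulate_timeseries(cfg)
        assert ts.diazotrophs == {ts.dominant_by_year[cfg.start_year]}
        catalog = demo_marker_catalog()
        ab = abundance_table(filter_hits(ts.hits), catalog, ts.metas)
        nif = marker_series(ab, ts.metas, "nitrogen fixation")
        series = normalize_coverage(ts.coverage, ts.mags, ts.metas)
        cov = series[next(iter(ts.diazotrophs))].as_series()
        ratio = (nif / cov).dropna()
        assert ratio.max() - ratio.min() <= 1e-9 * ratio.max()
        r, _, _ = correlate_series(nif, cov)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_nondiazotroph_dominant_decouples_marker_series(self):
        """Planted non-diazotroph dominance leaves the marker series without
        the dominant MAG's bloom shape."""
        cfg = SimConfig(seed=52, n_years=1, dominant_is_diazotroph=(False,),
                        minor_diazotroph=True, timeseries_nb_dispersion=None)
        ts = simulate_timeseries(cfg)
        dom = ts.dominant_by_year[cfg.start_year]
        assert dom not in ts.diazotrophs
        catalog = demo_marker_catalog()
        ab = abundance_table(filter_hits(ts.hits), catalog, ts.metas)
        nif = marker_series(ab, ts.metas, "nitrogen fixation")
        # flat diazotroph background -> essentially constant marker series
        assert nif.std() <= 0.02 * nif.mean()
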