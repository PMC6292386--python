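from datetime import date

import pytest

from lakemags import Lineage, MagRecord, MetagenomeInfo


@pytest.fixture
def small_mags() -> list[MagRecord]:
    return [
        MagRecord(
            "MEN.001", "mendota_epi",
            Lineage(phylum="Cyanobacteria", order="Nostocales"),
            completeness=85.0, contamination=3.0,
            genome_length=4_000_000, gene_count=4000,
        ),
        MagRecord(
            "MEN.002", "mendota_epi",
            Lineage(phylum="Proteobacteria", class_="Betaproteobacteria",
                    order="Burkholderiales"),
            completeness=62.0, contamination=1.5,
            genome_length=3_000_000, gene_count=3000,
        ),
        MagRecord(
            "TBE.001", "troutbog_epi",
            Lineage(phylum="Chlorobi", order="Chlorobiales"),
            completeness=95.0, contamination=4.0,
            genome_length=2_500_000, gene_count=2500,
        ),
        MagRecord(
            "TBH.001", "troutbog_hypo",
            Lineage(phylum="Proteobacteria"),
            completeness=55.0, contamination=8.0,
            genome_length=5_000_000, gene_count=5000,
        ),
    ]


@pytest.fixture
def two_site_metas() -> list[MetagenomeInfo]:
    return [
        MetagenomeInfo("M1", "mendota_epi", date(2008, 6, 1), 2_000_000),
        MetagenomeInfo("M2", "mendota_epi", date(2008, 6, 8), 1_000_000),
        MetagenomeInfo("T1", "troutbog_epi", date(2008, 6, 1), 2_000_000),
        MetagenomeInfo("T2", "troutbog_epi", date(2008, 6, 8), 4_000_000),
    ]
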