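"""Metagenome-assembled genome (MAG) bookkeeping.

A MAG is a draft genome binned from assembled metagenomic contigs. This
module holds the per-MAG metadata record, the medium/high-quality filter
(completeness at least 50%, contamination under 10%), dereplication of MAGs
that represent the same population (average nucleotide identity above a
threshold), the taxonomy convention used for aggregation (Proteobacteria is
split into classes because the phylum is too diverse to be one group), and a
proteome-level elemental metric: the mean number of nitrogen atoms per
amino-acid residue across a MAG's translated genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SITES",
    "Lineage",
    "MagRecord",
    "AniTable",
    "PopulationGroup",
    "qc_filter",
    "flag_populations",
    "effective_phylum",
    "nitrogen_per_residue",
    "NITROGEN_PER_AA",
]

#: The three sampling environments: Lake Mendota's epilimnion and the
#: epilimnion and hypolimnion of Trout Bog Lake.
SITES = ("mendota_epi", "troutbog_epi", "troutbog_hypo")

RANKS = ("phylum", "class_", "order", "family", "genus", "species")


@dataclass(frozen=True)
class Lineage:
    """Taxonomic lineage from phylum down; unknown ranks are None."""

    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def rank(self, name: str) -> str | None:
        if name == "class":
            name = "class_"
        if name not in RANKS:
            raise KeyError(f"unknown rank {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class MagRecord:
    """Metadata for one MAG.

    completeness and contamination are CheckM-style percentages in [0, 100];
    genome_length is in bases.
    """

    mag_id: str
    site: str
    lineage: Lineage = field(default_factory=Lineage)
    completeness: float = 0.0
    contamination: float = 0.0
    genome_length: int = 1
    gene_count: int = 0

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"completeness {self.completeness} outside [0, 100]")
        if not 0 <= self.contamination <= 100:
            raise ValueError(f"contamination {self.contamination} outside [0, 100]")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.gene_count < 0:
            raise ValueError("gene_count must be non-negative")


class AniTable:
    """Pairwise average nucleotide identity with symmetric lookup.

    Absent pairs are treated as below any threshold; ani(a, a) is 100.
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]]):
        self._ani: dict[frozenset[str], float] = {}
        for mag_a, mag_b, ani in pairs:
            if not 0 <= ani <= 100:
                raise ValueError(
                    f"ANI value {ani} for pair ({mag_a}, {mag_b}) outside [0, 100]"
                )
            self._ani[frozenset((mag_a, mag_b))] = ani

    def get(self, mag_a: str, mag_b: str) -> float | None:
        if mag_a == mag_b:
            return 100.0
        return self._ani.get(frozenset((mag_a, mag_b)))

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for key, ani in self._ani.items():
            a, b = sorted(key) if len(key) == 2 else (next(iter(key)),) * 2
            yield a, b, ani

    def __len__(self) -> int:
        return len(self._ani)


@dataclass(frozen=True)
class PopulationGroup:
    """One ANI-linked population: member mag_ids and a representative."""

    representative: str
    members: tuple[str, ...]


def qc_filter(
    mags: Sequence[MagRecord],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> list[MagRecord]:
    """Keep medium/high-quality MAGs.

    Retains MAGs with completeness >= min_completeness AND contamination
    < max_contamination (the "at least 50% complete, less than 10%
    contamination" convention for medium-quality draft genomes). Input order
    is preserved.
    """
    for name, value in (("min_completeness", min_completeness),
                        ("max_contamination", max_contamination)):
        if not 0 <= value <= 100:
            raise ValueError(f"{name} must be in [0, 100], got {value}")
    return [
        m
        for m in mags
        if m.completeness >= min_completeness and m.contamination < max_contamination
    ]


def flag_populations(
    mags: Sequence[MagRecord],
    ani: AniTable,
    threshold: float = 99.0,
) -> list[PopulationGroup]:
    """Partition MAGs into same-population groups by ANI linkage.

    Two MAGs are linked when ani > threshold; groups are the connected
    components of the resulting graph (single-linkage transitive closure).
    Each group's representative is the member with the highest completeness,
    ties broken by lower contamination, then lexicographic mag_id. The
    default threshold of 99 follows the ">99% = same population" convention;
    97 is the common looser alternative.

    Returns groups sorted by representative id; singletons are included, so
    the output is a partition of all input mag_ids.
    """
    if not 0 <= threshold <= 100:
        raise ValueError(f"threshold must be in [0, 100], got {threshold}")
    by_id = {m.mag_id: m for m in mags}
    parent = {mag_id: mag_id for mag_id in by_id}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, value in ani.pairs():
        if value > threshold and a in parent and b in parent and a != b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    components: dict[str, list[str]] = {}
    for mag_id in by_id:
        components.setdefault(find(mag_id), []).append(mag_id)

    groups = []
    for members in components.values():
        rep = min(
            members,
            key=lambda mid: (
                -by_id[mid].completeness,
                by_id[mid].contamination,
                mid,
            ),
        )
        groups.append(PopulationGroup(representative=rep, members=tuple(sorted(members))))
    groups.sort(key=lambda g: g.representative)
    return groups


def effective_phylum(record: MagRecord) -> str:
    """Taxon label used for aggregation.

    Proteobacteria is split into its classes (the phylum is too diverse to
    be informative as one unit); every other phylum is used as-is. Missing
    ranks yield "Unclassified-<rank above>"; a MAG with no phylum at all is
    "Unclassified-Bacteria".
    """
    phylum = record.lineage.phylum
    if phylum is None:
        return "Unclassified-Bacteria"
    if phylum == "Proteobacteria":
        cls = record.lineage.class_
        return cls if cls is not None else "Unclassified-Proteobacteria"
    return phylum


# Nitrogen atoms per residue in the polypeptide (backbone amide N plus side
# chain N), by one-letter code. 14 amino acids carry only the backbone N;
# N/Q/K/W carry one side-chain N; H two; R three.
NITROGEN_PER_AA: Mapping[str, int] = {
    "G": 1, "A": 1, "S": 1, "T": 1, "C": 1, "V": 1, "L": 1,
    "I": 1, "M": 1, "P": 1, "F": 1, "Y": 1, "D": 1, "E": 1,
    "N": 2, "Q": 2, "K": 2, "W": 2,
    "H": 3,
    "R": 4,
}

_N_FOR_X = sum(NITROGEN_PER_AA.values()) / len(NITROGEN_PER_AA)  # 1.45


def nitrogen_per_residue(proteome: Mapping[str, str]) -> float:
    """Mean nitrogen atoms per amino-acid residue across a proteome.

    A proxy for the nitrogen cost of a genome's protein complement: N-rich
    proteomes are disfavoured under nitrogen limitation. The ambiguity code
    X contributes the unweighted alphabet average (1.45 atoms).

    Raises ValueError on an empty proteome or an unknown residue letter.
    """
    total_n = 0.0
    total_len = 0
    for gene_id, seq in proteome.items():
        for aa in seq:
            if aa == "X":
                total_n += _N_FOR_X
            elif aa in NITROGEN_PER_AA:
                total_n += NITROGEN_PER_AA[aa]
            else:
                raise ValueError(
                    f"illegal amino-acid letter {aa!r} in gene {gene_id!r}"
                )
            total_len += 1
    if total_len == 0:
        raise ValueError("empty proteome: nitrogen per residue is undefined")
    result = total_n / total_len
    assert not math.isnan(result)
    return result
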