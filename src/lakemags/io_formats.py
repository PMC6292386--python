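"""Readers and writers for the pipeline's tabular and sequence formats.

Everything is plain text: TSV with mandatory headers for annotation tables,
MAG metadata, ANI tables, marker catalogs, metagenome info and coverage;
12-column BLAST tabular for homology hits; FASTA for protein sequences; a
YAML pathway catalog. Readers validate on the way in and report offending
line numbers; writers round-trip exactly (read(write(x)) == x).

Functional annotation identifiers are namespaced to keep the four
annotation systems apart: ``KO:K02586``, ``COG:COG1348``, ``PFAM:PF00142``,
``TIGR:TIGR1287``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .mag_catalog import AniTable, Lineage, MagRecord
from .pathway_inference import PathwayDefinition, StepDef

logger = logging.getLogger(__name__)

__all__ = [
    "ANNOTATION_NAMESPACES",
    "FormatError",
    "HitRecord",
    "MarkerCatalog",
    "read_annotation_table",
    "write_annotation_table",
    "read_blast_tab",
    "write_blast_tab",
    "read_protein_fasta",
    "write_protein_fasta",
    "read_matrix",
    "write_matrix",
    "read_marker_catalog",
    "write_marker_catalog",
    "read_mag_table",
    "write_mag_table",
    "read_ani_table",
    "write_ani_table",
    "read_metagenome_table",
    "write_metagenome_table",
    "read_coverage_table",
    "write_coverage_table",
    "read_pathway_catalog",
    "write_pathway_catalog",
]

ANNOTATION_NAMESPACES = ("KO:", "COG:", "PFAM:", "TIGR:")

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit of a metagenomic ORF against a marker protein."""

    metagenome_id: str
    query_id: str
    subject_id: str
    percent_identity: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(
                f"percent_identity {self.percent_identity} outside [0, 100]"
            )
        if self.bitscore < 0:
            raise ValueError(f"bitscore {self.bitscore} is negative")


class MarkerCatalog:
    """Mapping from marker gene family id to its function category.

    Marker ids are TIGRFAM/COG/PFAM accessions (e.g. TIGR1287, the nifH
    nitrogenase marker); categories are metabolic capabilities such as
    "nitrogen fixation". Each marker belongs to exactly one category.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self._category: dict[str, str] = {}
        for marker_id, category in entries:
            if marker_id in self._category and self._category[marker_id] != category:
                raise ValueError(
                    f"marker {marker_id!r} mapped to both "
                    f"{self._category[marker_id]!r} and {category!r}"
                )
            self._category[marker_id] = category

    def category_of(self, marker_id: str) -> str:
        return self._category[marker_id]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._category

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(set(self._category.values())))

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(sorted(self._category))

    def markers_in(self, category: str) -> tuple[str, ...]:
        return tuple(
            sorted(m for m, c in self._category.items() if c == category)
        )

    def items(self) -> Iterable[tuple[str, str]]:
        return sorted(self._category.items())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerCatalog) and self._category == other._category

    def __len__(self) -> int:
        return len(self._category)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _check_namespace(annotation_id: str) -> bool:
    return any(
        annotation_id.startswith(ns) and len(annotation_id) > len(ns)
        for ns in ANNOTATION_NAMESPACES
    )


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a per-gene functional annotation table.

    TSV with header columns mag_id, gene_id, annotation_id; annotation ids
    must carry one of the KO:/COG:/PFAM:/TIGR: namespaces. Duplicate rows
    are collapsed with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["mag_id", "gene_id", "annotation_id"], path)
    df = df[["mag_id", "gene_id", "annotation_id"]]
    for col in df.columns:
        bad = df.index[df[col].isna() | (df[col].astype(str).str.len() == 0)]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise FormatError(f"{path}: empty {col} at line {bad[0] + 2}")
    bad_ns = [
        (i, a)
        for i, a in zip(df.index, df["annotation_id"])
        if not _check_namespace(a)
    ]
    if bad_ns:
        i, a = bad_ns[0]
        raise FormatError(
            f"{path}: annotation_id {a!r} at line {i + 2} lacks a "
            f"{'/'.join(ANNOTATION_NAMESPACES)} namespace"
        )
    n_before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    if len(df) < n_before:
        logger.warning(
            "%s: collapsed %d duplicate annotation row(s)", path, n_before - len(df)
        )
    return df


def write_annotation_table(table: pd.DataFrame, path: str | Path) -> None:
    table[["mag_id", "gene_id", "annotation_id"]].to_csv(path, sep="\t", index=False)


def read_blast_tab(path: str | Path, metagenome_id: str) -> list[HitRecord]:
    """Read BLAST tabular output (the conventional 12-column dialect).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. No header. Only query, subject, percent
    identity and bitscore are retained.
    """
    path = Path(path)
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} columns, expected 12"
                )
            try:
                pident = float(fields[2])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            try:
                records.append(
                    HitRecord(
                        metagenome_id=metagenome_id,
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=pident,
                        bitscore=bitscore,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_blast_tab(hits: Sequence[HitRecord], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (unused columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        repr(h.percent_identity),
                        "0", "0", "0", "0", "0", "0", "0", "0.0",
                        repr(h.bitscore),
                    ]
                )
                + "\n"
            )


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into {gene_id: sequence}.

    Keys are the first whitespace-delimited token of each header; a single
    trailing stop codon (*) is stripped. Duplicate ids and letters outside
    the 20-letter alphabet plus X are errors.
    """
    path = Path(path)
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        if gene_id in proteome:
            raise FormatError(f"{path}: duplicate sequence id {gene_id!r}")
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        illegal = set(seq) - AMINO_ALPHABET
        if illegal:
            raise FormatError(
                f"{path}: illegal character(s) {sorted(illegal)} in {gene_id!r}"
            )
        proteome[gene_id] = seq
    return proteome


def write_protein_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id, seq in proteome.items():
            fh.write(f">{gene_id}\n{seq}\n")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled 2-D table as TSV at full precision.

    Row and column labels must be unique; shortest-repr float formatting
    makes read_matrix(write_matrix(x)) exact.
    """
    if matrix.index.has_duplicates:
        raise ValueError("duplicate row labels")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate column labels")
    out = matrix.copy()
    out.index.name = out.index.name or "row_id"
    out.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df


def read_marker_catalog(path: str | Path) -> MarkerCatalog:
    """Read a marker catalog TSV (columns marker_id, function_category)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["marker_id", "function_category"], path)
    return MarkerCatalog(zip(df["marker_id"], df["function_category"]))


def write_marker_catalog(catalog: MarkerCatalog, path: str | Path) -> None:
    pd.DataFrame(catalog.items(), columns=["marker_id", "function_category"]).to_csv(
        path, sep="\t", index=False
    )


_MAG_COLUMNS = [
    "mag_id", "site", "phylum", "class", "order", "family", "genus",
    "species", "completeness", "contamination", "genome_length", "gene_count",
]


def read_mag_table(path: str | Path) -> list[MagRecord]:
    """Read MAG metadata TSV; lineage ranks use NA for unknown."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _MAG_COLUMNS, path)

    def _rank(v: str) -> str | None:
        return None if v in ("", "NA") else v

    records = []
    for _, row in df.iterrows():
        records.append(
            MagRecord(
                mag_id=row["mag_id"],
                site=row["site"],
                lineage=Lineage(
                    phylum=_rank(row["phylum"]),
                    class_=_rank(row["class"]),
                    order=_rank(row["order"]),
                    family=_rank(row["family"]),
                    genus=_rank(row["genus"]),
                    species=_rank(row["species"]),
                ),
                completeness=float(row["completeness"]),
                contamination=float(row["contamination"]),
                genome_length=int(row["genome_length"]),
                gene_count=int(row["gene_count"]),
            )
        )
    return records


def write_mag_table(mags: Sequence[MagRecord], path: str | Path) -> None:
    rows = []
    for m in mags:
        lin = m.lineage
        rows.append(
            {
                "mag_id": m.mag_id,
                "site": m.site,
                "phylum": lin.phylum or "NA",
                "class": lin.class_ or "NA",
                "order": lin.order or "NA",
                "family": lin.family or "NA",
                "genus": lin.genus or "NA",
                "species": lin.species or "NA",
                "completeness": repr(m.completeness),
                "contamination": repr(m.contamination),
                "genome_length": m.genome_length,
                "gene_count": m.gene_count,
            }
        )
    pd.DataFrame(rows, columns=_MAG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ani_table(path: str | Path) -> AniTable:
    """Read pairwise ANI TSV (columns mag_a, mag_b, ani; percent)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"mag_a": str, "mag_b": str, "ani": float})
    _require_columns(df, ["mag_a", "mag_b", "ani"], path)
    return AniTable(zip(df["mag_a"], df["mag_b"], df["ani"]))


def write_ani_table(ani: AniTable, path: str | Path) -> None:
    rows = sorted(ani.pairs())
    with open(path, "w") as fh:
        fh.write("mag_a\tmag_b\tani\n")
        for a, b, value in rows:
            fh.write(f"{a}\t{b}\t{value!r}\n")


def read_metagenome_table(path: str | Path):
    """Read metagenome info TSV.

    Columns: metagenome_id, site, sample_date (ISO), read_count, and an
    optional base_count. Returns a list of MetagenomeInfo.
    """
    from .marker_survey import MetagenomeInfo

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["metagenome_id", "site", "sample_date", "read_count"], path)
    metas = []
    for _, row in df.iterrows():
        base_count = None
        if "base_count" in df.columns:
            raw = row["base_count"]
            if isinstance(raw, str) and raw not in ("", "NA"):
                base_count = int(raw)
        metas.append(
            MetagenomeInfo(
                metagenome_id=row["metagenome_id"],
                site=row["site"],
                sample_date=date.fromisoformat(row["sample_date"]),
                read_count=int(row["read_count"]),
                base_count=base_count,
            )
        )
    return metas


def write_metagenome_table(metas, path: str | Path) -> None:
    rows = [
        {
            "metagenome_id": m.metagenome_id,
            "site": m.site,
            "sample_date": m.sample_date.isoformat(),
            "read_count": m.read_count,
            "base_count": m.base_count if m.base_count is not None else "NA",
        }
        for m in metas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    """Read a mapped-bases coverage TSV (mag_id, metagenome_id, mapped_bases)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        float_precision="round_trip",
        dtype={"mag_id": str, "metagenome_id": str, "mapped_bases": float},
    )
    _require_columns(df, ["mag_id", "metagenome_id", "mapped_bases"], path)
    if (df["mapped_bases"] < 0).any():
        raise FormatError(f"{path}: negative mapped_bases")
    return df


def write_coverage_table(table: pd.DataFrame, path: str | Path) -> None:
    table[["mag_id", "metagenome_id", "mapped_bases"]].to_csv(
        path, sep="\t", index=False
    )


def read_pathway_catalog(path: str | Path) -> list[PathwayDefinition]:
    """Read a YAML pathway catalog.

    Schema: a list of {pathway_id, steps: [{step_id, annotation_ids,
    unique}]}; `unique` marks steps diagnostic for the pathway (required in
    addition to the 50% completeness rule).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise FormatError(f"{path}: expected a top-level list of pathways")
    catalog = []
    seen: set[str] = set()
    for entry in raw:
        pid = entry["pathway_id"]
        if pid in seen:
            raise FormatError(f"{path}: duplicate pathway_id {pid!r}")
        seen.add(pid)
        steps = []
        for step in entry["steps"]:
            ids = frozenset(step["annotation_ids"])
            for a in ids:
                if not _check_namespace(a):
                    raise FormatError(
                        f"{path}: pathway {pid!r} step {step['step_id']!r}: "
                        f"annotation id {a!r} lacks a namespace"
                    )
            steps.append(
                StepDef(
                    step_id=step["step_id"],
                    annotation_ids=ids,
                    unique=bool(step.get("unique", False)),
                )
            )
        catalog.append(PathwayDefinition(pathway_id=pid, steps=tuple(steps)))
    return catalog


def write_pathway_catalog(catalog: Sequence[PathwayDefinition], path: str | Path) -> None:
    data = [
        {
            "pathway_id": p.pathway_id,
            "steps": [
                {
                    "step_id": s.step_id,
                    "annotation_ids": sorted(s.annotation_ids),
                    "unique": s.unique,
                }
                for s in p.steps
            ],
        }
        for p in catalog
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
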