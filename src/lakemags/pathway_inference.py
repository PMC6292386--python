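"""Pathway presence calling from genome annotations.

A pathway is a set of enzymatic steps; each step is satisfied when the
genome carries at least one gene annotated with any of the step's synonym
identifiers (KEGG orthologs, COGs, PFAMs, TIGRFAMs are pooled as evidence
for the same enzyme). A pathway is called present in a MAG when

* at least 50% of its steps are covered (completeness fraction >= 0.5), and
* every step flagged as unique to the pathway is covered.

Unique steps are diagnostic: a mostly complete pathway missing its
signature enzyme is not called. Multi-copy genes count once per step — the
rule is about presence, not dosage. Calls are aggregated by site and
effective phylum (Proteobacteria split into classes) to link metabolic
potential to taxonomic groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet, Iterable, Sequence

import pandas as pd

from .mag_catalog import MagRecord, effective_phylum

__all__ = [
    "StepDef",
    "PathwayDefinition",
    "PathwayCall",
    "PresenceMatrix",
    "step_covered",
    "score_pathway",
    "call_all",
    "aggregate_presence",
]

#: Minimum fraction of steps required for a presence call (inclusive).
PRESENCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class StepDef:
    """One enzymatic step: any of annotation_ids is evidence for it."""

    step_id: str
    annotation_ids: frozenset[str]
    unique: bool = False

    def __post_init__(self) -> None:
        if not self.annotation_ids:
            raise ValueError(f"step {self.step_id!r} has no annotation ids")


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    steps: tuple[StepDef, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"pathway {self.pathway_id!r} has no steps")
        step_ids = [s.step_id for s in self.steps]
        if len(set(step_ids)) != len(step_ids):
            raise ValueError(
                f"pathway {self.pathway_id!r} has duplicate step ids"
            )

    @property
    def unique_steps(self) -> tuple[StepDef, ...]:
        return tuple(s for s in self.steps if s.unique)

    @property
    def annotation_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.steps:
            out |= s.annotation_ids
        return frozenset(out)


@dataclass(frozen=True)
class PathwayCall:
    """Result of scoring one pathway in one MAG."""

    mag_id: str
    pathway_id: str
    completeness_fraction: float
    unique_steps_satisfied: bool
    present: bool

    def __post_init__(self) -> None:
        expected = (
            self.completeness_fraction >= PRESENCE_THRESHOLD
            and self.unique_steps_satisfied
        )
        if self.present != expected:
            raise ValueError(
                "present flag inconsistent with the 50%-plus-unique-steps rule"
            )


def step_covered(step: StepDef, mag_annotations: AbstractSet[str]) -> bool:
    """True iff any synonym of the step occurs in the MAG's annotation set."""
    return not step.annotation_ids.isdisjoint(mag_annotations)


def score_pathway(
    pathway: PathwayDefinition, mag_annotations: AbstractSet[str], mag_id: str = ""
) -> PathwayCall:
    """Score one pathway against one MAG's annotation set.

    completeness_fraction = covered steps / total steps (unique steps count
    toward the fraction like any other step); unique_steps_satisfied is
    vacuously true when the pathway declares no unique steps.
    """
    covered = sum(step_covered(s, mag_annotations) for s in pathway.steps)
    fraction = covered / len(pathway.steps)
    unique_ok = all(step_covered(s, mag_annotations) for s in pathway.unique_steps)
    return PathwayCall(
        mag_id=mag_id,
        pathway_id=pathway.pathway_id,
        completeness_fraction=fraction,
        unique_steps_satisfied=unique_ok,
        present=fraction >= PRESENCE_THRESHOLD and unique_ok,
    )


class PresenceMatrix:
    """MAG x pathway completeness fractions and boolean presence calls."""

    def __init__(
        self,
        calls: Iterable[PathwayCall],
        mag_ids: Sequence[str] | None = None,
        pathway_ids: Sequence[str] | None = None,
    ):
        self._calls = list(calls)
        if mag_ids is None:
            mag_ids = sorted({c.mag_id for c in self._calls})
        if pathway_ids is None:
            pathway_ids = sorted({c.pathway_id for c in self._calls})
        self.completeness = pd.DataFrame(
            0.0, index=pd.Index(mag_ids, name="mag_id"),
            columns=pd.Index(pathway_ids, name="pathway_id"),
        )
        self.presence = pd.DataFrame(
            False, index=self.completeness.index, columns=self.completeness.columns
        )
        for c in self._calls:
            self.completeness.loc[c.mag_id, c.pathway_id] = c.completeness_fraction
            self.presence.loc[c.mag_id, c.pathway_id] = c.present

    @property
    def calls(self) -> list[PathwayCall]:
        return list(self._calls)

    @property
    def mag_ids(self) -> list[str]:
        return list(self.completeness.index)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.completeness.columns)


def call_all(
    annotations: pd.DataFrame,
    catalog: Sequence[PathwayDefinition],
    mag_ids: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Score every (MAG, pathway) pair.

    `annotations` is a validated annotation table (mag_id, gene_id,
    annotation_id). MAGs listed in `mag_ids` but absent from the table get
    completeness 0 everywhere; by default the MAG set is taken from the
    table itself.
    """
    pathway_ids = [p.pathway_id for p in catalog]
    if len(set(pathway_ids)) != len(pathway_ids):
        dupes = sorted({p for p in pathway_ids if pathway_ids.count(p) > 1})
        raise ValueError(f"duplicate pathway_id(s) in catalog: {dupes}")

    ann_sets: dict[str, set[str]] = {
        mag: set(group["annotation_id"])
        for mag, group in annotations.groupby("mag_id")
    }
    all_mags = list(mag_ids) if mag_ids is not None else sorted(ann_sets)
    calls = [
        score_pathway(p, ann_sets.get(mag, set()), mag_id=mag)
        for mag in all_mags
        for p in catalog
    ]
    return PresenceMatrix(calls, mag_ids=all_mags, pathway_ids=pathway_ids)


def aggregate_presence(
    matrix: PresenceMatrix, mags: Sequence[MagRecord]
) -> pd.DataFrame:
    """Aggregate presence calls by (site, effective_phylum, pathway).

    Returns a long table with n_mags, n_present and fraction per group.
    Groups with zero present calls are still reported. Every mag_id in the
    matrix must appear in `mags`.
    """
    by_id = {m.mag_id: m for m in mags}
    unknown = [m for m in matrix.mag_ids if m not in by_id]
    if unknown:
        raise KeyError(f"mag_id(s) in matrix but not in metadata: {unknown}")

    rows = []
    groups: dict[tuple[str, str], list[str]] = {}
    for mag_id in matrix.mag_ids:
        rec = by_id[mag_id]
        groups.setdefault((rec.site, effective_phylum(rec)), []).append(mag_id)
    for (site, phylum), members in sorted(groups.items()):
        sub = matrix.presence.loc[members]
        for pathway_id in matrix.pathway_ids:
            n_present = int(sub[pathway_id].sum())
            rows.append(
                {
                    "site": site,
                    "effective_phylum": phylum,
                    "pathway_id": pathway_id,
                    "n_mags": len(members),
                    "n_present": n_present,
                    "fraction": n_present / len(members),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "site", "effective_phylum", "pathway_id",
            "n_mags", "n_present", "fraction",
        ],
    )
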