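"""Synthetic inputs with planted, known structure.

Every downstream stage of the pipeline can be exercised without any
download: this module generates MAG metadata and annotation tables with
known (planted) pathway content, marker-gene hit tables with known site
effects, and multi-year coverage/marker time series with known
diazotroph populations. Each generator returns the planted truth alongside
the data, so recovery can be checked exactly.

The statistical assumptions mirror each downstream stage:

* genome incompleteness is i.i.d. gene dropout at rate (1 - completeness),
  the simplest mechanism that stresses the 50%-of-steps presence rule the
  way real partial MAGs do; contamination adds foreign annotations;
* marker hit counts are negative-binomial with multiplicative site
  effects — overdispersed counts are the standard null for metagenomic hit
  counts and give the rank-sum comparison realistic noise;
* seasonal population dynamics are Gaussian blooms (a stand-in shape, not
  a mechanistic model), with nitrogenase counts coupled to the summed
  coverage of the planted diazotrophs.

Default sizes are the study design being emulated: 99/31/63 MAGs across
the three sites, completeness 50-99%, 94 epilimnion metagenomes over five
years (~19 per ice-free season), 47 per Trout Bog layer, 150 bp reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import HitRecord, MarkerCatalog, read_marker_catalog, read_pathway_catalog
from .mag_catalog import SITES, Lineage, MagRecord
from .marker_survey import MetagenomeInfo
from .pathway_inference import PathwayDefinition

__all__ = [
    "ConfigError",
    "SimConfig",
    "SimulatedMags",
    "SimulatedTimeseries",
    "demo_pathway_catalog",
    "demo_marker_catalog",
    "simulate_mags",
    "simulate_marker_hits",
    "simulate_timeseries",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def demo_pathway_catalog() -> list[PathwayDefinition]:
    """The bundled demonstration pathway catalog (synthetic id mapping)."""
    with resources.as_file(
        resources.files("lakemags.data") / "demo_pathways.yaml"
    ) as path:
        return read_pathway_catalog(path)


def demo_marker_catalog() -> MarkerCatalog:
    """The bundled functional marker catalog (nitrogenase TIGRFAMs etc.)."""
    with resources.as_file(
        resources.files("lakemags.data") / "demo_markers.tsv"
    ) as path:
        return read_marker_catalog(path)


#: (phylum, class or None, sampling weight) — a freshwater-like community.
DEFAULT_TAXA: tuple[tuple[str, str | None, float], ...] = (
    ("Actinobacteria", None, 0.20),
    ("Bacteroidetes", None, 0.12),
    ("Cyanobacteria", None, 0.08),
    ("Verrucomicrobia", None, 0.10),
    ("Planctomycetes", None, 0.06),
    ("Acidobacteria", None, 0.06),
    ("Chlorobi", None, 0.08),
    ("Proteobacteria", "Alphaproteobacteria", 0.08),
    ("Proteobacteria", "Betaproteobacteria", 0.12),
    ("Proteobacteria", "Gammaproteobacteria", 0.05),
    ("Proteobacteria", "Deltaproteobacteria", 0.03),
    ("Proteobacteria", "Epsilonproteobacteria", 0.02),
)


def _default_presence_prob() -> dict[tuple[str, str], float]:
    phyla = sorted({t[0] for t in DEFAULT_TAXA})
    prob: dict[tuple[str, str], float] = {}
    # near-universal polyamine metabolism; common assimilatory sulfate
    # reduction and mannose use
    for phylum in phyla:
        prob[(phylum, "polyamine_biosynthesis")] = 0.94
        prob[(phylum, "polyamine_degradation")] = 0.87
        prob[(phylum, "assimilatory_sulfate_reduction")] = 0.70
        prob[(phylum, "mannose_degradation")] = 0.50
    prob.update(
        {
            ("Cyanobacteria", "nitrogen_fixation"): 0.70,
            ("Chlorobi", "nitrogen_fixation"): 0.60,
            ("Proteobacteria", "nitrogen_fixation"): 0.30,
            ("Acidobacteria", "nitrogen_fixation"): 0.20,
            ("Verrucomicrobia", "nitrogen_fixation"): 0.20,
            ("Bacteroidetes", "nitrogen_fixation"): 0.15,
            ("Cyanobacteria", "cbb_carbon_fixation"): 0.90,
            ("Proteobacteria", "cbb_carbon_fixation"): 0.20,
            ("Chlorobi", "reductive_tca"): 0.90,
            ("Chlorobi", "dissimilatory_sulfate_reduction"): 0.70,
            ("Proteobacteria", "dissimilatory_sulfate_reduction"): 0.10,
            ("Bacteroidetes", "xylose_degradation"): 0.50,
            ("Planctomycetes", "xylose_degradation"): 0.50,
            ("Verrucomicrobia", "xylose_degradation"): 0.50,
            ("Actinobacteria", "xylose_degradation"): 0.40,
            ("Proteobacteria", "aerobic_anoxygenic_phototrophy"): 0.40,
            ("Acidobacteria", "aerobic_anoxygenic_phototrophy"): 0.10,
        }
    )
    return prob


def _default_site_effect() -> dict[tuple[str, str], float]:
    # nitrogenase most abundant in the humic hypolimnion, then its
    # epilimnion; oxidative sulfur markers and RuBisCO enriched in the
    # humic lake; everything else flat
    return {
        ("nitrogen fixation", "troutbog_hypo"): 5.0,
        ("nitrogen fixation", "troutbog_epi"): 2.0,
        ("sulfide oxidation", "troutbog_epi"): 3.0,
        ("sulfide oxidation", "troutbog_hypo"): 3.0,
        ("thiosulfate oxidation", "troutbog_epi"): 3.0,
        ("thiosulfate oxidation", "troutbog_hypo"): 3.0,
        ("carbon fixation", "troutbog_epi"): 2.0,
        ("denitrification", "troutbog_hypo"): 3.0,
    }


#: Background (non-catalog) annotation pool: housekeeping stand-ins.
_BACKGROUND_POOL = tuple(f"KO:K9{i:04d}" for i in range(200))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the emulated design as defaults.

    seed drives every random draw; a fixed config is byte-reproducible
    across process restarts.
    """

    seed: int = 0
    n_mags_per_site: Mapping[str, int] = field(
        default_factory=lambda: {
            "mendota_epi": 99,
            "troutbog_epi": 31,
            "troutbog_hypo": 63,
        }
    )
    taxa: tuple[tuple[str, str | None, float], ...] = DEFAULT_TAXA
    pathways: tuple[PathwayDefinition, ...] = ()
    pathway_presence_prob: Mapping[tuple[str, str], float] = field(
        default_factory=_default_presence_prob
    )
    default_presence_prob: float = 0.05
    completeness_range: tuple[float, float] = (0.5, 0.99)
    contamination_rate: float = 0.02
    n_background_genes: int = 60
    # marker-survey arm
    marker_base_rate: float = 5e-6  # expected hits per read per category
    marker_site_effect: Mapping[tuple[str, str], float] = field(
        default_factory=_default_site_effect
    )
    nb_dispersion: float = 2.0
    decoy_fraction: float = 0.2  # sub-threshold (10-30% identity) junk hits
    # time-series arm
    n_years: int = 5
    start_year: int = 2008
    n_samples_per_year: int = 19
    bloom_width_days: float = 30.0
    dominant_is_diazotroph: tuple[bool, ...] = (True, False, False, True, True)
    marker_copy_factor: float = 50.0  # nif hits per unit diazotroph coverage
    timeseries_nb_dispersion: float | None = 5.0  # None = noise-free coupling
    timeseries_read_count: int = 2_000_000
    minor_diazotroph: bool = True  # perennial low-level diazotroph population

    def resolved_pathways(self) -> tuple[PathwayDefinition, ...]:
        return self.pathways if self.pathways else tuple(demo_pathway_catalog())

    def validate(self) -> None:
        if not self.taxa:
            raise ConfigError("taxa list is empty")
        if any(w <= 0 for _, _, w in self.taxa):
            raise ConfigError("taxon weights must be positive")
        for key, p in self.pathway_presence_prob.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"presence probability {p} for {key} outside [0, 1]")
        if not 0 <= self.default_presence_prob <= 1:
            raise ConfigError("default_presence_prob outside [0, 1]")
        lo, hi = self.completeness_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError(f"completeness_range {self.completeness_range} invalid")
        if not 0 <= self.contamination_rate <= 1:
            raise ConfigError("contamination_rate outside [0, 1]")
        for key, mult in self.marker_site_effect.items():
            if mult <= 0:
                raise ConfigError(f"site effect {mult} for {key} must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not 0 <= self.decoy_fraction:
            raise ConfigError("decoy_fraction must be non-negative")
        if self.n_samples_per_year < 2:
            raise ConfigError("need at least 2 samples per year")
        if self.bloom_width_days <= 0:
            raise ConfigError("bloom_width_days must be positive")
        if len(self.dominant_is_diazotroph) < self.n_years:
            raise ConfigError(
                "dominant_is_diazotroph must cover every simulated year"
            )


@dataclass(frozen=True)
class SimulatedMags:
    mags: list[MagRecord]
    annotations: pd.DataFrame  # mag_id, gene_id, annotation_id
    truth: pd.DataFrame  # mag_id, pathway_id, planted (bool)


@dataclass(frozen=True)
class SimulatedTimeseries:
    mags: list[MagRecord]
    metas: list[MetagenomeInfo]
    coverage: pd.DataFrame  # mag_id, metagenome_id, mapped_bases
    hits: list[HitRecord]
    diazotrophs: frozenset[str]
    dominant_by_year: dict[int, str]


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with given mean and size/dispersion parameter k
    (variance = mean + mean^2 / k)."""
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_mags(config: SimConfig) -> SimulatedMags:
    """Generate MAG metadata and annotations with planted pathway content.

    Each MAG draws a taxon by weight and a completeness uniform in
    completeness_range. Every pathway is planted with its (phylum, pathway)
    probability; a planted pathway contributes one gene per step annotation
    id. Background housekeeping genes come from a pool disjoint from the
    catalog. Each gene then survives independently with probability equal
    to the completeness (i.i.d. dropout), and contamination adds foreign
    annotations (drawn from catalog + background ids) at contamination_rate.

    The truth table records planted presence per (MAG, pathway); with
    dropout 0 and contamination 0 and a catalog whose annotation ids are
    disjoint across pathways (the bundled demonstration catalog is),
    downstream presence calls equal the truth exactly.
    """
    config.validate()
    catalog = config.resolved_pathways()
    rng = np.random.default_rng([config.seed, 0])
    weights = np.array([w for _, _, w in config.taxa], dtype=float)
    weights /= weights.sum()

    mags: list[MagRecord] = []
    ann_rows: list[tuple[str, str, str]] = []
    truth_rows: list[tuple[str, str, bool]] = []
    all_catalog_ids = sorted({a for p in catalog for a in p.annotation_ids})
    contaminant_pool = all_catalog_ids + list(_BACKGROUND_POOL)

    for site in SITES:
        n_site = int(config.n_mags_per_site.get(site, 0))
        for i in range(n_site):
            mag_id = f"{site}.{i:03d}"
            phylum, class_, _ = config.taxa[rng.choice(len(config.taxa), p=weights)]
            completeness = float(
                rng.uniform(config.completeness_range[0], config.completeness_range[1])
            )

            genes: list[str] = []  # annotation id per gene, pre-dropout
            for pathway in catalog:
                prob = config.pathway_presence_prob.get(
                    (phylum, pathway.pathway_id), config.default_presence_prob
                )
                planted = bool(rng.random() < prob)
                truth_rows.append((mag_id, pathway.pathway_id, planted))
                if planted:
                    for step in pathway.steps:
                        genes.extend(sorted(step.annotation_ids))
            genes.extend(
                rng.choice(len(_BACKGROUND_POOL), size=config.n_background_genes)
                .astype(int)
                .tolist()
            )
            # replace pool indices with ids
            genes = [
                g if isinstance(g, str) else _BACKGROUND_POOL[g] for g in genes
            ]

            kept = [g for g in genes if rng.random() < completeness]
            n_contam = int(rng.binomial(len(kept), config.contamination_rate)) if kept else 0
            contam = [
                contaminant_pool[j]
                for j in rng.choice(len(contaminant_pool), size=n_contam).astype(int)
            ]
            final = kept + contam
            for gi, ann in enumerate(final):
                ann_rows.append((mag_id, f"{mag_id}.g{gi:04d}", ann))

            n_total = len(final)
            realized_contam = 100.0 * n_contam / n_total if n_total else 0.0
            mags.append(
                MagRecord(
                    mag_id=mag_id,
                    site=site,
                    lineage=Lineage(phylum=phylum, class_=class_),
                    completeness=100.0 * completeness,
                    contamination=realized_contam,
                    genome_length=max(1, n_total * 1000),
                    gene_count=max(n_total, 1),
                )
            )

    annotations = pd.DataFrame(
        ann_rows, columns=["mag_id", "gene_id", "annotation_id"]
    )
    truth = pd.DataFrame(truth_rows, columns=["mag_id", "pathway_id", "planted"])
    return SimulatedMags(mags=mags, annotations=annotations, truth=truth)


def simulate_marker_hits(
    config: SimConfig,
    catalog: MarkerCatalog,
    metagenomes: Sequence[tuple[str, str, int]],
) -> list[HitRecord]:
    """Generate homology hits per metagenome with planted site effects.

    For each (metagenome, function category) the hit count is negative
    binomial with mean = marker_base_rate x read_count x site effect and
    dispersion nb_dispersion. Hits land on random markers of the category
    with percent identity uniform on [30, 100]; a Poisson number of
    sub-threshold decoys (identity on [10, 30)) with mean decoy_fraction x
    the category mean is added per category. Every hit gets a distinct ORF
    id, so the best-hit filter retains exactly the above-threshold hits.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    for mid, site, read_count in metagenomes:
        if site not in SITES:
            raise ConfigError(f"metagenome {mid!r} has unknown site {site!r}")
        if read_count <= 0:
            raise ConfigError(f"metagenome {mid!r} has non-positive read_count")

    hits: list[HitRecord] = []
    for mid, site, read_count in metagenomes:
        orf_counter = 0
        for category in catalog.categories:
            markers = catalog.markers_in(category)
            effect = config.marker_site_effect.get((category, site), 1.0)
            mean = config.marker_base_rate * read_count * effect
            n_real = _nb_draw(rng, mean, config.nb_dispersion)
            n_decoy = int(rng.poisson(config.decoy_fraction * mean))
            for j in range(n_real + n_decoy):
                decoy = j >= n_real
                pident = (
                    float(rng.uniform(10.0, 30.0 - 1e-9))
                    if decoy
                    else float(rng.uniform(30.0, 100.0))
                )
                hits.append(
                    HitRecord(
                        metagenome_id=mid,
                        query_id=f"{mid}.orf{orf_counter:06d}",
                        subject_id=markers[int(rng.choice(len(markers)))],
                        percent_identity=pident,
                        bitscore=float(rng.uniform(50.0, 250.0)),
                    )
                )
                orf_counter += 1
    return hits


def _season_dates(year: int, n: int) -> list[date]:
    """n sampling dates evenly spaced over the ice-free season (May-Oct)."""
    start, end = date(year, 5, 1), date(year, 10, 31)
    span = (end - start).days
    return [start + timedelta(days=round(k * span / (n - 1))) for k in range(n)]


def simulate_timeseries(config: SimConfig) -> SimulatedTimeseries:
    """Generate a multi-year bloom/marker time series with planted coupling.

    One Cyanobacteria MAG per year gets a dominating mid-summer Gaussian
    bloom (amplitude ~10x the background populations); per-sample
    nitrogenase hit counts follow copy_factor x the summed coverage of the
    planted diazotrophs, with negative-binomial noise
    (timeseries_nb_dispersion) or exactly (None). In the exact regime the
    planted diazotroph coverages are rescaled to the integer hit counts so
    the proportionality holds to machine precision.

    Whether each year's dominant MAG fixes nitrogen comes from
    dominant_is_diazotroph, reproducing the design in which marker
    correlation is expected in diazotroph-dominated years only.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    years = [config.start_year + k for k in range(config.n_years)]
    nif_markers = demo_marker_catalog().markers_in("nitrogen fixation")

    # sampling design: one metagenome per date, fixed size
    metas: list[MetagenomeInfo] = []
    for year in years:
        for d in _season_dates(year, config.n_samples_per_year):
            metas.append(
                MetagenomeInfo(
                    metagenome_id=f"MEN_{d.isoformat()}",
                    site="mendota_epi",
                    sample_date=d,
                    read_count=config.timeseries_read_count,
                )
            )

    # populations: one dominant bloomer per year + two perennial minor ones
    genome_length = 3_000_000
    mag_ids = [f"CYANO_{y}" for y in years] + ["CYANO_minor1", "CYANO_minor2"]
    mags = [
        MagRecord(
            mag_id=mid,
            site="mendota_epi",
            lineage=Lineage(phylum="Cyanobacteria", order="Nostocales"),
            completeness=90.0,
            contamination=2.0,
            genome_length=genome_length,
            gene_count=3000,
        )
        for mid in mag_ids
    ]
    dominant_by_year = {y: f"CYANO_{y}" for y in years}
    diazotrophs = frozenset(
        f"CYANO_{y}"
        for y, is_diazo in zip(years, config.dominant_is_diazotroph)
        if is_diazo
    )
    if config.minor_diazotroph:
        diazotrophs |= frozenset(["CYANO_minor1"])

    # Ideal normalized coverage per (mag, sample). The year's dominant
    # bloomer and the non-diazotrophic minor population follow Gaussian
    # blooms; the perennial minor diazotroph and off-year bloomers sit at
    # flat background levels so that in years whose dominant MAG does not
    # fix nitrogen the nitrogenase signal carries no seasonal shape.
    coverage: dict[tuple[str, str], float] = {}
    width = config.bloom_width_days
    for year in years:
        year_metas = [m for m in metas if m.sample_date.year == year]
        mid_season = date(year, 7, 20).toordinal()
        peak_dom = mid_season + rng.normal(0, 10)
        peak_minor2 = mid_season + rng.normal(0, 20)
        for m in year_metas:
            t = m.sample_date.toordinal()
            coverage[(dominant_by_year[year], m.metagenome_id)] = 10.0 * float(
                np.exp(-((t - peak_dom) ** 2) / (2 * width**2))
            )
            coverage[("CYANO_minor1", m.metagenome_id)] = 0.8
            coverage[("CYANO_minor2", m.metagenome_id)] = 0.6 * float(
                np.exp(-((t - peak_minor2) ** 2) / (2 * width**2))
            )
            for other in years:
                if other != year:
                    coverage[(dominant_by_year[other], m.metagenome_id)] = 0.02

    # nitrogenase counts coupled to summed diazotroph coverage
    hits: list[HitRecord] = []
    for m in metas:
        total_diaz = sum(coverage[(mid, m.metagenome_id)] for mid in diazotrophs)
        mean = config.marker_copy_factor * total_diaz
        if config.timeseries_nb_dispersion is None:
            count = int(round(mean))
            if mean > 0 and count != mean:
                # exact-coupling regime: quantize coverages to the integer
                # count so marker hits stay exactly proportional
                scale = count / mean
                for mid in diazotrophs:
                    coverage[(mid, m.metagenome_id)] *= scale
        else:
            count = _nb_draw(rng, mean, config.timeseries_nb_dispersion)
        for j in range(count):
            hits.append(
                HitRecord(
                    metagenome_id=m.metagenome_id,
                    query_id=f"{m.metagenome_id}.orf{j:06d}",
                    subject_id=nif_markers[j % len(nif_markers)],
                    percent_identity=float(rng.uniform(30.0, 100.0)),
                    bitscore=float(rng.uniform(50.0, 250.0)),
                )
            )

    # invert normalized coverage to mapped bases
    gigabases = config.timeseries_read_count * 150 / 1e9
    cov_rows = [
        {
            "mag_id": mid,
            "metagenome_id": meta_id,
            "mapped_bases": value * genome_length * gigabases,
        }
        for (mid, meta_id), value in sorted(coverage.items())
    ]
    coverage_df = pd.DataFrame(
        cov_rows, columns=["mag_id", "metagenome_id", "mapped_bases"]
    )
    return SimulatedTimeseries(
        mags=mags,
        metas=metas,
        coverage=coverage_df,
        hits=hits,
        diazotrophs=diazotrophs,
        dominant_by_year=dominant_by_year,
    )
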