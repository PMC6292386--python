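# Methods

This note documents the models, rules and numerical choices behind
`lakemags`, and what the synthetic-data generator does and does not
emulate.

## Study design being emulated

The package models a comparative, genome-resolved survey of two stratified
lakes sampled over multiple ice-free seasons: a eutrophic epilimnion
(`mendota_epi`) and the epilimnion and hypolimnion of a humic lake
(`troutbog_epi`, `troutbog_hypo`). The default synthetic design mirrors
that setting: 99/31/63 MAGs per site (193 total), genome completeness
drawn uniformly on 50–99%, 94 epilimnion metagenomes over five years
(~19 per season) and 47 per humic-lake layer, 150 bp reads.

## MAG catalog

* **Quality rule.** A MAG is retained when completeness ≥ 50% **and**
  contamination < 10% (the medium/high-quality draft-genome convention).
  The asymmetric boundary semantics ("at least" vs "less than") are fixed
  and tested.
* **Population grouping.** Pairs with ANI above the threshold (default 99;
  97 available — both conventions circulate and neither is endorsed here)
  are linked, and populations are the connected components (single
  linkage). Single linkage is the least-assumption closure of a pairwise
  flag list; the representative is the most complete member (ties: lower
  contamination, then lexicographic id).
* **Proteome nitrogen.** Mean nitrogen atoms per residue counts the full
  polypeptide content: one backbone amide N per residue plus side-chain N
  (N/Q/K/W +1, H +2, R +3). `X` contributes the unweighted alphabet
  average (1.45). Peptide-bond water loss does not move any nitrogen, so
  the per-residue count is unaffected by chain length.

## Pathway presence rule

A pathway definition is an ordered set of enzymatic steps; each step lists
the annotation ids (KO/COG/PFAM/TIGRFAM, namespaced to avoid collisions)
accepted as evidence, and may be flagged *unique* (diagnostic). A genome's
call is:

* completeness fraction = covered steps / total steps (unique steps count
  like any other step);
* present ⇔ fraction ≥ 0.5 (inclusive) **and** all unique steps covered
  (vacuously true with none).

Multi-copy genes count once per step: the rule is about presence of a
capability, not dosage. Evidence from the four annotation systems is
pooled per step, so a step is covered by any synonym. Aggregation is by
(site, effective phylum), where Proteobacteria is replaced by its class
(the phylum is too heterogeneous to be one group) and missing ranks yield
`Unclassified-<parent>` labels.

The bundled `data/demo_pathways.yaml` is a small demonstration catalog
(10 pathways, 3–5 steps each) with illustrative id mappings, not a curated
KEGG/MetaCyc export; its annotation ids are deliberately disjoint across
pathways so planted-truth simulations are unambiguous. Real catalogs may
share ids between pathways; the scoring rule handles that, but the
exact-truth-recovery guarantee is stated for disjoint catalogs only.

## Marker survey

* **Filtering.** Identity cutoff 30%, inclusive. By default only the best
  hit per ORF (highest bitscore, ties by lexicographic subject) is
  counted, so one read cannot be counted against several related markers
  of the same family; `best_hit_only=False` keeps all passing hits.
* **Normalization.** Hits per million reads. "Metagenome size" could also
  be read as base pairs; `MetagenomeInfo.base_count` carries it where
  available and the coverage arm uses it, but marker abundances normalize
  by reads.
* **Test.** Two-sided Wilcoxon rank-sum. The exact null distribution is
  enumerated when min(n₁, n₂) ≤ 8 and the pooled sample is tie-free;
  otherwise the normal approximation with tie and continuity corrections.
  Only two site pairs are compared — the two epilimnia, and the two layers
  of the humic lake; the eutrophic-epilimnion vs humic-hypolimnion
  contrast confounds lake type with depth and is not run. The Bonferroni
  family is the full grid of (category × tested pair), the most
  conservative reading of "corrected for multiple pairwise testing".
  Direction ("higher site") is by median, consistent with a rank test,
  and only reported when the adjusted p-value clears α.

## Glycoside hydrolases

GH coding density = 100 × (genes with ≥ 1 GH domain) / gene count; a gene
with several GH domains counts once for density but contributes each
distinct family to diversity. Subfamilies (GH13_10) collapse to the parent
family by default (`collapse_subfamilies=False` keeps them). Non-GH CAZyme
classes (GT/PL/CE/CBM/AA) are parsed, ignored and logged. The
density–diversity association is Pearson's r, reported as r² with the
two-sided t-transform p-value (n − 2 df); the r² framing implies a linear
fit, so a rank correlation is deliberately not the default. The gene-count
denominator is taken from MAG metadata as given (whether it excludes RNA
genes is upstream's choice).

## Time series

Normalized coverage is (mapped bases / genome length) / metagenome
gigabases — mean depth per one-gigabase metagenome — with read_count × 150
bp standing in when base counts are absent. The per-year dominant MAG is
the group member with the highest within-year mean coverage (stable
against sampling gaps), reported with a dominance ratio (top/runner-up
mean) so borderline years are visible; exact ties break lexicographically
and are logged. Series correlation is Pearson on inner-joined dates
(Spearman and log1p transforms available as flags), requiring ≥ 3 shared
dates.

## Synthetic-data generator

The generator is the package's study stand-in; each arm implements the
statistical assumption the corresponding analysis is built on.

* **Genomes.** Each MAG draws a taxon by weight from a freshwater-like
  community (12 taxa, Proteobacteria split into five classes) and plants
  each pathway with a per-(phylum, pathway) probability; defaults encode
  the qualitative ecology being emulated (polyamine pathways near-
  universal at 0.94/0.87, nitrogen fixation concentrated in Cyanobacteria
  and Chlorobi, reductive TCA in Chlorobi, and so on). Incompleteness is
  i.i.d. gene dropout at rate 1 − completeness — the simplest mechanism
  that stresses the 50% rule the way real partial bins do — and
  contamination adds foreign annotations at a per-gene rate (default 2%).
  Real MAG incompleteness is not i.i.d. (whole contigs drop out together),
  so passing recall bounds here shows the scoring rule behaves correctly
  under random gene loss, not that real bins lose genes randomly.
* **Marker counts.** Negative binomial with mean = base rate × read count
  × site effect and dispersion k = 2 (variance m + m²/k): overdispersed
  counts are the standard null for metagenomic hit tallies. Hits receive
  identities uniform on [30, 100] plus a configurable fraction of
  sub-threshold decoys on [10, 30); each hit gets a distinct ORF id.
  Default site effects plant nitrogenase enrichment in the humic lake
  (hypolimnion strongest) and oxidative sulfur markers in both humic
  layers.
* **Seasons.** Population trajectories are Gaussian blooms (peak ± jitter
  around mid-July, width 30 d) — a stand-in shape chosen to be unimodal
  and seasonal, not a mechanistic model. One Cyanobacteria MAG per year
  receives a dominating bloom (amplitude 10 vs 0.6–0.8 background);
  whether each year's dominant fixes nitrogen follows
  `dominant_is_diazotroph` (default True/False/False/True/True across
  2008–2012). Nitrogenase counts follow copy_factor × the summed coverage
  of planted diazotrophs with NB noise; the perennial minor diazotroph and
  off-year populations are held at flat coverage so non-diazotroph years
  carry no seasonal marker shape to correlate with. With noise disabled
  the generator draws the integer counts first and rescales the planted
  diazotroph coverages onto them, making the marker–coverage
  proportionality exact rather than exact-up-to-rounding; this keeps the
  noise-free limit a real identity instead of an approximation.

Determinism: every generator seeds `numpy.random.default_rng` with
`[seed, arm-index]`, so a fixed `SimConfig` reproduces outputs exactly
across processes, and the three arms are decorrelated.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` run the designs above at the
default sizes (193 MAGs, 47 metagenomes per compared site, 5 × 19
time-series samples) with replicate counts of 100 for power/pattern
checks, 500 for null calibration and 10,000 for moment calibration;
thresholds on stochastic checks (e.g. power ≥ 95%, type-I error in
[0.03, 0.07], false-positive rate ≤ 10%) carry the Monte-Carlo margins
those replicate counts support. Exhaustive checks (rank-sum enumeration up
to n = 6 per group; all annotation subsets of an 11-id universe) are exact.

## Known limitations

* The pathway catalog shipped is demonstrational; scientific use requires
  a curated catalog in the same YAML schema.
* Pathway presence is genomic potential only — no expression or activity
  inference, and no dosage weighting.
* The generator does not simulate reads, assembly, binning, or
  phylogenetically realistic annotation error; conclusions about those
  upstream steps cannot be drawn from these tests.
* Single-linkage population grouping can chain distinct populations
  through intermediates at permissive ANI thresholds; inspect groups when
  using 97.
* Marker abundance normalization ignores gene length; cross-category
  comparisons of absolute levels inherit that bias, while between-site
  comparisons of one category (the supported use) do not.
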