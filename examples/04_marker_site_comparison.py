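"""Functional marker gene survey: abundance normalization + site contrasts.

Simulates BLAST-style hits for the full metagenome design (94 eutrophic
epilimnion + 47 + 47 humic layer samples), filters at 30% identity with
best-hit-per-ORF, normalizes to hits per million reads, and tests the two
site contrasts with Wilcoxon rank-sum + Bonferroni.
"""

from datetime import date

from lakemags import (
    MetagenomeInfo,
    SimConfig,
    abundance_table,
    compare_sites,
    demo_marker_catalog,
    filter_hits,
    simulate_marker_hits,
)

cfg = SimConfig(seed=42)
catalog = demo_marker_catalog()
design = (
    [(f"ME{i:02d}", "mendota_epi", 2_000_000) for i in range(94)]
    + [(f"TE{i:02d}", "troutbog_epi", 2_000_000) for i in range(47)]
    + [(f"TH{i:02d}", "troutbog_hypo", 2_000_000) for i in range(47)]
)
metas = [MetagenomeInfo(m, s, date(2008, 6, 1), rc) for m, s, rc in design]

hits = simulate_marker_hits(cfg, catalog, design)
kept = filter_hits(hits)  # 30% identity cutoff, best hit per ORF
print(f"{len(hits)} raw hits -> {len(kept)} retained after filtering")

ab = abundance_table(kept, catalog, metas)
comparisons = compare_sites(ab, metas)

print(f"\n{len(comparisons)} comparisons "
      f"({len(catalog.categories)} categories x 2 site pairs), Bonferroni-corrected:")
for c in comparisons:
    if c.higher_site != "ns":
        print(f"  {c.function_category:22s} {c.site_a} vs {c.site_b}: "
              f"p_adj = {c.p_adjusted:.2e}, higher in {c.higher_site}")
# The planted design enriches nitrogenase in the humic lake (strongest in
# the hypolimnion) and oxidative sulfur markers in both humic layers; only
# those contrasts should reach significance.
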