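"""Marker-assisted selection: favorable alleles, efficiency, best haplotype.

At each QTL the favorable allele is the one whose homozygote group has
the lower mean rating.  Selection efficiency averages favorable-allele
enrichment among the most resistant accessions (rating 1) and
unfavorable-allele enrichment among the most susceptible.
"""

import numpy as np

import podpop as pp

cfg = pp.SimulationConfig(n_wild=50, panel_sizes=(400,), snps_per_chrom=50,
                          n_qtl=12, heritability=0.8, missing_rate=0.0,
                          het_rate=0.0, seed=41)
panels, truth = pp.simulate_panels(cfg)
panel = panels[1]
records = pp.simulate_trait(panel, truth, cfg)
ratings = np.array([t.rating for t in records])

tab = pp.favorable_alleles(ratings, panel, truth.qtl_snp_ids)
pct = pp.group_percentages(tab, ratings)
print("favorable-allele % by rating group (first 3 QTLs):")
print(pct.head(3).round(1).to_string())

eff = pp.panel_selection_efficiency(pct)
per_snp = sorted(((pp.snp_selection_efficiency(s, pct), s) for s in tab.snp_ids),
                 reverse=True)
print(f"panel selection efficiency: {eff:.2f} "
      f"(0.5 = uninformative markers, 1.0 = perfect)")
print("top 3 SNPs by efficiency:",
      [(s, round(e, 2)) for e, s in per_snp[:3]])

ranked = pp.rank_haplotypes(tab, ratings)
best = ranked.iloc[0]
print(f"best haplotype: {best.accession_id} carries {best.n_favorable} of "
      f"{len(tab.snp_ids)} favorable alleles ({best.percent:.1f}%), "
      f"rating {best.rating:.0f}")
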