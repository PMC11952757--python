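"""Simulate a wild + cultivated study design and run the genotype QC chain.

Builds one wild and two cultivated panels sharing a SNP map, with
domestication sweeps at 5% of SNPs, then applies the QC order used for
real panels: heterozygotes to missing, 10% missingness filter,
across-panel monomorphic filter, common-SNP intersection, and LD-kNN
imputation of the remaining gaps.
"""

import podpop as pp

cfg = pp.SimulationConfig(n_wild=150, panel_sizes=(150, 150),
                          snps_per_chrom=25, seed=11)
panels, truth = pp.simulate_panels(cfg)
print(f"simulated {len(panels)} panels x {panels[0].n_snps} SNPs; "
      f"{len(truth.swept_snp_ids)} swept SNPs, {len(truth.qtl_snp_ids)} QTLs")

panels = [pp.filter_missingness(pp.hets_to_missing(p)) for p in panels]
panels = pp.intersect_snps(panels)
panels = pp.filter_monomorphic(panels, scope="across-all")
print(f"{panels[0].n_snps} SNPs common and polymorphic after QC")

imputed = [pp.impute_ld_knn(p) for p in panels]
print("missing fraction after LD-kNN imputation:",
      [round(p.missing_fraction(), 4) for p in imputed])
# Every SNP that still had observed carriers is now complete; downstream
# stages (PCA, kinship, scans) require the imputed panels.
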