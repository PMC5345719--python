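"""Single-QTL genome scan with multiple imputation on a simulated cross.

One QTL (additive 0.5, dominance 0.25) on chromosome 3 at 60 cM; 600 F2
individuals.  The scan fits trait ~ additive + dominance on a 1-cM grid of
genotype draws, combines evidence over draws, and calibrates the
genome-wide LOD threshold by 200 phenotype permutations.
"""

from f2gbs import F2SimConfig, QTLSpec, scan, sim_f2, sim_map

cfg = F2SimConfig(n_individuals=600, n_markers=200, seed=41,
                  qtl=(QTLSpec("3", 60.0, additive=0.5, dominance=0.25),))
gmap = sim_map(cfg)
g, phenotype, _ = sim_f2(gmap, cfg)

result = scan(g, gmap, phenotype, step_cM=1.0, n_draws=8, n_perm=200, seed=42)
print(f"genome-wide LOD threshold (alpha=0.05): {result.threshold:.2f}")
for p in result.peaks:
    print(f"chr {p.chromosome}: peak {p.position_cM:.0f} cM, "
          f"LOD {p.lod:.1f}, 95% interval "
          f"[{p.interval_cM[0]:.0f}, {p.interval_cM[1]:.0f}] cM, "
          f"{p.percent_variance:.1f}% variance, "
          f"a={p.additive_effect:.2f}, d={p.dominance_effect:.2f}")
print("\nThe peak should fall within a few cM of the simulated QTL at 60 cM")
print("and the effects should recover a=0.5, d=0.25 up to sampling error;")
print("a positive additive effect means the parent-2 allele raises the trait.")
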