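"""Show how genotype errors distend a genetic map and correction restores it.

Simulates the 12-chromosome cross (1270 cM total), flips 2% of genotypes
to random wrong codes, and estimates the map by chained two-point EM
before and after error correction.
"""

from f2gbs import F2SimConfig, estimate_map, postprocess, sim_f2, sim_map
from f2gbs.simulate import inject_genotype_errors

cfg = F2SimConfig(n_individuals=500, n_markers=400, seed=31)
gmap = sim_map(cfg)
g, _, _ = sim_f2(gmap, cfg)

clean_est = estimate_map(g).total_length_cM()
noisy = inject_genotype_errors(g, error_rate=0.02, seed=32)
noisy_est = estimate_map(noisy).total_length_cM()
fixed, _ = postprocess(noisy)
fixed_est = estimate_map(fixed).total_length_cM()

print(f"true simulated map : {gmap.total_length_cM():7.1f} cM")
print(f"clean data estimate: {clean_est:7.1f} cM")
print(f"with 2% errors     : {noisy_est:7.1f} cM")
print(f"after correction   : {fixed_est:7.1f} cM")
print("\nEvery isolated wrong genotype fakes a double recombinant, so raw")
print("error-ridden data inflates the map severely; imputation plus the two")
print("correction passes bring the total back near the simulated truth.")
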