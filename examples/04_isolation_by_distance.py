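"""Isolation by distance: restricted vs strong migration.

Pairwise Weir-Cockerham FST between sampling sites is linearized as
FST/(1-FST) and compared with great-circle distance in a Mantel permutation
test. A stepping-stone expansion with m = 0.01 shows a clear IBD signal; the
same landscape with m = 0.25 is well mixed and the signal collapses.
"""

from refugia import SimConfig, ibd_test, simulate

for m in (0.01, 0.25):
    sim = simulate(SimConfig(seed=1, migration=m))
    res = ibd_test(sim.genotypes, sim.variants, sim.samples, n_perm=999, seed=1)
    print(f"migration {m:.2f}: Mantel r = {res.r:+.3f}, p = {res.p:.4f} "
          f"({res.n_snps_used} LD-pruned SNPs, {res.n_sites} sites)")
# SNP filtering follows the standard recipe: MAF > 10% then PLINK-style
# indep-pairwise 50 10 0.2 pruning; p is one-tailed for the IBD hypothesis.
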