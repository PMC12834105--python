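"""Simulate a postglacial range expansion and write its data files.

A refuge deme in one corner of an 8x8 grid expands wave by wave with 5
founders per new deme; 5 individuals per deme are sampled ~250 generations
after the expansion completes and written as VCF + sample CSV + an LGM
presence raster.
"""

from refugia import SimConfig, simulate, write_outputs

cfg = SimConfig(seed=1)
sim = simulate(cfg)
paths = write_outputs(sim, "scratch/example_sim")

print(f"simulated {sim.genotypes.n_individuals} individuals at "
      f"{sim.genotypes.n_sites} segregating sites")
print(f"refuge (expansion origin) at lon/lat {sim.origin_lonlat}")
print("files:", ", ".join(paths.values()))
# n_sites is every biallelic SNP segregating among the sampled individuals;
# the presence raster marks the demes colonized at the glacial maximum
# snapshot (here: the refuge deme only).
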