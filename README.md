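# refugia

Spatial population genomics of postglacial range expansions.

Species that survived the Last Glacial Maximum in a restricted refuge and
re-expanded afterwards leave a spatial footprint in their genomes: genetic
diversity declines with distance from the refuge, runs of homozygosity
(ROH) accumulate along the expansion axis, deleterious variants surf on the
wave front, and genetic differentiation builds up with geographic distance
when gene flow is restricted. `refugia` packages the statistics used to
read that footprint from genotype data and sampling coordinates, plus a
forward serial-founder simulator that generates all inputs synthetically —
so every estimator can be exercised on data whose generating process is
known.

For population geneticists and conservation genomicists working from a VCF
with functional annotations (synonymous / missense / loss-of-function and
ancestral alleles), a sample table with lon/lat, and a binary species
presence raster for the glacial period.

## What it computes

* **Diversity** — per-individual heterozygosity
  H_i = n_het / (n_het + n_hom) over called genotypes.
* **Inbreeding** — PLINK-style windowed ROH detection; per-individual count
  and total length of tracts in the 5 kb–1 Mb band, which dates the
  underlying inbreeding loops to g = 100 / (2·L_cM) generations,
  g ∈ [50, 10,000].
* **Genetic load** — P_n/(P_n+P_s), the derived-frequency-weighted
  P_n f_n/(P_s f_s), and loss-of-function allele dosage, all polarized on
  ancestral-allele annotations.
* **Isolation by distance** — pairwise Weir–Cockerham (1984) F_ST between
  sampling sites on a MAF > 10%, `indep-pairwise 50 10 0.2` LD-pruned SNP
  set; F_ST/(1−F_ST) against great-circle distance in a Mantel permutation
  test.
* **Spatial interpolation** — variogram fitting and ordinary kriging of any
  per-individual statistic onto a lon/lat grid.
* **Gradient tests** — Pearson correlation of each statistic with
  great-circle distance to the refuge center (the centroid of
  presence-predicted raster cells), two-tailed, with Benjamini–Hochberg FDR
  across the statistics of a run.
* **Simulation** — a forward Wright–Fisher serial-founder expansion on a
  deme lattice (tskit-recorded genealogy, standing ancestral variation,
  infinite-sites mutations with functional classes), emitting VCF, sample
  CSV, and presence raster.

## Worked example

```python
from refugia import SimConfig, simulate, heterozygosity, ibd_test

sim = simulate(SimConfig(seed=1))            # 8x8 demes, K=5 founders, m=0.01
het = heterozygosity(sim.genotypes)
res = ibd_test(sim.genotypes, sim.variants, sim.samples, n_perm=999, seed=1)
print(f"Mantel r = {res.r:+.3f}, p = {res.p:.4f}")
```

The `examples/` scripts run one capability each. On the default expansion
(`examples/02`, `examples/04`) they print:

```
heterozygosity: 0.000 .. 0.284
r(heterozygosity, refuge distance) = -0.454  (p = 1.10e-17)
r(total ROH bp,   refuge distance) = +0.475  (p = 1.98e-19)
median ROH length 198 kb ~ inbreeding loop 252 generations ago (g = 100 / 2L_cM)

migration 0.01: Mantel r = +0.655, p = 0.0010 (546 LD-pruned SNPs, 64 sites)
migration 0.25: Mantel r = +0.117, p = 0.0090 (908 LD-pruned SNPs, 64 sites)
```

Diversity falls and homozygosity rises with distance from the refuge — the
serial-founder footprint — and the Mantel isolation-by-distance signal that
is strong under restricted migration collapses toward zero when the same
landscape is well mixed.

The full pipeline (simulate or load files → diversity → load → F_ST/IBD →
kriging and gradient tests, with a JSON manifest) runs from one config:

```sh
refugia run-all --config examples/demo_config.yaml
```

Subcommands `simulate`, `filter`, `diversity`, `roh`, `load`, `fst`, `ibd`,
`krige`, and `gradient` wrap the same library functions with file IO.

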