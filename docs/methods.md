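# Methods

`refugia` implements a spatial population-genomics workflow for species that
survived glacial maxima in a restricted refuge and re-expanded afterwards:
per-individual diversity and inbreeding statistics, genetic-load proxies,
isolation by distance, geostatistical interpolation, and refuge-distance
gradient tests — together with a forward range-expansion simulator that
generates inputs with the spatial structure those analyses assume.

## The range-expansion simulator

### Model

The landscape is a `grid_height x grid_width` lattice of demes registered to
lon/lat (cell (r, c) centered at `lon0 + c*cell_deg`, `lat0 - r*cell_deg`,
north-up). One refuge deme evolves alone for `burn_in` generations; the
range then expands in waves every `colonization_interval` generations: each
uncolonized 4-neighbor of the colonized set is founded by `founders` (K)
diploids whose parents are drawn from its nearest colonized neighbor (ties
broken in fixed N, E, S, W order). Colonized demes hold `deme_size` (N)
diploids; reproduction is Wright–Fisher with random mating. Each offspring
gamete chooses its parent deme (each colonized 4-neighbor with probability
`migration`, otherwise the home deme; probabilities renormalized if they
exceed 1), then a uniform parent within it, and recombines with an
independent fair chromosome start and Poisson(`L * recomb_cM_per_Mb / 100 Mb`)
crossovers per chromosome. After the final wave the metapopulation evolves
`post_expansion` more generations, then `sample_per_deme` individuals per
deme are emitted at deme-center coordinates.

Genealogy is recorded exactly, as haplotype copying mosaics (half-open
intervals referencing parental haplotypes) held in tskit tables and
simplified every 25 generations. Two layers of neutral structure are added
to the recorded genealogy at the end:

* **Standing variation.** The genealogy's roots are coalesced under a
  single ancestral population of `ancestral_Ne` diploids (recombination at
  the same per-bp rate). A refuge population carries diversity accumulated
  over deep time at large historical size; without this step a simulation
  started from identical haplotypes is near-clonal and no statistic behaves
  like data. The default `ancestral_Ne = 20,000` is the order of magnitude
  PSMC-style reconstructions give for alpine vertebrates and yields roughly
  2 x 10^4 segregating sites on the default genome.
* **Mutations.** Infinite-sites neutral mutations at `mu` per bp per
  generation (default 4.6e-9) are overlaid on every branch; each site gets
  a functional class (SYN/NONSYN/LOF) drawn from `class_probs` and an
  ancestral state equal to the mutation's absence, so derived-allele
  polarization is exact. Mutations carry no fitness effects: the analyses
  measure mutation classes and frequencies, not selection, so a neutral
  model is sufficient and keeps the post-hoc overlay valid.

### Defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| grid | 8 x 8, origin (0, 0) | refuge at the range margin expanding across the plateau |
| N, K | 100, 5 | strong serial founder effect per colonization |
| migration m | 0.01 per neighbor | restricted stepping-stone gene flow |
| colonization_interval | 5 gen | rapid postglacial spread (~70 generations grid-wide) |
| burn_in | 50 gen (4N if `ancestral_Ne = 0`) | local equilibration of the refuge deme; deep ancestry comes from the coalescent root |
| post_expansion | 250 gen | the 5 kb–1 Mb ROH band dates inbreeding 50–10,000 generations old (g = 100/2L_cM); sampling must postdate colonization by well over 50 generations for founder tracts to recombine into the band |
| genome | 2 chromosomes x 10 Mb, 1 cM/Mb | desk-scale but enough sites for stable ROH/load statistics |
| mu | 4.6e-9 /bp/gen | the rate used for these species' demographic reconstructions |
| class_probs | 0.30 / 0.65 / 0.05 | roughly the missense:synonymous:LOF proportions of coding SNP annotation |
| lgm_epoch | end of burn-in | the presence raster then marks the refuge alone, so the refuge center equals the expansion origin |

Runs are bit-reproducible from `seed`; every random draw (forward
reproduction, root coalescence, mutation overlay, class assignment,
sampling) flows from one generator.

### What the simulator does *not* emulate

Real data differ in ways that matter for interpreting green tests:
genotyping error and missingness (simulated data are complete), linked
selection and real functional annotation (classes are exchangeable labels),
landscape heterogeneity (all demes are equally habitable), overlapping
colonization routes, and — most importantly — scale. A 6,400-individual
metapopulation compresses coalescence times: simulated individuals carry
~50% of their genome in identity-by-descent tracts young enough to fall in
the 5 kb–1 Mb ROH band, versus a few percent in real genome-scale data.
One consequence is documented below (ROH count saturation). Passing tests
demonstrate that the estimators measure what they claim on data whose
generating process is known, not that any particular species matches the
simulated regime.

## Statistics

**Heterozygosity** is the fraction of an individual's called genotypes that
are heterozygous (missing genotypes excluded from both counts); a
`callable_bp` divisor is available to convert to a per-bp rate on real data.

**ROH detection** adapts the PLINK `--homozyg` windowed scan: windows of 50
consecutive SNPs pass with at most 1 heterozygous and 5 missing calls; a
SNP is run-eligible when at least 5% of the windows covering it pass;
maximal eligible runs are trimmed to homozygous called endpoints and
reported when they contain >= 25 SNPs and span >= 5 kb. Eligibility is by
hit fraction alone, so a single heterozygote inside a long homozygous tract
does not split it — the behavior the window-het allowance exists to
provide. The per-individual summary counts tracts with 5 kb <= length < 1 Mb
(closed left, open right); g = 100/(2 L_cM) dates a tract's inbreeding
loop. All parameters are exposed; the 5 kb lower bound makes the dating
band reachable, which is the only constraint the summary fixes.

*Known limitation (count saturation).* Where band-aged IBD covers a large
fraction of the genome, adjacent tracts merge into runs longer than 1 Mb
and the band **count** stops increasing with inbreeding burden — it bends
over, while the **total length** keeps rising. Serial K=5 founding puts
simulated range fronts in exactly this regime, so on simulated expansions
the count gradient with refuge distance is flat-to-negative even though the
total-length gradient is robustly positive. Both statistics are computed
and reported everywhere ROH enter.

**Genetic load.** Sites with unknown ancestral state are excluded. Per
individual: Pn and Ps count nonsynonymous and synonymous polymorphic sites
carrying >= 1 derived allele; `ratio_ns = Pn/(Pn+Ps)`;
`freq_ratio = (Pn fn)/(Ps fs)` with fn, fs the mean population derived
frequencies over the individual's carried sites; `lof_dosage` sums derived
allele dosage at LOF sites (allele count rather than carrier-site count, per
the "number of LOF mutations" reading). NONSYN defaults to missense only,
with `include_lof_in_nonsyn` for sensitivity; `population_load` provides
the per-site-group analogue (segregating-site counts, within-group
frequencies) for checking that conclusions do not depend on the
per-individual reading. Empty denominators propagate as NaN and are dropped
by interpolation and correlation, never imputed.

**FST and isolation by distance.** Pairwise FST between sampling sites is
the Weir–Cockerham (1984) estimator: per-locus variance components a
(among populations), b, c (within), summed over loci polymorphic in the
pooled pair as sum(a)/sum(a+b+c). Negative estimates are retained.
Upstream filters follow the standard recipe: minor-allele frequency
strictly > 0.10, then `indep-pairwise 50 10 0.2` LD pruning on genotype
dosage r^2 (windows indexed on the original site order; within a window
the offending pair's lower-call-count member is removed, ties dropping the
later position; missing genotypes pairwise-deleted). Genetic distance is
linearized as FST/(1−FST); an FST of 1 maps to infinity and is replaced by
the largest finite entry plus a rank-preserving epsilon (logged) rather
than clamped. Geographic distance is great-circle (haversine, R = 6371.0088
km) — coordinates are lon/lat, so planar Euclidean distance is offered only
as a sensitivity flag. The Mantel statistic is the Pearson correlation of
strictly-lower-triangle entries under simultaneous row/column permutation,
p = (1 + #{r_perm >= r_obs})/(1 + n_perm), one-tailed (greater) by default
because IBD is a directional hypothesis; exact enumeration replaces
sampling when `n_perm=None`. The permutation count and tail are choices of
this package, stated here because the upstream convention varies.

**Kriging and gradients.** The empirical semivariogram bins squared value
differences by great-circle distance (12 lags to half the maximum pairwise
distance by default); a spherical/exponential/gaussian model is fitted by
weighted least squares (weights N(h)/h^2, nugget bounded at 0,
deterministic multi-start over range values). `range_km` is the model's
distance-scale parameter — for the exponential family the effective range
(95% of sill) is ~3x it. Ordinary kriging solves the semivariance system
with a Lagrange unbiasedness constraint per node of a 100 x 100 grid over
the 5%-padded sample bounding box; duplicate coordinates (co-sampled
individuals at one deme) are jittered by 1e-6 degrees (logged); the system
is LU-factorized once and applied to all nodes. With a zero nugget the
surface honors every datum to 1e-6. Statistics with a strong spatial trend
(the diversity gradient itself) make the empirical variogram grow without a
clear sill; the fitted range is then large and only the slope near the
origin is identified — the interpolated surface remains well defined, but
the range parameter should not be interpreted on trended fields. The
refuge center is the arithmetic
lon/lat centroid of presence-predicted raster cells (planar mean, a
spherical mode exists) — at sub-continental extent the difference is
negligible. Gradient tests are Pearson correlations of a per-individual
statistic against great-circle distance to the center, two-tailed p from
the t distribution with n−2 df, with Benjamini–Hochberg FDR applied across
the family of statistics tested in one run (heterozygosity, ROH count,
ratio_ns, freq_ratio, lof_dosage).

## Pipeline

`run_all` executes simulation (or file input) -> diversity -> load ->
differentiation -> spatial, writing per-stage CSVs, ESRI ASCII rasters
(nodata −9999), result JSONs, and a manifest echoing the configuration,
seed, versions, and row counts. Any stage error aborts with a stage-tagged
exception and leaves a `FAILED` marker beside the partial outputs. The MAF
and LD filters apply inside the IBD stage only; heterozygosity, ROH and
load use all segregating sites, matching standard practice of filtering
only for the differentiation analysis.

## Numerical conventions

VCF positions are 1-based; all internal intervals are 0-based half-open;
dosage missingness is −1; undefined statistics are NaN. Variant sites are
unique and sorted on (chrom, pos). Variogram fits refit their own
theoretical curve to 1e-6; kriging weight sums are within 1e-8 of 1.
Degenerate inputs fail loudly (zero-variance gradient statistics, groups
smaller than 2, empty sample sets) or are logged and skipped (chromosomes
with fewer SNPs than one window, sites with unknown ancestral state,
deme pairs with no usable loci — reported as FST 0, i.e., indistinguishable).

## Problem sizes

Default test and acceptance runs use the 8 x 8 / N=100 / 2 x 10 Mb
configuration (~320 sampled individuals, ~2 x 10^4 SNPs, ~5-15 s per run);
statistical calibration uses 500 null replicates with 199 permutations at
n = 30; oracle checks use <= 5-locus, <= 12-individual instances where
brute-force enumeration is exact.
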