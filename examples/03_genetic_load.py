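"""Three genetic-load statistics and their refuge-distance gradients.

Pn/(Pn+Ps) is the nonsynonymous carrier-site ratio, Pn*fn/(Ps*fs) weights it
by derived-allele frequencies, and the LOF dosage counts loss-of-function
alleles — drift at the expanding front lets mildly deleterious variants
surf to high frequency (expansion load).
"""

from refugia import SimConfig, compute_load, derived_freqs, simulate
from refugia.spatial import gradient_table, gradient_test

sim = simulate(SimConfig(seed=1))
dfreq = derived_freqs(sim.genotypes, sim.variants)
load = compute_load(sim.genotypes, sim.variants, dfreq)

print(load[["sample_id", "Pn", "Ps", "ratio_ns", "freq_ratio", "lof_dosage"]].head())

results = [gradient_test(load[c].to_numpy(float), sim.samples, sim.origin_lonlat,
                         statistic=c)
           for c in ("ratio_ns", "freq_ratio", "lof_dosage")]
print(gradient_table(results).round(4))
# r > 0 means the load statistic increases away from the refuge (the
# expansion-load direction); the sign varies between runs and metrics, as
# load gradients are much weaker than the diversity gradient. q is the
# Benjamini-Hochberg FDR-adjusted p across the three tests.
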