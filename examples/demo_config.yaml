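# Demo pipeline: simulate a serial-founder expansion from a corner refuge on
# an 8x8 deme grid (the package defaults), then run every analysis stage.
# Run with:  refugia run-all --config examples/demo_config.yaml
seed: 5
outdir: refugia_demo_out
simulate: {}          # all SimConfig defaults: 8x8 grid, N=100, K=5, m=0.01
ibd:
  n_perm: 9999
roh:
  lo_bp: 5000
  hi_bp: 1000000
krige:
  family: exponential
  statistics: [heterozygosity, roh_count]
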