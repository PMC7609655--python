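# Full pipeline on the default synthetic stand.
seed: 1
out_dir: results/demo
years: [2007, 2017]
simulate:
  error_rate: 0.02      # per-locus genotyping error
  null_rate: 0.02       # per-locus null-allele rate
  cells_per_ring: 30
  rho: 0.3
thresholds:
  max_mismatch: 2
  max_null: 2
  alpha: 0.05
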