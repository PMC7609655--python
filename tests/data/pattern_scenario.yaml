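# Scenario reproducing the qualitative verdict pattern across the eight
# ring traits: spatially dominated growth and earlywood traits, latewood
# density/wall thickness with group variance on coincident genetic and
# spatial partitions, and a structureless latewood hydraulic diameter.
seed: 0
stands:
  study_layout: {}          # default 47-tree / 11-group population
  aligned_clonal:           # 12 clonal groups, one per spatial group
    n_groups: 12
    ramets: 3
variances:
  strong_group:             # shared group variance on coincident partitions
    sigma2_S: 1.0
    sigma2_tree: 0.1
    sigma2_R: 0.4
    rho: 0.3
traits:
  EWW:    {stand: study_layout, variance: spatial_only, expected: spatial}
  LWW:    {stand: study_layout, variance: spatial_only, expected: spatial}
  CWT.ew: {stand: study_layout, variance: spatial_only, expected: spatial}
  DEN.ew: {stand: study_layout, variance: spatial_only, expected: spatial}
  DH.ew:  {stand: study_layout, variance: spatial_only, expected: spatial}
  CWT.lw: {stand: aligned_clonal, variance: strong_group, expected: grouped}
  DEN.lw: {stand: aligned_clonal, variance: strong_group, expected: grouped}
  DH.lw:  {stand: study_layout, variance: no_structure, expected: "null"}
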