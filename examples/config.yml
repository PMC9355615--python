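# Example run configuration: simulate a heterogeneous-selection dataset and
# analyse it end to end. Replace `simulate:` with an `inputs:` block of TSV
# paths to analyse real data.
simulate:
  regime: heterogeneous_selection
  n_sites: 10
  quadrats_per_site: 2
  depths: [surface, subsurface]
  reads_per_sample: 2000
  n_otus: 200
  lognormal_sigma: 1.5
  niche_breadth: 8.0
seed: 1
depth_layer: both
guilds: [total, mycorrhizal, saprotrophic, pathotrophic]
n_null: 199
n_perm: 199
alpha: 0.05
rarefy_depth: auto
deviation_mode: ses
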