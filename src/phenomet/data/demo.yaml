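# Bundled demo configuration: a desk-scale synthetic run that finishes in
# well under five minutes on one CPU.  All values can be overridden; omitted
# keys fall back to pipeline.DEFAULT_CONFIG.
seed: 0
synth:
  layout: compact          # 96-well plate with vehicle border
  n_treatments: 12
  n_features: 100
  n_cells_per_well: 200
  n_moa_classes: 3
  n_affected: 20
  effect_sd: 3.0
  effect_jitter: 0.5
  active_fraction: 0.5
  n_ms_features: 60
  n_active_ms: 12
  false_presence_rate: 0.005
  background_cardinality: 4
histdiff:
  n_bins: 32
  smoothing: 1.0
  vehicle_pool_fraction: 0.5
  vehicle_stat: max
featsel:
  su_threshold: 0.0
  n_bins: 5
network:
  min_activity: 0.03
  min_cluster: 0.5
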