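# Desk-scale phantom study: two-site cohort with a planted parcel effect.
seed: 1
simulate:
  shape: [48, 48, 48]
  k_parcels: 30
  effect_parcels: [1, 2, 3]
  effect_size: 0.5
  noise_sd: 0.2
  n_per_class: 30
  sites:
    - [siteA, [1.2, 1.0, 1.0]]
    - [siteB, [1.0, 1.0, 1.0]]
preprocess:
  target_spacing: 1.5
  target_shape: 24
  clip_percentiles: [0.5, 99.5]
model:
  architecture: tiny_3d
  width: 8
  max_epochs: 20
  eval_every: 2
  learning_rate: 0.001
  batch_size: 2
regions:
  percentile: 90
  target_class: symmetric
  stratify: outcome
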