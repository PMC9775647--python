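# Demo pipeline configuration: 5 training + 20 transfer synthetic specimens.
# Run with:  hepix all --config examples/demo.yaml
out_dir: scratch/demo-run
seed: 1
image_size: [256, 256]
train_cohort:
  label: mouse
  n_specimens: 5
  stage_distribution: {I: 1.0}
  spec_overrides:
    cancer_fraction: 0.5
    texture_amplitude_noncancer: 20.0
transfer_cohort:
  label: human
  n_specimens: 20
  stage_distribution: {I: 0.25, II: 0.2, III: 0.2, IV-A: 0.15, IV-B: 0.2}
  unknown_fraction: 0.1
  spec_overrides:
    cancer_fraction: 0.8
    texture_amplitude_noncancer: 20.0
mbf:
  intensity: true
  edges: false
  texture: true
  sigma_min: 3
  sigma_max: 7
  multichannel: true
cluster:
  n_clusters: 30
  n_init: 2
  max_iter: 100
  noise_clusters: []
  max_pixels_per_image: 20000
entropy:
  k: 20
  log_base: 2
  levels: 256
n_draws: 10000
histogram_bins: 64
top_k: 3
bottom_k: 3
label_source: annotation
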