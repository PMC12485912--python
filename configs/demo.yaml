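# Demo pipeline configuration: completes end-to-end on one CPU in ~1 minute.
#   s2f run-all --config configs/demo.yaml --out demo_out --seed 1
out_dir: demo_out
seed: 1
window_length: 1024
maf_mask_threshold: 0.05
simulate: true
sim:
  n_individuals: 600
  n_sites: 80
  n_causal: 10
  h2: 0.6
  protein_altering_fraction: 0.02
  n_pwms: 3
  pwm_width: 6
train:
  epochs: 18
  batch_size: 16
  accum_steps: 2
  lr_peak: 0.007
  conv_channels: [16]
  kernels: [7]
  dilations: [1]
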