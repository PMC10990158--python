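kind: glass-radial
seed: 0
output_dir: runs/glass-planted
schedule:
  beta_start: 1.0
  beta_end: 3.0e-04
  n_steps: 8000
  n_checkpoints: 40
model:
  latent_dim: 4
  encoder_hidden: [32, 32]
  decoder_hidden: [128]
  learning_rate: 0.001
  batch_size: 256
glass:
  n_samples: 20000
  label_noise: 0.1
  planted_shell: 7
  planted_type: 0
  density: 1.0
  fraction_a: 0.65
  hard_core: 0.5
  r_max: 5.0
eval:
  K: 512
  n_batches: 2
  n_label_samples: 4
  eval_every: 2
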