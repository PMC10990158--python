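kind: circuit
seed: 0
output_dir: runs/circuit-reference
schedule:
  beta_start: 1.0
  beta_end: 3.0e-05
  n_steps: 30000
  n_checkpoints: 90
model:
  latent_dim: 8
  encoder_hidden: [64, 64]
  decoder_hidden: [128, 128]
  learning_rate: 0.001
  batch_size: 256
circuit:
  n_inputs: 10
  n_gates: 12
  circuit_seed: 115
eval:
  n_mc_exact: 20000
  n_label_samples: 8
  eval_every: 2
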