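# dib — distributed information bottleneck

Feature-wise lossy compression for information decomposition in complex
systems.

## The problem

A set of measurements X = (X1, …, XN) of a system — gate states of a
Boolean network, radial density bands around a particle, per-particle
positions — collectively predicts some relevance variable Y.  *Which bits
of which measurements matter?*  Mutual information I(X_S;Y) over subsets
answers this exactly but needs 2^N evaluations, and a black-box classifier
answers nothing.  The distributed information bottleneck (distributed IB)
gives each measurement its own stochastic compression channel Xi → Ui and
trains all channels jointly with a predictor of Y under the objective

    L = β · Σi I(Ui;Xi) − I(U;Y),

so every transmitted bit must earn its keep.  Annealing the bottleneck
strength β from large to small in one optimization run produces a whole
spectrum of compression schemes ordered by total utilized information
Σi I(Ui;Xi): the information plane.  Reading off the per-channel
informations along the sweep decomposes the predictive content of X —
which measurements carry it, how much, and (through distinguishability
matrices) which *distinctions* within a measurement are kept.

The package implements, on numpy with an internal autodiff engine:

* `dib.boolean_circuit` — random AND/OR/XOR circuits, exact truth-table
  joint distributions, exact subset informations and the per-cardinality
  frontier: the ground-truth oracle the learned decomposition is compared
  against.
* `dib.encoders` — per-feature channels: MLPs mapping a value to a
  diagonal Gaussian in latent space, closed-form KL cost to a standard
  Gaussian prior.
* `dib.dib_objective` — the training loss, geometric β schedules, and the
  annealed sweep with log-spaced plus information-triggered checkpoints.
* `dib.mi_estimation` — precise per-channel information: contrastive
  lower / leave-one-out upper bounds and an exact-mixture Monte-Carlo
  oracle for enumerable features; the variational bound on I(U;Y).
* `dib.info_analysis` — information-plane points, allocation heatmaps,
  informative-subset selection, distinguishability matrices
  (1 − Bhattacharyya), threshold detection, conditional histograms.
* `dib.glass_synthetic` — synthetic two-type 2D particle neighborhoods
  with a planted radial-shell rearrangement rule, 100 radial-band density
  features, g(r), and the linear max-margin (softness) baseline.
* `dib.set_basis` — the per-particle measurement basis: one shared channel
  per particle type, permutation-invariant set predictors, positional
  information maps.
* `dib.orchestration` / `dib.cli` — YAML-configured runs with
  reproducible artifacts (`dib circuit sweep`, `dib glass synthesize`, …).

## Worked example

Decompose a 10-input Boolean circuit (from
`examples/circuit_information_decomposition.py`, abridged):

```python
from dib.boolean_circuit import generate_circuit, subset_frontier, truth_table
from dib.dib_objective import DIBModel, SweepConfig, TabularDataset, train_sweep
from dib.info_analysis import EvalConfig, info_plane

circuit = generate_circuit(n_inputs=10, n_gates=12, seed=115)
table = truth_table(circuit)                      # 1024 rows, exact joint
entries, envelope = subset_frontier(table)        # all 1024 subset MIs

dataset = TabularDataset.from_truth_table(table)
checkpoints = train_sweep(dataset, SweepConfig(n_steps=30_000, full_batch=False), seed=0)
model = DIBModel.build(dataset, SweepConfig(), __import__("numpy").random.default_rng(0))
points = info_plane(checkpoints, dataset, model, EvalConfig())
```

Representative output (one CPU, a few minutes):

```
H(Y) = 0.9723 bits
exact frontier envelope: 0:0.000  1:0.060  2:0.157  3:0.363 ... 10:0.972
final info-plane point:  total 10.000 bits, predictive 0.972 bits, accuracy 1.000
```

The final sweep point utilizes all ten bits of input information and its
predictive information equals the output entropy H(Y): the circuit is
fully explained.  Intermediate points allocate their limited budget to the
most informative inputs, tracing the upper boundary of the exact subset
frontier (the black-points-vs-gray-curve picture); per-channel estimates
carry bound intervals of order 10⁻⁴–10⁻³ bits, tight enough to read
single allocations off the heatmap.

The synthetic-glass analogue (`examples/glass_planted_shell_recovery.py`)
plants a low-density-shell rearrangement rule in 2D particle
neighborhoods; the sweep's ≈1-bit point concentrates its bits on the
planted radial band, the learned compression is a threshold at the planted
cutoff, and accuracy at large budgets matches the linear softness
baseline.  `examples/per_particle_positional_information.py` does the same
with raw per-particle positions and a permutation-invariant predictor, and
`examples/mi_bound_tightness.py` shows the estimator bracket.

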