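"""How precisely can the per-channel information be measured?

Trains a short sweep on the 2-input AND truth table, freezes the two
channels at the final checkpoint, and compares three estimates of each
I(Ui;Xi): the contrastive lower bound, the leave-one-out upper bound, and
an unbiased Monte-Carlo evaluation of the exact Gaussian-mixture integral.
Because each channel compresses a single binary measurement, the bound
interval is tiny — typically well under 0.01 bits.

Runtime: under a minute on one CPU.
"""

import numpy as np

from dib.boolean_circuit import BooleanCircuit, truth_table
from dib.dib_objective import DIBModel, SweepConfig, TabularDataset, train_sweep
from dib.mi_estimation import channel_mi_bounds, exact_discrete_channel_mi

table = truth_table(BooleanCircuit(2, (("AND", (0, 1)),), 2))
dataset = TabularDataset.from_truth_table(table)
config = SweepConfig(
    beta_start=1.0, beta_end=1e-4, n_steps=3000, n_checkpoints=10,
    latent_dim=4, encoder_hidden=(16,), decoder_hidden=(32,),
)
checkpoints = train_sweep(dataset, config, seed=0)
model = DIBModel.build(dataset, config, np.random.default_rng(0))
model.load_checkpoint(checkpoints[-1])

pmf = (np.array([0.0, 1.0]), np.array([0.5, 0.5]))
print("channel   lower      upper      gap        exact oracle")
for i, ch in enumerate(model.channels):
    est = channel_mi_bounds(ch, pmf, K=4096, n_batches=32, seed=i)
    mi, se = exact_discrete_channel_mi(ch, pmf, n_mc=100_000, seed=i)
    print(
        f"x{i+1:<7} {est.lower_bits:9.5f} {est.upper_bits:10.5f} "
        f"{est.gap_bits:10.5f} {mi:10.5f} ± {se:.5f} bits"
    )
print(
    "\nthe oracle must lie between the bounds; the gap is the estimation"
    "\nprecision available to the information-plane analysis."
)
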