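"""Where does the information live when particles are the measurements?

Trains the per-particle basis on planted-rule neighborhoods: one shared
compression channel per particle type maps raw (x, y) positions to latent
distributions, and a permutation-invariant predictor classifies the
compressed set.  The schedule anneals β upward (learn freely, then
compress), with rotation augmentation phased in once the feature has
formed.  No positional structure is imposed on the channels, yet the
per-particle information cost organizes into a radially symmetric
near-center band whose outer edge is the planted radius.

Runtime: several minutes on one CPU (most of it the 9 000-step sweep).
"""

import numpy as np

from dib.glass_synthetic import PlantedRule, synthesize_neighborhoods
from dib.set_basis import (
    SetSweepConfig,
    positional_distinguishability,
    positional_info_map,
    train_set_sweep,
)

rule = PlantedRule(shell_index=7, particle_type=0, label_noise=0.1)
glass = synthesize_neighborhoods(4000, rule, seed=0)
print(f"planted radius r = {rule.shell_radius:.2f} (type A)")

model, checkpoints = train_set_sweep(glass.neighborhoods, SetSweepConfig(), seed=0)
final = checkpoints[-1]
print(f"final checkpoint: beta {final.beta:.3g}, "
      f"per-neighborhood cost {final.kl_bits.sum():.1f} bits")

info_map = positional_info_map(model.channels, glass.neighborhoods[:1500], particle_type=0)
ok = ~np.isnan(info_map.radial_bits)
print("\nradially averaged per-particle information (bits):")
for r, b in zip(info_map.radial_r[ok][::3], info_map.radial_bits[ok][::3]):
    if r < 2.5:
        marker = "  <- planted band" if abs(r - rule.shell_radius) < 0.1 else ""
        print(f"  r = {r:4.2f}: {b:7.3f}{marker}")
print(
    "\nthe information forms a plateau from the inner boundary out to the"
    "\nplanted band (hard-core exclusion makes those particles informative"
    "\ntoo) and collapses beyond it — the band is the region's outer edge."
)

angles = np.linspace(0, 2 * np.pi, 24, endpoint=False)
ring = rule.shell_radius * np.column_stack([np.cos(angles), np.sin(angles)])
d = positional_distinguishability(model.channel_a, [rule.shell_radius, 0.0], ring)
print(
    f"\ndistinguishability around the planted ring: mean {d.mean():.3f}, "
    f"std {d.std():.3f} (small std = azimuthally symmetric encoding)"
)
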