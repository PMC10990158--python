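"""Optional adapter for externally deposited glass-neighborhood datasets.

The analyses in this package run on the synthetic generator
(:mod:`dib.glass_synthetic`); this adapter lets the same pipeline consume
an externally provided dataset of labeled particle neighborhoods instead.
It accepts the package's extended-XYZ-like text format (see
:func:`dib.glass_synthetic.read_xyz`): a count line, a comment line with
``label=<0|1> r_max=<float>``, then ``<type> <x> <y>`` rows per
neighborhood.  Externally deposited archives must be converted to this
format first; no binary formats are read here.

Nothing in the test suite requires this module.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

from .dib_objective import TabularDataset
from .glass_synthetic import ParticleNeighborhood, _features_batch, read_xyz

__all__ = ["load_neighborhood_file", "neighborhoods_to_dataset"]


def load_neighborhood_file(path) -> List[ParticleNeighborhood]:
    """Read labeled neighborhoods from an extended-XYZ-like text file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(
            f"neighborhood file {p} not found; external datasets are optional — "
            "use dib.glass_synthetic.synthesize_neighborhoods for the synthetic pipeline"
        )
    return read_xyz(p)


def neighborhoods_to_dataset(nbhds: List[ParticleNeighborhood]) -> TabularDataset:
    """Featurize neighborhoods into the 100-column radial-density dataset."""
    from .glass_synthetic import N_SHELLS

    feats = _features_batch(nbhds)
    labels = [n.label for n in nbhds]
    ids = [f"{'AB'[t]}_r{k}" for t in (0, 1) for k in range(N_SHELLS)]
    return TabularDataset(features=feats, labels=labels, feature_ids=ids)
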