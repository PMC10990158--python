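"""Per-particle measurement basis: shared channels and a set predictor.

Instead of fixed radial-density features, each particle's raw position
(x, y) is a measurement.  One compression channel is shared by all
particles of a type (one for A, one for B); the compressed set — which has
no canonical ordering — is decoded by a permutation-invariant predictor.
The information cost attributed to a particle is the KL of its encoding to
the prior, so maps of cost versus position show *where* in the
neighborhood the model takes its bits from, without any positional
structure being imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._autograd import Parameter, Tensor, concat, log_softmax, softmax
from .dib_objective import SweepCheckpoint, TrainingFailure, make_beta_schedule
from .encoders import LN2, EncoderChannel, kl_to_prior_bits
from .glass_synthetic import ParticleNeighborhood
from .info_analysis import _bhattacharyya_coefficient
from .nn import MLP, Adam, Linear

__all__ = [
    "PerParticleChannel",
    "SetPredictor",
    "SetDIBModel",
    "SetSweepConfig",
    "PositionalInfoMap",
    "encode_neighborhood_set",
    "set_predict",
    "train_set_sweep",
    "positional_info_map",
    "positional_distinguishability",
]


class PerParticleChannel(EncoderChannel):
    """Compression channel shared by every particle of one type; input (x, y).

    Positions are divided by ``position_scale`` before the MLP so the tanh
    stack sees O(1) inputs across the whole neighborhood.
    """

    def __init__(
        self,
        particle_type: int,
        rng,
        latent_dim: int = 4,
        hidden=(32, 32),
        position_scale: float = 2.5,
    ):
        super().__init__(
            feature_id=f"type_{'AB'[particle_type]}",
            rng=rng,
            n_in=2,
            latent_dim=latent_dim,
            hidden=hidden,
            standardization=(0.0, position_scale),
        )
        self.particle_type = particle_type


class SetPredictor:
    """Permutation-invariant decoder over a set of latent samples.

    ``pooling='attention'`` (default): per-element embedding, one residual
    self-attention block, then attention pooling with a learned query —
    two attention stages in total.  ``pooling='sum'`` is a cheaper
    deep-sets variant (sum pooling of the embeddings).  Padded elements
    are masked out of every attention softmax and every sum; the empty set
    decodes through the zero pooled vector to a learned bias output.
    """

    def __init__(
        self,
        latent_dim: int,
        n_classes: int,
        rng: np.random.Generator,
        hidden: int = 64,
        pooling: str = "attention",
        pool_scale: float = 1.0,
    ):
        if pooling not in ("attention", "sum"):
            raise ValueError("pooling must be 'attention' or 'sum'")
        self.pooling = pooling
        self.hidden = hidden
        # sum pooling is rescaled (typically by 1/mean set size) so the
        # head sees O(1) activations instead of an O(S) sum that would
        # saturate the tanh layers; counts stay linearly decodable
        self.pool_scale = float(pool_scale)
        self.embed = MLP(latent_dim, (hidden,), hidden, rng)
        if pooling == "attention":
            self.q_proj = Linear(hidden, hidden, rng)
            self.k_proj = Linear(hidden, hidden, rng)
            self.v_proj = Linear(hidden, hidden, rng)
            self.pool_query = Parameter(rng.normal(0.0, 0.1, size=(1, hidden)))
        # the head is NOT zero-initialized: with ~10^2 prior-noise latents
        # pooled together, a zero head gives the channels no gradient path
        # at all and the whole model sits at a dead symmetric point.  The
        # sweep still starts at 0 transmitted bits because the channels
        # themselves start at the prior.
        self.head = MLP(hidden, (hidden,), n_classes, rng)

    @property
    def parameters(self):
        ps = list(self.embed.parameters)
        if self.pooling == "attention":
            ps += self.q_proj.parameters + self.k_proj.parameters + self.v_proj.parameters
            ps.append(self.pool_query)
        ps += self.head.parameters
        return ps

    def __call__(self, u: Tensor, mask: np.ndarray) -> Tensor:
        """u: (B, S, d) latent samples; mask: (B, S) 1 for real particles."""
        B, S = mask.shape
        if S == 0 or mask.sum() == 0:
            pooled = Tensor(np.zeros((B, self.hidden)))
            return log_softmax(self.head(pooled), axis=-1)
        m = Tensor(mask[:, :, None])  # (B, S, 1)
        e = self.embed(u) * m
        if self.pooling == "sum":
            pooled = e.sum(axis=1) * self.pool_scale
        else:
            bias = Tensor((mask[:, None, :] - 1.0) * 1e9)  # (B, 1, S) over keys
            q, k, v = self.q_proj(e), self.k_proj(e), self.v_proj(e) * m
            scores = (q @ k.swaplast()) * (1.0 / np.sqrt(self.hidden)) + bias
            e = (e + softmax(scores, axis=-1) @ v) * m
            kp = self.k_proj(e)
            vp = self.v_proj(e) * m
            ps = (self.pool_query @ kp.swaplast()) * (1.0 / np.sqrt(self.hidden)) + bias
            pooled = (softmax(ps, axis=-1) @ vp).reshape(B, self.hidden)
        return log_softmax(self.head(pooled), axis=-1)


@dataclass
class SetSweepConfig:
    # learn-then-compress: β is annealed upward so the permutation-invariant
    # feature can form before the information penalty prices it
    beta_start: float = 1e-6
    beta_end: float = 3e-3
    n_steps: int = 9000
    latent_dim: int = 4
    encoder_hidden: tuple = (64, 64)
    predictor_hidden: int = 64
    pooling: str = "sum"  # deep-sets pooling; "attention" also available
    learning_rate: float = 3e-3
    batch_size: int = 64
    n_checkpoints: int = 40
    position_scale: float = 2.5
    pool_scale: Optional[float] = None  # None: set to 1/mean set size
    # the neighborhood distribution is rotation-invariant, so randomly
    # rotating each training neighborhood is exact data augmentation; it
    # drives the shared channels toward properly radial encodings.  It is
    # phased in after a fraction of the run: from the very start it raises
    # gradient variance exactly when the weak seed signal needs coherence
    rotation_augment: bool = True
    rotation_augment_start_frac: float = 0.4


class SetDIBModel:
    """Two shared per-type channels plus a permutation-invariant predictor."""

    def __init__(self, config: SetSweepConfig, n_classes: int, rng: np.random.Generator):
        self.config = config
        self.channel_a = PerParticleChannel(
            0, rng, config.latent_dim, config.encoder_hidden, config.position_scale
        )
        self.channel_b = PerParticleChannel(
            1, rng, config.latent_dim, config.encoder_hidden, config.position_scale
        )
        self.predictor = SetPredictor(
            config.latent_dim,
            n_classes,
            rng,
            hidden=config.predictor_hidden,
            pooling=config.pooling,
            pool_scale=config.pool_scale if config.pool_scale is not None else 1.0,
        )
        self.n_classes = n_classes

    @property
    def channels(self):
        return {0: self.channel_a, 1: self.channel_b}

    @property
    def parameters(self):
        return self.channel_a.parameters + self.channel_b.parameters + self.predictor.parameters

    def loss(self, xy, type_mask_a, mask, labels, beta, rng):
        """xy: (B,S,2); type_mask_a: (B,S) 1 for type A; mask: (B,S); labels: (B,)."""
        B, S, _ = xy.shape
        flat = xy.reshape(B * S, 2)
        outs = []
        for ch in (self.channel_a, self.channel_b):
            mean, scale = ch.forward(flat)
            outs.append((mean.reshape(B, S, -1), scale.reshape(B, S, -1)))
        ma = (type_mask_a * mask)[:, :, None]
        mb = ((1.0 - type_mask_a) * mask)[:, :, None]
        mean = outs[0][0] * Tensor(ma) + outs[1][0] * Tensor(mb)
        # padded/other-type entries get scale 1 so their KL contribution is 0
        scale = outs[0][1] * Tensor(ma) + outs[1][1] * Tensor(mb) + Tensor(1.0 - ma - mb)
        kl = (mean.square() + scale.square() - 1.0 - scale.log() * 2.0).sum(axis=2) * 0.5
        kl_per_nbhd = (kl * Tensor(mask)).sum(axis=1)
        kl_mean = kl_per_nbhd.mean()
        eps = rng.standard_normal(mean.shape)
        u = mean + scale * Tensor(eps)
        logp = self.predictor(u, mask)
        onehot = np.zeros((B, self.n_classes))
        onehot[np.arange(B), labels] = 1.0
        ce = -(logp * Tensor(onehot)).sum(axis=-1).mean()
        loss = kl_mean * float(beta) + ce
        return loss, {"kl_bits": np.array([float(kl_mean.data) / LN2]), "ce_nats": float(ce.data)}

    # ------------------------------------------------------------- snapshot
    def snapshot_checkpoint(self, step, beta, parts, loss) -> SweepCheckpoint:
        return SweepCheckpoint(
            step=step,
            beta=beta,
            channel_snapshots=[self.channel_a.snapshot(), self.channel_b.snapshot()],
            decoder_snapshot=[p.data.copy() for p in self.predictor.parameters],
            loss_nats=loss,
            kl_bits=parts["kl_bits"].copy(),
            ce_nats=parts["ce_nats"],
        )

    def load_checkpoint(self, ckpt: SweepCheckpoint):
        self.channel_a.load_snapshot(ckpt.channel_snapshots[0])
        self.channel_b.load_snapshot(ckpt.channel_snapshots[1])
        for p, a in zip(self.predictor.parameters, ckpt.decoder_snapshot):
            p.data[...] = a

    # ----------------------------------------------------------- evaluation
    def predict_logprob(self, nbhds: Sequence[ParticleNeighborhood], rng, n_samples: int = 4):
        from scipy.special import logsumexp

        xy, ta, mask, _ = pad_neighborhoods(nbhds)
        B, S, _ = xy.shape
        flat = xy.reshape(B * S, 2)
        lat_a = self.channel_a.encode(flat)
        lat_b = self.channel_b.encode(flat)
        ma = (ta * mask).reshape(B * S, 1)
        mb = ((1 - ta) * mask).reshape(B * S, 1)
        mean = lat_a.mean * ma + lat_b.mean * mb
        scale = lat_a.scale * ma + lat_b.scale * mb + (1.0 - ma - mb)
        acc = []
        for _ in range(n_samples):
            u = mean + scale * rng.standard_normal(mean.shape)
            logp = self.predictor(Tensor(u.reshape(B, S, -1)), mask).data
            acc.append(logp)
        return logsumexp(np.stack(acc), axis=0) - np.log(n_samples)


def pad_neighborhoods(nbhds: Sequence[ParticleNeighborhood]):
    """Pad a list of neighborhoods to (B, S, 2) arrays with masks."""
    B = len(nbhds)
    S = max((len(n.types) for n in nbhds), default=0)
    xy = np.zeros((B, S, 2))
    ta = np.zeros((B, S))
    mask = np.zeros((B, S))
    labels = np.array([n.label for n in nbhds], dtype=int)
    for i, n in enumerate(nbhds):
        k = len(n.types)
        xy[i, :k] = n.xy
        ta[i, :k] = (n.types == 0).astype(float)
        mask[i, :k] = 1.0
    return xy, ta, mask, labels


def encode_neighborhood_set(channels: dict, nbhd: ParticleNeighborhood):
    """One latent per particle via its type's channel, plus per-particle KL bits."""
    if not set(np.unique(nbhd.types)).issubset(set(channels)):
        raise ValueError("channels must cover every particle type present")
    latents, kl_bits = [], np.zeros(len(nbhd.types))
    for i, (t, pos) in enumerate(zip(nbhd.types, nbhd.xy)):
        lat = channels[int(t)].encode(pos[None, :])
        latents.append(lat)
        kl_bits[i] = kl_to_prior_bits(lat)[0]
    return latents, kl_bits


def set_predict(model: SetDIBModel, nbhd: ParticleNeighborhood):
    """Label distribution for one neighborhood.

    Decodes at the latent means (no sampling), so the output is exactly
    invariant to the ordering of the particles up to float round-off.
    """
    xy, ta, mask, _ = pad_neighborhoods([nbhd])
    B, S, _ = xy.shape
    if S == 0:
        return np.exp(model.predictor(Tensor(np.zeros((1, 0, model.config.latent_dim))), mask).data[0])
    flat = xy.reshape(B * S, 2)
    lat_a = model.channel_a.encode(flat)
    lat_b = model.channel_b.encode(flat)
    ma = (ta * mask).reshape(B * S, 1)
    mb = ((1 - ta) * mask).reshape(B * S, 1)
    mean = lat_a.mean * ma + lat_b.mean * mb
    logp = model.predictor(Tensor(mean.reshape(B, S, -1)), mask).data
    return np.exp(logp[0])


def train_set_sweep(
    nbhds: Sequence[ParticleNeighborhood],
    config: SetSweepConfig = None,
    seed: int = 0,
    model: SetDIBModel = None,
    progress: bool = False,
) -> Tuple[SetDIBModel, List[SweepCheckpoint]]:
    """β-annealed training of the set model; returns (model, checkpoints)."""
    config = config or SetSweepConfig()
    if config.pool_scale is None:
        mean_size = float(np.mean([len(n.types) for n in nbhds])) or 1.0
        config = replace(config, pool_scale=1.0 / mean_size)
    rng = np.random.default_rng(seed)
    labels_all = np.array([n.label for n in nbhds])
    if len(np.unique(labels_all)) < 2:
        raise ValueError("dataset must contain at least 2 classes")
    if model is None:
        model = SetDIBModel(config, int(labels_all.max()) + 1, rng)
    schedule = make_beta_schedule(config.beta_start, config.beta_end, config.n_steps)
    opt = Adam(model.parameters, lr=config.learning_rate)
    ckpt_steps = set(
        np.unique(np.round(np.geomspace(1, config.n_steps, config.n_checkpoints)).astype(int)).tolist()
    )
    checkpoints = []
    n = len(nbhds)
    for step, beta in enumerate(schedule, start=1):
        idx = rng.integers(0, n, size=min(config.batch_size, n))
        xy, ta, mask, labels = pad_neighborhoods([nbhds[j] for j in idx])
        if config.rotation_augment and step >= config.rotation_augment_start_frac * config.n_steps:
            ang = rng.uniform(0.0, 2.0 * np.pi, size=len(idx))
            c, s = np.cos(ang)[:, None], np.sin(ang)[:, None]
            x, y = xy[:, :, 0], xy[:, :, 1]
            xy = np.stack([c * x - s * y, s * x + c * y], axis=2)
        loss, parts = model.loss(xy, ta, mask, labels, float(beta), rng)
        if not np.isfinite(loss.data):
            raise TrainingFailure(step, float(beta), parts)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if step in ckpt_steps:
            checkpoints.append(model.snapshot_checkpoint(step, float(beta), parts, float(loss.data)))
            if progress:
                print(
                    f"step {step:6d}  beta {beta:9.3g}  KL {parts['kl_bits'].sum():7.3f} bits  "
                    f"CE {parts['ce_nats']:7.4f} nats"
                )
    return model, checkpoints


@dataclass
class PositionalInfoMap:
    """Mean per-particle information cost binned over position."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    mean_bits: np.ndarray  # (nx, ny); NaN where unoccupied
    occupancy: np.ndarray  # (nx, ny) particle counts
    radial_r: np.ndarray
    radial_bits: np.ndarray  # NaN where unoccupied

    @property
    def peak_radius(self) -> float:
        ok = ~np.isnan(self.radial_bits)
        return float(self.radial_r[ok][np.argmax(self.radial_bits[ok])])


def positional_info_map(
    channels: dict,
    nbhds: Sequence[ParticleNeighborhood],
    particle_type: int = 0,
    n_cells: int = 50,
    r_max: float = 5.0,
    annulus_width: float = 0.1,
) -> PositionalInfoMap:
    """Per-cell and radially averaged per-particle KL cost for one type."""
    if not nbhds:
        raise ValueError("dataset must be nonempty")
    xs, ys, bits = [], [], []
    ch = channels[particle_type]
    for nb in nbhds:
        sel = nb.types == particle_type
        if not sel.any():
            continue
        pos = nb.xy[sel]
        kb = ch.kl_bits(pos)
        xs.append(pos[:, 0])
        ys.append(pos[:, 1])
        bits.append(kb)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    b = np.concatenate(bits)
    edges = np.linspace(-r_max, r_max, n_cells + 1)
    occ, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    tot, _, _ = np.histogram2d(x, y, bins=[edges, edges], weights=b)
    with np.errstate(invalid="ignore"):
        mean_map = np.where(occ > 0, tot / np.maximum(occ, 1), np.nan)
    r = np.hypot(x, y)
    redges = np.arange(0.0, r_max + annulus_width, annulus_width)
    rocc, _ = np.histogram(r, bins=redges)
    rtot, _ = np.histogram(r, bins=redges, weights=b)
    with np.errstate(invalid="ignore"):
        rmean = np.where(rocc > 0, rtot / np.maximum(rocc, 1), np.nan)
    return PositionalInfoMap(
        x_edges=edges,
        y_edges=edges,
        mean_bits=mean_map,
        occupancy=occ,
        radial_r=0.5 * (redges[:-1] + redges[1:]),
        radial_bits=rmean,
    )


def positional_distinguishability(
    channel: EncoderChannel, reference: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """1 - BC between the encoding at ``reference`` and at each position."""
    reference = np.asarray(reference, float).reshape(1, 2)
    positions = np.asarray(positions, float).reshape(-1, 2)
    lat_ref = channel.encode(reference)
    lat = channel.encode(positions)
    var = lat.scale**2
    vsum = var + lat_ref.scale**2
    dmu = lat.mean - lat_ref.mean
    db = 0.25 * (dmu**2 / vsum).sum(axis=1) + 0.5 * np.log(
        vsum / (2.0 * lat.scale * lat_ref.scale)
    ).sum(axis=1)
    return 1.0 - np.exp(-db)
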