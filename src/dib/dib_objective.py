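"""The distributed-IB objective and the β-annealed training sweep.

One bottleneck per feature: every feature Xi is compressed by its own
channel into Ui, the sampled latents are concatenated and decoded into a
label distribution, and the loss is

    L = β · Σ_i E[KL(p(u_i|x_i) || r(u))]  +  E[-log q(y | u_1..u_N)]

in nats.  The KL term upper-bounds Σ_i I(Ui;Xi); the cross-entropy term
upper-bounds H(Y|U), so minimizing L maximizes a lower bound on I(U;Y)
subject to the information penalty.  A single optimization run anneals β
from a strong bottleneck (every channel pinned at the prior, 0 bits) to a
weak one (all information transmitted), producing a continuum of
compression schemes; checkpoints taken along the way are the raw material
for the information-plane analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from ._autograd import Tensor, concat, log_softmax
from .encoders import LN2, EncoderChannel, GroupedEncoderChannels
from .nn import MLP, Adam

__all__ = [
    "TabularDataset",
    "DIBModel",
    "SweepConfig",
    "SweepCheckpoint",
    "TrainingFailure",
    "dib_loss",
    "make_beta_schedule",
    "train_sweep",
]


class TrainingFailure(RuntimeError):
    """Raised when the loss becomes non-finite; carries diagnostics."""

    def __init__(self, step: int, beta: float, diagnostics: dict):
        self.step, self.beta, self.diagnostics = step, beta, diagnostics
        super().__init__(f"non-finite loss at step {step} (beta={beta:.3g}): {diagnostics}")


@dataclass
class TabularDataset:
    """Rows = samples, columns = partial measurements Xi, plus labels Y.

    ``weights`` holds exact row probabilities for enumerated distributions
    (truth tables) and triggers full-batch training with exact weighting;
    otherwise rows are sampled in minibatches.  ``discrete_support[i]`` is
    the enumerable value set of feature i (or None for continuous).
    """

    features: np.ndarray
    labels: np.ndarray
    feature_ids: List[str]
    weights: Optional[np.ndarray] = None
    discrete_support: Optional[list] = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels must have the same number of rows")
        if self.features.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids must match the number of feature columns")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def label_marginal(self) -> np.ndarray:
        w = self.weights if self.weights is not None else np.full(len(self.labels), 1.0 / len(self.labels))
        return np.bincount(self.labels, weights=w, minlength=self.n_classes)

    def label_entropy_bits(self) -> float:
        p = self.label_marginal()
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    @classmethod
    def from_truth_table(cls, table) -> "TabularDataset":
        return cls(
            features=table.inputs.astype(float),
            labels=table.outputs.astype(int),
            feature_ids=[f"x{i+1}" for i in range(table.n_inputs)],
            weights=table.probs.copy(),
            discrete_support=[np.array([0.0, 1.0])] * table.n_inputs,
        )


@dataclass
class SweepConfig:
    beta_start: float = 1.0
    beta_end: float = 3e-5
    n_steps: int = 30_000
    latent_dim: int = 8
    encoder_hidden: tuple = (64, 64)
    decoder_hidden: tuple = (128, 128)
    learning_rate: float = 1e-3
    batch_size: int = 256
    n_checkpoints: int = 100
    standardize: bool = True  # ignored for enumerable binary features
    activation: str = "tanh"
    # enumerated datasets train full-batch with exact weights by default;
    # row-sampled minibatches inject the gradient noise that helps open
    # channels whose information is only jointly (XOR-like) useful
    full_batch: bool = True
    # extra event-triggered checkpoints: snapshot when the running KL total
    # (bits) first crosses each level, so fast opening cascades still leave
    # finely spaced points on the low-information part of the trajectory
    checkpoint_bit_levels: tuple = ()


@dataclass
class SweepCheckpoint:
    step: int
    beta: float
    channel_snapshots: list
    decoder_snapshot: list
    loss_nats: float
    kl_bits: np.ndarray  # per-channel training KL (upper bound on I(Ui;Xi))
    ce_nats: float


class DIBModel:
    """Per-feature channels plus a shared MLP decoder.

    Datasets whose features are all continuous scalars use a grouped
    channel bank (stacked parameters, batched matmuls) for speed; the
    per-feature view objects it exposes behave like individual channels
    for all analysis purposes.
    """

    def __init__(self, channels, decoder: MLP, n_classes: int, grouped=None):
        self.grouped = grouped
        self._channels = None if grouped is not None else list(channels)
        self.decoder = decoder
        self.n_classes = n_classes

    @property
    def channels(self):
        if self.grouped is not None:
            return self.grouped.views()
        return self._channels

    @classmethod
    def build(cls, dataset: TabularDataset, config: SweepConfig, rng: np.random.Generator) -> "DIBModel":
        n_feat = dataset.n_features
        all_continuous = dataset.discrete_support is None or all(
            s is None for s in dataset.discrete_support
        )
        grouped = None
        channels = None
        if all_continuous and config.activation == "tanh":
            standardization = None
            if config.standardize:
                mu = dataset.features.mean(axis=0)
                sd = dataset.features.std(axis=0)
                sd[sd == 0] = 1.0
                standardization = (mu, sd)
            grouped = GroupedEncoderChannels(
                dataset.feature_ids,
                rng,
                latent_dim=config.latent_dim,
                hidden=config.encoder_hidden,
                standardization=standardization,
            )
        else:
            channels = []
            for i, fid in enumerate(dataset.feature_ids):
                col = dataset.features[:, i]
                discrete = (
                    dataset.discrete_support is not None
                    and dataset.discrete_support[i] is not None
                )
                standardization = None
                if config.standardize and not discrete:
                    sd = col.std()
                    standardization = (float(col.mean()), float(sd) if sd > 0 else 1.0)
                channels.append(
                    EncoderChannel(
                        feature_id=fid,
                        rng=rng,
                        latent_dim=config.latent_dim,
                        hidden=config.encoder_hidden,
                        standardization=standardization,
                        activation=config.activation,
                    )
                )
        decoder = MLP(
            n_feat * config.latent_dim,
            config.decoder_hidden,
            dataset.n_classes,
            rng,
            zero_init_head=True,
            activation=config.activation,
        )
        return cls(channels, decoder, dataset.n_classes, grouped=grouped)

    @property
    def parameters(self):
        ps = []
        if self.grouped is not None:
            ps.extend(self.grouped.parameters)
        else:
            for ch in self._channels:
                ps.extend(ch.parameters)
        ps.extend(self.decoder.parameters)
        return ps

    # ------------------------------------------------------------------ loss
    def _encode_batch(self, features: np.ndarray, codes: Optional[list]):
        """Per-channel (mean, scale) Tensors; uses the gather shortcut for discrete features."""
        outs = []
        for i, ch in enumerate(self.channels):
            if codes is not None and codes[i] is not None:
                values, code = codes[i]
                outs.append(ch.forward_gathered(values, code))
            else:
                outs.append(ch.forward(features[:, i]))
        return outs

    def loss(
        self,
        features: np.ndarray,
        labels: np.ndarray,
        beta: float,
        rng: np.random.Generator,
        weights: Optional[np.ndarray] = None,
        codes: Optional[list] = None,
    ):
        """Distributed-IB loss (nats) as a differentiable Tensor, plus parts."""
        n = features.shape[0]
        if n == 0:
            raise ValueError("empty batch")
        if labels.shape[0] != n:
            raise ValueError("feature/label length mismatch")
        if beta < 0:
            raise ValueError("beta must be non-negative")
        w = None if weights is None else Tensor(weights)
        if self.grouped is not None:
            mean, scale = self.grouped.forward(features)  # (N, B, d)
            kl_row = (mean.square() + scale.square() - 1.0 - scale.log() * 2.0).sum(axis=2) * 0.5
            kl_ch = (kl_row * w).sum(axis=1) if w is not None else kl_row.mean(axis=1)
            kl_total = kl_ch.sum()
            kl_parts = list(kl_ch.data)
            eps = rng.standard_normal(mean.shape)
            n_feat = mean.shape[0]
            u = (mean + scale * Tensor(eps)).transpose(1, 0, 2).reshape(
                n, n_feat * self.grouped.latent_dim
            )
        else:
            latents = self._encode_batch(features, codes)
            kl_total = Tensor(0.0)
            kl_parts = []
            samples = []
            for mean, scale in latents:
                kl_row = (mean.square() + scale.square() - 1.0 - scale.log() * 2.0).sum(axis=1) * 0.5
                kl_mean = (kl_row * w).sum() if w is not None else kl_row.mean()
                kl_parts.append(float(kl_mean.data))
                kl_total = kl_total + kl_mean
                eps = rng.standard_normal(mean.shape)
                samples.append(mean + scale * Tensor(eps))
            u = concat(samples, axis=-1)
        logits = self.decoder(u)
        logp = log_softmax(logits, axis=-1)
        onehot = np.zeros((n, self.n_classes))
        onehot[np.arange(n), labels] = 1.0
        nll_row = -(logp * Tensor(onehot)).sum(axis=-1)
        ce = (nll_row * w).sum() if w is not None else nll_row.mean()

        loss = kl_total * float(beta) + ce
        parts = {
            "kl_bits": np.array(kl_parts) / LN2,
            "ce_nats": float(ce.data),
        }
        return loss, parts

    # ----------------------------------------------------------- evaluation
    def predict_logprob(self, features: np.ndarray, rng: np.random.Generator, n_samples: int = 8) -> np.ndarray:
        """Mean predicted log-probabilities over latent draws, (n, n_classes), nats."""
        from scipy.special import logsumexp

        n = features.shape[0]
        if self.grouped is not None:
            mean_t, scale_t = self.grouped.forward(features)
            nf, d = mean_t.shape[0], self.grouped.latent_dim
            mean = np.transpose(mean_t.data, (1, 0, 2)).reshape(n, nf * d)
            scale = np.transpose(scale_t.data, (1, 0, 2)).reshape(n, nf * d)
        else:
            latents = [ch.encode(features[:, i]) for i, ch in enumerate(self.channels)]
            mean = np.concatenate([lat.mean for lat in latents], axis=1)
            scale = np.concatenate([lat.scale for lat in latents], axis=1)
        acc = []
        for _ in range(n_samples):
            u = mean + scale * rng.standard_normal(mean.shape)
            logits = self.decoder(Tensor(u)).data
            logp = logits - logsumexp(logits, axis=1, keepdims=True)
            acc.append(logp)
        # average predictive distribution over draws, in log space
        return logsumexp(np.stack(acc), axis=0) - np.log(n_samples)

    # ------------------------------------------------------------- snapshot
    def snapshot_checkpoint(self, step: int, beta: float, parts: dict, loss: float) -> SweepCheckpoint:
        if self.grouped is not None:
            channel_snapshots = [self.grouped.snapshot()]
        else:
            channel_snapshots = [ch.snapshot() for ch in self._channels]
        return SweepCheckpoint(
            step=step,
            beta=beta,
            channel_snapshots=channel_snapshots,
            decoder_snapshot=[p.data.copy() for p in self.decoder.parameters],
            loss_nats=loss,
            kl_bits=parts["kl_bits"].copy(),
            ce_nats=parts["ce_nats"],
        )

    def load_checkpoint(self, ckpt: SweepCheckpoint) -> None:
        if self.grouped is not None:
            self.grouped.load_snapshot(ckpt.channel_snapshots[0])
        else:
            for ch, snap in zip(self._channels, ckpt.channel_snapshots):
                ch.load_snapshot(snap)
        for p, a in zip(self.decoder.parameters, ckpt.decoder_snapshot):
            p.data[...] = a


def dib_loss(model: DIBModel, features, labels, beta, rng=None, weights=None):
    """Functional wrapper returning the scalar loss in nats (float)."""
    rng = rng or np.random.default_rng(0)
    loss, _ = model.loss(np.asarray(features, float), np.asarray(labels, int), beta, rng, weights)
    return float(loss.data)


def make_beta_schedule(beta_start: float, beta_end: float, n_steps: int) -> np.ndarray:
    """Geometric interpolation from beta_start to beta_end, inclusive."""
    if beta_start <= 0 or beta_end <= 0:
        raise ValueError("beta endpoints must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    if n_steps == 1:
        return np.array([beta_start])
    return np.geomspace(beta_start, beta_end, n_steps)


def _checkpoint_steps(n_steps: int, n_checkpoints: int) -> np.ndarray:
    steps = np.unique(np.round(np.geomspace(1, n_steps, n_checkpoints)).astype(int))
    return steps


def train_sweep(
    dataset: TabularDataset,
    config: SweepConfig = None,
    seed: int = 0,
    model: DIBModel = None,
    progress: bool = False,
) -> list:
    """Run one β-annealed optimization and return the checkpoint list.

    The sweep is a single continuous optimization: β follows the geometric
    schedule step by step while the same parameters keep training.
    Enumerated datasets (``weights`` set) train full-batch with exact row
    weighting; sampled datasets use minibatches.
    """
    config = config or SweepConfig()
    rng = np.random.default_rng(seed)
    if dataset.n_classes < 2:
        raise ValueError("dataset must contain at least 2 classes")
    if model is None:
        model = DIBModel.build(dataset, config, rng)
    schedule = make_beta_schedule(config.beta_start, config.beta_end, config.n_steps)
    opt = Adam(model.parameters, lr=config.learning_rate)
    ckpt_steps = set(_checkpoint_steps(config.n_steps, config.n_checkpoints).tolist())

    full_batch = dataset.weights is not None and config.full_batch
    codes = None
    if dataset.discrete_support is not None:
        codes = []
        for i, support in enumerate(dataset.discrete_support):
            if support is None:
                codes.append(None)
            else:
                col = dataset.features[:, i]
                code = np.searchsorted(support, col)
                codes.append((support.astype(float), code))

    checkpoints = []
    pending_levels = set(float(x) for x in config.checkpoint_bit_levels)
    n = dataset.features.shape[0]
    for step, beta in enumerate(schedule, start=1):
        if full_batch:
            feats, labs, w = dataset.features, dataset.labels, dataset.weights
            batch_codes = codes
        else:
            # rows sampled by probability (uniform weights -> uniform rows)
            if dataset.weights is not None:
                idx = rng.choice(n, size=min(config.batch_size, n), p=dataset.weights)
            else:
                idx = rng.integers(0, n, size=min(config.batch_size, n))
            feats, labs, w = dataset.features[idx], dataset.labels[idx], None
            batch_codes = None
            if codes is not None:
                batch_codes = [
                    None if c is None else (c[0], c[1][idx]) for c in codes
                ]
        loss, parts = model.loss(feats, labs, float(beta), rng, weights=w, codes=batch_codes)
        if not np.isfinite(loss.data):
            raise TrainingFailure(step, float(beta), {"kl_bits": parts["kl_bits"], "ce_nats": parts["ce_nats"]})
        opt.zero_grad()
        loss.backward()
        opt.step()
        take = step in ckpt_steps
        if pending_levels:
            tot_bits = parts["kl_bits"].sum()
            crossed = [lv for lv in pending_levels if tot_bits >= lv]
            if crossed:
                pending_levels.difference_update(crossed)
                take = True
        if take:
            checkpoints.append(model.snapshot_checkpoint(step, float(beta), parts, float(loss.data)))
            if progress:
                print(
                    f"step {step:6d}  beta {beta:9.3g}  KL {parts['kl_bits'].sum():7.3f} bits  "
                    f"CE {parts['ce_nats']:7.4f} nats"
                )
    return checkpoints
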