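"""Per-feature stochastic compression channels.

Each feature gets its own channel: a deterministic MLP mapping a raw value
to a diagonal Gaussian p(u|x) in a d-dimensional latent space.  The prior
r(u) is a standard Gaussian, fixed throughout training; the information
cost of a channel is the expected KL divergence from p(u|x) to r(u), which
upper-bounds I(U;X).

The output head of the MLP starts at zero, so a fresh channel maps every
value to the prior exactly (mean 0, scale 1): sweeps start at 0 bits by
construction.  Scales are parameterized as softplus(pre + c) + floor with
c = ln(e-1), so pre = 0 gives scale 1.

Internal losses are in nats; everything reported to the user is in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._autograd import Parameter, Tensor, concat, gather_rows
from .nn import MLP

__all__ = ["GaussianLatent", "EncoderChannel", "kl_to_prior_bits", "sample_latent"]

LN2 = float(np.log(2.0))
_SCALE_OFFSET = float(np.log(np.e - 1.0))  # softplus(offset) == 1
_SCALE_FLOOR = 1e-6


@dataclass
class GaussianLatent:
    """Batch of diagonal Gaussians: mean/scale arrays of shape (batch, dim)."""

    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=float))
        self.scale = np.atleast_2d(np.asarray(self.scale, dtype=float))
        if self.mean.shape != self.scale.shape:
            raise ValueError("mean and scale must have the same shape")
        if np.any(self.scale <= 0):
            raise ValueError("scale must be positive")

    @property
    def dim(self) -> int:
        return self.mean.shape[1]

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Reparameterized draw: mean + scale * standard normal."""
        return self.mean + self.scale * rng.standard_normal(self.mean.shape)

    def log_prob(self, u: np.ndarray) -> np.ndarray:
        """log p(u) in nats for u of shape (batch, dim) -> (batch,)."""
        u = np.atleast_2d(u)
        z = (u - self.mean) / self.scale
        return -0.5 * (z**2).sum(axis=1) - np.log(self.scale).sum(axis=1) - 0.5 * self.dim * np.log(2 * np.pi)

    def cross_log_prob(self, u: np.ndarray) -> np.ndarray:
        """log p_j(u_i) for every (i, j) pair -> (n_u, batch) matrix, nats."""
        u = np.atleast_2d(u)
        z = (u[:, None, :] - self.mean[None, :, :]) / self.scale[None, :, :]
        return (
            -0.5 * (z**2).sum(axis=2)
            - np.log(self.scale).sum(axis=1)[None, :]
            - 0.5 * self.dim * np.log(2 * np.pi)
        )


def kl_to_prior_bits(latent: GaussianLatent) -> np.ndarray:
    """Closed-form KL(p(u|x) || N(0, I)) per row, in bits."""
    m, s = latent.mean, latent.scale
    nats = 0.5 * (m**2 + s**2 - 1.0 - 2.0 * np.log(s)).sum(axis=1)
    return nats / LN2


class EncoderChannel:
    """Lossy compression channel for one feature.

    Parameters
    ----------
    feature_id : str
        Name of the feature the channel compresses.
    rng : numpy.random.Generator
        Drives weight initialization.
    n_in : int
        Dimension of the raw feature (1 for scalar features, 2 for positions).
    latent_dim : int
        Latent dimensionality d.
    hidden : tuple of int
        Hidden widths of the encoder MLP.
    standardization : (mean, std) or None
        Affine transform applied to raw values before the MLP; stored with
        the channel so evaluation matches training.
    """

    def __init__(
        self,
        feature_id: str,
        rng: np.random.Generator,
        n_in: int = 1,
        latent_dim: int = 8,
        hidden: tuple = (64, 64),
        standardization: Optional[tuple] = None,
        activation: str = "tanh",
    ):
        self.feature_id = feature_id
        self.latent_dim = latent_dim
        self.n_in = n_in
        self.net = MLP(n_in, hidden, 2 * latent_dim, rng, zero_init_head=True, activation=activation)
        self.standardization = standardization

    # -------------------------------------------------------------- training
    def _standardize(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite input to channel {self.feature_id!r}")
        if self.standardization is not None:
            mu, sd = self.standardization
            values = (values - mu) / sd
        return values

    def forward(self, values: np.ndarray):
        """Differentiable encode: returns (mean, scale) Tensors (batch, d)."""
        x = Tensor(self._standardize(values))
        out = self.net(x)
        d = self.latent_dim
        mean = out[:, :d]
        scale = (out[:, d:] + _SCALE_OFFSET).softplus() + _SCALE_FLOOR
        return mean, scale

    def forward_gathered(self, unique_values: np.ndarray, codes: np.ndarray):
        """Encode unique values then gather rows by code (cheap for discrete features)."""
        mean_u, scale_u = self.forward(unique_values)
        return gather_rows(mean_u, codes), gather_rows(scale_u, codes)

    # ------------------------------------------------------------ evaluation
    def encode(self, values: np.ndarray) -> GaussianLatent:
        """Non-differentiable encode for analysis; one latent per value."""
        mean, scale = self.forward(values)
        return GaussianLatent(mean=mean.data.copy(), scale=scale.data.copy())

    def kl_bits(self, values: np.ndarray) -> np.ndarray:
        """Per-value information cost KL(p(u|x) || r(u)) in bits."""
        return kl_to_prior_bits(self.encode(values))

    # -------------------------------------------------------------- snapshot
    @property
    def parameters(self):
        return self.net.parameters

    def snapshot(self) -> list:
        return [p.data.copy() for p in self.parameters]

    def load_snapshot(self, arrays: list) -> None:
        for p, a in zip(self.parameters, arrays):
            p.data[...] = a


def sample_latent(latent: GaussianLatent, rng: np.random.Generator) -> np.ndarray:
    """Module-level alias for :meth:`GaussianLatent.sample`."""
    return latent.sample(rng)


class GroupedEncoderChannels:
    """A bank of N scalar-feature channels with stacked parameters.

    Mathematically identical to N independent :class:`EncoderChannel`
    objects with the same architecture, but the forward pass runs as a
    handful of batched matmuls over a leading channel axis instead of N
    separate graphs — the practical difference between minutes and an hour
    when N is in the hundreds.  Individual channels are exposed as views
    for analysis code.
    """

    def __init__(
        self,
        feature_ids,
        rng: np.random.Generator,
        latent_dim: int = 8,
        hidden: tuple = (64, 64),
        standardization=None,  # (means, stds) arrays of length N, or None
    ):
        self.feature_ids = list(feature_ids)
        n = len(self.feature_ids)
        self.latent_dim = latent_dim
        self.hidden = tuple(hidden)
        self.standardization = standardization
        dims = [1, *hidden, 2 * latent_dim]
        self.weights, self.biases = [], []
        for li, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            last = li == len(dims) - 2
            if last:
                w = np.zeros((n, a, b))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / (a + b)), size=(n, a, b))
            self.weights.append(Parameter(w))
            self.biases.append(Parameter(np.zeros((n, 1, b))))

    @property
    def n_channels(self) -> int:
        return len(self.feature_ids)

    @property
    def parameters(self):
        return [*self.weights, *self.biases]

    def _standardize(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)  # (B, N)
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite input to grouped channels")
        if self.standardization is not None:
            mu, sd = self.standardization
            values = (values - mu[None, :]) / sd[None, :]
        return values

    def forward(self, values: np.ndarray):
        """values (B, N) -> mean, scale Tensors of shape (N, B, d)."""
        x = Tensor(self._standardize(values).T[:, :, None])  # (N, B, 1)
        n_layers = len(self.weights)
        for li, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ w + b
            if li < n_layers - 1:
                x = x.tanh()
        d = self.latent_dim
        mean = x[:, :, :d]
        scale = (x[:, :, d:] + _SCALE_OFFSET).softplus() + _SCALE_FLOOR
        return mean, scale

    # ----------------------------------------------------------- snapshots
    def snapshot(self) -> list:
        return [p.data.copy() for p in self.parameters]

    def load_snapshot(self, arrays: list) -> None:
        for p, a in zip(self.parameters, arrays):
            p.data[...] = a

    # ---------------------------------------------------------- view path
    def channel_view(self, i: int) -> "GroupedChannelView":
        return GroupedChannelView(self, i)

    def views(self):
        return [self.channel_view(i) for i in range(self.n_channels)]


class GroupedChannelView:
    """Read-only per-feature view of a :class:`GroupedEncoderChannels` bank.

    Implements the evaluation surface of :class:`EncoderChannel` (encode,
    kl_bits, feature_id) against the bank's current parameters.
    """

    def __init__(self, bank: GroupedEncoderChannels, index: int):
        self.bank = bank
        self.index = index
        self.feature_id = bank.feature_ids[index]
        self.latent_dim = bank.latent_dim

    def encode(self, values: np.ndarray) -> GaussianLatent:
        values = np.asarray(values, dtype=float).ravel()
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite input to channel {self.feature_id!r}")
        x = values
        if self.bank.standardization is not None:
            mu, sd = self.bank.standardization
            x = (x - mu[self.index]) / sd[self.index]
        h = x[:, None]
        n_layers = len(self.bank.weights)
        for li, (w, b) in enumerate(zip(self.bank.weights, self.bank.biases)):
            h = h @ w.data[self.index] + b.data[self.index, 0]
            if li < n_layers - 1:
                h = np.tanh(h)
        d = self.latent_dim
        scale = np.logaddexp(h[:, d:] + _SCALE_OFFSET, 0.0) + _SCALE_FLOOR
        return GaussianLatent(mean=h[:, :d].copy(), scale=scale)

    def kl_bits(self, values: np.ndarray) -> np.ndarray:
        return kl_to_prior_bits(self.encode(values))
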