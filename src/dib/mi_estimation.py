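"""Precise per-channel mutual-information estimates for frozen channels.

Because each channel's conditional p(u|x) is a known diagonal Gaussian,
I(U;X) is the mutual information of a Gaussian mixture and can be
bracketed tightly from samples:

* lower (contrastive):   E_j [ log p(u_j|x_j) - log (1/K) Σ_k p(u_j|x_k) ]
* upper (leave-one-out): E_j [ log p(u_j|x_j) - log (1/(K-1)) Σ_{k≠j} p(u_j|x_k) ]

with x_1..x_K drawn from the feature marginal and u_j ~ p(u|x_j).  For
features with enumerable support the mixture sum collapses onto the
distinct values, and an unbiased Monte-Carlo evaluation of the exact
mixture integral is available as an oracle.  All results in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import logsumexp

from .encoders import LN2, EncoderChannel, GaussianLatent

__all__ = [
    "MIEstimate",
    "channel_mi_bounds",
    "exact_discrete_channel_mi",
    "predictive_info",
]


@dataclass
class MIEstimate:
    lower_bits: float
    upper_bits: float
    n_samples: int
    std_error: float

    @property
    def mid_bits(self) -> float:
        return 0.5 * (self.lower_bits + self.upper_bits)

    @property
    def gap_bits(self) -> float:
        return self.upper_bits - self.lower_bits


def _draw_values(feature, K: int, rng: np.random.Generator):
    """Draw K feature values from either an empirical sample or a (values, probs) pmf."""
    if isinstance(feature, tuple):
        values, probs = feature
        values = np.asarray(values, dtype=float)
        probs = np.asarray(probs, dtype=float)
        idx = rng.choice(len(values), size=K, p=probs)
        return values[idx], (values, probs, idx)
    sample = np.asarray(feature, dtype=float)
    idx = rng.integers(0, len(sample), size=K)
    return sample[idx], None


def _batch_bounds_discrete(
    channel: EncoderChannel, values: np.ndarray, probs: np.ndarray, idx: np.ndarray, rng
) -> Tuple[float, float]:
    """One batch of bounds exploiting enumerable support (counts instead of K×K)."""
    K = len(idx)
    lat = channel.encode(values)  # (V, d) encodings of the distinct values
    u = GaussianLatent(lat.mean[idx], lat.scale[idx]).sample(rng)  # (K, d)
    logp = lat.cross_log_prob(u)  # (K, V): log p(u_j | v)
    counts = np.bincount(idx, minlength=len(values)).astype(float)
    log_counts = np.where(counts > 0, np.log(np.maximum(counts, 1e-300)), -np.inf)
    own = logp[np.arange(K), idx]
    total = logsumexp(logp + log_counts[None, :], axis=1)  # log Σ_k p(u_j|x_k)
    lower = float(np.mean(own - (total - np.log(K))))
    # leave-one-out: remove the j-th term (one copy of own) from the sum
    with np.errstate(divide="ignore"):
        diff = np.log1p(-np.minimum(np.exp(own - total), 1.0 - 1e-16))
    loo = total + diff
    upper = float(np.mean(own - (loo - np.log(K - 1))))
    return lower / LN2, upper / LN2


def _batch_bounds_continuous(channel: EncoderChannel, x: np.ndarray, rng) -> Tuple[float, float]:
    K = len(x)
    lat = channel.encode(x)
    u = lat.sample(rng)
    logp = lat.cross_log_prob(u)  # (K, K)
    own = np.diag(logp)
    total = logsumexp(logp, axis=1)
    lower = float(np.mean(own - (total - np.log(K))))
    mask = np.ones((K, K), dtype=bool)
    np.fill_diagonal(mask, False)
    loo = logsumexp(np.where(mask, logp, -np.inf), axis=1)
    upper = float(np.mean(own - (loo - np.log(K - 1))))
    return lower / LN2, upper / LN2


def channel_mi_bounds(
    channel: EncoderChannel,
    feature,
    K: int = 4096,
    n_batches: int = 32,
    seed: int = 0,
) -> MIEstimate:
    """Contrastive lower / leave-one-out upper bounds on I(U;X), in bits.

    ``feature`` is either an array of sampled values or a ``(values,
    probs)`` pmf for enumerable features.  Standard errors are jackknife
    estimates over the batch means.
    """
    if K < 2:
        raise ValueError("batch size K must be at least 2")
    rng = np.random.default_rng(seed)
    lowers, uppers = [], []
    for _ in range(n_batches):
        x, disc = _draw_values(feature, K, rng)
        if disc is not None:
            values, probs, idx = disc
            lo, up = _batch_bounds_discrete(channel, values, probs, idx, rng)
        else:
            lo, up = _batch_bounds_continuous(channel, x, rng)
        lowers.append(lo)
        uppers.append(up)
    lowers, uppers = np.array(lowers), np.array(uppers)
    n = len(lowers)
    if n > 1:
        # jackknife over batches (equals the usual std error of the mean here)
        jk = np.array([np.delete(lowers, i).mean() for i in range(n)])
        se_lo = float(np.sqrt((n - 1) * np.mean((jk - jk.mean()) ** 2)))
        jk = np.array([np.delete(uppers, i).mean() for i in range(n)])
        se_up = float(np.sqrt((n - 1) * np.mean((jk - jk.mean()) ** 2)))
        se = max(se_lo, se_up)
    else:
        se = float("nan")
    return MIEstimate(
        lower_bits=float(lowers.mean()),
        upper_bits=float(uppers.mean()),
        n_samples=K * n_batches,
        std_error=se,
    )


def exact_discrete_channel_mi(
    channel: EncoderChannel,
    pmf: Tuple[np.ndarray, np.ndarray],
    n_mc: int = 100_000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Unbiased Monte-Carlo estimate of the exact mixture MI, in bits.

    For enumerable support, I(U;X) = Σ_x p(x) E_{u~p(u|x)} [ log p(u|x) -
    log Σ_x' p(x') p(u|x') ] exactly; the only error is Monte-Carlo noise
    in the expectation over u.  Returns (mi_bits, std_error_bits).
    """
    values, probs = pmf
    values = np.asarray(values, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if len(values) > 64:
        raise ValueError("support too large for the exact oracle (max 64 values)")
    rng = np.random.default_rng(seed)
    lat = channel.encode(values)
    idx = rng.choice(len(values), size=n_mc, p=probs)
    u = GaussianLatent(lat.mean[idx], lat.scale[idx]).sample(rng)
    logp = lat.cross_log_prob(u)  # (n_mc, V)
    own = logp[np.arange(n_mc), idx]
    mix = logsumexp(logp + np.log(np.maximum(probs, 1e-300))[None, :], axis=1)
    integrand = (own - mix) / LN2
    return float(integrand.mean()), float(integrand.std(ddof=1) / np.sqrt(n_mc))


def estimates_table(
    model,
    checkpoints,
    dataset,
    K: int = 1024,
    n_batches: int = 4,
    seed: int = 0,
):
    """Per-checkpoint, per-feature bound estimates as a tidy DataFrame.

    Columns: checkpoint, step, beta, feature_id, lower_bits, upper_bits, se.
    """
    import pandas as pd

    rows = []
    for k, ck in enumerate(checkpoints):
        model.load_checkpoint(ck)
        for i, ch in enumerate(model.channels):
            support = None
            if dataset.discrete_support is not None:
                support = dataset.discrete_support[i]
            if support is not None:
                col = dataset.features[:, i]
                w = dataset.weights if dataset.weights is not None else np.full(
                    len(col), 1.0 / len(col)
                )
                probs = np.array([w[col == v].sum() for v in support])
                feature = (support, probs / probs.sum())
            else:
                feature = dataset.features[:, i]
            est = channel_mi_bounds(
                ch, feature, K=K, n_batches=n_batches, seed=seed + 97 * k + i
            )
            rows.append(
                {
                    "checkpoint": k,
                    "step": ck.step,
                    "beta": ck.beta,
                    "feature_id": dataset.feature_ids[i],
                    "lower_bits": est.lower_bits,
                    "upper_bits": est.upper_bits,
                    "se": est.std_error,
                }
            )
    return pd.DataFrame(rows)


def predictive_info(
    model,
    dataset,
    n_samples: int = 8,
    seed: int = 0,
) -> Tuple[float, float]:
    """Variational lower bound on I(U;Y) in bits, plus argmax accuracy.

    Computes H(Y) - E[-log q(y|u)] with the empirical label marginal; the
    decoder cross-entropy upper-bounds H(Y|U), so the difference
    lower-bounds the predictive information.
    """
    marginal = dataset.label_marginal()
    if np.count_nonzero(marginal) < 2:
        raise ValueError("degenerate labels: only one class present")
    rng = np.random.default_rng(seed)
    logp = model.predict_logprob(dataset.features, rng, n_samples=n_samples)
    n = len(dataset.labels)
    w = dataset.weights if dataset.weights is not None else np.full(n, 1.0 / n)
    ce_bits = float(-(w * logp[np.arange(n), dataset.labels]).sum() / LN2)
    h_y = dataset.label_entropy_bits()
    info = h_y - ce_bits
    acc = float((w * (logp.argmax(axis=1) == dataset.labels)).sum())
    return info, acc
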