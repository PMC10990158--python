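"""From sweep checkpoints to analysis artifacts.

The sweep produces a sequence of compression schemes; this module turns
them into the objects one actually reads: the distributed information
plane (predictive information vs. total utilized information), per-feature
allocation heatmaps, the set of informative features at a checkpoint, and
distinguishability matrices that show *which* distinctions between raw
values a channel transmits.

Distinguishability between two encoded values is 1 minus the Bhattacharyya
coefficient of their conditional Gaussians: 0 means the two raw values are
encoded identically (indistinguishable to the decoder), 1 means their
encodings do not overlap at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .dib_objective import DIBModel, SweepCheckpoint, TabularDataset
from .encoders import EncoderChannel
from .mi_estimation import channel_mi_bounds, exact_discrete_channel_mi, predictive_info

__all__ = [
    "InfoPlanePoint",
    "AllocationHeatmap",
    "DistinguishabilityMatrix",
    "ThresholdSummary",
    "EvalConfig",
    "info_plane",
    "allocation_heatmap",
    "informative_subsets",
    "distinguishability_matrix",
    "detect_threshold",
    "conditional_histograms",
]


@dataclass
class InfoPlanePoint:
    beta: float
    step: int
    channel_bits: np.ndarray  # per-feature I(Ui;Xi) estimates
    predictive_bits: float
    accuracy: float
    feature_ids: List[str]

    @property
    def total_bits(self) -> float:
        return float(self.channel_bits.sum())


@dataclass
class AllocationHeatmap:
    feature_ids: List[str]
    total_bits: np.ndarray  # per column
    matrix: np.ndarray  # (n_features, n_checkpoints)


@dataclass
class DistinguishabilityMatrix:
    grid: np.ndarray  # m raw feature values
    matrix: np.ndarray  # (m, m) in [0, 1]

    def __post_init__(self):
        m = len(self.grid)
        if self.matrix.shape != (m, m):
            raise ValueError("matrix must be m x m")


@dataclass
class ThresholdSummary:
    cutoff: Optional[float]
    within_mean: float
    between_mean: float
    error: float
    degenerate: bool = False
    cut_index: Optional[int] = None


@dataclass
class EvalConfig:
    """How per-channel information is estimated at each checkpoint."""

    n_mc_exact: int = 20_000  # oracle draws for enumerable features
    K: int = 1024  # bound batch size for continuous features
    n_batches: int = 4
    n_label_samples: int = 8
    seed: int = 0


def _channel_bits(
    model: DIBModel, dataset: TabularDataset, cfg: EvalConfig, seed: int
) -> np.ndarray:
    bits = np.empty(len(model.channels))
    for i, ch in enumerate(model.channels):
        support = None
        if dataset.discrete_support is not None:
            support = dataset.discrete_support[i]
        if support is not None:
            col = dataset.features[:, i]
            w = dataset.weights if dataset.weights is not None else np.full(len(col), 1.0 / len(col))
            probs = np.array([w[col == v].sum() for v in support])
            probs = probs / probs.sum()
            mi, _ = exact_discrete_channel_mi(ch, (support, probs), n_mc=cfg.n_mc_exact, seed=seed + i)
            bits[i] = mi
        else:
            est = channel_mi_bounds(
                ch, dataset.features[:, i], K=cfg.K, n_batches=cfg.n_batches, seed=seed + i
            )
            bits[i] = est.mid_bits
    return bits


def info_plane(
    checkpoints: Sequence[SweepCheckpoint],
    dataset: TabularDataset,
    model: DIBModel,
    eval_config: EvalConfig = None,
) -> List[InfoPlanePoint]:
    """One information-plane point per checkpoint, ordered by total bits.

    The horizontal coordinate uses per-channel estimates (exact mixture
    oracle for enumerable features, bound midpoints otherwise); the
    vertical coordinate is the variational lower bound on I(U;Y).
    """
    if len(checkpoints) == 0:
        raise ValueError("need at least one checkpoint")
    cfg = eval_config or EvalConfig()
    points = []
    for k, ck in enumerate(checkpoints):
        model.load_checkpoint(ck)
        try:
            bits = _channel_bits(model, dataset, cfg, seed=cfg.seed + 1000 * k)
            pred, acc = predictive_info(model, dataset, n_samples=cfg.n_label_samples, seed=cfg.seed + k)
        except Exception as exc:  # noqa: BLE001 - annotate with checkpoint id
            raise RuntimeError(f"information estimation failed at checkpoint step={ck.step}") from exc
        points.append(
            InfoPlanePoint(
                beta=ck.beta,
                step=ck.step,
                channel_bits=bits,
                predictive_bits=pred,
                accuracy=acc,
                feature_ids=list(dataset.feature_ids),
            )
        )
    points.sort(key=lambda p: p.total_bits)
    return points


def allocation_heatmap(points: Sequence[InfoPlanePoint]) -> AllocationHeatmap:
    """Per-feature bits as a matrix, columns ordered by total information."""
    if not points:
        raise ValueError("no points")
    ids = points[0].feature_ids
    for p in points:
        if p.feature_ids != ids:
            raise ValueError("inconsistent feature sets across points")
    order = np.argsort([p.total_bits for p in points])
    matrix = np.stack([points[i].channel_bits for i in order], axis=1)
    totals = np.array([points[i].total_bits for i in order])
    return AllocationHeatmap(feature_ids=list(ids), total_bits=totals, matrix=matrix)


def informative_subsets(point: InfoPlanePoint, threshold_bits: float = 0.1) -> set:
    """Features carrying at least ``threshold_bits`` at this sweep point."""
    if threshold_bits < 0:
        raise ValueError("threshold must be non-negative")
    return {
        fid
        for fid, b in zip(point.feature_ids, point.channel_bits)
        if b >= threshold_bits and b > 0.0
    }


def _bhattacharyya_coefficient(mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Pairwise BC for a set of diagonal Gaussians -> (m, m) in (0, 1]."""
    var = scale**2
    vsum = var[:, None, :] + var[None, :, :]
    dmu = mean[:, None, :] - mean[None, :, :]
    db = 0.25 * (dmu**2 / vsum).sum(axis=2) + 0.5 * np.log(
        vsum / (2.0 * scale[:, None, :] * scale[None, :, :])
    ).sum(axis=2)
    return np.exp(-db)


def distinguishability_matrix(channel: EncoderChannel, grid: np.ndarray) -> DistinguishabilityMatrix:
    """1 - Bhattacharyya coefficient between the encodings of grid values."""
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("need at least two grid values")
    standardization = getattr(channel, "standardization", None)
    if standardization is not None:
        mu, sd = standardization
        z = (grid - mu) / sd
        if np.any(np.abs(z) > 6):
            import warnings

            warnings.warn(
                f"grid for channel {channel.feature_id!r} extends beyond 6 standard "
                "deviations of the training distribution; encodings there are extrapolated",
                stacklevel=2,
            )
    lat = channel.encode(grid)
    bc = _bhattacharyya_coefficient(lat.mean, lat.scale)
    mat = 1.0 - bc
    np.fill_diagonal(mat, 0.0)
    mat = np.clip(0.5 * (mat + mat.T), 0.0, 1.0)  # symmetrize away float noise
    return DistinguishabilityMatrix(grid=grid, matrix=mat)


def quantile_grid(sample: np.ndarray, m: int = 64) -> np.ndarray:
    """Default value grid: m equally spaced quantiles of the sample."""
    qs = np.linspace(0.0, 1.0, m)
    return np.quantile(np.asarray(sample, float), qs)


def detect_threshold(dmat: DistinguishabilityMatrix) -> ThresholdSummary:
    """Best two-block description of a distinguishability matrix.

    Scans every cut position along the (sorted) value grid; for each cut
    the matrix is approximated by three constants (within lower block,
    within upper block, between blocks) and the cut minimizing the squared
    residual is returned.  The cutoff value is the midpoint of the grid
    values flanking the best cut.
    """
    mat, grid = dmat.matrix, dmat.grid
    m = len(grid)
    if m < 3:
        raise ValueError("need at least 3 grid values")
    off = ~np.eye(m, dtype=bool)
    if np.all(np.abs(mat[off]) < 1e-12):
        return ThresholdSummary(
            cutoff=None, within_mean=0.0, between_mean=0.0, error=0.0, degenerate=True
        )
    best = None
    for c in range(1, m):
        lo, hi = np.arange(m) < c, np.arange(m) >= c
        blocks = [np.ix_(lo, lo), np.ix_(hi, hi), np.ix_(lo, hi)]
        err = 0.0
        means = []
        for bi, block in enumerate(blocks):
            vals = mat[block]
            if bi < 2:  # within blocks: exclude the diagonal
                sub_off = off[block]
                vals = vals[sub_off]
            if vals.size == 0:
                means.append(0.0)
                continue
            mu = vals.mean()
            means.append(mu)
            err += ((vals - mu) ** 2).sum()
        err += ((mat[np.ix_(hi, lo)] - means[2]) ** 2).sum()
        if best is None or err < best[0]:
            best = (err, c, means)
    err, c, means = best
    n_lo, n_hi = c, m - c
    within_vals = np.concatenate(
        [
            mat[np.ix_(np.arange(m) < c, np.arange(m) < c)][off[:c, :c]],
            mat[np.ix_(np.arange(m) >= c, np.arange(m) >= c)][off[:n_hi, :n_hi]],
        ]
    )
    return ThresholdSummary(
        cutoff=float(0.5 * (grid[c - 1] + grid[c])),
        within_mean=float(within_vals.mean()) if within_vals.size else 0.0,
        between_mean=float(means[2]),
        error=float(err),
        cut_index=c,
    )


def conditional_histograms(
    dataset: TabularDataset, feature_id: str, n_bins: int = 32
):
    """Class-conditional histograms of one feature on a shared grid.

    Returns ``(edges, hist0, hist1, overlap)`` where the histograms are
    density-normalized and overlap = Σ min(p0, p1)·binwidth ∈ [0, 1].
    """
    if feature_id not in dataset.feature_ids:
        raise ValueError(f"unknown feature {feature_id!r}")
    i = dataset.feature_ids.index(feature_id)
    col = dataset.features[:, i]
    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: both classes required")
    edges = np.histogram_bin_edges(col, bins=n_bins)
    h0, _ = np.histogram(col[y == 0], bins=edges, density=True)
    h1, _ = np.histogram(col[y == 1], bins=edges, density=True)
    widths = np.diff(edges)
    overlap = float((np.minimum(h0, h1) * widths).sum())
    return edges, h0, h1, overlap
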