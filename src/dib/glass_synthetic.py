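"""Synthetic stand-in for the sheared-glass rearrangement dataset.

Generates 2D local particle neighborhoods (small type A and large type B
particles around a central type-A particle) from a hard-core point
process, plants a shell-localized rearrangement rule (low occupancy of one
radial band ⇒ rearrangement), and featurizes each neighborhood into 100
Gaussian-smeared radial-band densities (50 shells per type).  Because the
labeling rule is planted, recovery tests can check that the distributed IB
allocates its bits to the right shell and learns the right threshold.

Distances are in simulation length units (σ_AB = 1).  The generator
emulates the statistical shape of the deposited glass dataset — two
particle types, binary labels, balanced classes, label signal in a
near-center radial band — but not the physics that produced it: there is
no shear, no interaction potential beyond the hard core, and no spatial
correlation between positive and negative samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

__all__ = [
    "ParticleNeighborhood",
    "PlantedRule",
    "GlassParams",
    "GlassDataset",
    "shell_grid",
    "synthesize_neighborhoods",
    "radial_density_features",
    "radial_distribution_function",
    "linear_baseline",
    "write_xyz",
    "read_xyz",
]

N_SHELLS = 50
SHELL_R_MIN = 0.25
SHELL_R_MAX = 5.0
SHELL_WIDTH = 0.1


def shell_grid() -> np.ndarray:
    """50 shell centers uniformly spaced on (0.25, 5.0]."""
    dr = (SHELL_R_MAX - SHELL_R_MIN) / N_SHELLS
    return SHELL_R_MIN + dr * np.arange(1, N_SHELLS + 1)


@dataclass
class ParticleNeighborhood:
    """Particles within r_max of the neighborhood center (a type-A particle at the origin)."""

    xy: np.ndarray  # (n, 2) positions
    types: np.ndarray  # (n,) 0 = A (small), 1 = B (large)
    r_max: float
    label: int = 0

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.types = np.asarray(self.types, dtype=int)
        r = np.hypot(self.xy[:, 0], self.xy[:, 1])
        if np.any(r > self.r_max + 1e-9):
            raise ValueError("all particles must lie within r_max of the center")
        if np.any((self.types != 0) & (self.types != 1)):
            raise ValueError("types must be 0 (A) or 1 (B)")

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.xy[:, 0], self.xy[:, 1])


@dataclass
class PlantedRule:
    """Ground-truth labeling: low occupancy of one radial shell ⇒ rearrangement."""

    shell_index: int = 7  # type-A shell at r ≈ 1.0
    particle_type: int = 0
    label_noise: float = 0.1

    def __post_init__(self):
        if not (0 <= self.shell_index < N_SHELLS):
            raise ValueError("shell index out of range")
        if not (0.0 <= self.label_noise <= 0.5):
            raise ValueError("label noise must lie in [0, 0.5]")

    @property
    def feature_column(self) -> int:
        return self.particle_type * N_SHELLS + self.shell_index

    @property
    def shell_radius(self) -> float:
        return float(shell_grid()[self.shell_index])


@dataclass
class GlassParams:
    """Point-process parameters (Kob-Andersen-like composition, declared config)."""

    density: float = 1.0  # particles per unit area
    fraction_a: float = 0.65
    hard_core: float = 0.5  # minimum center-to-center distance
    r_max: float = 5.0


@dataclass
class GlassDataset:
    neighborhoods: List[ParticleNeighborhood]
    features: np.ndarray  # (n, 100) radial-band densities
    labels: np.ndarray  # (n,)
    true_feature: np.ndarray  # planted-shell occupancy before noise
    threshold: float  # the planted rule's τ (feature median)
    rule: PlantedRule
    params: GlassParams

    @property
    def feature_ids(self) -> List[str]:
        return [f"{'AB'[t]}_r{k}" for t in (0, 1) for k in range(N_SHELLS)]


def _sample_neighborhood(params: GlassParams, rng: np.random.Generator) -> ParticleNeighborhood:
    """Random sequential addition of hard disks in a disc, center occupied by a type-A particle."""
    area = np.pi * params.r_max**2
    n_target = rng.poisson(params.density * area)
    pts = np.empty((n_target, 2))
    n_acc = 0
    attempts = 0
    max_attempts = 200 * max(n_target, 1)
    hc2 = params.hard_core**2
    while n_acc < n_target and attempts < max_attempts:
        m = max(n_target - n_acc, 16)
        r = params.r_max * np.sqrt(rng.random(m))
        th = 2 * np.pi * rng.random(m)
        cand = np.column_stack([r * np.cos(th), r * np.sin(th)])
        # keep the hard core clear of the central particle too
        cand = cand[(cand**2).sum(axis=1) >= hc2]
        for p in cand:
            if n_acc == n_target:
                break
            d2 = ((pts[:n_acc] - p) ** 2).sum(axis=1)
            if n_acc == 0 or d2.min() >= hc2:
                pts[n_acc] = p
                n_acc += 1
        attempts += m
    if n_acc < n_target:
        raise RuntimeError(
            f"packing failed: placed {n_acc}/{n_target} disks "
            f"(density {params.density} with hard core {params.hard_core})"
        )
    types = (rng.random(n_acc) >= params.fraction_a).astype(int)
    return ParticleNeighborhood(xy=pts[:n_acc].copy(), types=types, r_max=params.r_max)


def radial_density_features(
    nbhd: ParticleNeighborhood, centers: Optional[np.ndarray] = None, width: float = SHELL_WIDTH
) -> np.ndarray:
    """100 Gaussian-smeared shell counts: type-A block then type-B block.

    feature(t, k) = Σ_{particles of type t} exp(-(r - r_k)^2 / (2 w^2)).
    """
    centers = shell_grid() if centers is None else np.asarray(centers, float)
    out = np.zeros(2 * len(centers))
    r = nbhd.radii
    for t in (0, 1):
        rt = r[nbhd.types == t]
        if rt.size:
            out[t * len(centers) : (t + 1) * len(centers)] = np.exp(
                -((rt[:, None] - centers[None, :]) ** 2) / (2 * width**2)
            ).sum(axis=0)
    return out


def _features_batch(nbhds: List[ParticleNeighborhood], width: float = SHELL_WIDTH) -> np.ndarray:
    centers = shell_grid()
    return np.stack([radial_density_features(n, centers, width) for n in nbhds])


def synthesize_neighborhoods(
    n: int,
    rule: PlantedRule = None,
    params: GlassParams = None,
    seed: int = 0,
) -> GlassDataset:
    """Generate n labeled neighborhoods with a planted shell rule.

    The rule thresholds the true occupancy of the planted shell at its
    median over the generated set (low occupancy ⇒ label 1), so classes
    are balanced by construction; labels are then flipped independently
    with probability ``rule.label_noise``.
    """
    if n < 2:
        raise ValueError("need at least 2 neighborhoods")
    rule = rule or PlantedRule()
    params = params or GlassParams()
    rng = np.random.default_rng(seed)
    nbhds = [_sample_neighborhood(params, rng) for _ in range(n)]
    features = _features_batch(nbhds)
    true_feature = features[:, rule.feature_column].copy()
    tau = float(np.median(true_feature))
    labels = (true_feature < tau).astype(int)
    flips = rng.random(n) < rule.label_noise
    labels = np.where(flips, 1 - labels, labels)
    for nb, lab in zip(nbhds, labels):
        nb.label = int(lab)
    return GlassDataset(
        neighborhoods=nbhds,
        features=features,
        labels=labels,
        true_feature=true_feature,
        threshold=tau,
        rule=rule,
        params=params,
    )


def radial_distribution_function(
    nbhds: List[ParticleNeighborhood],
    pair: str = "AA",
    n_bins: int = 50,
    fraction: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """g(r) about the central type-A particle, for AA or AB pairs.

    Counts neighbors of the requested type in annuli around the center and
    normalizes by annulus area and the partner number density, so an
    ideal-gas configuration gives g ≈ 1 everywhere.  Returns (r, g).
    """
    if pair not in ("AA", "AB"):
        raise ValueError("pair must be 'AA' or 'AB'")
    if len(nbhds) < 100:
        raise ValueError("need at least 100 neighborhoods for stable averaging")
    t = 0 if pair == "AA" else 1
    r_max = nbhds[0].r_max
    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    n_partner = 0
    area = np.pi * r_max**2
    for nb in nbhds:
        rt = nb.radii[nb.types == t]
        n_partner += rt.size
        h, _ = np.histogram(rt, bins=edges)
        counts += h
    rho = n_partner / (len(nbhds) * area)
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    with np.errstate(invalid="ignore"):
        g = counts / (len(nbhds) * rho * annulus)
    r = 0.5 * (edges[:-1] + edges[1:])
    return r, np.nan_to_num(g)


def linear_baseline(
    features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> Tuple[np.ndarray, float]:
    """Maximum-margin linear classifier (the softness direction).

    Standardizes the features, fits a linear SVM on an 80/20 split and
    returns (weight vector in standardized feature space, held-out accuracy).
    """
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate labels: both classes required")
    Xtr, Xte, ytr, yte = train_test_split(
        np.asarray(features, float), labels, test_size=0.2, random_state=seed, stratify=labels
    )
    scaler = StandardScaler().fit(Xtr)
    clf = LinearSVC(C=1.0, random_state=seed)
    clf.fit(scaler.transform(Xtr), ytr)
    acc = float(clf.score(scaler.transform(Xte), yte))
    return clf.coef_.ravel().copy(), acc


# ------------------------------------------------------------------ text io
def write_xyz(path, nbhds: List[ParticleNeighborhood]) -> None:
    """Extended-XYZ-like text: count line, comment with label and r_max, `type x y` rows."""
    with open(path, "w") as fh:
        for nb in nbhds:
            fh.write(f"{len(nb.types)}\n")
            fh.write(f"label={nb.label} r_max={nb.r_max}\n")
            for t, (x, y) in zip(nb.types, nb.xy):
                fh.write(f"{'AB'[t]} {x:.8f} {y:.8f}\n")


def read_xyz(path) -> List[ParticleNeighborhood]:
    nbhds = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        count = int(lines[i])
        meta = dict(kv.split("=") for kv in lines[i + 1].split())
        rows = lines[i + 2 : i + 2 + count]
        types = np.array([0 if r.split()[0] == "A" else 1 for r in rows])
        xy = np.array([[float(r.split()[1]), float(r.split()[2])] for r in rows]).reshape(-1, 2)
        nbhds.append(
            ParticleNeighborhood(
                xy=xy, types=types, r_max=float(meta["r_max"]), label=int(meta["label"])
            )
        )
        i += 2 + count
    return nbhds
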