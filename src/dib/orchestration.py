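"""Experiment configuration, artifact management and reporting.

Ties the pieces together: an :class:`ExperimentConfig` describes one
experiment (circuit, glass-radial or glass-set), :func:`run_experiment`
executes generate → sweep → information plane → analysis and writes a
self-contained artifact directory (config copy, log, HDF5 checkpoint
store, info-plane CSV, heatmap HDF5, plots, manifest with checksums), and
:func:`report` renders a single-page markdown summary from the artifact.
Runs are reproducible from config + seed; the manifest checksums are
stable across reruns.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Literal, Optional

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from .boolean_circuit import generate_circuit, subset_frontier, truth_table
from .dib_objective import DIBModel, SweepConfig, TabularDataset, train_sweep
from .glass_synthetic import GlassParams, PlantedRule, synthesize_neighborhoods
from .info_analysis import (
    EvalConfig,
    allocation_heatmap,
    distinguishability_matrix,
    detect_threshold,
    info_plane,
    informative_subsets,
    quantile_grid,
)

__all__ = ["ExperimentConfig", "run_experiment", "report", "load_config"]


class ScheduleSpec(BaseModel):
    beta_start: float = 1.0
    beta_end: float = 3e-5
    n_steps: int = 12_000
    n_checkpoints: int = 60


class ModelSpec(BaseModel):
    latent_dim: int = 8
    encoder_hidden: List[int] = Field(default_factory=lambda: [64, 64])
    decoder_hidden: List[int] = Field(default_factory=lambda: [128, 128])
    learning_rate: float = 1e-3
    batch_size: int = 256
    pooling: str = "attention"  # glass-set runs only


class CircuitDataSpec(BaseModel):
    n_inputs: int = 10
    n_gates: int = 12
    circuit_seed: int = 1


class GlassDataSpec(BaseModel):
    n_samples: int = 20_000
    label_noise: float = 0.1
    planted_shell: int = 7
    planted_type: int = 0
    density: float = 1.0
    fraction_a: float = 0.65
    hard_core: float = 0.5
    r_max: float = 5.0


class EvalSpec(BaseModel):
    n_mc_exact: int = 20_000
    K: int = 1024
    n_batches: int = 4
    n_label_samples: int = 8
    eval_every: int = 1  # evaluate every k-th checkpoint


class ExperimentConfig(BaseModel):
    kind: Literal["circuit", "glass-radial", "glass-set"]
    seed: int = 0
    output_dir: str = "runs/experiment"
    schedule: ScheduleSpec
    model: ModelSpec = Field(default_factory=ModelSpec)
    circuit: Optional[CircuitDataSpec] = None
    glass: Optional[GlassDataSpec] = None
    eval: EvalSpec = Field(default_factory=EvalSpec)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        keys = sorted({".".join(str(p) for p in e["loc"]) for e in exc.errors()})
        raise ValueError(f"invalid config; offending keys: {keys}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save_checkpoints(path: Path, checkpoints) -> None:
    with h5py.File(path, "w") as fh:
        for k, ck in enumerate(checkpoints):
            g = fh.create_group(f"checkpoint_{k:04d}")
            g.attrs["step"] = ck.step
            g.attrs["beta"] = ck.beta
            g.attrs["loss_nats"] = ck.loss_nats
            g.attrs["ce_nats"] = ck.ce_nats
            g.create_dataset("kl_bits", data=ck.kl_bits, track_times=False)
            for i, snap in enumerate(ck.channel_snapshots):
                cg = g.create_group(f"channel_{i:03d}")
                for j, arr in enumerate(snap):
                    cg.create_dataset(f"p{j}", data=arr, track_times=False)
            dg = g.create_group("decoder")
            for j, arr in enumerate(ck.decoder_snapshot):
                dg.create_dataset(f"p{j}", data=arr, track_times=False)


def _plot_info_plane(points, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    totals = [p.total_bits for p in points]
    preds = [p.predictive_bits for p in points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(totals, preds, "o-", ms=3, color="k")
    ax.set_xlabel(r"total utilized information $\sum_i I(U_i;X_i)$ (bits)")
    ax.set_ylabel(r"predictive information $I(U;Y)$ (bits)")
    ax.set_title("distributed information plane")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_heatmap(hm, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(hm.matrix, aspect="auto", cmap="viridis", origin="lower")
    ax.set_xlabel("checkpoint (ordered by total bits)")
    ax.set_ylabel("feature")
    fig.colorbar(im, ax=ax, label="I(Ui;Xi) (bits)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_experiment(config: ExperimentConfig):
    """Execute one experiment end to end; returns the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg):
        log_lines.append(msg)

    sweep_cfg = SweepConfig(
        beta_start=config.schedule.beta_start,
        beta_end=config.schedule.beta_end,
        n_steps=config.schedule.n_steps,
        n_checkpoints=config.schedule.n_checkpoints,
        latent_dim=config.model.latent_dim,
        encoder_hidden=tuple(config.model.encoder_hidden),
        decoder_hidden=tuple(config.model.decoder_hidden),
        learning_rate=config.model.learning_rate,
        batch_size=config.model.batch_size,
    )

    if config.kind == "circuit":
        spec = config.circuit or CircuitDataSpec()
        circuit = generate_circuit(spec.n_inputs, spec.n_gates, spec.circuit_seed)
        table = truth_table(circuit)
        dataset = TabularDataset.from_truth_table(table)
        (out / "circuit.json").write_text(circuit.to_json())
        table.to_csv(out / "truth_table.csv")
        if spec.n_inputs <= 14:
            _, envelope = subset_frontier(table)
            np.savetxt(out / "frontier_envelope.csv", envelope, header="envelope_bits", comments="")
        log(f"circuit H(Y) = {table.output_entropy():.6f} bits")
    elif config.kind == "glass-radial":
        spec = config.glass or GlassDataSpec()
        glass = synthesize_neighborhoods(
            spec.n_samples,
            rule=PlantedRule(
                shell_index=spec.planted_shell,
                particle_type=spec.planted_type,
                label_noise=spec.label_noise,
            ),
            params=GlassParams(
                density=spec.density,
                fraction_a=spec.fraction_a,
                hard_core=spec.hard_core,
                r_max=spec.r_max,
            ),
            seed=config.seed,
        )
        dataset = TabularDataset(
            features=glass.features,
            labels=glass.labels,
            feature_ids=glass.feature_ids,
        )
        log(f"planted shell column {glass.rule.feature_column}, tau = {glass.threshold:.4f}")
    elif config.kind == "glass-set":
        return _run_glass_set(config, out)
    else:  # pragma: no cover - pydantic forbids it
        raise ValueError(config.kind)

    log(f"training sweep: {config.schedule.n_steps} steps, "
        f"beta {config.schedule.beta_start} -> {config.schedule.beta_end}")
    checkpoints = train_sweep(dataset, sweep_cfg, seed=config.seed)
    for ck in checkpoints:
        log(
            f"step {ck.step:6d} beta {ck.beta:10.4g} "
            f"KL {ck.kl_bits.sum():8.4f} bits CE {ck.ce_nats:8.5f} nats"
        )
    _save_checkpoints(out / "checkpoints.h5", checkpoints)

    model = DIBModel.build(dataset, sweep_cfg, np.random.default_rng(config.seed))
    eval_cfg = EvalConfig(
        n_mc_exact=config.eval.n_mc_exact,
        K=config.eval.K,
        n_batches=config.eval.n_batches,
        n_label_samples=config.eval.n_label_samples,
        seed=config.seed,
    )
    eval_ckpts = checkpoints[:: config.eval.eval_every]
    if eval_ckpts[-1] is not checkpoints[-1]:
        eval_ckpts = eval_ckpts + [checkpoints[-1]]
    points = info_plane(eval_ckpts, dataset, model, eval_cfg)
    pd.DataFrame(
        {
            "beta": [p.beta for p in points],
            "step": [p.step for p in points],
            "total_bits": [p.total_bits for p in points],
            "predictive_bits": [p.predictive_bits for p in points],
            "accuracy": [p.accuracy for p in points],
            **{
                fid: [p.channel_bits[i] for p in points]
                for i, fid in enumerate(dataset.feature_ids)
            },
        }
    ).to_csv(out / "info_plane.csv", index=False)

    hm = allocation_heatmap(points)
    with h5py.File(out / "analysis.h5", "w") as fh:
        fh.create_dataset("heatmap/matrix", data=hm.matrix, track_times=False)
        fh.create_dataset("heatmap/total_bits", data=hm.total_bits, track_times=False)
        fh.attrs["feature_ids"] = [fid.encode() for fid in hm.feature_ids]
        # distinguishability of the most informative channel at the final point
        final = points[-1]
        top = int(np.argmax(final.channel_bits))
        model.load_checkpoint(checkpoints[-1])
        grid = np.unique(quantile_grid(dataset.features[:, top], 64))
        if len(grid) >= 3:
            dmat = distinguishability_matrix(model.channels[top], grid)
            fh.create_dataset("distinguishability/grid", data=dmat.grid, track_times=False)
            fh.create_dataset("distinguishability/matrix", data=dmat.matrix, track_times=False)
            ts = detect_threshold(dmat)
            if not ts.degenerate:
                fh.attrs["threshold_cutoff"] = ts.cutoff
            fh.attrs["threshold_feature"] = dataset.feature_ids[top]

    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    _plot_info_plane(points, plots / "info_plane.png")
    _plot_heatmap(hm, plots / "allocation_heatmap.png")

    (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")

    _write_manifest(out, config)
    return out


def _write_manifest(out: Path, config: ExperimentConfig) -> None:
    manifest = {
        "config_hash": config.config_hash(),
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _run_glass_set(config: ExperimentConfig, out: Path):
    """Per-particle basis experiment: shared type channels + set predictor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .set_basis import SetSweepConfig, positional_info_map, train_set_sweep

    spec = config.glass or GlassDataSpec()
    glass = synthesize_neighborhoods(
        spec.n_samples,
        rule=PlantedRule(
            shell_index=spec.planted_shell,
            particle_type=spec.planted_type,
            label_noise=spec.label_noise,
        ),
        params=GlassParams(
            density=spec.density,
            fraction_a=spec.fraction_a,
            hard_core=spec.hard_core,
            r_max=spec.r_max,
        ),
        seed=config.seed,
    )
    set_cfg = SetSweepConfig(
        beta_start=config.schedule.beta_start,
        beta_end=config.schedule.beta_end,
        n_steps=config.schedule.n_steps,
        n_checkpoints=config.schedule.n_checkpoints,
        latent_dim=config.model.latent_dim,
        encoder_hidden=tuple(config.model.encoder_hidden),
        learning_rate=config.model.learning_rate,
        batch_size=config.model.batch_size,
        pooling=config.model.pooling,
    )
    model, checkpoints = train_set_sweep(glass.neighborhoods, set_cfg, seed=config.seed)
    _save_checkpoints(out / "checkpoints.h5", checkpoints)
    info_map = positional_info_map(
        model.channels, glass.neighborhoods, particle_type=spec.planted_type, r_max=spec.r_max
    )
    with h5py.File(out / "positional_map.h5", "w") as fh:
        fh.create_dataset("mean_bits", data=info_map.mean_bits, track_times=False)
        fh.create_dataset("occupancy", data=info_map.occupancy, track_times=False)
        fh.create_dataset("radial_r", data=info_map.radial_r, track_times=False)
        fh.create_dataset("radial_bits", data=info_map.radial_bits, track_times=False)
        fh.attrs["peak_radius"] = info_map.peak_radius

    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(
        info_map.mean_bits.T,
        origin="lower",
        extent=[-spec.r_max, spec.r_max, -spec.r_max, spec.r_max],
        cmap="magma",
    )
    fig.colorbar(im, ax=ax, label="per-particle information (bits)")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(plots / "positional_map.png", dpi=120)
    plt.close(fig)

    log_lines = [
        f"glass-set run: {spec.n_samples} neighborhoods, planted shell {spec.planted_shell}",
        f"final KL {checkpoints[-1].kl_bits.sum():.4f} bits, CE {checkpoints[-1].ce_nats:.5f} nats",
        f"positional map peak radius {info_map.peak_radius:.3f}",
    ]
    (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    _write_manifest(out, config)
    return out


def report(artifact_dir) -> Path:
    """Render a one-page markdown summary of a run artifact (idempotent)."""
    out = Path(artifact_dir)
    missing = [
        name
        for name in ("info_plane.csv", "analysis.h5", "config.yaml")
        if not (out / name).exists()
    ]
    if missing:
        raise FileNotFoundError(f"incomplete artifact, missing: {missing}")
    df = pd.read_csv(out / "info_plane.csv")
    meta_cols = {"beta", "step", "total_bits", "predictive_bits", "accuracy"}
    feature_cols = [c for c in df.columns if c not in meta_cols]
    lines = ["# Run summary", ""]
    lines.append(f"Checkpoints evaluated: {len(df)}")
    lines.append(
        f"Final point: total {df.total_bits.iloc[-1]:.3f} bits, "
        f"predictive {df.predictive_bits.iloc[-1]:.3f} bits, "
        f"accuracy {df.accuracy.iloc[-1]:.4f}"
    )
    lines.append("")
    for target in (1.0, 5.0, 20.0):
        if df.total_bits.max() < target - 0.5:
            continue
        row = df.iloc[(df.total_bits - target).abs().argmin()]
        alloc = row[feature_cols].astype(float)
        top = alloc[alloc >= 0.1].sort_values(ascending=False)
        lines.append(
            f"## Near {target:g} bits (total {row.total_bits:.3f}, "
            f"predictive {row.predictive_bits:.3f})"
        )
        if len(top):
            for fid, b in top.items():
                lines.append(f"- {fid}: {b:.3f} bits")
        else:
            lines.append("- no feature at or above 0.1 bits")
        lines.append("")
    with h5py.File(out / "analysis.h5", "r") as fh:
        if "threshold_cutoff" in fh.attrs:
            lines.append(
                f"Learned threshold on {fh.attrs['threshold_feature']}: "
                f"cutoff {float(fh.attrs['threshold_cutoff']):.4f}"
            )
    if (out / "plots" / "info_plane.png").exists():
        lines.append("")
        lines.append("![information plane](plots/info_plane.png)")
    path = out / "summary.md"
    path.write_text("\n".join(lines) + "\n")
    return path
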