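"""Figures, run configuration and the end-to-end pipeline.

The pipeline composes the stages in the order the analysis runs:
simulate (or ingest) -> complete-track filter -> trajectory metrics ->
symmetry augmentation -> feature construction -> shuffled 80/20 split
-> train -> confusion-matrix evaluation -> figures. Every run writes
its intermediates as CSV, the figures as PNG, a log, and the fully
resolved configuration as YAML next to the outputs, so a run directory
is self-describing and reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import augmentation, classifier, dataset_builder, motility_sim, track_io
from . import traj_metrics
from .classifier import ConfusionMatrix, ModelConfig, TrainResult
from .motility_sim import JumperParams, MoverParams, SimConfig, SpinnerParams
from .track_io import ClassLabel, TrackSet

__all__ = [
    "RunConfig",
    "plot_trajectories",
    "plot_metric_boxplots",
    "plot_training_report",
    "run_pipeline",
]

logger = logging.getLogger("macrotraj")

_CLASS_COLORS = {"M0": "tab:red", "M1": "tab:green", "M2": "tab:blue"}


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    tracks_path: str | None = None  # None -> simulate
    out_dir: str = "run"
    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    split_seed: int = 0
    train_fraction: float = 0.8
    center_on_start: bool = True
    standardize: bool = False
    include_identity: bool = True
    group_by_origin: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = SimConfig(
                **{
                    k: v
                    for k, v in sim.items()
                    if k not in ("spinner", "jumper", "mover")
                },
                spinner=SpinnerParams(**_tupled(sim.get("spinner", {}))),
                jumper=JumperParams(**sim.get("jumper", {})),
                mover=MoverParams(**sim.get("mover", {})),
            )
        model = d.pop("model", {})
        if isinstance(model, dict):
            if "hidden_sizes" in model:
                model["hidden_sizes"] = tuple(model["hidden_sizes"])
            model = ModelConfig(**model)
        return cls(sim=sim, model=model, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _tupled(d: dict) -> dict:
    d = dict(d)
    if "center" in d:
        d["center"] = tuple(d["center"])
    return d


# -- figures ----------------------------------------------------------------


def plot_trajectories(tracks: TrackSet, mode: str, out_path) -> str:
    """Plot all trajectories of a TrackSet.

    Modes: ``2d`` overlays x-y paths colored by class; ``3d_xyt``
    renders each track as a curve in (x, y, t) space; ``time_gradient``
    shades each path from light (start) to dark (end), marking the
    start with an orange and the end with a red dot.
    """
    if len(tracks) == 0:
        raise ValueError("cannot plot an empty TrackSet")
    if mode not in ("2d", "3d_xyt", "time_gradient"):
        raise ValueError(f"unknown plot mode {mode!r}")

    if mode == "3d_xyt":
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        for traj in tracks:
            xy = traj.xy
            color = _CLASS_COLORS.get(traj.label.value if traj.label else "", None)
            ax.plot(xy[:, 0], xy[:, 1], traj.times, lw=0.8, color=color)
        ax.set_xlabel(f"x [{tracks.units}]")
        ax.set_ylabel(f"y [{tracks.units}]")
        ax.set_zlabel("t [min]")
    else:
        fig, ax = plt.subplots(figsize=(6, 5))
        for traj in tracks:
            xy = traj.xy
            if mode == "2d":
                color = _CLASS_COLORS.get(
                    traj.label.value if traj.label else "", None
                )
                ax.plot(xy[:, 0], xy[:, 1], lw=0.8, color=color)
            else:  # time_gradient
                n = len(xy)
                base = _CLASS_COLORS.get(
                    traj.label.value if traj.label else "", "tab:gray"
                )
                rgba = np.array(matplotlib.colors.to_rgba(base))
                for i in range(n - 1):
                    shade = 0.15 + 0.85 * i / max(n - 2, 1)  # light -> dark
                    seg_color = rgba.copy()
                    seg_color[:3] = 1 - shade * (1 - seg_color[:3])
                    ax.plot(xy[i : i + 2, 0], xy[i : i + 2, 1], color=seg_color)
                ax.plot(*xy[0], "o", color="orange", zorder=3)
                ax.plot(*xy[-1], "o", color="red", zorder=3)
        ax.set_xlabel(f"x [{tracks.units}]")
        ax.set_ylabel(f"y [{tracks.units}]")
        ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return str(out_path)


def plot_metric_boxplots(metrics: pd.DataFrame, out_path) -> str:
    """Three box-plot panels (hull perimeter, hull area, max pairwise
    distance), one box per class, from a :func:`summarize_metrics` table."""
    panels = ("hull_perimeter", "hull_area", "max_pairwise_distance")
    missing = [c for c in panels + ("label",) if c not in metrics.columns]
    if missing:
        raise track_io.TrackFormatError(f"missing metric columns: {missing}")
    classes = [c.value for c in
               (ClassLabel.M0, ClassLabel.M1, ClassLabel.M2)
               if c.value in set(metrics["label"].dropna())]
    fig, axes = plt.subplots(1, 3, figsize=(11, 4))
    for ax, col in zip(axes, panels):
        data = [metrics.loc[metrics["label"] == c, col] for c in classes]
        ax.boxplot(data, tick_labels=classes)
        ax.set_title(col.replace("_", " "))
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return str(out_path)


def plot_training_report(
    result: TrainResult, cm: ConfusionMatrix, out_dir
) -> tuple[str, str]:
    """Training-curve panel and annotated confusion-matrix heatmap."""
    lengths = {len(result.loss), len(result.accuracy),
               len(result.val_loss), len(result.val_accuracy)}
    if len(lengths) != 1:
        raise ValueError(f"history length mismatch: {sorted(lengths)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    epochs = np.arange(1, len(result.loss) + 1)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(epochs, result.loss, label="training loss")
    ax1.plot(epochs, result.val_loss, label="validation loss")
    ax1.set_xlabel("epoch"); ax1.set_ylabel("cross-entropy"); ax1.legend()
    ax2.plot(epochs, result.accuracy, label="training accuracy")
    ax2.plot(epochs, result.val_accuracy, label="validation accuracy")
    ax2.set_xlabel("epoch"); ax2.set_ylabel("accuracy"); ax2.legend()
    fig.tight_layout()
    curves_path = out_dir / "training_curves.png"
    fig.savefig(curves_path, dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    pct = cm.percent
    ax.imshow(pct, cmap="Blues", vmin=0, vmax=100)
    ax.set_xticks(range(3), cm.col_labels)
    ax.set_yticks(range(3), cm.row_labels)
    for i in range(3):
        for j in range(3):
            ax.text(j, i, f"{pct[i, j]:.0f}%", ha="center", va="center",
                    color="white" if pct[i, j] > 50 else "black")
    ax.set_xlabel("predicted"); ax.set_ylabel("true")
    fig.tight_layout()
    cm_path = out_dir / "confusion_matrix.png"
    fig.savefig(cm_path, dpi=150)
    plt.close(fig)
    return str(curves_path), str(cm_path)


# -- pipeline ---------------------------------------------------------------


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("macrotraj")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and return the run directory.

    Writes: tracks.csv, metrics.csv, augmented_tracks.csv,
    features.csv, split_manifest.csv, history.csv,
    confusion_counts.csv, confusion_percent.csv, model.npz, four
    figures, run.log and the resolved config.yaml.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out)
    try:
        if config.tracks_path:
            tracks = track_io.read_tracks(
                config.tracks_path,
                frame_interval=config.sim.frame_interval,
                n_frames=config.sim.n_frames,
            )
            logger.info("read %d tracks from %s", len(tracks), config.tracks_path)
        else:
            tracks = motility_sim.generate_labeled_dataset(config.sim)
            logger.info(
                "simulated %d tracks (%d per class, seed %d)",
                len(tracks), config.sim.n_per_class, config.sim.seed,
            )
        track_io.write_tracks(tracks, out / "tracks.csv")

        complete = track_io.filter_complete_tracks(tracks)
        logger.info("complete-track filter: %d of %d retained",
                    len(complete), len(tracks))

        metrics = traj_metrics.summarize_metrics(complete)
        metrics.to_csv(out / "metrics.csv", index=False)

        augmented = augmentation.augment_trackset(
            complete, include_identity=config.include_identity
        )
        logger.info("augmentation: %d -> %d records", len(complete), len(augmented))
        track_io.write_tracks(augmented, out / "augmented_tracks.csv")

        records = dataset_builder.build_dataset(
            augmented,
            center_on_start=config.center_on_start,
            standardize=config.standardize,
            require_labels=True,
        )
        _write_features(records, out / "features.csv")

        split = dataset_builder.shuffle_split(
            records,
            train_fraction=config.train_fraction,
            seed=config.split_seed,
            group_by_origin=config.group_by_origin,
        )
        logger.info("split: %d train / %d validation (seed %d)",
                    len(split.train), len(split.validation), split.seed)
        manifest = pd.DataFrame(
            [(r.cell_id, part)
             for part, rows in (("train", split.train),
                                ("validation", split.validation))
             for r in rows],
            columns=["cell_id", "partition"],
        )
        manifest.to_csv(out / "split_manifest.csv", index=False)

        model = classifier.build_model(config.model, len(records[0].features))
        result = classifier.train(model, split.train, split.validation)
        cm, accuracy = classifier.evaluate(model, split.validation)
        logger.info("validation accuracy %.3f; per-class %s",
                    accuracy, np.round(cm.per_class_accuracy, 3).tolist())

        pd.DataFrame({
            "epoch": np.arange(1, len(result.loss) + 1),
            "loss": result.loss,
            "accuracy": result.accuracy,
            "val_loss": result.val_loss,
            "val_accuracy": result.val_accuracy,
        }).to_csv(out / "history.csv", index=False)
        pd.DataFrame(cm.counts, index=cm.row_labels, columns=cm.col_labels
                     ).to_csv(out / "confusion_counts.csv")
        pd.DataFrame(cm.percent, index=cm.row_labels, columns=cm.col_labels
                     ).to_csv(out / "confusion_percent.csv")
        model.save(out / "model.npz")

        plot_trajectories(complete, "2d", out / "trajectories_2d.png")
        plot_trajectories(complete, "time_gradient",
                          out / "trajectories_time_gradient.png")
        plot_metric_boxplots(metrics, out / "metric_boxplots.png")
        plot_training_report(result, cm, out)

        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "n_tracks": len(tracks),
                    "n_complete": len(complete),
                    "n_augmented": len(augmented),
                    "n_train": len(split.train),
                    "n_validation": len(split.validation),
                    "overall_accuracy": accuracy,
                    "per_class_accuracy": cm.per_class_accuracy.tolist(),
                },
                fh,
                indent=2,
            )
    finally:
        logging.getLogger("macrotraj").removeHandler(handler)
        handler.close()
    return out


def _write_features(records, path) -> None:
    n_feat = len(records[0].features)
    df = pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                **{f"f_{i}": v for i, v in enumerate(r.features)},
                "label": r.label.value if r.label else "",
            }
            for r in records
        ],
        columns=["cell_id"] + [f"f_{i}" for i in range(n_feat)] + ["label"],
    )
    df.to_csv(path, index=False, float_format="%.17g")
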