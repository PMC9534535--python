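"""Experiment orchestration: stimuli -> simulation -> analysis -> report.

An experiment is described by an ExperimentConfig (dataset choice, trial
counts, network and neuron parameters, master seed).  ``run_experiment``
generates or loads the stimuli, presents every image once to a freshly
wired untrained network, writes the tuning-curve analysis artifacts
(CSV/JSON) and optional figures, and returns a report listing every output
file with run metadata.  Identical (config, seed) pairs reproduce
byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .analysis import (
    SCALES,
    average_normalized_curves,
    compute_tuning_curves,
    fit_all_scales,
    preference_distribution,
    summarize,
    write_outputs,
)
from .errors import ConfigError
from .network import LIFParams, NetworkConfig, TrialResult, simulate_dataset
from .stimuli import (
    StimulusDataset,
    StimulusImage,
    export_dataset,
    generate_digit_dataset,
    generate_numerosity_dataset,
    read_idx_images,
    subsample_per_class,
)

logger = logging.getLogger(__name__)

DATASETS = ("numerosity", "mnist", "digit-fixture")


@dataclass(frozen=True)
class ExperimentConfig:
    dataset: str = "numerosity"
    images_per_class: int = 30
    master_seed: int = 0
    output_dir: str = "results"
    emit_figures: bool = False
    repeats: int = 1
    chunk_size: int = 25
    mnist_images_path: str | None = None
    mnist_labels_path: str | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        problems = []
        if self.dataset not in DATASETS:
            problems.append(f"dataset must be one of {DATASETS}, got {self.dataset!r}")
        if self.images_per_class < 1:
            problems.append("images_per_class must be >= 1")
        if self.repeats < 1:
            problems.append("repeats must be >= 1")
        if self.chunk_size < 1:
            problems.append("chunk_size must be >= 1")
        if self.dataset == "mnist" and not (
            self.mnist_images_path and self.mnist_labels_path
        ):
            problems.append(
                "dataset 'mnist' needs mnist_images_path and mnist_labels_path "
                "(IDX files, e.g. train-images-idx3-ubyte / train-labels-idx1-ubyte)"
            )
        if problems:
            raise ConfigError(problems)

    @property
    def log2_shift(self) -> float:
        """Digit classes include 0; shift by 1 before log2."""
        return 0.0 if self.dataset == "numerosity" else 1.0

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        payload.pop("emit_figures")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class ExperimentReport:
    """Paths of every artifact a run produced, plus run metadata."""

    paths: dict[str, str]
    seed: int
    config_hash: str
    started: str
    finished: str
    version: str
    summary: dict


# ---------------------------------------------------------------------------
# Config validation

_TOP_KEYS = {
    "dataset",
    "images_per_class",
    "master_seed",
    "output_dir",
    "emit_figures",
    "repeats",
    "chunk_size",
    "mnist_images_path",
    "mnist_labels_path",
    "network",
    "lif",
}
_NETWORK_KEYS = {f.name for f in dataclasses.fields(NetworkConfig)} - {"lif"}
_LIF_KEYS = {f.name for f in dataclasses.fields(LIFParams)}


def _unknown_key_message(key: str, known: set[str], where: str) -> str:
    close = difflib.get_close_matches(key, sorted(known), n=1)
    hint = f"; did you mean {close[0]!r}?" if close else ""
    return f"unknown {where} key {key!r}{hint}"


def validate_config(raw: str | dict | Path | None) -> ExperimentConfig:
    """Parse and validate a YAML/dict configuration, reporting all violations at once.

    An empty config yields the full default experiment (Table-style LIF
    constants, N(0.5, 0.1) feedforward weights, alpha 10/20, 2 s at 1 ms).
    """
    if raw is None:
        data: dict = {}
    elif isinstance(raw, dict):
        data = dict(raw)
    else:
        text = Path(raw).read_text() if isinstance(raw, Path) else raw
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError([f"config root must be a mapping, got {type(data).__name__}"])

    problems: list[str] = []
    for key in data:
        if key not in _TOP_KEYS:
            problems.append(_unknown_key_message(key, _TOP_KEYS, "top-level"))
    net_data = data.get("network") or {}
    lif_data = data.get("lif") or {}
    for key in net_data:
        if key not in _NETWORK_KEYS:
            problems.append(_unknown_key_message(key, _NETWORK_KEYS, "network"))
    for key in lif_data:
        if key not in _LIF_KEYS:
            problems.append(_unknown_key_message(key, _LIF_KEYS, "lif"))
    if problems:
        raise ConfigError(problems)

    try:
        lif = LIFParams(**lif_data)
        if "grid_shape" in net_data:
            net_data = {**net_data, "grid_shape": tuple(net_data["grid_shape"])}
        network = NetworkConfig(**{k: v for k, v in net_data.items()}, lif=lif)
        top = {k: v for k, v in data.items() if k not in ("network", "lif")}
        return ExperimentConfig(**top, network=network)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError([str(exc)]) from exc


# ---------------------------------------------------------------------------
# Stages


def load_stimuli(config: ExperimentConfig) -> list[StimulusImage]:
    """Generate or read the stimulus set named by the configuration."""
    if config.dataset == "numerosity":
        return list(
            generate_numerosity_dataset(config.images_per_class, config.master_seed).images
        )
    if config.dataset == "digit-fixture":
        return list(
            generate_digit_dataset(config.images_per_class, config.master_seed).images
        )
    for path in (config.mnist_images_path, config.mnist_labels_path):
        if not Path(path).exists():
            raise FileNotFoundError(
                f"MNIST IDX file not found: {path} (expected files like "
                "train-images-idx3-ubyte and train-labels-idx1-ubyte)"
            )
    images = read_idx_images(config.mnist_images_path, config.mnist_labels_path)
    return subsample_per_class(images, config.images_per_class, config.master_seed)


def analyze_trials(trials: Sequence[TrialResult], log2_shift: float = 0.0):
    """Run the full tuning-curve analysis; returns (curves, averages, fits, distribution)."""
    curves = compute_tuning_curves(trials)
    distribution = preference_distribution(curves)
    averages = average_normalized_curves(curves)
    fits = fit_all_scales(averages, log2_shift=log2_shift)
    return curves, averages, fits, distribution


def run_experiment(config: ExperimentConfig, progress: bool = False) -> ExperimentReport:
    """Execute one full experiment and write all artifacts under output_dir.

    With ``repeats > 1`` the experiment is repeated under master seeds
    spawned from ``master_seed``, each in its own subdirectory, and the
    top-level summary aggregates the per-run summaries (for variance
    estimation across seeds); artifacts of run 0 are listed in the report.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    if config.repeats > 1:
        seeds = [
            int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(config.master_seed).spawn(config.repeats)
        ]
    else:
        seeds = [config.master_seed]

    summaries = []
    first_paths: dict[str, Path] = {}
    for run_idx, seed in enumerate(seeds):
        run_dir = out_root if config.repeats == 1 else out_root / f"run_{run_idx}"
        run_cfg = dataclasses.replace(
            config, master_seed=seed, output_dir=str(run_dir), repeats=1
        )
        logger.info("run %d/%d: dataset=%s seed=%d", run_idx + 1, len(seeds),
                    config.dataset, seed)
        t0 = time.monotonic()
        images = load_stimuli(run_cfg)
        logger.info("stimuli: %d images in %.1fs", len(images), time.monotonic() - t0)
        t0 = time.monotonic()
        trials = simulate_dataset(
            images,
            run_cfg.network,
            seed=run_cfg.master_seed,
            chunk_size=run_cfg.chunk_size,
            progress=progress,
        )
        logger.info("simulation: %d trials in %.1fs", len(trials), time.monotonic() - t0)
        curves, averages, fits, distribution = analyze_trials(
            trials, log2_shift=run_cfg.log2_shift
        )
        paths = write_outputs(run_dir, trials, curves, averages, fits, distribution)
        if config.emit_figures:
            paths.update(render_figures(run_dir))
        summaries.append(summarize(curves, fits, distribution))
        if run_idx == 0:
            first_paths = paths

    summary = summaries[0] if len(summaries) == 1 else _aggregate(summaries)
    finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    report = ExperimentReport(
        paths={k: str(v) for k, v in first_paths.items()},
        seed=config.master_seed,
        config_hash=config.config_hash(),
        started=started,
        finished=finished,
        version=__version__,
        summary=summary,
    )
    (out_root / "report.json").write_text(
        json.dumps(dataclasses.asdict(report), indent=2)
    )
    return report


def _aggregate(summaries: list[dict]) -> dict:
    """Mean over per-seed summaries of the scalar summary statistics."""
    scales = summaries[0]["mean_r2_per_scale"].keys()
    classes = summaries[0]["preference_percent_selective"].keys()
    return {
        "n_runs": len(summaries),
        "mean_r2_per_scale": {
            s: float(np.mean([m["mean_r2_per_scale"][s] for m in summaries]))
            for s in scales
        },
        "preference_percent_selective": {
            c: float(
                np.mean([m["preference_percent_selective"][c] for m in summaries])
            )
            for c in classes
        },
        "n_selective_mean": float(np.mean([m["n_selective"] for m in summaries])),
        "per_run": summaries,
    }


def render_figures(run_dir: str | Path) -> dict[str, Path]:
    """Render the standard figures from a run directory's CSVs (not from memory).

    Produces average tuning curves on linear and log2 axes, the preference
    histogram, the mean-r^2 bar chart and the sigma-vs-preference scatter.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    run_dir = Path(run_dir)
    fig_dir = run_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    averages = pd.read_csv(run_dir / "average_tuning_curves.csv")
    shift = 1.0 if averages["class"].min() == 0 else 0.0
    for scale in ("linear", "log2"):
        fig, ax = plt.subplots(figsize=(5, 4))
        for pref, grp in averages.groupby("preferred_class"):
            x = grp["class"].to_numpy(dtype=float)
            if scale == "log2":
                x = np.log2(x + shift)
            ax.plot(x, grp["normalized_response"], marker="o", label=f"prefers {pref}")
        ax.set_xlabel("class" if scale == "linear" else "log2(class)")
        ax.set_ylabel("normalized mean response")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = fig_dir / f"average_tuning_curves_{scale}.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths[f"figure_curves_{scale}"] = p

    prefs = pd.read_csv(run_dir / "preferences.csv")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(prefs["class"], prefs["percent"])
    ax.set_xlabel("preferred class")
    ax.set_ylabel("% of selective units")
    fig.tight_layout()
    paths["figure_preferences"] = fig_dir / "preference_distribution.png"
    fig.savefig(paths["figure_preferences"], dpi=150)
    plt.close(fig)

    fits = pd.read_csv(run_dir / "fits.csv")
    fits = fits[fits["converged"]]
    fig, ax = plt.subplots(figsize=(5, 4))
    means = fits.groupby("scale")["r2"].mean().reindex(list(SCALES))
    ax.bar(means.index, 100.0 * means.to_numpy())
    ax.set_ylabel("mean r^2 (%)")
    fig.tight_layout()
    paths["figure_r2"] = fig_dir / "mean_r2_per_scale.png"
    fig.savefig(paths["figure_r2"], dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for scale, grp in fits.groupby("scale"):
        ax.scatter(grp["preferred_class"], grp["sigma"], label=scale)
    ax.set_xlabel("preferred class")
    ax.set_ylabel("fitted sigma")
    ax.legend(fontsize=8)
    fig.tight_layout()
    paths["figure_sigma"] = fig_dir / "sigma_vs_preference.png"
    fig.savefig(paths["figure_sigma"], dpi=150)
    plt.close(fig)
    return paths
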