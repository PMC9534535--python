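"""Bernoulli rate coding: image -> spike raster.

Each pixel drives one input channel.  At every millisecond step the channel
emits a spike with probability p = gain * pixel_value (gain 0.2 by default),
independently across steps and channels, for the full 2 s stimulus window.
A zero pixel is therefore silent and a saturated pixel fires at 0.2 spikes
per ms in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidProbabilityError
from .stimuli import StimulusImage


@dataclass(frozen=True)
class SpikeTrain:
    """A binary time x units raster with its timing metadata."""

    raster: np.ndarray  # (timesteps, units), uint8 in {0,1}
    dt: float  # ms
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2-D (timesteps x units)")
        if abs(self.raster.shape[0] * self.dt - self.duration) > 1e-9:
            raise ValueError("timesteps * dt must equal duration")

    @property
    def n_steps(self) -> int:
        return self.raster.shape[0]

    @property
    def n_units(self) -> int:
        return self.raster.shape[1]

    def spike_counts(self) -> np.ndarray:
        return self.raster.sum(axis=0, dtype=np.int64)


def encode_bernoulli(
    image: StimulusImage,
    duration: float = 2000.0,
    dt: float = 1.0,
    gain: float = 0.2,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> SpikeTrain:
    """Encode an image as independent Bernoulli spike trains.

    Per timestep of length ``dt`` ms, unit *u* spikes with probability
    ``gain * pixels[u]``; draws are independent across steps and units and
    deterministic given ``seed``.

    Raises
    ------
    InvalidProbabilityError
        If ``gain`` times the maximum intensity exceeds 1.
    ValueError
        If ``duration`` is not an integer multiple of ``dt``.
    """
    steps = duration / dt
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(f"duration {duration} is not divisible by dt {dt}")
    n_steps = int(round(steps))
    p = gain * image.pixels.ravel()
    if p.max() > 1.0:
        raise InvalidProbabilityError(
            f"gain {gain} x max intensity {image.pixels.max()} exceeds probability 1"
        )
    rng = np.random.default_rng(seed)
    raster = np.zeros((n_steps, p.size), dtype=np.uint8)
    active = np.flatnonzero(p > 0)
    if active.size:
        raster[:, active] = rng.random((n_steps, active.size)) < p[active]
    return SpikeTrain(raster=raster, dt=dt, duration=duration)


def save_spike_train(train: SpikeTrain, path: str | Path, source_id: str = "") -> None:
    """Save a raster as a compressed .npz plus a JSON sidecar (dt, duration, source)."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), raster=train.raster)
    sidecar = {"dt": train.dt, "duration": train.duration, "source_id": source_id}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_spike_train(path: str | Path) -> SpikeTrain:
    path = Path(path)
    raster = np.load(path.with_suffix(".npz"))["raster"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return SpikeTrain(raster=raster, dt=meta["dt"], duration=meta["duration"])
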