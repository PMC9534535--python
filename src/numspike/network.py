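"""Untrained two-layer current-based LIF network with lateral inhibition.

The model is a 28x28 input layer and a 28x28 output layer of current-based
leaky integrate-and-fire neurons.  Encoder spikes inject current into the
input layer; input spikes propagate forward through a dense feedforward
matrix whose weights are drawn fresh for every image from N(0.5, 0.1)
(mean, variance) and are never adjusted — the network is untrained by
construction.  Within each layer, every pair of distinct neurons is coupled
by a negative (inhibitory) weight that decays with the Euclidean distance
between their grid positions:

    w(R) = -exp(-R^2 / (2 alpha^2))        (``corrected`` form, default)
    w(R) = -exp(-R^2 * alpha^2)            (``literal`` form)

where ``alpha`` is the standard deviation of the Gaussian kernel (10 for
the input layer, 20 for the output layer).  The ``literal`` product form
is kept selectable for comparison, but it inverts the role of alpha
(larger alpha would then *shrink* the inhibition range), so the Gaussian
form is the default.

Integration is Euler at dt = 1 ms with exact exponential decay factors for
the linear voltage and current dynamics.  Threshold crossings are detected
at the start of each step, so a neuron driven above threshold during step t
emits its spike at step t+1; lateral and feedforward spike propagation both
carry a one-timestep synaptic delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .encoding import SpikeTrain, encode_bernoulli
from .errors import ConfigError
from .stimuli import StimulusImage

LateralForm = Literal["corrected", "literal"]


@dataclass(frozen=True)
class LIFParams:
    """Current-based LIF neuron constants (voltages in mV, times in ms)."""

    thresh: float = -52.0
    rest: float = -65.0
    reset: float = -65.0
    refrac: float = 5.0
    tc_decay: float = 100.0
    tc_i_decay: float = 2.0

    def __post_init__(self) -> None:
        problems = []
        if not self.thresh > self.rest:
            problems.append("thresh must exceed rest")
        if not self.reset <= self.thresh:
            problems.append("reset must not exceed thresh")
        if self.refrac < 0:
            problems.append("refrac must be >= 0")
        if self.tc_decay <= 0 or self.tc_i_decay <= 0:
            problems.append("time constants must be positive")
        if problems:
            raise ConfigError(problems)


@dataclass(frozen=True)
class NetworkConfig:
    """Layer geometry, weight statistics, inhibition widths and timing."""

    grid_shape: tuple[int, int] = (28, 28)
    ff_weight_mean: float = 0.5
    ff_weight_variance: float = 0.1
    alpha_input: float = 10.0
    alpha_output: float = 20.0
    lateral_form: LateralForm = "corrected"
    input_injection_amplitude: float = 1.0
    encoder_gain: float = 0.2
    dt: float = 1.0
    duration: float = 2000.0
    lif: LIFParams = field(default_factory=LIFParams)

    def __post_init__(self) -> None:
        problems = []
        if self.alpha_input <= 0 or self.alpha_output <= 0:
            problems.append("alpha_input and alpha_output must be positive")
        if self.ff_weight_variance <= 0:
            problems.append("ff_weight_variance must be positive")
        if self.lateral_form not in ("corrected", "literal"):
            problems.append(f"unknown lateral_form {self.lateral_form!r}")
        if self.dt <= 0 or self.duration <= 0:
            problems.append("dt and duration must be positive")
        if not (0 < self.encoder_gain <= 1):
            problems.append("encoder_gain must lie in (0, 1]")
        if problems:
            raise ConfigError(problems)

    @property
    def n_units(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass(frozen=True)
class LateralKernel:
    """Within-layer inhibitory weights on a 2-D neuron grid."""

    weights: np.ndarray  # (units, units), symmetric, non-positive, zero diagonal
    alpha: float
    form: LateralForm


@dataclass
class LIFState:
    """Mutable per-unit simulation state (supports an optional batch axis)."""

    v: np.ndarray
    i: np.ndarray
    refrac_count: np.ndarray

    @classmethod
    def resting(
        cls, shape: int | tuple[int, ...], params: LIFParams, dtype=np.float64
    ) -> "LIFState":
        shp = (shape,) if isinstance(shape, int) else shape
        return cls(
            v=np.full(shp, params.rest, dtype=dtype),
            i=np.zeros(shp, dtype=dtype),
            refrac_count=np.zeros(shp, dtype=dtype),
        )


def build_lateral_weights(
    grid_shape: tuple[int, int] = (28, 28),
    alpha: float = 10.0,
    form: LateralForm = "corrected",
) -> LateralKernel:
    """Build the distance-dependent inhibition kernel for one layer.

    Self-connections are excluded (zero diagonal); all off-diagonal entries
    are negative and their magnitude is non-increasing in distance for the
    corrected form.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if form not in ("corrected", "literal"):
        raise ValueError(f"unknown lateral form {form!r}")
    rows, cols = np.divmod(np.arange(int(np.prod(grid_shape))), grid_shape[1])
    coords = np.column_stack([rows, cols]).astype(np.float64)
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    if form == "corrected":
        weights = -np.exp(-r2 / (2.0 * alpha**2))
    else:
        weights = -np.exp(-r2 * alpha**2)
    np.fill_diagonal(weights, 0.0)
    return LateralKernel(weights=weights, alpha=alpha, form=form)


def build_feedforward_weights(
    seed: int | np.random.SeedSequence | np.random.Generator,
    shape: tuple[int, int] = (784, 784),
    mean: float = 0.5,
    variance: float = 0.1,
) -> np.ndarray:
    """Draw a fresh dense feedforward matrix, entries i.i.d. N(mean, variance).

    ``W[x, y]`` is the weight from input unit x to output unit y.  No
    clipping is applied; deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    return rng.normal(mean, np.sqrt(variance), size=shape)


def lif_step(
    state: LIFState,
    external_current: np.ndarray,
    params: LIFParams,
    dt: float = 1.0,
) -> tuple[LIFState, np.ndarray]:
    """Advance current-based LIF units by one timestep (state updated in place).

    Order of operations per step:

    1. units at or above threshold emit a spike, reset to ``reset`` and
       enter the refractory period;
    2. synaptic current decays by exp(-dt/tc_i_decay) and receives the
       external current;
    3. non-refractory units decay toward rest by exp(-dt/tc_decay) and then
       integrate ``i * dt``; refractory units hold ``reset`` and ignore
       input;
    4. refractory counters decrement by dt (floored at 0).

    Returns the state and the binary spike vector.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    spikes = state.v >= params.thresh
    state.v[spikes] = params.reset
    state.refrac_count[spikes] = params.refrac

    state.i *= np.exp(-dt / params.tc_i_decay)
    state.i += external_current

    active = state.refrac_count <= 0
    dv = np.exp(-dt / params.tc_decay)
    state.v[active] = (
        params.rest + (state.v[active] - params.rest) * dv + state.i[active] * dt
    )
    np.maximum(state.refrac_count - dt, 0.0, out=state.refrac_count)
    return state, spikes.astype(external_current.dtype, copy=False)


@dataclass(frozen=True)
class TrialResult:
    """Per-output-unit spike counts and rates for one image presentation."""

    spike_counts: np.ndarray  # (units,), int
    rates: np.ndarray  # Hz
    image_label: int
    kind: str
    seed: int


def _feedforward_current(spikes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Batched s_b^T W_b with a sparse fast path (input spiking is sparse)."""
    batch, n = spikes.shape
    nnz = int(np.count_nonzero(spikes))
    if nnz == 0:
        return np.zeros((batch, n), dtype=weights.dtype)
    if nnz * n * 4 < batch * n * n:
        out = np.zeros((batch, n), dtype=weights.dtype)
        for b in range(batch):
            idx = np.flatnonzero(spikes[b])
            if idx.size:
                out[b] = weights[b, idx].sum(axis=0)
        return out
    return np.matmul(spikes[:, None, :], weights)[:, 0, :]


def _run_dynamics(
    rasters: np.ndarray,  # (batch, steps, units) uint8 encoder spikes
    ff_weights: np.ndarray,  # (batch, units, units)
    k_in: np.ndarray,
    k_out: np.ndarray,
    config: NetworkConfig,
) -> np.ndarray:
    """Simulate a batch of trials; returns (batch, units) output spike counts."""
    batch, steps, n = rasters.shape
    if ff_weights.shape != (batch, n, n) or k_in.shape != (n, n) or k_out.shape != (n, n):
        raise ConfigError(
            [
                f"shape mismatch: rasters {rasters.shape}, feedforward "
                f"{ff_weights.shape}, lateral {k_in.shape}/{k_out.shape}"
            ]
        )
    params = config.lif
    dt = config.dt
    amp = config.input_injection_amplitude
    st_in = LIFState.resting((batch, n), params, dtype=np.float32)
    st_out = LIFState.resting((batch, n), params, dtype=np.float32)
    s_in_prev = np.zeros((batch, n), dtype=np.float32)
    s_out_prev = np.zeros((batch, n), dtype=np.float32)
    counts = np.zeros((batch, n), dtype=np.int64)
    for t in range(steps):
        ext_in = amp * rasters[:, t].astype(np.float32)
        if s_in_prev.any():
            ext_in += s_in_prev @ k_in
        _, s_in = lif_step(st_in, ext_in, params, dt)
        ext_out = _feedforward_current(s_in_prev, ff_weights)
        if s_out_prev.any():
            ext_out += s_out_prev @ k_out
        _, s_out = lif_step(st_out, ext_out, params, dt)
        counts += s_out.astype(np.int64)
        s_in_prev, s_out_prev = s_in, s_out
    return counts


def simulate_trial(
    image: StimulusImage,
    config: NetworkConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    kernels: tuple[LateralKernel, LateralKernel] | None = None,
) -> TrialResult:
    """Present one image to a freshly wired network and record output activity.

    The trial seed is split into one substream for the Bernoulli encoder and
    one for the feedforward weight draw, so results are identical whether a
    trial runs alone or inside a batched dataset sweep.
    """
    config = config or NetworkConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    entropy = int(ss.entropy) if isinstance(ss.entropy, (int, np.integer)) else 0
    enc_ss, w_ss = ss.spawn(2)
    train = encode_bernoulli(
        image, config.duration, config.dt, config.encoder_gain, seed=enc_ss
    )
    weights = build_feedforward_weights(
        w_ss,
        (config.n_units, config.n_units),
        config.ff_weight_mean,
        config.ff_weight_variance,
    ).astype(np.float32)
    if kernels is None:
        kernels = default_kernels(config)
    k_in = kernels[0].weights.astype(np.float32)
    k_out = kernels[1].weights.astype(np.float32)
    counts = _run_dynamics(train.raster[None], weights[None], k_in, k_out, config)[0]
    return TrialResult(
        spike_counts=counts,
        rates=counts / (config.duration / 1000.0),
        image_label=image.label,
        kind=image.kind,
        seed=entropy,
    )


def default_kernels(config: NetworkConfig) -> tuple[LateralKernel, LateralKernel]:
    """The input- and output-layer inhibition kernels for a configuration."""
    return (
        build_lateral_weights(config.grid_shape, config.alpha_input, config.lateral_form),
        build_lateral_weights(config.grid_shape, config.alpha_output, config.lateral_form),
    )


def simulate_dataset(
    images: Sequence[StimulusImage],
    config: NetworkConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    chunk_size: int = 25,
    progress: bool = False,
) -> list[TrialResult]:
    """Present every image once, each with a fresh feedforward weight draw.

    Per-trial random streams are spawned from the master seed by trial
    index; trials are simulated in chunks to bound memory while keeping the
    inner updates batched.
    """
    config = config or NetworkConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    entropy = int(ss.entropy) if isinstance(ss.entropy, (int, np.integer)) else 0
    trial_seeds = ss.spawn(len(images))
    kernels = default_kernels(config)
    k_in = kernels[0].weights.astype(np.float32)
    k_out = kernels[1].weights.astype(np.float32)
    n = config.n_units
    results: list[TrialResult] = []
    indices = range(0, len(images), chunk_size)
    if progress:
        from tqdm import tqdm

        indices = tqdm(indices, desc="simulating", unit="chunk")
    for start in indices:
        block = list(range(start, min(start + chunk_size, len(images))))
        rasters = np.zeros((len(block), int(config.duration / config.dt), n), np.uint8)
        weights = np.zeros((len(block), n, n), dtype=np.float32)
        for j, idx in enumerate(block):
            enc_ss, w_ss = trial_seeds[idx].spawn(2)
            rasters[j] = encode_bernoulli(
                images[idx], config.duration, config.dt, config.encoder_gain, seed=enc_ss
            ).raster
            weights[j] = build_feedforward_weights(
                w_ss, (n, n), config.ff_weight_mean, config.ff_weight_variance
            )
        counts = _run_dynamics(rasters, weights, k_in, k_out, config)
        for j, idx in enumerate(block):
            results.append(
                TrialResult(
                    spike_counts=counts[j],
                    rates=counts[j] / (config.duration / 1000.0),
                    image_label=images[idx].label,
                    kind=images[idx].kind,
                    seed=entropy,
                )
            )
    return results
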