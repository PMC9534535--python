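# Methods

## Model overview

The network is two 28×28 layers of current-based leaky integrate-and-fire
(LIF) neurons. The input layer stands for the early visual pathway (one
neuron per image pixel), the output layer for a downstream ventral-stream
stage. The model is untrained by construction: the dense input→output
weight matrix is drawn i.i.d. from N(μ = 0.5, σ² = 0.1) **freshly for every
image presentation** and never modified, so any systematic tuning in the
output layer is a property of the architecture (random excitatory
convergence plus lateral inhibition), not of learning. Statistics are
therefore computed across presentations: a unit's tuning curve averages
over 30 independent wirings per class.

### Neuron dynamics

Each neuron carries a membrane voltage `v`, a synaptic current `i`, and a
refractory counter. Per 1 ms step:

1. **Spike detection first.** Units with `v ≥ −52 mV` emit a spike, reset
   to `−65 mV`, and become refractory for 5 ms. Detecting threshold
   crossings at the start of the step (rather than after integration) makes
   a unit that crosses threshold during step *t* fire at step *t + 1*,
   giving every spike-mediated interaction a uniform one-step synaptic
   delay and making the contract "a unit at threshold fires regardless of
   input" hold exactly.
2. Current decays by `exp(−dt/2 ms)` and receives this step's external
   current (encoder injections, feedforward drive, lateral inhibition).
3. Non-refractory units decay toward rest by `exp(−dt/100 ms)` and then
   integrate `i·dt`. Refractory units hold the reset voltage and ignore
   input. The exponential factors are exact for the linear decay terms, so
   subthreshold relaxation matches the closed form to machine precision.
4. Refractory counters decrement by `dt`, floored at zero.

The voltage has no lower bound. In discrete time the refractory period
admits at most one spike per `refrac + dt = 6 ms`, i.e. at most
`floor((T−1)/6) + 1` spikes in `T` steps — one more than the continuous
`duration/(refrac+dt)` estimate, because a spike can occur in the first
step.

### Lateral inhibition

Within each layer all distinct pairs are coupled by a negative weight that
decays with the Euclidean grid distance `R`:

    w(R) = −exp(−R² / (2α²))     α = 10 (input layer), 20 (output layer)

`α` is the standard deviation of the Gaussian kernel: larger `α` widens the
inhibition range. A `literal` kernel variant `w = −exp(−R²·α²)` is also
selectable for comparison; it inverts the role of `α` (at `α = 10` it
zeroes all off-diagonal couplings), so the Gaussian form is the default. Self-connections are excluded:
`w(0) = −1` self-inhibition is not part of the model's description, and
refractoriness already limits self-firing. Lateral spikes act through the
same one-step-delayed current injection as all other drive; each layer
applies its inhibition as a single recurrent stage, not an iterated
relaxation.

### Encoder coupling

Each encoder spike injects `input_injection_amplitude` (default 1.0)
current units into its input-layer neuron. The coupling strength between
encoder and input layer is not constrained by the model's published
description; 1.0 places single-pixel drive (expected 0.2 spikes/ms) at a
steady-state depolarization of ≈ 40 mV — comfortably suprathreshold — while
keeping encoder and lateral currents on the same scale, so inhibition can
meaningfully compete with drive. It is configurable.

## Stimuli

**Numerosity images.** 1–5 items on a blank 28×28 field, 30 images per
numerosity. Each item is the centered-disk pixel set
`{(dx,dy): dx²+dy² ≤ 8.5}`, which contains exactly 25 pixels, at intensity
1.0 on a 0.0 background. Item centers are sampled uniformly with rejection:
≥ 3 px from the frame edge and ≥ 6 px apart (Euclidean), which provably
keeps the 25-pixel masks disjoint; placement aborts with an error after
10,000 rejected proposals rather than ever rendering fewer items. Per-image
RNG streams are spawned from the dataset seed by index, so datasets are
reproducible regardless of generation order.

**Digits.** MNIST is read from its IDX files (big-endian magic 0x803/0x801,
bytes scaled by 1/255) when available. For download-free operation the
package ships a synthetic fixture: seven-segment-style stroke glyphs with
seed-controlled translation (≤ 2 px) and stroke-thickness jitter, softened
by a Gaussian edge profile. The fixture emulates MNIST's *format*
(28×28 grayscale in [0,1], one centered glyph, 10 balanced classes) but not
its *content statistics*: handwriting curvature, stroke-width diversity,
and in particular the glyph-specific ink distributions that concentrate
MNIST preferences on particular digits. Results that depend only on the
symbolic/non-symbolic contrast (flat-ish preference spread, poor linear
Gaussian fits, absent distance effect) transfer; exact per-digit preference
percentages do not.

**Encoding.** Bernoulli rate coding: per 1 ms step a pixel's channel spikes
with probability `0.2 × pixel`, independently across steps and channels,
for 2 s. The encoder draws no refractoriness and exactly one RNG substream
per presentation.

## Analysis

- **Selectivity.** A unit is numerosity/number-selective iff it fired at
  least once and its per-class mean rate has a unique argmax. Ties are
  excluded rather than broken so the preference histogram is unbiased.
  Preference percentages use selective units as the denominator; the run
  summary also reports the all-units denominator.
- **Average curves.** Same-preference tuning curves are averaged unit-wise,
  then min–max normalized to [0, 1].
- **Gaussian fits.** `a·exp(−(t−μ)²/(2σ²))` is fitted by least squares
  (scipy `curve_fit`) to each average curve with the class axis transformed
  by x, √x, ∛x, or log₂x. For digit classes the log₂ axis uses
  `log₂(x+1)` so class 0 stays in-domain. Initialization: `a` at the curve
  maximum, `μ` at the transformed argmax, `σ` at half the transformed
  range, with a multi-start over smaller widths (one inter-class spacing
  and a quarter of it) for sharply peaked curves. Parameters are bounded —
  `a ∈ [0, 2]`, `μ` within ±2 abscissa spans, `σ ∈ [10⁻³, 10 spans]` —
  because curves peaked at the range edge are asymptotically half-Gaussians
  whose unbounded fit diverges along a correlated `a, μ, σ` ridge.
  Non-convergent fits are reported as failed, excluded from means, and
  counted in the summary. `r² = 1 − SS_res/SS_tot`.
- **Size/distance statistics.** The distance effect is quantified as the
  largest single-step increase of an average curve moving away from its
  peak; the size effect as the Spearman rank correlation between linear-
  scale `σ` and preferred class.

## Problem sizes and determinism

The standard experiment is 150 images × 2 s at 1 ms resolution; one run
takes roughly 20–45 s on a single CPU (trials are simulated in chunks of
25 with fully vectorized state updates and a sparse fast path for spike
propagation). Headline statistics average three independent master seeds.
The digit experiment uses 15 images per class (150 trials) for parity with
the numerosity run. All randomness flows from a single master seed through
`numpy` `SeedSequence` spawning (dataset → trial → encoder/weights), so a
trial simulates identically alone or inside a batch, and a full rerun with
the same config and seed reproduces every CSV byte-for-byte.

## Known limitations

- **Far-tail distance-effect violations.** Total output activity grows with
  numerosity (more foreground pixels → more feedforward drive), so the
  average curves of units preferring small numerosities rise slightly again
  at the largest class (≈ 0.05–0.08 normalized units at class 5 for the
  pref-2 curve). The distance effect holds to ≈ 0.05 normalized units
  elsewhere. A global activity-normalization stage (not part of this model)
  would remove the trend.
- **Log-symmetry is a low-preference phenomenon.** Log compression reduces
  the mass skewness of curves peaked at small numerosities (their long
  right tails shorten). Curves peaked at the top of the tested range are
  truncated ramps: log₂ compresses spacing near their peak and stretches
  their left flank, so their |skewness| necessarily grows under the
  transform. Symmetry comparisons are therefore meaningful only for
  preferences in the lower part of the range.
- **Per-seed fluctuation.** With 784 units and 30 presentations per class,
  preference percentages move by a few points between master seeds, and the
  mean-r² ordering across scales can locally invert by < 1 point within a
  single seed; seed-averaged statistics are stable.
- **Untrained by design.** No plasticity of any kind is modelled; spike
  traces, which LIF implementations carry only to serve learning rules,
  are deliberately not implemented.
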