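# Methods

## Model structure

The sensory layer is a bank of N = 12 orientation channels with raised-cosine
tuning `|cos(θ − φ_i)|^m`, m = 23, evenly covering [0, π). Contrast enters
linearly in the stimulus drive and the drive is raised to n = 1.5 before
temporal filtering, so contrast-response nonlinearity arises jointly from the
exponent and from divisive normalization. Three nested linear filters plus one
division produce the response:

1. excitatory window: one-pole low-pass of `d_i^n`, time constant τ_E;
2. suppressive window: one-pole low-pass of the pool-weighted sum of
   excitatory drives, time constant τ_S;
3. divisive stage: `g_i = e_i / (s_i + σ^n)`;
4. response dynamics: one-pole low-pass of `g_i`, time constant τ_R = 52 ms
   (forward Euler, Δt = 2 ms).

All stages are strictly causal one-pole recursions, so simulation is
vectorizable with `scipy.signal.lfilter` while remaining step-by-step
("online") in the mathematical sense: outputs at time t never depend on
inputs after t, and truncating a stimulus reproduces the prefix of the
trace bitwise.

Spatial variants label stimulus channels with locations ("center",
"surround"); each location gets its own copy of the tuning bank, excitation
is location-specific, and suppression is pooled across locations with
weight 1, which produces surround suppression.

## Discretizing the temporal windows

The continuous-time windows are `w(u) = (1/τ) exp(−u/τ)`. On a 2 ms grid the
raw per-step sum of these weights has a gain that depends on Δt and diverges
from the τ → 0 limit. The package therefore defaults to the gain-normalized
recursion

    y_t = α y_{t−1} + (1 − α) x_t,     α = exp(−Δt/τ)

whose sustained-input gain is exactly 1 for every τ, and which degenerates
continuously to the identity at τ = 0 (τ = 0 is defined as a unit impulse
window, avoiding the 1/τ singularity). This keeps σ = 0.1 on the intended
scale of the drives. Two observations support this choice: the
duration-doubling response ratios over the (τ_E, τ_S) grid fall in
[1.30, 1.60], matching the reported subadditivity band almost exactly, and
the reverse-correlation receptive-field time constants land within a few
percent of the reference values. The literal per-step `1/τ` sum remains
available via `SensoryParams(filter_mode="literal")`.

The normalization denominator is `s + σ^n`, with σ raised to the same
exponent as the stimulus drive. Two alternative readings, `(s + σ)^n` and
`(s^n + σ^n)`, were evaluated and rejected: both push the duration-doubling
ratios outside the subadditivity band (up to 1.85).

## Decision layer

Each of the two decision units reads out one target's axis through the
difference of the noiseless population templates for the clockwise- and
counterclockwise-tilted stimulus at unit contrast (tilt ±10° by default;
all suppression-index results are ratios and are insensitive to the exact
tilt). Within the decision layer the drives are instantaneous functions of
the sensory response — the long integration constant τ_D = 1e5 ms already
supplies the layer's memory — and the suppressive drive is the summed
magnitude of the two units' drives, which keeps the shared denominator
nonnegative for signed evidence. The semi-saturation enters as σ_D^n
(σ_D = 0.7) to mirror the sensory-layer denominator. d′ is the absolute
final evidence times a fixed scale (1e5 by default, 1e4 in the
contrast-interaction preset); no noise model is added because the readout
is deterministic — the sign of the evidence is the choice, the magnitude
the sensitivity.

On the discrete 12-channel grid the two axes' templates are not perfectly
orthogonal (cross-projection ≈ 1e-4), so with both temporal windows at zero
the non-target still modulates the target's evidence at the 1e-4 level.
"No suppression without temporal windows" therefore holds to ~1e-3 in the
suppression index rather than exactly.

## Stimulus protocols

Protocols are event lists rendered onto the Δt grid with half-open
intervals (onset inclusive, offset exclusive). The standard pulse is 30 ms
at 64% contrast. Experiment-specific defaults: 2,000 ms pulses in 8,100 ms
trials (500 ms prestimulus) for transient–sustained analyses; 300 ms pulses
for adaptation (ISI 100–1,500 ms); 100 ms simultaneous center–surround
pulses with σ = 0.02 and 20 log-spaced center contrasts in [0.05, 1];
orthogonal 30 ms pulses for masking; 64%/16% contrast pairs on orthogonal
axes at SOA 250 ms for the contrast-interaction analyses. Where a trial
length is not dictated by the protocol it is padded (3,000 ms after the
last offset by default) so responses decay to baseline before the trial
ends; summed-response metrics are then insensitive to the trial end. The
random binary protocol drives a single unit directly (bypassing orientation
tuning) with i.i.d. Bernoulli(0.5) bits per 2 ms step; the rate is
configurable.

## Reverse correlation and fitting

Temporal receptive fields are estimated by correlating, across 10,000
independent 1,200 ms trials, the stimulus bit at each time point with the
final-time excitatory drive, suppressive drive and response (Pearson
product-moment per lag; correlation and cross-covariance differ only by a
constant per-lag scale here, and every comparison to an analytic form
refits a free scale). The shuffled null re-pairs stimuli and responses by
a fixed-point-free permutation. The per-lag estimator carries independent
noise of order 1/√n_sims at every lag, which matters in two places: overlay
comparisons against analytic shapes are made on boxcar-smoothed curves, and
the difference-of-Gammas fit

    h(l) = l e^{−l/τ₁} − k l e^{−l/τ₂}   (scale free; convention τ₁ ≥ τ₂)

is weakly identified in k: profiling the residual over k with the time
constants re-optimized changes R² by under 2% across k from ~2 to ~50, and
the fitted (τ₁, k) wander along this valley from seed to seed (τ₁ by about
±10 ms at 10,000 trials). Fitting uses Nelder–Mead with 100 restarts, τ₁
and τ₂ initialized uniformly in (0, 900), k at 0; nonpositive time
constants are rejected with a large penalty, and the optimal scale is
solved in closed form for each candidate. A noiseless self-consistency
test recovers synthetic parameters to better than 1%.

## What the generators emulate — and what they do not

The stimulus builders reproduce idealized experimental protocols: perfectly
timed, full-field, noise-free orientation/contrast events. They do not
model pixel-level stimuli, eye movements, response variability, or neuron-
to-neuron heterogeneity of time constants (all units share τ_E and τ_S in
a simulation). Passing tests therefore establish the model's *mechanistic*
behavior under clean conditions, not quantitative agreement with any
particular recorded dataset.

## Numerical choices

- Forward Euler at Δt = 2 ms; a warning is raised if Δt ≥ τ_R.
- The denominator is bounded below by σ^n by construction; no extra epsilon.
- Threshold metrics (time-to-peak at 99% of the within-stimulus maximum,
  time-to-half-max after offset) return a "not reached" sentinel (`None`)
  instead of extrapolating.
- Summed-response metrics integrate over the full trial including the
  prestimulus period (zeros contribute nothing); AUC is step-sum × Δt.
- Suppressive pooling and temporal filtering commute (both linear); the
  implementation filters the pooled signal once.
- Orientation has period π throughout; `|cos|` handles the wrap.

## Problem sizes used by the shipped analyses

Reverse correlation uses the full 10,000 × 600-step campaign (a few seconds
when vectorized across trials; the 100-restart fit dominates at ~15 s). The
subadditivity preset runs 20 simulations of 3,000 steps. The SOA sweep for
suppression elimination runs three two-target simulations per SOA in 100 ms
steps from 250 ms, stopping when both indices fall below threshold. The
joint-suppression map defaults to the full 21 × 21 (τ_E, τ_S) grid and is
the longest preset (~10 min); pass a coarser grid for quick looks.

## Known limitations

- The contrast-dependent suppression indices decay with an effective
  constant of ~500–600 ms at (τ_E, τ_S) = (400, 100) ms, governed by the
  sensory drives' τ_E tail; under the 0.01-per-target criterion both
  indices first clear threshold near 1,550 ms of SOA. Stricter or looser
  thresholds move this point; the package reports the swept SI table so
  any criterion can be applied.
- The fitted lobe-weight k of the difference-of-Gammas form should be read
  together with τ₁ (see the identifiability note above); comparisons of k
  across conditions are only meaningful at matched fit settings.
- Attention layers, multi-layer hierarchies, spiking/conductance dynamics
  and continuous spatial maps are out of scope; space is represented by two
  discrete locations, which suffices for surround suppression.
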