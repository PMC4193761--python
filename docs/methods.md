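# Methods

This note records the scientific and numerical choices behind `spikecomp`:
the model equations and integration scheme, the provenance of every
default parameter, what the synthetic benchmarks do and do not emulate,
and the design decisions taken where the published material leaves the
procedure open.

## Neuron, synapse and plasticity models

Neurons are adaptive exponential integrate-and-fire (AdEx) point neurons
with two conductance channels (one excitatory, one inhibitory reversal
potential and decay constant per neuron — mirroring substrates that
provide exactly two synaptic input circuits per cell). Setting the slope
factor Δ_T = 0 removes the exponential term and yields a plain LIF neuron;
the spike condition is then V ≥ V_T, while for Δ_T > 0 it is V ≥ V_spike.
During the refractory period V is clamped to V_reset while conductances
continue to evolve. Units are nF, nS, mV, ms, pA throughout.

Short-term plasticity follows the Tsodyks–Markram scheme with mutually
exclusive depression and facilitation modes. State lives per synapse and
is updated only at presynaptic events with the closed-form inter-spike
recursions (exact for exponential recovery), not by continuous
integration:
R ← 1 − (1 − R·(1−u))·exp(−Δt/τ_rec), and in facilitation mode
u ← U + (u − U)·exp(−Δt/τ_facil) followed by the jump u ← u + U(1−u).

## Integration scheme

Fixed-step exponential Euler, default dt = 0.01 ms for single-cell work
and 0.1 ms for network experiments (both configurable). Per step the
synaptic conductances decay exactly, the adaptation current relaxes
exactly toward a(V−E_L), and V moves toward the instantaneous equilibrium
voltage with rate g_tot/C_m; the exponential spike-initiation current is
evaluated explicitly at the step start with its argument capped (beyond
the cap the neuron is guaranteed to cross V_spike within the step). With
no synaptic input the scheme is exact, which the LIF-relaxation test
exploits at machine precision. A 0.5 mV sup-norm agreement against an
adaptive-step reference integration (scipy `solve_ivp` at rtol 1e-10)
is enforced in the test suite for mixed subthreshold bombardment.

Delays are rounded to the nearest step (minimum one) and realized with a
ring buffer of pending conductance increments; simulation is bitwise
reproducible given (network, duration, dt, seed). Poisson sources draw
per-bin counts (exactly equivalent in distribution to binning an
event-time realization); pulse packets and explicit spike-train sources
are realized as event lists. Fractional pulse-packet intensities assign
the extra spikes round-robin across sources so total counts are
deterministic.

## Benchmark parameterizations and their provenance

The three benchmark architectures are re-implementations from their
published descriptions. Where a value appears in the main text we use it
verbatim; values that were published only in supplementary tables we
could not obtain are **placeholders** chosen from the cited model lineage
and calibrated once so the network reproduces the documented qualitative
behaviour. All of them are config entries that can be overridden per
experiment.

**Synfire chain.** Main-text values: 6 groups × (100 RS + 25 FS), Poisson
background 2 kHz through 1 nS per neuron, 20 ms intergroup delay,
pulse-packet stimulus population of 100 sources wired like an RS group.
Placeholder values: LIF parameters (τ_m = 10 ms, C_m = 0.25 nF,
E_L = V_reset = −70 mV, V_T = −57 mV, τ_ref = 2 ms), fixed in-degrees 60
(RS and stimulus sources) with all-to-all local FS→RS inhibition, synaptic
time constants 1.5 ms (exc) / 8 ms (inh), local inhibition delay 4 ms.
Feed-forward weights (0.75 nS) were calibrated once so that the
undistorted chain sits at the canonical attractor — every RS cell fires
exactly once per volley (a = 1) with sub-0.1 ms volley spread, weak
stimuli (a₀ ≲ 0.3) die out, and the spontaneous rate is below 0.1 Hz —
which places the propagation margin where the published scans put it
(failure between 30% and 40% homogeneous loss). These conditions define
the loss-scan experiments and are not adjusted per run.

**AI network.** Main-text values: 3920 neurons on a single toroidal
sheet, Gaussian distance profile, conduction velocity in the
0.1–0.5 m s⁻¹ range (we use 0.2), mean distance-dependent delay 1.55 ms,
survival boundary near 8 Hz. Placeholder values: 80% excitatory fraction,
AdEx parameters of the regular-spiking/fast-spiking family (τ_m = 20 ms,
E_L = V_reset = −60 mV, V_T = −50 mV, Δ_T = 2.5 mV, τ_w = 600 ms,
b = 5 pA for PY, b = 0 for INH, τ_syn 5/10 ms, E_rev 0/−80 mV),
in-degrees K_E = 100 and K_I = 25, default weights (9, 67) nS. The torus
(2 mm) and spatial footprint σ = 0.24 mm realize the published 1.55 ms
mean delay at v = 0.2 mm/ms. In-degrees are **exactly equal** across
neurons (weighted sampling without replacement under the Gaussian kernel,
Gumbel top-k), because the reference network's across-neuron rate CV is
small precisely for that reason; binomially-sampled connectivity is also
available (`distance_gaussian` rule).

**Layer 2/3 attractor memory.** Main-text values: 9 HC × 9 MC grid with
30 PYR + 2 RSNP + 1 BAS per MC (2673 neurons), 25% local PYR–PYR
connectivity, orthogonal patterns (MC i of every HC), BAS fed by the 8
closest MCs and projecting to all PYR of the home HC, PYR→RSNP onto
foreign patterns in foreign HCs, RSNP→PYR within the home MC, 5 L4 source
cells per MC, diffuse one-source-per-PYR background, axonal velocity
0.2 mm/ms giving delays ~0.5–8 ms over the hexagonal HC grid. "Closest"
MCs are measured on the MC index ring (no intra-HC geometry is
published); cell positions are HC centroids, so delays are HC-resolved
with a 0.5 ms intra-HC floor. Neuron/synapse parameters and the
non-local connection probabilities are placeholders (adaptive LIF fits
with Δ_T = 0; depressing PYR synapses U = 0.25, τ_rec = 500 ms) and are
labelled non-authoritative in the config; the packaged protocols
(completion, blink) are therefore validated against scripted mock
backends with known activation rules, not against quantitative published
dwell-time values.

## Distortion models

Synapse loss deletes each instantiated synapse independently with
probability p (global or per projection label); synapses mediating
external input can be exempted, matching studies in which stimulus
delivery is prioritized. Weight noise draws each weight from
N(w, (r·w)²) clipped at zero — receptor identity never flips — and the
clipping inflates the mean by Φ(1/r) + r·φ(1/r) − 1 (0.425% at r = 0.5),
which is left uncorrected by default (it is negligible at the studied
levels) with an optional re-centering flag. Fixed-pattern noise is
obtained by freezing the seed; redrawing per run emulates trial-to-trial
variability. Uniform delays overwrite every delay with a constant
(default 1.5 ms), preserving the original statistics in metadata.

## Compensation strategies

* **Loss → weight scaling.** Every surviving weight of projection j is
  multiplied by 1/(1−p_j), restoring the expected summed conductance per
  target neuron exactly in expectation (at the price of higher input
  variance).
* **Weight noise → multi-source background.** The one-private-source
  background is rewired to k sources drawn without replacement from a
  shared pool, each firing at 1/k of the per-neuron rate, so the expected
  background conductance is conserved exactly and per-synapse noise
  averages as 1/√k. Mean pairwise source-set overlap is k²/pool.
* **Weight noise → membrane rebalancing.** For single-synapse background,
  (E_L′, w′) are solved so the free-membrane mean and variance match the
  undistorted values. The moments come from an effective-current
  (diffusion-limit) approximation with a self-consistent operating point,
  **averaged over the clipped-noise factor by quadrature** — each neuron's
  single noisy synapse sits at its own operating point, and plugging
  E[X²] into one global operating point overestimates the variance of
  strong synapses whose driving force saturates. Verified by simulation:
  mean within 2%, variance within 5%.
* **Fixed delays → prolonged inhibition.** The local FS→RS synaptic time
  constant is stretched (default ×3) and the inhibitory weight rescaled;
  the separatrix position is then steered by the weight scale. The total
  inhibitory charge per event (∝ w·τ) is reported for comparison.
* **Mean-field time rescaling.** Single-neuron gain functions (output
  rate vs. afferent Poisson rate at (1−p)·K_E/K_I inputs) are measured for
  the reference and distorted configurations; λ is the ratio of their
  stable self-consistent fixed points, and the distorted network is run
  λ-times adjusted: g_L, a, b scale with λ, all time constants, the
  refractory period and delays scale with 1/λ. By default the conductance
  jumps also scale with λ, which makes the mapping exact — the rescaled
  autonomous system replays the original spike pattern at t/λ (asserted
  to machine precision) and rates scale exactly by λ. A fixed-jump
  variant (`scale_weights=False`) is provided for substrates where the
  weights cannot be touched; it is approximate and under-compensates.
  Note the single-neuron fixed point itself deviates from the measured
  network rate by tens of percent (the usual mean-field gap: afferents
  are neither Poisson nor independent), so end-to-end success is judged
  against the reference network rate.
* **Iterative per-neuron calibration.** Under frozen (fixed-pattern)
  distortions, each iteration simulates the network, measures each
  neuron's rate over the post-transient window (500 ms default), and
  shifts its spike-initiation threshold V_T by α·(ν_i − ν_target) mV
  (α default 0.1 mV/Hz, config-exposed). Ten iterations restore the mean
  PY rate of the default AI network under 50% fixed-pattern weight noise
  to within 5% with the rate CV below twice the reference. The loop
  aborts with a partial trace when the error exceeds its starting value
  and stops improving for three consecutive iterations.

## Analysis choices

* **Attractor detection** (published algorithm unavailable): per-pattern
  PYR rates in 5 ms bins, 20 ms Gaussian smoothing; a pattern activates
  above λ_on = 3× the all-pattern mean rate and deactivates below
  λ_off = 2× (hysteresis); simultaneous super-threshold patterns resolve
  winner-take-all by rate, so episodes never overlap; episodes shorter
  than 20 ms are discarded. All constants are keyword arguments.
* **Volley measurement**: a = spikes / RS population size, σ = sample
  standard deviation of spike times within the response window;
  propagation succeeds iff a₆ ≥ 0.5 (closed boundary — a₆ clusters near
  0 and 1).
* **Separatrix** (published fit unavailable): logistic regression of
  success on (σ₀, σ₀², a₀); boundary = 50% contour; transition width =
  a-direction distance between the 5% and 95% contours (2·ln 19/|coef_a|).
* **Volley filter**: a spike survives if ≥ 10 same-population spikes fall
  within ±2 ms; idempotent on volleys that pass intact.
* **AI statistics**: survival = any network spike within the final 100 ms;
  rates over the post-500 ms window; CV_ISI averaged over neurons with
  ≥ 3 ISIs; CC = mean pairwise Pearson correlation of 2 ms-binned counts
  over ~1000 random PY pairs; spectrum = periodogram of the 1 ms-binned
  population rate, Gaussian-smoothed (2 Hz), peak above 2 Hz. Bin widths
  and smoothing are config-exposed (the published constants are
  supplementary-only).

## Problem sizes and what the tests show

The default test suite runs every analysis at the published default
network sizes (synfire 750, AI 3920, L2/3 2673 neurons) with simulation
windows of 250 ms (synfire scans), 1.5–2.5 s (AI statistics and the
iterative loop) and 10% loss grids with 5 repetitions — sizes chosen so
a complete validation runs in minutes on one core while every stochastic
assertion keeps ≥ 4σ or majority-vote margins. The 22 445-neuron AI
realization is constructed and checked structurally; its reference
firing-rate and spectrum measurements are multi-hour runs driven through
the sweep CLI rather than the default suite.

The synthetic benchmarks emulate network-level distortion phenomenology:
they do not model substrate-specific spike loss and jitter from
communication bandwidth, parameter discretization, or noise on non-weight
parameters, and the L2/3 placeholder parameters reproduce the
architecture, not the published dwell-time statistics. Passing tests
therefore certify the simulator, the distortion/compensation algebra and
the analysis pipeline — not agreement with any particular biological
dataset.

## Known limitations

* One excitatory and one inhibitory conductance channel per neuron; a
  projection that stretches τ_syn changes the channel of its target
  population (fine for the synfire chain, where all RS inhibition is
  local, but a modelling constraint in general).
* The background pool must be the last declared population for
  multi-source rewiring (resizing would otherwise shift global ids).
* Heterogeneous per-neuron parameters are supported through overrides of
  scalar fields (used by the iterative calibration), not full per-neuron
  parameter tables.
* The mean-field gain-function machinery assumes a single dominant
  recurrent loop with equal excitatory/inhibitory rates; networks with
  strongly distinct population rates need per-population gain functions.
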