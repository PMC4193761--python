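# spikecomp

Spiking cortical network benchmarks under neuromorphic-style distortions —
and the compensation strategies that restore their dynamics.

Analog neuromorphic substrates emulate conductance-based point neurons in
silicon. The emulation is fast and power-efficient, but the mapped network
differs from the ideal model in systematic ways: a fraction of synapses
cannot be realized (**synapse loss**), synaptic weights carry fixed-pattern
and trial-to-trial variability (**weight noise**, a zero-clipped Gaussian
with σ/μ up to 50%), and axonal **delays are fixed** by the substrate
(~1.5 ms) instead of being configurable. `spikecomp` is a workbench for
studying — in ideal software simulation — what these distortions do to
network function, and for designing calibration procedures that undo them.
It is aimed at modellers preparing networks for analog neural hardware and
at anyone who needs quantified robustness of spiking dynamics to
connectivity and parameter perturbations.

## The models

All neurons follow the adaptive exponential integrate-and-fire (AdEx)
equations with exponential-decay conductance synapses:

```
C_m dV/dt = -g_L (V - E_L) + g_L Δ_T exp[(V - V_T)/Δ_T] + Σ_i g_i(t)(E_i - V) - w + I
τ_w dw/dt = a (V - E_L) - w,     V ≥ V_spike ⇒ V ← V_reset, w ← w + b
```

with Δ_T = 0 reducing to leaky integrate-and-fire, plus optional
Tsodyks–Markram short-term plasticity (release u·R per spike, resource
recovery with τ_rec, facilitation with τ_facil — mutually exclusive modes).

Three benchmark architectures exercise complementary dynamical regimes:

* **Synfire chain with feed-forward inhibition** — 6 groups of 100 RS + 25
  FS cells; a Gaussian pulse packet (a spikes/source, spread σ) either
  propagates to the last group or dies out. The boundary in the (σ, a)
  plane (the *separatrix*) and the success of propagation are the
  functionality criteria.
* **Self-sustained asynchronous-irregular (AI) network** — 3920 AdEx
  neurons (80% PY / 20% INH) on a 2 mm torus, Gaussian distance-dependent
  connectivity, conduction delays distance/velocity (mean 1.55 ms).
  Criteria: survival, mean/CV of rates, CV_ISI, pairwise correlation,
  spectrum peak.
* **Layer 2/3 attractor memory** — 9 hypercolumns × 9 minicolumns of
  30 PYR + 2 RSNP + 1 BAS cells (2673 neurons); same-index minicolumns
  form orthogonal patterns that compete through basket-cell and disynaptic
  RSNP inhibition. Criteria: attractor dwell/competition times, UP/DOWN
  membrane states, pattern completion, attentional blink.

Compensation strategies implemented: weight scaling by 1/(1−p) after loss,
multi-source background pools (averaging out weight noise), resting
potential/background rebalancing from free-membrane moment matching,
prolonged local inhibition replacing configurable delays, mean-field time
rescaling from measured gain functions, and per-neuron iterative threshold
calibration.

## Worked example

```python
import spikecomp as sc

# build the synfire chain, delete 30% of internal synapses, simulate
net = sc.build_synfire().instantiate(seed=42)
lossy, report = sc.apply_synapse_loss(
    net, sc.DistortionConfig(loss_p=0.3, exempt_external=True, seed=1))
res = sc.simulate(lossy, duration=250.0, dt=0.1, seed=7)

point = sc.measure_pulse_packet(res.spikes, "RS_5", window=(160.0, 182.0))
print(f"last group: a = {point.a:.2f}, sigma = {point.sigma:.2f} ms")
print("propagated:", sc.classify_propagation(point))
```

prints

```
last group: a = 1.00, sigma = 0.40 ms
propagated: True
```

— at 30% loss every RS cell of the last group still fires exactly once,
in a volley that has widened from ~0.07 ms (undistorted) to 0.40 ms: the
loss thins each neuron's afferent pool and desynchronizes the packet
before it kills it.
Raise `loss_p` to 0.4 and `a` drops to 0.0 (extinction); apply
`sc.compensate_loss_by_weights(lossy, {...: 0.9})` after a 90% loss draw
and propagation is restored.

The same workflow drives the other models, e.g.

```python
net = sc.build_ai().instantiate(seed=3)
spikes = sc.simulate(net, duration=2000.0, dt=0.1, seed=21).spikes
print(sc.ai_statistics(spikes, "PY").as_dict())
# {'mean_rate': 10.41, 'cv_rates': 0.44, 'cv_isi': 1.49, 'cc': 0.004,
#  'spectrum_peak': 14.7, 'survived': True}
```

A `spikecomp` command-line tool exposes `build`, `distort`, `compensate`,
`simulate`, `analyze`, `sweep`, `report` and `loss-scan` subcommands over
YAML configs (see `src/spikecomp/configs/`).

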