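# Self-sustained asynchronous irregular network on a 2 mm torus.
# 3920 AdEx neurons (80% PY / 20% INH), Gaussian distance-dependent
# connectivity (sigma 0.24 mm), conduction delays at 0.2 mm/ms
# (mean instantiated delay ~1.55 ms).
model:
  name: ai
  n_neurons: 3920
duration: 2000.0
dt: 0.1
sweep:
  model.params.g_exc: [6.0, 9.0, 12.0]
  model.params.g_inh: [40.0, 67.0, 90.0]
repetitions: 1
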