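# Feed-forward synfire chain with feed-forward inhibition.
# Default realization: 6 groups of 100 RS + 25 FS LIF neurons, 2 kHz / 1 nS
# Poisson background per neuron, pulse-packet stimulus into group 0.
model:
  name: synfire
  n_groups: 6
  n_rs: 100
  n_fs: 25
duration: 250.0
dt: 0.1
distortion:
  loss_p: 0.0
  noise_ratio: 0.0
  exempt_external: true
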