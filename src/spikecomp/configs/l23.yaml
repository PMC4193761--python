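# Cortical layer 2/3 attractor memory: 9 HC x 9 MC, 30 PYR + 2 RSNP + 1 BAS
# per MC (2673 neurons).  Neuron/synapse parameter defaults are
# non-authoritative placeholders (fitted values live in unavailable
# supplementary tables); override any entry under model.params.
model:
  name: l23
  n_hc: 9
  n_mc_per_hc: 9
  n_pyr_per_mc: 30
duration: 5000.0
dt: 0.1
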