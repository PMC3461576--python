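# 16-state AMPAR kinetic scheme (adapted from the Robert & Howe occupancy
# model): closed states C0-C4 with 0-4 glutamate molecules bound, open states
# O2-O4 entered from the 2-, 3- and 4-liganded closed states, a desensitized
# row D1-D4 and a deep (slowly recovering) desensitized row DD1-DD4.
#
# Units: ms^-1, or mM^-1 ms^-1 where `glu: true`.  Defaults are calibrated to
# macroscopic AMPAR EPSC phenomenology: sub-ms activation by the millimolar
# cleft transient, a few-ms decay (the open-state dwell time lumps single-
# channel burst behaviour, so the closing rate is an effective burst
# terminator, not a microscopic closing rate), strong desensitization at
# sustained agonist with a ~20 ms fast and ~100 ms slow recovery component.
# All rates are config-overridable.
scheme_version: 1
resting_state: C0
open_states: {O2: g2, O3: g3, O4: g4}
desensitized_2glu: D2
desensitized_states: [D1, D2, D3, D4, DD1, DD2, DD3, DD4]
states: [C0, C1, C2, C3, C4, O2, O3, O4, D1, D2, D3, D4, DD1, DD2, DD3, DD4]
transitions:
  # glutamate binding (4 equivalent sites) / unbinding
  - {from: C0, to: C1, rate: 20.0, glu: true}
  - {from: C1, to: C0, rate: 8.0}
  - {from: C1, to: C2, rate: 15.0, glu: true}
  - {from: C2, to: C1, rate: 16.0}
  - {from: C2, to: C3, rate: 10.0, glu: true}
  - {from: C3, to: C2, rate: 24.0}
  - {from: C3, to: C4, rate: 5.0, glu: true}
  - {from: C4, to: C3, rate: 32.0}
  # channel opening/closing; opening rate grows with occupancy
  - {from: C2, to: O2, rate: 4.0}
  - {from: O2, to: C2, rate: 0.12}
  - {from: C3, to: O3, rate: 8.0}
  - {from: O3, to: C3, rate: 0.12}
  - {from: C4, to: O4, rate: 20.0}
  - {from: O4, to: C4, rate: 0.12}
  # desensitization from liganded closed states, fast recovery component
  - {from: C1, to: D1, rate: 0.15}
  - {from: D1, to: C1, rate: 0.05}
  - {from: C2, to: D2, rate: 0.35}
  - {from: D2, to: C2, rate: 0.05}
  - {from: C3, to: D3, rate: 0.35}
  - {from: D3, to: C3, rate: 0.05}
  - {from: C4, to: D4, rate: 0.35}
  - {from: D4, to: C4, rate: 0.05}
  # binding within the desensitized row (higher affinity)
  - {from: D1, to: D2, rate: 30.0, glu: true}
  - {from: D2, to: D1, rate: 0.2}
  - {from: D2, to: D3, rate: 20.0, glu: true}
  - {from: D3, to: D2, rate: 0.4}
  - {from: D3, to: D4, rate: 10.0, glu: true}
  - {from: D4, to: D3, rate: 0.6}
  # deep desensitization, slow recovery component
  - {from: D1, to: DD1, rate: 0.005}
  - {from: DD1, to: D1, rate: 0.004}
  - {from: D2, to: DD2, rate: 0.01}
  - {from: DD2, to: D2, rate: 0.01}
  - {from: D3, to: DD3, rate: 0.01}
  - {from: DD3, to: D3, rate: 0.01}
  - {from: D4, to: DD4, rate: 0.01}
  - {from: DD4, to: D4, rate: 0.01}
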