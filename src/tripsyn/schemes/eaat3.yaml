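# EAAT3 (EAAC1) neuronal transporter cycle (adapted from the Larsson scheme).
# Same alternating-access topology as the EAAT2 file, with lower glutamate
# affinity and a faster turnover (~50-90 s^-1), as measured for the neuronal
# carrier.  Clamped ion concentrations are folded into pseudo-first-order
# rates; all rates are config-overridable.
scheme_version: 1
resting_state: Na2ToH
glu_binding:
  k3: {from: Na2To, to: Na2ToG}
  k6: {from: Na2ToH, to: Na2ToGH}
states: [To, NaTo, Na2To, Na2ToH, Na2ToG, Na2ToGH, HGN3To, HGN3Ti, Ti, KTi, KTo]
transitions:
  - {from: To, to: NaTo, rate: 2.0}
  - {from: NaTo, to: To, rate: 1.0}
  - {from: NaTo, to: Na2To, rate: 2.0}
  - {from: Na2To, to: NaTo, rate: 1.0}
  - {from: Na2To, to: Na2ToH, rate: 2.0}
  - {from: Na2ToH, to: Na2To, rate: 1.0}
  - {from: Na2To, to: Na2ToG, rate: 3.0, glu: true}
  - {from: Na2ToG, to: Na2To, rate: 1.0}
  - {from: Na2ToH, to: Na2ToGH, rate: 3.0, glu: true}
  - {from: Na2ToGH, to: Na2ToH, rate: 1.0}
  - {from: Na2ToG, to: Na2ToGH, rate: 2.0}
  - {from: Na2ToGH, to: Na2ToG, rate: 1.0}
  - {from: Na2ToGH, to: HGN3To, rate: 2.0}
  - {from: HGN3To, to: Na2ToGH, rate: 0.02}
  - {from: HGN3To, to: HGN3Ti, rate: 0.05}
  - {from: HGN3Ti, to: HGN3To, rate: 0.01}
  - {from: HGN3Ti, to: Ti, rate: 0.5}
  - {from: Ti, to: HGN3Ti, rate: 0.0001}
  - {from: Ti, to: KTi, rate: 1.0}
  - {from: KTi, to: Ti, rate: 0.2}
  - {from: KTi, to: KTo, rate: 0.09}
  - {from: KTo, to: KTi, rate: 0.03}
  - {from: KTo, to: To, rate: 1.0}
  - {from: To, to: KTo, rate: 0.05}
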