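# EAAT2 (GLT-1) transporter cycle (adapted from the Bergles alternating-access
# scheme).  Outward-facing states bind 2 Na+ and H+ (in either order with
# glutamate; the Na2To/Na2ToH <-> Na2ToG/Na2ToGH square), then glutamate and a
# third Na+, giving the fully loaded outward state HGN3To.  Translocation
# carries the load inward (HGN3Ti), substrates are released to the cytosol
# (Ti), and the empty carrier counter-transports K+ back to the outward face
# (KTi -> KTo -> To), the rate-limiting relocation step.
#
# Clamped ion concentrations (Na_o 140 mM, K_i 120 mM, H_o pH 7.3, K_o 3 mM)
# are folded into pseudo-first-order rates.  Glutamate binding rates are the
# published k3 = k6 = 6 mM^-1 ms^-1 and k-3 = k-6 = 0.5 ms^-1; the remaining
# rates are calibrated to GLT-1 phenomenology: translocation of the loaded
# carrier is rate-limiting, so cycling is ~8 s^-1 and uptake capacity
# recovers over >200 ms after a release event.  All rates are
# config-overridable.
scheme_version: 1
resting_state: Na2ToH
glu_binding:
  k3: {from: Na2To, to: Na2ToG}
  k6: {from: Na2ToH, to: Na2ToGH}
states: [To, NaTo, Na2To, Na2ToH, Na2ToG, Na2ToGH, HGN3To, HGN3Ti, Ti, KTi, KTo]
transitions:
  # sodium binding at the outward face (x [Na]_o, fast)
  - {from: To, to: NaTo, rate: 5.0}
  - {from: NaTo, to: To, rate: 0.5}
  - {from: NaTo, to: Na2To, rate: 5.0}
  - {from: Na2To, to: NaTo, rate: 0.5}
  # protonation (x [H]_o, fast)
  - {from: Na2To, to: Na2ToH, rate: 5.0}
  - {from: Na2ToH, to: Na2To, rate: 0.5}
  # glutamate binding: k3/k-3 and k6/k-6
  - {from: Na2To, to: Na2ToG, rate: 6.0, glu: true}
  - {from: Na2ToG, to: Na2To, rate: 0.5}
  - {from: Na2ToH, to: Na2ToGH, rate: 6.0, glu: true}
  - {from: Na2ToGH, to: Na2ToH, rate: 0.5}
  # protonation of the glutamate-bound state (thermodynamic square)
  - {from: Na2ToG, to: Na2ToGH, rate: 5.0}
  - {from: Na2ToGH, to: Na2ToG, rate: 0.5}
  # third Na+ locks the load (fast on, near-irreversible once fully loaded)
  - {from: Na2ToGH, to: HGN3To, rate: 10.0}
  - {from: HGN3To, to: Na2ToGH, rate: 0.004}
  # translocation of the loaded carrier (slow)
  - {from: HGN3To, to: HGN3Ti, rate: 0.008}
  - {from: HGN3Ti, to: HGN3To, rate: 0.002}
  # cytosolic release of Na+/H+/glutamate (lumped; [Glu]_i ~ 0)
  - {from: HGN3Ti, to: Ti, rate: 0.5}
  - {from: Ti, to: HGN3Ti, rate: 0.0001}
  # K+ binding inside (x [K]_i) and relocation outward
  - {from: Ti, to: KTi, rate: 1.0}
  - {from: KTi, to: Ti, rate: 0.2}
  - {from: KTi, to: KTo, rate: 0.05}
  - {from: KTo, to: KTi, rate: 0.015}
  # K+ release outside (x [K]_o for the reverse)
  - {from: KTo, to: To, rate: 1.0}
  - {from: To, to: KTo, rate: 0.05}
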