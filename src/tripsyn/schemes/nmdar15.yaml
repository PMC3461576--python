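# 15-state NMDAR kinetic scheme (adapted from the Ambert model family):
# RiGj = closed state with i glutamate and j glycine molecules bound,
# O = open state (from the fully liganded R2G2), Df/Ds = fast/slow
# desensitized states, MB = memantine-blocked open state, AG/AY =
# competitive-antagonist-bound states at the glutamate/glycine sites.
#
# Glycine is clamped at a saturating concentration (0.1 mM) and its binding
# steps are folded into pseudo-first-order rates; memantine and antagonist
# concentrations default to zero, leaving MB/AG/AY present but unreachable.
# The fast voltage-dependent Mg block is NOT part of the scheme: it is the
# multiplicative Woodhull factor applied in the current equation.
#
# Units: ms^-1, or mM^-1 ms^-1 where `glu: true`.  Glutamate binding is
# fast and tight (kon 1.5e7 M^-1 s^-1 per site, slow unbinding), so a single
# vesicular transient near-saturates the receptor, as observed for synaptic
# NMDARs; deactivation is slow (~100 ms, NR2B-like) and rebinding of
# residual cleft glutamate prolongs the EPSC tail.  Desensitization
# develops over tens-to-hundreds of ms with very slow recovery.  All rates
# are config-overridable.
scheme_version: 1
resting_state: R0G2
glycine_mM: 0.1
open_states: [O]
desensitized_states: [Df, Ds]
states: [R0G0, R0G1, R0G2, R1G0, R1G1, R1G2, R2G0, R2G1, R2G2, O, Df, Ds, MB, AG, AY]
transitions:
  # glycine binding (2 equivalent sites, pseudo-first-order at 0.1 mM)
  - {from: R0G0, to: R0G1, rate: 2.0}
  - {from: R0G1, to: R0G0, rate: 0.0066}
  - {from: R0G1, to: R0G2, rate: 1.0}
  - {from: R0G2, to: R0G1, rate: 0.0132}
  - {from: R1G0, to: R1G1, rate: 2.0}
  - {from: R1G1, to: R1G0, rate: 0.0066}
  - {from: R1G1, to: R1G2, rate: 1.0}
  - {from: R1G2, to: R1G1, rate: 0.0132}
  - {from: R2G0, to: R2G1, rate: 2.0}
  - {from: R2G1, to: R2G0, rate: 0.0066}
  - {from: R2G1, to: R2G2, rate: 1.0}
  - {from: R2G2, to: R2G1, rate: 0.0132}
  # glutamate binding (2 equivalent sites)
  - {from: R0G0, to: R1G0, rate: 30.0, glu: true}
  - {from: R1G0, to: R0G0, rate: 0.008}
  - {from: R1G0, to: R2G0, rate: 15.0, glu: true}
  - {from: R2G0, to: R1G0, rate: 0.016}
  - {from: R0G1, to: R1G1, rate: 30.0, glu: true}
  - {from: R1G1, to: R0G1, rate: 0.008}
  - {from: R1G1, to: R2G1, rate: 15.0, glu: true}
  - {from: R2G1, to: R1G1, rate: 0.016}
  - {from: R0G2, to: R1G2, rate: 30.0, glu: true}
  - {from: R1G2, to: R0G2, rate: 0.008}
  - {from: R1G2, to: R2G2, rate: 15.0, glu: true}
  - {from: R2G2, to: R1G2, rate: 0.016}
  # gating
  - {from: R2G2, to: O, rate: 0.05}
  - {from: O, to: R2G2, rate: 0.2}
  # desensitization (fast entry from the fully liganded closed state,
  # slow deep state; recovery is much slower than entry)
  - {from: R2G2, to: Df, rate: 0.003}
  - {from: Df, to: R2G2, rate: 0.002}
  - {from: Df, to: Ds, rate: 0.0004}
  - {from: Ds, to: Df, rate: 0.0004}
  # blocker/antagonist branches; forward rates are (concentration x kon)
  # with all concentrations defaulting to zero
  - {from: O, to: MB, rate: 0.0}
  - {from: MB, to: O, rate: 0.01}
  - {from: R0G2, to: AG, rate: 0.0}
  - {from: AG, to: R0G2, rate: 0.01}
  - {from: R0G0, to: AY, rate: 0.0}
  - {from: AY, to: R0G0, rate: 0.01}
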