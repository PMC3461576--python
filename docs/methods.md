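# Methods

`tripsyn` simulates glutamatergic transmission at a tripartite synapse — a
release site, a postsynaptic density (PSD) carrying AMPA and NMDA
receptors, and an ensheathing astrocytic process carrying EAAT2 (GLT-1)
glutamate transporters — and the consequences of astrocytic glutamate
uptake for paired-pulse plasticity and for spiking of a reduced
conductance-based neuron.  This note records the model, its assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Cleft diffusion

A vesicle releases Q molecules (default 3,000) instantaneously at the
centre of a thin cleft of height δ = 20 nm.  Lateral free diffusion
(D = 0.4 µm²/ms) in the slab gives the two-dimensional heat kernel

    Glu(r, t) = Q / (4 π δ D t) · exp(−r² / (4 D t)),

converted from molecules/µm³ to mM via Avogadro's number
(1 molecule/µm³ = 1.66054×10⁻⁶ mM).  The kernel conserves mass exactly and
peaks at t* = r²/(4D) for fixed r; both properties are tested by
quadrature and grid search.  Receptors are evaluated at a single
representative radius r_receptor = 0.1 µm (the PSD edge; configurable per
run).  Multiple releases superpose linearly.  The kernel has no loss term,
so its 1/t tail persists; clearance of that tail is exactly what the
transporter model contributes.

Degenerate inputs: the kernel is evaluated only for t > t₀ (it is defined
as 0 at or before the release instant), and the ODE integrator restarts at
each release event with a capped step (0.01 ms for 1 ms) so the
sub-millisecond transient is resolved.

## Kinetic schemes

Every receptor and transporter is a continuous-time Markov scheme with
occupancy vector x, dx/dt = (A + Glu·B)x, where A and B are generator
matrices in column convention (columns sum to zero, so total probability
is conserved to solver precision).  Schemes are declared in YAML files
shipped with the package; every rate constant is overridable from user
configuration, because only a handful of them are experimentally pinned.
Piecewise-constant inputs admit a closed-form solution by chained matrix
exponentials, which the test suite uses as the independent oracle for the
ODE integrator (agreement to rtol 10⁻⁶, occupancy sums within 10⁻⁹ of 1).

### AMPAR (16 states)

Closed states C0–C4 (0–4 glutamate bound, four equivalent sites), open
states O2–O4 with unitary conductances 9, 15 and 21 pS, a desensitized row
D1–D4 with a ~20 ms recovery component, and a deep row DD1–DD4 with a
~100 ms component.  Current: I_AMPA = 80 · (9·O2 + 15·O3 + 21·O4) · (V − 0)
in pS·mV → pA.  The defaults are calibrated to macroscopic EPSC
phenomenology rather than single-channel data: sub-millisecond activation
by the millimolar transient, a few-millisecond decay, and paired-pulse
depression persisting to ~300 ms.  The open-state closing rate
(0.12 ms⁻¹) is an *effective burst terminator* — real AMPAR channels
flicker within bursts, and the open dwell time here lumps the burst that
sets the macroscopic decay.  Glutamate affinity is deliberately low
(per-site Kd ≈ 1.6 mM), consistent with the receptor's rapid, low-affinity
activation; this also makes the EPSC decay insensitive to the dilute
kernel tail, which is what the data on transporter-independent AMPAR decay
kinetics require.

### NMDAR (15 states)

A glutamate axis (R0→R1→R2, two equivalent sites) crossed with a glycine
axis (G0→G1→G2), an open state entered from the fully liganded R2G2, fast
and slow desensitized states, and blocker/antagonist branches (memantine,
competitive antagonists) that are present in the scheme but unreachable at
their default zero concentrations.  Glycine is clamped saturating
(0.1 mM) and folded into pseudo-first-order rates.  Glutamate binding is
fast and tight (1.5×10⁷ M⁻¹s⁻¹ per site), so a single vesicular transient
near-saturates the receptor — as observed for synaptic NMDARs — and the
peak of the NMDAR EPSC is nearly independent of transporter density, while
its decay (deactivation ~100 ms, NR2B-like, prolonged by rebinding of
residual cleft glutamate) is the uptake-sensitive observable.

Voltage dependence lives in the current equation, not the scheme:

* Woodhull Mg²⁺ block: unblocked(V) = 1 / (1 + ([Mg]ₒ/K₀)·e^(−δzFV/RT)),
  with electrical distance δ = 0.8, z = 2, [Mg]ₒ = 1 mM, and the printed
  constants R = 8.31434 J mol⁻¹K⁻¹, F = 9.64867×10⁴ C mol⁻¹, T = 273.15 K
  (override T = 310 K for physiological temperature).  K₀ is not an
  independently pinned constant here; it defaults to 12.96 mM, the value
  that gives an unblocked fraction of 0.1 at −70 mV in 1 mM Mg²⁺ at the
  default temperature — a literature-typical figure.  All asserted
  Mg-block properties (limits, monotonicity, the J-shaped I–V with its
  negative-slope region between −90 and 0 mV) are insensitive to K₀.
* Open-channel conductance: g(V) = g1 + (g2 − g1)/(1 + e^(αV)) with
  g1 = 40 pS, g2 = 247 pS, α = 0.01 mV⁻¹ — a sigmoid between the two
  liganded-open conductance levels, equal to their mean at 0 mV.

I_NMDA = 20 · unblocked(V) · g(V) · (V − 0) · O(t).

### EAAT2 (astrocytic) and EAAT3 (neuronal) transporters

An 11-state alternating-access cycle: outward-facing binding of 2 Na⁺ and
H⁺ (in either order relative to glutamate — a thermodynamic square through
Na2To/Na2ToH/Na2ToG/Na2ToGH), glutamate binding with the pinned rates
k3 = k6 = 6 mM⁻¹ms⁻¹ and k−3 = k−6 = 0.5 ms⁻¹, a third Na⁺ that locks the
fully loaded outward state HGN3To, slow translocation (0.008 ms⁻¹, the
rate-limiting step), cytosolic release, and K⁺ counter-transport
relocating the empty carrier.  Clamped ion concentrations are folded into
pseudo-first-order rates.  The cycle turns over at ~8 s⁻¹ and the
capacity to take up fresh glutamate recovers over hundreds of
milliseconds after a release — the HGN3To occupancy perturbation decays
with a 95% recovery time of ~700 ms, matching the published observation
that the transporter recovers only at inter-pulse intervals beyond
~200 ms.  EAAT3 shares the topology with faster turnover and lower
glutamate affinity; its population is small (90 µm⁻² over the 100–400 nm
perisynaptic annulus → 42 carriers vs 650 for EAAT2), which is why its
effect on EPSCs is minor.

Per-transporter glutamate flux is the net binding rate
dGluₒ/dt = k6·Glu·Na2ToH − k−6·Na2ToGH + k3·Glu·Na2To − k−3·Na2ToG,
which is linear in the free concentration: flux = a(x)·Glu − b(x).

Transporter counts: count = round(density × coverage × area).  The
effective ensheathment area is fixed at 0.1 µm², the value consistent with
the published per-synapse counts (650 at 13,000 µm⁻² and 50% coverage; 325
at half density).  The lateral area of the literal 400 nm × 20 nm
ensheathment cylinder (2πrδ ≈ 0.05 µm²) is *not* consistent with those
counts; we treat the printed counts as authoritative and the effective
area as the reconciling constant (configurable).

## Uptake-driven depletion of the receptor input

The standalone operation `apply_uptake` implements plain bookkeeping on
precomputed trajectories: cumulative per-transporter flux × count,
converted molecules → mM via the cleft volume, subtracted from a free
trace and floored at zero.  It is useful for post-hoc accounting and is
tested against its contracts (no-transporter identity, zero floor,
monotonicity in count).

The coupled orchestrator uses a self-consistent formulation instead,
because a naive cumulative subtraction saturates: with hundreds of
carriers the accumulated debit exceeds the dilute kernel tail within a
fraction of a millisecond and clamps the receptor input to exactly zero at
*any* density, erasing the graded density dependence of the NMDAR decay
and distorting the EPSC decay shape.  The coupled model combines two
physically distinct effects:

1. **Pool depletion.**  Molecules bound or transported since the current
   release are gone from that release's diffusing pool, so the kernel is
   scaled by (1 − M/Q), where M is the cleared-molecule register (count ×
   cumulative flux), restarted at each release.  This term is
   parameter-free and density-graded at all times.
2. **Quasi-steady sink.**  Ongoing uptake flux is balanced against
   diffusive replenishment of the receptor vicinity (volume V = π r_v² δ
   with r_v = 0.27 µm, between the PSD edge and the ensheathment;
   exchange time τ = 0.3 ms).  With flux linear in concentration the
   self-consistent depleted concentration is closed form:

       Glu_dep = (Glu_free·(1 − M/Q) + Σᵢ cᵢ·bᵢ) / (1 + Σᵢ cᵢ·aᵢ),

   cᵢ = nᵢ·τ/V (in concentration units).  Depletion strengthens with
   transporter count and with the occupancy of receptive carrier states,
   weakens while carriers are loaded — the recovery effect that produces
   paired-pulse facilitation — and returns glutamate through the
   unbinding term bᵢ.  The expression is smooth, which the stiff solver
   appreciates.

V and τ are the two lumped coupling constants of the sink; they were
calibrated once so that full-density uptake reduces the single-release
AMPAR peak by ~30–40% while leaving the *normalized* AMPAR decay shape at
half density within a fraction of a percent of the transporter-free shape
— the two single-release constraints the model is required to satisfy
simultaneously.  They are configuration fields (`uptake_volume_um3`,
`uptake_exchange_ms`), not physical measurements.

All receptor and transporter blocks evolve on the same depleted
concentration, as one coupled ODE system (LSODA, rtol 10⁻⁸/atol 10⁻¹⁰,
restarted at release events), and I_syn = I_AMPA + I_NMDA holds exactly on
every output sample.

## Paired-pulse analysis

The paired-pulse ratio is peak₂/peak₁ of |I_syn|, with the second-pulse
peak measured after subtracting the residual current at the second release
time (the raw, unsubtracted convention is also computed; the published
convention is not stated).  With uptake enabled the model facilitates
(PPR > 1) at 10–100 ms intervals and relaxes to ~1 by 500 ms; without
uptake it depresses (PPR < 1) with the same relaxation.  The mechanism is
the one the simulations expose directly: uptake clips the first pulse and
shortens its glutamate exposure (less desensitization), and the
still-loaded carriers spare the second pulse; without uptake, receptor
desensitization alone governs and depresses the pair.

## Reduced neuron

The published neuron-level results used a morphologically detailed CA1
pyramidal cell; reproducing its exact spike counts requires that
morphology and is out of scope.  The package uses a two-compartment
stand-in: a soma with classic Hodgkin–Huxley Na⁺/K⁺ channels (rest
≈ −65 mV) and an equivalent dendritic compartment (lumped passive cable,
16,000 µm², leak 0.5 mS/cm², 40 nS coupling) receiving the synaptic
current.  All 16 synapses are identical and receive the same release
train, so one representative synapse is integrated and its current scaled
by 16 × gain; the membrane potential is a state of the same ODE system,
so the receptors (hence the NMDAR Mg block) see the dendritic voltage
continuously rather than through a discrete coupling step.

Synaptic strength: the published tuning factor of 6 is specific to the
detailed morphology, so the package calibrates instead.  Bisection on a
synchronous single-pulse protocol (no uptake) finds the threshold gain
(~3.6 with default passives — the documented factor 6 therefore spikes and
half of it does not, preserving the published contract), and
uptake-comparison experiments run at 1.35 × threshold: a near-threshold
operating point at which full transporter-mediated depletion of a
recovered input abolishes the spike while desensitized short-interval
inputs still fire.  Spikes are upward crossings of 0 mV with a 2 ms
refractory period (configurable).

At this operating point, seeded 2-Hz random-interval trains (exponential
intervals, 1 ms floor, 4 s duration) reproduce the published phenomena:
spike counts with uptake are never larger than without; surviving spikes
arrive with ~1–3 ms delays; and failures concentrate on inputs preceded by
long intervals (median preceding interval of failed spikes ≈ 400–550 ms
versus ≈ 90 ms for preserved spikes), because long intervals let the
transporters recover their full uptake capacity.

## What the simulations do and do not show

The release train generator *is* the study condition: exponential
inter-event intervals at 2 Hz (or 5 Hz), fixed seeds, every event
releasing exactly Q = 3,000 molecules from one site.  Real synapses add
vesicle depletion, release-probability dynamics, multi-site spillover,
tortuous extracellular geometry, and morphology-dependent dendritic
integration — none of which are modeled.  Passing tests therefore show
that the kinetic machinery, the uptake coupling, and the near-threshold
spiking logic jointly reproduce the published single-synapse and
reduced-neuron phenomenology; they do not certify quantitative spike
counts for any real cell.

Problem sizes used by the test suite and the acceptance script — single
releases with 600 ms tails, paired pulses at 10–500 ms, ten 4-second
2-Hz trials per condition — were chosen as the smallest runs that exercise
every mechanism; all are set in one place and scale up by configuration.

## Numerical choices

* LSODA throughout (stiff transients after each release, smooth decay
  between); dense 55–63-state systems, finite-difference Jacobians.
* Solver restarts at every release event; 0.01 ms max step for 1 ms after
  each event; output grid 0.05 ms.
* Synapse runs at rtol 10⁻⁸/atol 10⁻¹⁰; neuron runs at 10⁻⁶/10⁻⁸ (the
  spike threshold crossing is far above the integration error).
* Stationary distributions from the generator's null space initialize
  every scheme; the oracle tests pin ODE-vs-expm agreement to rtol 10⁻⁶.
* Determinism is bit-level: identical configuration and seed reproduce
  identical traces and spike times.

## Known limitations

* The kinetic rate tables are calibrated composites: topologies and the
  pinned constants follow the cited scheme families, but most individual
  rates are set to reproduce macroscopic phenomenology and are exposed as
  configuration rather than claimed as measurements.
* The uptake sink is a lumped two-parameter closure of a spatial problem;
  it cannot capture absorbing-boundary effects on the kernel's functional
  form.
* The reduced neuron's absolute spike counts, thresholds and gains are
  stand-in quantities; only orderings and timing contrasts are asserted.
* Fixed ion concentrations (Na⁺, K⁺, H⁺) and clamped glycine; no
  transporter anion currents, no temperature dependence, no
  gliotransmission.
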