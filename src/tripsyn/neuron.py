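"""Reduced conductance-based neuron driven by the tripartite synapse model.

A CA1 pyramidal cell stand-in with two compartments: a soma carrying
Hodgkin-Huxley Na+/K+ spiking channels and an equivalent dendritic
compartment (lumped passive cable) that receives the synaptic current.
``n_synapses`` identical synapses all receive the same release train, so a
single representative synapse is integrated and its composite EPSC is
injected as a current source scaled by ``n_synapses x synaptic_gain``.
The receptors read the dendritic membrane potential continuously (the
synapse states and the membrane are one coupled ODE system), so the NMDAR
Mg block follows the local depolarization.

The default gain of 6 matches the published tuning for a morphologically
detailed cell; because the threshold factor is morphology-dependent,
:func:`calibrate_gain` recovers the spiking threshold for this reduced
morphology by bisection on a synchronous single-pulse protocol (the
default passive parameters put it near 3.6, so the documented gain of 6
spikes and half of it does not).  Uptake-comparison experiments run at
:func:`operating_gain` = 1.35 x that threshold: a near-threshold operating
point at which glutamate uptake decides spike success, the regime the
spike-failure phenomenon requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cleft import free_glutamate_fn
from .protocols import StimulusProtocol, single_pulse
from .synapse import CoupledSynapse, SynapseConfig, TraceSet, _integrate

__all__ = [
    "NeuronConfig",
    "SpikeTrain",
    "run_neuron",
    "detect_spikes",
    "calibrate_gain",
    "operating_gain",
    "compare_uptake",
    "uptake_trials",
]

#: near-threshold operating margin above the synchronous-pulse threshold
DEFAULT_GAIN_MARGIN = 1.35


@dataclass(frozen=True)
class NeuronConfig:
    """Reduced-neuron parameters.

    Areas in um^2, specific conductances in mS/cm^2, specific capacitance in
    uF/cm^2, coupling conductance in nS, potentials in mV.
    """

    n_synapses: int = 16
    synaptic_gain: float = 6.0
    soma_area_um2: float = 1500.0
    dend_area_um2: float = 16000.0
    cm_uF_cm2: float = 1.0
    g_na: float = 120.0
    g_k: float = 36.0
    g_leak: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.4
    g_leak_dend: float = 0.5
    e_leak_dend: float = -65.0
    g_couple_nS: float = 40.0
    threshold_mV: float = 0.0
    refractory_ms: float = 2.0
    rtol: float = 1e-6
    atol: float = 1e-8
    jitter_seed: int | None = None

    def __post_init__(self):
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be >= 1")
        if self.synaptic_gain <= 0:
            raise ValueError("synaptic_gain must be > 0")

    @property
    def c_soma_pF(self) -> float:
        return self.cm_uF_cm2 * self.soma_area_um2 * 1e-2  # uF/cm2 * um2 -> pF

    @property
    def c_dend_pF(self) -> float:
        return self.cm_uF_cm2 * self.dend_area_um2 * 1e-2


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spike times (ms), strictly increasing, refractory-separated."""

    times: tuple
    threshold_mV: float
    refractory_ms: float

    def __len__(self) -> int:
        return len(self.times)


# -- Hodgkin-Huxley gating kinetics (classic squid parameters, rest -65 mV) --


def _safe_exprel(x):
    # x / (1 - exp(-x)) without the 0/0 singularity
    return np.where(np.abs(x) < 1e-7, 1.0 + x / 2.0, x / (1.0 - np.exp(-np.clip(x, -500, 500))))


def _alpha_m(v):
    return 1.0 * _safe_exprel((v + 40.0) / 10.0)


def _beta_m(v):
    return 4.0 * np.exp(-(v + 65.0) / 18.0)


def _alpha_h(v):
    return 0.07 * np.exp(-(v + 65.0) / 20.0)


def _beta_h(v):
    return 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))


def _alpha_n(v):
    return 0.1 * _safe_exprel((v + 55.0) / 10.0)


def _beta_n(v):
    return 0.125 * np.exp(-(v + 65.0) / 80.0)


def _gate_steady(v):
    am, bm = _alpha_m(v), _beta_m(v)
    ah, bh = _alpha_h(v), _beta_h(v)
    an, bn = _alpha_n(v), _beta_n(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


class _NeuronSystem:
    """Coupled synapse + two-compartment membrane vector field."""

    def __init__(self, syn_config: SynapseConfig, cfg: NeuronConfig):
        self.syn = CoupledSynapse(syn_config)
        self.cfg = cfg
        n = self.syn.n
        self.i_vd, self.i_vs = n, n + 1
        self.i_m, self.i_h, self.i_n = n + 2, n + 3, n + 4
        self.n = n + 5
        # absolute conductances, nS: mS/cm^2 x um^2 x 1e-2
        a_s = cfg.soma_area_um2 * 1e-2
        self.g_na, self.g_k, self.g_l = cfg.g_na * a_s, cfg.g_k * a_s, cfg.g_leak * a_s
        self.g_ld = cfg.g_leak_dend * cfg.dend_area_um2 * 1e-2
        self.scale = cfg.n_synapses * cfg.synaptic_gain

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n)
        y0[: self.syn.n] = self.syn.initial_state()
        v_rest = self._resting_potential()
        y0[self.i_vd] = v_rest
        y0[self.i_vs] = v_rest
        m, h, n_ = _gate_steady(v_rest)
        y0[self.i_m], y0[self.i_h], y0[self.i_n] = m, h, n_
        return y0

    def _resting_potential(self) -> float:
        # fixed point of the somatic membrane equation with steady-state gates
        v = -65.0
        for _ in range(200):
            m, h, n_ = _gate_steady(v)
            num = (
                self.g_na * m**3 * h * self.cfg.e_na
                + self.g_k * n_**4 * self.cfg.e_k
                + self.g_l * self.cfg.e_leak
                + self.g_ld * self.cfg.e_leak_dend  # dendrite pulls via coupling
            )
            den = self.g_na * m**3 * h + self.g_k * n_**4 + self.g_l + self.g_ld
            v_new = num / den
            if abs(v_new - v) < 1e-10:
                break
            v = v_new
        return v

    def rhs(self, events):
        syn = self.syn
        cfg = self.cfg
        syn_rhs = syn.rhs(events)
        c_d, c_s = cfg.c_dend_pF, cfg.c_soma_pF
        g_c = cfg.g_couple_nS

        def f(t, y):
            dy = np.empty_like(y)
            dy[: syn.n] = syn_rhs(t, y[: syn.n])
            v_d, v_s = y[self.i_vd], y[self.i_vs]
            m, h, n_ = y[self.i_m], y[self.i_h], y[self.i_n]
            i_ampa, i_nmda = syn.currents(y[: syn.n], v_d)
            i_syn = self.scale * (i_ampa + i_nmda)  # pA, inward-negative
            dy[self.i_vd] = (
                -self.g_ld * (v_d - cfg.e_leak_dend) - g_c * (v_d - v_s) - i_syn
            ) / c_d
            i_na = self.g_na * m**3 * h * (v_s - cfg.e_na)
            i_k = self.g_k * n_**4 * (v_s - cfg.e_k)
            i_l = self.g_l * (v_s - cfg.e_leak)
            dy[self.i_vs] = (-i_na - i_k - i_l - g_c * (v_s - v_d)) / c_s
            dy[self.i_m] = _alpha_m(v_s) * (1.0 - m) - _beta_m(v_s) * m
            dy[self.i_h] = _alpha_h(v_s) * (1.0 - h) - _beta_h(v_s) * h
            dy[self.i_n] = _alpha_n(v_s) * (1.0 - n_) - _beta_n(v_s) * n_
            return dy

        return f


def run_current_injection(
    amplitude_pA: float,
    duration_ms: float = 5.0,
    t_total: float = 60.0,
    neuron_config: NeuronConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, SpikeTrain]:
    """Membrane-only simulation of a somatic square current injection.

    Exercises the two-compartment spiking machinery without synapses;
    returns (t, V_soma, spikes).  Inward (depolarizing) current is a
    positive ``amplitude_pA`` here.
    """
    from scipy.integrate import solve_ivp

    cfg = neuron_config or NeuronConfig()
    sys_ = _NeuronSystem(SynapseConfig(), cfg)
    y0 = sys_.initial_state()[sys_.syn.n :]
    g_c, c_d, c_s = cfg.g_couple_nS, cfg.c_dend_pF, cfg.c_soma_pF

    def f(t, y):
        v_d, v_s, m, h, n_ = y
        i_inj = amplitude_pA if 5.0 <= t < 5.0 + duration_ms else 0.0
        dv_d = (-sys_.g_ld * (v_d - cfg.e_leak_dend) - g_c * (v_d - v_s)) / c_d
        i_na = sys_.g_na * m**3 * h * (v_s - cfg.e_na)
        i_k = sys_.g_k * n_**4 * (v_s - cfg.e_k)
        i_l = sys_.g_l * (v_s - cfg.e_leak)
        dv_s = (-i_na - i_k - i_l - g_c * (v_s - v_d) + i_inj) / c_s
        return [
            dv_d,
            dv_s,
            _alpha_m(v_s) * (1 - m) - _beta_m(v_s) * m,
            _alpha_h(v_s) * (1 - h) - _beta_h(v_s) * h,
            _alpha_n(v_s) * (1 - n_) - _beta_n(v_s) * n_,
        ]

    t_grid = np.arange(0.0, t_total, 0.05)
    sol = solve_ivp(
        f, (0.0, t_total), y0, t_eval=t_grid, method="LSODA",
        rtol=cfg.rtol, atol=cfg.atol, max_step=1.0,
    )
    if not sol.success:
        raise RuntimeError(f"current-injection run failed: {sol.message}")
    v_s = sol.y[1]
    return sol.t, v_s, detect_spikes(sol.t, v_s, cfg.threshold_mV, cfg.refractory_ms)


def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float = 0.0, refractory: float = 2.0) -> SpikeTrain:
    """Upward threshold crossings of a membrane trace with a refractory gap."""
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -np.inf
    for i in crossings:
        if t[i] - last >= refractory:
            times.append(float(t[i]))
            last = t[i]
    return SpikeTrain(times=tuple(times), threshold_mV=threshold, refractory_ms=refractory)


def run_neuron(
    protocol: StimulusProtocol,
    syn_config: SynapseConfig,
    neuron_config: NeuronConfig | None = None,
) -> tuple[TraceSet, SpikeTrain]:
    """Simulate the neuron for a release protocol.

    Returns the trace set (synaptic channels plus ``V_dend``/``V_soma``) and
    the detected spike train.
    """
    cfg = neuron_config or NeuronConfig()
    system = _NeuronSystem(syn_config, cfg)
    events = list(protocol.events)
    t_end = (events[-1].t0 if events else 0.0) + syn_config.tail
    t_grid = np.arange(0.0, t_end + syn_config.dt_out / 2, syn_config.dt_out)

    if events:
        glu_free = free_glutamate_fn(
            events, syn_config.geometry.r_receptor, syn_config.diffusion
        )
        traj = _integrate(
            system.rhs(events),
            system.initial_state(),
            [ev.t0 for ev in events],
            t_grid,
            cfg.rtol,
            cfg.atol,
            syn_config.solver,
            on_event=system.syn.reset_uptake_register,
        )
        glu_free_vec = np.array([glu_free(t) for t in t_grid])
    else:
        traj = np.tile(system.initial_state(), (len(t_grid), 1))
        glu_free_vec = np.zeros_like(t_grid)

    v_d = traj[:, system.i_vd]
    v_s = traj[:, system.i_vs]
    ch = system.syn.channels(t_grid, traj[:, : system.syn.n], glu_free_vec, v_d)
    ch["V_dend"] = v_d
    ch["V_soma"] = v_s
    trace = TraceSet(t=t_grid, channels=ch)
    spikes = detect_spikes(t_grid, v_s, cfg.threshold_mV, cfg.refractory_ms)
    return trace, spikes


def calibrate_gain(
    syn_config: SynapseConfig,
    neuron_config: NeuronConfig | None = None,
    lo: float = 0.5,
    hi: float = 24.0,
    tol: float = 0.1,
) -> float:
    """Bisection threshold gain for one spike from a synchronous single pulse.

    Uses the no-uptake configuration (the published tuning criterion:
    synchronous activation of all synapses must spike with probability 1).
    """
    from dataclasses import replace

    cfg = neuron_config or NeuronConfig()
    syn = syn_config.without_uptake()
    proto = single_pulse(t0=2.0)

    def spikes_at(gain: float) -> int:
        _, st = run_neuron(proto, syn, replace(cfg, synaptic_gain=gain))
        return len(st)

    if spikes_at(hi) == 0:
        raise RuntimeError("no spike even at the maximum gain; check neuron parameters")
    if spikes_at(lo) > 0:
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid) > 0:
            hi = mid
        else:
            lo = mid
    return hi


def operating_gain(
    syn_config: SynapseConfig,
    neuron_config: NeuronConfig | None = None,
    margin: float = DEFAULT_GAIN_MARGIN,
) -> float:
    """Near-threshold synaptic gain for uptake-comparison experiments.

    ``margin`` x the bisection threshold of :func:`calibrate_gain`: high
    enough that desensitized short-interval inputs still spike without
    uptake, low enough that full transporter-mediated depletion of a
    recovered input can abolish the spike.
    """
    return margin * calibrate_gain(syn_config, neuron_config)


def _preceding_intervals(event_times: np.ndarray, spike_times) -> np.ndarray:
    """Input inter-event interval preceding the event attributed to each spike.

    Each spike is attributed to the latest release at or before it.  The
    first release of a train has no predecessor; its interval is +inf
    (transporters and receptors are fully rested).
    """
    out = []
    for ts in spike_times:
        k = int(np.searchsorted(event_times, ts, side="right")) - 1
        if k <= 0:
            out.append(np.inf)
        else:
            out.append(float(event_times[k] - event_times[k - 1]))
    return np.array(out)


def compare_uptake(
    protocol: StimulusProtocol,
    syn_config: SynapseConfig,
    neuron_config: NeuronConfig | None = None,
    match_window: float = 20.0,
) -> dict:
    """Run the same protocol with and without glutamate uptake and pair spikes.

    Off-arm spikes are matched to on-arm spikes by nearest neighbour within
    ``match_window`` ms (each on-arm spike used once); unmatched off-arm
    spikes are counted as failures.  Returns a dict with spike counts,
    per-match timing deltas (on minus off, ms) and the preceding input
    intervals of failed and preserved spikes.
    """
    cfg = neuron_config or NeuronConfig()
    _, spikes_on = run_neuron(protocol, syn_config, cfg)
    _, spikes_off = run_neuron(protocol, syn_config.without_uptake(), cfg)
    t_on = np.array(spikes_on.times)
    t_off = np.array(spikes_off.times)

    used = np.zeros(len(t_on), dtype=bool)
    deltas, matched_off = [], []
    for ts in t_off:
        if len(t_on) == 0:
            break
        d = np.abs(t_on - ts)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= match_window:
            used[j] = True
            deltas.append(float(t_on[j] - ts))
            matched_off.append(ts)
    failed_off = [ts for ts in t_off if ts not in matched_off]

    ev = protocol.event_times
    return {
        "spikes_on": len(t_on),
        "spikes_off": len(t_off),
        "n_failures": len(failed_off),
        "deltas_ms": np.array(deltas),
        "failed_spike_times": np.array(failed_off),
        "preserved_spike_times": np.array(matched_off),
        "failed_preceding_intervals": _preceding_intervals(ev, failed_off),
        "preserved_preceding_intervals": _preceding_intervals(ev, matched_off),
    }


def uptake_trials(
    mean_rate: float,
    duration: float,
    seeds,
    syn_config: SynapseConfig,
    neuron_config: NeuronConfig | None = None,
):
    """Repeated uptake-on/off comparisons over seeded random trains.

    Returns a pandas DataFrame with one row per trial (seed, spike counts,
    failures, mean delay) and attaches the pooled interval statistics in
    ``df.attrs``.
    """
    import pandas as pd

    from .protocols import generate_rit

    rows, fails, keeps, all_deltas = [], [], [], []
    for seed in seeds:
        proto = generate_rit(mean_rate, duration, seed)
        res = compare_uptake(proto, syn_config, neuron_config)
        rows.append(
            {
                "seed": seed,
                "n_events": proto.n_events,
                "spikes_on": res["spikes_on"],
                "spikes_off": res["spikes_off"],
                "n_failures": res["n_failures"],
                "mean_delta_ms": float(np.mean(res["deltas_ms"]))
                if len(res["deltas_ms"])
                else np.nan,
            }
        )
        fails.extend(res["failed_preceding_intervals"].tolist())
        keeps.extend(res["preserved_preceding_intervals"].tolist())
        all_deltas.extend(res["deltas_ms"].tolist())
    df = pd.DataFrame(rows)
    df.attrs["failed_preceding_intervals"] = np.array(fails)
    df.attrs["preserved_preceding_intervals"] = np.array(keeps)
    df.attrs["deltas_ms"] = np.array(all_deltas)
    return df
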