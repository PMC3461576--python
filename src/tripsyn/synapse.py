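"""Synapse orchestration: release -> diffusion -> uptake -> receptor currents.

The full synapse is one coupled ODE system.  Free glutamate at the receptor
radius is the closed-form superposition of release kernels; the transporter
cycles and the AMPAR/NMDAR occupancies all evolve on the *depleted*
concentration.  Depletion is a quasi-steady sink balance: the transporter
populations remove glutamate at their net binding flux, and the diffusive
replenishment of the receptor vicinity (volume V, exchange time tau) sets
the concentration deficit that flux sustains.  With the per-transporter
flux linear in the local concentration, flux_i = a_i(x) glu - b_i(x), the
self-consistent depleted concentration is closed-form:

    glu_dep = (glu_free + sum_i c_i b_i) / (1 + sum_i c_i a_i),
    c_i = n_i * tau / V   (molecules -> mM via Avogadro),

so depletion strengthens with transporter count and with the occupancy of
glutamate-receptive carrier states, weakens while carriers are loaded
(the recovery effect), and returns glutamate when carriers unbind.

The composite EPSC is I_syn = I_AMPA + I_NMDA, evaluated at the holding
potential (synapse-only runs are voltage-clamped; the neuron module couples
the same system to a membrane potential state instead).

The composite EPSC is I_syn = I_AMPA + I_NMDA, evaluated at the holding
potential (synapse-only runs are voltage-clamped; the neuron module couples
the same system to a membrane potential state instead).

The integrator is restarted at every release event, with a capped step size
in a short window after each event so the sub-millisecond glutamate
transient is resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .ampar import AMPARParams
from .cleft import CleftGeometry, DiffusionParams, free_glutamate_fn
from .kinetics import stationary_distribution
from .nmdar import NMDARParams, mg_block_factor, nmdar_conductance
from .protocols import StimulusProtocol
from .transporters import EAAT2Params, EAAT3Params, binding_coeffs_fn, flux_fn
from .units import MM_PER_MOLECULE_PER_UM3, PS_MV_TO_PA

__all__ = [
    "SynapseConfig",
    "TraceSet",
    "run_synapse",
    "ppr",
    "desensitization_readout",
]


#: radius (um) of the receptor vicinity whose cleft volume converts cleared
#: molecules into the concentration debit; lies between the PSD edge (0.1 um)
#: and the astrocytic ensheathment (0.4 um)
RECEPTOR_VICINITY_RADIUS_UM = 0.27


@dataclass(frozen=True)
class SynapseConfig:
    """Complete synapse-level configuration (all sub-models plus solver knobs)."""

    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    geometry: CleftGeometry = field(default_factory=CleftGeometry)
    eaat2: EAAT2Params | None = field(default_factory=EAAT2Params)
    eaat3: EAAT3Params | None = None
    ampar: AMPARParams = field(default_factory=AMPARParams)
    nmdar: NMDARParams = field(default_factory=NMDARParams)
    v_hold: float = -70.0
    #: volume (um^3) of the receptor vicinity through which the uptake sink
    #: acts; None -> pi * r_vicinity^2 * delta with r_vicinity =
    #: RECEPTOR_VICINITY_RADIUS_UM (between the PSD edge and the ensheathment)
    uptake_volume_um3: float | None = None
    #: effective diffusive exchange (replenishment) time of the receptor
    #: vicinity, ms; together with the volume it sets the uptake coupling
    #: c = n * tau / V in the quasi-steady sink balance
    uptake_exchange_ms: float = 0.3
    rtol: float = 1e-8
    atol: float = 1e-10
    dt_out: float = 0.05
    tail: float = 500.0
    solver: str = "LSODA"

    def without_uptake(self) -> "SynapseConfig":
        return replace(self, eaat2=None, eaat3=None)


@dataclass
class TraceSet:
    """Time grid plus named channels; I_syn is exactly I_AMPA + I_NMDA."""

    t: np.ndarray
    channels: dict

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "t":
            return self.t
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            )
        return self.channels[name]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, **self.channels})

    def value_at(self, name: str, at: float) -> float:
        """Linear interpolation of a channel at time ``at`` (ms)."""
        return float(np.interp(at, self.t, self[name]))


class CoupledSynapse:
    """State layout, vector field and readouts of the coupled synapse system.

    State vector: [EAAT2 cycle, EAAT2 cumulative flux, EAAT3 cycle, EAAT3
    cumulative flux, AMPAR 16 states, NMDAR 15 states], with transporter
    blocks present only when the corresponding population is enabled.
    """

    def __init__(self, config: SynapseConfig):
        self.config = config
        geom = config.geometry
        if config.uptake_volume_um3 is not None:
            self.volume = config.uptake_volume_um3
        else:
            self.volume = (
                math.pi * RECEPTOR_VICINITY_RADIUS_UM**2 * config.diffusion.delta
            )

        self.blocks = []  # (name, slice, scheme)
        mats = []
        i = 0

        tau = config.uptake_exchange_ms
        self._transporters = []  # (slice, cum_index, flux, coeffs, c, count)
        for params in (config.eaat2, config.eaat3):
            if params is None or params.count == 0:
                continue
            scheme = params.scheme()
            sl = slice(i, i + scheme.n)
            self.blocks.append((params.scheme_name, sl, scheme))
            mats.append((sl, scheme.A, scheme.B))
            # uptake coupling: n transporters x exchange time / vicinity
            # volume, in mM per (probability/ms) of per-transporter flux
            c = params.count * tau * MM_PER_MOLECULE_PER_UM3 / self.volume
            self._transporters.append(
                (
                    sl,
                    i + scheme.n,
                    flux_fn(scheme),
                    binding_coeffs_fn(scheme),
                    c,
                    params.count,
                )
            )
            i += scheme.n + 1  # +1 for the cumulative-flux state
        self._cum_indices = [tr[1] for tr in self._transporters]

        self.ampar_scheme = config.ampar.scheme()
        self.sl_ampar = slice(i, i + self.ampar_scheme.n)
        mats.append((self.sl_ampar, self.ampar_scheme.A, self.ampar_scheme.B))
        i += self.ampar_scheme.n

        self.nmdar_scheme = config.nmdar.scheme()
        self.sl_nmdar = slice(i, i + self.nmdar_scheme.n)
        mats.append((self.sl_nmdar, self.nmdar_scheme.A, self.nmdar_scheme.B))
        i += self.nmdar_scheme.n

        self.n = i
        self.A = np.zeros((self.n, self.n))
        self.B = np.zeros((self.n, self.n))
        for sl, A, B in mats:
            self.A[sl, sl] = A
            self.B[sl, sl] = B

        amp = config.ampar
        sch = self.ampar_scheme
        self._ampar_g = np.zeros(sch.n)
        for s, g in (("O2", amp.g2), ("O3", amp.g3), ("O4", amp.g4)):
            self._ampar_g[sch.index(s)] = g
        self._i_nmda_open = self.nmdar_scheme.index("O")

    # -- state handling -------------------------------------------------

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n)
        for _, sl, scheme in self.blocks:
            y0[sl] = stationary_distribution(scheme.generator(0.0))
        y0[self.sl_ampar] = stationary_distribution(self.ampar_scheme.generator(0.0))
        y0[self.sl_nmdar] = stationary_distribution(self.nmdar_scheme.generator(0.0))
        return y0

    def reset_uptake_register(self, y: np.ndarray) -> np.ndarray:
        """Zero the per-release cleared-molecule registers.

        Called at each release event: the pool-depletion factor 1 - M/Q
        refers to the molecules removed from the *current* release's pool,
        so the register restarts when a fresh vesicle fuses.  Transporter
        occupancies persist and carry the recovery dynamics.
        """
        y = y.copy()
        y[self._cum_indices] = 0.0
        return y

    def _pool_factor(self, y, Q):
        """Fraction of the current release's glutamate still in the cleft."""
        removed = 0.0
        for tr in self._transporters:
            removed = removed + tr[5] * np.asarray(y)[..., tr[1]]
        return np.clip(1.0 - removed / Q, 0.0, 1.0)

    def glu_depleted(self, glu_free, y, Q=None):
        """Depleted concentration for state/trajectory ``y``.

        Applies the pool-depletion factor (when ``Q`` is given) and the
        quasi-steady sink balance.
        """
        y = np.asarray(y)
        s_a, s_b = 0.0, 0.0
        for sl, _, _, coeffs, c, _ in self._transporters:
            a, b = coeffs(y[..., sl])
            s_a = s_a + c * a
            s_b = s_b + c * b
        pool = 1.0 if Q is None else self._pool_factor(y, Q)
        return np.maximum(0.0, (np.asarray(glu_free) * pool + s_b) / (1.0 + s_a))

    def rhs(self, events):
        """Vector field for a given release-event list.

        The concentration driving every block combines (i) the free kernel
        at the receptor radius, (ii) the pool-depletion factor 1 - M/Q for
        molecules already removed from the current release, and (iii) the
        closed-form quasi-steady sink balance of ongoing uptake flux
        against diffusive replenishment (see module docstring).
        """
        A, B = self.A, self.B
        transporters = self._transporters
        glu_free_fn = free_glutamate_fn(
            events, self.config.geometry.r_receptor, self.config.diffusion
        )
        ev_t = np.array([ev.t0 for ev in events])
        ev_q = np.array([ev.Q for ev in events])

        def f(t, y):
            s_a, s_b = 0.0, 0.0
            removed = 0.0
            for sl, cum_i, _, coeffs, c, count in transporters:
                a, b = coeffs(y[sl])
                s_a += c * a
                s_b += c * b
                removed += count * y[cum_i]
            k = int(np.searchsorted(ev_t, t, side="right")) - 1
            pool = 1.0
            if k >= 0 and ev_q[k] > 0:
                pool = 1.0 - removed / ev_q[k]
                if pool < 0.0:
                    pool = 0.0
            glu = (glu_free_fn(t) * pool + s_b) / (1.0 + s_a)
            if glu < 0.0:
                glu = 0.0
            dy = A @ y + glu * (B @ y)
            for sl, cum_i, flux, _, _, _ in transporters:
                dy[cum_i] = flux(y[sl], glu)
            return dy

        return f

    # -- readouts --------------------------------------------------------

    def currents(self, y, v):
        """(I_AMPA, I_NMDA) in pA; ``y`` may be a trajectory, ``v`` scalar/array."""
        y = np.asarray(y)
        amp, nmd = self.config.ampar, self.config.nmdar
        g_open = y[..., self.sl_ampar] @ self._ampar_g  # pS
        i_ampa = amp.nb_ampa * g_open * (np.asarray(v) - amp.v_rev) * PS_MV_TO_PA
        o = y[..., self.sl_nmdar.start + self._i_nmda_open]
        if np.isscalar(v) or np.asarray(v).ndim == 0:
            block = mg_block_factor(float(v), nmd)
            g_v = nmdar_conductance(float(v), nmd)
        else:
            v_arr = np.asarray(v, dtype=float)
            block = np.array([mg_block_factor(vi, nmd) for vi in v_arr])
            g_v = np.array([nmdar_conductance(vi, nmd) for vi in v_arr])
        i_nmda = nmd.nb_nmda * block * g_v * (np.asarray(v) - nmd.v_rev) * o * PS_MV_TO_PA
        return i_ampa, i_nmda

    def channels(self, t, traj, glu_free_vec, v, Q=None) -> dict:
        i_ampa, i_nmda = self.currents(traj, v)
        amp_sch, nmd_sch = self.ampar_scheme, self.nmdar_scheme
        a0 = self.sl_ampar.start
        n0 = self.sl_nmdar.start
        ch = {
            "glu_free": np.asarray(glu_free_vec, dtype=float),
            "glu_depleted": self.glu_depleted(glu_free_vec, traj, Q=Q),
            "I_AMPA": i_ampa,
            "I_NMDA": i_nmda,
            "I_syn": i_ampa + i_nmda,
            "ampar_open": sum(
                traj[:, a0 + amp_sch.index(s)] for s in ("O2", "O3", "O4")
            ),
            "ampar_desensitized": traj[
                :, a0 + amp_sch.index(amp_sch.meta["desensitized_2glu"])
            ],
            "ampar_desensitized_total": sum(
                traj[:, a0 + amp_sch.index(s)]
                for s in amp_sch.meta["desensitized_states"]
            ),
            "nmdar_open": traj[:, n0 + nmd_sch.index("O")],
            "nmdar_desensitized": sum(
                traj[:, n0 + nmd_sch.index(s)]
                for s in nmd_sch.meta["desensitized_states"]
            ),
        }
        for name, sl, scheme in self.blocks:
            ch[f"{name}_HGN3To"] = traj[:, sl.start + scheme.index("HGN3To")]
        tau = self.config.uptake_exchange_ms
        for (name, sl, scheme), tr in zip(self.blocks, self._transporters):
            conv = tr[4] / tau if tau > 0 else 0.0
            ch[f"{name}_cleared_mM"] = conv * traj[:, tr[1]]
        return ch


#: window after each release event integrated with a capped step (ms)
_FINE_WINDOW = 1.0
_FINE_MAX_STEP = 0.01


def _integrate(f, y0, event_times, t_grid, rtol, atol, method, on_event=None):
    """Piecewise integration restarted at release events.

    ``on_event(y)`` is applied to the state at every release-event boundary
    (used to restart the per-release uptake register).
    """
    y = np.asarray(y0, dtype=float).copy()
    traj = np.empty((len(t_grid), len(y)))

    # segment boundaries: start, each event, fine-window ends, end
    t0, t1 = t_grid[0], t_grid[-1]
    bounds = {t0, t1}
    for te in event_times:
        if t0 < te < t1:
            bounds.add(te)
        end_fine = te + _FINE_WINDOW
        if t0 < end_fine < t1:
            bounds.add(end_fine)
    bounds = sorted(bounds)
    events = np.asarray(event_times)

    filled = 0
    if t_grid[0] == bounds[0]:
        traj[0] = y
        filled = 1
    for a, b in zip(bounds[:-1], bounds[1:]):
        if on_event is not None and np.any(np.abs(events - a) < 1e-12):
            y = on_event(y)
        in_fine = np.any((events <= a + 1e-12) & (a < events + _FINE_WINDOW))
        max_step = _FINE_MAX_STEP if in_fine else np.inf
        mask = (t_grid > a + 1e-12) & (t_grid <= b + 1e-12)
        t_eval = np.concatenate([t_grid[mask], [b]])
        sol = solve_ivp(
            f,
            (a, b),
            y,
            method=method,
            t_eval=np.unique(t_eval),
            rtol=rtol,
            atol=atol,
            max_step=max_step,
        )
        if not sol.success:
            raise RuntimeError(f"synapse integration failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1]
        n_out = int(np.sum(mask))
        if n_out:
            # grid points in this segment are the first entries of sol.t
            take = np.isin(sol.t, t_grid[mask])
            traj[filled : filled + n_out] = sol.y[:, take].T
            filled += n_out
    if filled != len(t_grid):
        raise RuntimeError("internal error: output grid not fully covered")
    return traj


def run_synapse(protocol: StimulusProtocol, config: SynapseConfig) -> TraceSet:
    """Simulate the synapse for a stimulus protocol; returns a :class:`TraceSet`.

    Deterministic given (config, protocol.events).  The time grid spans from
    0 to the last event plus ``config.tail`` at ``config.dt_out`` resolution.
    """
    system = CoupledSynapse(config)
    events = list(protocol.events)
    t_end = (events[-1].t0 if events else 0.0) + config.tail
    t_grid = np.arange(0.0, t_end + config.dt_out / 2, config.dt_out)

    if not events:
        y0 = system.initial_state()
        traj = np.tile(y0, (len(t_grid), 1))
        glu_free_vec = np.zeros_like(t_grid)
        ch = system.channels(t_grid, traj, glu_free_vec, config.v_hold)
        return TraceSet(t=t_grid, channels=ch)

    glu_free = free_glutamate_fn(events, config.geometry.r_receptor, config.diffusion)
    traj = _integrate(
        system.rhs(events),
        system.initial_state(),
        [ev.t0 for ev in events],
        t_grid,
        config.rtol,
        config.atol,
        config.solver,
        on_event=system.reset_uptake_register,
    )
    glu_free_vec = np.array([glu_free(t) for t in t_grid])
    ch = system.channels(
        t_grid, traj, glu_free_vec, config.v_hold, Q=events[0].Q
    )
    return TraceSet(t=t_grid, channels=ch)


def ppr(
    trace: TraceSet,
    protocol: StimulusProtocol,
    baseline_subtracted: bool = True,
    channel: str = "I_syn",
) -> float:
    """Paired-pulse ratio: second-pulse peak |current| / first-pulse peak.

    The second-pulse peak is measured after subtracting the residual current
    still flowing at the time of the second release (set
    ``baseline_subtracted=False`` for the raw convention).
    """
    if protocol.n_events != 2:
        raise ValueError("ppr requires a protocol with exactly two release events")
    t1, t2 = (ev.t0 for ev in protocol.events)
    i_syn = trace[channel]
    t = trace.t
    w1 = (t >= t1) & (t < t2)
    w2 = t >= t2
    peak1 = float(np.max(np.abs(i_syn[w1])))
    if peak1 == 0.0:
        raise ValueError("first-pulse response is identically zero")
    if baseline_subtracted:
        baseline = float(np.interp(t2, t, i_syn))
        peak2 = float(np.max(np.abs(i_syn[w2] - baseline)))
    else:
        peak2 = float(np.max(np.abs(i_syn[w2])))
    return peak2 / peak1


def desensitization_readout(trace: TraceSet, receptor: str, at: float) -> float:
    """Desensitized-state occupancy of ``receptor`` ('ampar'|'nmdar') at ``at`` ms."""
    channel = {"ampar": "ampar_desensitized", "nmdar": "nmdar_desensitized"}.get(receptor)
    if channel is None:
        raise ValueError("receptor must be 'ampar' or 'nmdar'")
    return trace.value_at(channel, at)
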