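"""NMDA receptor: 15-state kinetic scheme, Woodhull Mg block and current.

The scheme (see ``schemes/nmdar15.yaml``) tracks glutamate and glycine
binding, gating and desensitization.  The current through the open state is
scaled by two voltage dependences applied outside the scheme:

* a Woodhull block by external Mg2+ binding at electrical distance
  ``delta_elec`` within the membrane field,

      unblocked(V) = 1 / (1 + ([Mg]_o / K0) exp(-delta z F V / (R T))),

* a sigmoidal open-channel conductance interpolating between the two
  liganded-open conductance levels g1 and g2,

      g(V) = g1 + (g2 - g1) / (1 + exp(alpha V)).

I_NMDA = nb_NMDA * unblocked(V) * g(V) * (V - V_rev) * O(t), in pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .kinetics import SchemeSpec, integrate_scheme, load_scheme, validate_state_vector
from .units import F_FARADAY, PS_MV_TO_PA, R_GAS

__all__ = [
    "NMDARParams",
    "mg_block_factor",
    "nmdar_conductance",
    "nmdar_rate_matrix",
    "integrate_nmdar",
    "nmdar_current",
]


@dataclass(frozen=True)
class NMDARParams:
    """NMDAR population parameters.

    K0 (Mg dissociation constant at 0 mV) is not an experimentally pinned
    value here: the default is calibrated so the unblocked fraction at
    -70 mV in 1 mM external Mg is 0.1 at the default temperature, a
    literature-typical figure.  Temperature defaults to 273.15 K for
    consistency with the printed constants; override with 310 K for
    physiological conditions.
    """

    nb_nmda: int = 20
    g1: float = 40.0
    g2: float = 247.0
    alpha: float = 0.01
    mg_out: float = 1.0
    delta_elec: float = 0.8
    z: int = 2
    K0: float = 12.96
    T: float = 273.15
    v_rev: float = 0.0
    glycine: float = 0.1
    rate_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.nb_nmda < 0:
            raise ValueError("nb_nmda must be >= 0")
        if min(self.g1, self.g2) <= 0:
            raise ValueError("conductances must be > 0")
        if not (0.0 <= self.delta_elec <= 1.0):
            raise ValueError("delta_elec must lie in [0, 1]")
        if self.mg_out < 0:
            raise ValueError("mg_out must be >= 0")

    def scheme(self) -> SchemeSpec:
        return load_scheme("nmdar15", self.rate_overrides or None)


def mg_block_factor(v: float, params: NMDARParams | None = None) -> float:
    """Fraction of NMDARs not blocked by Mg2+ at membrane potential ``v`` (mV).

    Strictly increasing in ``v``; 1 when ``mg_out`` is 0; 0.5 at 0 mV when
    ``mg_out`` equals ``K0``.
    """
    params = params or NMDARParams()
    if not math.isfinite(v):
        raise ValueError("v must be finite")
    if params.mg_out == 0:
        return 1.0
    # v in mV -> volts for the Boltzmann factor
    expo = -params.delta_elec * params.z * F_FARADAY * (v * 1e-3) / (R_GAS * params.T)
    return 1.0 / (1.0 + (params.mg_out / params.K0) * math.exp(expo))


def nmdar_conductance(v: float, params: NMDARParams | None = None) -> float:
    """Open-channel conductance (pS) at membrane potential ``v`` (mV).

    Sigmoidal between the g1 and g2 plateaus with steepness ``alpha``;
    equals (g1 + g2)/2 at v = 0.
    """
    params = params or NMDARParams()
    if not math.isfinite(v):
        raise ValueError("v must be finite")
    return params.g1 + (params.g2 - params.g1) / (1.0 + math.exp(params.alpha * v))


def nmdar_rate_matrix(glu: float, params: NMDARParams | None = None) -> np.ndarray:
    """15-state generator matrix at glutamate concentration ``glu`` (mM)."""
    params = params or NMDARParams()
    return params.scheme().generator(glu)


def integrate_nmdar(
    glu_fn,
    t_grid: np.ndarray,
    params: NMDARParams | None = None,
    initial: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the NMDAR occupancy trajectory for glutamate input ``glu_fn(t)``."""
    params = params or NMDARParams()
    scheme = params.scheme()
    return integrate_scheme(scheme, glu_fn, np.asarray(t_grid, float), initial, rtol, atol)


def nmdar_current(state: np.ndarray, v: float, params: NMDARParams | None = None) -> float:
    """NMDAR current (pA) for an occupancy vector at membrane potential ``v`` (mV)."""
    params = params or NMDARParams()
    scheme = params.scheme()
    x = validate_state_vector(state, scheme.n)
    o = x[scheme.index("O")]
    i_open = nmdar_conductance(v, params) * (v - params.v_rev) * o  # pS mV
    return params.nb_nmda * mg_block_factor(v, params) * i_open * PS_MV_TO_PA
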