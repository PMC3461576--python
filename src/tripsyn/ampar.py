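"""AMPA receptor: 16-state kinetic scheme and channel current.

The receptor binds up to four glutamate molecules; channels open from the
2-, 3- and 4-liganded closed states with occupancy-dependent unitary
conductances, and desensitize into a liganded non-conducting row with fast
and slow recovery components.  The AMPAR-mediated current is

    I_AMPA = nb_AMPA (g2 O2 + g3 O3 + g4 O4) (V - V_rev)

with conductances in pS, voltage in mV and current in pA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .kinetics import SchemeSpec, integrate_scheme, load_scheme, validate_state_vector
from .units import PS_MV_TO_PA

__all__ = ["AMPARParams", "ampar_rate_matrix", "integrate_ampar", "ampar_current"]


@dataclass(frozen=True)
class AMPARParams:
    """AMPAR population parameters.

    nb_ampa receptors with unitary conductances g2/g3/g4 (pS) for the open
    states with 2/3/4 glutamate bound; reversal potential v_rev (mV).
    """

    nb_ampa: int = 80
    g2: float = 9.0
    g3: float = 15.0
    g4: float = 21.0
    v_rev: float = 0.0
    rate_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.nb_ampa < 0:
            raise ValueError("nb_ampa must be >= 0")
        if min(self.g2, self.g3, self.g4) <= 0:
            raise ValueError("conductances must be > 0")

    def scheme(self) -> SchemeSpec:
        return load_scheme("ampar16", self.rate_overrides or None)


def ampar_rate_matrix(glu: float, params: AMPARParams | None = None) -> np.ndarray:
    """16-state generator matrix at glutamate concentration ``glu`` (mM)."""
    params = params or AMPARParams()
    return params.scheme().generator(glu)


def integrate_ampar(
    glu_fn,
    t_grid: np.ndarray,
    params: AMPARParams | None = None,
    initial: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Integrate the AMPAR occupancy trajectory for glutamate input ``glu_fn(t)``."""
    params = params or AMPARParams()
    scheme = params.scheme()
    return integrate_scheme(scheme, glu_fn, np.asarray(t_grid, float), initial, rtol, atol)


def ampar_current(state: np.ndarray, v: float, params: AMPARParams | None = None) -> float:
    """AMPAR current (pA) for an occupancy vector at membrane potential ``v`` (mV)."""
    params = params or AMPARParams()
    scheme = params.scheme()
    x = validate_state_vector(state, scheme.n)
    o2, o3, o4 = (x[scheme.index(s)] for s in ("O2", "O3", "O4"))
    g_total = params.g2 * o2 + params.g3 * o3 + params.g4 * o4  # pS
    return params.nb_ampa * g_total * (v - params.v_rev) * PS_MV_TO_PA
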