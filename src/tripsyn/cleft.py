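"""Glutamate concentration in the synaptic cleft after vesicular release.

The cleft is treated as a thin slab of height ``delta``; an impulsive release
of ``Q`` glutamate molecules at the origin spreads laterally by free
diffusion, giving the two-dimensional heat kernel

    Glu(r, t) = Q / (4 pi delta D t) * exp(-r^2 / (4 D t))

in molecules/um^3, converted to mM for the receptor and transporter rate
equations.  The kernel conserves mass: integrating ``Glu * delta`` over the
plane returns ``Q`` molecules at every ``t > 0``, and for fixed ``r > 0`` the
concentration peaks at ``t* = r^2 / (4 D)``.

Multiple release events superpose linearly; uptake-driven depletion is
applied downstream (see :mod:`tripsyn.transporters`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import MM_PER_MOLECULE_PER_UM3

__all__ = [
    "DiffusionParams",
    "CleftGeometry",
    "ReleaseEvent",
    "glut_concentration",
    "superpose",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Cleft diffusion parameters.

    Parameters
    ----------
    D : float
        Glutamate diffusion coefficient, um^2/ms.
    delta : float
        Cleft height, um.
    Q : float
        Glutamate molecules per release event.
    """

    D: float = 0.4
    delta: float = 0.02
    Q: float = 3000.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.D) and self.D > 0):
            raise ValueError(f"D must be finite and > 0, got {self.D}")
        if not (math.isfinite(self.delta) and self.delta > 0):
            raise ValueError(f"delta must be finite and > 0, got {self.delta}")
        if not (math.isfinite(self.Q) and self.Q >= 0):
            raise ValueError(f"Q must be finite and >= 0, got {self.Q}")


@dataclass(frozen=True)
class CleftGeometry:
    """Radial geometry of the synapse.

    ``r_receptor`` is the radial distance of the modeled receptor population
    from the release site (default: the PSD edge); ``r_astro`` is the radius
    at which the astrocytic ensheathment sits.
    """

    r_psd: float = 0.1
    r_astro: float = 0.4
    r_receptor: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_receptor <= self.r_psd <= self.r_astro):
            raise ValueError(
                "require 0 <= r_receptor <= r_psd <= r_astro, got "
                f"r_receptor={self.r_receptor}, r_psd={self.r_psd}, "
                f"r_astro={self.r_astro}"
            )


@dataclass(frozen=True)
class ReleaseEvent:
    """A single impulsive vesicular release of ``Q`` molecules at ``t0`` ms."""

    t0: float
    Q: float = 3000.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t0) and self.t0 >= 0):
            raise ValueError(f"t0 must be finite and >= 0, got {self.t0}")
        if not (math.isfinite(self.Q) and self.Q >= 0):
            raise ValueError(f"Q must be finite and >= 0, got {self.Q}")


def glut_concentration(r, t, params: DiffusionParams):
    """Cleft glutamate concentration (mM) at radius ``r`` and time ``t``.

    ``t`` is time since release; ``t <= 0`` returns 0.  Accepts scalars or
    arrays (broadcast), returns the same shape.

    Raises
    ------
    ValueError
        For non-finite or negative ``r``/non-finite ``t``.
    """
    r_arr = np.asarray(r, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(r_arr)) or np.any(r_arr < 0):
        raise ValueError("r must be finite and >= 0")
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")

    out = np.zeros(np.broadcast_shapes(r_arr.shape, t_arr.shape))
    r_b, t_b = np.broadcast_arrays(r_arr, t_arr)
    pos = t_b > 0
    if np.any(pos):
        tt = t_b[pos]
        rr = r_b[pos]
        dens = (
            params.Q
            / (4.0 * math.pi * params.delta * params.D * tt)
            * np.exp(-(rr**2) / (4.0 * params.D * tt))
        )
        out[pos] = dens * MM_PER_MOLECULE_PER_UM3
    if out.ndim == 0 or (np.isscalar(r) and np.isscalar(t)):
        return float(out) if out.ndim == 0 else out
    return out


def superpose(events, r, t, params: DiffusionParams):
    """Linear superposition of release kernels at radius ``r``, time ``t`` (mM).

    ``events`` must be sorted by ``t0``.  Each event contributes
    ``glut_concentration(r, t - t0)`` with its own ``Q``; events at or after
    ``t`` contribute nothing.
    """
    t0s = [ev.t0 for ev in events]
    if any(b < a for a, b in zip(t0s, t0s[1:])):
        raise ValueError("events must be sorted by t0")
    t_arr = np.asarray(t, dtype=float)
    total = np.zeros_like(t_arr, dtype=float)
    for ev in events:
        p = DiffusionParams(D=params.D, delta=params.delta, Q=ev.Q)
        total = total + glut_concentration(r, t_arr - ev.t0, p)
    if np.isscalar(t):
        return float(total)
    return total


# Convenience used by the synapse orchestrator: args = (events, r, params)
def free_glutamate_fn(events, r: float, params: DiffusionParams):
    """Return a callable ``glu_free(t)`` (mM) superposing all release events."""

    events = sorted(events, key=lambda ev: ev.t0)
    t0s = np.array([ev.t0 for ev in events])
    qs = np.array([ev.Q for ev in events])
    coef = 1.0 / (4.0 * math.pi * params.delta * params.D)
    inv4d = 1.0 / (4.0 * params.D)

    def glu_free(t: float) -> float:
        tau = t - t0s
        mask = tau > 0
        if not np.any(mask):
            return 0.0
        tau = tau[mask]
        dens = qs[mask] * coef / tau * np.exp(-(r**2) * inv4d / tau)
        return float(np.sum(dens)) * MM_PER_MOLECULE_PER_UM3

    return glu_free
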