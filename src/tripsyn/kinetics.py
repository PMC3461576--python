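"""Generic machinery for ligand-gated kinetic (Markov) schemes.

Every receptor/transporter model in the package is a continuous-time Markov
scheme whose transition rates are either constant or proportional to the
glutamate concentration.  The occupancy vector ``x`` (probabilities summing
to 1) therefore evolves as

    dx/dt = (A + glu * B) x

where ``A`` collects the glutamate-independent rates and ``B`` the
glutamate-binding rates (per mM).  Both are generator matrices in column
convention: off-diagonal entry (j, i) is the i -> j rate and every column
sums to zero, so the total probability is conserved exactly.

Schemes are declared in YAML files (state list + transition list) shipped
with the package and are fully overridable from user configuration.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.linalg import expm, null_space

__all__ = [
    "SchemeSpec",
    "load_scheme",
    "validate_state_vector",
    "stationary_distribution",
    "propagate_expm",
    "integrate_scheme",
]

_STATE_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SchemeSpec:
    """A kinetic scheme: state names plus affine generator ``G(glu) = A + glu B``."""

    name: str
    states: tuple
    A: np.ndarray
    B: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def generator(self, glu: float) -> np.ndarray:
        """Generator matrix at glutamate concentration ``glu`` (mM)."""
        if not np.isfinite(glu) or glu < 0:
            raise ValueError(f"glu must be finite and >= 0, got {glu}")
        return self.A + glu * self.B

    def resting_state(self, state: str | None = None) -> np.ndarray:
        """Unit vector on a named state (default: the scheme's declared rest state)."""
        if state is None:
            state = self.meta.get("resting_state", self.states[0])
        x0 = np.zeros(self.n)
        x0[self.index(state)] = 1.0
        return x0

    def with_overrides(self, overrides: Mapping[str, float]) -> "SchemeSpec":
        """Return a copy with named transition rates replaced.

        Keys are ``"FROM->TO"``; values replace the base rate of that
        transition (same glutamate dependence as declared).
        """
        transitions = [dict(tr) for tr in self.meta["transitions"]]
        known = {f"{tr['from']}->{tr['to']}" for tr in transitions}
        unknown = set(overrides) - known
        if unknown:
            raise KeyError(f"unknown transitions in override: {sorted(unknown)}")
        for tr in transitions:
            key = f"{tr['from']}->{tr['to']}"
            if key in overrides:
                tr["rate"] = float(overrides[key])
        return build_scheme(self.name, list(self.states), transitions, dict(self.meta))


def build_scheme(name, states, transitions, meta=None) -> SchemeSpec:
    """Assemble a :class:`SchemeSpec` from a transition list.

    Each transition is a mapping with keys ``from``, ``to``, ``rate`` and an
    optional boolean ``glu`` marking rates proportional to glutamate
    concentration (units mM^-1 ms^-1 instead of ms^-1).
    """
    states = tuple(states)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for tr in transitions:
        i, j = idx[tr["from"]], idx[tr["to"]]
        rate = float(tr["rate"])
        if rate < 0:
            raise ValueError(f"negative rate in {name}: {tr}")
        M = B if tr.get("glu", False) else A
        M[j, i] += rate
        M[i, i] -= rate
    meta = dict(meta or {})
    meta["transitions"] = [dict(tr) for tr in transitions]
    return SchemeSpec(name=name, states=states, A=A, B=B, meta=meta)


def load_scheme(name: str, overrides: Mapping[str, float] | None = None) -> SchemeSpec:
    """Load a packaged scheme (``ampar16``, ``nmdar15``, ``eaat2``, ``eaat3``)."""
    ref = importlib.resources.files("tripsyn.schemes").joinpath(f"{name}.yaml")
    data = yaml.safe_load(ref.read_text())
    meta = {k: v for k, v in data.items() if k not in ("states", "transitions")}
    scheme = build_scheme(name, data["states"], data["transitions"], meta)
    if overrides:
        scheme = scheme.with_overrides(overrides)
    return scheme


def validate_state_vector(x: np.ndarray, n: int, tol: float = 1e-6) -> np.ndarray:
    """Check an occupancy vector: length ``n``, entries in [0,1], sum 1."""
    x = np.asarray(x, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"state vector must have shape ({n},), got {x.shape}")
    if np.any(x < -tol) or np.any(x > 1 + tol):
        raise ValueError("state occupancies must lie in [0, 1]")
    if abs(float(np.sum(x)) - 1.0) > tol:
        raise ValueError(f"state occupancies must sum to 1, got {np.sum(x)}")
    return x


def stationary_distribution(G: np.ndarray) -> np.ndarray:
    """Stationary occupancy of a generator matrix via its null space."""
    ns = null_space(G)
    if ns.shape[1] == 0:
        raise ValueError("generator has no null space")
    # pick the null vector with a consistent sign and unit probability mass
    v = ns[:, 0]
    v = np.where(np.abs(v) < 1e-14, 0.0, v)
    if np.sum(v) < 0:
        v = -v
    if np.any(v < -1e-10):
        raise ValueError("null space vector is not a distribution")
    return np.clip(v, 0.0, None) / np.sum(v)


def propagate_expm(scheme: SchemeSpec, x0: np.ndarray, segments) -> np.ndarray:
    """Propagate through piecewise-constant glutamate via matrix exponentials.

    ``segments`` is a sequence of ``(glu, duration_ms)`` pairs.  This is the
    closed-form solution for piecewise-constant input and serves as the
    independent oracle for the ODE integrator.
    """
    x = np.asarray(x0, dtype=float).copy()
    for glu, dt in segments:
        x = expm(scheme.generator(glu) * dt) @ x
    return x


def integrate_scheme(
    scheme: SchemeSpec,
    glu_fn: Callable[[float], float],
    t_grid: np.ndarray,
    x0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> np.ndarray:
    """Integrate ``dx/dt = (A + glu(t) B) x`` on ``t_grid``.

    Returns the trajectory with shape ``(len(t_grid), n)``.  Raises
    ``RuntimeError`` with the solver message on failure.
    """
    if x0 is None:
        x0 = scheme.resting_state()
    x0 = validate_state_vector(np.asarray(x0, dtype=float), scheme.n)
    A, B = scheme.A, scheme.B

    def rhs(t, x):
        return (A + glu_fn(t) * B) @ x

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        x0,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"{scheme.name} integration failed: {sol.message}")
    return sol.y.T
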