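"""Deterministic models of plasmid replication control and reporter circuits.

Two model families live here:

* the two-plasmid replication system, in which a repressor plasmid A held at
  constant copy number blocks the replication of a plasmid B that otherwise
  replicates autocatalytically::

      dA/dt = 0
      dB/dt = k1*B - k2*A*B

  The non-trivial stationary state of B exists only when the constant A copy
  number equals the rate ratio k1/k2; away from that knife edge B either
  grows without bound or is lost.

* the reporter circuits carried by plasmids in the signal-sensing use cases:
  an exogenous signal binds the promoter on each plasmid copy, and the bound
  (``inducible`` mode) or free (``repurposed`` mode) promoter drives a
  fluorescent reporter that degrades at a first-order rate.

All circuit rates are expressed in molecules and hours.  Signals are treated
as exogenous, piecewise-constant inputs (their derivatives are zero by
default); an optional signal-conservation mode integrates the signal balance
equations verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TwoPlasmidParams",
    "CircuitParams",
    "CircuitState",
    "two_plasmid_rhs",
    "equilibrium_copy_number",
    "integrate_two_plasmid",
    "circuit_rhs",
    "circuit_steady_state",
    "integrate_circuit",
]

CircuitMode = Literal["inducible", "repurposed"]

#: integrator tolerances; rates span 1..200 so the system can be stiff
_RTOL = 1e-8
_ATOL = 1e-10


@dataclass(frozen=True)
class TwoPlasmidParams:
    """Parameters of the two-plasmid replication-repression system.

    ``k1`` is the replication rate of plasmid B, ``k2`` the rate at which one
    copy of the constant repressor plasmid A blocks B's replication; ``A0``
    and ``B0`` are the initial copy numbers (A stays at ``A0`` forever).
    Defaults are the published scenario values (dimensionless units).
    """

    k1: float = 0.05
    k2: float = 0.005
    A0: float = 100.0
    B0: float = 100.0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 < 0:
            raise ValueError("rates must satisfy k1 > 0 and k2 >= 0")
        if self.A0 < 0 or self.B0 < 0:
            raise ValueError("copy numbers must be non-negative")


def two_plasmid_rhs(A: float, B: float, params: TwoPlasmidParams) -> tuple[float, float]:
    """Time derivatives ``(dA/dt, dB/dt)`` of the two-plasmid system.

    A is constant by construction (``dA/dt = 0``); B replicates at ``k1`` per
    copy and is repressed at ``k2`` per (A copy x B copy).
    """
    if A < 0 or B < 0:
        raise ValueError("copy numbers must be non-negative")
    return 0.0, params.k1 * B - params.k2 * A * B


def equilibrium_copy_number(params: TwoPlasmidParams) -> float:
    """Constant A copy number ``A* = k1/k2`` at which dB/dt = 0 for all B > 0.

    Raises :class:`ValueError` when ``k2 = 0`` (no finite equilibrium: B grows
    unconditionally).
    """
    if params.k2 == 0:
        raise ValueError("k2 = 0: repression absent, no finite equilibrium exists")
    return params.k1 / params.k2


def integrate_two_plasmid(
    params: TwoPlasmidParams, t_end: float, n_points: int = 201
) -> np.ndarray:
    """Integrate the two-plasmid system; returns an ``(n_points, 3)`` array
    with columns ``t, A, B``.

    The growth/decay of B is exponential with constant rate
    ``k1 - k2*A0``, so an adaptive stiff-capable method (LSODA) is used and
    any integrator failure is surfaced as a :class:`RuntimeError`.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")

    def rhs(t: float, y: np.ndarray) -> list[float]:
        dA, dB = two_plasmid_rhs(y[0], max(y[1], 0.0), params)
        return [dA, dB]

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [params.A0, params.B0],
        method="LSODA",
        t_eval=t_eval,
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    traj = np.column_stack([sol.t, sol.y[0], sol.y[1]])
    return _clip_negative(traj)


def _clip_negative(traj: np.ndarray) -> np.ndarray:
    """Clip tolerance-level negative undershoot to zero (with a warning)."""
    neg = traj[:, 1:] < 0
    if neg.any():
        worst = float(traj[:, 1:][neg].min())
        warnings.warn(
            f"clipped negative state components (min {worst:.3e}) to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        traj[:, 1:] = np.clip(traj[:, 1:], 0.0, None)
    return traj


# ---------------------------------------------------------------------------
# reporter circuits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircuitParams:
    """Rate constants of the plasmid-borne reporter circuits (per hour).

    ``k1``: signal-promoter binding; ``k2``: unbinding; ``k3``: merged
    transcription+translation of the reporter; ``k4``: reporter degradation;
    ``k1r``: repression of plasmid B's promoter by signal s1 (repurposed mode
    only).

    ``s1_repression_includes_k2`` keeps the repression flux written with the
    doubled rate factor ``k1r*k2`` exactly as published; set it to False to
    use the plain rate ``k1r``.
    """

    k1: float = 1.0
    k2: float = 50.0
    k3: float = 200.0
    k4: float = 1.0
    k1r: float = 30.0
    s1_repression_includes_k2: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "s1_repression_includes_k2":
                continue
            if getattr(self, f.name) < 0:
                raise ValueError(f"rate {f.name} must be non-negative")

    @property
    def repression_rate(self) -> float:
        """Effective binding rate of s1 to plasmid B's promoter."""
        return self.k1r * self.k2 if self.s1_repression_includes_k2 else self.k1r


@dataclass
class CircuitState:
    """State of the two reporter circuits in one cell.

    ``pA``/``pAa`` are the free/bound promoter copies on plasmid A (their sum
    equals the plasmid A copy number of the host cell and is conserved by the
    binding kinetics); likewise ``pB``/``pBa`` for plasmid B.  ``s1``/``s2``
    are the exogenous signal levels in [0, 1]; ``RFP``/``GFP`` the reporter
    protein amounts (molecules).
    """

    pA: float = 0.0
    pAa: float = 0.0
    pB: float = 0.0
    pBa: float = 0.0
    s1: float = 0.0
    s2: float = 0.0
    RFP: float = 0.0
    GFP: float = 0.0

    _ORDER = ("pA", "pAa", "pB", "pBa", "s1", "s2", "RFP", "GFP")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in self._ORDER], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "CircuitState":
        return cls(**dict(zip(cls._ORDER, map(float, values))))

    def validate(self) -> None:
        for name in self._ORDER:
            if getattr(self, name) < 0:
                raise ValueError(f"circuit state component {name} is negative")


def circuit_rhs(
    state: CircuitState,
    params: CircuitParams,
    mode: CircuitMode = "inducible",
    signal_conservation: bool = False,
) -> CircuitState:
    """Time derivative of a :class:`CircuitState`.

    ``inducible`` mode: s1 induces plasmid A's promoter (bound promoter pAa
    drives RFP) and s2 induces plasmid B's (bound pBa drives GFP).

    ``repurposed`` mode: s2 is absent; s1 is simultaneously the inducer of
    plasmid A's circuit and a repressor of plasmid B's promoter, whose *free*
    form pB drives GFP.

    Signals are exogenous by default (zero derivative); with
    ``signal_conservation=True`` the signal balances mirror the promoter
    binding fluxes.  Both modes conserve the promoter totals pA+pAa and
    pB+pBa.
    """
    state.validate()
    k1, k2, k3, k4 = params.k1, params.k2, params.k3, params.k4
    d = CircuitState()

    bindA = k1 * state.s1 * state.pA - k2 * state.pAa
    d.pA = -bindA
    d.pAa = bindA
    d.RFP = k3 * state.pAa - k4 * state.RFP

    if mode == "inducible":
        bindB = k1 * state.s2 * state.pB - k2 * state.pBa
        d.pB = -bindB
        d.pBa = bindB
        d.GFP = k3 * state.pBa - k4 * state.GFP
        if signal_conservation:
            d.s1 = -bindA
            d.s2 = -bindB
    elif mode == "repurposed":
        bindB = params.repression_rate * state.s1 * state.pB - k2 * state.pBa
        d.pB = -bindB
        d.pBa = bindB
        d.GFP = k3 * state.pB - k4 * state.GFP
        if signal_conservation:
            d.s1 = -bindA - bindB
    else:
        raise ValueError(f"unknown circuit mode: {mode!r}")
    return d


def circuit_steady_state(
    params: CircuitParams,
    nA: float,
    nB: float,
    s1: float,
    s2: float = 0.0,
    mode: CircuitMode = "inducible",
) -> CircuitState:
    """Closed-form fixed point of :func:`circuit_rhs` at constant signals.

    For a promoter pool of ``n`` copies driven by a binding rate ``kon*s``
    against unbinding ``k2``, the bound fraction at stationarity is
    ``kon*s / (kon*s + k2)``; reporters then settle at ``k3/k4`` times the
    promoter species that drives them.
    """
    for name, level in (("s1", s1), ("s2", s2)):
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"signal {name} must lie in [0, 1]")
    if nA < 0 or nB < 0:
        raise ValueError("copy numbers must be non-negative")

    k1, k2, k3, k4 = params.k1, params.k2, params.k3, params.k4
    if k4 == 0:
        raise ValueError("k4 = 0: reporters have no steady state")

    pAa = nA * k1 * s1 / (k1 * s1 + k2) if (k1 * s1 + k2) > 0 else 0.0
    st = CircuitState(pA=nA - pAa, pAa=pAa, s1=s1, RFP=k3 * pAa / k4)
    if mode == "inducible":
        pBa = nB * k1 * s2 / (k1 * s2 + k2) if (k1 * s2 + k2) > 0 else 0.0
        st.pB, st.pBa, st.s2 = nB - pBa, pBa, s2
        st.GFP = k3 * pBa / k4
    elif mode == "repurposed":
        kon = params.repression_rate
        pBa = nB * kon * s1 / (kon * s1 + k2) if (kon * s1 + k2) > 0 else 0.0
        st.pB, st.pBa = nB - pBa, pBa
        st.GFP = k3 * st.pB / k4
    else:
        raise ValueError(f"unknown circuit mode: {mode!r}")
    return st


def integrate_circuit(
    state0: CircuitState,
    params: CircuitParams,
    mode: CircuitMode = "inducible",
    t_end: float = 100.0,
    n_points: int = 101,
    signal_conservation: bool = False,
) -> np.ndarray:
    """Integrate the reporter circuit ODEs; returns ``(n_points, 9)`` with
    columns ``t`` followed by the :class:`CircuitState` components."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    state0.validate()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        st = CircuitState.from_array(np.clip(y, 0.0, None))
        return circuit_rhs(st, params, mode, signal_conservation).as_array()

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        state0.as_array(),
        method="LSODA",
        t_eval=t_eval,
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return _clip_negative(np.column_stack([sol.t, sol.y.T]))
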