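"""Conductance-based soma models.

A soma model consists of a leak current, a set of voltage-activated currents,
and an external current applied directly to the somatic compartment,

    C_sigma dv/dt = G_sigma (E_L - v) + sum_j G_j (E_j - v) prod_i a_i^{p_i} + I_ext.

Each gating variable ``a_i`` relaxes to its steady-state curve ``a_inf(v)``
with a voltage-dependent time constant ``tau(v)``; gates flagged as
instantaneous are algebraically replaced by their steady-state curves.

Units throughout: mV, ms, nS, pF, pA (so nS * mV = pA and pA / pF = mV/ms).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Gate",
    "ActiveCurrent",
    "SomaModel",
    "soma_rhs",
    "morris_lecar_soma",
]

_DIFF_H = 1e-4  # mV; central-difference step for gating-curve derivatives


@dataclass(frozen=True)
class Gate:
    """A single activation/inactivation variable.

    ``tau is None`` marks the gate as instantaneous: it is eliminated from the
    dynamic state and evaluated on its steady-state curve wherever it appears.
    ``dinf`` is an optional analytic derivative of the steady-state curve;
    a central difference is used when it is absent.
    """

    name: str
    inf: Callable[[float], float]
    tau: Callable[[float], float] | None = None
    dinf: Callable[[float], float] | None = None
    exponent: int = 1

    @property
    def instantaneous(self) -> bool:
        return self.tau is None

    def dinf_dv(self, v: float) -> float:
        if self.dinf is not None:
            return self.dinf(v)
        return (self.inf(v + _DIFF_H) - self.inf(v - _DIFF_H)) / (2.0 * _DIFF_H)


@dataclass(frozen=True)
class ActiveCurrent:
    """One voltage-activated current G (E - v) * prod(gates)."""

    name: str
    G: float  # maximal conductance, nS
    E: float  # reversal potential, mV
    gates: tuple[Gate, ...] = ()


@dataclass
class SomaModel:
    """Point conductance-based neuron used as the active compartment."""

    C_sigma: float  # pF
    G_sigma: float  # nS (somatic leak)
    E_L: float  # mV
    currents: tuple[ActiveCurrent, ...] = ()
    name: str = "soma"
    # set by factories that match a compiled fast-integration pattern
    _ml_params: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.C_sigma <= 0:
            raise ValueError("C_sigma must be positive")
        if self.G_sigma <= 0:
            raise ValueError("G_sigma must be positive")

    # -- state layout ------------------------------------------------------

    @property
    def dynamic_gates(self) -> tuple[Gate, ...]:
        """Gates carrying their own ODE, in state order."""
        out: list[Gate] = []
        for cur in self.currents:
            for g in cur.gates:
                if not g.instantaneous:
                    out.append(g)
        return tuple(out)

    @property
    def n_gates(self) -> int:
        return len(self.dynamic_gates)

    def gate_steady_states(self, v: float) -> np.ndarray:
        return np.array([g.inf(v) for g in self.dynamic_gates], dtype=float)

    def gate_time_constants(self, v: float) -> np.ndarray:
        return np.array([g.tau(v) for g in self.dynamic_gates], dtype=float)

    # -- currents ----------------------------------------------------------

    def _gate_value(self, gate: Gate, v: float, dyn: Sequence[float]) -> float:
        if gate.instantaneous:
            return gate.inf(v)
        return float(dyn[self.dynamic_gates.index(gate)])

    def i_ion(self, v: float, gating: Sequence[float]) -> float:
        """Total membrane current (leak + active) at (v, gating), in pA."""
        i = self.G_sigma * (self.E_L - v)
        for cur in self.currents:
            fac = 1.0
            for g in cur.gates:
                fac *= self._gate_value(g, v, gating) ** g.exponent
            i += cur.G * (cur.E - v) * fac
        return i

    def i_active_inf(self, v: float) -> float:
        """Active (non-leak) current with every gate at steady state, pA."""
        i = 0.0
        for cur in self.currents:
            fac = 1.0
            for g in cur.gates:
                fac *= g.inf(v) ** g.exponent
            i += cur.G * (cur.E - v) * fac
        return i

    def di_active_inf_dv(self, v: float) -> float:
        """d/dv of :meth:`i_active_inf` (nS)."""
        out = 0.0
        for cur in self.currents:
            vals = [g.inf(v) for g in cur.gates]
            fac = 1.0
            for g, a in zip(cur.gates, vals):
                fac *= a ** g.exponent
            dfac = 0.0
            for k, g in enumerate(cur.gates):
                dfac += _dprod_term(cur.gates, vals, k) * g.dinf_dv(v)
            out += cur.G * (-fac + (cur.E - v) * dfac)
        return out

    def d2i_active_inf_dv2(self, v: float, h: float = 1e-3) -> float:
        return (self.di_active_inf_dv(v + h) - self.di_active_inf_dv(v - h)) / (2.0 * h)

    # -- right-hand side and partial derivatives ---------------------------

    def f_S(self, v: float, gating: Sequence[float], I_ext: float = 0.0) -> float:
        """dv/dt of the isolated soma (mV/ms)."""
        return (self.i_ion(v, gating) + I_ext) / self.C_sigma

    def partials_at_steady(self, v: float):
        """Partial derivatives of f_S at the equilibrium gating values.

        Returns ``(df_dv, df_da, dainf, tau)`` where ``df_dv`` holds the
        dynamic gates frozen (instantaneous gates track v), and the arrays run
        over the dynamic gates in state order.  These are the ingredients of
        the characteristic function used for the stability analysis.
        """
        dyn = self.dynamic_gates
        a_inf = self.gate_steady_states(v)
        df_dv = -self.G_sigma
        df_da = np.zeros(len(dyn))
        for cur in self.currents:
            vals = [self._gate_value(g, v, a_inf) for g in cur.gates]
            fac = 1.0
            for g, a in zip(cur.gates, vals):
                fac *= a ** g.exponent
            # derivative through the instantaneous gates only
            dfac_inst = 0.0
            for k, g in enumerate(cur.gates):
                if g.instantaneous:
                    dfac_inst += _dprod_term(cur.gates, vals, k) * g.dinf_dv(v)
            df_dv += cur.G * (-fac + (cur.E - v) * dfac_inst)
            for k, g in enumerate(cur.gates):
                if g.instantaneous:
                    continue
                j = dyn.index(g)
                df_da[j] += cur.G * (cur.E - v) * _dprod_term(cur.gates, vals, k)
        dainf = np.array([g.dinf_dv(v) for g in dyn])
        tau = self.gate_time_constants(v)
        return df_dv / self.C_sigma, df_da / self.C_sigma, dainf, tau


def _dprod_term(gates, vals, k):
    """d/d(a_k) of prod_j a_j^{p_j}: p_k a_k^{p_k - 1} * prod_{j != k} a_j^{p_j}."""
    g = gates[k]
    a = vals[k]
    term = float(g.exponent) * (a ** (g.exponent - 1) if g.exponent != 1 else 1.0)
    for j, (gj, aj) in enumerate(zip(gates, vals)):
        if j != k:
            term *= aj ** gj.exponent
    return term


def soma_rhs(soma: SomaModel, v: float, gating: Sequence[float], I_ext: float = 0.0) -> float:
    """dv/dt of the soma at (v, gating) with external current I_ext (mV/ms).

    Instantaneous gates are substituted by their steady-state curves; dynamic
    gate values are supplied in ``gating`` and must lie in [0, 1].
    """
    if not np.isfinite(v):
        raise ValueError("non-finite somatic voltage v")
    gating = np.asarray(gating, dtype=float)
    if gating.shape != (soma.n_gates,):
        raise ValueError(
            f"expected {soma.n_gates} dynamic gating values, got {gating.shape}"
        )
    for g, a in zip(soma.dynamic_gates, gating):
        if not np.isfinite(a):
            raise ValueError(f"non-finite gating variable {g.name!r}")
        if not (0.0 <= a <= 1.0):
            raise ValueError(f"gating variable {g.name!r} outside [0, 1]: {a}")
    return soma.f_S(v, gating, I_ext)


def morris_lecar_soma(
    C_sigma: float = 20.0,
    G_sigma: float = 2.0,
    E_L: float = -60.0,
    G_Ca: float = 4.0,
    E_Ca: float = 120.0,
    G_K: float = 8.0,
    E_K: float = -80.0,
    V1: float = -1.2,
    V2: float = 18.0,
    V3: float = 12.0,
    V4: float = 17.4,
    phi: float = 1.0 / 15.0,
) -> SomaModel:
    """Morris-Lecar soma in the class-I excitability regime.

    The Ca2+ activation m is instantaneous; the K+ activation w is the single
    dynamic gate with tau_w(v) = 1 / (phi cosh((v - V3) / (2 V4))).  The
    default values place spiking onset at a saddle-node on an invariant cycle
    for a soma in isolation (class I), with G_sigma = 2 nS and C_sigma = 20 pF.
    """

    def m_inf(v, V1=V1, V2=V2):
        return 0.5 * (1.0 + math.tanh((v - V1) / V2))

    def dm_inf(v, V1=V1, V2=V2):
        return 0.5 / (V2 * math.cosh((v - V1) / V2) ** 2)

    def w_inf(v, V3=V3, V4=V4):
        return 0.5 * (1.0 + math.tanh((v - V3) / V4))

    def dw_inf(v, V3=V3, V4=V4):
        return 0.5 / (V4 * math.cosh((v - V3) / V4) ** 2)

    def tau_w(v, V3=V3, V4=V4, phi=phi):
        return 1.0 / (phi * math.cosh((v - V3) / (2.0 * V4)))

    m = Gate("m", m_inf, tau=None, dinf=dm_inf)
    w = Gate("w", w_inf, tau=tau_w, dinf=dw_inf)
    soma = SomaModel(
        C_sigma=C_sigma,
        G_sigma=G_sigma,
        E_L=E_L,
        currents=(
            ActiveCurrent("Ca", G_Ca, E_Ca, gates=(m,)),
            ActiveCurrent("K", G_K, E_K, gates=(w,)),
        ),
        name="morris-lecar",
    )
    soma._ml_params = (
        C_sigma, G_sigma, E_L, G_Ca, E_Ca, G_K, E_K, V1, V2, V3, V4, phi,
    )
    return soma
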