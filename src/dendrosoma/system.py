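"""Dendrite-and-soma (DS) systems and their compartmental discretisation.

The DS model couples an active point soma to a spatially continuous passive
cable through continuity of potential at x = 0 and a sealed end at x = L:

    dv_sigma/dt = f_S(a, v_sigma) + I_ext/C_sigma
                  + (rho G_sigma lambda / C_sigma) dv_delta/dx |_{x=0}
    tau_delta dv_delta/dt = E_L - v_delta + lambda^2 d^2 v_delta / dx^2

For simulation the cable is discretised into M evenly spaced compartments
(cell-centred second-order scheme; the sealed end is a natural no-flux
boundary of the finite-volume stencil and the soma couples to the first
compartment through a half-segment axial conductance).  Every electrical
quantity depends on the cable only through (tau_delta, rho, ell), so the
discretised equations are written in electrotonic units with step
h = ell / M.

A semi-infinite cable is simulated as a finite cable truncated at ell = 5,
beyond which the distal end is electrically invisible; analytic operations
elsewhere in the package use the true semi-infinite formulas.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dendrite import DendriteSpec
from .soma import SomaModel, morris_lecar_soma

__all__ = ["DSSystem", "ds_system", "discretise"]

SEMI_INFINITE_TRUNCATION = 5.0  # electrotonic length used to simulate ell = inf


@dataclass
class DSSystem:
    """A soma, a cable, and a compartmental resolution.

    State layout: ``[v_sigma, dynamic gates..., v_delta[1..M]]``.  When
    ``dendrite.tau_delta == 0`` the cable is instantaneous and the system
    reduces exactly to a point neuron with leak G_in; the cable states are
    then dropped (M contributes no state).
    """

    soma: SomaModel
    dendrite: DendriteSpec
    M: int = 50

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")

    # -- geometry ----------------------------------------------------------

    @property
    def ell_eff(self) -> float:
        """Electrotonic length used for discretisation (truncated if inf)."""
        if self.dendrite.ell is None:
            return SEMI_INFINITE_TRUNCATION
        return self.dendrite.ell

    @property
    def h(self) -> float:
        """Electrotonic compartment length ell_eff / M."""
        return self.ell_eff / self.M

    @property
    def dx(self) -> float | None:
        """Physical compartment length (um) when lambda_ is known."""
        lam = self.dendrite.lambda_
        return None if lam is None else self.h * lam

    @property
    def instantaneous_cable(self) -> bool:
        return self.dendrite.tau_delta == 0.0

    @property
    def n_cable(self) -> int:
        return 0 if self.instantaneous_cable else self.M

    @property
    def n_state(self) -> int:
        return 1 + self.soma.n_gates + self.n_cable

    @property
    def G_in(self) -> float:
        return self.dendrite.G_in(self.soma.G_sigma)

    def G_in_discrete(self) -> float:
        """DC input conductance of the discretised cable (nS).

        Differs from the analytic G_in by the O(h^2) truncation error of the
        compartmental scheme; simulation-based protocols that compare against
        saddle-node currents use this value so that sub-0.1 pA current
        offsets are meaningful.
        """
        if self.instantaneous_cable or self.dendrite.rho == 0.0:
            return self.G_in
        M, h = self.M, self.h
        c = 1.0 / h ** 2
        A = np.zeros((M, M))
        b = np.zeros(M)
        for i in range(M):
            A[i, i] = -1.0
            if i == 0:
                A[i, i] -= 2.0 * c
                b[i] = -2.0 * c  # coupling to v_sigma = 1 (E_L = 0 gauge)
                if M > 1:
                    A[i, i] -= c
                    A[i, 1] += c
            elif i == M - 1:
                A[i, i] -= c
                A[i, i - 1] += c
            else:
                A[i, i] -= 2.0 * c
                A[i, i - 1] += c
                A[i, i + 1] += c
        v = np.linalg.solve(A, b)
        g_ax = 2.0 * self.dendrite.rho * self.soma.G_sigma / h
        return float(self.soma.G_sigma + g_ax * (1.0 - v[0]))

    # -- state helpers -----------------------------------------------------

    def initial_state(self, v: float | None = None) -> np.ndarray:
        """Uniform state at voltage v (default E_L) with gates at rest."""
        if v is None:
            v = self.soma.E_L
        y = np.empty(self.n_state)
        y[0] = v
        y[1:1 + self.soma.n_gates] = self.soma.gate_steady_states(v)
        y[1 + self.soma.n_gates:] = v
        return y

    def cable_centres(self) -> np.ndarray:
        """Electrotonic coordinates of the compartment centres."""
        return (np.arange(self.M) + 0.5) * self.h

    def equilibrium_profile(self, v_sigma: float) -> np.ndarray:
        """Closed-form steady cable profile for somatic potential v_sigma.

        v*(xi) = E_L + (v_sigma - E_L) cosh(ell - xi) / cosh(ell) for the
        finite cable (exp(-xi) for the truncated semi-infinite cable uses the
        same formula with ell = ell_eff, which is indistinguishable at
        ell >= 5).
        """
        xi = self.cable_centres()
        ell = self.ell_eff
        E_L = self.soma.E_L
        return E_L + (v_sigma - E_L) * np.cosh(ell - xi) / math.cosh(ell)

    def state_from_vsigma(self, v_sigma: float) -> np.ndarray:
        """Full equilibrium state implied by a somatic potential."""
        y = np.empty(self.n_state)
        y[0] = v_sigma
        y[1:1 + self.soma.n_gates] = self.soma.gate_steady_states(v_sigma)
        if self.n_cable:
            y[1 + self.soma.n_gates:] = self.equilibrium_profile(v_sigma)
        return y

    # -- dynamics ----------------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, I_ext: float = 0.0) -> np.ndarray:
        """Time derivative of the full state (autonomous; t is ignored)."""
        soma = self.soma
        K = soma.n_gates
        v = y[0]
        a = y[1:1 + K]
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise FloatingPointError(f"non-finite state component at index {bad}")
        dy = np.empty_like(y)
        dy[0] = soma.f_S(v, a, I_ext)
        ainf = soma.gate_steady_states(v)
        tau = soma.gate_time_constants(v)
        dy[1:1 + K] = (ainf - a) / tau

        if self.instantaneous_cable:
            # quasi-static cable acts as an extra leak G_in - G_sigma
            G_extra = self.dendrite.G_delta(soma.G_sigma)
            dy[0] += G_extra * (soma.E_L - v) / soma.C_sigma
            return dy

        vd = y[1 + K:]
        td = self.dendrite.tau_delta
        c = 1.0 / self.h ** 2
        lap = np.empty(self.M)
        lap[0] = c * ((vd[1] - vd[0]) if self.M > 1 else 0.0) + 2.0 * c * (v - vd[0])
        if self.M > 1:
            lap[1:-1] = c * (vd[2:] - 2.0 * vd[1:-1] + vd[:-2])
            lap[-1] = c * (vd[-2] - vd[-1])
        dy[1 + K:] = (soma.E_L - vd + lap) / td
        # axial current into the soma through the half-segment conductance
        g_ax = 2.0 * self.dendrite.rho * soma.G_sigma / self.h
        dy[0] += g_ax * (vd[0] - v) / soma.C_sigma
        return dy

    def jacobian(self, y: np.ndarray, I_ext: float = 0.0) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs` at state y."""
        soma = self.soma
        K = soma.n_gates
        n = self.n_state
        v = y[0]
        a = y[1:1 + K]
        J = np.zeros((n, n))
        df_dv, df_da = soma_partials_at_state(soma, v, a)
        J[0, 0] = df_dv
        J[0, 1:1 + K] = df_da
        h = 1e-4
        for k, g in enumerate(soma.dynamic_gates):
            tau = g.tau(v)
            dtau = (g.tau(v + h) - g.tau(v - h)) / (2.0 * h)
            J[1 + k, 0] = g.dinf_dv(v) / tau - (g.inf(v) - a[k]) * dtau / tau ** 2
            J[1 + k, 1 + k] = -1.0 / tau

        if self.instantaneous_cable:
            J[0, 0] -= self.dendrite.G_delta(soma.G_sigma) / soma.C_sigma
            return J

        td = self.dendrite.tau_delta
        c = 1.0 / self.h ** 2
        i0 = 1 + K
        for i in range(self.M):
            J[i0 + i, i0 + i] = -1.0 / td
            if i > 0:
                J[i0 + i, i0 + i - 1] += c / td
                J[i0 + i, i0 + i] -= c / td
            if i < self.M - 1:
                J[i0 + i, i0 + i + 1] += c / td
                J[i0 + i, i0 + i] -= c / td
        # soma coupling of the first compartment
        J[i0, 0] += 2.0 * c / td
        J[i0, i0] -= 2.0 * c / td
        g_ax = 2.0 * self.dendrite.rho * soma.G_sigma / self.h
        J[0, 0] -= g_ax / soma.C_sigma
        J[0, i0] += g_ax / soma.C_sigma
        return J


def soma_partials_at_state(soma: SomaModel, v: float, gating) -> tuple[float, np.ndarray]:
    """(df_S/dv, df_S/da) at an arbitrary state.

    Dynamic gates are held at the supplied values while instantaneous gates
    track v on their steady-state curves.
    """
    from .soma import _dprod_term

    dyn = soma.dynamic_gates
    df_dv = -soma.G_sigma
    df_da = np.zeros(len(dyn))
    for cur in soma.currents:
        vals = [g.inf(v) if g.instantaneous else float(gating[dyn.index(g)])
                for g in cur.gates]
        fac = 1.0
        for g, val in zip(cur.gates, vals):
            fac *= val ** g.exponent
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
    C = soma.C_sigma
    return df_dv / C, df_da / C


def discretise(system: DSSystem):
    """Return (rhs, jac) callables for the (1 + K + M)-dimensional ODE.

    ``rhs(t, y, I_ext=0)`` and ``jac(y, I_ext=0)``; the Jacobian is analytic
    and matches finite differences of the rhs.
    """
    return system.rhs, system.jacobian


def ds_system(
    G_in: float,
    tau_delta: float,
    ell: float | None = None,
    M: int = 50,
    soma: SomaModel | None = None,
    lambda_: float | None = None,
) -> DSSystem:
    """Convenience constructor from the bifurcation parameters (G_in, tau_delta).

    ``ell=None`` requests a semi-infinite cable (simulated truncated at
    ell = 5).  The default soma is the class-I Morris-Lecar model.
    """
    if soma is None:
        soma = morris_lecar_soma()
    dend = DendriteSpec.from_G_in(G_in, soma.G_sigma, tau_delta, ell=ell, lambda_=lambda_)
    return DSSystem(soma=soma, dendrite=dend, M=M)
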