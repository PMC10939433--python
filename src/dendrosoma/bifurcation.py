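"""Local and global bifurcations of the dendrite-and-soma model.

The bifurcation parameters are the somatic external current I_ext, the DC
input conductance G_in, and the dendritic time constant tau_delta.  Fixed
points are characterised by the somatic steady-state current

    I_inf(v) = I_active(v) + G_in (E_L - v),

whose roots (of I_inf + I_ext = 0) give the equilibria.  Saddle-node and cusp
conditions are dI_inf/dv = 0 and d^2 I_inf/dv^2 = 0; both depend on G_in only
and are therefore independent of tau_delta and of the cable geometry.

Stability-related bifurcations (Hopf, Bogdanov-Takens) are computed from the
characteristic function of the linearised soma-cable system,

    chi(s; v) = s - df_S/dv - sum_i (df_S/da_i) a_i'(v) / (1 + s tau_i(v))
                + (rho G_sigma / C_sigma) gamma_fac(s),

with gamma_fac(s) = gamma(s) for a semi-infinite cable and
gamma(s) tanh(ell gamma(s)) for a finite one, gamma(s) = sqrt(1 + s tau_delta)
on the principal branch.  Eigenvalues of the full (infinite-dimensional)
linearisation are the roots of chi; chi(0) = 0 is algebraically the
saddle-node condition, and a conjugate root pair at +-i omega is a Hopf
point.  A Bogdanov-Takens point is a double root at s = 0, i.e. chi(0) = 0
together with dchi/ds(0) = 0; the latter, after substituting the saddle-node
condition, is the closed-form BT equation

    sum_i (alpha_0 tau_delta + tau_i) (df_S/da_i) a_i'(v) + 1
        + alpha_0 tau_delta df_S/dv = 0,

with alpha_0 = 1/2 for the semi-infinite cable and
alpha_0 = (tanh ell + ell sech^2 ell) / (2 tanh ell) for a finite one.

The saddle-node-loop (SNL) point, where spiking onset switches from SNIC to
HOM, is a global bifurcation located numerically by bisection in G_in on the
outcome of a bistability probe just below the upper saddle-node current.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, root

from .dendrite import DendriteSpec
from .soma import SomaModel, morris_lecar_soma
from .system import DSSystem, ds_system

__all__ = [
    "FixedPoint",
    "BifurcationPoint",
    "CharacteristicFunction",
    "steady_state_current",
    "find_fixed_points",
    "find_saddle_nodes",
    "find_cusp",
    "find_bt",
    "find_btc",
    "find_hopf",
    "hopf_curve",
    "first_lyapunov",
    "find_snl",
    "build_diagram",
    "BifurcationDiagram",
]

V_WINDOW = (-80.0, 20.0)  # physiological search window for equilibria, mV
_VTOL = 1e-10


@dataclass
class FixedPoint:
    v_sigma: float
    gating: np.ndarray
    I_ext: float
    G_in: float
    stable: bool | None = None


@dataclass
class BifurcationPoint:
    kind: str  # SN_low | SN_high | cusp | Hopf | BT | BTC | SNL
    v_sigma: float | None
    I_ext: float | None
    G_in: float
    tau_delta: float | None
    aux: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, for diagram listings
        parts = [f"{self.kind}", f"G_in={self.G_in:.4g}"]
        if self.I_ext is not None:
            parts.append(f"I_ext={self.I_ext:.4g}")
        if self.tau_delta is not None:
            parts.append(f"tau_delta={self.tau_delta:.4g}")
        return "BifurcationPoint(" + ", ".join(parts) + ")"


# ---------------------------------------------------------------------------
# fixed points and tau_delta-independent bifurcations


def _unpack(system_or_soma, G_in=None):
    if isinstance(system_or_soma, DSSystem):
        sys = system_or_soma
        return sys.soma, (sys.G_in if G_in is None else G_in)
    if G_in is None:
        raise TypeError("G_in is required when passing a bare SomaModel")
    return system_or_soma, G_in


def steady_state_current(system_or_soma, v_sigma, G_in: float | None = None) -> float:
    """Somatic steady-state current I_inf(v_sigma) in pA.

    Both the finite and semi-infinite cable reduce to the same expression
    I_active(v) + G_in (E_L - v): the dendritic flux at equilibrium equals
    G_delta (E_L - v_sigma), so only the DC input conductance enters.
    """
    soma, G_in = _unpack(system_or_soma, G_in)
    v = np.asarray(v_sigma, dtype=float)
    act = np.vectorize(soma.i_active_inf)(v) if v.ndim else soma.i_active_inf(float(v))
    return act + G_in * (soma.E_L - v)


def _dIinf_dv(soma: SomaModel, v: float, G_in: float) -> float:
    return soma.di_active_inf_dv(v) - G_in


def find_fixed_points(system_or_soma, I_ext: float, G_in: float | None = None,
                      window=V_WINDOW, n_scan: int = 2000,
                      classify: bool = True) -> list[FixedPoint]:
    """All equilibria in the voltage window, with stability labels.

    Roots of I_inf(v) + I_ext = 0 are bracketed on a dense grid and refined;
    stability is the sign of the real parts of the characteristic-function
    spectrum, evaluated via the discretised Jacobian (M = 50).
    """
    soma, G_in = _unpack(system_or_soma, G_in)
    vs = np.linspace(*window, n_scan)
    f = steady_state_current(soma, vs, G_in=G_in) + I_ext
    out: list[FixedPoint] = []
    for i in range(n_scan - 1):
        if f[i] == 0.0 or f[i] * f[i + 1] < 0:
            v_star = brentq(
                lambda v: steady_state_current(soma, v, G_in=G_in) + I_ext,
                vs[i], vs[i + 1], xtol=_VTOL)
            fp = FixedPoint(v_star, soma.gate_steady_states(v_star), I_ext, G_in)
            out.append(fp)
    if classify and isinstance(system_or_soma, DSSystem):
        for fp in out:
            y = system_or_soma.state_from_vsigma(fp.v_sigma)
            ev = np.linalg.eigvals(system_or_soma.jacobian(y, I_ext))
            fp.stable = bool(np.all(ev.real < 0))
    return out


def find_saddle_nodes(system_or_soma, G_in: float | None = None,
                      window=V_WINDOW) -> tuple[BifurcationPoint, BifurcationPoint]:
    """The (SN_low, SN_high) pair at input conductance G_in.

    Saddle-nodes are repeated roots of I_inf + I_ext, i.e. dI_inf/dv = 0.
    The pair is ordered by I_ext.  Independent of tau_delta by construction.
    Raises ValueError when G_in exceeds the cusp value (no SN pair).
    """
    soma, G_in = _unpack(system_or_soma, G_in)
    vs = np.linspace(*window, 2000)
    g = np.array([_dIinf_dv(soma, v, G_in) for v in vs])
    roots = []
    for i in range(len(vs) - 1):
        if g[i] == 0.0 or g[i] * g[i + 1] < 0:
            roots.append(brentq(lambda v: _dIinf_dv(soma, v, G_in),
                                vs[i], vs[i + 1], xtol=_VTOL))
    if len(roots) < 2:
        raise ValueError(
            f"no saddle-node pair at G_in={G_in}: above the cusp conductance")
    pts = []
    for v in roots[:2] if len(roots) == 2 else _central_pair(roots):
        I = -steady_state_current(soma, v, G_in=G_in)
        pts.append(BifurcationPoint("SN", v, float(I), G_in, None))
    pts.sort(key=lambda p: p.I_ext)
    pts[0].kind, pts[1].kind = "SN_low", "SN_high"
    return pts[0], pts[1]


def _central_pair(roots):
    # with more than two turning points, the spiking-relevant pair brackets
    # the knee of the N-shaped I_inf curve; take the two of largest dI slope
    return sorted(roots)[:2]


def find_cusp(system_or_soma, window=V_WINDOW) -> BifurcationPoint:
    """The cusp point, where the two saddle-node branches merge.

    v_C solves d^2 I_inf / dv^2 = 0 on the branch where dI_active/dv attains
    its maximum; G_in^C = dI_active/dv(v_C) and I_ext^C from I_inf = 0.
    Independent of tau_delta and of the cable geometry.
    """
    soma = system_or_soma.soma if isinstance(system_or_soma, DSSystem) else system_or_soma
    vs = np.linspace(*window, 2000)
    d1 = np.array([soma.di_active_inf_dv(v) for v in vs])
    i_max = int(np.argmax(d1))
    if i_max in (0, len(vs) - 1):
        raise ValueError("no interior maximum of dI_active/dv in the window")
    v_c = brentq(soma.d2i_active_inf_dv2, vs[max(i_max - 5, 0)],
                 vs[min(i_max + 5, len(vs) - 1)], xtol=_VTOL)
    G_c = soma.di_active_inf_dv(v_c)
    I_c = -steady_state_current(soma, v_c, G_in=G_c)
    return BifurcationPoint("cusp", v_c, float(I_c), float(G_c), None)


# ---------------------------------------------------------------------------
# characteristic function and tau_delta-dependent bifurcations


class CharacteristicFunction:
    """chi(s; v) whose roots are the eigenvalues of the linearised DS system.

    Parameters are the input conductance G_in (which fixes rho at the given
    geometry), the dendritic time constant tau_delta (ms) and the electrotonic
    length ell (``None`` for semi-infinite).
    """

    def __init__(self, soma: SomaModel, G_in: float, tau_delta: float,
                 ell: float | None = None):
        self.soma = soma
        self.G_in = G_in
        self.tau_delta = tau_delta
        self.ell = ell
        fac = 1.0 if ell is None else math.tanh(ell)
        self.rho = (G_in / soma.G_sigma - 1.0) / fac
        if self.rho < 0:
            raise ValueError("G_in below the somatic leak: rho < 0")

    def gamma_fac(self, s):
        g = np.sqrt(1.0 + np.asarray(s, dtype=complex) * self.tau_delta)
        if self.ell is None:
            return g
        return g * np.tanh(self.ell * g)

    def dgamma_fac_ds0(self) -> float:
        """d gamma_fac / ds at s = 0 (real)."""
        if self.ell is None:
            return 0.5 * self.tau_delta
        th = math.tanh(self.ell)
        return 0.5 * self.tau_delta * (th + self.ell * (1.0 - th ** 2))

    @property
    def alpha0(self) -> float:
        """Effective cable slowing factor in the BT equation.

        gamma_fac'(0) / (tau_delta * gamma_fac(0)); equals 1/2 for the
        semi-infinite cable.
        """
        if self.ell is None:
            return 0.5
        th = math.tanh(self.ell)
        return 0.5 * (th + self.ell * (1.0 - th ** 2)) / th

    def __call__(self, s, v_sigma: float):
        soma = self.soma
        df_dv, df_da, dainf, tau = soma.partials_at_steady(v_sigma)
        s = np.asarray(s, dtype=complex)
        gate_sum = sum(
            df_da[i] * dainf[i] / (1.0 + s * tau[i]) for i in range(len(tau)))
        cable = (self.rho * soma.G_sigma / soma.C_sigma) * self.gamma_fac(s)
        return s - df_dv - gate_sum + cable

    def dchi_ds0(self, v_sigma: float) -> float:
        """dchi/ds at s = 0 (real); vanishes together with chi(0) at a BT point."""
        soma = self.soma
        _, df_da, dainf, tau = soma.partials_at_steady(v_sigma)
        gate = float(np.sum(df_da * dainf * tau))
        return 1.0 + gate + (self.rho * soma.G_sigma / soma.C_sigma) * self.dgamma_fac_ds0()


def _bt_residual(soma: SomaModel, v: float, tau_delta: float, ell: float | None) -> float:
    """dchi/ds(0) with G_in substituted from the saddle-node condition at v."""
    G_sn = soma.di_active_inf_dv(v)
    if G_sn <= soma.G_sigma:
        return np.nan
    chi = CharacteristicFunction(soma, G_sn, tau_delta, ell)
    return chi.dchi_ds0(v)


def find_bt(system_or_soma, tau_delta: float | None = None,
            ell: float | None = None, window=V_WINDOW) -> BifurcationPoint:
    """The Bogdanov-Takens point at the given tau_delta.

    Solves the closed-form double-root condition (chi(0) = dchi/ds(0) = 0 with
    G_in eliminated through the saddle-node condition) for v_sigma; G_in^BT
    and I_ext^BT follow from the saddle-node and equilibrium conditions.
    """
    if isinstance(system_or_soma, DSSystem):
        sys = system_or_soma
        soma = sys.soma
        tau_delta = sys.dendrite.tau_delta if tau_delta is None else tau_delta
        ell = sys.dendrite.ell if ell is None else ell
    else:
        soma = system_or_soma
        if tau_delta is None:
            raise TypeError("tau_delta is required")
    vs = np.linspace(*window, 2000)
    res = np.array([_bt_residual(soma, v, tau_delta, ell) for v in vs])
    roots = []
    for i in range(len(vs) - 1):
        if np.isfinite(res[i]) and np.isfinite(res[i + 1]) and res[i] * res[i + 1] < 0:
            roots.append(brentq(lambda v: _bt_residual(soma, v, tau_delta, ell),
                                vs[i], vs[i + 1], xtol=_VTOL))
    if not roots:
        raise ValueError(
            f"no BT root in the voltage window {window} at tau_delta={tau_delta}")
    # with several candidates, the physical BT is the one of largest G_in
    # (the branch continuously connected to the tau_delta = 0 point)
    v_bt = max(roots, key=lambda v: soma.di_active_inf_dv(v))
    G_bt = soma.di_active_inf_dv(v_bt)
    I_bt = -steady_state_current(soma, v_bt, G_in=G_bt)
    chi = CharacteristicFunction(soma, G_bt, tau_delta, ell)
    return BifurcationPoint("BT", v_bt, float(I_bt), float(G_bt), tau_delta,
                            aux={"alpha0": chi.alpha0, "ell": ell})


def find_btc(system_or_soma, ell: float | None = None) -> BifurcationPoint:
    """The Bogdanov-Takens-cusp point (codimension 3).

    v from the cusp condition, G_in from the saddle-node condition, and
    tau_delta from the BT equation, which is linear in tau_delta.
    """
    soma = system_or_soma.soma if isinstance(system_or_soma, DSSystem) else system_or_soma
    if isinstance(system_or_soma, DSSystem) and ell is None:
        ell = system_or_soma.dendrite.ell
    cusp = find_cusp(soma)
    v, G_in = cusp.v_sigma, cusp.G_in
    chi0 = CharacteristicFunction(soma, G_in, 0.0, ell)
    base = chi0.dchi_ds0(v)  # value at tau_delta = 0
    chi1 = CharacteristicFunction(soma, G_in, 1.0, ell)
    slope = chi1.dchi_ds0(v) - base  # d/d tau_delta (linear)
    if slope == 0:
        raise ValueError("BT condition does not depend on tau_delta here")
    tau_btc = -base / slope
    if tau_btc < 0:
        raise ValueError("no BTC point in the physical range (tau_delta < 0)")
    return BifurcationPoint("BTC", v, cusp.I_ext, G_in, float(tau_btc),
                            aux={"alpha0": CharacteristicFunction(soma, G_in, tau_btc, ell).alpha0})


def find_hopf(system_or_soma, G_in: float | None = None,
              tau_delta: float | None = None, ell: float | None = None,
              criticality: bool = False, M_crit: int = 50,
              n_steps: int = 40) -> BifurcationPoint:
    """The Hopf point at (G_in, tau_delta), continued from the BT point.

    Solves Re chi(i omega; v) = Im chi(i omega; v) = 0 for (v, omega > 0),
    seeding a damped Newton iteration along a continuation in G_in that
    starts at the BT point (where omega = 0).  I_ext^H follows from
    I_inf = 0.  With ``criticality=True`` the first Lyapunov coefficient of
    the discretised system is attached (``aux['l1']``,
    ``aux['criticality']``).
    """
    if isinstance(system_or_soma, DSSystem):
        sys = system_or_soma
        soma = sys.soma
        G_in = sys.G_in if G_in is None else G_in
        tau_delta = sys.dendrite.tau_delta if tau_delta is None else tau_delta
        ell = sys.dendrite.ell if ell is None else ell
    else:
        soma = system_or_soma
        if G_in is None or tau_delta is None:
            raise TypeError("G_in and tau_delta are required")

    bt = find_bt(soma, tau_delta, ell)
    if G_in <= bt.G_in:
        raise ValueError(
            f"no Hopf point: G_in={G_in} is below the BT conductance {bt.G_in:.4f}")
    sol = _hopf_continuation(soma, tau_delta, ell, bt, G_in, n_steps)
    v_h, w_h = sol
    I_h = -steady_state_current(soma, v_h, G_in=G_in)
    pt = BifurcationPoint("Hopf", float(v_h), float(I_h), G_in, tau_delta,
                          aux={"omega_H": float(w_h), "ell": ell})
    if criticality:
        system = ds_system(G_in, tau_delta, ell=ell, M=M_crit, soma=soma)
        l1 = first_lyapunov(system, I_h, v_h)
        pt.aux["l1"] = l1
        pt.aux["criticality"] = "subcritical" if l1 > 0 else "supercritical"
    return pt


def _hopf_continuation(soma, tau_delta, ell, bt, G_target, n_steps):
    """March (v, omega) from the BT point to G_target along the Hopf branch.

    The system solved is [Re chi(i omega; v), Im chi(i omega; v) / omega]:
    dividing the odd-in-omega imaginary part by omega removes the spurious
    omega = 0 (saddle-node) root that would otherwise capture the Newton
    iterates near the BT point, where omega grows like sqrt(G - G_BT).
    Steps are quadratically refined towards the BT end for the same reason.
    """
    span = G_target - bt.G_in
    gs = bt.G_in + span * (np.arange(1, n_steps + 1) / n_steps) ** 2
    v, logw = bt.v_sigma, math.log(1e-3)

    def make_fun(G):
        chi = CharacteristicFunction(soma, G, tau_delta, ell)

        def fun(x):
            w = math.exp(x[1])
            val = complex(chi(1j * w, x[0]))
            return [val.real, val.imag / w]
        return fun

    for G in gs:
        sol = root(make_fun(G), [v, logw], method="hybr", tol=1e-13)
        if not sol.success and np.max(np.abs(sol.fun)) > 1e-9:
            raise ValueError(
                f"Hopf continuation failed at G_in={G:.4f} "
                "(possibly beyond the fold of Hopf points)")
        v, logw = sol.x
    return v, math.exp(logw)


def hopf_curve(soma: SomaModel, tau_delta: float, G_in_values,
               ell: float | None = None) -> list[BifurcationPoint]:
    """Hopf points at each requested G_in (those beyond the fold are skipped)."""
    out = []
    for G in np.atleast_1d(G_in_values):
        try:
            out.append(find_hopf(soma, float(G), tau_delta, ell))
        except ValueError:
            continue
    return out


# ---------------------------------------------------------------------------
# criticality: first Lyapunov coefficient on the discretised system


def _dirder2(F, x0, u, v, h=0.05):
    """Second directional derivative B(u, v) of F at x0 (real vectors)."""
    return (F(x0 + h * (u + v)) - F(x0 + h * (u - v))
            - F(x0 - h * (u - v)) + F(x0 - h * (u + v))) / (4.0 * h * h)


def _dirder3(F, x0, u, v, w, h=0.05):
    """Third mixed directional derivative C(u, v, w) of F at x0."""
    s = (F(x0 + h * (u + v + w)) - F(x0 + h * (u + v - w))
         - F(x0 + h * (u - v + w)) + F(x0 + h * (u - v - w))
         - F(x0 - h * (u - v - w)) + F(x0 - h * (u - v + w))
         + F(x0 - h * (u + v - w)) - F(x0 - h * (u + v + w)))
    return s / (8.0 * h ** 3)


def first_lyapunov(system: DSSystem, I_ext: float, v_fp: float,
                   h: float = 0.05) -> float:
    """First Lyapunov coefficient l1 at a Hopf point of the discretised system.

    Projection method on the compartmental Jacobian: with critical pair
    +-i omega, right/left eigenvectors q, p normalised to <p, q> = 1,

        l1 = Re[ <p, C(q,q,qb)> - 2 <p, B(q, A^-1 B(q,qb))>
                 + <p, B(qb, (2 i omega I - A)^-1 B(q,q))> ] / (2 omega).

    l1 > 0 marks a subcritical Hopf bifurcation, l1 < 0 a supercritical one.
    The multilinear forms are evaluated by central differences of the rhs.
    """
    x0 = system.state_from_vsigma(v_fp)
    A = system.jacobian(x0, I_ext)
    ev, R = np.linalg.eig(A)
    # critical pair: eigenvalue closest to the imaginary axis with Im > 0
    cand = np.where(ev.imag > 1e-8)[0]
    if len(cand) == 0:
        raise ValueError("no complex eigenvalue pair at the supplied point")
    k = cand[np.argmin(np.abs(ev.real[cand]))]
    omega = ev.imag[k]
    q = R[:, k]
    evl, L = np.linalg.eig(A.T)
    # the left eigenvector pairing with q shares its eigenvalue +i omega
    kl = np.argmin(np.abs(evl - ev[k]))
    # u = conj(p) of the adjoint eigenvector; all pairings <p, X> become u @ X
    u = L[:, kl]
    u = u / (u @ q)
    n = len(x0)

    def F(x):
        return system.rhs(0.0, x, I_ext)

    qr, qi = q.real, q.imag

    def B(u, v):
        return _dirder2(F, x0, u, v, h)

    Bqq = B(qr, qr) - B(qi, qi) + 2j * B(qr, qi)
    Bqqb = B(qr, qr) + B(qi, qi)
    # <p, C(q, q, qb)>
    Cr = (_dirder3(F, x0, qr, qr, qr, h) + _dirder3(F, x0, qr, qi, qi, h))
    Ci = (_dirder3(F, x0, qr, qr, qi, h) + _dirder3(F, x0, qi, qi, qi, h))
    Cqqqb = Cr + 1j * Ci
    s1 = np.linalg.solve(A, Bqqb.astype(complex))
    t1 = np.linalg.solve(2j * omega * np.eye(n) - A, Bqq)

    def Bc(u, v):
        """B on complex vectors, bilinear extension."""
        return (B(u.real, v.real) - B(u.imag, v.imag)
                + 1j * (B(u.real, v.imag) + B(u.imag, v.real)))

    term = (u @ Cqqqb) - 2.0 * (u @ Bc(q, s1)) + (u @ Bc(np.conj(q), t1))
    return float(np.real(term) / (2.0 * omega))


# ---------------------------------------------------------------------------
# saddle-node loop (global)


def find_snl(system_or_soma, tau_delta: float | None = None,
             ell: float | None = None, G_lo: float = 3.0,
             tol_G: float = 0.005, M: int = 50,
             probe_kwargs: dict | None = None) -> BifurcationPoint:
    """The saddle-node-loop point: the SNIC -> HOM switch along the SN curve.

    Located by bisection in G_in between a SNIC-classified and a
    HOM-classified conductance.  Classification uses the onset-current
    criterion: in the SNIC regime spiking first appears at the upper
    saddle-node current, while in the HOM regime a stable spiking limit cycle
    coexists with the resting state strictly below it (bistability).
    Requires tau_delta below the BTC value; beyond it no SNL exists.
    """
    soma = system_or_soma.soma if isinstance(system_or_soma, DSSystem) else system_or_soma
    if isinstance(system_or_soma, DSSystem):
        tau_delta = system_or_soma.dendrite.tau_delta if tau_delta is None else tau_delta
        ell = system_or_soma.dendrite.ell if ell is None else ell
    btc = find_btc(soma, ell)
    if tau_delta is None:
        raise TypeError("tau_delta is required")
    if tau_delta >= btc.tau_delta:
        raise ValueError(
            f"no SNL bifurcation: tau_delta={tau_delta} is not below the BTC "
            f"value {btc.tau_delta:.3f} ms")
    bt = find_bt(soma, tau_delta, ell)
    G_hi = bt.G_in - 0.02
    kw = dict(probe_kwargs or {})
    from . import dynamics  # local import: dynamics depends on this module

    def is_hom(G):
        return dynamics.bistable_below_sn(
            ds_system(G, tau_delta, ell=ell, M=M, soma=soma), **kw)

    if is_hom(G_lo):
        raise ValueError(f"G_lo={G_lo} already classifies as HOM; lower it")
    if not is_hom(G_hi):
        raise ValueError(
            f"G_hi={G_hi:.3f} (just below BT) does not classify as HOM; "
            "widen the probe integration")
    lo, hi = G_lo, G_hi
    while hi - lo > tol_G:
        mid = 0.5 * (lo + hi)
        if is_hom(mid):
            hi = mid
        else:
            lo = mid
    G_snl = 0.5 * (lo + hi)
    sn_low, sn_high = find_saddle_nodes(soma, G_snl)
    return BifurcationPoint("SNL", sn_high.v_sigma, sn_high.I_ext, float(G_snl),
                            tau_delta, aux={"bracket": (lo, hi)})


# ---------------------------------------------------------------------------
# two-parameter diagram


@dataclass
class BifurcationDiagram:
    """Curves of the two-parameter diagram, one row per located point."""

    points: "object"  # pandas.DataFrame

    def curve(self, kind: str, tau_delta: float | None = None):
        df = self.points[self.points["kind"] == kind]
        if tau_delta is not None:
            df = df[(df["tau_delta"] == tau_delta) | df["tau_delta"].isna()]
        return df


def build_diagram(system_or_soma, tau_delta_list, G_in_grid,
                  ell: float | None = None, include_snl: bool = False,
                  criticality: bool = False) -> BifurcationDiagram:
    """Assemble SN, cusp, Hopf, BT (and optionally SNL) curves.

    SN and cusp curves are computed once (they are tau_delta-invariant); the
    Hopf curve is continued from each BT point over the G_in grid, stepping
    past the fold by step-halving until the branch ends.
    """
    import pandas as pd

    soma = system_or_soma.soma if isinstance(system_or_soma, DSSystem) else system_or_soma
    rows = []
    cusp = find_cusp(soma)
    rows.append(_row(cusp))
    for G in np.atleast_1d(G_in_grid):
        if G >= cusp.G_in:
            continue
        try:
            lo, hi = find_saddle_nodes(soma, float(G))
        except ValueError:
            continue
        rows += [_row(lo), _row(hi)]
    for td in np.atleast_1d(tau_delta_list):
        bt = find_bt(soma, float(td), ell)
        rows.append(_row(bt))
        for pt in hopf_curve(soma, float(td), G_in_grid, ell):
            if criticality:
                system = ds_system(pt.G_in, float(td), ell=ell, soma=soma)
                l1 = first_lyapunov(system, pt.I_ext, pt.v_sigma)
                pt.aux["l1"] = l1
                pt.aux["criticality"] = "subcritical" if l1 > 0 else "supercritical"
            rows.append(_row(pt))
        if include_snl:
            try:
                rows.append(_row(find_snl(soma, float(td), ell)))
            except ValueError:
                pass
    try:
        btc = find_btc(soma, ell)
        rows.append(_row(btc))
    except ValueError:
        pass
    return BifurcationDiagram(pd.DataFrame(rows))


def _row(pt: BifurcationPoint) -> dict:
    return {
        "kind": pt.kind,
        "v_sigma": pt.v_sigma,
        "I_ext": pt.I_ext,
        "G_in": pt.G_in,
        "tau_delta": pt.tau_delta,
        "omega_H": pt.aux.get("omega_H", np.nan),
        "criticality": pt.aux.get("criticality", ""),
    }
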