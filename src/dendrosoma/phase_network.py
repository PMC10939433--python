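"""Phase reduction and network synchronisation of weakly coupled neurons.

For a pair of weakly coupled identical oscillators the phase difference
psi obeys  d psi/dt = Delta_omega + H(psi), with the coupling function H.
For instantaneous current-based synapses H is twice the odd part of the PRC,

    H(psi) = PRC(psi) - PRC(-psi),

so phase-locked states are the zeros of H (for zero detuning) and are stable
where H' < 0.  Network synchrony is summarised by

    R = sqrt( N/(N-1) * (sum_i psi_i^2 - 1/N) ),

where the psi_i are the N cyclic gaps between consecutive neuron phases
(summing to 1): R = 1 for the fully in-phase state and R = 0 for the splay
state.  Compartmental network simulations use impulse synapses -- a fixed
somatic voltage jump per presynaptic spike, zero delay -- calibrated against
the measured PRC.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .system import DSSystem
from . import dynamics as _dyn
from ._kernels import run_network

__all__ = [
    "CouplingFunction",
    "coupling_from_prc",
    "phase_locked_states",
    "simulate_phase_ode",
    "synchrony_R",
    "NetworkResult",
    "simulate_compartmental_network",
]


@dataclass
class CouplingFunction:
    """Periodic coupling function H(psi) on [0, 1)."""

    psi: np.ndarray
    H: np.ndarray
    delta_omega: float = 0.0  # detuning, cycles/ms
    source: object = None  # PRCurve it was derived from, if any
    _spline: CubicSpline = field(default=None, repr=False)

    def __post_init__(self):
        order = np.argsort(self.psi)
        p, h = self.psi[order], self.H[order]
        self._spline = CubicSpline(np.concatenate([p, [p[0] + 1.0]]),
                                   np.concatenate([h, [h[0]]]),
                                   bc_type="periodic")

    def __call__(self, psi):
        return self._spline(np.mod(psi, 1.0))

    def derivative(self, psi):
        return self._spline(np.mod(psi, 1.0), 1)


def coupling_from_prc(prc) -> CouplingFunction:
    """H(psi) = PRC(psi) - PRC(-psi) with periodic linear interpolation.

    For identical neurons H is odd about 0 (hence H(0) = H(1/2) = 0 up to
    interpolation error) and its zeros with negative slope are the stable
    phase locks of the pair.
    """
    theta = prc.theta
    y = prc.delta_theta
    if np.any(~np.isfinite(y)):
        raise ValueError("PRC contains non-finite values")
    # periodic interpolant of the PRC on [0, 1)
    tp = np.concatenate([theta - 1.0, theta, theta + 1.0])
    yp = np.concatenate([y, y, y])
    fwd = np.interp(theta, tp, yp)
    bwd = np.interp(-theta, tp, yp)
    return CouplingFunction(theta.copy(), fwd - bwd, source=prc)


def phase_locked_states(H: CouplingFunction, delta_omega: float = 0.0,
                        n_scan: int = 4000) -> list[tuple[float, bool]]:
    """Roots of Delta_omega + H(psi) with stability (H' < 0) flags."""
    from scipy.optimize import brentq

    psi = np.linspace(0.0, 1.0, n_scan, endpoint=False)
    f = delta_omega + H(psi)
    roots = []
    for i in range(n_scan):
        j = (i + 1) % n_scan
        a, b = psi[i], psi[i] + 1.0 / n_scan
        if f[i] == 0.0:
            roots.append(psi[i])
        elif f[i] * f[j] < 0:
            roots.append(brentq(lambda x: delta_omega + float(H(x)), a, b,
                                xtol=1e-12))
    out = []
    for r in roots:
        out.append((float(np.mod(r, 1.0)), bool(H.derivative(r) < 0)))
    return out


def simulate_phase_ode(H: CouplingFunction, delta_omega: float, psi0: float,
                       duration: float, dt: float = None) -> tuple[np.ndarray, np.ndarray]:
    """Integrate d psi/dt = Delta_omega + H(psi) with periodic wrapping.

    Time is in the same units as H (ms when H comes from an unnormalised
    PRC divided by the period, or ISIs when H is per cycle).  Fixed-step RK4.
    """
    if dt is None:
        amp = float(np.max(np.abs(H.H))) + abs(delta_omega)
        dt = min(0.01 / max(amp, 1e-12), duration / 100.0)
    n = int(np.ceil(duration / dt))
    t = np.empty(n + 1)
    psi = np.empty(n + 1)
    t[0], psi[0] = 0.0, np.mod(psi0, 1.0)
    x = psi[0]
    for k in range(n):
        f = lambda p: delta_omega + float(H(p))
        k1 = f(x)
        k2 = f(x + 0.5 * dt * k1)
        k3 = f(x + 0.5 * dt * k2)
        k4 = f(x + dt * k3)
        x = np.mod(x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 1.0)
        t[k + 1] = (k + 1) * dt
        psi[k + 1] = x
    return t, psi


def synchrony_R(psis) -> float:
    """Synchrony measure from the N cyclic phase gaps psi_i (sum to 1).

    R = sqrt(N/(N-1) (sum psi_i^2 - 1/N)): 1 for in-phase (one gap equals 1),
    0 for the splay state (all gaps 1/N).
    """
    psis = np.asarray(psis, dtype=float)
    n = len(psis)
    if n < 2:
        raise ValueError("need at least two phase differences")
    if np.any(psis < -1e-12):
        raise ValueError("phase differences must be non-negative")
    s = psis.sum()
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"phase differences must sum to 1 (got {s})")
    val = n / (n - 1) * (np.sum(psis ** 2) - 1.0 / n)
    if val < 1e-14:  # rounding noise below machine precision of the sum
        return 0.0
    return float(np.sqrt(val))


def phase_gaps(thetas) -> np.ndarray:
    """Cyclic gaps between sorted phases on the unit circle (sum to 1)."""
    th = np.sort(np.mod(np.asarray(thetas, dtype=float), 1.0))
    gaps = np.diff(np.concatenate([th, [th[0] + 1.0]]))
    return gaps


@dataclass
class NetworkResult:
    spike_times: list[np.ndarray]  # per neuron, ms
    t_cycles: np.ndarray  # reference-cycle times, ms
    psi: np.ndarray  # (n_cycles, N) cyclic phase gaps per cycle
    R: np.ndarray  # synchrony per cycle
    isi: float  # mean network ISI, ms
    params: dict = field(default_factory=dict)

    @property
    def t_isi(self) -> np.ndarray:
        """Cycle times in units of the network inter-spike interval."""
        return self.t_cycles / self.isi


def _network_phases(spike_trains, duration):
    """Per-cycle phase gaps and R from the spike rasters.

    Cycles are anchored to neuron 0's spikes; each neuron's phase is the
    elapsed fraction of the current cycle since its own last spike.
    """
    ref = spike_trains[0]
    out_t, out_psi, out_R = [], [], []
    for k in range(1, len(ref)):
        t0 = ref[k]
        T = ref[k] - ref[k - 1]
        if T <= 0:
            continue
        thetas = []
        ok = True
        for st in spike_trains:
            prev = st[st <= t0 + 1e-9]
            if len(prev) == 0:
                ok = False
                break
            thetas.append(((t0 - prev[-1]) / T) % 1.0)
        if not ok:
            continue
        gaps = phase_gaps(thetas)
        out_t.append(t0)
        out_psi.append(gaps)
        out_R.append(synchrony_R(gaps))
    return np.array(out_t), np.array(out_psi), np.array(out_R)


def simulate_compartmental_network(
        system: DSSystem, N: int, I_ext: float, v_jump: float,
        duration: float, init_phases, dt: float | None = None,
        threshold: float = _dyn.SPIKE_THRESHOLD) -> NetworkResult:
    """All-to-all network of N identical DS neurons with impulse synapses.

    Every neuron runs at the tonic-spiking current ``I_ext`` (typically the
    onset current, so all uncoupled rates are equal) and each presynaptic
    spike instantaneously adds ``v_jump`` mV to every other soma.  Initial
    conditions place each neuron at the requested phase of its unperturbed
    limit cycle.  Returns spike rasters plus per-cycle phase gaps and the
    synchrony trace R(t).
    """
    init_phases = np.asarray(init_phases, dtype=float)
    if init_phases.shape != (N,):
        raise ValueError("init_phases must have length N")
    if dt is None:
        dt = _dyn.default_dt(system)
    y0, t_ref = _dyn.limit_cycle_state(system, I_ext, dt=dt, threshold=threshold)
    Y0 = np.empty((N, system.n_state))
    for i, ph in enumerate(init_phases):
        ph = float(np.mod(ph, 1.0))
        if ph < 1e-9:
            Y0[i] = y0
        else:
            res = _dyn.integrate(system, I_ext, ph * t_ref, y0=y0, dt=dt,
                                 record_dt=0, threshold=threshold)
            Y0[i] = res.y_end
    p = _dyn._pack(system)
    W = np.full((N, N), float(v_jump))
    np.fill_diagonal(W, 0.0)
    sp_t, sp_i, n_sp, _ = run_network(Y0, p, np.full(N, float(I_ext)), W,
                                      float(duration), float(dt),
                                      float(threshold), _dyn._MAX_SPIKES)
    trains = [np.asarray(sp_t[sp_i == i]) for i in range(N)]
    for i, st in enumerate(trains):
        if len(st) == 0:
            raise RuntimeError(f"neuron {i} never spiked during the network run")
    t_c, psi, R = _network_phases(trains, duration)
    isi = float(np.mean(np.diff(trains[0]))) if len(trains[0]) > 1 else np.nan
    return NetworkResult(trains, t_c, psi, R, isi,
                         params={"N": N, "I_ext": I_ext, "v_jump": v_jump,
                                 "duration": duration, "dt": dt,
                                 "init_phases": init_phases.tolist(),
                                 "period_uncoupled": t_ref})
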