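"""Time integration, spike detection, onset currents, and phase-response curves.

The onset current is defined operationally, as in current-clamp experiments:
the smallest somatic current at which the neuron fires sustained regular
spikes at or above a target rate (1 Hz by default).  The search bisects with
downward continuation from a spiking state, so that in bistable (homoclinic)
regimes the spiking branch is followed below the upper saddle-node current.

Phase-response curves are measured by the direct method: at the onset
current, a tonically spiking neuron receives a single somatic voltage step
``delta_v`` at phase theta of its cycle, and the shift of the next spike is
recorded in units of the unperturbed period.  The perturbation is auto-tuned
so the peak advance stays in [0.05, 0.1] of a cycle (approximately linear
regime).  Phase zero is the upward crossing of the spike-detection threshold;
positive shifts are advances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import DSSystem
from . import _kernels

__all__ = [
    "SpikeTrain",
    "PRCurve",
    "default_dt",
    "integrate",
    "onset_current",
    "bistable_below_sn",
    "measure_prc",
    "classify_prc",
    "limit_cycle_state",
]

SPIKE_THRESHOLD = 0.0  # mV, upward crossing
_MAX_SPIKES = 200_000


@dataclass
class SpikeTrain:
    times: np.ndarray  # ms, strictly increasing
    threshold: float
    duration: float  # ms

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def rate(self) -> float:
        """Mean rate in Hz (count over duration)."""
        return 1000.0 * self.n / self.duration

    def isi(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def cv_isi(self) -> float:
        isi = self.isi()
        if len(isi) < 2:
            return np.nan
        return float(np.std(isi) / np.mean(isi))

    @property
    def regular(self) -> bool:
        return self.n >= 3 and self.cv_isi < 0.01


@dataclass
class Trajectory:
    t: np.ndarray
    v_sigma: np.ndarray
    y_end: np.ndarray
    spikes: SpikeTrain


@dataclass
class PRCurve:
    theta: np.ndarray  # phases in (0, 1)
    delta_theta: np.ndarray  # phase shift, cycle fraction (advance > 0)
    delta_v: float  # perturbation, mV
    I_ext: float  # pA
    period: float  # ms
    meta: dict = field(default_factory=dict)

    def normalised(self) -> np.ndarray:
        """PRC scaled to unit peak (for cross-model comparison)."""
        peak = np.max(self.delta_theta)
        if peak <= 0:
            raise ValueError("PRC has no positive peak to normalise by")
        return self.delta_theta / peak

    @property
    def peak_phase(self) -> float:
        return float(self.theta[int(np.argmax(self.delta_theta))])


def standard_phase_grid(n_phases: int = 100) -> np.ndarray:
    """Mid-bin phases theta_k = k/n - 1/(2n), k = 1..n (0.005, 0.015, ...)."""
    k = np.arange(1, n_phases + 1)
    return k / n_phases - 0.5 / n_phases


# ---------------------------------------------------------------------------
# low-level dispatch


def _pack(system: DSSystem) -> np.ndarray:
    mlp = system.soma._ml_params
    if mlp is None:
        raise NotImplementedError(
            "fast integration requires a Morris-Lecar-pattern soma "
            "(built by morris_lecar_soma)")
    C, G_sigma, E_L, G_Ca, E_Ca, G_K, E_K, V1, V2, V3, V4, phi = mlp
    if system.instantaneous_cable:
        # the cable collapses to an extra static leak: fold it into G_L
        G_eff = system.G_in
        return np.array([C, G_eff, E_L, G_Ca, E_Ca, G_K, E_K,
                         V1, V2, V3, V4, phi, 0.0, 0.0, 1.0])
    return np.array([C, G_sigma, E_L, G_Ca, E_Ca, G_K, E_K, V1, V2, V3, V4,
                     phi, system.dendrite.rho, system.dendrite.tau_delta,
                     system.h])


def _state(system: DSSystem, y0) -> np.ndarray:
    if y0 is None:
        return system.initial_state()
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (system.n_state,):
        raise ValueError(f"state must have shape ({system.n_state},)")
    return y0


def default_dt(system) -> float:
    """Largest step respecting RK4 stability of the cable, capped at 25 us."""
    if not isinstance(system, DSSystem):
        return system.default_dt()
    if system.instantaneous_cable:
        return 0.025
    td = system.dendrite.tau_delta
    c = 1.0 / system.h ** 2
    dt_cable = 0.8 * 2.78 * td / (4.0 * c + 1.0)
    return float(min(0.025, dt_cable))


def integrate(system: DSSystem, I_ext: float, duration: float,
              y0=None, dt: float | None = None, record_dt: float = 1.0,
              threshold: float = SPIKE_THRESHOLD,
              pert_time: float = -1.0, pert_dv: float = 0.0) -> Trajectory:
    """Fixed-step RK4 integration with interpolated spike times.

    ``record_dt <= 0`` disables trace recording (spikes are still detected).
    An optional single somatic voltage step (``pert_time``, ``pert_dv``)
    implements the PRC perturbation protocol.  Besides :class:`DSSystem`,
    any object exposing ``_kernel_run`` (e.g. a fully branched
    :class:`~dendrosoma.morphology.CompartmentalCell`) is accepted.
    """
    if dt is None:
        dt = default_dt(system)
    y0 = _state(system, y0)
    stride = max(int(round(record_dt / dt)), 1) if record_dt > 0 else 0
    if hasattr(system, "_kernel_run"):
        sp, n_sp, y_end, trace = system._kernel_run(
            y0, float(I_ext), float(duration), float(dt), float(threshold),
            float(pert_time), float(pert_dv), stride, _MAX_SPIKES)
    else:
        p = _pack(system)
        sp, n_sp, y_end, trace = _kernels.run_single(
            y0, p, float(I_ext), float(duration), float(dt), float(threshold),
            float(pert_time), float(pert_dv), stride, _MAX_SPIKES)
    if not np.all(np.isfinite(y_end)):
        raise FloatingPointError(
            f"trajectory diverged (last finite sample of v_sigma: "
            f"{trace[np.isfinite(trace)][-1] if len(trace) else 'n/a'})")
    t = np.arange(len(trace)) * stride * dt if stride else np.empty(0)
    return Trajectory(t, trace, y_end,
                      SpikeTrain(np.asarray(sp), threshold, duration))


# ---------------------------------------------------------------------------
# onset current


@dataclass
class OnsetResult:
    I_ext: float  # pA
    rate: float  # Hz achieved at onset
    rate_target: float
    spiking_state: np.ndarray  # a state on the spiking attractor at I_ext
    class_hint: str  # "class I" if rate ~ target, else "class II"


def _sustained(system, I_ext, y0, transient, window, rate_target, dt,
               min_spikes):
    """Probe for sustained regular spiking; returns (bool, rate, y_end, spikes)."""
    tr = integrate(system, I_ext, transient, y0=y0, dt=dt, record_dt=0)
    res = integrate(system, I_ext, window, y0=tr.y_end, dt=dt, record_dt=0)
    st = res.spikes
    ok = (st.n >= min_spikes and st.rate >= rate_target
          and st.times[-1] > 0.75 * window and st.cv_isi < 0.05)
    return ok, st.rate, res.y_end, st


def onset_current(system: DSSystem, rate_target: float = 1.0,
                  I_start: float = 20.0, I_ceiling: float = 400.0,
                  tol: float = 0.01, transient: float | None = None,
                  window: float | None = None, dt: float | None = None,
                  min_spikes: int = 10, search_factor: float = 1.2) -> OnsetResult:
    """Smallest I_ext with sustained spiking at >= rate_target Hz.

    Scans geometrically (factor ``search_factor``) from ``I_start`` until
    spiking appears, then bisects to ``tol`` (pA), each probe continuing from
    the most recent spiking state so the spiking branch is followed into
    bistable regions.  The scan factor is deliberately modest: the tonic
    spiking band is bounded above by depolarisation block (or the upper Hopf
    point), and a coarse doubling search can step right over it.  Raises if
    no tonic spiking is found up to ``I_ceiling`` (e.g. beyond the fold of
    Hopf points, where spiking is impossible at any current).
    """
    if transient is None:
        transient = 5.0 * 1000.0 / rate_target
    if window is None:
        window = (min_spikes + 2) * 1000.0 / rate_target
    if dt is None:
        dt = default_dt(system)
    I_hi = I_start
    y_spk = None
    while True:
        ok, rate, y_end, _ = _sustained(system, I_hi, None, transient, window,
                                        rate_target, dt, min_spikes)
        if ok:
            y_spk = y_end
            rate_hi = rate
            break
        if I_hi >= I_ceiling:
            raise ValueError(
                f"no tonic spiking found up to I_ext = {I_ceiling} pA")
        I_hi = min(search_factor * I_hi, I_ceiling)
    I_lo = 0.0
    while I_hi - I_lo > tol:
        mid = 0.5 * (I_lo + I_hi)
        ok, rate, y_end, _ = _sustained(system, mid, y_spk, transient, window,
                                        rate_target, dt, min_spikes)
        if ok:
            I_hi, rate_hi, y_spk = mid, rate, y_end
        else:
            I_lo = mid
    hint = "class I" if rate_hi < 2.0 * rate_target else "class II"
    return OnsetResult(I_hi, rate_hi, rate_target, y_spk, hint)


def bistable_below_sn(system: DSSystem, delta_I: float = 0.1,
                      transient: float = 10_000.0, window: float = 20_000.0,
                      burn_in: float | None = None, margin: float = 5.0,
                      dt: float | None = None, min_spikes: int = 5) -> bool:
    """Does a spiking attractor persist just below the upper saddle-node?

    Burns in above I_SN,high (where spiking is the only attractor in the
    SNIC/HOM regimes), then drops the current to I_SN,high - delta_I and asks
    whether spiking is sustained.  True marks the homoclinic (bistable)
    regime; False the SNIC regime, where the stable rest state recaptures the
    trajectory.  This probe is the classifier behind the saddle-node-loop
    search.

    The saddle-node current is evaluated at the *discretised* input
    conductance: the compartmental scheme's DC conductance differs from the
    analytic G_in at O(h^2), which shifts the fold current by about 0.1 pA --
    larger than ``delta_I`` would otherwise resolve.
    """
    from .bifurcation import find_saddle_nodes

    if dt is None:
        dt = default_dt(system)
    if burn_in is None:
        burn_in = transient
    _, sn_high = find_saddle_nodes(system.soma, system.G_in_discrete())
    tr = integrate(system, sn_high.I_ext + margin, burn_in, dt=dt, record_dt=0)
    probe_I = sn_high.I_ext - delta_I
    tr2 = integrate(system, probe_I, transient, y0=tr.y_end, dt=dt, record_dt=0)
    res = integrate(system, probe_I, window, y0=tr2.y_end, dt=dt, record_dt=0)
    st = res.spikes
    return bool(st.n >= min_spikes and st.times[-1] > 0.75 * window)


# ---------------------------------------------------------------------------
# phase-response curves


def limit_cycle_state(system: DSSystem, I_ext: float,
                      dt: float | None = None, threshold: float = SPIKE_THRESHOLD,
                      settle_spikes: int = 12):
    """A state at phase zero of the steady spiking cycle and the period.

    Runs until the inter-spike interval has converged, then returns the state
    at the first step boundary after a threshold crossing together with the
    reference period measured from that state (so the sub-step offset cancels
    from phase calculations downstream).
    """
    if dt is None:
        dt = default_dt(system)
    y = system.initial_state()
    period = 1000.0
    st = None
    for _ in range(6):
        res = integrate(system, I_ext, max(4000.0, (settle_spikes + 2) * period),
                        y0=y, dt=dt, record_dt=0, threshold=threshold)
        y = res.y_end
        st = res.spikes
        if st.n >= 2:
            period = float(np.mean(st.isi()))
        if st.n >= 4 and np.std(st.isi()[-3:]) < 1e-3 * np.mean(st.isi()[-3:]):
            break
    else:
        raise RuntimeError(f"spiking did not settle at I_ext={I_ext}")
    period = float(np.mean(st.isi()[-3:]))
    # land the state just past an upward crossing: rerun to the step boundary
    # right after the next spike
    res = integrate(system, I_ext, 1.5 * period, y0=y, dt=dt, record_dt=0,
                    threshold=threshold)
    t_sp = res.spikes.times[0]
    n_steps = int(np.ceil((t_sp + 0.5 * dt) / dt))
    res2 = integrate(system, I_ext, (n_steps - 0.5) * dt, y0=y, dt=dt,
                     record_dt=0, threshold=threshold)
    y0 = res2.y_end
    # reference next-spike time from the phase-zero state
    ref = integrate(system, I_ext, 1.6 * period, y0=y0, dt=dt, record_dt=0,
                    threshold=threshold)
    if ref.spikes.n == 0:
        raise RuntimeError("reference cycle lost the spike")
    t_ref = float(ref.spikes.times[0])
    return y0, t_ref


def _period_guess(res):
    if res is None or res.spikes.n < 2:
        return 1000.0
    return float(np.mean(res.spikes.isi()))


def _prc_pass(system, I_ext, y0, t_ref, thetas, delta_v, dt, threshold):
    # window of 3 periods: strong delays (Hopf-like responses) can push the
    # next spike well past the unperturbed cycle
    out = np.empty(len(thetas))
    for i, th in enumerate(thetas):
        res = integrate(system, I_ext, 3.0 * t_ref, y0=y0, dt=dt, record_dt=0,
                        threshold=threshold, pert_time=th * t_ref,
                        pert_dv=delta_v)
        sp = res.spikes.times
        sp = sp[sp > th * t_ref - 1e-9]
        if len(sp) == 0:
            out[i] = np.nan
        else:
            out[i] = (t_ref - sp[0]) / t_ref
    return out


def measure_prc(system: DSSystem, I_ext: float, delta_v: float | None = None,
                n_phases: int = 100, dt: float | None = None,
                threshold: float = SPIKE_THRESHOLD,
                target_peak: float = 0.075, max_retune: int = 5) -> PRCurve:
    """Direct-method PRC at tonic spiking under I_ext.

    When ``delta_v`` is None it is auto-tuned (on a coarse 10-phase pass) so
    the peak advance falls within [0.05, 0.1] cycles; perturbations that
    trigger an immediate spike at every phase are shrunk and retried.
    """
    if dt is None:
        dt = default_dt(system)
    y0, t_ref = limit_cycle_state(system, I_ext, dt=dt, threshold=threshold)
    thetas = standard_phase_grid(n_phases)
    auto = delta_v is None
    dv = 1.0 if auto else delta_v
    if auto:
        coarse = standard_phase_grid(10)
        for _ in range(max_retune):
            shifts = _prc_pass(system, I_ext, y0, t_ref, coarse, dv, dt, threshold)
            peak = np.nanmax(shifts) if np.any(np.isfinite(shifts)) else np.nan
            if not np.isfinite(peak) or peak <= 0 or np.any(np.isnan(shifts)):
                dv *= 0.5  # perturbation knocked the cycle out entirely
                continue
            if 0.05 <= peak <= 0.1:
                break
            dv = float(np.clip(dv * target_peak / peak, 1e-3, 25.0))
    shifts = _prc_pass(system, I_ext, y0, t_ref, thetas, dv, dt, threshold)
    return PRCurve(thetas, shifts, dv, I_ext, t_ref,
                   meta={"dt": dt, "threshold": threshold})


def classify_prc(prc: PRCurve, neg_area_thresh: float = 0.05,
                 hom_peak_phase: float = 0.45, neg_tol: float = 0.02) -> str:
    """Label a PRC as ``"SNIC"``, ``"HOM"`` or ``"Hopf"``.

    Hopf-like responses carry a substantial negative lobe (delay region);
    among non-negative PRCs, the homoclinic signature is a positive skew with
    the peak clearly before mid-cycle, while the SNIC form is symmetric with
    its peak near theta = 0.5.  Thresholds: negative lobe above
    ``neg_area_thresh`` of total |area| is Hopf-like; otherwise peak phase
    below ``hom_peak_phase`` is HOM; negative excursions within ``neg_tol``
    of the peak are ignored as noise.  Defaults separate the three onset
    classes with comfortable margins when the PRC is measured at onset (the
    1 Hz protocol).
    """
    y = prc.delta_theta
    y = y[np.isfinite(y)]
    if len(y) == 0:
        raise ValueError("PRC contains no finite values")
    peak = np.max(y)
    neg = np.clip(-y, 0.0, None)
    neg_area = float(np.sum(neg) / np.sum(np.abs(y)))
    if neg_area > neg_area_thresh and np.min(y) < -neg_tol * peak:
        return "Hopf"
    if prc.peak_phase < hom_peak_phase:
        return "HOM"
    return "SNIC"
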