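"""Passive input admittance and impedance of the S and DS models.

For an isopotential (S) neuron the input admittance is a first-order filter,
Y_in = G_L + i omega C_m.  Attaching a passive cable adds a frequency-
dependent dendritic term:

    Y_in(omega) = G_sigma + i omega C_sigma + rho G_sigma gamma(omega) tanh(ell gamma(omega))

for the finite cable, with the tanh factor dropping out in the semi-infinite
limit, where gamma(omega) = sqrt(1 + i omega tau_delta) on the principal
branch (Re gamma > 0).  At omega = 0 both forms reduce to the DC input
conductance G_in.  Frequencies are angular, in rad/ms.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dendrite import DendriteSpec

__all__ = [
    "gamma",
    "admittance_S",
    "admittance_DS",
    "ImpedanceSpectrum",
    "spectrum_S",
    "spectrum_DS",
    "compare_spectra",
    "default_omega_grid",
]


def default_omega_grid(n: int = 200) -> np.ndarray:
    """Log-spaced angular frequency grid, 1e-2 to 1e2 rad/ms."""
    return np.logspace(-2, 2, n)


def gamma(omega, tau_delta: float) -> np.ndarray:
    """Cable propagation factor sqrt(1 + i omega tau_delta), principal branch."""
    return np.sqrt(1.0 + 1j * np.asarray(omega, dtype=float) * tau_delta)


def admittance_S(G_L: float, C_m: float, omega) -> np.ndarray:
    """First-order input admittance of the point neuron (nS)."""
    if G_L <= 0:
        raise ValueError("G_L must be positive")
    return G_L + 1j * np.asarray(omega, dtype=float) * C_m


def admittance_DS(dendrite: DendriteSpec, G_sigma: float, C_sigma: float, omega) -> np.ndarray:
    """Somatic input admittance of the DS model (nS).

    Reduces to :func:`admittance_S` with G_L = G_in when tau_delta = 0.
    """
    g = gamma(omega, dendrite.tau_delta)
    fac = g if dendrite.ell is None else g * np.tanh(dendrite.ell * g)
    return G_sigma + 1j * np.asarray(omega, dtype=float) * C_sigma + dendrite.rho * G_sigma * fac


@dataclass
class ImpedanceSpectrum:
    """Admittance/impedance over a frequency grid, with provenance."""

    omega: np.ndarray
    Y_in: np.ndarray
    model: str  # "S", "DS-finite" or "DS-semi-infinite"
    params: dict = field(default_factory=dict)

    @property
    def Z_in(self) -> np.ndarray:
        return 1.0 / self.Y_in

    @property
    def G_in(self) -> float:
        """DC input conductance Y_in(omega -> 0)."""
        return float(np.real(self.Y_in[np.argmin(np.abs(self.omega))])) if 0.0 not in self.omega \
            else float(np.real(self.Y_in[list(self.omega).index(0.0)]))


def spectrum_S(G_L: float, C_m: float, omega=None) -> ImpedanceSpectrum:
    if omega is None:
        omega = default_omega_grid()
    omega = np.asarray(omega, dtype=float)
    return ImpedanceSpectrum(omega, admittance_S(G_L, C_m, omega), "S",
                             {"G_L": G_L, "C_m": C_m})


def spectrum_DS(dendrite: DendriteSpec, G_sigma: float, C_sigma: float,
                omega=None) -> ImpedanceSpectrum:
    if omega is None:
        omega = default_omega_grid()
    omega = np.asarray(omega, dtype=float)
    model = "DS-semi-infinite" if dendrite.ell is None else "DS-finite"
    return ImpedanceSpectrum(
        omega, admittance_DS(dendrite, G_sigma, C_sigma, omega), model,
        {"G_sigma": G_sigma, "C_sigma": C_sigma, "tau_delta": dendrite.tau_delta,
         "rho": dendrite.rho, "ell": dendrite.ell})


def compare_spectra(spectra: list[ImpedanceSpectrum], rtol: float = 1e-9):
    """Per-frequency |Z_in| table and pairwise dominance flags.

    All spectra must share the same omega grid and the same DC input
    conductance G_in (the comparison is only meaningful at matched G_in).
    Returns ``(table, dominates)`` where ``table[k]`` is |Z| for spectrum k
    and ``dominates[i][j]`` is True when |Z_i| >= |Z_j| at every omega > 0.
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to compare")
    omega = spectra[0].omega
    for sp in spectra[1:]:
        if sp.omega.shape != omega.shape or not np.allclose(sp.omega, omega):
            raise ValueError("spectra are on different frequency grids")
    g0 = np.real(spectra[0].Y_in[0]) if omega[0] == 0 else None
    gins = [float(np.real(admit_at_zero(sp))) for sp in spectra]
    del g0
    if max(gins) - min(gins) > rtol * max(1.0, abs(gins[0])) + 1e-9:
        raise ValueError(f"G_in mismatch across models: {gins}")
    table = [np.abs(sp.Z_in) for sp in spectra]
    nz = omega > 0
    dominates = [[bool(np.all(ti[nz] >= tj[nz] - 1e-15)) for tj in table] for ti in table]
    return table, dominates


def admit_at_zero(sp: ImpedanceSpectrum) -> complex:
    """DC admittance of a spectrum, evaluated exactly from its parameters."""
    p = sp.params
    if sp.model == "S":
        return complex(p["G_L"])
    rho, ell = p["rho"], p["ell"]
    fac = 1.0 if ell is None else np.tanh(ell)
    return complex(p["G_sigma"] * (1.0 + rho * fac))
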