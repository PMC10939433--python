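"""Passive dendritic cables and their reduced parametrisation.

The equivalent dendrite is described by four quantities: the passive time
constant tau_delta (ms), the electrotonic length constant lambda (um), the
physical length L (um, or semi-infinite), and the dendritic dominance factor
rho -- the ratio of the cable's characteristic conductance to the somatic leak
conductance.  The DC input conductance seen at the soma is

    G_in = G_sigma (1 + rho tanh(L / lambda))      (finite cable)
    G_in = G_sigma (1 + rho)                       (semi-infinite cable)
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DendriteSpec", "dendrite_from_biophysics"]


@dataclass(frozen=True)
class DendriteSpec:
    """Reduced description of a passive equivalent dendrite.

    ``ell`` is the electrotonic length L / lambda; ``None`` means the cable is
    semi-infinite.  ``lambda_`` (um) is only needed when a physical length is
    required (e.g. when writing morphologies); all electrical quantities
    depend on (tau_delta, rho, ell) alone.
    """

    tau_delta: float  # ms
    rho: float
    ell: float | None = None
    lambda_: float | None = None  # um

    def __post_init__(self) -> None:
        if self.tau_delta < 0:
            raise ValueError("tau_delta must be >= 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.ell is not None and self.ell <= 0:
            raise ValueError("ell must be positive for a finite cable")

    @property
    def semi_infinite(self) -> bool:
        return self.ell is None

    @property
    def L(self) -> float | None:
        """Physical length (um), when lambda_ is known."""
        if self.ell is None or self.lambda_ is None:
            return None
        return self.ell * self.lambda_

    @property
    def end_factor(self) -> float:
        """tanh(ell) for a finite cable, 1 for a semi-infinite one."""
        return 1.0 if self.ell is None else math.tanh(self.ell)

    def G_delta(self, G_sigma: float) -> float:
        """Dendritic contribution to the DC input conductance (nS)."""
        return self.rho * G_sigma * self.end_factor

    def G_in(self, G_sigma: float) -> float:
        """Total DC input conductance at the soma (nS)."""
        return G_sigma + self.G_delta(G_sigma)

    @classmethod
    def from_G_in(
        cls,
        G_in: float,
        G_sigma: float,
        tau_delta: float,
        ell: float | None = None,
        lambda_: float | None = None,
    ) -> "DendriteSpec":
        """Build the spec whose DC input conductance equals ``G_in``.

        Inverts G_in = G_sigma (1 + rho tanh(ell)); with ``ell=None`` the
        semi-infinite form G_in = G_sigma (1 + rho) is used.
        """
        if G_in < G_sigma:
            raise ValueError("G_in cannot be below the somatic leak G_sigma")
        fac = 1.0 if ell is None else math.tanh(ell)
        rho = (G_in / G_sigma - 1.0) / fac
        return cls(tau_delta=tau_delta, rho=rho, ell=ell, lambda_=lambda_)


def dendrite_from_biophysics(
    c_delta: float,
    g_delta: float,
    r_a: float,
    d: float,
    L: float | None,
    G_sigma: float,
) -> DendriteSpec:
    """Equivalent-dendrite parameters from per-area membrane properties.

    Parameters
    ----------
    c_delta : membrane capacitance per area, uF/cm^2
    g_delta : leak conductance per area, mS/cm^2
    r_a : axial resistivity, Ohm cm
    d : cable diameter, um
    L : cable length, um (``None`` for semi-infinite)
    G_sigma : somatic leak conductance, nS

    The defining relations are tau_delta = c_delta / g_delta,
    lambda = sqrt(d / (4 r_a g_delta)) and rho = pi d lambda g_delta /
    G_sigma.  Unit bookkeeping: uF/cm^2 over mS/cm^2 is ms directly; lengths
    are converted to cm for the radical and the conductance product, and the
    resulting characteristic conductance (S) is compared against G_sigma in
    nS.
    """
    for nm, val in (("c_delta", c_delta), ("g_delta", g_delta), ("r_a", r_a),
                    ("d", d), ("G_sigma", G_sigma)):
        if val <= 0:
            raise ValueError(f"{nm} must be positive")
    if L is not None and L <= 0:
        raise ValueError("L must be positive (or None for semi-infinite)")

    tau_delta = c_delta / g_delta  # ms
    d_cm = d * 1e-4
    g_S = g_delta * 1e-3  # S/cm^2
    lambda_cm = math.sqrt(d_cm / (4.0 * r_a * g_S))
    lambda_um = lambda_cm * 1e4
    G_char_S = math.pi * d_cm * lambda_cm * g_S  # characteristic conductance, S
    rho = G_char_S / (G_sigma * 1e-9)
    ell = None if L is None else L / lambda_um
    return DendriteSpec(tau_delta=tau_delta, rho=rho, ell=ell, lambda_=lambda_um)
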