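"""Run configuration: structured parameter files and reproducibility plumbing.

Configs are plain JSON or YAML mappings with two top-level sections, ``soma``
and ``dendrite``, plus optional run settings.  Every run echoes the fully
resolved parameter set (defaults filled in) to the log and to a JSON sidecar
next to the outputs, so a saved config reproduces the run exactly.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dendrite import DendriteSpec
from .soma import SomaModel, morris_lecar_soma
from .system import DSSystem

log = logging.getLogger("dendrosoma")

SOMA_KEYS = ("C_sigma", "G_sigma", "E_L", "G_Ca", "E_Ca", "G_K", "E_K",
             "V1", "V2", "V3", "V4", "phi")


@dataclass
class RunConfig:
    soma: dict = field(default_factory=dict)
    dendrite: dict = field(default_factory=dict)
    M: int = 50
    seed: int = 0
    outdir: str = "."
    extra: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {k: data.pop(k) for k in ("soma", "dendrite", "M", "seed", "outdir")
                 if k in data}
        return cls(**known, extra=data)

    def build_soma(self) -> SomaModel:
        bad = set(self.soma) - set(SOMA_KEYS)
        if bad:
            raise ValueError(f"unknown soma parameters: {sorted(bad)}")
        return morris_lecar_soma(**self.soma)

    def build_dendrite(self, G_sigma: float) -> DendriteSpec:
        d = dict(self.dendrite)
        tau_delta = d.pop("tau_delta", 10.0)
        ell = d.pop("ell", None)
        lambda_ = d.pop("lambda_", None)
        if "G_in" in d:
            return DendriteSpec.from_G_in(d.pop("G_in"), G_sigma, tau_delta,
                                          ell=ell, lambda_=lambda_)
        rho = d.pop("rho", 1.0)
        if d:
            raise ValueError(f"unknown dendrite parameters: {sorted(d)}")
        return DendriteSpec(tau_delta=tau_delta, rho=rho, ell=ell, lambda_=lambda_)

    def build_system(self) -> DSSystem:
        soma = self.build_soma()
        return DSSystem(soma, self.build_dendrite(soma.G_sigma), M=self.M)

    def resolved(self) -> dict:
        """The fully resolved parameter set, for echoing/serialisation."""
        soma = self.build_soma()
        dend = self.build_dendrite(soma.G_sigma)
        return {
            "soma": {k: soma._ml_params[i] for i, k in enumerate(SOMA_KEYS)},
            "dendrite": {"tau_delta": dend.tau_delta, "rho": dend.rho,
                         "ell": dend.ell, "lambda_": dend.lambda_,
                         "G_in": dend.G_in(soma.G_sigma)},
            "M": self.M, "seed": self.seed, "outdir": self.outdir,
            **({"extra": self.extra} if self.extra else {}),
        }

    def echo(self) -> None:
        log.info("resolved configuration: %s", json.dumps(self.resolved()))

    def write_sidecar(self, path) -> None:
        Path(path).write_text(json.dumps(self.resolved(), indent=2) + "\n")
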