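"""Flat run configuration with validation and provenance.

One RunConfig carries every tunable used across the pipeline; defaults
are the protocol's published values where published, otherwise the
documented package choices.  Configs load from simple ``key = value``
text files, and a stable hash of the configuration is written alongside
outputs for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

from .errors import ConfigurationError


@dataclass
class RunConfig:
    density: float = 5.0          # surface points / Å^2
    probe_radius: float = 1.4     # Å, water probe
    contact_cutoff: float = 8.0   # Å, Cα–Cα contact criterion
    occurrence_threshold: float = 0.25
    order: int = 20               # Zernike expansion order N
    grid_size: int = 64           # disk-image pixels per side
    patch_radius: float = 9.0     # Å
    weight_a: float = 10.0
    weight_b: float = 0.04
    weight_c: float = 32.1
    weight_d: float = 0.5
    beta: float = 1.0
    n_steps: int = 6000
    n_runs: int = 10
    max_mutations: int = 5
    top_k: int = 100
    dielectric: float = 1.0
    alphabet: str = "ADEFGHIKLMNPQRSTVWY"
    penalty_variant: str = "signed_quadratic"
    placer_backend: str = "naive"   # naive | scwrl4
    seed: int = 0

    def __post_init__(self):
        positive = (
            "density", "contact_cutoff", "patch_radius", "beta", "dielectric",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.probe_radius < 0:
            raise ConfigurationError("probe_radius must be >= 0")
        if not 0 <= self.occurrence_threshold <= 1:
            raise ConfigurationError("occurrence_threshold must be in [0, 1]")
        if self.order < 0:
            raise ConfigurationError("order must be >= 0")
        if self.grid_size < 8:
            raise ConfigurationError("grid_size must be >= 8")
        for name in ("n_steps", "n_runs", "top_k"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.max_mutations < 0:
            raise ConfigurationError("max_mutations must be >= 0")
        if self.penalty_variant not in ("signed_quadratic", "literal_cubic"):
            raise ConfigurationError(
                f"unknown penalty_variant {self.penalty_variant!r}"
            )
        if self.placer_backend not in ("naive", "scwrl4"):
            raise ConfigurationError(
                f"unknown placer_backend {self.placer_backend!r}"
            )
        if len(set(self.alphabet)) < 2:
            raise ConfigurationError("alphabet needs at least 2 residues")

    @classmethod
    def from_text(cls, text: str, **overrides) -> "RunConfig":
        """Parse ``key = value`` lines ('#' comments allowed) and apply
        keyword overrides on top (CLI precedence)."""
        values: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(
                    f"config line {lineno} is not 'key = value': {line!r}"
                )
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ConfigurationError(f"unknown config key {key!r} (line {lineno})")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                values[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                values[key] = int(raw)
            elif isinstance(current, float):
                values[key] = float(raw)
            else:
                values[key] = raw
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def provenance(self) -> dict:
        from . import __version__

        return {
            "package": "zernipep",
            "version": __version__,
            "config": self.to_dict(),
            "config_hash": self.digest(),
            "seed": self.seed,
        }
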