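"""Simulation configuration: parameter container, validation and (de)serialization.

All lengths are in µm, times in s, forces in pN, stiffnesses in pN/µm,
viscosity in pN·s/µm² and energies (kT) in pN·µm.

Several parameter values adopted by the original study live in supplementary
tables that are not redistributed here; the defaults below are documented
stand-ins chosen to sit in the physiological range and are all overridable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from ..errors import ConfigurationError

#: fold-increase of a nucleated filament's length happens over this many seconds
NUCLEATION_GROWTH_TIME_S = 20.0
#: initial length of a nucleated filament, µm
NUCLEATION_SEED_LENGTH_UM = 0.5
#: lattice-hand detachment rate, 1/s (the attachment rate is
#: ``complex_lattice_affinity`` times this, making the affinity dimensionless)
LATTICE_OFF_RATE_S = 1.0


@dataclass
class SimConfig:
    """All parameters of one simulation run.

    The two-phase protocol runs a motor/filament-only bundling phase for
    ``t_bundle`` seconds, adds ``n_complexes`` condensate complexes, then
    continues to ``t_total``.
    """

    # geometry / integration
    arena_radius: float = 10.0          # µm, circular arena with soft confinement
    dt: float = 0.005                   # s
    t_bundle: float = 100.0             # s, phase-1 duration
    t_total: float = 500.0              # s, full duration
    snapshot_interval: float = 25.0     # s, cadence of recorded snapshots

    # filaments
    n_filaments: int = 50
    filament_length: float = 8.0        # µm
    filament_rigidity: float = 20.0     # pN·µm² (microtubule flexural rigidity)
    filament_segment_length: float = 2.0  # µm, discretization target

    # bivalent minus-end-directed motor couplers
    n_hset: int = 200
    hset_binding_rate: float = 5.0      # 1/s within the capture range
    hset_unbinding_rate: float = 0.1    # 1/s (swept to vary processivity)
    hset_speed: float = 0.087           # µm/s, unloaded gliding speed
    hset_stall_force: float = 5.0       # pN
    hset_link_stiffness: float = 100.0  # pN/µm
    hset_binding_range: float = 0.05    # µm, capture radius
    hset_diffusion: float = 1.0         # µm²/s, free-coupler diffusion

    # condensate complexes
    n_complexes: int = 100
    complex_adhesive_on_rate: float = 5.0    # 1/s within range
    complex_adhesive_off_rate: float = 0.01  # 1/s
    complex_adhesive_range: float = 0.2      # µm
    complex_adhesive_stiffness: float = 50.0  # pN/µm
    complex_lattice_affinity: float = 1.0    # dimensionless k_on/k_off of the weak lattice hand
    complex_radius: float = 0.1              # µm, hydrodynamic radius (sets drag)
    nucleation_enabled: bool = False

    # medium
    viscosity: float = 1.0              # pN·s/µm² (cytoplasm-like)
    temperature_kT: float = 0.0042      # pN·µm (~300 K)
    confine_stiffness: float = 10.0     # pN/µm, inward push outside the arena

    seed: int = 0

    # ------------------------------------------------------------------ #

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if not self.t_bundle <= self.t_total:
            raise ConfigurationError(
                f"t_bundle ({self.t_bundle}) must be <= t_total ({self.t_total})"
            )
        if self.arena_radius <= 0:
            raise ConfigurationError("arena_radius must be positive")
        if self.filament_length <= 0:
            raise ConfigurationError("filament_length must be positive")
        if self.filament_segment_length <= 0:
            raise ConfigurationError("filament_segment_length must be positive")
        for name in (
            "hset_binding_rate",
            "hset_unbinding_rate",
            "complex_adhesive_on_rate",
            "complex_adhesive_off_rate",
            "complex_lattice_affinity",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("n_filaments", "n_hset", "n_complexes"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ConfigurationError(f"{name} must be a non-negative integer")
        if self.viscosity <= 0:
            raise ConfigurationError("viscosity must be positive")
        if self.temperature_kT < 0:
            raise ConfigurationError("temperature_kT must be >= 0")
        if self.hset_speed < 0 or self.hset_stall_force <= 0:
            raise ConfigurationError("hset_speed >= 0 and hset_stall_force > 0 required")

    # -- derived quantities -------------------------------------------- #

    @property
    def n_vertices_per_filament(self) -> int:
        """Number of vertices discretizing one filament (>= 2)."""
        return max(2, round(self.filament_length / self.filament_segment_length) + 1)

    @property
    def complex_drag(self) -> float:
        """Stokes drag of one complex, pN·s/µm."""
        import math

        return 6.0 * math.pi * self.viscosity * self.complex_radius

    @property
    def vertex_drag(self) -> float:
        """Drag assigned to each filament vertex, pN·s/µm.

        Slender-body drag per unit length ~ 3·η for an aspect ratio of order
        10; distributed uniformly over the vertices.
        """
        seg = self.filament_length / (self.n_vertices_per_filament - 1)
        return 3.0 * self.viscosity * seg

    # -- serialization -------------------------------------------------- #

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}"
            )
        return cls(**d)

    def replace(self, **overrides: Any) -> "SimConfig":
        return SimConfig.from_dict({**self.to_dict(), **overrides})

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        """Read a YAML or JSON config file (one document per run)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # JSON is a YAML subset
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix in {".yml", ".yaml"}:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            p.write_text(json.dumps(self.to_dict(), indent=2))
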