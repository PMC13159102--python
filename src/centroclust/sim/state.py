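"""Mutable simulation state and its constructors.

The state is a struct-of-arrays: filament vertices, motor-coupler heads and
condensate complexes all live in flat numpy arrays so a step touches no
Python-level per-entity loops.

Conventions
-----------
* Filament vertex 0 is the minus end; abscissae are arc length from the
  minus end, so motors walk toward abscissa 0.
* A head/hand is encoded as ``(filament index, abscissa)`` with filament
  index ``-1`` meaning free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError
from .config import (
    NUCLEATION_GROWTH_TIME_S,
    NUCLEATION_SEED_LENGTH_UM,
    SimConfig,
)

FREE = -1


@dataclass
class SimState:
    time: float
    rng: np.random.Generator

    # filaments: (n_fil, n_vert, 2) vertices, per-filament rest segment length
    fil_vertices: np.ndarray
    fil_rest_seg: np.ndarray        # current rest length per segment, µm
    fil_target_seg: np.ndarray      # rest length once fully grown, µm
    fil_growth_rate: np.ndarray     # d(rest_seg)/dt, µm/s (0 for mature filaments)

    # bivalent motor couplers: base position + two heads
    motor_pos: np.ndarray           # (n_m, 2), position while fully unbound
    motor_fil: np.ndarray           # (n_m, 2) int
    motor_abs: np.ndarray           # (n_m, 2) float

    # condensate complexes (empty arrays until added)
    complexes_added: bool = False
    cx_pos: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    cx_motor_fil: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    cx_motor_abs: np.ndarray = field(default_factory=lambda: np.empty(0))
    cx_lattice_fil: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    cx_lattice_abs: np.ndarray = field(default_factory=lambda: np.empty(0))
    cx_adh_partner: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    cx_nucleated_fil: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    # ------------------------------------------------------------------ #

    @property
    def n_filaments(self) -> int:
        return self.fil_vertices.shape[0]

    @property
    def n_complexes(self) -> int:
        return self.cx_pos.shape[0]

    def filament_lengths(self) -> np.ndarray:
        """Current contour (rest) length of every filament, µm."""
        n_seg = self.fil_vertices.shape[1] - 1
        return self.fil_rest_seg * n_seg

    def minus_ends(self) -> np.ndarray:
        """(n_fil, 2) minus-end positions."""
        return self.fil_vertices[:, 0, :].copy()

    def points_on_filaments(
        self, fil: np.ndarray, absc: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Positions and unit tangents (minus→plus) at given attachment sites.

        ``fil`` must contain valid filament indices (no FREE entries).
        """
        n_seg = self.fil_vertices.shape[1] - 1
        ds = self.fil_rest_seg[fil]
        seg = np.minimum((absc / ds).astype(np.int64), n_seg - 1)
        np.maximum(seg, 0, out=seg)
        v0 = self.fil_vertices[fil, seg]
        v1 = self.fil_vertices[fil, seg + 1]
        w = (absc - seg * ds) / ds
        np.minimum(w, 1.0, out=w)
        np.maximum(w, 0.0, out=w)
        w = w[:, None]
        d = v1 - v0
        pts = v0 + w * d
        norm = np.sqrt(np.einsum("ij,ij->i", d, d))[:, None]
        norm[norm == 0] = 1.0
        return pts, d / norm

    def scatter_force_on_filaments(
        self, fil: np.ndarray, absc: np.ndarray, force: np.ndarray, out: np.ndarray
    ) -> None:
        """Distribute point forces at attachment sites onto bounding vertices."""
        n_seg = self.fil_vertices.shape[1] - 1
        ds = self.fil_rest_seg[fil]
        seg = np.minimum((absc / ds).astype(np.int64), n_seg - 1)
        np.maximum(seg, 0, out=seg)
        w = (absc - seg * ds) / ds
        np.minimum(w, 1.0, out=w)
        np.maximum(w, 0.0, out=w)
        w = w[:, None]
        flat = out.reshape(-1, 2)
        n_vert = self.fil_vertices.shape[1]
        idx0 = fil * n_vert + seg
        np.add.at(flat, idx0, (1.0 - w) * force)
        np.add.at(flat, idx0 + 1, w * force)


# ---------------------------------------------------------------------- #
# constructors


def _straight_filament(center, angle, length, n_vert):
    s = np.linspace(-0.5, 0.5, n_vert) * length
    direction = np.array([np.cos(angle), np.sin(angle)])
    return center[None, :] + s[:, None] * direction[None, :]


def init_network(config: SimConfig, rng: np.random.Generator | None = None) -> SimState:
    """Build the phase-1 state: filaments and unbound motor couplers only.

    Filament centers are placed uniformly in the arena (rejecting centers
    whose filament would leave the arena entirely is unnecessary under soft
    confinement; centers are drawn inside a margin instead) with uniform
    random orientations.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_vert = config.n_vertices_per_filament
    n_fil = config.n_filaments
    R = config.arena_radius
    half = config.filament_length / 2.0
    margin = max(R - half, 0.25 * R)

    centers = _uniform_disk(rng, n_fil, margin)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n_fil)
    vertices = np.empty((n_fil, n_vert, 2))
    for i in range(n_fil):
        vertices[i] = _straight_filament(centers[i], angles[i], config.filament_length, n_vert)

    seg = config.filament_length / (n_vert - 1)
    motor_pos = _uniform_disk(rng, config.n_hset, R)

    return SimState(
        time=0.0,
        rng=rng,
        fil_vertices=vertices,
        fil_rest_seg=np.full(n_fil, seg),
        fil_target_seg=np.full(n_fil, seg),
        fil_growth_rate=np.zeros(n_fil),
        motor_pos=motor_pos,
        motor_fil=np.full((config.n_hset, 2), FREE, dtype=np.int64),
        motor_abs=np.zeros((config.n_hset, 2)),
    )


def add_complexes(state: SimState, config: SimConfig, rng: np.random.Generator | None = None) -> SimState:
    """Add ``n_complexes`` condensate complexes uniformly in the arena.

    Each complex carries one minus-end-walking motor hand, one weak lattice
    hand, two adhesive hands and optionally nucleates one filament whose
    minus end is anchored to the complex and which grows to full length over
    ``NUCLEATION_GROWTH_TIME_S`` seconds.
    """
    if state.complexes_added:
        raise ConfigurationError("complexes have already been added to this state")
    if state.time < config.t_bundle - 1e-9:
        raise ConfigurationError(
            f"complexes are added at t >= t_bundle ({config.t_bundle} s); state is at {state.time} s"
        )
    if rng is None:
        rng = state.rng

    n = config.n_complexes
    state.cx_pos = _uniform_disk(rng, n, config.arena_radius)
    state.cx_motor_fil = np.full(n, FREE, dtype=np.int64)
    state.cx_motor_abs = np.zeros(n)
    state.cx_lattice_fil = np.full(n, FREE, dtype=np.int64)
    state.cx_lattice_abs = np.zeros(n)
    state.cx_adh_partner = np.full((n, 2), FREE, dtype=np.int64)
    state.cx_nucleated_fil = np.full(n, FREE, dtype=np.int64)
    state.complexes_added = True

    if config.nucleation_enabled and n > 0:
        n_vert = config.n_vertices_per_filament
        target_seg = config.filament_length / (n_vert - 1)
        seed_seg = NUCLEATION_SEED_LENGTH_UM / (n_vert - 1)
        growth = (target_seg - seed_seg) / NUCLEATION_GROWTH_TIME_S
        angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
        new_vertices = np.empty((n, n_vert, 2))
        for i in range(n):
            direction = np.array([np.cos(angles[i]), np.sin(angles[i])])
            s = np.linspace(0.0, NUCLEATION_SEED_LENGTH_UM, n_vert)
            new_vertices[i] = state.cx_pos[i][None, :] + s[:, None] * direction[None, :]
        first_new = state.n_filaments
        state.cx_nucleated_fil = np.arange(first_new, first_new + n, dtype=np.int64)
        state.fil_vertices = np.concatenate([state.fil_vertices, new_vertices], axis=0)
        state.fil_rest_seg = np.concatenate([state.fil_rest_seg, np.full(n, seed_seg)])
        state.fil_target_seg = np.concatenate([state.fil_target_seg, np.full(n, target_seg)])
        state.fil_growth_rate = np.concatenate([state.fil_growth_rate, np.full(n, growth)])

    return state


def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
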