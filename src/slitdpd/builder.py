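"""Initial-configuration construction for bulk and slit systems.

Coordinate convention: every axis is centred on the origin, so positions
lie in [-L/2, L/2) along periodic directions.  In a slit the reflecting
planes sit at x = ±D/2 and the frozen wall beads occupy slabs of thickness
one cutoff immediately outside them, |x| in (D/2, D/2 + 1].

Chains are seeded as freely-jointed random walks with step 0.5 r_c: the
soft DPD potentials tolerate the resulting overlaps and pre-equilibration
erases any memory of the initial state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SPECIES, BoxGeometry, ChainSpec, SystemParams

__all__ = ["Configuration", "build_bulk", "build_slit", "make_wall_layer"]

_SPECIES_CODE = {s: i for i, s in enumerate(SPECIES)}


@dataclass
class Configuration:
    """A full particle configuration; the unit passed between engine and analyses.

    positions/velocities are (N, 3) float arrays in reduced units, species
    is a length-N array of single-character labels in {A, B, S, W},
    chain_id is -1 for solvent and wall beads, and frozen marks immobile
    wall beads.
    """

    positions: np.ndarray
    velocities: np.ndarray
    species: np.ndarray
    chain_id: np.ndarray
    frozen: np.ndarray
    geometry: BoxGeometry
    time: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.positions)
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64).reshape(n, 3)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64).reshape(n, 3)
        self.species = np.asarray(self.species, dtype="<U1")
        self.chain_id = np.asarray(self.chain_id, dtype=np.int64)
        self.frozen = np.asarray(self.frozen, dtype=bool)
        for name in ("velocities", "species", "chain_id", "frozen"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match positions ({n})")
        bad = set(np.unique(self.species)) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species labels {sorted(bad)}")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def mobile(self) -> np.ndarray:
        return ~self.frozen

    @property
    def n_chains(self) -> int:
        cids = self.chain_id[self.chain_id >= 0]
        return int(cids.max()) + 1 if cids.size else 0

    def species_codes(self) -> np.ndarray:
        """Integer species codes in canonical A=0, B=1, S=2, W=3 order."""
        codes = np.empty(self.n_beads, dtype=np.int8)
        for s, c in _SPECIES_CODE.items():
            codes[self.species == s] = c
        return codes

    def chain_beads(self, chain: int) -> np.ndarray:
        """Bead indices of one chain, in chain (block) order."""
        return np.flatnonzero(self.chain_id == chain)

    def copy(self) -> "Configuration":
        return Configuration(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            chain_id=self.chain_id.copy(),
            frozen=self.frozen.copy(),
            geometry=self.geometry,
            time=self.time,
            meta=dict(self.meta),
        )


def _maxwell_velocities(n: int, rng: np.random.Generator, kT: float = 1.0) -> np.ndarray:
    """Maxwell velocities at kT with the centre-of-mass momentum removed."""
    v = rng.normal(0.0, np.sqrt(kT), size=(n, 3))
    if n:
        v -= v.mean(axis=0)
    return v


def _random_walk_chain(
    n: int, start: np.ndarray, step: float, rng: np.random.Generator
) -> np.ndarray:
    """Freely-jointed random walk of n beads with fixed step length."""
    pos = np.empty((n, 3))
    pos[0] = start
    for k in range(1, n):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos[k] = pos[k - 1] + step * u
    return pos


def _wrap_or_reflect(pos: np.ndarray, geom: BoxGeometry) -> np.ndarray:
    """Fold positions into the box: wrap periodic axes, mirror the slit axis."""
    L = np.array([geom.Lx, geom.Ly, geom.Lz])
    pos = pos.copy()
    for ax, per in enumerate(geom.periodic):
        if per:
            pos[:, ax] -= L[ax] * np.round(pos[:, ax] / L[ax])
        else:
            # reflect into (-D/2, D/2): triangle-wave fold
            half = L[ax] / 2.0
            x = np.mod(pos[:, ax] + half, 2 * L[ax])
            x = np.where(x > L[ax], 2 * L[ax] - x, x)
            pos[:, ax] = np.clip(x - half, -half + 1e-9, half - 1e-9)
    return pos


def _place_chains(
    params: SystemParams,
    chain: ChainSpec,
    geom: BoxGeometry,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    n = chain.n
    total_mobile = int(round(params.rho * geom.volume))
    n_poly = params.n_chains * n
    if n_poly > total_mobile:
        raise ValueError(
            f"overfull system: {params.n_chains} chains x {n} beads exceed "
            f"rho*V = {total_mobile} beads"
        )
    lo = np.array([-geom.Lx / 2, -geom.Ly / 2, -geom.Lz / 2])
    hi = -lo
    positions = []
    species: list[str] = []
    chain_ids = []
    seq = list(chain.sequence)
    for c in range(params.n_chains):
        start = rng.uniform(lo, hi)
        walk = _wrap_or_reflect(_random_walk_chain(n, start, 0.5, rng), geom)
        positions.append(walk)
        species.extend(seq)
        chain_ids.extend([c] * n)
    n_solvent = total_mobile - n_poly
    if n_solvent:
        positions.append(rng.uniform(lo, hi, size=(n_solvent, 3)))
        species.extend(["S"] * n_solvent)
        chain_ids.extend([-1] * n_solvent)
    pos = np.vstack(positions) if positions else np.empty((0, 3))
    return pos, species, np.array(chain_ids, dtype=np.int64)


def build_bulk(
    params: SystemParams,
    chain: ChainSpec,
    geom: BoxGeometry,
    seed: int | None = None,
) -> Configuration:
    """Build a fully periodic bulk box at density rho.

    Total bead count is round(rho V); n_chains random-walk chains plus
    solvent fill it.  Velocities are Maxwell at kT = 1 with zero total
    momentum.
    """
    if geom.kind != "bulk":
        raise ValueError("build_bulk requires bulk geometry")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pos, species, chain_ids = _place_chains(params, chain, geom, rng)
    vel = _maxwell_velocities(len(pos), rng)
    return Configuration(
        positions=pos,
        velocities=vel,
        species=np.array(species, dtype="<U1"),
        chain_id=chain_ids,
        frozen=np.zeros(len(pos), dtype=bool),
        geometry=geom,
    )


def make_wall_layer(
    geom: BoxGeometry, rho_wall: float = 3.0, seed: int | None = None, thickness: float = 1.0
) -> np.ndarray:
    """Random frozen-bead positions in slabs just outside both reflecting planes.

    One slab of thickness 1 r_c per side suffices because every pair force
    cuts off at r_c: mobile beads cannot see past it.  rho_wall = 0 returns
    an empty array (purely reflecting wall with the soft surface potential).
    """
    if rho_wall < 0:
        raise ValueError("rho_wall must be non-negative")
    if geom.kind != "slit":
        raise ValueError("wall layers exist only for slit geometry")
    rng = np.random.default_rng(seed)
    n_side = int(round(rho_wall * thickness * geom.Ly * geom.Lz))
    if n_side == 0:
        return np.empty((0, 3))
    half = geom.D / 2.0
    out = []
    for sign in (-1.0, 1.0):
        yz = rng.uniform(
            [-geom.Ly / 2, -geom.Lz / 2], [geom.Ly / 2, geom.Lz / 2], size=(n_side, 2)
        )
        # |x| in (D/2, D/2 + thickness]
        x = sign * (half + rng.uniform(0.0, thickness, size=n_side))
        out.append(np.column_stack([x, yz]))
    return np.vstack(out)


def build_slit(
    params: SystemParams,
    chain: ChainSpec,
    geom: BoxGeometry,
    seed: int | None = None,
    rho_wall: float = 3.0,
) -> Configuration:
    """Build a slit system: mobile beads between the planes, frozen walls outside.

    Mobile bead count is round(rho D Ly Lz); wall beads are frozen, at rest,
    and carry species W with chain_id -1.
    """
    if geom.kind != "slit":
        raise ValueError("build_slit requires slit geometry")
    if geom.D < 4:
        raise ValueError("slit width D must be at least 4 (two wall repulsion ranges)")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pos, species, chain_ids = _place_chains(params, chain, geom, rng)
    vel = _maxwell_velocities(len(pos), rng)
    n_mobile = len(pos)

    wall = make_wall_layer(geom, rho_wall, seed=rng.integers(2**31))
    n_wall = len(wall)
    return Configuration(
        positions=np.vstack([pos, wall]) if n_wall else pos,
        velocities=np.vstack([vel, np.zeros((n_wall, 3))]) if n_wall else vel,
        species=np.array(species + ["W"] * n_wall, dtype="<U1"),
        chain_id=np.concatenate([chain_ids, np.full(n_wall, -1, dtype=np.int64)]),
        frozen=np.concatenate([np.zeros(n_mobile, dtype=bool), np.ones(n_wall, dtype=bool)]),
        geometry=geom,
    )
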