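"""Synthetic configurations with known ground truth, and scaled-down
simulation scenarios.

The planted generators build chains whose B beads fill a prescribed core
shape (sphere, cylinder, wall-hugging pancake) with the A blocks in a
surrounding shell.  Construction is verified by rejection: a candidate is
re-drawn until the three-contact clustering criterion provably holds for
the planted object (and, for pancakes, until the adsorption criterion
holds), so downstream analyses can be scored against exact truth without
running any dynamics.

What the generators emulate — and what they do not: planted cores have
uniform bead density and no corona/solvent interpenetration, so they test
the *criteria* (clustering, adsorption, shape metrics) rather than the
thermodynamics that real trajectories carry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .aggregates import cluster, contact_pairs, wall_contacting_chains
from .builder import Configuration
from .model import (
    BoxGeometry,
    ChainSpec,
    InteractionTable,
    SystemParams,
    WALL_SCENARIOS,
    chains_for_concentration,
)

__all__ = [
    "PlantedObject",
    "PlantedTruth",
    "Scene",
    "plant_micelle",
    "plant_rod",
    "plant_pancake",
    "Scenario",
    "scenario",
    "SCENARIO_NAMES",
]

_MAX_TRIES = 200


@dataclass
class PlantedObject:
    """One planted aggregate before global chain ids are assigned."""

    positions: np.ndarray  # (A_S * n, 3), chains contiguous, block order
    species: np.ndarray
    n_chains: int
    chain: ChainSpec
    label: str  # intended location label ("free" / "adsorbed")
    shape: dict  # e.g. {"kind": "sphere", "radius": 2.0}


@dataclass
class PlantedTruth:
    """Ground truth serialized alongside a planted configuration."""

    aggregates: list[tuple[int, ...]]  # chain-id sets, one per planted object
    labels: list[str]
    shapes: list[dict]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "aggregates": [list(a) for a in self.aggregates],
                "labels": self.labels,
                "shapes": self.shapes,
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            aggregates=[tuple(a) for a in d["aggregates"]],
            labels=list(d["labels"]),
            shapes=list(d["shapes"]),
            seed=int(d["seed"]),
        )


def _chain_counts(chain: ChainSpec) -> tuple[np.ndarray, np.ndarray]:
    seq = np.array(chain.sequence)
    return np.flatnonzero(seq == "A"), np.flatnonzero(seq == "B")


def _uniform_ball(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    r = radius * rng.uniform(size=n) ** (1.0 / 3.0)
    return v * r[:, None]

def _uniform_shell(n: int, r_in: float, r_out: float, rng) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    u = rng.uniform(size=n)
    r = (r_in**3 + u * (r_out**3 - r_in**3)) ** (1.0 / 3.0)
    return v * r[:, None]


def _check_single_aggregate(obj: PlantedObject, geom: BoxGeometry,
                            threshold: int = 3) -> bool:
    cfg = _object_config(obj, geom)
    aggset = cluster(contact_pairs(cfg), obj.n_chains, threshold=threshold)
    return len(aggset) == 1


def _object_config(obj: PlantedObject, geom: BoxGeometry) -> Configuration:
    n = obj.chain.n
    cids = np.repeat(np.arange(obj.n_chains), n)
    m = len(obj.positions)
    return Configuration(
        positions=obj.positions,
        velocities=np.zeros((m, 3)),
        species=obj.species,
        chain_id=cids,
        frozen=np.zeros(m, dtype=bool),
        geometry=geom,
    )


def plant_micelle(
    A_S: int,
    core_radius: float = 2.0,
    center=(0.0, 0.0, 0.0),
    chain: ChainSpec | None = None,
    seed: int = 0,
    shell_width: float = 1.5,
    geom: BoxGeometry | None = None,
) -> PlantedObject:
    """A roughly spherical core–shell micelle of A_S chains.

    B beads are uniform in a ball of ``core_radius`` about the centre, A
    beads in the spherical shell just outside it.  Re-drawn until the
    three-contact criterion joins all chains into one aggregate; raises if
    the core is too dilute to guarantee that at the given A_S.
    """
    if A_S < 1:
        raise ValueError("association number must be >= 1")
    chain = chain or ChainSpec()
    geom = geom or BoxGeometry.bulk(100.0)  # effectively open space for the check
    rng = np.random.default_rng(seed)
    ia, ib = _chain_counts(chain)
    center = np.asarray(center, dtype=float)
    for _ in range(_MAX_TRIES):
        pos = np.empty((A_S * chain.n, 3))
        for c in range(A_S):
            base = c * chain.n
            pos[base + ib] = center + _uniform_ball(len(ib), core_radius, rng)
            pos[base + ia] = center + _uniform_shell(
                len(ia), core_radius, core_radius + shell_width, rng
            )
        obj = PlantedObject(
            positions=pos,
            species=np.tile(np.array(chain.sequence), A_S),
            n_chains=A_S,
            chain=chain,
            label="free",
            shape={"kind": "sphere", "radius": core_radius, "A_S": A_S},
        )
        if A_S == 1 or _check_single_aggregate(obj, geom):
            return obj
    raise ValueError(
        f"cannot satisfy the contact criterion: core_radius={core_radius} too "
        f"large for A_S={A_S}"
    )


def plant_rod(
    A_S: int,
    diameter: float = 3.0,
    length: float = 6.0,
    center=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
    chain: ChainSpec | None = None,
    seed: int = 0,
    shell_width: float = 1.5,
    geom: BoxGeometry | None = None,
) -> PlantedObject:
    """A rod-like aggregate: B blocks fill a cylinder along ``axis``.

    Each chain's B block is a compact blob anchored at a random position
    inside the cylinder (chains in a cylindrical micelle core are locally
    segregated, not spread over the whole rod); anchors are dense enough
    that neighbouring blobs overlap and the contact criterion percolates
    along the rod.  With length == diameter the shape degenerates toward
    the spherical micelle; long rods give a gyration spectrum with two
    flat components and one growing as length^2 / 12.
    """
    if A_S < 1:
        raise ValueError("association number must be >= 1")
    if length < diameter:
        raise ValueError("rod length must be at least its diameter")
    chain = chain or ChainSpec()
    geom = geom or BoxGeometry.bulk(max(100.0, 4 * length))
    rng = np.random.default_rng(seed)
    ia, ib = _chain_counts(chain)
    center = np.asarray(center, dtype=float)
    u = np.asarray(axis, dtype=float)
    u /= np.linalg.norm(u)
    # orthonormal frame
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    def cyl_points(n: int, r_in: float, r_out: float, z: np.ndarray) -> np.ndarray:
        phi = rng.uniform(0, 2 * np.pi, n)
        r = np.sqrt(rng.uniform(r_in**2, r_out**2, n))
        return (
            center
            + np.outer(z, u)
            + np.outer(r * np.cos(phi), e1)
            + np.outer(r * np.sin(phi), e2)
        )

    blob_sigma = 0.4  # local extent of one chain's B block
    anchor_radius = min(0.5, diameter / 4.0)
    for _ in range(_MAX_TRIES):
        pos = np.empty((A_S * chain.n, 3))
        # stratified anchors along the axis so neighbouring blobs overlap
        strat = rng.permutation(A_S)
        for c in range(A_S):
            base = c * chain.n
            z_anchor = -length / 2 + (strat[c] + rng.uniform()) * length / A_S
            anchor = cyl_points(1, 0.0, anchor_radius, np.array([z_anchor]))[0]
            blob = anchor + rng.normal(0.0, blob_sigma, size=(len(ib), 3))
            # keep the blob inside the cylinder cross-section
            radial = blob - center - np.outer((blob - center) @ u, u)
            rr = np.linalg.norm(radial, axis=1)
            over = rr > diameter / 2.0
            blob[over] -= radial[over] * (1.0 - (diameter / 2.0) / rr[over, None])
            pos[base + ib] = blob
            pos[base + ia] = cyl_points(
                len(ia), diameter / 2.0, diameter / 2.0 + shell_width,
                rng.uniform(-length / 2, length / 2, len(ia)),
            )
        obj = PlantedObject(
            positions=pos,
            species=np.tile(np.array(chain.sequence), A_S),
            n_chains=A_S,
            chain=chain,
            label="free",
            shape={"kind": "rod", "diameter": diameter, "length": length, "A_S": A_S},
        )
        if A_S == 1 or _check_single_aggregate(obj, geom):
            return obj
    raise ValueError(
        f"cannot satisfy the contact criterion: rod {diameter}x{length} too "
        f"dilute for A_S={A_S}"
    )


def plant_pancake(
    A_S: int,
    geom: BoxGeometry,
    side: int = -1,
    thickness: float = 0.8,
    radius: float = 2.5,
    center_yz=(0.0, 0.0),
    chain: ChainSpec | None = None,
    seed: int = 0,
    wall_contact_cutoff: float = 1.0,
) -> PlantedObject:
    """A pancake-shaped adsorbed aggregate hugging one slit wall.

    B beads lie within ``thickness`` of the chosen reflecting plane
    (side -1: lower wall, +1: upper) inside a lateral disc of ``radius``;
    A beads float in a slab just above.  thickness <= wall_contact_cutoff
    guarantees every B bead is wall-contacting, so the adsorption
    criterion holds by construction (verified before returning).
    """
    if geom.kind != "slit":
        raise ValueError("pancakes require slit geometry")
    if thickness > wall_contact_cutoff:
        raise ValueError(
            "cannot guarantee adsorption: thickness exceeds the wall-contact cutoff"
        )
    if side not in (-1, 1):
        raise ValueError("side must be -1 (lower wall) or +1 (upper wall)")
    chain = chain or ChainSpec()
    rng = np.random.default_rng(seed)
    ia, ib = _chain_counts(chain)
    half = geom.D / 2.0
    cy, cz = center_yz

    def disc(n: int, r_max: float, x_lo: float, x_hi: float) -> np.ndarray:
        phi = rng.uniform(0, 2 * np.pi, n)
        r = r_max * np.sqrt(rng.uniform(size=n))
        x = rng.uniform(x_lo, x_hi, n)
        return np.column_stack([x, cy + r * np.cos(phi), cz + r * np.sin(phi)])

    if side < 0:
        b_lo, b_hi = -half, -half + thickness
        a_lo, a_hi = -half + thickness, -half + thickness + 1.0
    else:
        b_lo, b_hi = half - thickness, half
        a_lo, a_hi = half - thickness - 1.0, half - thickness

    for _ in range(_MAX_TRIES):
        pos = np.empty((A_S * chain.n, 3))
        for c in range(A_S):
            base = c * chain.n
            pos[base + ib] = disc(len(ib), radius, b_lo, b_hi)
            pos[base + ia] = disc(len(ia), radius + 1.0, a_lo, a_hi)
        obj = PlantedObject(
            positions=pos,
            species=np.tile(np.array(chain.sequence), A_S),
            n_chains=A_S,
            chain=chain,
            label="adsorbed",
            shape={"kind": "pancake", "thickness": thickness, "radius": radius,
                   "side": side, "A_S": A_S},
        )
        cfg = _object_config(obj, geom)
        ok_cluster = A_S == 1 or _check_single_aggregate(obj, geom)
        ok_ads = wall_contacting_chains(cfg, wall_contact_cutoff) == set(range(A_S))
        if ok_cluster and ok_ads:
            return obj
    raise ValueError("cannot satisfy the planted-pancake guarantees")


@dataclass
class Scene:
    """Assembles planted objects into one configuration with exact truth."""

    geometry: BoxGeometry
    seed: int = 0
    objects: list[PlantedObject] = field(default_factory=list)

    def add(self, obj: PlantedObject) -> "Scene":
        self.objects.append(obj)
        return self

    def build(self) -> tuple[Configuration, PlantedTruth]:
        positions, species, chain_ids = [], [], []
        truth_aggs, labels, shapes = [], [], []
        next_chain = 0
        for obj in self.objects:
            positions.append(obj.positions)
            species.append(obj.species)
            cids = next_chain + np.repeat(np.arange(obj.n_chains), obj.chain.n)
            chain_ids.append(cids)
            truth_aggs.append(tuple(range(next_chain, next_chain + obj.n_chains)))
            labels.append(obj.label)
            shapes.append(obj.shape)
            next_chain += obj.n_chains
        pos = np.vstack(positions) if positions else np.empty((0, 3))
        n = len(pos)
        cfg = Configuration(
            positions=pos,
            velocities=np.zeros((n, 3)),
            species=np.concatenate(species) if species else np.empty(0, dtype="<U1"),
            chain_id=np.concatenate(chain_ids) if chain_ids else np.empty(0, np.int64),
            frozen=np.zeros(n, dtype=bool),
            geometry=self.geometry,
        )
        return cfg, PlantedTruth(
            aggregates=truth_aggs, labels=labels, shapes=shapes, seed=self.seed
        )


# ---------------------------------------------------------------------------
# scaled-down end-to-end scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = (
    "bulk-small",
    "slit-inert",
    "slit-repulsive",
    "slit-weak-attract",
    "slit-strong-attract",
)

#: Desk-scale run schedule: long enough for micellization and adsorption to
#: develop from a random start in a 12-wide box, short enough for minutes-long
#: runs.  Full-scale studies would use 25-wide boxes and 1e7+ steps.
_SCENARIO_STEPS = 200_000
_SCENARIO_PRE_EQUIL = 50_000
_SCENARIO_SAMPLE = 10_000


@dataclass
class Scenario:
    """A named, fully parameterised scaled-down study condition."""

    name: str
    params: SystemParams
    chain: ChainSpec
    geom: BoxGeometry
    table: InteractionTable

    @property
    def concentration(self) -> float:
        from .model import concentration

        return concentration(self.params.n_chains, self.chain.n,
                             self.params.rho, self.geom.volume)


def scenario(
    name: str,
    seed: int = 0,
    c: float = 25.6,
    steps: int = _SCENARIO_STEPS,
    pre_equil_steps: int = _SCENARIO_PRE_EQUIL,
    sample_period: int = _SCENARIO_SAMPLE,
) -> Scenario:
    """Build a named scaled-down scenario.

    ``bulk-small`` is a 12^3 periodic box; the slit scenarios use D = 10
    with 12 x 12 lateral extent and wall affinities a_BW = 25 (inert),
    30 (slightly repulsive), 20 (slightly attractive) or 15 (strongly
    attractive).  All run at rho = 3 and c = 25.6 % by default.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    chain = ChainSpec()
    if name == "bulk-small":
        geom = BoxGeometry.bulk(12.0)
        table = InteractionTable.default()
    else:
        geom = BoxGeometry.slit(10.0, L=12.0)
        wall = name.removeprefix("slit-")
        table = InteractionTable.wall_scenario(wall)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # nearest-integer chain count is intended
        n_chains = chains_for_concentration(c, chain.n, 3.0, geom.volume)
    params = SystemParams(
        rho=3.0,
        n_chains=n_chains,
        steps=steps,
        pre_equil_steps=pre_equil_steps,
        sample_period=sample_period,
        seed=seed,
    )
    return Scenario(name=name, params=params, chain=chain, geom=geom, table=table)
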