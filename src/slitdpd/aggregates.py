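"""Aggregate detection and adsorbed/free classification.

Two beads on different chains form a contact pair when their
minimum-image distance is below the interaction cutoff r_c.  Two chains
belong to the same aggregate when they share at least ``threshold``
(default 3) B–B contact pairs; aggregates are the connected components of
the resulting chain graph, so unimers are simply aggregates of size one.

A chain is wall-contacting when at least three of its B beads lie within
the wall-contact cutoff of a reflecting plane, and an aggregate is
adsorbed when it contains at least one wall-contacting chain; everything
else is free.  "In contact with the wall" here means within r_c of the
nearest reflecting plane, mirroring the bead–bead contact rule and
independent of the random frozen-bead placement; a wall-bead proximity
mode is available via ``mode="beads"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .builder import Configuration

__all__ = ["Aggregate", "AggregateSet", "contact_pairs", "cluster", "classify_adsorption"]


@dataclass
class Aggregate:
    """One aggregate: its member chains and (in slits) its location label."""

    chains: tuple[int, ...]
    label: str | None = None  # "adsorbed" | "free" | None (bulk)

    @property
    def A_S(self) -> int:
        """Association number: the number of chains in the aggregate."""
        return len(self.chains)


@dataclass
class AggregateSet:
    """Partition of all chains of one frame into aggregates."""

    aggregates: list[Aggregate]
    n_chains: int
    contact_counts: dict[tuple[int, int], int] = field(default_factory=dict)
    threshold: int = 3

    def __post_init__(self) -> None:
        covered = sorted(c for ag in self.aggregates for c in ag.chains)
        if covered != list(range(self.n_chains)):
            raise ValueError("aggregates must partition all chains exactly once")

    def __iter__(self):
        return iter(self.aggregates)

    def __len__(self) -> int:
        return len(self.aggregates)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([ag.A_S for ag in self.aggregates], dtype=np.int64)

    def labelled(self, label: str) -> list[Aggregate]:
        return [ag for ag in self.aggregates if ag.label == label]


def _periodic_tree_coords(config: Configuration, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map positions to a non-negative box for cKDTree with toroidal topology.

    Non-periodic axes get a box dimension large enough that wrap-around can
    never produce a spurious short image.
    """
    geom = config.geometry
    pos = config.positions[idx].copy()
    L = np.array([geom.Lx, geom.Ly, geom.Lz])
    box = L.copy()
    for ax, per in enumerate(geom.periodic):
        if not per:
            span = 2.0 * (L[ax] / 2.0 + 2.0)  # mobile + wall slabs, padded
            box[ax] = 4.0 * span
        pos[:, ax] = np.mod(pos[:, ax] + box[ax] / 2.0, box[ax])
    return pos, box


def contact_pairs(
    config: Configuration, cutoff: float = 1.0, species: str = "B"
) -> dict[tuple[int, int], int]:
    """Count inter-chain contact pairs of the core-forming species.

    Returns a dict mapping chain-id pairs (c1 < c2) to the number of
    bead pairs (one bead on each chain) closer than ``cutoff`` under
    minimum-image distances in the periodic directions.
    """
    sel = np.flatnonzero((config.species == species) & (config.chain_id >= 0))
    if sel.size == 0:
        return {}
    pos, box = _periodic_tree_coords(config, sel)
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    counts: dict[tuple[int, int], int] = {}
    cid = config.chain_id[sel]
    for i, j in pairs:
        c1, c2 = int(cid[i]), int(cid[j])
        if c1 == c2:
            continue
        key = (c1, c2) if c1 < c2 else (c2, c1)
        counts[key] = counts.get(key, 0) + 1
    return counts


def cluster(
    contacts: dict[tuple[int, int], int], n_chains: int, threshold: int = 3
) -> AggregateSet:
    """Partition chains into aggregates by the contact-pair criterion.

    Chains are graph vertices; an edge joins two chains sharing at least
    ``threshold`` contact pairs; aggregates are the connected components
    (membership is transitive: chains with no direct contacts still join
    through intermediates).  Thresholds 1–4 are the physically sensible
    range; 3 is the default criterion.
    """
    if threshold < 1:
        raise ValueError("contact threshold must be >= 1")
    if n_chains == 0:
        return AggregateSet(aggregates=[], n_chains=0, contact_counts=dict(contacts),
                            threshold=threshold)
    edges = [(c1, c2) for (c1, c2), cnt in contacts.items() if cnt >= threshold]
    if edges:
        e = np.array(edges)
        adj = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n_chains, n_chains)
        )
        _, comp = connected_components(adj, directed=False)
    else:
        comp = np.arange(n_chains)
    groups: dict[int, list[int]] = {}
    for chain, c in enumerate(comp):
        groups.setdefault(int(c), []).append(chain)
    aggs = [Aggregate(chains=tuple(sorted(g))) for g in groups.values()]
    aggs.sort(key=lambda a: a.chains[0])
    return AggregateSet(
        aggregates=aggs, n_chains=n_chains, contact_counts=dict(contacts),
        threshold=threshold,
    )


def wall_contacting_chains(
    config: Configuration,
    wall_contact_cutoff: float = 1.0,
    min_contacts: int = 3,
    species: str = "B",
    mode: str = "plane",
) -> set[int]:
    """Chains with at least ``min_contacts`` core beads in wall contact.

    ``mode="plane"``: a bead is in contact when its distance to the nearest
    reflecting plane is below the cutoff.  ``mode="beads"``: when it is
    within the cutoff of any frozen wall bead.
    """
    geom = config.geometry
    if geom.kind != "slit":
        raise ValueError("wall contact is defined for slit geometry only")
    sel = np.flatnonzero((config.species == species) & (config.chain_id >= 0))
    if sel.size == 0:
        return set()
    if mode == "plane":
        d = geom.D / 2.0 - np.abs(config.positions[sel, 0])
        touching = d < wall_contact_cutoff
    elif mode == "beads":
        wall = np.flatnonzero(config.frozen)
        if wall.size == 0:
            return set()
        posw, box = _periodic_tree_coords(config, wall)
        posb, _ = _periodic_tree_coords(config, sel)
        tree = cKDTree(posw, boxsize=box)
        touching = np.array(
            [len(nb) > 0 for nb in tree.query_ball_point(posb, wall_contact_cutoff)]
        )
    else:
        raise ValueError(f"unknown wall-contact mode {mode!r}")
    cid = config.chain_id[sel][touching]
    chains, counts = np.unique(cid, return_counts=True)
    return {int(c) for c, n in zip(chains, counts) if n >= min_contacts}


def classify_adsorption(
    config: Configuration,
    aggset: AggregateSet,
    wall_contact_cutoff: float = 1.0,
    mode: str = "plane",
) -> AggregateSet:
    """Label every aggregate adsorbed or free.

    An aggregate is adsorbed when at least one member chain has three or
    more B beads in wall contact; all remaining aggregates (including
    unimers) are free.  Labels are set in place and the set is returned.
    """
    contacting = wall_contacting_chains(config, wall_contact_cutoff, mode=mode)
    for ag in aggset.aggregates:
        ag.label = "adsorbed" if any(c in contacting for c in ag.chains) else "free"
    return aggset


def analyse_frame(
    config: Configuration,
    threshold: int = 3,
    cutoff: float = 1.0,
    classify: bool | None = None,
    wall_contact_cutoff: float = 1.0,
) -> AggregateSet:
    """Convenience: contacts -> clustering -> (slit only) adsorption labels."""
    contacts = contact_pairs(config, cutoff=cutoff)
    aggset = cluster(contacts, config.n_chains, threshold=threshold)
    if classify is None:
        classify = config.geometry.kind == "slit"
    if classify:
        classify_adsorption(config, aggset, wall_contact_cutoff)
    return aggset
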