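"""Contact-pair clustering and adsorption classification.

The clustering implementation is cross-checked against a brute-force
oracle: all-pairs O(n^2) minimum-image contact counting followed by a
transitive closure by repeated set merging.
"""

import itertools

import numpy as np
import pytest

from slitdpd.aggregates import (
    analyse_frame,
    classify_adsorption,
    cluster,
    contact_pairs,
    wall_contacting_chains,
)
from slitdpd.fixtures import Scene, plant_micelle, plant_pancake
from slitdpd.model import BoxGeometry

from conftest import make_config


# ------------------------------------------------------------------ oracle

def brute_force_contacts(config, cutoff=1.0):
    """O(n^2) minimum-image B–B contact counting."""
    geom = config.geometry
    L = np.array([geom.Lx, geom.Ly, geom.Lz])
    sel = np.flatnonzero((config.species == "B") & (config.chain_id >= 0))
    counts = {}
    for i, j in itertools.combinations(sel, 2):
        c1, c2 = config.chain_id[i], config.chain_id[j]
        if c1 == c2:
            continue
        dr = config.positions[i] - config.positions[j]
        for ax, per in enumerate(geom.periodic):
            if per:
                dr[ax] -= L[ax] * np.round(dr[ax] / L[ax])
        if np.linalg.norm(dr) < cutoff:
            key = (min(c1, c2), max(c1, c2))
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_force_components(contacts, n_chains, threshold):
    """Transitive closure by repeated merging of overlapping sets."""
    groups = [{c} for c in range(n_chains)]
    for (c1, c2), cnt in contacts.items():
        if cnt < threshold:
            continue
        g1 = next(g for g in groups if c1 in g)
        g2 = next(g for g in groups if c2 in g)
        if g1 is not g2:
            g1 |= g2
            groups.remove(g2)
    return sorted(tuple(sorted(g)) for g in groups)


# ------------------------------------------------------------------- tests

class TestContactPairs:
    def test_overlapping_b_blocks_give_combinatorial_maximum(self, chain):
        """Two chains with coincident B blocks share 5x5 = 25 contacts."""
        geom = BoxGeometry.bulk(25.0)
        seq = list(chain.sequence) * 2
        pos = np.zeros((20, 3))
        # A beads far apart, B beads of both chains inside one small ball
        pos[:5] = [0, 0, 5]
        pos[10:15] = [0, 0, -5]
        rng = np.random.default_rng(0)
        pos[5:10] = rng.uniform(-0.2, 0.2, (5, 3))
        pos[15:20] = rng.uniform(-0.2, 0.2, (5, 3))
        cfg = make_config(pos, seq, [0] * 10 + [1] * 10, geom)
        counts = contact_pairs(cfg)
        assert counts == {(0, 1): 25}

    def test_distant_chains_share_nothing(self, chain):
        geom = BoxGeometry.bulk(25.0)
        seq = list(chain.sequence) * 2
        pos = np.zeros((20, 3))
        pos[10:] = [10.0, 0, 0]
        cfg = make_config(pos, seq, [0] * 10 + [1] * 10, geom)
        assert contact_pairs(cfg) == {}

    def test_periodic_image_contacts_counted(self, chain):
        """B beads touching across the periodic boundary are contacts."""
        geom = BoxGeometry.bulk(25.0)
        seq = list(chain.sequence) * 2
        pos = np.zeros((20, 3))
        pos[:5] = [0, 0, 8]
        pos[10:15] = [0, 0, -8]
        pos[5:10] = [0, 0, 12.3]  # near +z face
        pos[15:20] = [0, 0, -12.3]  # near -z face: distance 0.4 across boundary
        cfg = make_config(pos, seq, [0] * 10 + [1] * 10, geom)
        counts = contact_pairs(cfg)
        assert counts.get((0, 1), 0) == 25

    def test_matches_brute_force_on_random_configs(self, chain):
        geom = BoxGeometry.bulk(8.0)
        rng = np.random.default_rng(42)
        for trial in range(5):
            n_chains = 12
            pos = rng.uniform(-4, 4, (n_chains * 10, 3))
            seq = list(chain.sequence) * n_chains
            cids = np.repeat(np.arange(n_chains), 10)
            cfg = make_config(pos, seq, cids, geom)
            assert contact_pairs(cfg) == brute_force_contacts(cfg)


class TestCluster:
    def test_transitive_membership(self):
        """Chains joined through an intermediate form one aggregate."""
        contacts = {(0, 1): 3, (1, 2): 3, (0, 2): 0}
        aggset = cluster(contacts, 3, threshold=3)
        assert len(aggset) == 1
        assert aggset.aggregates[0].chains == (0, 1, 2)
        assert aggset.aggregates[0].A_S == 3

    def test_subthreshold_contacts_leave_unimers(self):
        aggset = cluster({(0, 1): 2}, 2, threshold=3)
        assert sorted(a.chains for a in aggset) == [(0,), (1,)]

    def test_empty_system(self):
        assert len(cluster({}, 0)) == 0

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            cluster({}, 2, threshold=0)

    def test_partition_invariant(self):
        rng = np.random.default_rng(3)
        n = 30
        contacts = {
            (i, j): int(rng.integers(0, 6))
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.2
        }
        aggset = cluster(contacts, n, threshold=3)
        assert int(aggset.sizes.sum()) == n

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_closure(self, seed, chain):
        geom = BoxGeometry.bulk(6.0)
        rng = np.random.default_rng(seed)
        n_chains = int(rng.integers(5, 25))
        pos = rng.uniform(-3, 3, (n_chains * 10, 3))
        cfg = make_config(
            pos, list(chain.sequence) * n_chains,
            np.repeat(np.arange(n_chains), 10), geom,
        )
        contacts = contact_pairs(cfg)
        for threshold in (1, 2, 3, 4):
            got = sorted(a.chains for a in cluster(contacts, n_chains, threshold))
            want = brute_force_components(contacts, n_chains, threshold)
            assert got == want

    def test_lower_threshold_never_splits_aggregates(self, chain):
        """Monotonicity: relaxing the criterion can only merge chains."""
        geom = BoxGeometry.bulk(6.0)
        rng = np.random.default_rng(11)
        n_chains = 20
        pos = rng.uniform(-3, 3, (n_chains * 10, 3))
        cfg = make_config(
            pos, list(chain.sequence) * n_chains,
            np.repeat(np.arange(n_chains), 10), geom,
        )
        contacts = contact_pairs(cfg)
        n_aggs = [len(cluster(contacts, n_chains, t)) for t in (1, 2, 3, 4)]
        assert n_aggs == sorted(n_aggs)


class TestAdsorption:
    def test_three_wall_contact_beads_adsorb_whole_aggregate(self, slit_geom):
        cfg, truth = (
            Scene(slit_geom, seed=0)
            .add(plant_pancake(5, slit_geom, side=-1, seed=0))
            .build()
        )
        aggset = analyse_frame(cfg)
        assert len(aggset) == 1
        assert aggset.aggregates[0].label == "adsorbed"

    def test_two_contact_beads_are_not_enough(self, chain, slit_geom):
        # one chain: 2 B beads within 1 r_c of the lower wall, rest central
        pos = np.zeros((10, 3))
        pos[:5, 0] = 0.0  # A beads mid-slit
        pos[5:7, 0] = -4.5  # two B beads near wall (plane at -5)
        pos[7:], pos[7:, 0] = 0.0, 0.0
        cfg = make_config(pos, chain.sequence, [0] * 10, slit_geom)
        aggset = analyse_frame(cfg)
        assert aggset.aggregates[0].label == "free"

    def test_central_micelle_is_free(self, slit_geom):
        cfg, _ = (
            Scene(slit_geom, seed=1)
            .add(plant_micelle(8, core_radius=1.5, center=(0, 0, 0), seed=1))
            .build()
        )
        aggset = analyse_frame(cfg)
        assert [a.label for a in aggset] == ["free"]

    def test_bulk_geometry_rejected(self, chain):
        geom = BoxGeometry.bulk(10.0)
        cfg = make_config(np.zeros((10, 3)), chain.sequence, [0] * 10, geom)
        aggset = analyse_frame(cfg, classify=False)
        with pytest.raises(ValueError):
            classify_adsorption(cfg, aggset)

    def test_labels_partition_aggregates(self, slit_geom):
        scene = Scene(slit_geom, seed=5)
        scene.add(plant_pancake(4, slit_geom, side=1, seed=5))
        scene.add(plant_micelle(6, core_radius=1.5, center=(0, 3, 3), seed=6))
        cfg, _ = scene.build()
        aggset = analyse_frame(cfg)
        n_ads = len(aggset.labelled("adsorbed"))
        n_free = len(aggset.labelled("free"))
        assert n_ads + n_free == len(aggset)
        assert n_ads == 1 and n_free == 1

    def test_wall_contact_count_rule(self, chain, slit_geom):
        # exactly 3 B beads within the cutoff -> contacting
        pos = np.zeros((10, 3))
        pos[5:8, 0] = -4.2
        cfg = make_config(pos, chain.sequence, [0] * 10, slit_geom)
        assert wall_contacting_chains(cfg) == {0}
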