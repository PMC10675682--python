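"""Forces, integration, boundaries, and thermostat behaviour.

Closed-form single-pair forces are asserted directly; the cell-list
kernel is cross-checked against an O(n^2) numpy evaluation of the same
conservative physics on random configurations.
"""

import math

import numpy as np
import pytest

from slitdpd.builder import Configuration, build_bulk, build_slit
from slitdpd.engine import (
    ForceField,
    bond_force,
    compute_forces,
    conservative_force,
    dissipative_random_force,
    measure_temperature,
    reflect,
    run,
    step,
    wall_force,
)
from slitdpd.model import BoxGeometry, ChainSpec, InteractionTable, SystemParams

from conftest import make_config


class TestPairForces:
    def test_conservative_vanishes_at_cutoff(self):
        assert np.allclose(conservative_force([1.0, 0, 0], 25.0), 0.0)

    def test_conservative_midrange_magnitude(self):
        f = conservative_force([0.5, 0, 0], 25.0)
        assert np.linalg.norm(f) == pytest.approx(12.5)
        assert f[0] > 0  # repulsive, along r_ij

    def test_conservative_beyond_cutoff(self):
        assert np.allclose(conservative_force([1.7, 0, 0], 40.0), 0.0)

    def test_dissipative_zero_for_perpendicular_motion(self):
        f_d, _ = dissipative_random_force(
            [0.5, 0, 0], [0, 1.0, 0], 4.5, 3.0, 0.05, theta=0.3
        )
        assert np.allclose(f_d, 0.0)

    def test_dissipative_parallel_magnitude(self):
        """gamma w_R^2 (e.v) = 4.5 * 0.25 * 1 at r = 0.5."""
        f_d, _ = dissipative_random_force(
            [0.5, 0, 0], [1.0, 0, 0], 4.5, 3.0, 0.05, theta=0.0
        )
        assert np.linalg.norm(f_d) == pytest.approx(1.125)
        assert f_d[0] < 0  # friction opposes approach... here opposes v along e

    def test_random_force_zero_mean(self):
        """Monte-Carlo: the random force averages to zero."""
        rng = np.random.default_rng(0)
        thetas = rng.uniform(-math.sqrt(3), math.sqrt(3), 100_000)
        acc = np.zeros(3)
        for t in thetas[:1000]:
            _, f_r = dissipative_random_force(
                [0.5, 0, 0], [0, 0, 0], 4.5, 3.0, 0.05, theta=t
            )
            acc += f_r
        # per-draw std of F_R,x is sigma*w/sqrt(dt)*1 = 6.7; 1000 draws
        assert abs(acc[0]) / 1000 < 4 * 6.7 / math.sqrt(1000)

    def test_bond_force_at_equilibrium(self):
        assert np.allclose(bond_force([0.3, 0, 0], K=4.0, r0=0.3), 0.0)

    def test_bond_force_attractive_magnitude(self):
        f = bond_force([1.0, 0, 0], K=4.0, r0=0.0)
        assert np.linalg.norm(f) == pytest.approx(4.0)
        assert f[0] < 0  # pulls i toward j

    def test_bonded_pair_newton_third_law(self):
        f_i = bond_force([0.7, 0.2, -0.1], K=4.0)
        f_j = bond_force([-0.7, -0.2, 0.1], K=4.0)
        assert np.allclose(f_i + f_j, 0.0)


class TestWallForce:
    def test_zero_at_range_boundary(self):
        assert wall_force(1.2, 25.0, 1.2) == 0.0

    def test_contact_magnitude(self):
        assert wall_force(0.0, 25.0, 1.2) == pytest.approx(25.0)

    def test_half_range(self):
        assert wall_force(0.6, 25.0, 1.2) == pytest.approx(12.5)


class TestReflect:
    def test_normal_component_inverted(self):
        x, vx = reflect(-5.2, -2.0, 5.0)
        assert vx == 2.0
        assert x == pytest.approx(-4.8)

    def test_kinetic_energy_preserved(self):
        x, vx = reflect(5.3, 3.0, 5.0)
        assert abs(vx) == 3.0

    def test_inside_untouched(self):
        assert reflect(4.0, 1.0, 5.0) == (4.0, 1.0)


class TestForceKernel:
    def brute_conservative(self, cfg, ff):
        """O(n^2) conservative + bond + wall forces (no thermostat)."""
        geom = cfg.geometry
        L = np.array([geom.Lx, geom.Ly, geom.Lz])
        a = ff._a_mat
        types = cfg.species_codes()
        n = cfg.n_beads
        f = np.zeros((n, 3))
        for i in range(n):
            for j in range(i + 1, n):
                if cfg.frozen[i] and cfg.frozen[j]:
                    continue
                dr = cfg.positions[i] - cfg.positions[j]
                for ax, per in enumerate(geom.periodic):
                    if per:
                        dr[ax] -= L[ax] * np.round(dr[ax] / L[ax])
                r = np.linalg.norm(dr)
                if 0 < r < 1.0:
                    fij = a[types[i], types[j]] * (1 - r) * dr / r
                    f[i] += fij
                    f[j] -= fij
        for b0, b1 in ff.bonds(cfg):
            dr = cfg.positions[b1] - cfg.positions[b0]
            for ax, per in enumerate(geom.periodic):
                if per:
                    dr[ax] -= L[ax] * np.round(dr[ax] / L[ax])
            r = np.linalg.norm(dr)
            if r > 0:
                fb = ff.chain.K * (r - ff.chain.r0) * dr / r
                f[b0] += fb
                f[b1] -= fb
        if geom.kind == "slit":
            half = geom.D / 2
            for i in range(n):
                if cfg.frozen[i]:
                    continue
                x = cfg.positions[i, 0]
                d = half - abs(x)
                if d < geom.x_c:
                    f[i, 0] += -np.sign(x) * geom.a_wall * (1 - max(d, 0) / geom.x_c)
        return f

    def _noiseless_ff(self, geom, chain=None):
        """Thermostat disabled (gamma=sigma=0 keeps the FDT balance)."""
        table = InteractionTable.default(gamma=0.0, sigma=0.0)
        return ForceField(table=table, chain=chain or ChainSpec(), geom=geom)

    @pytest.mark.parametrize("kind", ["bulk", "slit"])
    def test_kernel_matches_brute_force(self, kind, chain):
        rng = np.random.default_rng(17)
        if kind == "bulk":
            geom = BoxGeometry.bulk(5.0)
        else:
            geom = BoxGeometry.slit(5.0, L=5.0)
        n_chains = 4
        pos = rng.uniform(-2.2, 2.2, (n_chains * 10 + 20, 3))
        species = list(chain.sequence) * n_chains + ["S"] * 20
        cids = list(np.repeat(np.arange(n_chains), 10)) + [-1] * 20
        cfg = make_config(pos, species, cids, geom)
        ff = self._noiseless_ff(geom)
        f, _ = compute_forces(cfg, ff, seed=0)
        assert np.allclose(f, self.brute_conservative(cfg, ff), atol=1e-10)

    def test_pairwise_antisymmetry_total_force_zero_in_bulk(self, chain):
        geom = BoxGeometry.bulk(6.0)
        rng = np.random.default_rng(23)
        pos = rng.uniform(-3, 3, (200, 3))
        cfg = make_config(pos, ["S"] * 200, [-1] * 200, geom)
        ff = ForceField(table=InteractionTable.default(), chain=chain, geom=geom)
        f, _ = compute_forces(cfg, ff, seed=5)
        # conservative + dissipative + random all pairwise antisymmetric
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_exact_overlap_counted_not_crashing(self, chain):
        geom = BoxGeometry.bulk(5.0)
        pos = np.zeros((2, 3))
        cfg = make_config(pos, ["S", "S"], [-1, -1], geom)
        ff = self._noiseless_ff(geom)
        f, overlaps = compute_forces(cfg, ff, seed=0)
        assert overlaps == 1
        assert np.allclose(f, 0.0)


class TestIntegration:
    def test_zero_forces_zero_velocities_is_fixed_point(self, chain):
        geom = BoxGeometry.bulk(6.0)
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])  # beyond cutoff
        cfg = make_config(pos, ["S", "S"], [-1, -1], geom)
        table = InteractionTable.default(gamma=0.0, sigma=0.0)
        ff = ForceField(table=table, chain=chain, geom=geom)
        new = step(cfg, ff, seed=0)
        assert np.allclose(new.positions, cfg.positions)
        assert np.allclose(new.velocities, 0.0)

    def test_free_flight_is_linear(self, chain):
        """With all interactions off, positions advance as x + v dt."""
        geom = BoxGeometry.bulk(10.0)
        table = InteractionTable(
            a={k: 0.0 for k in ("AA", "AB", "AS", "AW", "BB", "BS", "BW",
                                "SS", "SW", "WW")},
            gamma=0.0, sigma=0.0,
        )
        ff = ForceField(table=table, chain=chain, geom=geom)
        rng = np.random.default_rng(2)
        pos = rng.uniform(-5, 5, (50, 3))
        vel = rng.normal(size=(50, 3))
        cfg = make_config(pos, ["S"] * 50, [-1] * 50, geom, velocities=vel.copy())
        new = cfg
        for k in range(10):
            new = step(new, ff, seed=k)
        expect = pos + 10 * 0.05 * vel
        expect -= 10.0 * np.round(expect / 10.0)
        assert np.allclose(new.positions, expect, atol=1e-12)

    def test_frozen_beads_never_move(self, chain):
        geom = BoxGeometry.slit(6.0, L=6.0)
        params = SystemParams(rho=3.0, n_chains=5, steps=200, sample_period=200,
                              seed=3)
        cfg = build_slit(params, chain, geom, seed=3)
        ff = ForceField(table=InteractionTable.default(), chain=chain, geom=geom)
        wall0 = cfg.positions[cfg.frozen].copy()
        traj = run(cfg, ff, params, seed=3)
        assert np.array_equal(traj.frames[-1].positions[cfg.frozen], wall0)

    def test_same_seed_bit_identical(self, chain):
        geom = BoxGeometry.bulk(5.0)
        params = SystemParams(rho=3.0, n_chains=6, steps=50, sample_period=50,
                              seed=8)
        cfg = build_bulk(params, chain, geom, seed=8)
        ff = ForceField(table=InteractionTable.default(), chain=chain, geom=geom)
        t1 = run(cfg, ff, params, seed=8)
        t2 = run(cfg, ff, params, seed=8)
        assert np.array_equal(t1.frames[-1].positions, t2.frames[-1].positions)
        assert np.array_equal(t1.frames[-1].velocities, t2.frames[-1].velocities)

    def test_slit_beads_stay_inside(self, chain):
        geom = BoxGeometry.slit(6.0, L=6.0)
        params = SystemParams(rho=3.0, n_chains=10, steps=300, sample_period=100,
                              seed=5)
        cfg = build_slit(params, chain, geom, seed=5)
        ff = ForceField(table=InteractionTable.default(), chain=chain, geom=geom)
        traj = run(cfg, ff, params, seed=5)
        for frame in traj:
            assert np.all(np.abs(frame.positions[frame.mobile, 0]) <= 3.0)

    def test_frame_count_arithmetic(self, chain):
        geom = BoxGeometry.bulk(5.0)
        params = SystemParams(rho=3.0, n_chains=0, steps=1000, sample_period=300,
                              seed=1)
        cfg = build_bulk(params, chain, geom, seed=1)
        ff = ForceField(table=InteractionTable.default(), chain=chain, geom=geom)
        assert len(run(cfg, ff, params, seed=1)) == 3  # floor(1000/300)


class TestTemperature:
    def test_all_at_rest(self, chain):
        geom = BoxGeometry.bulk(5.0)
        cfg = make_config(np.zeros((10, 3)), ["S"] * 10, [-1] * 10, geom)
        assert measure_temperature(cfg) == 0.0

    def test_equipartition_of_maxwell_draws(self, chain):
        geom = BoxGeometry.bulk(15.0)
        cfg = build_bulk(SystemParams(rho=3.0, n_chains=0, seed=11), chain, geom)
        assert measure_temperature(cfg) == pytest.approx(1.0, abs=0.02)

    def test_quadratic_in_speed(self, chain):
        geom = BoxGeometry.bulk(8.0)
        cfg = build_bulk(SystemParams(rho=3.0, n_chains=0, seed=12), chain, geom)
        doubled = cfg.copy()
        doubled.velocities *= 2.0
        assert measure_temperature(doubled) == pytest.approx(
            4.0 * measure_temperature(cfg)
        )

    def test_short_run_thermostats_near_unity(self, chain):
        """A few hundred steps of dense solvent stay near kT = 1."""
        geom = BoxGeometry.bulk(6.0)
        params = SystemParams(rho=3.0, n_chains=0, steps=500, sample_period=100,
                              seed=21)
        cfg = build_bulk(params, chain, geom, seed=21)
        ff = ForceField(table=InteractionTable.default(), chain=chain, geom=geom)
        traj = run(cfg, ff, params, seed=21)
        kts = [measure_temperature(f) for f in traj]
        assert 0.9 < np.mean(kts) < 1.15
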