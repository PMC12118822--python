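"""Polymer engine: initialization, Boltzmann oracles, LEF-bond coupling."""

import numpy as np
import pytest
from scipy import integrate as sciint

from smcsim import extrusion1d as e1d
from smcsim.polymer3d import (Conformation, ForceField, IntegratorParams,
                              compute_forces, init_conformation, integrate,
                              nm_per_unit, update_lef_bonds)


class TestInit:
    def test_two_bead_walk_has_unit_bond(self):
        c = init_conformation(2, "random_walk", seed=0)
        assert np.linalg.norm(c.positions[1] - c.positions[0]) == pytest.approx(1.0)

    def test_random_walk_end_to_end_statistics(self):
        """<R^2> = n b^2 for an n-step unit random walk (3 SE over seeds)."""
        n = 2000
        r2 = [np.sum((init_conformation(n + 1, "random_walk", seed=s).positions[-1]
                      - init_conformation(n + 1, "random_walk", seed=s).positions[0]) ** 2)
              for s in range(60)]
        se = np.std(r2) / np.sqrt(len(r2))
        assert abs(np.mean(r2) - n) < 3 * se

    def test_helix_mode_requires_geometry(self):
        with pytest.raises(ValueError, match="loop_array and geometry"):
            init_conformation(10, "helix_backbone", seed=0)

    def test_rejects_tiny_systems(self):
        with pytest.raises(ValueError):
            init_conformation(1, "random_walk")

    def test_coarse_grained_length_scale(self):
        assert nm_per_unit(200.0) == pytest.approx(10.0)
        assert nm_per_unit(1600.0) == pytest.approx(20.0)  # 8x bp -> 2x diameter


class TestIntegrator:
    def test_zero_forces_zero_temperature_fixed_point(self):
        c = init_conformation(5, "random_walk", seed=0)
        ff = ForceField(repulsion_a=0.0)
        out = integrate(c, ff, IntegratorParams(n_steps=100, temperature=0.0, seed=1),
                        include_chain_bonds=False)
        assert np.allclose(out.positions, c.positions)

    def test_seeded_determinism(self):
        c = init_conformation(20, "random_walk", seed=3)
        ff = ForceField(angle_k=1.5)
        a = integrate(c, ff, IntegratorParams(n_steps=200, seed=9))
        b = integrate(c, ff, IntegratorParams(n_steps=200, seed=9))
        assert np.array_equal(a.positions, b.positions)

    def test_divergence_detected(self):
        c = Conformation(np.array([[0.0, 0, 0], [1e5, 0, 0]]), bp_per_bead=200)
        ff = ForceField(repulsion_a=0.0,
                        constant_forces=np.array([[1, 1e6, 0.0, 0.0]]))
        with pytest.raises(RuntimeError, match="diverged"):
            integrate(c, ff, IntegratorParams(n_steps=200, seed=0),
                      include_chain_bonds=False)

    def test_bond_length_matches_boltzmann_average(self):
        """Mean bond length of a k=10, L0=1 harmonic dimer at T=1 matches the
        1D radial Boltzmann integral within 2%."""
        f = lambda r: r**2 * np.exp(-5.0 * (r - 1.0) ** 2)
        target = (sciint.quad(lambda r: r * f(r), 0, 10)[0]
                  / sciint.quad(f, 0, 10)[0])
        c = Conformation(np.array([[0.0, 0, 0], [1.0, 0, 0]]), bp_per_bead=200)
        ff = ForceField(repulsion_a=0.0)
        rs = []
        for i in range(250):
            c = integrate(c, ff, IntegratorParams(n_steps=60, seed=1000 + i))
            rs.append(np.linalg.norm(c.positions[1] - c.positions[0]))
        assert np.mean(rs) == pytest.approx(target, rel=0.02)

    def test_cylinder_wall_radial_boltzmann_oracle(self):
        """Fraction of samples inside the wall radius matches the Boltzmann
        integral of the implemented wall potential within 3 SE."""
        radius, eps, sigma = 5.0, 1.0, 0.5
        c = Conformation(np.array([[0.0, 0, 10.0], [0.5, 0, 10.0]]), bp_per_bead=200)
        ff = ForceField(repulsion_a=0.0, cylinder=(radius, 20.0, eps, sigma))
        rhos = []
        for i in range(500):
            c = integrate(c, ff, IntegratorParams(n_steps=25, seed=2000 + i),
                          include_chain_bonds=False)
            rhos.extend(np.linalg.norm(c.positions[:, :2], axis=1))
        rhos = np.asarray(rhos)

        def u_wall(r):
            inside = eps * np.exp(-0.5 * (radius - r) ** 2 / sigma**2)
            outside = eps + 0.5 * (eps / sigma**2) * (r - radius) ** 2
            return np.where(r <= radius, inside, outside)

        grid = np.linspace(0, radius + 6 * sigma, 4000)
        w = grid * np.exp(-u_wall(grid))
        expected_inside = np.trapezoid(w[grid <= radius], grid[grid <= radius]) \
            / np.trapezoid(w, grid)
        observed = np.mean(rhos <= radius)
        # decorrelate: samples 25 steps apart are correlated over ~ the radial
        # relaxation time; use a conservative effective n
        n_eff = len(rhos) / 20
        se = np.sqrt(expected_inside * (1 - expected_inside) / n_eff)
        assert abs(observed - expected_inside) < 3 * se + 0.01

    def test_chain_connectivity_preserved(self):
        c = init_conformation(50, "random_walk", seed=4)
        ff = ForceField(angle_k=1.5)
        out = integrate(c, ff, IntegratorParams(n_steps=500, seed=5))
        bl = np.linalg.norm(np.diff(out.positions, axis=0), axis=1)
        assert bl.max() < 3.0  # no broken bonds

    def test_soft_repulsion_allows_strand_passage(self):
        """Two interlinked rings unlink within a bounded run: the DPD-style
        soft core permits strand passage for topological equilibration."""
        n = 24
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = n / (2 * np.pi)
        ring1 = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)])
        ring2 = np.column_stack([r + r * np.cos(th), np.zeros(n), r * np.sin(th)])
        pos = np.vstack([ring1, ring2])
        c = Conformation(pos, bp_per_bead=200, chains=[(0, n), (n, 2 * n)])
        bonds = np.array([[n - 1, 0], [2 * n - 1, n]])  # close the rings
        ff = ForceField(bonds=bonds, bond_k=np.full(2, 10.0), bond_l0=np.ones(2),
                        repulsion_a=3.0)

        def com_dist(conf):
            return np.linalg.norm(conf.positions[:n].mean(0) - conf.positions[n:].mean(0))

        for i in range(60):
            c = integrate(c, ff, IntegratorParams(n_steps=500, seed=i))
            if com_dist(c) > 3 * r:
                break
        assert com_dist(c) > 3 * r  # rings drifted apart -> linking changed


class TestLefBonds:
    def test_bond_placement_from_leg_positions(self):
        lat = e1d.Lattice(n_sites=100)
        sp = e1d.LEFSpecies(name="c", separation_d_kb=100.0,
                            processivity_lambda_kb=None, loading="synchronous")
        st = e1d.initialize_state(lat, [sp], seed=0)
        st.lefs[0].legs = [10, 30]
        ff = update_lef_bonds(ForceField(), st, bp_per_bead=1000.0, n_beads=100)
        assert ff.lef_bonds.tolist() == [[10, 30]]

    def test_unbinding_removes_bond(self):
        lat = e1d.Lattice(n_sites=100)
        sp = e1d.LEFSpecies(name="c", separation_d_kb=50.0,
                            processivity_lambda_kb=None, loading="synchronous")
        st = e1d.initialize_state(lat, [sp], seed=0)
        for lef in st.lefs:
            lef.legs = [10 * (1 + lef.lef_id), 10 * (1 + lef.lef_id) + 5]
        ff = update_lef_bonds(ForceField(), st, 1000.0)
        n0 = len(ff.lef_bonds)
        st.lefs[0].bound = False
        ff = update_lef_bonds(ff, st, 1000.0)
        assert len(ff.lef_bonds) == n0 - 1

    def test_leg_outside_polymer_rejected(self):
        lat = e1d.Lattice(n_sites=100)
        sp = e1d.LEFSpecies(name="c", separation_d_kb=100.0,
                            processivity_lambda_kb=None, loading="synchronous")
        st = e1d.initialize_state(lat, [sp], seed=0)
        st.lefs[0].legs = [10, 90]
        with pytest.raises(ValueError, match="outside polymer"):
            update_lef_bonds(ForceField(), st, bp_per_bead=1000.0, n_beads=50)

    def test_replayed_trajectory_matches_leg_tables(self):
        """Across several 1D updates, the 3D bond set always equals the
        current set of nonzero loops (replay oracle)."""
        lat = e1d.Lattice(n_sites=200)
        sp = e1d.LEFSpecies(name="c", separation_d_kb=60.0,
                            processivity_lambda_kb=150.0)
        st = e1d.initialize_state(lat, [sp], seed=8)
        ff = ForceField()
        for _ in range(5):
            e1d.run_epochs(st, 10)
            ff = update_lef_bonds(ff, st, bp_per_bead=1000.0, n_beads=200)
            expected = sorted(tuple(sorted(l.legs)) for l in st.bound_lefs()
                              if l.legs[0] != l.legs[1])
            assert sorted(map(tuple, ff.lef_bonds.tolist())) == expected
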