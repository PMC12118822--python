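"""Loop arrays, geometry relations, force specs, cohesion planting."""

import math

import numpy as np
import pytest

from smcsim import mitotic_builder as mb


def consecutive_array(seed=0, l_chrom=100.0, l_loop=400.0, n_gap=2, bpb=4000.0):
    return mb.sample_consecutive_loops(l_chrom, l_loop, n_gap, seed=seed,
                                       bp_per_bead=bpb)


class TestLoopArrays:
    def test_expected_loop_count(self):
        arr = consecutive_array()
        assert len(arr.loops) == pytest.approx(250, rel=0.15)  # 100 Mb / 400 kb

    def test_sampled_mean_close_to_target(self):
        arr = mb.sample_consecutive_loops(200.0, 400.0, 2, seed=1, bp_per_bead=4000.0)
        sizes = np.array([(b - a) for a, b, _ in arr.loops]) * arr.bp_per_bead / 1e3
        assert len(sizes) >= 400
        assert sizes.mean() == pytest.approx(400.0, rel=0.05)

    def test_coverage_conservation_in_beads(self):
        arr = consecutive_array(n_gap=3)
        covered = sum(b - a + 1 for a, b, _ in arr.loops)
        roots = sorted(arr.layer("root"))
        gaps = sum(a2 - b1 - 1 for (_, b1), (a2, _) in zip(roots, roots[1:]))
        trailing = arr.n_beads - 1 - roots[-1][1]
        assert covered + gaps + trailing == arr.n_beads

    def test_rejects_subbead_loops(self):
        with pytest.raises(ValueError, match="below one bead"):
            mb.sample_consecutive_loops(10.0, 1.0, 2, bp_per_bead=4000.0)

    def test_consecutive_loops_do_not_cross(self):
        arr = consecutive_array(seed=3)
        roots = sorted(arr.layer("root"))
        for (a1, b1), (a2, b2) in zip(roots, roots[1:]):
            assert b1 < a2

    def test_overlapping_array_contains_crossing_pairs(self):
        """At 900 kb loops / one per 360 kb, independent placement overlaps."""
        arr = mb.sample_overlapping_loops(135.0, 900.0, 360.0, seed=0,
                                          bp_per_bead=4000.0)
        loops = sorted(arr.layer("root"))
        crossings = sum(
            1 for i, (a1, b1) in enumerate(loops)
            for a2, b2 in loops[i + 1:i + 20]
            if a1 < a2 < b1 < b2)
        assert crossings >= 1


class TestNested:
    def test_nested_count_per_root(self):
        root = consecutive_array(seed=5)
        nested = mb.subdivide_nested(root, 100.0, 0, seed=6)
        n_root = len(nested.layer("root"))
        n_nested = len(nested.layer("nested"))
        assert n_nested / n_root == pytest.approx(4.0, rel=0.2)  # 400/100

    def test_nested_boundaries_inside_roots(self):
        root = consecutive_array(seed=5)
        nested = mb.subdivide_nested(root, 100.0, 1, seed=6)
        roots = nested.layer("root")
        for a, b in nested.layer("nested"):
            assert any(ra <= a and b <= rb for ra, rb in roots)

    def test_zero_gap_nested_tiles_exactly(self):
        root = consecutive_array(seed=5)
        nested = mb.subdivide_nested(root, 100.0, 0, seed=6)
        for ra, rb in nested.layer("root"):
            subs = sorted((a, b) for a, b in nested.layer("nested")
                          if ra <= a and b <= rb)
            assert subs[0][0] == ra and subs[-1][1] == rb
            for (_, b1), (a2, _) in zip(subs, subs[1:]):
                assert a2 == b1  # shared anchors, no gaps

    def test_degenerate_nesting_warns(self):
        root = consecutive_array(seed=5, l_loop=100.0)
        with pytest.warns(UserWarning, match="degenerate"):
            mb.subdivide_nested(root, 400.0, 0, seed=6)


class TestGeometry:
    def test_condensin1_stretch_four_microns(self):
        p = mb.GeometryParams(l_chrom_mb=100.0, l_loop_kb=100.0, l_gap_nm=20.0,
                              l_turn_mb=100.0, rho_v_mb_per_um3=77.0,
                              sigma_c_nm=48.0, rho_l_mb_per_um=25.0,
                              mode="stretched_periodic")
        g = mb.derive_geometry(p)
        assert g.l_cyl_nm == pytest.approx(4000.0)

    def test_pitch_linear_density_interconversion(self):
        p = mb.GeometryParams(l_chrom_mb=100.0, l_loop_kb=400.0, l_gap_nm=80.0,
                              l_turn_mb=17.0, rho_v_mb_per_um3=44.0,
                              sigma_c_nm=48.0, pitch_nm=400.0)
        assert p.rho_l == pytest.approx(42.5)
        g = mb.derive_geometry(p)
        # round trip: rho_L from returned pitch and l_turn reproduces input
        assert p.l_turn_mb / (g.pitch_nm / 1000.0) == pytest.approx(p.rho_l, abs=1e-12)

    def test_cylinder_radius(self):
        p = mb.GeometryParams(l_chrom_mb=100.0, l_loop_kb=400.0, l_gap_nm=80.0,
                              l_turn_mb=17.0, rho_v_mb_per_um3=44.0,
                              sigma_c_nm=48.0, rho_l_mb_per_um=42.5)
        g = mb.derive_geometry(p)
        assert g.r_cyl_nm == pytest.approx(554.0, abs=2.0)

    def test_exactly_one_density_spec(self):
        with pytest.raises(ValueError, match="exactly one"):
            mb.GeometryParams(l_chrom_mb=100.0, l_loop_kb=400.0, l_gap_nm=80.0,
                              l_turn_mb=17.0, rho_v_mb_per_um3=44.0, sigma_c_nm=48.0,
                              rho_l_mb_per_um=42.5, pitch_nm=400.0)

    def test_periodic_box_volume_matches_density(self):
        p = mb.GeometryParams(l_chrom_mb=30.0, l_loop_kb=100.0, l_gap_nm=20.0,
                              l_turn_mb=30.0, rho_v_mb_per_um3=77.0,
                              sigma_c_nm=48.0, rho_l_mb_per_um=25.0,
                              mode="stretched_periodic")
        g = mb.derive_geometry(p)
        wx, wy, lz = np.asarray(g.box_nm) / 1000.0  # um
        assert wx * wy * lz == pytest.approx(30.0 / 77.0, rel=1e-9)


class TestForceSpec:
    def geometry(self, mode="cylinder_helix"):
        p = mb.GeometryParams(l_chrom_mb=100.0, l_loop_kb=400.0, l_gap_nm=80.0,
                              l_turn_mb=17.0, rho_v_mb_per_um3=44.0,
                              sigma_c_nm=48.0, pitch_nm=400.0, mode=mode)
        return mb.derive_geometry(p)

    def test_anchor_and_gap_bond_counts(self):
        arr = consecutive_array(seed=7)
        ff = mb.build_force_spec(arr, self.geometry(), "cylinder_helix", 4000.0)
        n_loops = len(arr.loops)
        assert len(ff.bonds) == n_loops + (n_loops - 1)

    def test_ghosts_and_terminal_torsions(self):
        arr = consecutive_array(seed=7)
        ff = mb.build_force_spec(arr, self.geometry(), "cylinder_helix", 4000.0)
        assert len(ff.ghost_beads) == 4
        assert len(ff.torsion_quadruplets) == 2

    def test_one_angular_pin_per_turn(self):
        arr = consecutive_array(seed=7)
        geom = self.geometry()
        ff = mb.build_force_spec(arr, geom, "cylinder_helix", 4000.0)
        # 2 terminal pins + floor(l_chrom / l_turn) per-turn pins
        assert len(ff.angular_pins) == 2 + math.floor(100.0 / 17.0)

    def test_mode_array_mismatch_rejected(self):
        arr = mb.sample_overlapping_loops(135.0, 900.0, 360.0, seed=0,
                                          bp_per_bead=4000.0)
        with pytest.raises(ValueError, match="consecutive"):
            mb.build_force_spec(arr, self.geometry(), "cylinder_helix", 4000.0)

    def test_overlapping_pins_match_anchor_angles(self):
        arr = mb.sample_overlapping_loops(135.0, 900.0, 360.0, seed=0,
                                          bp_per_bead=4000.0)
        geom = self.geometry("overlapping_helix")
        ff = mb.build_force_spec(arr, geom, "overlapping_helix", 4000.0)
        assert len(ff.angular_pins) == 2 * len(arr.loops)
        # stiffness tuned to 1 kT at 1.2 rad: 0.5 k (1.2)^2 = 1
        k = ff.angular_pins[0, 2]
        assert 0.5 * k * 1.2**2 == pytest.approx(1.0)


class TestConformations:
    def test_helix_anchor_z_extent_matches_turns(self):
        arr = consecutive_array(seed=8, l_chrom=50.0)
        p = mb.GeometryParams(l_chrom_mb=50.0, l_loop_kb=400.0, l_gap_nm=80.0,
                              l_turn_mb=17.0, rho_v_mb_per_um3=44.0,
                              sigma_c_nm=48.0, pitch_nm=400.0)
        geom = mb.derive_geometry(p)
        conf = mb.helix_conformation(arr, geom, 4000.0, seed=1)
        bb = arr.backbone_beads()
        z = conf.positions[bb, 2]
        u = mb.nm_per_unit(4000.0)
        assert z.max() - z.min() == pytest.approx(geom.l_cyl_nm / u, rel=0.05)

    def test_helix_appends_four_ghosts(self):
        arr = consecutive_array(seed=8, l_chrom=50.0)
        p = mb.GeometryParams(l_chrom_mb=50.0, l_loop_kb=400.0, l_gap_nm=80.0,
                              l_turn_mb=17.0, rho_v_mb_per_um3=44.0,
                              sigma_c_nm=48.0, pitch_nm=400.0)
        conf = mb.helix_conformation(arr, mb.derive_geometry(p), 4000.0, seed=1)
        assert conf.n_beads == arr.n_beads + 4
        assert conf.chains == [(0, arr.n_beads)]


class TestCohesion:
    def test_sites_poisson_count_and_midpoints(self):
        arr = consecutive_array(seed=9)
        spec = mb.plant_cohesion(arr, f_coh_per_mb=1.0, seed=2)
        n = len(spec["beads"])
        assert abs(n - 100) < 4 * math.sqrt(100)  # Poisson CI on 100 Mb
        midpoints = {(a + b) // 2 for a, b, _ in arr.loops}
        assert set(spec["beads"].tolist()) <= midpoints

    def test_zero_frequency_empty(self):
        arr = consecutive_array(seed=9)
        assert len(mb.plant_cohesion(arr, 0.0, seed=2)["beads"]) == 0

    def test_lateral_force_units(self):
        arr = consecutive_array(seed=9)
        spec = mb.plant_cohesion(arr, 1.0, seed=2)
        # 0.1 kT/nm at 4 kb beads (nm_per_unit ~ 27.1) -> ~2.71 kT/unit
        assert spec["force_kt_per_unit"] == pytest.approx(
            0.1 * mb.nm_per_unit(4000.0))
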