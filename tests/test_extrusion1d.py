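"""1D loop-extrusion engine: contracts, collisions, barriers, statistics."""

import numpy as np
import pytest
from scipy import stats

from smcsim import extrusion1d as e1d


class TestInitialization:
    def test_counts_from_separation_floor(self):
        lat = e1d.Lattice(n_sites=20_000)
        sp = e1d.LEFSpecies(name="cohesin", separation_d_kb=300.0,
                            processivity_lambda_kb=100.0)
        st = e1d.initialize_state(lat, [sp], seed=0)
        assert len(st.bound_lefs()) == 66  # floor(20000/300)

    def test_single_synchronous_condensin(self, single_condensin):
        assert len(single_condensin.bound_lefs()) == 1
        assert e1d.loop_size_stats(single_condensin)["sizes_kb"][0] == 0.0

    def test_seeded_determinism_of_placement(self, small_lattice):
        sp = e1d.LEFSpecies(name="c", separation_d_kb=20.0, processivity_lambda_kb=50.0)
        a = e1d.initialize_state(small_lattice, [sp], seed=42)
        b = e1d.initialize_state(small_lattice, [sp], seed=42)
        assert [l.legs for l in a.lefs] == [l.legs for l in b.lefs]

    def test_overdense_configuration_rejected(self):
        lat = e1d.Lattice(n_sites=10)
        sp = e1d.LEFSpecies(name="c", separation_d_kb=0.5)
        with pytest.raises(ValueError, match="over-dense"):
            e1d.initialize_state(lat, [sp], seed=0)

    def test_barrier_validation(self):
        with pytest.raises(ValueError):
            e1d.Lattice(n_sites=10, barriers=((20, 0.9),))
        with pytest.raises(ValueError):
            e1d.Lattice(n_sites=10, barriers=((5, 1.5),))


class TestStepping:
    def test_free_extruder_loop_grows_two_sites_per_epoch(self, single_condensin):
        e1d.run_epochs(single_condensin, 5)
        stats_ = e1d.loop_size_stats(single_condensin)
        lef = single_condensin.bound_lefs()[0]
        # 2k sites unless a lattice edge interfered
        expected = min(10, lef.legs[1] - 0 + (200 - 1 - lef.legs[0]))
        assert stats_["sizes_kb"][0] == expected

    def test_converging_extruders_stall_adjacent(self):
        lat = e1d.Lattice(n_sites=100)
        sp = e1d.LEFSpecies(name="condensin", separation_d_kb=50.0,
                            processivity_lambda_kb=None)
        st = e1d.initialize_state(lat, [sp], seed=3)
        e1d.run_epochs(st, 200)
        sites = sorted(s for l in st.bound_lefs() for s in l.legs)
        assert len(set(sites)) == len(sites)  # never share a site

    def test_seeded_trajectory_determinism(self):
        def run():
            lat = e1d.Lattice(n_sites=500, barriers=((100, 0.9), (400, 0.9)))
            sp = e1d.LEFSpecies(name="cohesin", separation_d_kb=50.0,
                                processivity_lambda_kb=80.0, barrier_mode="capturable")
            st = e1d.initialize_state(lat, [sp], seed=11)
            e1d.run_epochs(st, 300)
            return [(l.legs[:], l.captured[:], l.bound) for l in st.lefs]

        assert run() == run()

    def test_push_displaces_diffuser(self):
        """A condensin pushing a diffusing cohesive leg drives it forward."""
        lat = e1d.Lattice(n_sites=50)
        condensin = e1d.LEFSpecies(name="condensin", separation_d_kb=50.0,
                                   processivity_lambda_kb=None, loading="synchronous")
        pol = e1d.CollisionPolicy({("condensin", "walker"): "push"})
        st = e1d.initialize_state(lat, [condensin], pol, seed=0)
        cond = st.lefs[0]
        cond.legs = [20, 21]
        st.occupancy = {20: 0, 21: 0}
        walker_sp = e1d.LEFSpecies(name="walker", separation_d_kb=50.0,
                                   processivity_lambda_kb=None, motion="diffusing",
                                   step_interval=10**6)  # effectively frozen
        st.species["walker"] = walker_sp
        w = e1d.LEF(lef_id=1, species="walker", legs=[23, 23])
        st.lefs.append(w)
        st.occupancy[23] = 1
        for _ in range(5):
            e1d.step_epoch(st)
        # condensin's right leg moved 5 sites; the walker was pushed ahead of it
        assert cond.legs[1] == 26
        assert w.legs == [27, 27]

    def test_unload_removes_blocker(self):
        lat = e1d.Lattice(n_sites=60)
        condensin = e1d.LEFSpecies(name="condensin", separation_d_kb=60.0,
                                   processivity_lambda_kb=None, loading="synchronous")
        pol = e1d.CollisionPolicy({("condensin", "cohesin"): "unload"})
        st = e1d.initialize_state(lat, [condensin], pol, seed=0)
        st.lefs[0].legs = [30, 31]
        st.occupancy = {30: 0, 31: 0}
        st.species["cohesin"] = e1d.LEFSpecies(
            name="cohesin", separation_d_kb=60.0, processivity_lambda_kb=None,
            step_interval=10**6, rebind=False)
        blocker = e1d.LEF(lef_id=1, species="cohesin", legs=[33, 33])
        st.lefs.append(blocker)
        st.occupancy[33] = 1
        e1d.run_epochs(st, 3)
        assert not blocker.bound
        assert st.lefs[0].legs[1] >= 33

    def test_bypass_steps_over_blocker(self):
        lat = e1d.Lattice(n_sites=60)
        condensin = e1d.LEFSpecies(name="condensin", separation_d_kb=60.0,
                                   processivity_lambda_kb=None, loading="synchronous")
        pol = e1d.CollisionPolicy({("condensin", "cohesin"): "bypass"})
        st = e1d.initialize_state(lat, [condensin], pol, seed=0)
        st.lefs[0].legs = [30, 31]
        st.occupancy = {30: 0, 31: 0}
        st.species["cohesin"] = e1d.LEFSpecies(
            name="cohesin", separation_d_kb=60.0, processivity_lambda_kb=None,
            step_interval=10**6)
        blocker = e1d.LEF(lef_id=1, species="cohesin", legs=[32, 32])
        st.lefs.append(blocker)
        st.occupancy[32] = 1
        e1d.step_epoch(st)
        assert st.lefs[0].legs[1] == 33  # jumped over the occupied site
        assert blocker.legs == [32, 32]  # untouched

    def test_barrier_capture_holds_leg(self):
        lat = e1d.Lattice(n_sites=40, barriers=((25, 1.0),))
        sp = e1d.LEFSpecies(name="cohesin", separation_d_kb=40.0,
                            processivity_lambda_kb=None, loading="synchronous",
                            barrier_mode="capturable")
        st = e1d.initialize_state(lat, [sp], seed=0)
        st.lefs[0].legs = [20, 21]
        st.occupancy = {20: 0, 21: 0}
        e1d.run_epochs(st, 10)
        lef = st.lefs[0]
        assert lef.legs[1] == 25 and lef.captured[1]
        assert lef.legs[0] == 10 and not lef.captured[0]

    def test_transparent_species_ignores_barriers(self):
        lat = e1d.Lattice(n_sites=40, barriers=((25, 1.0),))
        sp = e1d.LEFSpecies(name="condensin", separation_d_kb=40.0,
                            processivity_lambda_kb=None, loading="synchronous",
                            barrier_mode="transparent")
        st = e1d.initialize_state(lat, [sp], seed=0)
        st.lefs[0].legs = [20, 21]
        st.occupancy = {20: 0, 21: 0}
        e1d.run_epochs(st, 10)
        assert st.lefs[0].legs == [10, 31]


class TestStatistics:
    def test_gap_fraction_trivial_cases(self, small_lattice):
        sp = e1d.LEFSpecies(name="c", separation_d_kb=200.0,
                            processivity_lambda_kb=None, loading="synchronous")
        st = e1d.initialize_state(small_lattice, [sp], seed=0)
        st.lefs[0].legs = [50, 149]  # half of 200 covered
        assert e1d.gap_fraction(st) == pytest.approx(0.5)
        st.lefs[0].bound = False
        assert e1d.gap_fraction(st) == 1.0

    def test_empty_stats_flagged(self, small_lattice):
        sp = e1d.LEFSpecies(name="c", separation_d_kb=200.0,
                            processivity_lambda_kb=None, loading="synchronous")
        st = e1d.initialize_state(small_lattice, [sp], seed=0)
        st.lefs[0].bound = False
        out = e1d.loop_size_stats(st)
        assert out["n"] == 0 and np.isnan(out["mean_kb"])

    def test_collision_limited_mean_loop_near_separation(self):
        """Immortal synchronous condensins stall against each other; mean
        loop approaches the separation d, and loops + gaps conserve length."""
        lat = e1d.Lattice(n_sites=2000)
        sp = e1d.LEFSpecies(name="condensin", separation_d_kb=100.0,
                            processivity_lambda_kb=None, loading="synchronous")
        st = e1d.initialize_state(lat, [sp], seed=5)
        e1d.run_epochs(st, 600)
        out = e1d.loop_size_stats(st)
        total = out["sizes_kb"].sum() + out["n"]  # inclusive bead per loop
        covered = (1 - e1d.gap_fraction(st)) * 2000
        assert total == pytest.approx(covered)
        assert out["mean_kb"] == pytest.approx(100.0, rel=0.25)

    def test_steady_state_gap_matches_mean_field_formula(self, steady_state_factory):
        """Non-interacting extruders reproduce g = e^(-lambda/d) within 3 SE."""
        for ratio in (0.5, 1.0, 2.0):
            st = steady_state_factory(100.0 * ratio, 100.0, self_default="bypass")
            gs = []
            for _ in range(200):
                e1d.run_epochs(st, 10)
                gs.append(e1d.gap_fraction(st))
            g = np.mean(gs)
            # effective sample size: snapshots 10 epochs apart are correlated
            # on the lifetime scale (~ lambda/2 epochs)
            n_eff = max(4, len(gs) / (100.0 * ratio / 2 / 10))
            se = np.std(gs) / np.sqrt(n_eff)
            assert abs(g - np.exp(-ratio)) < 3 * max(se, 0.005), (ratio, g)

    def test_loop_sizes_exponential_for_dilute_species(self, steady_state_factory):
        """Dilute extruders have ~exponential steady-state loop sizes."""
        st = steady_state_factory(100.0, 500.0, n_sites=10_000, burn_epochs=1500)
        sizes = []
        while len(sizes) < 2000:
            e1d.run_epochs(st, 25)
            sizes.extend(e1d.loop_size_stats(st)["sizes_kb"])
        sizes = np.asarray(sizes[:2000])
        sizes = sizes[sizes > 0]
        res = stats.kstest(sizes, "expon", args=(0, sizes.mean()))
        assert res.pvalue > 0.01

    def test_stall_policy_loops_never_interleave(self, steady_state_factory):
        st = steady_state_factory(200.0, 100.0, n_sites=2000, seed=9)
        for _ in range(20):
            e1d.run_epochs(st, 20)
            assert e1d.noncrossing_violations(st) == 0

    def test_bypass_policy_produces_interleavings(self, steady_state_factory):
        st = steady_state_factory(200.0, 100.0, n_sites=2000, seed=9,
                                  self_default="bypass")
        seen = 0
        for _ in range(20):
            e1d.run_epochs(st, 20)
            seen += e1d.noncrossing_violations(st)
        assert seen >= 1


class TestTwoChain:
    def test_cohesive_cohesin_spans_chains(self):
        lat = e1d.Lattice(n_sites=200, chain_bounds=(100,))
        sp = e1d.LEFSpecies(name="cohesive_cohesin", separation_d_kb=25.0,
                            processivity_lambda_kb=None, motion="diffusing",
                            two_chain=True)
        st = e1d.initialize_state(lat, [sp], seed=2)
        assert len(st.bound_lefs()) == 4  # floor(100/25)
        for lef in st.bound_lefs():
            chains = {lat.chain_of(leg) for leg in lef.legs}
            assert chains == {0, 1}

    def test_diffusing_legs_stay_on_their_chain(self):
        lat = e1d.Lattice(n_sites=200, chain_bounds=(100,))
        sp = e1d.LEFSpecies(name="cohesive_cohesin", separation_d_kb=50.0,
                            processivity_lambda_kb=None, motion="diffusing",
                            two_chain=True)
        st = e1d.initialize_state(lat, [sp], seed=2)
        e1d.run_epochs(st, 500)
        for lef in st.bound_lefs():
            assert sorted(lat.chain_of(leg) for leg in lef.legs) == [0, 1]

    def test_two_chain_loops_excluded_from_coverage(self):
        lat = e1d.Lattice(n_sites=200, chain_bounds=(100,))
        sp = e1d.LEFSpecies(name="cohesive_cohesin", separation_d_kb=25.0,
                            processivity_lambda_kb=None, motion="diffusing",
                            two_chain=True)
        st = e1d.initialize_state(lat, [sp], seed=2)
        assert e1d.gap_fraction(st) == 1.0


class TestTables:
    def test_lef_table_round_trip_semantics(self, single_condensin):
        e1d.run_epochs(single_condensin, 3)
        df = e1d.lef_table(single_condensin)
        assert len(df) == 1
        lef = single_condensin.bound_lefs()[0]
        assert df.left_kb[0] == min(lef.legs) and df.right_kb[0] == max(lef.legs)
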