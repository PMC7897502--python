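"""Loop extrusion: loading, translocation/collision, turnover, rate, runs."""
import numpy as np
import pytest

from condensim import (ChainState, Extruder, LEParams, SimParams,
                       SpecialSites, attempt_translocation, extrusion_forces,
                       extrusion_rate, load_extruders, p_sliding_for_rate,
                       run_free_chain, run_le, turnover)


class HandSteppedOracle:
    """Independent transcription of the translocation rules for tiny cases.

    Feet advance deterministically (p_sliding = 1); a foot stalls when its
    destination bead, or any of the ``buffer`` beads beyond it, is occupied
    by another foot, or when the destination lies off an end.
    """

    def __init__(self, loads, n_beads, buffer=1):
        self.front = list(loads)
        self.rear = list(loads)
        self.n = n_beads
        self.buffer = buffer

    def occupied(self):
        occ = {}
        for a in self.front + self.rear:
            occ[a] = occ.get(a, 0) + 1
        return occ

    def blocked(self, dest, direction):
        if dest < 0 or dest >= self.n:
            return True
        occ = self.occupied()
        for b in range(self.buffer + 1):
            probe = dest + b * direction
            if 0 <= probe < self.n and occ.get(probe, 0) > 0:
                return True
        return False

    def step(self):
        for k in range(len(self.front)):
            dest = self.front[k] + 1
            if not self.blocked(dest, 1):
                self.front[k] = dest
            dest = self.rear[k] - 1
            if not self.blocked(dest, -1):
                self.rear[k] = dest


class TestLoadExtruders:
    def test_full_occupancy_158_at_load_sites(self, sites):
        ex = load_extruders(sites, 1.0, rng_seed=0)
        assert len(ex) == 158
        for e in ex:
            assert e.front_anchor == e.rear_anchor == e.load_site

    def test_zero_occupancy(self, sites):
        assert load_extruders(sites, 0.0, rng_seed=0) == []

    def test_no_shared_load_sites(self, sites):
        ex = load_extruders(sites, 0.75, rng_seed=2)
        loads = [e.load_site for e in ex]
        assert len(set(loads)) == len(loads)


class TestTranslocation:
    def test_zero_probability_no_motion(self):
        ex = [Extruder(10, 10, 10)]
        attempt_translocation(ex, 100, 0.0, rng=0)
        assert (ex[0].front_anchor, ex[0].rear_anchor) == (10, 10)

    def test_single_extruder_symmetric_until_chain_end(self):
        ex = [Extruder(3, 3, 3)]
        for _ in range(10):
            attempt_translocation(ex, 8, 1.0, rng=0)
        # front stalls at bead 7 (end), rear at bead 0
        assert ex[0].front_anchor == 7
        assert ex[0].rear_anchor == 0
        assert ex[0].front_stalled and ex[0].rear_stalled

    def test_two_extruders_collide_and_continue_asymmetrically(self):
        """Inner feet stall on collision; outer feet keep extruding."""
        ex = [Extruder(10, 10, 10), Extruder(14, 14, 14)]
        oracle = HandSteppedOracle([10, 14], 30)
        for _ in range(12):
            attempt_translocation(ex, 30, 1.0, rng=0)
            oracle.step()
            assert [e.front_anchor for e in ex] == oracle.front
            assert [e.rear_anchor for e in ex] == oracle.rear
        # deadlocked inner feet kept one empty bead apart; outer feet
        # kept extruding
        assert ex[0].front_stalled and ex[1].rear_stalled
        assert ex[1].rear_anchor - ex[0].front_anchor == 2
        assert ex[0].rear_anchor == 0          # reached the telomere end
        assert ex[1].front_anchor == 14 + 12   # never blocked

    def test_inner_feet_deadlock_persists_while_blocked(self):
        ex = [Extruder(11, 11, 11), Extruder(13, 13, 13)]
        attempt_translocation(ex, 100, 1.0, rng=0)
        # e0 front tries 11->12 but 13 sits inside its exclusion zone
        assert ex[0].front_anchor == 11 and ex[0].front_stalled
        assert ex[1].rear_stalled
        attempt_translocation(ex, 100, 1.0, rng=0)
        assert ex[0].front_anchor == 11 and ex[0].front_stalled

    def test_zero_buffer_allows_adjacent_stalling(self):
        """With the exclusion zone disabled, feet pack onto adjacent beads."""
        ex = [Extruder(10, 10, 10), Extruder(14, 14, 14)]
        for _ in range(6):
            attempt_translocation(ex, 30, 1.0, rng=0, collision_buffer=0)
        assert ex[1].rear_anchor - ex[0].front_anchor == 1

    def test_anchor_exclusivity_invariant(self, sites):
        rng = np.random.default_rng(0)
        ex = load_extruders(sites, 1.0, rng_seed=0)
        for _ in range(200):
            attempt_translocation(ex, 1880, 0.5, rng=rng)
        anchors = [e.front_anchor for e in ex] + [e.rear_anchor for e in ex]
        counts = {}
        for a in anchors:
            counts[a] = counts.get(a, 0) + 1
        # a bead may hold both feet of one extruder only at its load point
        for e in ex:
            if e.front_anchor != e.rear_anchor:
                assert counts[e.front_anchor] == 1
                assert counts[e.rear_anchor] == 1


class TestExtrusionForces:
    def test_concentric_zero(self):
        state = ChainState(np.zeros((5, 3)))
        ex = [Extruder(2, 2, 2)]
        ff, fr, fb = extrusion_forces(ex, state, np.zeros((1, 3)),
                                      np.zeros((1, 3)))
        assert np.allclose(ff, 0) and np.allclose(fr, 0) and np.allclose(fb, 0)

    def test_displaced_foot_hooke(self):
        state = ChainState(np.zeros((5, 3)))
        ex = [Extruder(2, 3, 1)]
        feet_front = np.array([[15.0, 0, 0]])
        feet_rear = np.array([[0.0, 0, 0]])
        ff, fr, fb = extrusion_forces(ex, state, feet_front, feet_rear)
        # extrusion spring 1.5 pN toward anchor + structure spring 1.5 pN
        np.testing.assert_allclose(ff[0], [-3.0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fb[3], [1.5, 0, 0], atol=1e-12)

    def test_global_force_balance(self):
        rng = np.random.default_rng(1)
        state = ChainState(rng.uniform(-100, 100, (20, 3)))
        ex = [Extruder(5, 8, 2), Extruder(15, 16, 12)]
        feet_front = rng.uniform(-100, 100, (2, 3))
        feet_rear = rng.uniform(-100, 100, (2, 3))
        ff, fr, fb = extrusion_forces(ex, state, feet_front, feet_rear)
        total = ff.sum(axis=0) + fr.sum(axis=0) + fb.sum(axis=0)
        np.testing.assert_allclose(total, 0.0, atol=1e-10)


class TestTurnover:
    def test_zero_probability_no_change(self, sites):
        ex = load_extruders(sites, 0.5, rng_seed=0)
        before = [(e.load_site, e.front_anchor, e.rear_anchor) for e in ex]
        turnover(ex, sites, 0.0, rng=0)
        assert before == [(e.load_site, e.front_anchor, e.rear_anchor)
                          for e in ex]

    def test_count_conserved_and_full_relocation(self, sites):
        ex = load_extruders(sites, 0.3, rng_seed=1)
        n_before = len(ex)
        # move anchors away so old intervals exist
        for e in ex:
            e.front_anchor = min(e.load_site + 3, sites.n_beads - 1)
        turnover(ex, sites, 1.0, rng=2)
        assert len(ex) == n_before
        for e in ex:
            assert e.front_anchor == e.rear_anchor == e.load_site
            assert e.load_site in sites.condensin_sites

    def test_relocation_targets_empty_sites(self, sites):
        ex = load_extruders(sites, 1.0, rng_seed=0)  # all sites loaded
        turnover(ex, sites, 1.0, rng=3)
        # with every site anchored, each condensin reloads onto a site
        # that was free at its own turn (its own vacated site included)
        loads = [e.load_site for e in ex]
        assert all(l in sites.condensin_sites for l in loads)
        assert len(ex) == 158


class TestExtrusionRate:
    def test_default_parameters_give_1_2_kb_s(self):
        assert extrusion_rate(3e-5, 2000, 1e-4) == pytest.approx(1.2)

    def test_zero_probability_zero_rate(self):
        assert extrusion_rate(0.0, 2000, 1e-4) == 0.0

    def test_rate_inversion_roundtrip(self):
        p = p_sliding_for_rate(1.2, 2000, 1e-4)
        assert p == pytest.approx(3e-5)
        assert extrusion_rate(p, 2000, 1e-4) == pytest.approx(1.2)

    def test_monte_carlo_single_extruder_matches_closed_form(self):
        """Measured loop growth of one unobstructed extruder vs formula."""
        rng = np.random.default_rng(7)
        n_reps, n_steps = 15, 100_000  # 10 simulated s each
        total_beads = 0
        for _ in range(n_reps):
            ex = [Extruder(940, 940, 940)]
            for _ in range(n_steps):
                attempt_translocation(ex, 1880, 3e-5, rng=rng)
            total_beads += (ex[0].front_anchor - ex[0].rear_anchor)
        measured_kb_s = total_beads * 2000 / 1000 / (n_reps * n_steps * 1e-4)
        assert measured_kb_s == pytest.approx(extrusion_rate(3e-5, 2000, 1e-4),
                                              rel=0.10)


class TestRunLE:
    def test_zero_occupancy_bit_identical_to_free_chain(
            self, sites, init_state, small_params):
        free = run_free_chain(small_params, sites, init_state=init_state)
        le = run_le(small_params, LEParams(occupancy=0.0), sites,
                    init_state=init_state)
        np.testing.assert_array_equal(free.positions, le.positions)

    def test_same_seed_bit_identical(self, sites, init_state, small_params):
        a = run_le(small_params, LEParams(occupancy=0.5), sites,
                   init_state=init_state)
        b = run_le(small_params, LEParams(occupancy=0.5), sites,
                   init_state=init_state)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.le_front_anchor, b.le_front_anchor)

    def test_anchor_monotonicity_between_turnovers(self, le_mitosis):
        """front anchors only grow, rear only shrink, except at reload."""
        fa = le_mitosis.le_front_anchor
        ra = le_mitosis.le_rear_anchor
        load = le_mitosis.le_load
        dfa = np.diff(fa, axis=0)
        dra = np.diff(ra, axis=0)
        # a reload resets both anchors onto the (possibly identical) load
        # site, so exclude snapshots that end with freshly-reset anchors
        reloaded = (np.diff(load, axis=0) != 0) | \
            ((fa[1:] == load[1:]) & (ra[1:] == load[1:]))
        assert np.all(dfa[~reloaded] >= 0)
        assert np.all(dra[~reloaded] <= 0)

    def test_anchor_exclusivity_in_snapshots(self, le_mitosis):
        for s in range(0, le_mitosis.n_snapshots,
                       max(1, le_mitosis.n_snapshots // 10)):
            fa = le_mitosis.le_front_anchor[s]
            ra = le_mitosis.le_rear_anchor[s]
            anchors = np.concatenate([fa, ra])
            vals, counts = np.unique(anchors, return_counts=True)
            shared = vals[counts > 1]
            # doubly-occupied beads only where one extruder holds both feet
            for v in shared:
                both = (fa == v) & (ra == v)
                assert counts[vals == v][0] == 2 and both.any()

    def test_extruded_intervals_form_laminar_family(self, le_mitosis):
        """Anchor intervals are pairwise disjoint or nested (no z-loops)."""
        s = le_mitosis.n_snapshots - 1
        fa = le_mitosis.le_front_anchor[s]
        ra = le_mitosis.le_rear_anchor[s]
        n = fa.size
        for i in range(n):
            for j in range(i + 1, n):
                disjoint = fa[i] < ra[j] or fa[j] < ra[i]
                nested = ((ra[i] <= ra[j] and fa[j] <= fa[i])
                          or (ra[j] <= ra[i] and fa[i] <= fa[j]))
                assert disjoint or nested

    def test_count_conserved_through_run(self, le_mitosis):
        assert np.all((le_mitosis.le_load >= 0)
                      & (le_mitosis.le_load < 1880))
        assert le_mitosis.le_load.shape[1] == 158
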