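"""Readouts: distances, contact curves, volumes, MSD, anisotropy,
clustering and localization filtering — against hand-built and brute-force
oracles."""
import numpy as np
import pandas as pd
import pytest

from condensim import (ContactCurve, SimParams, Trajectory, anisotropy,
                       anisotropy_ratio, cluster_condensins,
                       contact_frequency, enhanced_range,
                       fluorophore_distance_series, filter_localizations,
                       mean_distance_map, msd_exponent, voxel_volume)


def make_traj(positions, times=None, metadata=None, **kwargs):
    positions = np.asarray(positions, dtype=float)
    if times is None:
        times = np.arange(positions.shape[0], dtype=float)
    meta = {"model": "free", "params": {"bp_per_bead": 2000}}
    if metadata:
        meta.update(metadata)
    return Trajectory(metadata=meta, times=times, positions=positions,
                      **kwargs)


def naive_dbscan(points, eps, min_samples):
    """Textbook DBSCAN (BFS over eps-neighbourhoods) as an oracle."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        stack.append(k)
        cluster += 1
    return labels


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestFluorophoreDistances:
    def test_identical_indices_zero(self):
        traj = make_traj(np.random.default_rng(0).uniform(0, 100, (5, 10, 3)))
        d, med = fluorophore_distance_series(traj, (3, 3))
        assert np.all(d == 0) and med == 0

    def test_straightened_chain_upper_bound(self):
        pos = np.zeros((1, 1000, 3))
        pos[0, :, 0] = np.arange(1000) * 52.0
        traj = make_traj(pos)
        d, med = fluorophore_distance_series(traj, (0, 900))
        assert med == pytest.approx(46.8, rel=1e-9)  # 900 x 52 nm in um

    def test_index_out_of_range(self):
        traj = make_traj(np.zeros((1, 10, 3)))
        with pytest.raises(IndexError):
            fluorophore_distance_series(traj, (0, 10))


class TestMeanDistanceMap:
    def test_single_conformation_equals_pairwise_matrix(self):
        from scipy.spatial.distance import pdist, squareform
        rng = np.random.default_rng(1)
        pos = rng.uniform(-100, 100, (1, 20, 3))
        dmap = mean_distance_map([make_traj(pos)])
        np.testing.assert_allclose(dmap, squareform(pdist(pos[0])))

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(2)
        trajs = [make_traj(rng.uniform(-100, 100, (4, 15, 3)))
                 for _ in range(3)]
        dmap = mean_distance_map(trajs)
        np.testing.assert_array_equal(dmap, dmap.T)
        np.testing.assert_array_equal(np.diag(dmap), 0.0)

    def test_interval_subsampling_counts(self):
        pos = np.zeros((11, 5, 3))
        traj = make_traj(pos, times=np.arange(11) * 0.5)
        # interval 1 s on 0.5 s cadence -> snapshots 0, 2, 4, ...
        dmap = mean_distance_map([traj], interval=1.0)
        assert dmap.shape == (5, 5)


# ---------------------------------------------------------------------------
# contact curves
# ---------------------------------------------------------------------------

class TestContactFrequency:
    def test_collapsed_beads_combinatorial_frequencies(self):
        n = 50
        traj = make_traj(np.zeros((1, n, 3)))
        curve = contact_frequency([traj], cutoff_nm=500, bin_width_kb=20)
        assert curve.frequency.sum() == pytest.approx(1.0)
        seps_kb = np.array([(j - i) * 2.0 for i in range(n)
                            for j in range(i + 1, n)])
        expected, _ = np.histogram(seps_kb, bins=curve.bin_edges_kb)
        np.testing.assert_allclose(curve.frequency,
                                   expected / expected.sum(), atol=1e-12)

    def test_zero_cutoff_degenerate(self):
        traj = make_traj(np.zeros((1, 10, 3)))
        curve = contact_frequency([traj], cutoff_nm=0.0)
        assert curve.frequency.sum() == 0.0

    def test_normalization_with_sparse_contacts(self):
        rng = np.random.default_rng(3)
        traj = make_traj(rng.uniform(-2000, 2000, (3, 100, 3)))
        curve = contact_frequency([traj], cutoff_nm=500)
        if curve.frequency.sum() > 0:
            assert curve.frequency.sum() == pytest.approx(1.0)
        assert np.all(curve.frequency >= 0)


class TestEnhancedRange:
    def _curve(self, freq):
        return ContactCurve(bin_edges_kb=np.arange(0, 20 * len(freq) + 1, 20.0),
                            frequency=np.asarray(freq), cutoff_nm=500)

    def test_identical_curves_empty_interval(self):
        c = self._curve(np.full(50, 0.02))
        assert enhanced_range(c, c) is None

    def test_synthetic_crossing_recovered(self):
        base = np.full(50, 0.02)
        boosted = base.copy()
        boosted[3:30] += 0.01   # bins 60..600 kb enhanced
        boosted[30:] -= 0.005   # keep roughly comparable mass
        lo, hi = enhanced_range(self._curve(boosted), self._curve(base),
                                smooth=False)
        assert (lo, hi) == (60.0, 600.0)

    def test_smoothing_bridges_single_bin_dropout(self):
        base = np.full(50, 0.02)
        boosted = base.copy()
        boosted[3:30] += 0.01
        boosted[10] = base[10] - 1e-4   # one noisy bin inside the run
        lo, hi = enhanced_range(self._curve(boosted), self._curve(base),
                                smooth=True)
        # the dropout does not split the run; the 3-bin average may widen
        # the detected interval by at most one bin on each side
        assert lo in (40.0, 60.0) and hi in (600.0, 620.0)
        assert hi - lo >= 540.0

    def test_mismatched_bins_rejected(self):
        a = self._curve(np.full(50, 0.02))
        b = self._curve(np.full(40, 0.025))
        with pytest.raises(ValueError):
            enhanced_range(a, b)


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------

class TestVoxelVolume:
    def test_single_bead_one_voxel(self):
        assert voxel_volume(np.array([[10.0, 10.0, 10.0]])) == pytest.approx(
            0.001)

    def test_lattice_beads_count_exactly(self):
        rng = np.random.default_rng(4)
        grid_pts = rng.choice(30 ** 3, size=200, replace=False)
        pos = np.stack(np.unravel_index(grid_pts, (30, 30, 30)),
                       axis=1) * 100.0 + 50.0 - 1500.0
        assert voxel_volume(pos) == pytest.approx(200 * 0.001)

    def test_upper_bound(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-1400, 1400, (1880, 3))
        v = voxel_volume(pos)
        assert v <= min(1880 * 0.001, 14.14) + 1e-9

    def test_translation_within_voxel_stable(self):
        pos = np.array([[0.0, 0.0, 0.0], [130.0, 0.0, 0.0]])
        assert voxel_volume(pos) == voxel_volume(pos + 3.0)


# ---------------------------------------------------------------------------
# MSD and anisotropy
# ---------------------------------------------------------------------------

def tracked_traj(tracks, frame=0.02):
    """Build a trajectory carrying only dense tracks (W, T, 3)."""
    tracks = np.asarray(tracks, dtype=float)
    w = tracks.shape[0]
    return make_traj(np.zeros((1, 2, 3)), times=np.array([0.0]),
                     track_indices=np.arange(tracks.shape[1]),
                     track_times=np.arange(w) * frame,
                     track_positions=tracks)


class TestMSDExponent:
    def test_ballistic_track_exponent_two(self):
        t = np.arange(101) * 0.02
        tracks = np.zeros((101, 1, 3))
        tracks[:, 0, 0] = 30.0 * t
        res = msd_exponent(tracked_traj(tracks), project_2d=False, rng=0)
        assert res.mean == pytest.approx(2.0, abs=1e-6)

    def test_brownian_track_exponent_one(self):
        rng = np.random.default_rng(6)
        steps = rng.normal(0, 5.0, (101, 80, 3))
        tracks = np.cumsum(steps, axis=0)
        res = msd_exponent(tracked_traj(tracks), project_2d=True, rng=1)
        assert res.mean == pytest.approx(1.0, abs=0.1)
        assert res.ci95 > 0
        # the 95% interval contains the mean by construction
        assert res.mean - res.ci95 < res.mean < res.mean + res.ci95

    def test_immobile_track_skipped(self):
        tracks = np.zeros((101, 1, 3))
        with pytest.raises(ValueError, match="no usable"):
            msd_exponent(tracked_traj(tracks), project_2d=False, rng=0)

    def test_missing_tracks_rejected(self):
        traj = make_traj(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError, match="track"):
            msd_exponent(traj)


class TestAnisotropy:
    def test_pure_x_track_maximal(self):
        t = np.arange(50)
        track = np.stack([np.cumsum(np.random.default_rng(7).normal(
            0, 3, 50)), np.zeros(50)], axis=1)
        res = anisotropy([track], frame_s=0.02)
        np.testing.assert_allclose(res.eta, 1.0, atol=1e-12)
        assert res.dxy_ratio == pytest.approx(0.0)

    def test_isotropic_walks_small_eta(self):
        rng = np.random.default_rng(8)
        tracks = [np.cumsum(rng.normal(0, 3, (400, 2)), axis=0)
                  for _ in range(100)]
        res = anisotropy(tracks, frame_s=0.02)
        assert res.eta_bar < 0.1
        assert np.all((res.eta >= 0) & (res.eta <= 1))

    def test_eta_decreases_with_track_length(self):
        rng = np.random.default_rng(9)
        short = [np.cumsum(rng.normal(0, 3, (30, 2)), axis=0)
                 for _ in range(150)]
        long = [np.cumsum(rng.normal(0, 3, (1000, 2)), axis=0)
                for _ in range(150)]
        assert anisotropy(long, frame_s=0.02).eta_bar < \
            anisotropy(short, frame_s=0.02).eta_bar

    @pytest.mark.parametrize("eta_bar,ratio", [(0.048, 0.64), (0.019, 0.758)])
    def test_published_ratio_mapping(self, eta_bar, ratio):
        assert anisotropy_ratio(eta_bar) == pytest.approx(ratio, abs=0.005)

    def test_immobile_track_excluded(self):
        good = np.cumsum(np.random.default_rng(10).normal(0, 3, (50, 2)),
                         axis=0)
        res = anisotropy([good, np.zeros((50, 2))], frame_s=0.02)
        assert res.n_excluded == 1 and res.n_tracks == 1


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClusterCondensins:
    def test_all_far_apart_all_noise(self):
        pts = np.arange(10)[:, None] * np.array([500.0, 0, 0])
        report = cluster_condensins(pts, eps_nm=100, min_size=2)
        assert (report.labels == -1).all()
        assert np.isnan(report.median_size)
        assert report.median_nn == pytest.approx(500.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_dbscan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-500, 500, (4, 3))
        pts = np.vstack([c + rng.normal(0, 40, (20, 3)) for c in centers]
                        + [rng.uniform(-800, 800, (20, 3))])
        ours = cluster_condensins(pts, eps_nm=100, min_size=3).labels
        oracle = naive_dbscan(pts, eps=100, min_samples=3)
        # identical partitions up to label renaming (incl. the noise set)
        assert set(map(frozenset, (np.flatnonzero(ours == u)
                                   for u in set(ours) - {-1}))) == \
            set(map(frozenset, (np.flatnonzero(oracle == u)
                                for u in set(oracle) - {-1})))
        np.testing.assert_array_equal(ours == -1, oracle == -1)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(-300, 300, (60, 3))
        perm = rng.permutation(60)
        a = cluster_condensins(pts, eps_nm=120, min_size=2)
        b = cluster_condensins(pts[perm], eps_nm=120, min_size=2)
        assert sorted(a.sizes.tolist()) == sorted(b.sizes.tolist())
        assert a.median_nn == pytest.approx(b.median_nn)

    def test_empty_input(self):
        report = cluster_condensins(np.empty((0, 3)))
        assert report.labels.size == 0 and np.isnan(report.median_nn)


# ---------------------------------------------------------------------------
# localization filtering
# ---------------------------------------------------------------------------

class TestFilterLocalizations:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["x", "y", "z", "frame", "quality",
                                           "axial_precision", "blink_run"])

    def test_empty_table(self):
        table = self.make_table([])
        assert len(filter_localizations(table)) == 0

    def test_hand_built_six_rows_three_survive(self):
        rows = [
            (0, 0, 0, 1, 0.9, 50.0, 5),    # passes
            (1, 0, 0, 2, 0.7, 50.0, 5),    # low quality
            (2, 0, 0, 3, 0.9, 50.0, 3),    # blink not longer than 3 frames
            (3, 0, 0, 4, 0.9, 120.0, 5),   # poor axial precision
            (4, 0, 0, 5, 0.8, 100.0, 4),   # boundary values pass
            (5, 0, 0, 6, 1.0, 10.0, 9),    # passes
        ]
        out = filter_localizations(self.make_table(rows))
        assert out["x"].tolist() == [0, 4, 5]   # order preserved

    def test_all_pass_identity(self):
        rows = [(i, 0, 0, i, 0.95, 20.0, 6) for i in range(4)]
        table = self.make_table(rows)
        pd.testing.assert_frame_equal(filter_localizations(table), table)

    def test_missing_column_named_in_error(self):
        table = pd.DataFrame({"quality": [0.9], "blink_run": [5]})
        with pytest.raises(KeyError, match="axial_precision"):
            filter_localizations(table)
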