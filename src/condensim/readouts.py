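"""Quantitative observables computed from trajectories or localization tables.

Fluorophore distances, Hi-C-like mean distance maps and contact-frequency
curves, voxel-occupancy volumes, windowed MSD exponents with 3D-to-2D
projection, short-time anisotropy, DBSCAN condensin clustering, and
STORM-style localization filtering.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN

from .trajectory import Trajectory

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def fluorophore_distance_series(traj: Trajectory, pair: Sequence[int]):
    """Per-snapshot 3D Euclidean distance (um) between two beads.

    Returns ``(distances, median)``.
    """
    i, j = pair
    n = traj.n_beads
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError("bead index out of range")
    d = np.linalg.norm(traj.positions[:, i] - traj.positions[:, j], axis=1)
    d_um = d / 1000.0
    return d_um, float(np.median(d_um))


def pooled_fluorophore_distances(trajs: Sequence[Trajectory],
                                 pair: Sequence[int]):
    """Distances pooled over replicates; returns ``(distances, median)``."""
    pooled = np.concatenate(
        [fluorophore_distance_series(t, pair)[0] for t in trajs])
    return pooled, float(np.median(pooled))


def _select_snapshots(traj: Trajectory, interval: float | None):
    if interval is None:
        return np.arange(traj.n_snapshots)
    step = traj.times[1] - traj.times[0] if traj.n_snapshots > 1 else interval
    every = max(1, int(round(interval / step)))
    return np.arange(0, traj.n_snapshots, every)


def mean_distance_map(trajs: Sequence[Trajectory],
                      interval: float | None = None) -> np.ndarray:
    """Bead-by-bead Euclidean distance (nm) averaged over sampled
    conformations and replicates; symmetric with a zero diagonal."""
    if not trajs:
        raise ValueError("need at least one trajectory")
    n = trajs[0].n_beads
    acc = np.zeros(n * (n - 1) // 2)
    count = 0
    for traj in trajs:
        for s in _select_snapshots(traj, interval):
            acc += pdist(traj.positions[s])
            count += 1
    if count == 0:
        raise ValueError("no snapshots selected")
    return squareform(acc / count)


# ---------------------------------------------------------------------------
# contact curves
# ---------------------------------------------------------------------------

@dataclass
class ContactCurve:
    """Normalized interaction frequency vs genomic separation."""

    bin_edges_kb: np.ndarray     # (B+1,)
    frequency: np.ndarray        # (B,), sums to 1 when any contact exists
    cutoff_nm: float
    n_conformations: int = 0

    @property
    def bin_centers_kb(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_kb[:-1] + self.bin_edges_kb[1:])

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("bin_low_kb,bin_high_kb,frequency\n")
            for lo, hi, f in zip(self.bin_edges_kb[:-1], self.bin_edges_kb[1:],
                                 self.frequency):
                fh.write(f"{lo:g},{hi:g},{f:.10g}\n")


def contact_frequency(trajs: Sequence[Trajectory], cutoff_nm: float = 500.0,
                      bin_width_kb: float = 20.0,
                      interval: float | None = None) -> ContactCurve:
    """Count bead pairs within ``cutoff_nm``, bin them by genomic
    separation, and normalize the bin frequencies to sum to one."""
    if cutoff_nm < 0:
        raise ValueError("cutoff must be non-negative")
    if not trajs:
        raise ValueError("need at least one trajectory")
    meta = trajs[0].metadata.get("params", {})
    bp_per_bead = meta.get("bp_per_bead", 2000)
    n = trajs[0].n_beads
    genome_kb = n * bp_per_bead / 1000.0
    edges = np.arange(0.0, genome_kb + bin_width_kb, bin_width_kb)
    counts = np.zeros(edges.size - 1)
    n_conf = 0
    if cutoff_nm == 0.0:
        logger.warning("contact cutoff is 0 nm: no interactions; "
                       "returning an all-zero, unnormalized curve")
        return ContactCurve(edges, counts, cutoff_nm, 0)
    for traj in trajs:
        for s in _select_snapshots(traj, interval):
            tree = cKDTree(traj.positions[s])
            pairs = tree.query_pairs(cutoff_nm, output_type="ndarray")
            n_conf += 1
            if pairs.size == 0:
                continue
            sep_kb = np.abs(pairs[:, 1] - pairs[:, 0]) * bp_per_bead / 1000.0
            h, _ = np.histogram(sep_kb, bins=edges)
            counts += h
    total = counts.sum()
    if total > 0:
        counts = counts / total
    return ContactCurve(edges, counts, cutoff_nm, n_conf)


def enhanced_range(curve_mitosis: ContactCurve, curve_interphase: ContactCurve,
                   smooth: bool = True):
    """Genomic-distance interval (kb) over which mitotic contact frequency
    exceeds interphase frequency: the longest contiguous positive run of
    the (optionally 3-bin moving-averaged) difference.  Returns
    ``(kb_low, kb_high)`` or ``None`` when no bin is enhanced."""
    if (curve_mitosis.bin_edges_kb.shape != curve_interphase.bin_edges_kb.shape
            or not np.allclose(curve_mitosis.bin_edges_kb,
                               curve_interphase.bin_edges_kb)):
        raise ValueError("contact curves must share bin edges")
    diff = curve_mitosis.frequency - curve_interphase.frequency
    if smooth:
        kernel = np.ones(3) / 3.0
        diff = np.convolve(diff, kernel, mode="same")
    pos = diff > 0
    best_len, best_start = 0, -1
    run_len, run_start = 0, 0
    for i, flag in enumerate(pos):
        if flag:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    if best_len == 0:
        return None
    edges = curve_mitosis.bin_edges_kb
    return float(edges[best_start]), float(edges[best_start + best_len])


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------

def voxel_volume(positions, voxel_nm: float = 100.0,
                 origin_nm: float = -1500.0) -> float:
    """Chromatin volume (um^3) as the count of occupied cubic voxels.

    A voxel is occupied when it contains at least one bead centre; the grid
    is anchored at a fixed origin so the measure is stable across snapshots.
    """
    if voxel_nm <= 0:
        raise ValueError("voxel size must be positive")
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        pos = pos.reshape(-1, 3)
    idx = np.floor((pos - origin_nm) / voxel_nm).astype(np.int64)
    n_occ = np.unique(idx, axis=0).shape[0]
    return n_occ * (voxel_nm / 1000.0) ** 3


def volume_series(traj: Trajectory, voxel_nm: float = 100.0) -> np.ndarray:
    """Voxel volume (um^3) of every snapshot."""
    return np.array([voxel_volume(traj.positions[s], voxel_nm)
                     for s in range(traj.n_snapshots)])


# ---------------------------------------------------------------------------
# MSD and anisotropy
# ---------------------------------------------------------------------------

@dataclass
class MSDResult:
    exponents: np.ndarray        # one per (window, bead)
    mean: float
    ci95: float                  # half-width, 1.96 * SEM
    delays_s: np.ndarray
    msd_mean: np.ndarray         # grand-average MSD per delay
    n_skipped: int = 0


def _random_plane_basis(rng) -> np.ndarray:
    """Random orthonormal 3x2 projection basis (uniform plane orientation)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    return q[:, :2]


def _time_averaged_msd(xy: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD for lags 1..max_lag of one track (L, d)."""
    out = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        disp = xy[k:] - xy[:-k]
        out[k - 1] = np.mean(np.sum(disp * disp, axis=1))
    return out


def _fit_loglog(delays: np.ndarray, msd: np.ndarray) -> float:
    good = msd > 0
    if good.sum() < 2:
        return np.nan
    slope, _ = np.polyfit(np.log(delays[good]), np.log(msd[good]), 1)
    return float(slope)


def msd_exponent(traj: Trajectory, tracked_beads=None, window_s: float = 2.0,
                 stride_s: float = 30.0, fit_max_s: float = 0.5,
                 project_2d: bool = True, rng=None) -> MSDResult:
    """Windowed MSD power-law exponents of tracked beads.

    For each window (``window_s`` long, starting every ``stride_s``) and
    each tracked bead, the dense track is optionally projected onto a
    random 2D plane, the time-averaged MSD is computed per delay, and an
    ordinary least-squares log-log fit over delays up to ``fit_max_s``
    yields one exponent.  The trajectory must carry dense tracks (recorded
    at the imaging-like 20 ms cadence by the runners' ``track_beads``).
    Immobile windows (zero MSD) are skipped and counted.
    """
    if traj.track_positions is None:
        raise ValueError("trajectory has no dense tracks; rerun with track_beads")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tt = traj.track_times
    frame = tt[1] - tt[0]
    pos = traj.track_positions               # (W, T, 3)
    if tracked_beads is not None:
        want = np.asarray(tracked_beads)
        sel = [int(np.where(traj.track_indices == b)[0][0]) for b in want]
        pos = pos[:, sel]
    win_len = int(round(window_s / frame))
    max_lag = max(1, int(round(fit_max_s / frame)))
    stride = max(1, int(round(stride_s / frame)))
    delays = np.arange(1, max_lag + 1) * frame

    exponents = []
    msd_acc = np.zeros(max_lag)
    n_msd = 0
    n_skipped = 0
    for start in range(0, pos.shape[0] - win_len, stride):
        seg = pos[start:start + win_len + 1]
        for b in range(seg.shape[1]):
            track = seg[:, b, :]
            if project_2d:
                track = track @ _random_plane_basis(rng)
            msd = _time_averaged_msd(track, max_lag)
            if np.all(msd == 0):
                n_skipped += 1
                continue
            e = _fit_loglog(delays, msd)
            if np.isnan(e):
                n_skipped += 1
                continue
            exponents.append(e)
            msd_acc += msd
            n_msd += 1
    exponents = np.asarray(exponents)
    if exponents.size == 0:
        raise ValueError("no usable MSD windows in trajectory")
    mean = float(exponents.mean())
    ci = float(1.96 * exponents.std(ddof=1) / np.sqrt(exponents.size)) \
        if exponents.size > 1 else 0.0
    return MSDResult(exponents=exponents, mean=mean, ci95=ci,
                     delays_s=delays, msd_mean=msd_acc / max(n_msd, 1),
                     n_skipped=n_skipped)


@dataclass
class AnisotropyResult:
    delays_s: np.ndarray
    eta: np.ndarray              # eta(dt) averaged over tracks
    eta_bar: float               # mean over delays <= max_delay
    dxy_ratio: float             # implied (1 - sqrt(eta)) / (1 + sqrt(eta))
    n_tracks: int = 0
    n_excluded: int = 0


def anisotropy_ratio(eta_bar: float) -> float:
    """Implied ratio of directional diffusion coefficients,
    D_x / D_y = (1 - sqrt(eta)) / (1 + sqrt(eta)) with D_x <= D_y."""
    s = np.sqrt(eta_bar)
    return float((1.0 - s) / (1.0 + s))


def anisotropy(tracks: Sequence[np.ndarray], frame_s: float = 0.02,
               max_delay_s: float = 0.1) -> AnisotropyResult:
    """Short-time anisotropy of 2D tracks.

    Per track and delay, the time-averaged directional MSDs give
    eta = (<dx^2> - <dy^2>)^2 / (<dx^2> + <dy^2>)^2; eta(dt) averages over
    tracks, eta_bar over delays up to ``max_delay_s``.  Tracks with zero
    total MSD are excluded and counted.
    """
    max_lag = max(1, int(round(max_delay_s / frame_s)))
    delays = np.arange(1, max_lag + 1) * frame_s
    per_track = []
    n_excluded = 0
    for tr in tracks:
        tr = np.asarray(tr, dtype=float)
        if tr.ndim != 2 or tr.shape[1] != 2:
            raise ValueError("each track must be an (L, 2) array")
        if tr.shape[0] < 2:
            raise ValueError("each track needs at least two points")
        lags = min(max_lag, tr.shape[0] - 1)
        eta_k = np.full(max_lag, np.nan)
        total = 0.0
        for k in range(1, lags + 1):
            disp = tr[k:] - tr[:-k]
            dx2 = np.mean(disp[:, 0] ** 2)
            dy2 = np.mean(disp[:, 1] ** 2)
            dr2 = dx2 + dy2
            total += dr2
            eta_k[k - 1] = ((dx2 - dy2) / dr2) ** 2 if dr2 > 0 else np.nan
        if total == 0.0:
            n_excluded += 1
            logger.warning("anisotropy: excluding immobile track")
            continue
        per_track.append(eta_k)
    if not per_track:
        raise ValueError("no usable tracks")
    eta = np.nanmean(np.vstack(per_track), axis=0)
    eta_bar = float(np.nanmean(eta))
    return AnisotropyResult(delays_s=delays, eta=eta, eta_bar=eta_bar,
                            dxy_ratio=anisotropy_ratio(eta_bar),
                            n_tracks=len(per_track), n_excluded=n_excluded)


def projected_window_tracks(traj: Trajectory, window_s: float = 2.0,
                            stride_s: float = 30.0, rng=None) -> list:
    """2D-projected per-window, per-bead tracks (for anisotropy analysis),
    using the same windows as the MSD readout."""
    if traj.track_positions is None:
        raise ValueError("trajectory has no dense tracks")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tt = traj.track_times
    frame = tt[1] - tt[0]
    pos = traj.track_positions
    win_len = int(round(window_s / frame))
    stride = max(1, int(round(stride_s / frame)))
    tracks = []
    for start in range(0, pos.shape[0] - win_len, stride):
        seg = pos[start:start + win_len + 1]
        for b in range(seg.shape[1]):
            tracks.append(seg[:, b, :] @ _random_plane_basis(rng))
    return tracks


# ---------------------------------------------------------------------------
# condensin clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    labels: np.ndarray           # DBSCAN labels, -1 = noise
    sizes: np.ndarray            # size of each cluster (label order)
    median_size: float           # nan when no cluster
    nn_distances: np.ndarray     # per-point nearest-neighbour distance
    median_nn: float


def cluster_condensins(positions, eps_nm: float = 100.0,
                       min_size: int = 2) -> ClusterReport:
    """DBSCAN clustering of condensin positions plus nearest-neighbour
    statistics (eps 100 nm, minimum cluster membership 2 by default)."""
    pts = np.asarray(positions, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        return ClusterReport(labels=np.empty(0, dtype=int),
                             sizes=np.empty(0, dtype=int), median_size=np.nan,
                             nn_distances=np.empty(0), median_nn=np.nan)
    labels = DBSCAN(eps=eps_nm, min_samples=min_size).fit(pts).labels_
    uniq = np.unique(labels[labels >= 0])
    sizes = np.array([(labels == u).sum() for u in uniq], dtype=int)
    median_size = float(np.median(sizes)) if sizes.size else np.nan
    if pts.shape[0] > 1:
        tree = cKDTree(pts)
        dist, _ = tree.query(pts, k=2)
        nn = dist[:, 1]
    else:
        nn = np.array([np.inf])
    return ClusterReport(labels=labels, sizes=sizes, median_size=median_size,
                         nn_distances=nn, median_nn=float(np.median(nn)))


# ---------------------------------------------------------------------------
# STORM localization filtering
# ---------------------------------------------------------------------------

def filter_localizations(table: pd.DataFrame, min_quality: float = 0.8,
                         min_blink_frames: int = 3,
                         max_axial_precision_nm: float = 100.0) -> pd.DataFrame:
    """Quality filtering of STORM localizations.

    Keeps rows with quality >= ``min_quality``, blink runs strictly longer
    than ``min_blink_frames`` frames, and axial precision no worse than
    ``max_axial_precision_nm``.  Row order is preserved; removal counts per
    criterion are logged.
    """
    for col in ("quality", "blink_run", "axial_precision"):
        if col not in table.columns:
            raise KeyError(f"localization table is missing column '{col}'")
    q = table["quality"] >= min_quality
    b = table["blink_run"] > min_blink_frames
    p = table["axial_precision"] <= max_axial_precision_nm
    logger.info("localization filter: %d low quality, %d short blink, "
                "%d poor axial precision (of %d rows)",
                int((~q).sum()), int((~b).sum()), int((~p).sum()), len(table))
    return table[q & b & p]
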