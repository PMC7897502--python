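"""Synthetic-input generators.

Condensin binding-site maps that reproduce the published ChIP-derived
spacing statistics (158 sites on 1880 beads, mean neighbour gap 11.7 beads,
median gap 6 beads), fluorophore placement, and synthetic STORM-style
localization tables for exercising the analysis layer.  The exact genomic
ChIP coordinates are not public; matching the summary statistics of the
gap distribution is the fidelity criterion.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import round_half_up

LOCALIZATION_COLUMNS = ("x", "y", "z", "frame", "quality",
                        "axial_precision", "blink_run")


@dataclass(frozen=True)
class BindingSiteMap:
    """Sorted condensin binding-site bead indices on a chain."""

    n_beads: int
    site_indices: tuple

    def __post_init__(self):
        idx = np.asarray(self.site_indices)
        if idx.size == 0:
            raise ValueError("site map must contain at least one site")
        if np.any(np.diff(idx) < 1):
            raise ValueError("site indices must be strictly increasing")
        if idx[0] < 0 or idx[-1] >= self.n_beads:
            raise ValueError("site indices must lie within [0, n_beads)")

    @property
    def gaps(self) -> np.ndarray:
        return np.diff(np.asarray(self.site_indices))

    @property
    def mean_gap(self) -> float:
        return float(np.mean(self.gaps))

    @property
    def median_gap(self) -> float:
        return float(np.median(self.gaps))

    # -- plain-text round trips --------------------------------------------

    def to_bed(self, path, bp_per_bead: int = 2000, chrom: str = "chrI_L"):
        """Write as 0-based half-open BED (one bead = bp_per_bead bp)."""
        with open(path, "w") as fh:
            for i in self.site_indices:
                fh.write(f"{chrom}\t{i * bp_per_bead}\t{(i + 1) * bp_per_bead}\n")

    @classmethod
    def from_bed(cls, path, n_beads: int, bp_per_bead: int = 2000):
        idx = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track")):
                continue
            _, start, _ = line.split("\t")[:3]
            idx.append(int(start) // bp_per_bead)
        return cls(n_beads=n_beads, site_indices=tuple(sorted(idx)))

    def to_index_list(self, path):
        Path(path).write_text("\n".join(str(i) for i in self.site_indices) + "\n")

    @classmethod
    def from_index_list(cls, path, n_beads: int):
        idx = [int(t) for t in Path(path).read_text().split()]
        return cls(n_beads=n_beads, site_indices=tuple(sorted(idx)))


def generate_binding_sites(n_beads: int = 1880, n_sites: int = 158,
                           mean_gap: float = 11.7, median_gap: int = 6,
                           rng_seed: int = 0) -> BindingSiteMap:
    """Draw a binding-site map whose neighbour gaps hit target statistics.

    Gaps come from a two-component geometric mixture (short gaps truncated
    at the median, long gaps shifted above it), built so the sorted middle
    gap is exactly ``median_gap``.  A deterministic adjustment pass then
    nudges long gaps until the gap sum equals ``round(mean_gap * (n_sites-1))``,
    so the realized mean matches the target to < 0.01 beads on every seed.
    """
    if n_sites < 2:
        raise ValueError("need at least two sites")
    if median_gap > mean_gap:
        raise ValueError("median_gap must not exceed mean_gap")
    n_gaps = n_sites - 1
    target_sum = int(round(mean_gap * n_gaps))
    if target_sum + 1 > n_beads:
        raise ValueError(
            f"targets infeasible: {n_sites} sites with mean gap {mean_gap} "
            f"span {target_sum + 1} beads > chain length {n_beads}")
    if target_sum < n_gaps:
        raise ValueError("mean_gap must be >= 1 bead")

    rng = np.random.default_rng(rng_seed)
    n_low = (n_gaps - 1) // 2
    n_high = n_gaps - 1 - n_low

    # short gaps: geometric truncated into [1, median]; long: median + geometric
    low = np.minimum(rng.geometric(0.45, size=n_low), median_gap)
    low_sum = low.sum() if n_low else 0.0
    high_mean = (target_sum - low_sum - median_gap) / max(n_high, 1)
    p_high = min(1.0, 1.0 / max(high_mean - median_gap, 1.0))
    high = median_gap + rng.geometric(p_high, size=n_high)
    gaps = np.concatenate([low, [median_gap], high]).astype(np.int64)

    # deterministic adjustment: cycle over the long gaps until the sum is exact
    delta = target_sum - int(gaps.sum())
    high_pos = np.arange(n_low + 1, n_gaps)
    if n_high == 0:
        # a single gap (or none above the median): absorb the residual directly
        gaps[-1] += delta
        if gaps[-1] < 1:
            raise ValueError("targets infeasible for so few sites")
        delta = 0
    k = 0
    guard = 0
    while delta != 0:
        i = high_pos[k % n_high]
        if delta > 0:
            gaps[i] += 1
            delta -= 1
        elif gaps[i] > median_gap:
            gaps[i] -= 1
            delta += 1
        k += 1
        guard += 1
        if guard > 10_000_000:  # pragma: no cover - defensive
            raise RuntimeError("gap adjustment failed to converge")

    gaps = rng.permutation(gaps)
    span = int(gaps.sum())
    start = int(rng.integers(0, n_beads - span))
    sites = start + np.concatenate([[0], np.cumsum(gaps)])
    return BindingSiteMap(n_beads=n_beads, site_indices=tuple(int(s) for s in sites))


#: Seed of the frozen default map shipped with the package.
DEFAULT_SITE_SEED = 1270

_DEFAULT_MAP = None


def default_binding_sites(n_beads: int = 1880,
                          n_sites: int | None = None) -> BindingSiteMap:
    """The package's default (frozen-seed) condensin binding-site map.

    For non-standard chain lengths the site count scales with the chain so
    the published site density (158 per 1880 beads) is preserved.
    """
    global _DEFAULT_MAP
    if n_sites is None:
        n_sites = 158 if n_beads == 1880 else max(2, round(n_beads * 158 / 1880))
    if (_DEFAULT_MAP is None or _DEFAULT_MAP.n_beads != n_beads
            or len(_DEFAULT_MAP.site_indices) != n_sites):
        m = generate_binding_sites(n_beads=n_beads, n_sites=n_sites,
                                   rng_seed=DEFAULT_SITE_SEED)
        if n_beads == 1880 and n_sites == 158:
            _DEFAULT_MAP = m
        return m
    return _DEFAULT_MAP


def default_fluorophore_offsets_mb(n_beads: int = 1880,
                                   bp_per_bead: int = 2000) -> tuple:
    """Published fluorophore offsets (Mb) that fit on the given chain."""
    return tuple(mb for mb in (0.1, 0.7, 1.2, 1.8, 2.2)
                 if mb * 1e6 / bp_per_bead <= n_beads - 1)


def place_fluorophores(n_beads: int, offsets_mb=(0.1, 0.7, 1.2, 1.8, 2.2),
                       bp_per_bead: int = 2000,
                       reference_bead: int | None = None) -> tuple:
    """Bead indices of fluorophore-tagged loci.

    Offsets are genomic distances (Mb) from a reference locus close to the
    centromere; the default reference is the centromere-end terminal bead.
    Returned indices are sorted ascending.
    """
    if reference_bead is None:
        reference_bead = n_beads - 1
    out = []
    for mb in offsets_mb:
        beads = round_half_up(mb * 1e6 / bp_per_bead)
        idx = reference_bead - beads
        if idx < 0 or idx >= n_beads:
            raise ValueError(f"offset {mb} Mb falls outside the chain")
        out.append(idx)
    return tuple(sorted(out))


def _uniform_ball(rng, n, radius):
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - got) + 8, 3))
        keep = cand[np.sum(cand ** 2, axis=1) <= radius ** 2]
        take = min(n - got, keep.shape[0])
        pts[got:got + take] = keep[:take]
        got += take
    return pts


def synth_localizations(n_clusters: int = 5, cluster_size=4,
                        cluster_sigma_nm: float = 10.0,
                        noise_fraction: float = 0.1,
                        n_noise: int | None = None,
                        quality_dist=None, precision_dist=None,
                        blink_dist=None,
                        sphere_radius_nm: float = 1500.0,
                        min_center_sep_nm: float = 300.0,
                        n_frames: int = 20000,
                        rng_seed: int = 0):
    """Synthetic STORM-style localization table with ground-truth labels.

    Gaussian clusters (isotropic ``cluster_sigma_nm``) around centres placed
    uniformly in a sphere with a minimum mutual separation, plus uniform
    noise localizations.  Per-row quality, axial precision and blink-run
    values are drawn from the supplied samplers ``f(rng, size) -> array``
    (defaults produce a mix of passing and failing rows for the filter).

    Returns ``(table, labels)`` where ``table`` is a DataFrame with columns
    x, y, z, frame, quality, axial_precision, blink_run and ``labels`` holds
    the generating cluster index per row (-1 for noise).
    """
    rng = np.random.default_rng(rng_seed)
    if callable(cluster_size):
        sizes = np.array([int(cluster_size(rng)) for _ in range(n_clusters)])
    elif np.isscalar(cluster_size):
        sizes = np.full(n_clusters, int(cluster_size))
    else:
        sizes = np.asarray(cluster_size, dtype=int)
        if sizes.size != n_clusters:
            raise ValueError("cluster_size sequence must have n_clusters entries")
    if np.any(sizes < 1):
        raise ValueError("cluster sizes must be >= 1")

    centers = np.empty((n_clusters, 3))
    placed = 0
    attempts = 0
    while placed < n_clusters:
        cand = _uniform_ball(rng, 1, sphere_radius_nm - 3 * cluster_sigma_nm)[0]
        if placed == 0 or np.min(
                np.linalg.norm(centers[:placed] - cand, axis=1)) >= min_center_sep_nm:
            centers[placed] = cand
            placed += 1
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place cluster centres; "
                               "reduce min_center_sep_nm or n_clusters")

    pts = []
    labels = []
    for c in range(n_clusters):
        pts.append(centers[c] + rng.normal(0.0, cluster_sigma_nm, size=(sizes[c], 3)))
        labels.extend([c] * sizes[c])
    n_signal = int(sizes.sum()) if n_clusters > 0 else 0

    if n_noise is None:
        if n_clusters == 0:
            n_noise = 100
        else:
            if not 0.0 <= noise_fraction < 1.0:
                raise ValueError("noise_fraction must lie in [0, 1)")
            n_noise = int(round(noise_fraction * n_signal / (1.0 - noise_fraction)))
    if n_noise > 0:
        pts.append(_uniform_ball(rng, n_noise, sphere_radius_nm))
        labels.extend([-1] * n_noise)

    xyz = np.vstack(pts) if pts else np.empty((0, 3))
    n_rows = xyz.shape[0]
    if quality_dist is None:
        quality_dist = lambda r, size: r.uniform(0.5, 1.0, size=size)
    if precision_dist is None:
        precision_dist = lambda r, size: r.exponential(60.0, size=size)
    if blink_dist is None:
        blink_dist = lambda r, size: r.integers(1, 10, size=size)

    table = pd.DataFrame({
        "x": xyz[:, 0],
        "y": xyz[:, 1],
        "z": xyz[:, 2],
        "frame": rng.integers(0, n_frames, size=n_rows),
        "quality": np.clip(quality_dist(rng, n_rows), 0.0, 1.0),
        "axial_precision": precision_dist(rng, n_rows),
        "blink_run": blink_dist(rng, n_rows),
    })
    return table, np.asarray(labels, dtype=int)


def write_localizations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=list(LOCALIZATION_COLUMNS))


def read_localizations(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in LOCALIZATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"localization table missing column(s): {missing}")
    return table
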