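"""Trajectory container and file round-tripping.

A trajectory holds time-stamped chain snapshots, optional mechanism state
(diffusion-capture feet or extruder anchors/feet), and optional dense
single-bead tracks used for MSD/anisotropy analysis.  On disk it is a
self-describing HDF5 file (metadata as JSON attribute, arrays as datasets);
a flat CSV exporter is provided for interoperability.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

FORMAT_VERSION = 1


@dataclass
class Trajectory:
    """Snapshots of a single simulation replicate.

    ``positions`` has shape (S, N, 3) in nm; ``times`` (S,) in s, strictly
    increasing with the initial state at index 0.  ``metadata`` records the
    model kind ("free"|"dc"|"le"), all parameters and the seed, sufficient
    to reproduce the run bit-for-bit.
    """

    metadata: dict
    times: np.ndarray
    positions: np.ndarray
    # diffusion capture state
    dc_sites: Optional[np.ndarray] = None        # (C,)
    dc_front: Optional[np.ndarray] = None        # (S, C, 3)
    dc_rear: Optional[np.ndarray] = None         # (S, C, 3)
    capture_pair_counts: Optional[np.ndarray] = None  # (S,)
    # loop extrusion state
    le_load: Optional[np.ndarray] = None         # (S, E)
    le_front_anchor: Optional[np.ndarray] = None  # (S, E)
    le_rear_anchor: Optional[np.ndarray] = None   # (S, E)
    le_front_stalled: Optional[np.ndarray] = None  # (S, E) bool
    le_rear_stalled: Optional[np.ndarray] = None   # (S, E) bool
    le_front: Optional[np.ndarray] = None        # (S, E, 3)
    le_rear: Optional[np.ndarray] = None         # (S, E, 3)
    # dense tracks of selected beads
    track_indices: Optional[np.ndarray] = None   # (T,)
    track_times: Optional[np.ndarray] = None     # (W,)
    track_positions: Optional[np.ndarray] = None  # (W, T, 3)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (S, N, 3)")
        if self.times.shape[0] != self.positions.shape[0]:
            raise ValueError("times and positions disagree on snapshot count")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def model(self) -> str:
        return self.metadata.get("model", "free")

    @property
    def n_snapshots(self) -> int:
        return int(self.times.shape[0])

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[1])

    # -- persistence --------------------------------------------------------

    _ARRAYS = ("dc_sites", "dc_front", "dc_rear", "capture_pair_counts",
               "le_load", "le_front_anchor", "le_rear_anchor",
               "le_front_stalled", "le_rear_stalled", "le_front", "le_rear",
               "track_indices", "track_times", "track_positions")

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["format_version"] = FORMAT_VERSION
            fh.attrs["metadata"] = json.dumps(self.metadata, sort_keys=True)
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("positions", data=self.positions)
            for name in self._ARRAYS:
                arr = getattr(self, name)
                if arr is not None:
                    fh.create_dataset(name, data=np.asarray(arr))

    @classmethod
    def load(cls, path) -> "Trajectory":
        try:
            with h5py.File(path, "r") as fh:
                version = int(fh.attrs.get("format_version", -1))
                if version != FORMAT_VERSION:
                    raise ValueError(
                        f"unsupported trajectory format version {version} "
                        f"(expected {FORMAT_VERSION})")
                kwargs = {
                    "metadata": json.loads(fh.attrs["metadata"]),
                    "times": fh["times"][...],
                    "positions": fh["positions"][...],
                }
                for name in cls._ARRAYS:
                    if name in fh:
                        kwargs[name] = fh[name][...]
                return cls(**kwargs)
        except OSError as exc:
            raise ValueError(f"not a readable trajectory file: {path}: {exc}")

    def to_csv(self, path) -> None:
        """Flat text export: snapshot_time, bead_index, x, y, z."""
        with open(path, "w") as fh:
            fh.write("snapshot_time,bead_index,x,y,z\n")
            for s in range(self.n_snapshots):
                t = self.times[s]
                for b in range(self.n_beads):
                    x, y, z = self.positions[s, b]
                    fh.write(f"{t:.6g},{b},{x:.6f},{y:.6f},{z:.6f}\n")

    # -- convenience --------------------------------------------------------

    def condensin_points(self, snapshot: int, mode: str = "midpoint") -> np.ndarray:
        """Per-condensin representative 3D points for clustering readouts.

        ``midpoint`` averages the two feet; ``front`` uses the front foot.
        """
        if self.model == "dc":
            front, rear = self.dc_front[snapshot], self.dc_rear[snapshot]
        elif self.model == "le":
            front, rear = self.le_front[snapshot], self.le_rear[snapshot]
        else:
            raise ValueError("free-chain trajectories carry no condensins")
        if mode == "front":
            return np.asarray(front)
        if mode == "midpoint":
            return 0.5 * (np.asarray(front) + np.asarray(rear))
        raise ValueError("mode must be 'midpoint' or 'front'")
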