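"""Loop-extrusion mechanism.

Condensins load at binding sites; their two feet translocate symmetrically
outward one bead at a time, stall when the destination bead is anchored by
another foot or lies off a chain end, and turn over (unload + immediate
reload at an empty binding site) at T_exchange intervals.  Feet never pass
each other, so z-loops are excluded by construction; nested loops arise
when a condensin reloads inside another's extruded interval.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine
from .chain import ChainState, SpecialSites, _run
from .params import SimParams, LEParams, round_half_up
from .trajectory import Trajectory


@dataclass
class Extruder:
    """A loop-extruding condensin: load site, current anchors, stall flags."""

    load_site: int
    front_anchor: int
    rear_anchor: int
    front_stalled: bool = False
    rear_stalled: bool = False

    def __post_init__(self):
        if not self.rear_anchor <= self.load_site <= self.front_anchor:
            raise ValueError("anchors must bracket the load site")


def load_extruders(sites: SpecialSites, occupancy: float,
                   rng_seed: int = 0) -> list[Extruder]:
    """round(occupancy * n_sites) extruders, each with both anchors at its
    load site; load sites sampled uniformly without replacement."""
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    all_sites = np.asarray(sites.condensin_sites, dtype=int)
    if all_sites.size == 0:
        raise ValueError("site list is empty")
    n = round_half_up(occupancy * all_sites.size)
    rng = np.random.default_rng(rng_seed)
    chosen = np.sort(rng.choice(all_sites, size=n, replace=False))
    return [Extruder(load_site=int(s), front_anchor=int(s), rear_anchor=int(s))
            for s in chosen]


def _anchor_occupancy(extruders, chain_length):
    occ = np.zeros(chain_length, dtype=int)
    for e in extruders:
        occ[e.front_anchor] += 1
        occ[e.rear_anchor] += 1
    return occ


def attempt_translocation(extruders: list[Extruder], chain_length: int,
                          p_sliding: float, rng=None,
                          collision_buffer: int = 1) -> list[Extruder]:
    """One translocation sweep (in place).

    Every non-colliding foot advances its anchor by one bead with
    probability p_sliding; a foot stalls when the destination bead — or any
    of the ``collision_buffer`` beads beyond it — is anchored by another
    foot, or when the destination lies off a chain end.  Stall flags are
    re-evaluated on every attempt, so a stall releases once the blocker
    moves away or turns over.  One uniform is consumed per foot per sweep
    (front then rear, in list order).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    occ = _anchor_occupancy(extruders, chain_length)

    def blocked(dest, direction):
        if dest < 0 or dest >= chain_length:
            return True
        for b in range(collision_buffer + 1):
            probe = dest + b * direction
            if 0 <= probe < chain_length and occ[probe] > 0:
                return True
        return False

    for e in extruders:
        if rng.random() < p_sliding:
            dest = e.front_anchor + 1
            if blocked(dest, 1):
                e.front_stalled = True
            else:
                occ[e.front_anchor] -= 1
                e.front_anchor = dest
                occ[dest] += 1
                e.front_stalled = False
        if rng.random() < p_sliding:
            dest = e.rear_anchor - 1
            if blocked(dest, -1):
                e.rear_stalled = True
            else:
                occ[e.rear_anchor] -= 1
                e.rear_anchor = dest
                occ[dest] += 1
                e.rear_stalled = False
    return extruders


def extrusion_forces(extruders: list[Extruder], state: ChainState,
                     feet_front: np.ndarray, feet_rear: np.ndarray,
                     K_ten: float = 0.1, c4prime: float = 0.0):
    """Extrusion springs (foot to its anchor bead, eq c4') plus the
    structure spring between feet; third-law reactions on anchored beads.

    Returns ``(f_front, f_rear, f_beads)``.
    """
    ne = len(extruders)
    f_front = np.zeros((ne, 3))
    f_rear = np.zeros((ne, 3))
    f_beads = np.zeros_like(state.positions)

    def spring(pa, pb, k, eq):
        d = pb - pa
        r = np.linalg.norm(d)
        if r == 0.0:
            return np.zeros(3)
        return k * (r - eq) / r * d

    for k, e in enumerate(extruders):
        f = spring(feet_front[k], feet_rear[k], K_ten, 0.0)
        f_front[k] += f
        f_rear[k] -= f
        f = spring(feet_front[k], state.positions[e.front_anchor], K_ten, c4prime)
        f_front[k] += f
        f_beads[e.front_anchor] -= f
        f = spring(feet_rear[k], state.positions[e.rear_anchor], K_ten, c4prime)
        f_rear[k] += f
        f_beads[e.rear_anchor] -= f
    return f_front, f_rear, f_beads


def turnover(extruders: list[Extruder], sites: SpecialSites,
             p_onoff: float, rng=None) -> list[Extruder]:
    """Unload/reload sweep (in place), called at T_exchange multiples.

    Each extruder unloads with probability p_onoff and immediately reloads
    at a uniformly chosen empty binding site (no anchored foot), resetting
    both anchors; with no empty site it reloads at its own vacated site.
    The condensin count never changes.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    occ = _anchor_occupancy(extruders, sites.n_beads)
    all_sites = np.asarray(sites.condensin_sites, dtype=int)
    for e in extruders:
        if rng.random() < p_onoff:
            occ[e.front_anchor] -= 1
            occ[e.rear_anchor] -= 1
            empty = all_sites[occ[all_sites] == 0]
            if empty.size == 0:
                new = e.load_site
            else:
                new = int(empty[rng.integers(empty.size)])
            e.load_site = new
            e.front_anchor = new
            e.rear_anchor = new
            e.front_stalled = False
            e.rear_stalled = False
            occ[new] += 2
    return extruders


def extrusion_rate(p_sliding: float, bp_per_bead: int, dt: float) -> float:
    """Unobstructed extrusion speed in kb/s: both feet advance one bead per
    successful draw, so v = 2 * p_sliding * bp_per_bead / dt."""
    if p_sliding < 0 or bp_per_bead <= 0 or dt <= 0:
        raise ValueError("inputs must be positive (p_sliding non-negative)")
    return 2.0 * p_sliding * bp_per_bead / dt / 1000.0


def p_sliding_for_rate(rate_kb_s: float, bp_per_bead: int, dt: float) -> float:
    """Translocation probability that yields a target extrusion speed."""
    return rate_kb_s * 1000.0 * dt / (2.0 * bp_per_bead)


def run_le(params: SimParams, le: LEParams | None = None,
           sites: SpecialSites | None = None, track_beads=None,
           track_interval: float = 0.02,
           init_state: ChainState | None = None) -> Trajectory:
    """Full loop-extrusion dynamics with per-step translocation sweeps and
    turnover checks every T_exchange; snapshots record anchors, stall flags
    and feet positions."""
    le = le or LEParams()
    sites = sites or SpecialSites.default(params)
    if init_state is None:
        from .chain import init_conformation
        init_state = init_conformation(params, sites, rng_seed=params.seed)
    extruders = load_extruders(sites, le.occupancy, rng_seed=params.seed)
    return _run(params, sites, engine.MODE_LE, le=le, le_extruders=extruders,
                track_beads=track_beads, track_interval=track_interval,
                init_state=init_state)
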