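"""The bead-spring chromatin chain.

Topology and special sites, self-avoiding initialization inside a
cylindrical sub-volume of the nucleus, the three passive forces
(stochastic, tension, repulsion), the Euler-integrated overdamped-Langevin
stepper, and the free-chain runner.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from . import engine
from .fixtures import (default_binding_sites, default_fluorophore_offsets_mb,
                       place_fluorophores)
from .params import SimParams, DCParams, LEParams
from .trajectory import Trajectory

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass(frozen=True)
class SpecialSites:
    """Biologically marked beads on an otherwise homopolymer chain."""

    n_beads: int
    condensin_sites: tuple
    fluorophore_indices: tuple
    telomere_index: int = 0

    def __post_init__(self):
        for name in ("condensin_sites", "fluorophore_indices"):
            idx = np.asarray(getattr(self, name))
            if idx.size and (np.any(np.diff(idx) <= 0) or idx[0] < 0
                             or idx[-1] >= self.n_beads):
                raise ValueError(f"{name} must be strictly increasing and "
                                 "within [0, n_beads)")

    @property
    def centromere_index(self) -> int:
        return self.n_beads - 1

    @classmethod
    def default(cls, params: SimParams | None = None) -> "SpecialSites":
        p = params or SimParams()
        site_map = default_binding_sites(n_beads=p.n_beads)
        fluors = place_fluorophores(
            p.n_beads,
            offsets_mb=default_fluorophore_offsets_mb(p.n_beads, p.bp_per_bead),
            bp_per_bead=p.bp_per_bead)
        return cls(n_beads=p.n_beads,
                   condensin_sites=site_map.site_indices,
                   fluorophore_indices=fluors)


@dataclass
class ChainState:
    """3D bead positions (nm) at a simulation time (s)."""

    positions: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_beads, 3)")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def cylinder_dimensions(params: SimParams) -> tuple[float, float]:
    """Radius and full height (nm) of the largest-height cylinder of the
    configured volume inscribed in the nuclear sphere (h = 2*sqrt(R^2-r^2))."""
    R = params.nucleus_radius
    V = params.init_cylinder_volume_um3 * 1e9  # nm^3

    def f(r):
        return math.pi * r * r * 2.0 * math.sqrt(R * R - r * r) - V

    r_max = R * math.sqrt(2.0 / 3.0)  # volume-maximising radius
    if f(r_max) < 0:
        raise ValueError("cylinder volume too large to inscribe in nucleus")
    r = brentq(f, 1e-6 * R, r_max)
    h = 2.0 * math.sqrt(R * R - r * r)
    return r, h


def init_conformation(params: SimParams, sites: SpecialSites | None = None,
                      rng_seed: int = 0, max_attempts_per_bead: int = 10_000,
                      max_backtracks: int = 200) -> ChainState:
    """Self-avoiding random-walk conformation inside the init cylinder.

    The walk takes steps of length c2; a candidate bead is rejected when it
    leaves the cylinder or comes within d_rep0 of any already-placed bead
    other than its direct predecessor.  On exhaustion the walk backtracks a
    stretch of beads; a bounded number of backtracks is allowed before an
    explicit error.  The cylindrical constraint applies only here — the
    dynamics afterwards are confined by the nuclear sphere alone.
    """
    rng = np.random.default_rng(rng_seed)
    n = params.n_beads
    c2 = params.c2
    d0 = params.d_rep0
    r_cyl, h_cyl = cylinder_dimensions(params)

    cell = d0
    grid: dict[tuple, list] = {}

    def cell_of(p):
        return (int(p[0] // cell), int(p[1] // cell), int(p[2] // cell))

    def ok(p, last_index):
        if p[0] ** 2 + p[1] ** 2 > r_cyl ** 2 or abs(p[2]) > h_cyl / 2:
            return False
        cx, cy, cz = cell_of(p)
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    for j in grid.get((cx + ox, cy + oy, cz + oz), ()):
                        if j == last_index:
                            continue
                        q = pos[j]
                        if ((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2
                                + (p[2] - q[2]) ** 2) < d0 * d0:
                            return False
        return True

    def insert(i):
        grid.setdefault(cell_of(pos[i]), []).append(i)

    def remove(i):
        grid[cell_of(pos[i])].remove(i)

    pos = np.empty((n, 3))
    # first bead uniformly in the cylinder
    while True:
        x, y = rng.uniform(-r_cyl, r_cyl, 2)
        if x * x + y * y <= r_cyl ** 2:
            break
    pos[0] = (x, y, rng.uniform(-h_cyl / 2, h_cyl / 2))
    insert(0)

    backtracks = 0
    i = 1
    while i < n:
        placed = False
        for _ in range(max_attempts_per_bead):
            v = rng.normal(size=3)
            v *= c2 / np.linalg.norm(v)
            cand = pos[i - 1] + v
            if ok(cand, i - 1):
                pos[i] = cand
                insert(i)
                placed = True
                break
        if placed:
            i += 1
            continue
        backtracks += 1
        if backtracks > max_backtracks:
            raise RuntimeError(
                f"chain initialization failed at bead {i} after "
                f"{max_backtracks} backtracks")
        back_to = max(1, i - 50)
        for j in range(back_to, i):
            remove(j)
        i = back_to
    return ChainState(positions=pos, time=0.0)


# ---------------------------------------------------------------------------
# forces (API-level, used by unit tests and small-scale work; the jitted
# engine applies the identical physics inside the time loop)
# ---------------------------------------------------------------------------

def stochastic_force(params: SimParams, n: int, dt: float | None = None,
                     rng=None) -> np.ndarray:
    """Thermal kicks: i.i.d. Gaussian per component, zero mean, std
    sqrt(2*lambda*kBT/dt) under the default Euler-Maruyama convention."""
    if dt is None:
        dt = params.dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if params.noise_convention == "literal":
        sigma = math.sqrt(2.0 * params.lambda_damp * params.kBT)
    else:
        sigma = math.sqrt(2.0 * params.lambda_damp * params.kBT / dt)
    return sigma * rng.standard_normal((n, 3))


def tension_force(state: ChainState, params: SimParams) -> np.ndarray:
    """Hookean linker springs; equal and opposite on bond partners."""
    pos = state.positions
    n = pos.shape[0]
    if n < 2:
        raise ValueError("chain must have at least two beads")
    force = np.zeros_like(pos)
    bond = pos[1:] - pos[:-1]
    d = np.linalg.norm(bond, axis=1)
    zero = d == 0.0
    if np.any(zero):
        logger.warning("coincident connected beads at %d bond(s); "
                       "zero tension direction used", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(zero[:, None], 0.0,
                     (params.K_ten * (d - params.c2) / np.where(zero, 1.0, d))[:, None] * bond)
    force[:-1] += f
    force[1:] -= f
    return force


def repulsion_force(state: ChainState, params: SimParams) -> np.ndarray:
    """Constant-magnitude excluded-volume force below the d_rep0 cutoff.

    Uses the same linked-cell kernel as the integrator.  Exactly coincident
    beads get a deterministic tie-break direction hashed from the pair
    indices.
    """
    pos = np.ascontiguousarray(state.positions, dtype=float)
    force = np.zeros_like(pos)
    span = pos.max(axis=0) - pos.min(axis=0)
    side = int(np.max(span) / params.d_rep0) + 2
    head = np.full(side ** 3, -1, dtype=np.int32)
    nxt = np.empty(pos.shape[0], dtype=np.int32)
    engine._add_repulsion(pos, force, params.c3, params.d_rep0, head, nxt)
    return force


def euler_step(state: ChainState, net_forces: np.ndarray,
               params: SimParams) -> ChainState:
    """One overdamped Euler step: v = F/lambda, u += v*dt, then boundary."""
    forces = np.asarray(net_forces, dtype=float)
    if forces.shape != state.positions.shape:
        raise ValueError("force array shape does not match bead count")
    if not np.all(np.isfinite(forces)):
        bad = int(np.argwhere(~np.isfinite(forces))[0][0])
        raise FloatingPointError(
            f"non-finite force on bead {bad} at t={state.time:.6g} s")
    new = state.positions + forces * (params.dt / params.lambda_damp)
    engine._apply_boundary(new, params.nucleus_radius,
                           params.boundary == "reflect")
    return ChainState(positions=new, time=state.time + params.dt)


# ---------------------------------------------------------------------------
# runner
# ---------------------------------------------------------------------------

def _seed32(seed: int) -> int:
    return int(seed) % (2 ** 31 - 1)


def _run(params: SimParams, sites: SpecialSites, mode: int,
         dc: DCParams | None = None, dc_condensins=None,
         le: LEParams | None = None, le_extruders=None,
         track_beads=None, track_interval: float = 0.02,
         init_state: ChainState | None = None) -> Trajectory:
    """Shared engine wrapper for the three model kinds."""
    if init_state is None:
        init_state = init_conformation(params, sites, rng_seed=params.seed)
    pos0 = np.ascontiguousarray(init_state.positions, dtype=float)
    n_steps = params.n_steps
    snap_every = max(1, int(round(params.snapshot_interval / params.dt)))

    if track_beads is None:
        track_idx = np.empty(0, dtype=np.int64)
        track_every = 0
    else:
        track_idx = np.asarray(track_beads, dtype=np.int64)
        track_every = max(1, int(round(track_interval / params.dt)))

    kwargs_engine: dict = {}
    if mode == engine.MODE_DC:
        kwargs_engine.update(
            dc_site=np.asarray([c.site_bead for c in dc_condensins],
                               dtype=np.int64),
            dc_front0=np.asarray([c.front_foot for c in dc_condensins],
                                 dtype=float).reshape(-1, 3),
            dc_rear0=np.asarray([c.rear_foot for c in dc_condensins],
                                dtype=float).reshape(-1, 3),
            k_cond=dc.K_condensin, c5=dc.c5, d_cut=dc.d_cutoff,
            p_assoc=dc.p_capture, invert_p=not dc.force_active_below_p)
    elif mode == engine.MODE_LE:
        kwargs_engine.update(
            le_load0=[e.load_site for e in le_extruders],
            le_fa0=[e.front_anchor for e in le_extruders],
            le_ra0=[e.rear_anchor for e in le_extruders],
            p_slide=le.p_sliding, p_onoff=le.p_onoff,
            le_buffer=le.collision_buffer,
            t_exch_steps=max(1, int(round(le.T_exchange / params.dt))))

    out = engine.integrate(
        pos0, mode, n_steps, params.dt, params.lambda_damp,
        params.noise_sigma(), params.K_ten, params.c2, params.c3,
        params.d_rep0, params.nucleus_radius,
        params.boundary == "reflect", _seed32(params.seed),
        all_sites=np.asarray(sites.condensin_sites, dtype=np.int64),
        snap_every=snap_every, track_idx=track_idx,
        track_every=track_every, logger=logger, **kwargs_engine)
    snap_pos = out["snap_pos"]
    trk = out["trk"]

    n_snaps = snap_pos.shape[0]
    times = np.arange(n_snaps) * snap_every * params.dt
    model = {engine.MODE_FREE: "free", engine.MODE_DC: "dc",
             engine.MODE_LE: "le"}[mode]
    metadata = {
        "model": model,
        "params": params.to_dict(),
        "seed": params.seed,
        "code_version": __version__,
        "condensin_sites": [int(s) for s in sites.condensin_sites],
        "fluorophore_indices": [int(f) for f in sites.fluorophore_indices],
    }
    if dc is not None:
        metadata["dc_params"] = dc.to_dict()
    if le is not None:
        metadata["le_params"] = le.to_dict()

    kwargs = {}
    if mode == engine.MODE_DC:
        kwargs.update(dc_sites=kwargs_engine["dc_site"],
                      dc_front=out["snap_front"], dc_rear=out["snap_rear"],
                      capture_pair_counts=out["pair_count"])
    elif mode == engine.MODE_LE:
        kwargs.update(le_load=out["snap_load"],
                      le_front_anchor=out["snap_fa"],
                      le_rear_anchor=out["snap_ra"],
                      le_front_stalled=out["snap_stf"],
                      le_rear_stalled=out["snap_str"],
                      le_front=out["snap_lf"], le_rear=out["snap_lr"])
    if track_every > 0 and track_idx.size > 0:
        kwargs.update(
            track_indices=track_idx,
            track_times=np.arange(trk.shape[0]) * track_every * params.dt,
            track_positions=trk)
    return Trajectory(metadata=metadata, times=times, positions=snap_pos,
                      **kwargs)


def run_free_chain(params: SimParams, sites: SpecialSites | None = None,
                   track_beads=None, track_interval: float = 0.02,
                   init_state: ChainState | None = None) -> Trajectory:
    """Simulate the free chain (stochastic + tension + repulsion only)."""
    sites = sites or SpecialSites.default(params)
    return _run(params, sites, engine.MODE_FREE, track_beads=track_beads,
                track_interval=track_interval, init_state=init_state)
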