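"""Diffusion-capture mechanism.

Condensins (two 25 nm feet) are anchored at binding sites for the whole
run.  Front feet of condensins on distinct sites feel a pairwise Hookean
capture spring toward an equilibrium separation c5 while within the
capture cutoff; a fresh per-step uniform draw r_p gates the spring per
pair (suspended when r_p < p under the default dissociation reading).
Cluster valence is not capped; sterics regulate it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine
from .chain import ChainState, SpecialSites, _run
from .params import SimParams, DCParams, round_half_up
from .trajectory import Trajectory


@dataclass
class CondensinDC:
    """A chromatin-bound condensin: fixed host bead plus two mobile feet."""

    site_bead: int
    front_foot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rear_foot: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.front_foot = np.asarray(self.front_foot, dtype=float)
        self.rear_foot = np.asarray(self.rear_foot, dtype=float)


def occupy_sites(sites: SpecialSites, occupancy: float, rng_seed: int = 0,
                 state: ChainState | None = None) -> list[CondensinDC]:
    """Place round(occupancy * n_sites) condensins on sites chosen uniformly
    without replacement (round-half-up; 0.15 * 158 -> 24).

    Feet start concentric with the host bead when a chain state is given.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    all_sites = np.asarray(sites.condensin_sites, dtype=int)
    if all_sites.size == 0:
        raise ValueError("site list is empty")
    n = round_half_up(occupancy * all_sites.size)
    rng = np.random.default_rng(rng_seed)
    chosen = np.sort(rng.choice(all_sites, size=n, replace=False))
    out = []
    for s in chosen:
        p = state.positions[s].copy() if state is not None else np.zeros(3)
        out.append(CondensinDC(site_bead=int(s), front_foot=p.copy(),
                               rear_foot=p.copy()))
    return out


def structure_and_attach_forces(condensins: list[CondensinDC],
                                state: ChainState, params: DCParams,
                                K_ten: float = 0.1):
    """Structure spring (foot-foot, eq c4) and attachment springs
    (foot-host bead, eq c4'), with third-law reactions on the host bead.

    Returns ``(f_front, f_rear, f_beads)``.
    """
    nc = len(condensins)
    f_front = np.zeros((nc, 3))
    f_rear = np.zeros((nc, 3))
    f_beads = np.zeros_like(state.positions)

    def spring(pa, pb, k, eq):
        d = pb - pa
        r = np.linalg.norm(d)
        if r == 0.0:
            return np.zeros(3)
        return k * (r - eq) / r * d

    for k, c in enumerate(condensins):
        f = spring(c.front_foot, c.rear_foot, K_ten, params.c4)
        f_front[k] += f
        f_rear[k] -= f
        host = state.positions[c.site_bead]
        f = spring(c.front_foot, host, K_ten, params.c4prime)
        f_front[k] += f
        f_beads[c.site_bead] -= f
        f = spring(c.rear_foot, host, K_ten, params.c4prime)
        f_rear[k] += f
        f_beads[c.site_bead] -= f
    return f_front, f_rear, f_beads


def capture_forces(condensins: list[CondensinDC], params: DCParams,
                   rng=None) -> np.ndarray:
    """Pairwise capture springs between in-range front feet.

    For every unordered pair within d_cutoff one uniform is drawn in
    ascending (site-sorted) pair order; the Hookean force
    K_condensin * (d - c5) acts along the centre line on both feet when
    the draw makes the pair eligible this step (see
    :class:`~condensim.params.DCParams.probability_mode`).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nc = len(condensins)
    forces = np.zeros((nc, 3))
    order = sorted(range(nc), key=lambda k: condensins[k].site_bead)
    for ai in range(nc - 1):
        for bi in range(ai + 1, nc):
            a, b = order[ai], order[bi]
            if condensins[a].site_bead == condensins[b].site_bead:
                raise ValueError("condensins must occupy distinct sites")
            d = condensins[b].front_foot - condensins[a].front_foot
            r = np.linalg.norm(d)
            if r < params.d_cutoff:
                active = rng.random() < params.p_capture
                if not params.force_active_below_p:
                    active = not active
                if active and r > 0.0:
                    f = params.K_condensin * (r - params.c5) / r * d
                    forces[a] += f
                    forces[b] -= f
    return forces


def run_dc(params: SimParams, dc: DCParams | None = None,
           sites: SpecialSites | None = None, track_beads=None,
           track_interval: float = 0.02,
           init_state: ChainState | None = None) -> Trajectory:
    """Full diffusion-capture dynamics.

    Condensins are placed on round(occupancy * n_sites) sites (site choice
    seeded from the run seed) and never relocate; snapshots record both
    feet of every condensin plus the within-cutoff pair count.
    """
    dc = dc or DCParams()
    sites = sites or SpecialSites.default(params)
    if init_state is None:
        from .chain import init_conformation
        init_state = init_conformation(params, sites, rng_seed=params.seed)
    condensins = occupy_sites(sites, dc.occupancy, rng_seed=params.seed,
                              state=init_state)
    return _run(params, sites, engine.MODE_DC, dc=dc,
                dc_condensins=condensins, track_beads=track_beads,
                track_interval=track_interval, init_state=init_state)
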