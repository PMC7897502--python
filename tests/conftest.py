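"""Shared fixtures.

The session-scoped simulation fixtures below are the scaled-down study
conditions used by the steady-state readout tests: single replicates at
reduced duration (the published protocol is 10 x 1200 s per condition),
with dense 20 ms tracks of the condensin-site beads for MSD/anisotropy.
Every fixture seeds its own RNG so the suite is deterministic.
"""
from __future__ import annotations

import numpy as np
import pytest

from condensim import (DCParams, LEParams, SimParams, SpecialSites,
                       init_conformation, run_dc, run_free_chain, run_le)

BASE_SEED = 20210112  # fixed for the whole suite

#: durations (s) of the scaled-down steady-state runs
FREE_DURATION = 32.0
DC_MITOSIS_DURATION = 240.0   # condensin clustering plateaus by ~240 s
DC_INTERPHASE_DURATION = 50.0
LE_MITOSIS_DURATION = 60.0    # loop sizes are collision-limited within ~40 s
LE_INTERPHASE_DURATION = 45.0
DOSE_DURATION = 40.0


def make_params(duration, seed=BASE_SEED, snapshot_interval=1.0):
    return SimParams(duration=duration, snapshot_interval=snapshot_interval,
                     seed=seed)


@pytest.fixture(scope="session")
def sites():
    return SpecialSites.default()


@pytest.fixture(scope="session")
def small_params():
    """Cheap parameters for unit-level runs."""
    return SimParams(duration=0.2, snapshot_interval=0.05, seed=BASE_SEED)


@pytest.fixture(scope="session")
def init_state(sites):
    p = SimParams(seed=BASE_SEED)
    return init_conformation(p, sites, rng_seed=BASE_SEED)


@pytest.fixture(scope="session")
def free_tracked(sites, init_state):
    """Free chain with dense tracks of all condensin-site beads."""
    p = make_params(FREE_DURATION)
    return run_free_chain(p, sites, track_beads=sites.condensin_sites,
                          init_state=init_state)


@pytest.fixture(scope="session")
def dc_mitosis(sites, init_state):
    p = make_params(DC_MITOSIS_DURATION)
    return run_dc(p, DCParams(occupancy=1.0), sites,
                  track_beads=sites.condensin_sites, init_state=init_state)


@pytest.fixture(scope="session")
def dc_interphase(sites, init_state):
    p = make_params(DC_INTERPHASE_DURATION)
    return run_dc(p, DCParams(occupancy=0.15), sites,
                  track_beads=sites.condensin_sites, init_state=init_state)


@pytest.fixture(scope="session")
def le_mitosis(sites, init_state):
    p = make_params(LE_MITOSIS_DURATION)
    return run_le(p, LEParams(occupancy=1.0), sites,
                  track_beads=sites.condensin_sites, init_state=init_state)


@pytest.fixture(scope="session")
def le_interphase(sites, init_state):
    p = make_params(LE_INTERPHASE_DURATION)
    return run_le(p, LEParams(occupancy=0.15), sites,
                  track_beads=sites.condensin_sites, init_state=init_state)


@pytest.fixture(scope="session")
def dc_dose_runs(sites, init_state, dc_interphase, dc_mitosis):
    """DC titration: occupancy -> trajectory (15% and 100% reuse the
    interphase/mitosis fixtures; intermediate doses are shorter runs)."""
    runs = {0.15: dc_interphase, 1.0: dc_mitosis}
    for occ in (0.25, 0.5, 0.75):
        p = make_params(DOSE_DURATION)
        runs[occ] = run_dc(p, DCParams(occupancy=occ), sites,
                           init_state=init_state)
    return runs
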