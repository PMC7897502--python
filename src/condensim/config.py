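"""Run configuration: flat YAML files, validation, and the replicate runner.

A run config selects one model kind (free | dc | le), carries the physical
parameters as flat keys, and sets the replicate/seed policy: replicate r
uses ``seed + r`` so a manifest fully determines every output byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chain import SpecialSites, run_free_chain
from .dc import run_dc
from .fixtures import (BindingSiteMap, default_binding_sites,
                       default_fluorophore_offsets_mb, place_fluorophores)
from .le import run_le
from .params import SimParams, DCParams, LEParams

MODELS = ("free", "dc", "le")

_SIM_KEYS = {f.name for f in dataclasses.fields(SimParams)}
_DC_KEYS = {f.name for f in dataclasses.fields(DCParams)}
_LE_KEYS = {f.name for f in dataclasses.fields(LEParams)}


@dataclass
class RunConfig:
    model: str = "free"
    sim: SimParams = field(default_factory=SimParams)
    dc: DCParams | None = None
    le: LEParams | None = None
    site_map_path: str | None = None
    replicates: int = 10
    out_dir: str = "runs"
    track_condensin_sites: bool = False

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.model == "dc" and self.dc is None:
            self.dc = DCParams()
        if self.model == "le" and self.le is None:
            self.le = LEParams()
        if self.model != "dc":
            self.dc = None
        if self.model != "le":
            self.le = None
        if self.replicates < 0:
            raise ValueError("replicates must be non-negative")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        data = dict(data)
        model = data.pop("model", "free")
        sim_kwargs = {}
        dc_kwargs = {}
        le_kwargs = {}
        top = {}
        for key, value in data.items():
            if key.startswith("dc_") and key[3:] in _DC_KEYS:
                dc_kwargs[key[3:]] = value
            elif key.startswith("le_") and key[3:] in _LE_KEYS:
                le_kwargs[key[3:]] = value
            elif key in _SIM_KEYS:
                sim_kwargs[key] = value
            elif key in ("site_map_path", "replicates", "out_dir",
                         "track_condensin_sites"):
                top[key] = value
            else:
                raise ValueError(f"unknown config key: {key}")
        if dc_kwargs and le_kwargs:
            raise ValueError("config mixes dc_* and le_* keys; "
                             "exactly one mechanism block may be active")
        return cls(model=model, sim=SimParams(**sim_kwargs),
                   dc=DCParams(**dc_kwargs) if model == "dc" else None,
                   le=LEParams(**le_kwargs) if model == "le" else None,
                   **top)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a flat mapping")
        return cls.from_mapping(data)

    def to_mapping(self) -> dict:
        out = {"model": self.model, "site_map_path": self.site_map_path,
               "replicates": self.replicates, "out_dir": self.out_dir,
               "track_condensin_sites": self.track_condensin_sites}
        out.update(self.sim.to_dict())
        if self.dc is not None:
            out.update({f"dc_{k}": v for k, v in self.dc.to_dict().items()})
        if self.le is not None:
            out.update({f"le_{k}": v for k, v in self.le.to_dict().items()})
        return out

    def param_hash(self) -> str:
        blob = json.dumps(self.to_mapping(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def special_sites(self) -> SpecialSites:
        if self.site_map_path:
            site_map = BindingSiteMap.from_index_list(
                self.site_map_path, n_beads=self.sim.n_beads)
        else:
            site_map = default_binding_sites(n_beads=self.sim.n_beads)
        fluors = place_fluorophores(
            self.sim.n_beads,
            offsets_mb=default_fluorophore_offsets_mb(self.sim.n_beads,
                                                      self.sim.bp_per_bead),
            bp_per_bead=self.sim.bp_per_bead)
        return SpecialSites(n_beads=self.sim.n_beads,
                            condensin_sites=site_map.site_indices,
                            fluorophore_indices=fluors)


def run_replicates(config: RunConfig, progress=None) -> dict:
    """Run all replicates of a config; one trajectory file per replicate.

    Returns the manifest (also written to ``out_dir/manifest.json``):
    replicate seeds, parameter hash, file names, wall-clock and version.
    """
    from . import __version__

    sites = config.special_sites()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    entries = []
    for r in range(config.replicates):
        seed = config.sim.seed + r
        params = dataclasses.replace(config.sim, seed=seed)
        track = sites.condensin_sites if config.track_condensin_sites else None
        if config.model == "free":
            traj = run_free_chain(params, sites, track_beads=track)
        elif config.model == "dc":
            traj = run_dc(params, config.dc, sites, track_beads=track)
        else:
            traj = run_le(params, config.le, sites, track_beads=track)
        fname = f"{config.model}_rep{r:03d}.h5"
        traj.save(out_dir / fname)
        entries.append({"replicate": r, "seed": seed, "file": fname})
        if progress is not None:
            progress(r, config.replicates)
    manifest = {
        "model": config.model,
        "param_hash": config.param_hash(),
        "config": config.to_mapping(),
        "replicates": entries,
        "wall_clock_s": round(time.time() - started, 3),
        "code_version": __version__,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
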