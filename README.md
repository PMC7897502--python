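# condensim

Coarse-grained Brownian-dynamics simulation of mitotic chromosome
formation on the 3.76 Mb left arm of *Schizosaccharomyces pombe*
chromosome I, built to compare the two leading models of how the SMC
complex condensin folds chromatin:

* **diffusion capture (DC)** — condensins parked on their binding sites
  stabilise stochastic encounters between distant loci through a pairwise
  attractive spring within a 77 nm capture radius;
* **loop extrusion (LE)** — condensins load at binding sites and their two
  feet translocate symmetrically outward at ~1.2 kb/s, growing loops until
  they collide with a neighbour or turn over.

The package is for chromosome-biology and biophysics groups who want to
reproduce, probe or extend this model comparison: it provides the polymer
engine, both condensin mechanisms, and the complete readout suite used to
confront the models with experiments — fluorophore distances, Hi-C-like
distance maps and contact-frequency curves, voxel-occupancy volumes,
windowed MSD exponents with 2D projection, short-time anisotropy,
DBSCAN condensin clustering, and STORM localization filtering.

## Model

The chain is 1880 beads (25 nm radius, ~2 kb each) joined by Hookean
linkers (K = 0.1 pN/nm, rest length c₂ = 52 nm), with a constant 0.5 pN
excluded-volume repulsion below 50 nm, confined to a rigid 1.5 µm-radius
nucleus.  Bead i follows the overdamped Langevin equation

    0 = −λu̇ᵢ + Fᵢ_sto + Fᵢ_ten + Fᵢ_rep (+ mechanism terms),

integrated by forward Euler with Δt = 10⁻⁴ s; the thermal force has
per-component std √(2λk_BT/Δt) so D = k_BT/λ.  Condensins are two-foot
agents coupled to the chain by zero-rest-length springs; DC adds the
pairwise capture spring K(d − c₅) with c₅ = 52 nm, LE re-anchors the foot
springs bead-by-bead.  158 condensin binding sites follow the published
spacing statistics (mean gap 11.7 beads, median 6).  See
`docs/methods.md` for the full model description and design rationale.

## Worked example

Simulate a short in-silico mitosis under diffusion capture and measure
condensin clustering and the 1.8 Mb fluorophore distance:

```python
import numpy as np
from condensim import (SimParams, DCParams, SpecialSites, run_dc,
                       cluster_condensins, fluorophore_distance_series)

params = SimParams(duration=300.0, snapshot_interval=5.0, seed=1234)
sites = SpecialSites.default(params)
traj = run_dc(params, DCParams(occupancy=1.0), sites)

rep = cluster_condensins(traj.condensin_points(traj.n_snapshots - 1))
print("median cluster size:", rep.median_size)
print("median NN distance: %.0f nm" % rep.median_nn)

pair = (sites.centromere_index, sites.centromere_index - 900)  # 1.8 Mb
d, _ = fluorophore_distance_series(traj, pair)
print("1.8 Mb distance median (last 100 s): %.2f um"
      % np.median(d[traj.times > 200]))
```

Output (seed 1234):

```
median cluster size: 12.0
median NN distance: 29 nm
1.8 Mb distance median (last 100 s): 0.62 um
```

At full site occupancy the capture mechanism condenses the arm: condensins
gather into clusters (median size 12) with tight nearest-neighbour
spacing, and the 1.8 Mb locus pair contracts from its ~1.2–1.3 µm
interphase distance to below 1 µm.  Running the same protocol with
`run_le` instead leaves the pair near 1.3 µm and spreads condensins out
along a backbone with median cluster size 2 — the qualitative distinction
between the two mechanisms.

A command-line interface wraps the same functionality:

```sh
condensim simulate --model dc --occupancy 1.0 --duration 300 \
    --replicates 2 --seed 7 --out runs/
condensim analyze clusters runs/dc_rep000.h5 runs/dc_rep001.h5
condensim fixtures make-sites --seed 3 --out sites.txt
```

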