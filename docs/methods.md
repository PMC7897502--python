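# Methods

## The model

`condensim` simulates the 3.76 Mb left arm of *Schizosaccharomyces pombe*
chromosome I as a coarse-grained bead-spring polymer: 1880 consecutively
bonded beads of 25 nm radius, each standing for ~10 nucleosomes (~2 kb).
The chain lives inside a rigid sphere of 1.5 µm radius (14.14 µm³), the
virtual nucleus.  Bead dynamics follow the overdamped Langevin equation —
inertia is neglected against damping — integrated with the forward Euler
scheme: per step, v = F_net/λ and u(t+Δt) = u(t) + vΔt.

Three passive forces act on every bead:

* **Thermal (stochastic) force.**  Each Cartesian component is an
  independent Gaussian with zero mean.  Under the default
  `noise_convention="em"` (Euler–Maruyama) the per-step standard deviation
  is √(2λk_BT/Δt), which makes the free-bead diffusion coefficient
  D = k_BT/λ independent of the timestep.  A `"literal"` convention with
  std √(2λk_BT) (no Δt factor) is exposed for comparison; under it the
  effective diffusion scales with Δt.  The temperature is not part of the
  published parameter table; we fix k_BT = 4.11 pN·nm (298 K), which
  together with λ = 3×10⁻⁵ pN·s/nm (3×10⁻⁸ kg/s; 1 kg/s = 10³ pN·s/nm)
  gives D = 1.37×10⁵ nm²/s and reproduces the expected free-chain
  subdiffusion (MSD exponent ≈ 0.53, Rouse-like with excluded volume).
* **Tension.**  Hookean springs between bonded neighbours,
  K_ten = 0.1 pN/nm, equilibrium linker length c₂ = 52 nm.  (The published
  parameter table prints 5.2×10² nm for c₂ and c₅; that value is
  inconsistent with 25 nm beads and with the accompanying text, which
  states 52 nm — we use 52 nm and treat the table entry as a ×10
  typesetting error.)
* **Excluded volume.**  A constant-magnitude repulsion of c₃ = 0.5 pN along
  the centre line for every unordered bead pair closer than
  d_rep0 = 50 nm.  Exactly coincident beads receive a deterministic
  tie-break direction hashed from the pair indices.

Stability requires Δt·K_ten/λ < 1; at the defaults (Δt = 10⁻⁴ s) the ratio
is 0.33 and parameter validation enforces the bound.

**Boundary.**  The nuclear envelope is rigid.  By default a bead that
would exit is clamped radially back onto the sphere surface
(`boundary="clamp"`); a reflective fold (`"reflect"`) is available.

**Initialization.**  Chains start as self-avoiding random walks (step
length c₂, 50 nm exclusion) grown inside a 3.84 µm³ cylinder inscribed in
the nucleus — the genome fraction the arm represents.  Candidate beads are
resampled up to 10⁴ times; on exhaustion the walk backtracks 50 beads, and
a bounded number of backtracks precedes an explicit error.  The
cylindrical constraint is dropped once the dynamics start.

**Special sites.**  Bead 0 is the telomere, bead 1879 the centromere.
158 beads are condensin binding sites; five beads at 0.1/0.7/1.2/1.8/2.2 Mb
from the centromere-proximal reference mark fluorophore-tagged loci.  The
reference locus for fluorophore offsets is the centromere-end terminal
bead (the published description, "a locus close to the centromere", does
not give an exact index; the choice is config-exposed).

## Condensin mechanisms

Condensin is a pair of 25 nm "feet" joined by a Hookean structure spring
(K_ten, equilibrium 0 nm).  Feet receive thermal noise and damping exactly
like chain beads.

### Diffusion capture (DC)

Each condensin is tethered to its binding-site bead by attachment springs
(both feet, equilibrium 0 nm) and never relocates.  Front feet of
condensins on distinct sites interact pairwise: within a centre-centre
cutoff of 77 nm a Hookean capture spring (K = 0.1 pN/nm) pulls the pair
toward an equilibrium separation c₅ = 52 nm (two adjacent feet).  Each
in-range pair draws one fresh uniform r_p per step, in ascending site-pair
order.

The published description of the gating probability p = 0.01 admits two
readings, and they differ enormously in effect:

* **dissociation** (our default): the spring is suspended on steps where
  r_p < p — active ~99% of the time.  p acts as a per-pair turnover
  perturbation.
* **association**: the spring acts only when r_p < p — active ~1% of the
  time.

Only the dissociation reading produces the mitotic phenotype.  Under the
association reading a 400 s full-occupancy run shows no compaction
(median cluster size stays 2, nearest-neighbour distance ~72 nm, 1.8 Mb
fluorophore distance ~1.14 µm ≈ interphase); the time-averaged attraction
is ~100× too weak against k_BT.  Under the dissociation reading the same
conditions develop capture-pair counts that plateau within ~40 s,
condensin clusters whose median size reaches ~12 by ~240 s, median
nearest-neighbour distances of ~30 nm, and strong axial and volume
compaction.  Both readings are selectable via
`DCParams.probability_mode`.

Cluster valence is not capped; steric exclusion of the chain regulates it.
Pair eligibility is re-drawn every step — there are no persistent bond
objects — and a "capture pair" in the readouts means a front-foot pair
currently within the cutoff.

### Loop extrusion (LE)

Condensins load with both feet on one binding site; each foot then hops
outward (front toward higher indices, rear toward lower) one bead per
step with probability p_sliding, re-anchoring its extrusion spring
(K_ten, equilibrium 0 nm) to the new bead.  The unobstructed extrusion
speed is v = 2·p_sliding·n_bp/Δt; the default p_sliding = 3×10⁻⁵ gives
1.2 kb/s, matching single-molecule measurements.

**Collisions.**  A foot stalls when the destination bead — or any bead
within `collision_buffer` beads beyond it — is anchored by another foot,
or when it would step off a chain end.  Stalls are re-evaluated every
step, so a foot resumes when its blocker moves or turns over; the
non-colliding foot of a stalled condensin continues (asymmetric
extrusion).  The default buffer of one empty bead spaces collided
condensins two linkers (~104 nm) apart along the chain.  This choice is
fixed by the measured readouts: with feet stalling on directly adjacent
beads (buffer 0) the condensin backbone has a median nearest-neighbour
distance of ~62 nm and DBSCAN (eps 100 nm) merges it into large clusters,
whereas the published backbone shows ~107 nm spacing — two 52 nm
linkers — and clusters of rarely more than two.  Buffer 0 is available
for comparison.

**Turnover.**  Every T_exchange = 2 s each condensin unloads with
probability p_onoff = 0.01 and immediately reloads, anchors reset, at a
uniformly chosen empty binding site (one with no anchored foot; its own
vacated site qualifies when nothing else is free), keeping the condensin
count constant.  Reloading inside another condensin's extruded interval
creates nested loops without special-case code; feet never pass each
other, so the extruded intervals always form a laminar (disjoint-or-
nested) family and z-loops are excluded by construction.

**Occupancy.**  round(occupancy × 158) condensins, sites drawn uniformly
without replacement (round half-up: 15% → 24).  15% occupancy models
interphase (the nuclear condensin fraction), 100% mitosis.

## Readouts

* **Fluorophore distances** — per-snapshot 3D Euclidean distances (µm)
  between marked beads; medians pooled over replicates.  The "1.8 Mb
  pair" is the centromere reference bead and the bead 900 beads away.
* **Mean distance map** — bead × bead Euclidean distance averaged over
  conformations sampled at a configurable interval (1 s in the full
  protocol); symmetric, zero diagonal.
* **Contact frequency** — bead pairs within 500 nm, binned by genomic
  separation (20 kb bins by default; the bin width is not stated in the
  source description and is config-exposed), normalized to sum to one.
  The mitotically enhanced range is the longest contiguous run of bins
  where the mitotic curve exceeds the interphase curve, after an optional
  3-bin moving average that suppresses single-bin noise.
* **Voxel volume** — the count of occupied 100 nm cubic voxels (≥1 bead
  centre) × 10⁻³ µm³, on a grid anchored at the nucleus corner so the
  measure is translation-stable across snapshots.
* **MSD exponent** — dense 20 ms tracks (mirroring the live-imaging frame
  interval) of the 158 binding-site beads; for each 2 s window starting
  every 30 s and each bead, the track is projected onto a random 2D plane,
  the time-averaged MSD is computed per delay, and an ordinary
  least-squares log–log fit over delays ≤ 0.5 s yields one exponent.
  Reported as mean ± 1.96·SEM over all window/bead exponents; immobile
  windows are skipped and counted.
* **Anisotropy** — for 2D tracks, η(Δt) = ⟨(⟨Δx²⟩−⟨Δy²⟩)²/⟨Δr²⟩²⟩ with the
  directional MSDs time-averaged per track, η(Δt) averaged over tracks,
  and η̄ the mean over delays ≤ 0.1 s (tracks first, then delays; the
  averaging order is exposed).  The implied diffusion-coefficient ratio
  is D_x/D_y = (1−√η̄)/(1+√η̄).
* **Condensin clustering** — DBSCAN (scikit-learn; eps 100 nm, minimum
  membership 2) on one point per condensin, by default the midpoint of
  its two feet ("front" selectable); plus per-condensin nearest-neighbour
  distances.  Cluster statistics are medians per snapshot.
* **Localization filtering** — STORM-style tables keep rows with quality
  ≥ 0.8, blink runs strictly longer than 3 frames, and axial precision
  ≤ 100 nm; removal counts per criterion are logged.

## Synthetic inputs

The exact ChIP-derived condensin coordinates are not public; the
binding-site generator reproduces their summary statistics instead.  Gaps
between neighbouring sites are drawn from a two-component geometric
mixture (short gaps truncated at the median, long gaps shifted above it),
built so the middle order statistic is exactly 6 beads, then a
deterministic adjustment pass nudges long gaps until the gap total equals
round(11.7 × 157) — so the realized mean is 11.70 and the median 6 on
every seed.  The default map ships as a frozen seed (1270) of this
generator.  What the generator does *not* emulate: the clustering of real
condensin sites around highly transcribed genes and any correlation
between site spacing and local chromatin state; tests passing on this map
show the mechanisms' behaviour at the published site density and spacing
statistics, not at the true genomic positions.

Synthetic STORM tables place Gaussian clusters (default σ = 10 nm) at
centres ≥ 300 nm apart inside the nuclear sphere plus uniform noise, with
per-row quality/precision/blink values from pluggable samplers, and
return ground-truth labels.  They exercise the filtering and clustering
readouts; they do not model detector noise correlations or repeated
blinking of one fluorophore.

## Numerical and reproducibility choices

* Internal units: nm, s, pN.
* The integrator core is numba-compiled.  Randomness comes from a
  self-contained xoshiro256** stream with a 128-layer ziggurat Gaussian
  sampler, so a (seed, parameters) pair reproduces a run bit-for-bit
  independent of NumPy internals.  The per-step draw order is documented
  in `condensim.engine`.
* The excluded-volume search keeps a Verlet pair list (cutoff 4·d_rep0)
  built on a counting-sort cell grid over the chain's bounding box and
  rebuilt when any bead has drifted more than half the skin — exact, not
  approximate, with respect to the 50 nm force cutoff.  Equivalence with
  an O(N²) enumeration is tested.
* Replicate r of a run uses seed base_seed + r; trajectories store all
  parameters, the seed and the code version in their metadata.
* Trajectory files are HDF5 (`h5py`); a flat CSV exporter is provided.
  Configs are flat YAML; CLI flags override config keys.

## Scaled-down protocols

The published protocol — 10 replicates × 1200 s per condition — is far
beyond an interactive test budget (a full-occupancy DC replicate costs
~10⁷ integrator steps).  The test suite instead uses single replicates at
reduced duration, chosen where the relevant observable has reached steady
state: free chain 32 s (local MSD statistics equilibrate within
seconds), DC mitosis 240 s (capture-pair counts plateau by ~40 s; the
median cluster size stops growing by ~240 s), DC interphase 50 s,
LE mitosis 60 s (loop sizes are collision-limited within ~40 s),
LE interphase 45 s, titration runs 40 s.  The acceptance script uses a
100 s free-chain run and 50 × 100 s single-extruder lattice replicates.
Steady-state readouts are taken from the second half of each run.
Consequences: medians estimated from a single scaled-down replicate carry
sampling noise that the pooled 12 000-measurement protocol suppresses,
and slowly coarsening observables (LE backbone spacing, DC cluster size)
sit at the early edge of their plateaus.

## Known limitations

* No hydrodynamic interactions, bending rigidity, torsion,
  nucleosome-scale structure, topoisomerase strand passage, or second
  chromosome.
* Condensin feet do not take part in the excluded-volume force; their
  size enters only through c₅ and the capture cutoff.
* The Euler scheme is first-order; with the default Δt the bead
  displacement per step (~9 nm rms) is a substantial fraction of the
  repulsion range, which is faithful to the published discretization but
  means forces are sampled coarsely along trajectories.
* z-loops (mutual passage of extruders) and cluster-size caps are not
  modelled.
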