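"""Physical and numerical parameters of the chromatin-chain simulator.

Internal units are nanometres, seconds and piconewtons throughout.  The
damping constant is quoted in the literature in kg/s; 1 kg/s equals
10^3 pN·s/nm, so the default 3e-8 kg/s becomes 3e-5 pN·s/nm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

#: Unit conversion for the damping constant: 1 kg/s = 1e3 pN*s/nm.
KG_PER_S_TO_PN_S_PER_NM = 1.0e3

NOISE_CONVENTIONS = ("em", "literal")
BOUNDARY_MODES = ("clamp", "reflect")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the bead-spring chain and its integrator.

    The chain models the 3.76 Mb left arm of *S. pombe* chromosome I as
    1880 beads of 25 nm radius (~2 kb, ~10 nucleosomes each), confined to
    a 1.5 um-radius spherical nucleus and advanced with an Euler-integrated
    overdamped Langevin equation.

    Attributes
    ----------
    n_beads : number of chain beads.
    bead_radius : bead radius, nm.
    bp_per_bead : genomic coverage of one bead, bp.
    lambda_damp : damping constant lambda, pN*s/nm.
    kBT : thermal energy, pN*nm.  Sets the diffusion coefficient
        D = kBT / lambda via the fluctuation-dissipation relation.
    K_ten : linker spring constant, pN/nm.
    c2 : equilibrium linker length, nm.
    c3 : magnitude of the constant excluded-volume force, pN.
    d_rep0 : centre-centre cutoff of the repulsion force, nm.
    nucleus_radius : radius of the rigid spherical boundary, nm.
    init_cylinder_volume_um3 : volume of the cylindrical sub-region used
        for chain initialization, um^3.
    dt : integration timestep, s.
    duration : simulated time, s.
    snapshot_interval : cadence of full-chain snapshots, s.
    seed : base RNG seed of a run.
    noise_convention : "em" scales the thermal force as sqrt(2*lambda*kBT/dt)
        (Euler-Maruyama; diffusion independent of dt) or "literal"
        sqrt(2*lambda*kBT) with no dt factor.
    boundary : "clamp" projects escaping beads radially back onto the
        nuclear surface; "reflect" folds them back inside.
    """

    n_beads: int = 1880
    bead_radius: float = 25.0
    bp_per_bead: int = 2000
    lambda_damp: float = 3.0e-5
    kBT: float = 4.11
    K_ten: float = 0.1
    c2: float = 52.0
    c3: float = 0.5
    d_rep0: float = 50.0
    nucleus_radius: float = 1500.0
    init_cylinder_volume_um3: float = 3.84
    dt: float = 1.0e-4
    duration: float = 1200.0
    snapshot_interval: float = 10.0
    seed: int = 0
    noise_convention: str = "em"
    boundary: str = "clamp"

    def __post_init__(self) -> None:
        for name in ("bead_radius", "lambda_damp", "kBT", "K_ten", "c2", "c3",
                     "d_rep0", "nucleus_radius", "init_cylinder_volume_um3",
                     "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimParams.{name} must be strictly positive")
        if self.n_beads < 2:
            raise ValueError("SimParams.n_beads must be >= 2")
        if self.bp_per_bead <= 0:
            raise ValueError("SimParams.bp_per_bead must be strictly positive")
        if self.duration < 0:
            raise ValueError("SimParams.duration must be non-negative")
        if self.snapshot_interval <= 0:
            raise ValueError("SimParams.snapshot_interval must be positive")
        if self.dt * self.K_ten / self.lambda_damp >= 1.0:
            raise ValueError(
                "unstable integrator: dt * K_ten / lambda_damp must be < 1")
        if self.noise_convention not in NOISE_CONVENTIONS:
            raise ValueError(f"noise_convention must be one of {NOISE_CONVENTIONS}")
        if self.boundary not in BOUNDARY_MODES:
            raise ValueError(f"boundary must be one of {BOUNDARY_MODES}")
        cyl_nm3 = self.init_cylinder_volume_um3 * 1e9
        if cyl_nm3 >= self.nucleus_volume_um3 * 1e9:
            raise ValueError("init cylinder does not fit inside the nucleus")

    # -- derived quantities -------------------------------------------------

    @property
    def diffusion_coeff(self) -> float:
        """Free-bead diffusion coefficient D = kBT / lambda, nm^2/s."""
        return self.kBT / self.lambda_damp

    @property
    def nucleus_volume_um3(self) -> float:
        """Volume of the spherical nucleus, um^3 (14.14 at defaults)."""
        return 4.0 / 3.0 * math.pi * (self.nucleus_radius / 1000.0) ** 3

    @property
    def genome_length_bp(self) -> int:
        return self.n_beads * self.bp_per_bead

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def noise_sigma(self) -> float:
        """Per-component standard deviation of the thermal force, pN."""
        if self.noise_convention == "literal":
            return math.sqrt(2.0 * self.lambda_damp * self.kBT)
        return math.sqrt(2.0 * self.lambda_damp * self.kBT / self.dt)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DCParams:
    """Diffusion-capture mechanism parameters.

    Condensins sit immobile on their binding sites; front feet within
    ``d_cutoff`` of each other feel a Hookean capture spring toward an
    equilibrium separation ``c5``, gated each step per pair by a fresh
    uniform draw r_p against ``p_capture``.  Under the default
    ``probability_mode="dissociation"`` the spring is suspended on steps
    where r_p < p_capture (active ~99% of the time at p = 0.01), treating
    p as a pair turnover probability; ``"association"`` applies the spring
    only when r_p < p_capture — a far weaker, mostly-off coupling that
    produces no appreciable compaction.
    """

    K_condensin: float = 0.1   # pN/nm
    c5: float = 52.0           # nm, two adjacent 25 nm feet (+2 nm)
    d_cutoff: float = 77.0     # nm, centre-centre capture range
    p_capture: float = 0.01    # per-step, per-pair gating probability
    c4: float = 0.0            # nm, foot-foot equilibrium (structure force)
    c4prime: float = 0.0       # nm, foot-site equilibrium (attachment force)
    occupancy: float = 1.0     # fraction of binding sites carrying condensin
    probability_mode: str = "dissociation"

    def __post_init__(self) -> None:
        if self.K_condensin <= 0 or self.c5 <= 0 or self.d_cutoff <= 0:
            raise ValueError("DCParams spring constants/distances must be positive")
        if not self.c5 < self.d_cutoff:
            raise ValueError("DCParams requires c5 < d_cutoff")
        if not 0.0 <= self.p_capture <= 1.0:
            raise ValueError("DCParams.p_capture must lie in [0, 1]")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("DCParams.occupancy must lie in [0, 1]")
        if self.c4 < 0 or self.c4prime < 0:
            raise ValueError("DCParams.c4/c4prime must be non-negative")
        if self.probability_mode not in ("dissociation", "association"):
            raise ValueError("DCParams.probability_mode must be "
                             "'dissociation' or 'association'")

    @property
    def force_active_below_p(self) -> bool:
        """True when the spring acts on r_p < p (association reading)."""
        return self.probability_mode == "association"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LEParams:
    """Loop-extrusion mechanism parameters.

    Each loaded condensin's two feet hop outward along the chain, one bead
    at a time, each with per-step probability ``p_sliding``; at multiples of
    ``T_exchange`` every condensin unloads with probability ``p_onoff`` and
    immediately reloads at a uniformly chosen empty binding site.  The
    default ``p_sliding`` gives an unobstructed extrusion speed
    2 * p_sliding * bp_per_bead / dt = 1.2 kb/s.

    ``collision_buffer`` sets how many empty beads a colliding foot keeps
    between itself and a bead anchored by another condensin.  The default
    of 1 stalls feet one bead short of contact, which spaces collided
    condensins two linker lengths (~104 nm) apart along the chain — the
    spacing that reproduces the sparse condensin backbone; 0 lets feet
    stall on directly adjacent beads.
    """

    p_sliding: float = 3.0e-5  # per foot, per step
    T_exchange: float = 2.0    # s, turnover check interval
    p_onoff: float = 0.01      # per condensin, per turnover check
    occupancy: float = 1.0
    c4prime: float = 0.0       # nm, foot-anchor equilibrium (extrusion force)
    collision_buffer: int = 1  # empty beads kept between colliding feet

    def __post_init__(self) -> None:
        if self.collision_buffer < 0:
            raise ValueError("LEParams.collision_buffer must be >= 0")
        if not 0.0 <= self.p_sliding <= 1.0:
            raise ValueError("LEParams.p_sliding must lie in [0, 1]")
        if not 0.0 <= self.p_onoff <= 1.0:
            raise ValueError("LEParams.p_onoff must lie in [0, 1]")
        if self.T_exchange <= 0:
            raise ValueError("LEParams.T_exchange must be positive")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("LEParams.occupancy must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5))
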