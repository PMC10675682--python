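"""Model parameters, reduced units, and the Flory–Huggins ↔ DPD repulsion mapping.

Everything downstream works in DPD reduced units: the pair-interaction
cutoff ``r_c`` is the unit of length, ``kT`` the unit of energy and the
(common) bead mass ``m0`` the unit of mass, so the intrinsic time unit is
``tau = sqrt(m0 * r_c**2 / kT)``.  All three base units equal 1 internally.

The system modelled throughout the package is an A5B5 diblock copolymer in
a solvent S that is good for the A block and poor for the B block, studied
either in a fully periodic bulk box or in a slit between two walls (species
W) whose affinity for the B block is tunable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "SPECIES",
    "CHI_SLOPE",
    "ReducedUnits",
    "InteractionTable",
    "ChainSpec",
    "BoxGeometry",
    "SystemParams",
    "chi_to_a",
    "a_to_chi",
    "concentration",
    "chains_for_concentration",
    "cylinder_sphere_capacity_ratio",
]

#: Canonical species order used for integer codes everywhere in the package.
SPECIES = ("A", "B", "S", "W")

#: Slope of the Groot–Warren linear mapping between the Flory–Huggins
#: parameter chi and the DPD repulsion amplitude, valid for bead density
#: rho * r_c**3 = 3.
CHI_SLOPE = 3.27

#: Wall-affinity presets for the B-block/wall repulsion a_BW.  a_AW and
#: a_SW stay at 25 (athermal) in every scenario; only the insoluble block
#: feels the wall differently.
WALL_SCENARIOS = {
    "repulsive": 30.0,  # slightly repulsive wall
    "inert": 25.0,  # athermal wall
    "weak-attract": 20.0,  # slightly attractive (value configurable)
    "strong-attract": 15.0,  # strongly attractive
}


@dataclass(frozen=True)
class ReducedUnits:
    """DPD reduced unit system; all base units are 1 by construction."""

    r_c: float = 1.0
    kT: float = 1.0
    m0: float = 1.0
    dt: float = 0.05

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("timestep dt must be positive")

    @property
    def tau(self) -> float:
        """Intrinsic time unit sqrt(m0 r_c^2 / kT)."""
        return math.sqrt(self.m0 * self.r_c**2 / self.kT)


def chi_to_a(chi: float, a_ii: float = 25.0) -> float:
    """Map a Flory–Huggins parameter to a DPD repulsion amplitude.

    Uses the linear Groot–Warren relation ``a_ij = a_ii + 3.27 chi``
    calibrated for bead density ``rho r_c^3 = 3``: chi = 0 (compatible
    species) gives a_ij = 25, the theta state chi = 1/2 gives 26.64 (at
    two decimals) and a_ij = 40 corresponds to a strongly unfavourable
    chi = 4.59.

    Parameters
    ----------
    chi : float
        Flory–Huggins interaction parameter (dimensionless).
    a_ii : float
        Like-pair repulsion baseline in kT/r_c (default 25).
    """
    if a_ii < 0:
        raise ValueError("like-pair repulsion a_ii must be non-negative")
    return a_ii + CHI_SLOPE * chi


def a_to_chi(a_ij: float, a_ii: float = 25.0) -> float:
    """Invert :func:`chi_to_a`: ``chi = (a_ij - a_ii) / 3.27``."""
    return (a_ij - a_ii) / CHI_SLOPE


@dataclass
class InteractionTable:
    """Symmetric species-pair repulsion amplitudes plus thermostat constants.

    ``a`` maps unordered species pairs (2-char sorted strings such as
    ``"AB"``) to repulsion amplitudes.  ``gamma`` and ``sigma`` are the
    dissipative and random force coefficients; the fluctuation–dissipation
    theorem requires ``sigma**2 == 2 * gamma * kT``, which is checked at
    construction (gamma = 4.5, kT = 1 gives sigma = 3 exactly).
    """

    a: dict[str, float] = field(default_factory=dict)
    gamma: float = 4.5
    sigma: float = 3.0
    kT: float = 1.0

    def __post_init__(self) -> None:
        canon = {}
        for key, val in self.a.items():
            if len(key) != 2 or any(s not in SPECIES for s in key):
                raise ValueError(f"bad species pair {key!r}")
            if val < 0:
                raise ValueError(f"repulsion a[{key}] must be non-negative")
            canon["".join(sorted(key))] = float(val)
        self.a = canon
        self.check_fdt()

    def check_fdt(self) -> None:
        """Reject sigma/gamma combinations violating sigma^2 = 2 gamma kT."""
        if not math.isclose(self.sigma**2, 2.0 * self.gamma * self.kT, rel_tol=1e-12):
            raise ValueError(
                f"fluctuation-dissipation balance violated: sigma^2={self.sigma ** 2} "
                f"!= 2*gamma*kT={2 * self.gamma * self.kT}"
            )

    def get(self, s1: str, s2: str) -> float:
        return self.a["".join(sorted(s1 + s2))]

    def set_pair(self, s1: str, s2: str, value: float) -> None:
        if value < 0:
            raise ValueError("repulsion must be non-negative")
        self.a["".join(sorted(s1 + s2))] = float(value)

    def matrix(self):
        """4x4 numpy array of amplitudes in the canonical A,B,S,W order."""
        import numpy as np

        m = np.empty((4, 4))
        for i, si in enumerate(SPECIES):
            for j, sj in enumerate(SPECIES):
                m[i, j] = self.get(si, sj)
        return m

    @classmethod
    def default(cls, a_BW: float = 25.0, **kwargs) -> "InteractionTable":
        """Default amphiphilic parameter set.

        Like pairs and compatible pairs (A with solvent) are athermal at 25;
        the insoluble block B repels both A and the solvent at 40
        (chi ≈ 4.59, a medium-strong selective solvent).  The wall is
        athermal for A and S; its affinity for B is the one free knob.
        """
        a = {
            "AA": 25.0, "BB": 25.0, "SS": 25.0, "WW": 25.0,
            "AS": 25.0,
            "AB": 40.0, "BS": 40.0,
            "AW": 25.0, "SW": 25.0,
            "BW": float(a_BW),
        }
        return cls(a=a, **kwargs)

    @classmethod
    def wall_scenario(cls, name: str, **kwargs) -> "InteractionTable":
        """Preset table for a named wall-affinity scenario."""
        if name not in WALL_SCENARIOS:
            raise ValueError(
                f"unknown wall scenario {name!r}; choose from {sorted(WALL_SCENARIOS)}"
            )
        return cls.default(a_BW=WALL_SCENARIOS[name], **kwargs)


@dataclass(frozen=True)
class ChainSpec:
    """Linear block architecture of one copolymer chain.

    ``blocks`` is an ordered tuple of (species, run-length) pairs; the
    default is the symmetric A5B5 diblock.  Adjacent beads are tied by
    harmonic springs U = (K/2)(r - r0)^2 with K = 4 and r0 = 0 by default,
    i.e. the spring pulls bonded beads toward coincidence and the bond
    length is set by the balance with the soft pair repulsion.  Users whose
    convention is U = K(r - r0)^2 should double K.
    """

    blocks: tuple[tuple[str, int], ...] = (("A", 5), ("B", 5))
    K: float = 4.0
    r0: float = 0.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("spring constant K must be positive")
        if self.r0 < 0:
            raise ValueError("equilibrium bond length r0 must be non-negative")
        for sp, run in self.blocks:
            if sp not in ("A", "B"):
                raise ValueError(f"chain blocks must be polymer species A/B, got {sp!r}")
            if run < 1:
                raise ValueError("block run-lengths must be >= 1")

    @property
    def n(self) -> int:
        """Beads per chain."""
        return sum(run for _, run in self.blocks)

    @property
    def sequence(self) -> tuple[str, ...]:
        """Per-bead species labels in chain order."""
        return tuple(sp for sp, run in self.blocks for _ in range(run))


@dataclass(frozen=True)
class BoxGeometry:
    """Bulk periodic box or slit between two reflecting planes.

    For a slit the walls are perpendicular to x; ``Lx`` is then the slit
    width D, measured between the two reflecting planes at x = ±D/2, and
    periodicity applies only along y and z.  The soft wall potential
    U(x) = (a_wall x_c / 2)(1 - x/x_c)^2 acts on mobile beads within x_c
    of either plane (x_c = 1.2 suppresses density oscillations at the wall).
    """

    kind: str = "bulk"
    Lx: float = 25.0
    Ly: float = 25.0
    Lz: float = 25.0
    x_c: float = 1.2
    a_wall: float = 25.0

    def __post_init__(self) -> None:
        if self.kind not in ("bulk", "slit"):
            raise ValueError(f"geometry kind must be 'bulk' or 'slit', got {self.kind!r}")
        if min(self.Lx, self.Ly, self.Lz) <= 0:
            raise ValueError("box lengths must be positive")
        if self.kind == "slit" and self.Lx <= 2 * self.x_c:
            raise ValueError(
                f"slit width D={self.Lx} must exceed twice the wall repulsion "
                f"range x_c={self.x_c}"
            )

    @classmethod
    def bulk(cls, L: float = 25.0) -> "BoxGeometry":
        return cls(kind="bulk", Lx=L, Ly=L, Lz=L)

    @classmethod
    def slit(cls, D: float, L: float = 25.0, **kwargs) -> "BoxGeometry":
        return cls(kind="slit", Lx=D, Ly=L, Lz=L, **kwargs)

    @property
    def D(self) -> float:
        """Slit width (distance between the reflecting planes)."""
        if self.kind != "slit":
            raise AttributeError("D is defined for slit geometries only")
        return self.Lx

    @property
    def periodic(self) -> tuple[bool, bool, bool]:
        return (self.kind == "bulk", True, True)

    @property
    def volume(self) -> float:
        """Accessible volume: Lx*Ly*Lz in bulk, D*Ly*Lz in a slit."""
        return self.Lx * self.Ly * self.Lz

    @property
    def wall_area(self) -> float:
        """Area of one slit wall, Ly*Lz."""
        return self.Ly * self.Lz


@dataclass
class SystemParams:
    """Run-level parameters: density, chain count, schedule, seed."""

    rho: float = 3.0
    n_chains: int = 0
    steps: int = 0
    pre_equil_steps: int = 0
    sample_period: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("bead density rho must be positive")
        if self.n_chains < 0 or self.steps < 0 or self.pre_equil_steps < 0:
            raise ValueError("counts must be non-negative")
        if self.sample_period < 1:
            raise ValueError("sample_period must be >= 1")


def concentration(n_chains: int, n: int, rho: float, volume: float) -> float:
    """Volume concentration in percent, c = 100 N n / (rho V).

    Because DPD beads are soft and interpenetrate at rho > 1, the
    conventional volume fraction is normalised by the overall bead density:
    300 chains of 10 beads in a 25^3 box at rho = 3 give c = 6.4 %.
    """
    if volume <= 0 or rho <= 0:
        raise ValueError("invalid geometry: rho and V must be positive")
    if n_chains < 0 or n <= 0:
        raise ValueError("chain count must be >= 0 and beads per chain >= 1")
    return 100.0 * (n_chains * n) / (rho * volume)


def chains_for_concentration(c: float, n: int, rho: float, volume: float) -> int:
    """Number of chains that best realises a target concentration.

    Rounds to the nearest integer chain count; warns when the resulting
    concentration is not exactly the requested one (the achieved value is
    always within one chain's worth of it).
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if volume <= 0 or rho <= 0:
        raise ValueError("invalid geometry: rho and V must be positive")
    exact = c * rho * volume / (100.0 * n)
    n_chains = int(round(exact))
    if not math.isclose(exact, n_chains, abs_tol=1e-9):
        warnings.warn(
            f"target concentration {c}% not exactly realisable: using "
            f"{n_chains} chains giving c={concentration(n_chains, n, rho, volume):.4g}%",
            stacklevel=2,
        )
    return n_chains


def cylinder_sphere_capacity_ratio(n_spheres: int = 1) -> float:
    """Volume ratio of a cylinder (diameter D, length N·D) to N spheres of diameter D.

    The ratio is (pi D^2/4 · N D) / (N · pi D^3/6) = 3/2 independent of both
    N and D: a rod-like micelle core of the same diameter as N spherical
    cores holds 1.5 times as many chains, which is why long cylindrical
    associates relieve corona crowding at high concentration.
    """
    if n_spheres < 1:
        raise ValueError("need at least one sphere")
    # written out (rather than returning the constant) so the geometry is explicit
    d = 1.0
    cylinder = math.pi * d**2 / 4.0 * (n_spheres * d)
    spheres = n_spheres * math.pi * d**3 / 6.0
    return cylinder / spheres
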