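"""Core domain types for the constant-pH coarse-grained MD engine.

Units used throughout the package: length nm, time ps, energy kJ/mol,
mass amu, charge in elementary-charge units (e), temperature K.  All
*reported* simulation times are effective times: coarse-grained dynamics
are smoother than atomistic ones, and one formal time unit corresponds to
four effective units (see :func:`effective_time`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 8.314462618e-3
#: Coulomb constant 1/(4 pi eps0), kJ mol^-1 nm e^-2.
KE = 138.935458
#: Effective-to-formal time ratio of the coarse-grained dynamics.
TIME_SCALING = 4.0


class CgcphError(Exception):
    """Base class for package errors."""


@dataclass
class Bead:
    """A single coarse-grained bead (roughly four heavy atoms).

    A record view; the simulation state stores beads as flat arrays and
    materialises :class:`Bead` objects on demand.
    """

    index: int
    type_name: str
    mass: float                 # amu
    charge: float               # e
    lj_sigma: float             # nm
    lj_epsilon: float           # kJ/mol
    is_water: bool
    position: np.ndarray        # (3,) nm
    velocity: np.ndarray        # (3,) nm/ps

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"bead {self.index}: mass must be > 0")
        if self.lj_sigma <= 0:
            raise ValueError(f"bead {self.index}: lj_sigma must be > 0")
        if self.lj_epsilon < 0:
            raise ValueError(f"bead {self.index}: lj_epsilon must be >= 0")
        if self.is_water and self.charge not in (-1.0, 0.0, 1.0):
            raise ValueError("water bead charge must be -1, 0 or +1")


@dataclass
class TitratableSite:
    """A titratable bead with two charge states and a reference pKa.

    ``deprotonated`` is the discrete protonation flag; the continuous
    coupling parameter lambda (0 = protonated, 1 = deprotonated) lives in
    :class:`SystemState` and only leaves {0, 1} during a switch trajectory.
    """

    bead_index: int
    charge_protonated: float
    charge_deprotonated: float
    pka_ref: float
    deprotonated: bool = False

    def __post_init__(self) -> None:
        if self.charge_protonated == self.charge_deprotonated:
            raise ValueError("the two charge states must differ")
        if not np.isfinite(self.pka_ref):
            raise ValueError("pka_ref must be finite")

    def charge_at(self, lam: float) -> float:
        """Charge linearly interpolated in lambda between the two states."""
        return (1.0 - lam) * self.charge_protonated + lam * self.charge_deprotonated


@dataclass
class SimulationBox:
    """Orthorhombic periodic box."""

    lengths: np.ndarray  # (3,) nm

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.shape != (3,) or np.any(self.lengths <= 0):
            raise ValueError("box lengths must be three positive numbers")

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        inv = 1.0 / self.lengths
        return dr - self.lengths * np.rint(dr * inv)

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        return positions - self.lengths * np.floor(positions / self.lengths)


@dataclass
class SwitchProtocol:
    """Schedule for one nonequilibrium lambda-switch attempt.

    ``n_steps`` MD steps carry lambda linearly from one endpoint to the
    other; the default 200 steps is the routine protocol, escalated to
    1500 (with the cheap preswitch disabled) when large apparent-pKa
    shifts must be resolved by the work estimate alone.
    """

    n_steps: int = 200
    dt: float = 0.02           # ps, formal
    two_step: bool = True      # Hill-equation preswitch enabled

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def preswitch_disabled_full_switch(self) -> bool:
        return not self.two_step

    @classmethod
    def escalated(cls, dt: float = 0.02) -> "SwitchProtocol":
        """Full-switch-only protocol with the fine 1500-step schedule."""
        return cls(n_steps=1500, dt=dt, two_step=False)


@dataclass
class ForceFieldParams:
    """Nonbonded parameters and electrostatics controls.

    Pair LJ parameters default to Lorentz–Berthelot combination of the
    per-bead values; ``lj_table`` overrides individual type pairs, which
    is how the toy force field expresses hydrophobic mismatch.
    """

    lj_table: dict = field(default_factory=dict)  # (type_a, type_b) -> (sigma, epsilon)
    coulomb_constant: float = KE
    relative_dielectric: float = 15.0
    cutoff: float = 1.2        # nm
    switch_start: float = 0.9  # nm
    ewald_accuracy: float = 1e-5
    ewald_alpha: float | None = None  # nm^-1; None = derive from accuracy

    def __post_init__(self) -> None:
        if self.relative_dielectric <= 0:
            raise ValueError("relative_dielectric must be > 0")
        if not 0 < self.switch_start < self.cutoff:
            raise ValueError("need 0 < switch_start < cutoff")
        if not 0 < self.ewald_accuracy < 1:
            raise ValueError("ewald_accuracy must be in (0, 1)")

    def lj_pair(self, type_a: str, type_b: str,
                sigma_a: float, eps_a: float,
                sigma_b: float, eps_b: float) -> tuple[float, float]:
        key = (type_a, type_b) if (type_a, type_b) in self.lj_table else (type_b, type_a)
        if key in self.lj_table:
            return self.lj_table[key]
        return 0.5 * (sigma_a + sigma_b), float(np.sqrt(eps_a * eps_b))

    def validate_against(self, box: SimulationBox) -> None:
        if self.cutoff >= box.lengths.min() / 2:
            raise ValueError(
                f"cutoff {self.cutoff} nm must be < half the smallest box "
                f"length ({box.lengths.min() / 2:.3f} nm)")


@dataclass
class SystemState:
    """Full simulation state: the (x, lambda) pair plus topology.

    Positions/velocities/charges are flat numpy arrays indexed by bead;
    ``lambda_coupling`` holds one lambda per titratable site.  Outside a
    switch trajectory every lambda is exactly 0 or 1 and agrees with the
    site's boolean flag.  ``nb_ghost`` marks beads excluded from all
    nonbonded interactions (dummy particles); their charge still counts
    towards the net charge of the cell.
    """

    positions: np.ndarray          # (N, 3) nm
    velocities: np.ndarray         # (N, 3) nm/ps
    charges: np.ndarray            # (N,) e
    masses: np.ndarray             # (N,) amu
    lj_sigma: np.ndarray           # (N,) nm
    lj_epsilon: np.ndarray         # (N,) kJ/mol
    type_names: list[str]
    is_water: np.ndarray           # (N,) bool
    mol_ids: np.ndarray            # (N,) int; waters are one molecule each
    sites: list[TitratableSite]
    box: SimulationBox
    bond_indices: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 2), dtype=int))
    bond_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    bond_k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nb_ghost: np.ndarray = None    # (N,) bool
    lambda_coupling: np.ndarray = None  # (n_sites,)
    time_formal: float = 0.0       # ns
    rng: np.random.Generator = None

    def __post_init__(self) -> None:
        n = len(self.positions)
        self.positions = np.asarray(self.positions, dtype=float).reshape(n, 3)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(n, 3)
        for name in ("charges", "masses", "lj_sigma", "lj_epsilon"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.is_water = np.asarray(self.is_water, dtype=bool)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        if self.nb_ghost is None:
            self.nb_ghost = np.zeros(n, dtype=bool)
        self.nb_ghost = np.asarray(self.nb_ghost, dtype=bool)
        if self.lambda_coupling is None:
            self.lambda_coupling = np.array(
                [1.0 if s.deprotonated else 0.0 for s in self.sites])
        if self.rng is None:
            self.rng = np.random.default_rng(0)
        self.bond_indices = np.asarray(self.bond_indices, dtype=int).reshape(-1, 2)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)
        self.bond_k = np.asarray(self.bond_k, dtype=float)
        # topology-derived scratch (pair tables etc.); shared across copies
        self._cache: dict = {}
        self.apply_site_charges()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def bead(self, i: int) -> Bead:
        return Bead(index=i, type_name=self.type_names[i],
                    mass=float(self.masses[i]), charge=float(self.charges[i]),
                    lj_sigma=float(self.lj_sigma[i]),
                    lj_epsilon=float(self.lj_epsilon[i]),
                    is_water=bool(self.is_water[i]),
                    position=self.positions[i].copy(),
                    velocity=self.velocities[i].copy())

    @property
    def beads(self) -> Iterator[Bead]:
        return (self.bead(i) for i in range(self.n_beads))

    def apply_site_charges(self) -> None:
        """Write each site's lambda-interpolated charge into the charge array."""
        for lam, site in zip(self.lambda_coupling, self.sites):
            self.charges[site.bead_index] = site.charge_at(float(lam))

    def set_site_state(self, site_index: int, deprotonated: bool) -> None:
        site = self.sites[site_index]
        site.deprotonated = deprotonated
        self.lambda_coupling[site_index] = 1.0 if deprotonated else 0.0
        self.charges[site.bead_index] = site.charge_at(
            self.lambda_coupling[site_index])

    def copy(self) -> "SystemState":
        """Deep copy of all mutable per-frame data; topology arrays shared
        copies, rng state duplicated."""
        new = SystemState.__new__(SystemState)
        new.positions = self.positions.copy()
        new.velocities = self.velocities.copy()
        new.charges = self.charges.copy()
        new.masses = self.masses
        new.lj_sigma = self.lj_sigma
        new.lj_epsilon = self.lj_epsilon
        new.type_names = self.type_names
        new.is_water = self.is_water
        new.mol_ids = self.mol_ids
        new.sites = [replace(s) for s in self.sites]
        new.box = self.box
        new.bond_indices = self.bond_indices
        new.bond_r0 = self.bond_r0
        new.bond_k = self.bond_k
        new.nb_ghost = self.nb_ghost
        new.lambda_coupling = self.lambda_coupling.copy()
        new.time_formal = self.time_formal
        new._cache = self._cache
        new.rng = np.random.default_rng()
        new.rng.bit_generator.state = self.rng.bit_generator.state
        return new


def net_charge(state: SystemState) -> float:
    """Total charge of the cell in e, including titratable-site current-state
    charges and water bead charges.  Integer-valued outside switch
    trajectories."""
    return float(state.charges.sum())


def effective_time(formal_time: float) -> float:
    """Convert formal simulation time to effective time (x4).

    Coarse-grained dynamics run on a smoothed energy landscape; diffusive
    processes advance about four times faster than the formal clock, and
    all times reported by this package are effective.
    """
    if formal_time < 0:
        raise ValueError("formal_time must be >= 0")
    return TIME_SCALING * formal_time
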