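"""Synthetic toy-system builders.

Every test system is generated programmatically: a single titratable
site in a water bath, dispersed fatty-acid monomers, an N-mer micelle,
a rock-salt ionic lattice (the Ewald oracle), and a small bilayer patch
with embedded titratable fatty acids.

The toy force field is deliberately minimal but physically shaped like
a four-to-one coarse-grained model: all beads share sigma = 0.47 nm and
mass 72 amu; water-water and head-water cohesion 4.0 kJ/mol, tail-tail
3.5 kJ/mol, and a reduced tail-water epsilon (2.0 kJ/mol) expresses the
hydrophobic mismatch that drives self-assembly.  Titratable heads carry
charge 0 when protonated and -1 e when deprotonated (a carboxylate),
with a relative dielectric of 15 as is standard for non-polarizable
coarse-grained water.  These are method-validation systems: they probe
shift directions, cooperativity and charge bookkeeping, not
force-field-calibrated pKa values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (ForceFieldParams, SimulationBox, SystemState,
                    TitratableSite)

#: Coarse-grained water bead number density, beads/nm^3 (four waters per
#: bead at liquid-water density).
WATER_DENSITY = 8.3

SIGMA = 0.47     # nm, shared bead size
MASS = 72.0      # amu
EPS_WATER = 4.0  # kJ/mol
EPS_TAIL = 3.5
EPS_TAIL_WATER = 2.0
BOND_R0 = 0.47   # nm
BOND_K = 1250.0  # kJ/mol/nm^2
OLEIC_PKA = 4.73  # reference pKa of the dispersed fatty-acid headgroup


def toy_params(cutoff: float = 1.2, switch_start: float = 0.9,
               ewald_accuracy: float = 1e-5,
               relative_dielectric: float = 15.0) -> ForceFieldParams:
    """Force-field parameters matching the toy bead catalogue."""
    table = {("T", "W"): (SIGMA, EPS_TAIL_WATER),
             ("T", "D"): (SIGMA, EPS_TAIL_WATER)}
    return ForceFieldParams(lj_table=table, cutoff=cutoff,
                            switch_start=switch_start,
                            ewald_accuracy=ewald_accuracy,
                            relative_dielectric=relative_dielectric)


@dataclass
class FixtureSpec:
    """Declarative description of a toy system."""

    kind: str = "single_site"    # single_site | fa_solution | micelle |
                                 # ionic_lattice | bilayer_patch
    n_molecules: int = 1
    box_lengths: tuple = (1.6, 1.6, 1.6)
    pka_ref: float = OLEIC_PKA
    coupling: float = 1.0        # |deprotonated headgroup charge|, e
    seed: int = 0
    water_density: float = WATER_DENSITY
    lattice_spacing: float = 0.5     # ionic lattice only, nm
    fa_fraction: float = 0.25        # bilayer only

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


def build(spec: FixtureSpec) -> SystemState:
    builders = {"single_site": build_single_site,
                "fa_solution": build_fa_solution,
                "micelle": build_micelle,
                "ionic_lattice": build_ionic_lattice,
                "bilayer_patch": build_bilayer_patch}
    if spec.kind not in builders:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return builders[spec.kind](spec)


# ---------------------------------------------------------------------------
# helpers

def _lattice_points(box: np.ndarray, n_points: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Jittered cubic lattice filling the box; guarantees a minimum
    separation of ~0.3 nm at coarse-grained water density."""
    m = int(np.ceil(n_points ** (1 / 3)))
    while m ** 3 < n_points:
        m += 1
    spacing = box / m
    ax = [(np.arange(m) + 0.5) * spacing[d] for d in range(3)]
    pts = np.array(np.meshgrid(*ax, indexing="ij")).reshape(3, -1).T
    jitter = 0.08 * spacing.min()  # keeps minimum separation well clear of 0.3 nm
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    order = rng.permutation(len(pts))
    return pts[order]


def _assemble(solute_pos, solute_types, solute_charges, solute_mols,
              sites, bonds, box, spec, nb_ghost_solute=None,
              n_waters=None, exclude_near=0.42):
    """Add a water bath around the solute and build the SystemState."""
    rng = np.random.default_rng(spec.seed)
    box_arr = np.asarray(box, dtype=float)
    volume = float(np.prod(box_arr))
    solute_pos = np.asarray(solute_pos, dtype=float).reshape(-1, 3)
    n_solute = len(solute_pos)
    if n_waters is None:
        n_waters = max(0, int(round(spec.water_density * volume)) - n_solute)
    pts = _lattice_points(box_arr, n_waters + n_solute + 8, rng)
    if n_solute and len(pts):
        d = pts[:, None, :] - solute_pos[None, :, :]
        d -= box_arr * np.round(d / box_arr)
        ok = np.min(np.einsum("ijk,ijk->ij", d, d), axis=1) > exclude_near ** 2
        pts = pts[ok]
    water_pos = pts[:n_waters]
    n_waters = len(water_pos)
    n = n_solute + n_waters
    positions = np.vstack([solute_pos, water_pos]) if n_waters else solute_pos
    types = list(solute_types) + ["W"] * n_waters
    charges = np.concatenate([solute_charges, np.zeros(n_waters)])
    is_water = np.zeros(n, bool)
    is_water[n_solute:] = True
    mol_ids = np.concatenate([
        solute_mols,
        (max(solute_mols) + 1 if n_solute else 0) + np.arange(n_waters)])
    eps = np.array([EPS_TAIL if t == "T" else EPS_WATER for t in types])
    nb_ghost = np.zeros(n, bool)
    if nb_ghost_solute is not None:
        nb_ghost[:n_solute] = nb_ghost_solute
    bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
    return SystemState(
        positions=positions, velocities=np.zeros((n, 3)),
        charges=charges, masses=np.full(n, MASS),
        lj_sigma=np.full(n, SIGMA), lj_epsilon=eps,
        type_names=types, is_water=is_water,
        mol_ids=np.asarray(mol_ids, dtype=int), sites=list(sites),
        box=SimulationBox(np.asarray(box, dtype=float)),
        bond_indices=bonds, bond_r0=np.full(len(bonds), BOND_R0),
        bond_k=np.full(len(bonds), BOND_K),
        nb_ghost=nb_ghost, rng=np.random.default_rng(spec.seed))


def _head_site(bead_index: int, spec: FixtureSpec,
               deprotonated: bool) -> TitratableSite:
    q_dep = -(spec.coupling if spec.coupling > 0 else 1.0)
    return TitratableSite(bead_index=bead_index, charge_protonated=0.0,
                          charge_deprotonated=q_dep, pka_ref=spec.pka_ref,
                          deprotonated=deprotonated)


# ---------------------------------------------------------------------------
# builders

def build_single_site(spec: FixtureSpec) -> SystemState:
    """One titratable bead at the box centre in a neutral water bath.

    Total bead count is ``round(water_density * volume)``; the site
    replaces one water.  With ``coupling = 0`` the site is a nonbonded
    ghost: it feels and exerts no nonbonded interaction, so its
    titration must follow the bare Hill law — the engine's gold test.
    """
    box = np.asarray(spec.box_lengths, dtype=float)
    center = box / 2.0
    site = _head_site(0, spec, deprotonated=False)
    n_total = int(round(spec.water_density * float(np.prod(box))))
    state = _assemble(center[None, :], ["D"], np.array([0.0]), np.array([0]),
                      [site], np.zeros((0, 2)), box, spec,
                      nb_ghost_solute=np.array([spec.coupling == 0.0]),
                      n_waters=n_total - 1)
    return state


def build_fa_solution(spec: FixtureSpec) -> SystemState:
    """Dispersed two-bead fatty-acid monomers (tail T + titratable head D)."""
    rng = np.random.default_rng(spec.seed + 1)
    box = np.asarray(spec.box_lengths, dtype=float)
    n = spec.n_molecules
    anchors = _lattice_points(box, max(n, 8), rng)[:n]
    pos, types, mols, bonds, sites, charges = [], [], [], [], [], []
    for m in range(n):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        tail = anchors[m]
        head = tail + BOND_R0 * direction
        i_tail, i_head = 2 * m, 2 * m + 1
        pos += [tail, head]
        types += ["T", "D"]
        mols += [m, m]
        charges += [0.0, 0.0]
        bonds.append((i_tail, i_head))
        sites.append(_head_site(i_head, spec, deprotonated=False))
    return _assemble(np.array(pos), types, np.array(charges), np.array(mols),
                     sites, bonds, box, spec)


def build_micelle(spec: FixtureSpec) -> SystemState:
    """N-mer micelle: two-bead amphiphiles with heads on a sphere, tails
    inward, fully deprotonated, solvated in neutral water."""
    n = spec.n_molecules
    box = np.asarray(spec.box_lengths, dtype=float)
    area_per_head = 0.45  # nm^2; sets the head-shell radius
    r_head = max(np.sqrt(n * area_per_head / (4 * np.pi)), 0.55)
    # tails sit on a slightly stretched bond, with the inner-shell radius
    # floored so neighbouring tails start > 0.3 nm apart
    r_tail = max(r_head - 0.35, 0.35 * np.sqrt(n / (4 * np.pi)))
    center = box / 2.0
    from .analysis import _sphere_points
    shell = _sphere_points(n)
    pos, types, mols, bonds, sites, charges = [], [], [], [], [], []
    for m in range(n):
        head = center + r_head * shell[m]
        tail = center + r_tail * shell[m]
        i_tail, i_head = 2 * m, 2 * m + 1
        pos += [tail, head]
        types += ["T", "D"]
        mols += [m, m]
        charges += [0.0, 0.0]
        bonds.append((i_tail, i_head))
        sites.append(_head_site(i_head, spec, deprotonated=True))
    state = _assemble(np.array(pos), types, np.array(charges),
                      np.array(mols), sites, bonds, box, spec,
                      exclude_near=0.45)
    return state


def build_ionic_lattice(spec: FixtureSpec) -> SystemState:
    """Rock-salt arrangement of +-1 beads, net neutral — the direct
    lattice-sum (Madelung) oracle for the Ewald backend.

    ``n_molecules`` is interpreted as ions per box edge (even), so the
    cell holds ``n_molecules ** 3`` ions at ``lattice_spacing``.
    """
    m = spec.n_molecules if spec.n_molecules > 1 else 2
    if m % 2:
        raise ValueError("ions per edge must be even for a neutral cell")
    d = spec.lattice_spacing
    box = np.array([m * d] * 3)
    idx = np.array(np.meshgrid(*[np.arange(m)] * 3, indexing="ij"))
    idx = idx.reshape(3, -1).T
    pos = (idx + 0.5) * d
    q = np.where(idx.sum(axis=1) % 2 == 0, 1.0, -1.0)
    n = len(pos)
    return SystemState(
        positions=pos, velocities=np.zeros((n, 3)), charges=q,
        masses=np.full(n, MASS), lj_sigma=np.full(n, SIGMA),
        lj_epsilon=np.zeros(n),
        type_names=["NA" if c > 0 else "CL" for c in q],
        is_water=np.zeros(n, bool), mol_ids=np.arange(n), sites=[],
        box=SimulationBox(box), rng=np.random.default_rng(spec.seed))


def build_bilayer_patch(spec: FixtureSpec) -> SystemState:
    """Two-leaflet patch of three-bead lipids with embedded titratable FAs.

    Each lipid is a zwitterionic head pair (+1 choline-like over -1
    phosphate-like) bonded to one tail bead; a fraction ``fa_fraction``
    of the lattice positions carry a two-bead titratable fatty acid
    instead.  ``n_molecules`` is the per-leaflet molecule count (a
    square number gives a regular grid).
    """
    n_leaf = spec.n_molecules
    side = int(np.ceil(np.sqrt(n_leaf)))
    box = np.asarray(spec.box_lengths, dtype=float)
    spacing = box[0] / side
    z_mid = box[2] / 2.0
    rng = np.random.default_rng(spec.seed + 2)
    n_fa_leaf = int(round(spec.fa_fraction * n_leaf))
    pos, types, mols, bonds, sites, charges, ghost = [], [], [], [], [], [], []
    mol = 0
    for leaflet, zdir in ((0, 1.0), (1, -1.0)):
        fa_slots = set(rng.choice(n_leaf, size=n_fa_leaf, replace=False))
        for k in range(n_leaf):
            gx, gy = divmod(k, side)
            x = (gx + 0.5) * spacing
            y = (gy + 0.5) * spacing
            base = len(pos)
            if k in fa_slots:
                tail = [x, y, z_mid + zdir * 0.3]
                head = [x, y, z_mid + zdir * (0.3 + BOND_R0)]
                pos += [tail, head]
                types += ["T", "D"]
                charges += [0.0, 0.0]
                mols += [mol, mol]
                bonds.append((base, base + 1))
                sites.append(_head_site(base + 1, spec, deprotonated=False))
            else:
                tail = [x, y, z_mid + zdir * 0.3]
                phos = [x, y, z_mid + zdir * (0.3 + BOND_R0)]
                chol = [x, y, z_mid + zdir * (0.3 + 2 * BOND_R0)]
                pos += [tail, phos, chol]
                types += ["T", "P", "Q"]
                charges += [0.0, -1.0, 1.0]
                mols += [mol, mol, mol]
                bonds += [(base, base + 1), (base + 1, base + 2)]
            mol += 1
    return _assemble(np.array(pos), types, np.array(charges),
                     np.array(mols), sites, bonds, box, spec,
                     exclude_near=0.45)
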