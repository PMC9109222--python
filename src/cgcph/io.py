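"""Readers, writers and run configuration.

Structures are exchanged as GRO (native dialect: fixed width, nm,
3-decimal positions) or PDB (Angstrom, converted on read); parsing goes
through MDAnalysis.  Trajectories are concatenated GRO frames.  The
topology — bead types, per-bead charges, bonds and titratable sites —
travels in a small declarative YAML file defined by this package, since
structure formats carry no charge-state information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import (CgcphError, ForceFieldParams, SimulationBox, SystemState,
                    TitratableSite)

_NM_PER_ANGSTROM = 0.1


class StructureError(CgcphError):
    pass


class ConfigError(CgcphError):
    pass


# ---------------------------------------------------------------------------
# topology

def write_topology(state: SystemState, path) -> None:
    """Serialize bead types, charges, bonds and titratable sites to YAML."""
    types: dict = {}
    for i, t in enumerate(state.type_names):
        types.setdefault(t, {
            "mass": float(state.masses[i]),
            "sigma": float(state.lj_sigma[i]),
            "epsilon": float(state.lj_epsilon[i]),
            "water": bool(state.is_water[i])})
    doc = {
        "bead_types": types,
        "beads": [{"type": t, "charge": float(state.charges[i]),
                   "mol": int(state.mol_ids[i]),
                   **({"ghost": True} if state.nb_ghost[i] else {})}
                  for i, t in enumerate(state.type_names)],
        "bonds": [{"i": int(i), "j": int(j), "r0": float(r0), "k": float(k)}
                  for (i, j), r0, k in zip(state.bond_indices.tolist(),
                                           state.bond_r0, state.bond_k)],
        "sites": [{"bead": int(s.bead_index),
                   "q_protonated": float(s.charge_protonated),
                   "q_deprotonated": float(s.charge_deprotonated),
                   "pka_ref": float(s.pka_ref),
                   "deprotonated": bool(s.deprotonated)}
                  for s in state.sites],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_topology(path) -> dict:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise StructureError(f"malformed topology {path}: {exc}") from exc
    for key in ("bead_types", "beads"):
        if key not in doc:
            raise StructureError(f"topology {path} lacks required key {key!r}")
    return doc


# ---------------------------------------------------------------------------
# structure reading (GRO / PDB via MDAnalysis)

def _validate_gro(path: Path) -> None:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise StructureError(f"{path}: truncated GRO file ({len(lines)} lines)")
    try:
        natoms = int(lines[1].split()[0])
    except (ValueError, IndexError) as exc:
        raise StructureError(f"{path}, line 2: bad atom count "
                             f"{lines[1]!r}") from exc
    if len(lines) < natoms + 3:
        raise StructureError(
            f"{path}: truncated at line {len(lines)}; expected "
            f"{natoms + 3} lines for {natoms} atoms")


def read_structure(path, topology_path) -> SystemState:
    """Build a :class:`SystemState` from a GRO/PDB file plus a topology.

    Coordinates are converted to nm; absent velocities become zeros.
    """
    import MDAnalysis as mda

    path = Path(path)
    if path.suffix.lower() == ".gro":
        _validate_gro(path)
    top = read_topology(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:
            raise StructureError(f"cannot parse {path}: {exc}") from exc
    n = len(u.atoms)
    beads = top["beads"]
    if len(beads) != n:
        raise StructureError(
            f"{path} has {n} atoms but the topology lists {len(beads)} beads")
    positions = u.atoms.positions * _NM_PER_ANGSTROM
    try:
        velocities = u.atoms.velocities * _NM_PER_ANGSTROM
    except Exception:
        velocities = np.zeros_like(positions)
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise StructureError(f"{path}: missing or invalid box record")
    box = SimulationBox(dims[:3] * _NM_PER_ANGSTROM)
    btypes = top["bead_types"]
    type_names = [b["type"] for b in beads]
    for t in type_names:
        if t not in btypes:
            raise StructureError(f"bead type {t!r} missing from bead_types")
    sites = [TitratableSite(bead_index=s["bead"],
                            charge_protonated=s["q_protonated"],
                            charge_deprotonated=s["q_deprotonated"],
                            pka_ref=s["pka_ref"],
                            deprotonated=bool(s.get("deprotonated", False)))
             for s in top.get("sites", [])]
    bonds = top.get("bonds", [])
    return SystemState(
        positions=positions, velocities=velocities,
        charges=np.array([b["charge"] for b in beads]),
        masses=np.array([btypes[t]["mass"] for t in type_names]),
        lj_sigma=np.array([btypes[t]["sigma"] for t in type_names]),
        lj_epsilon=np.array([btypes[t]["epsilon"] for t in type_names]),
        type_names=type_names,
        is_water=np.array([bool(btypes[t].get("water", False))
                           for t in type_names]),
        mol_ids=np.array([b["mol"] for b in beads]),
        sites=sites, box=box,
        bond_indices=np.array([[b["i"], b["j"]] for b in bonds]).reshape(-1, 2),
        bond_r0=np.array([b["r0"] for b in bonds]),
        bond_k=np.array([b["k"] for b in bonds]),
        nb_ghost=np.array([bool(b.get("ghost", False)) for b in beads]))


# ---------------------------------------------------------------------------
# structure writing (fixed-width GRO; multi-frame files are the
# trajectory dialect — frames simply concatenated)

def _gro_frame(state: SystemState, title: str) -> str:
    lines = [title, f"{state.n_beads:5d}"]
    for i in range(state.n_beads):
        resid = (int(state.mol_ids[i]) + 1) % 100000
        name = state.type_names[i][:5]
        x, y, z = state.positions[i]
        vx, vy, vz = state.velocities[i]
        lines.append(f"{resid:5d}{name:<5s}{name:>5s}{(i + 1) % 100000:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}{vx:8.4f}{vy:8.4f}{vz:8.4f}")
    lx, ly, lz = state.box.lengths
    lines.append(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}")
    return "\n".join(lines) + "\n"


def write_structure(state: SystemState, path, title: str = "cgcph frame") -> None:
    if state.n_beads == 0:
        raise StructureError("refusing to write an empty state")
    Path(path).write_text(_gro_frame(state, title))


def write_trajectory(states, path) -> None:
    states = list(states)
    if not states:
        raise StructureError("refusing to write an empty trajectory")
    text = "".join(
        _gro_frame(s, f"cgcph frame {k} t={s.time_formal:.6f} ns")
        for k, s in enumerate(states))
    Path(path).write_text(text)


def read_trajectory_frames(path):
    """Parse a concatenated-GRO trajectory into a list of
    (positions_nm, velocities_nm_ps, box_lengths_nm) tuples."""
    lines = Path(path).read_text().splitlines()
    frames = []
    k = 0
    while k < len(lines):
        if not lines[k].strip() and k == len(lines) - 1:
            break
        try:
            natoms = int(lines[k + 1].split()[0])
        except (IndexError, ValueError) as exc:
            raise StructureError(
                f"{path}, line {k + 2}: bad frame header") from exc
        if k + natoms + 3 > len(lines) + 1:
            raise StructureError(f"{path}: truncated frame at line {k + 1}")
        pos = np.empty((natoms, 3))
        vel = np.zeros((natoms, 3))
        for a in range(natoms):
            ln = lines[k + 2 + a]
            try:
                pos[a] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
                if len(ln) >= 68:
                    vel[a] = [float(ln[44:52]), float(ln[52:60]),
                              float(ln[60:68])]
            except ValueError as exc:
                raise StructureError(
                    f"{path}, line {k + 3 + a}: bad coordinate record") from exc
        box = np.array([float(v) for v in lines[k + 2 + natoms].split()[:3]])
        frames.append((pos, vel, box))
        k += natoms + 3
    return frames


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Declarative run description (mirrors the experimental-design
    vocabulary: ``electro`` pme/switch, ``charge`` constant/fluctuating)."""

    structure: str
    topology: str
    electro: str = "pme"
    charge: str = "constant"
    ph: float | None = None
    ph_low: float | None = None
    ph_high: float | None = None
    cycles: int = 500
    md_steps_per_cycle: int = 10
    switch_steps: int = 200
    two_step: bool = True
    seed: int = 0
    temperature: float = 300.0
    friction: float = 1.0
    dt: float = 0.02
    cutoff: float = 1.2
    switch_start: float = 0.9
    ewald_accuracy: float = 1e-5
    relative_dielectric: float = 15.0
    lj_table: dict = field(default_factory=dict)
    window_ns: float | None = None
    output_prefix: str = "cgcph_out"

    def __post_init__(self) -> None:
        if self.electro not in ("pme", "switch"):
            raise ConfigError("electro must be 'pme' or 'switch'")
        if self.charge not in ("constant", "fluctuating"):
            raise ConfigError("charge must be 'constant' or 'fluctuating'")

    @property
    def neutralize(self) -> bool:
        return self.charge == "constant"

    def force_field(self) -> ForceFieldParams:
        table = {tuple(k.split("-")): tuple(v) for k, v in self.lj_table.items()}
        return ForceFieldParams(lj_table=table, cutoff=self.cutoff,
                                switch_start=self.switch_start,
                                ewald_accuracy=self.ewald_accuracy,
                                relative_dielectric=self.relative_dielectric)


def load_config(path) -> RunConfig:
    try:
        doc = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from exc
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for req in ("structure", "topology"):
        if req not in doc:
            raise ConfigError(f"config {path} lacks required key {req!r}")
    base = Path(path).parent
    for key in ("structure", "topology"):
        p = Path(doc[key])
        doc[key] = str(p if p.is_absolute() else base / p)
    return RunConfig(**doc)


def write_config(config: RunConfig, path) -> None:
    doc = {k: getattr(config, k) for k in RunConfig.__dataclass_fields__}
    doc = {k: v for k, v in doc.items() if v is not None}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
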