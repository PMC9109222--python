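"""Structural observables: SASA, aggregation propensity, aggregate
clustering, size-resolved deprotonation and charge statistics.

The aggregation propensity (AP) quantifies surface burial during
self-assembly as the ratio of the solvent-accessible surface area at the
start of a trajectory to its value at time t:

    AP(t) = SASA(t0) / SASA(t)

so AP = 1 for an unchanged structure and AP > 1 once molecules cluster
and bury surface.  SASA uses the Shrake-Rupley rolling-probe algorithm
on the coarse-grained beads (radius sigma/2 by default).  Aggregates are
single-linkage clusters of solute molecules: two molecules are in
contact when any inter-molecular bead pair is within the contact cutoff
(periodic minimum image), and connected components of the contact graph
are the aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .model import SystemState


@dataclass
class AggregateReport:
    """Cluster decomposition of the solute molecules in one frame."""

    cluster_labels: np.ndarray            # per-molecule integer label
    sizes: np.ndarray                     # molecules per cluster
    per_cluster_deprotonated_fraction: np.ndarray
    ap: float
    mean_charge: float                    # e, per molecule
    sum_abs_charge: float                 # e, per molecule

    def __post_init__(self) -> None:
        if self.sizes.sum() != len(self.cluster_labels):
            raise ValueError("cluster sizes do not add up to the molecule count")


# ---------------------------------------------------------------------------
# SASA

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(state_or_positions, radii=None, probe_radius: float = 0.24,
         n_sphere_points: int = 960, include_water: bool = False):
    """Shrake-Rupley solvent-accessible surface area.

    Accepts either a :class:`SystemState` (radii default to lj_sigma/2,
    waters excluded unless requested) or a plain (N, 3) position array
    with explicit ``radii``.  Returns ``(total_nm2, per_bead_nm2)``.
    The default probe radius 0.24 nm is half a coarse-grained water bead
    diameter.  Surfaces are evaluated without periodic images: the
    quantity of interest is the exposed surface of a compact aggregate.
    """
    if n_sphere_points < 16:
        raise ValueError("n_sphere_points must be >= 16")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if isinstance(state_or_positions, SystemState):
        state = state_or_positions
        mask = np.ones(state.n_beads, bool) if include_water else ~state.is_water
        pos = state.positions[mask]
        r = (0.5 * state.lj_sigma[mask] if radii is None
             else np.asarray(radii, float)[mask])
    else:
        pos = np.asarray(state_or_positions, dtype=float)
        if radii is None:
            raise ValueError("radii required with a plain position array")
        r = np.broadcast_to(np.asarray(radii, dtype=float), (len(pos),)).copy()
    n = len(pos)
    areas = np.zeros(n)
    if n == 0:
        return 0.0, areas
    # exactly coincident identical spheres are one surface: keep a single
    # representative and assign the duplicate zero area
    keys = {}
    rep = []
    for i in range(n):
        key = (tuple(np.round(pos[i], 9)), round(float(r[i]), 9))
        if key not in keys:
            keys[key] = i
            rep.append(i)
    if len(rep) < n:
        total, sub_areas = sasa(pos[rep], radii=r[rep],
                                probe_radius=probe_radius,
                                n_sphere_points=n_sphere_points)
        areas[np.asarray(rep)] = sub_areas
        return total, areas
    sphere = _sphere_points(n_sphere_points)
    expanded = r + probe_radius
    # neighbours within sum of expanded radii can occlude points
    d = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    cut = expanded[:, None] + expanded[None, :]
    for i in range(n):
        nbr = np.nonzero((dist[i] < cut[i]) & (np.arange(n) != i))[0]
        pts = pos[i] + expanded[i] * sphere
        if len(nbr):
            dd = pts[:, None, :] - pos[nbr][None, :, :]
            inside = np.any(
                np.einsum("pjk,pjk->pj", dd, dd) < (expanded[nbr] ** 2)[None, :],
                axis=1)
            exposed = np.count_nonzero(~inside)
        else:
            exposed = n_sphere_points
        areas[i] = exposed / n_sphere_points * 4.0 * np.pi * expanded[i] ** 2
    return float(areas.sum()), areas


def aggregation_propensity(sasa_initial: float, sasa_t: float) -> float:
    """AP = SASA(t0) / SASA(t); > 1 indicates burial of surface."""
    if sasa_initial <= 0 or sasa_t <= 0:
        raise ValueError("SASA values must be > 0")
    return sasa_initial / sasa_t


# ---------------------------------------------------------------------------
# clustering

def cluster_molecules(state: SystemState, contact_cutoff_nm: float = 0.6,
                      include_water: bool = False) -> np.ndarray:
    """Single-linkage aggregate labels for the solute molecules.

    Returns an integer label per molecule (ordered by first occurrence of
    each molecule id among the selected beads).
    """
    if contact_cutoff_nm <= 0:
        raise ValueError("contact cutoff must be > 0")
    mask = np.ones(state.n_beads, bool) if include_water else ~state.is_water
    mol_of_bead = state.mol_ids[mask]
    pos = state.positions[mask]
    mols, mol_index = np.unique(mol_of_bead, return_inverse=True)
    m = len(mols)
    if m == 0:
        return np.zeros(0, dtype=int)
    dr = pos[:, None, :] - pos[None, :, :]
    dr = state.box.minimum_image(dr)
    within = np.einsum("ijk,ijk->ij", dr, dr) < contact_cutoff_nm ** 2
    ii, jj = np.nonzero(within)
    inter = mol_index[ii] != mol_index[jj]
    rows, cols = mol_index[ii[inter]], mol_index[jj[inter]]
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    _, labels = connected_components(graph, directed=False)
    return labels


def aggregate_report(state: SystemState, sasa_initial: float | None = None,
                     contact_cutoff_nm: float = 0.6,
                     probe_radius: float = 0.24,
                     n_sphere_points: int = 960) -> AggregateReport:
    """Full per-frame aggregate decomposition with AP and charge stats."""
    labels = cluster_molecules(state, contact_cutoff_nm)
    sizes = np.bincount(labels)
    mask = ~state.is_water
    mols = np.unique(state.mol_ids[mask])
    site_mol = {}
    for k, site in enumerate(state.sites):
        site_mol.setdefault(state.mol_ids[site.bead_index], []).append(site)
    frac = np.zeros(len(sizes))
    for c in range(len(sizes)):
        flags = [s.deprotonated for mol in mols[labels == c]
                 for s in site_mol.get(mol, [])]
        frac[c] = np.mean(flags) if flags else 0.0
    total, _ = sasa(state, probe_radius=probe_radius,
                    n_sphere_points=n_sphere_points)
    ap = 1.0 if sasa_initial is None else aggregation_propensity(sasa_initial, total)
    mean_q, sum_abs = charge_stats(state)
    return AggregateReport(cluster_labels=labels, sizes=sizes,
                           per_cluster_deprotonated_fraction=frac,
                           ap=ap, mean_charge=mean_q, sum_abs_charge=sum_abs)


# ---------------------------------------------------------------------------
# protonation vs aggregate size, charge statistics

def size_resolved_deprotonation(labels_per_frame, per_site_series,
                                site_mol_ids) -> list[tuple[int, float]]:
    """Join aggregate sizes with per-site protonation, frame by frame.

    ``labels_per_frame``: sequence of per-molecule label arrays (one per
    frame); ``per_site_series``: (frames, sites) boolean deprotonation
    matrix; ``site_mol_ids``: molecule index of each titratable site.
    Returns sorted ``(aggregate size, mean deprotonated fraction)`` pairs.
    """
    per_site_series = np.asarray(per_site_series, dtype=bool)
    if len(labels_per_frame) == 0 or per_site_series.size == 0:
        raise ValueError("empty frame set")
    if len(labels_per_frame) != len(per_site_series):
        raise ValueError("frame counts of labels and series differ")
    site_mol_ids = np.asarray(site_mol_ids, dtype=int)
    if per_site_series.shape[1] != len(site_mol_ids):
        raise ValueError("site count mismatch between series and mol ids")
    acc: dict[int, list] = {}
    for labels, flags in zip(labels_per_frame, per_site_series):
        labels = np.asarray(labels, dtype=int)
        sizes = np.bincount(labels)
        for mol, flag in zip(site_mol_ids, flags):
            acc.setdefault(int(sizes[labels[mol]]), []).append(bool(flag))
    return sorted((size, float(np.mean(v))) for size, v in acc.items())


def charge_stats(state: SystemState, charges=None) -> tuple[float, float]:
    """Per-molecule charge statistics of the solute.

    Returns ``(mean_charge, sum_abs_charge)``: the net charge per solute
    molecule averaged over molecules, and the mean over molecules of the
    summed absolute charges of its charged groups (one group = one bead
    at coarse-grained resolution).
    """
    q = state.charges if charges is None else np.asarray(charges, dtype=float)
    mask = ~state.is_water
    mols = state.mol_ids[mask]
    uniq = np.unique(mols)
    if len(uniq) == 0:
        return 0.0, 0.0
    net = np.array([q[mask][mols == m].sum() for m in uniq])
    sabs = np.array([np.abs(q[mask][mols == m]).sum() for m in uniq])
    return float(net.mean()), float(sabs.mean())
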