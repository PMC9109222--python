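"""Potential energy and forces for the coarse-grained toy force field.

Nonbonded terms:

* Lennard-Jones 12-6 with a C1-continuous cubic switching function
  between ``switch_start`` and ``cutoff`` (potential-switch form: the
  pair potential is multiplied by ``s(r) = 1 - 3x^2 + 2x^3`` with
  ``x = (r - r_s)/(r_c - r_s)``, so both the potential and the force are
  continuous at both ends of the switching region).
* Coulomb, either (a) the same switched cutoff applied to ``q_i q_j
  k_e / (eps_r r)`` or (b) plain Ewald summation (real-space erfc sum,
  reciprocal-space Gaussian sum, self term).  For a non-neutral cell the
  Ewald sum only converges against a uniform neutralizing background;
  that background-correction energy is reported separately because it is
  precisely the artifact that stochastic charge neutralization removes.

Bonded terms: harmonic bonds; 1-2 bonded pairs are excluded from the
nonbonded sums (with the proper reciprocal-space correction under Ewald).
Beads flagged ``nb_ghost`` take part in no nonbonded interaction at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, erfc

from . import _kernels
from .model import CgcphError, ForceFieldParams, SystemState

_MIN_R = 1e-6  # nm; closer approaches are treated as overlapping beads


class OverlapError(CgcphError):
    pass


class NonNeutralCellError(CgcphError):
    pass


@dataclass
class EnergyBreakdown:
    """Energy components in kJ/mol; ``total`` is their sum."""

    lj: float = 0.0
    coulomb_real: float = 0.0
    coulomb_reciprocal: float = 0.0
    coulomb_self: float = 0.0
    background_correction: float = 0.0
    bonded: float = 0.0

    @property
    def total(self) -> float:
        return (self.lj + self.coulomb_real + self.coulomb_reciprocal
                + self.coulomb_self + self.background_correction + self.bonded)

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            lj=self.lj + other.lj,
            coulomb_real=self.coulomb_real + other.coulomb_real,
            coulomb_reciprocal=self.coulomb_reciprocal + other.coulomb_reciprocal,
            coulomb_self=self.coulomb_self + other.coulomb_self,
            background_correction=self.background_correction + other.background_correction,
            bonded=self.bonded + other.bonded)


# ---------------------------------------------------------------------------
# switching function

def switch_value(r: np.ndarray, r_s: float, r_c: float) -> np.ndarray:
    """s(r): 1 below r_s, smoothstep down to 0 at r_c."""
    r = np.asarray(r, dtype=float)
    x = np.clip((r - r_s) / (r_c - r_s), 0.0, 1.0)
    return 1.0 - x * x * (3.0 - 2.0 * x)


def switch_derivative(r: np.ndarray, r_s: float, r_c: float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    x = (r - r_s) / (r_c - r_s)
    inside = (x > 0.0) & (x < 1.0)
    ds = np.zeros_like(r)
    ds[inside] = -6.0 * x[inside] * (1.0 - x[inside]) / (r_c - r_s)
    return ds


# ---------------------------------------------------------------------------
# pair tables (topology-derived, cached on the state)

def _excluded_pairs(state: SystemState) -> set:
    return {tuple(sorted(p)) for p in state.bond_indices.tolist()}


def _excluded_keys(state: SystemState) -> np.ndarray:
    """Sorted encoded keys (i*N + j, i<j) of the bonded 1-2 exclusions."""
    if "excl_keys" not in state._cache:
        n = state.n_beads
        if len(state.bond_indices):
            lo = state.bond_indices.min(axis=1)
            hi = state.bond_indices.max(axis=1)
            state._cache["excl_keys"] = np.sort(lo.astype(np.int64) * n + hi)
        else:
            state._cache["excl_keys"] = np.zeros(0, dtype=np.int64)
    return state._cache["excl_keys"]


def _filter_excluded(state: SystemState, ii: np.ndarray, jj: np.ndarray):
    keys = _excluded_keys(state)
    if len(keys) == 0:
        return ii, jj
    n = state.n_beads
    enc = (np.minimum(ii, jj).astype(np.int64) * n
           + np.maximum(ii, jj).astype(np.int64))
    keep = ~np.isin(enc, keys)
    return ii[keep], jj[keep]


def _scatter_forces(forces: np.ndarray, ii, jj, fv) -> None:
    n = len(forces)
    for d in range(3):
        forces[:, d] += np.bincount(ii, weights=fv[:, d], minlength=n)
        forces[:, d] -= np.bincount(jj, weights=fv[:, d], minlength=n)


def _lj_pairs(state: SystemState, params: ForceFieldParams):
    """(i, j, sigma_ij, eps_ij) for every interacting LJ pair."""
    key = ("lj_pairs", tuple(sorted(params.lj_table.items())))
    if key in state._cache:
        return state._cache[key]
    n = state.n_beads
    ii, jj = np.triu_indices(n, 1)
    keep = ~(state.nb_ghost[ii] | state.nb_ghost[jj])
    ii, jj = _filter_excluded(state, ii[keep], jj[keep])
    sig = np.empty(len(ii))
    eps = np.empty(len(ii))
    for m, (a, b) in enumerate(zip(ii, jj)):
        sig[m], eps[m] = params.lj_pair(
            state.type_names[a], state.type_names[b],
            state.lj_sigma[a], state.lj_epsilon[a],
            state.lj_sigma[b], state.lj_epsilon[b])
    live = eps > 0
    out = (ii[live], jj[live], sig[live], eps[live])
    state._cache[key] = out
    return out


def _charged_indices(state: SystemState) -> np.ndarray:
    return np.nonzero((state.charges != 0.0) & ~state.nb_ghost)[0]


def _pair_distances(state: SystemState, ii, jj):
    dr = state.positions[ii] - state.positions[jj]
    dr = state.box.minimum_image(dr)
    r2 = np.einsum("ij,ij->i", dr, dr)
    return dr, r2


def _check_overlap(r2: np.ndarray) -> None:
    if r2.size and r2.min() < _MIN_R ** 2:
        raise OverlapError(
            f"overlapping beads: minimum pair distance {np.sqrt(r2.min()):.2e} nm")


# ---------------------------------------------------------------------------
# bonded

def bonded_energy_forces(state: SystemState):
    forces = np.zeros_like(state.positions)
    if len(state.bond_indices) == 0:
        return 0.0, forces
    ii, jj = state.bond_indices[:, 0], state.bond_indices[:, 1]
    dr, r2 = _pair_distances(state, ii, jj)
    r = np.sqrt(r2)
    _check_overlap(r2)
    dx = r - state.bond_r0
    energy = float(np.sum(0.5 * state.bond_k * dx * dx))
    fmag = -state.bond_k * dx / r  # force on i along dr
    fv = fmag[:, None] * dr
    _scatter_forces(forces, ii, jj, fv)
    return energy, forces


# ---------------------------------------------------------------------------
# Lennard-Jones

_NB_SKIN = 0.3  # nm; Verlet-list skin


def _lj_neighbours(state: SystemState, params: ForceFieldParams):
    """Verlet neighbour list over the LJ pair table: pairs within
    cutoff + skin, rebuilt once any bead has moved more than skin/2."""
    key = ("ljnb", params.cutoff, tuple(sorted(params.lj_table.items())))
    cached = state._cache.get(key)
    if cached is not None:
        snap, nb = cached
        disp = state.box.minimum_image(state.positions - snap)
        if np.einsum("ij,ij->i", disp, disp).max() < (0.5 * _NB_SKIN) ** 2:
            return nb
    ii, jj, sig, eps = _lj_pairs(state, params)
    if len(ii):
        _, r2 = _pair_distances(state, ii, jj)
        within = r2 < (params.cutoff + _NB_SKIN) ** 2
        nb = (ii[within], jj[within], sig[within], eps[within])
    else:
        nb = (ii, jj, sig, eps)
    state._cache[key] = (state.positions.copy(), nb)
    return nb


def lj_energy_forces(state: SystemState, params: ForceFieldParams):
    """Switched-cutoff LJ energy (kJ/mol) and per-bead forces (kJ/mol/nm)."""
    params.validate_against(state.box)
    forces = np.zeros_like(state.positions)
    ii, jj, sig, eps = _lj_neighbours(state, params)
    if len(ii) == 0:
        return 0.0, forces
    if _kernels.HAS_NUMBA:
        energy, min_r2 = _kernels.lj_switch_pairs(
            state.positions, ii, jj, sig, eps, state.box.lengths,
            params.switch_start, params.cutoff, forces)
        if min_r2 < _MIN_R ** 2:
            raise OverlapError(
                f"overlapping beads: minimum pair distance "
                f"{np.sqrt(min_r2):.2e} nm")
        return float(energy), forces
    dr, r2 = _pair_distances(state, ii, jj)
    within = r2 < params.cutoff ** 2
    ii, jj, sig, eps, dr, r2 = ii[within], jj[within], sig[within], eps[within], dr[within], r2[within]
    if len(ii) == 0:
        return 0.0, forces
    _check_overlap(r2)
    r = np.sqrt(r2)
    sr6 = (sig * sig / r2) ** 3
    u = 4.0 * eps * (sr6 * sr6 - sr6)
    du = 24.0 * eps * (sr6 - 2.0 * sr6 * sr6) / r  # dU/dr
    s = switch_value(r, params.switch_start, params.cutoff)
    ds = switch_derivative(r, params.switch_start, params.cutoff)
    energy = float(np.sum(u * s))
    dtot = du * s + u * ds
    fv = (-dtot / r)[:, None] * dr  # force on i
    _scatter_forces(forces, ii, jj, fv)
    return energy, forces


# ---------------------------------------------------------------------------
# Coulomb: switched cutoff

def coulomb_cutoff(state: SystemState, params: ForceFieldParams):
    """Switched-cutoff Coulomb energy and forces (minimum image)."""
    params.validate_against(state.box)
    forces = np.zeros_like(state.positions)
    idx = _charged_indices(state)
    if len(idx) < 2:
        return 0.0, forces
    a, b = np.triu_indices(len(idx), 1)
    ii, jj = _filter_excluded(state, idx[a], idx[b])
    dr, r2 = _pair_distances(state, ii, jj)
    within = r2 < params.cutoff ** 2
    ii, jj, dr, r2 = ii[within], jj[within], dr[within], r2[within]
    if len(ii) == 0:
        return 0.0, forces
    _check_overlap(r2)
    r = np.sqrt(r2)
    ke = params.coulomb_constant / params.relative_dielectric
    qq = state.charges[ii] * state.charges[jj]
    u = ke * qq / r
    s = switch_value(r, params.switch_start, params.cutoff)
    ds = switch_derivative(r, params.switch_start, params.cutoff)
    energy = float(np.sum(u * s))
    dtot = (-u / r) * s + u * ds
    fv = (-dtot / r)[:, None] * dr
    _scatter_forces(forces, ii, jj, fv)
    return energy, forces


# ---------------------------------------------------------------------------
# Coulomb: Ewald summation

def ewald_alpha(params: ForceFieldParams) -> float:
    """Splitting parameter: explicit override, else chosen so
    erfc(alpha r_c) ~ ewald_accuracy."""
    if params.ewald_alpha is not None:
        return params.ewald_alpha
    return np.sqrt(-np.log(params.ewald_accuracy)) / params.cutoff


def _kvectors(box_lengths: tuple, alpha: float, accuracy: float, cache: dict):
    key = ("kvecs", box_lengths, alpha, accuracy)
    if key in cache:
        return cache[key]
    kmax = 2.0 * alpha * np.sqrt(-np.log(accuracy))
    L = np.asarray(box_lengths)
    nmax = np.maximum(1, np.ceil(kmax * L / (2 * np.pi)).astype(int))
    nx = np.arange(0, nmax[0] + 1)
    ny = np.arange(-nmax[1], nmax[1] + 1)
    nz = np.arange(-nmax[2], nmax[2] + 1)
    grid = np.array(np.meshgrid(nx, ny, nz, indexing="ij")).reshape(3, -1).T
    # half space: nx>0, or nx=0 & ny>0, or nx=ny=0 & nz>0
    gx, gy, gz = grid[:, 0], grid[:, 1], grid[:, 2]
    half = (gx > 0) | ((gx == 0) & (gy > 0)) | ((gx == 0) & (gy == 0) & (gz > 0))
    grid = grid[half]
    kv = 2 * np.pi * grid / L
    k2 = np.einsum("ij,ij->i", kv, kv)
    keep = k2 <= kmax * kmax
    grid, kv, k2 = grid[keep], kv[keep], k2[keep]
    gfac = np.exp(-k2 / (4 * alpha * alpha)) / k2
    out = (kv, k2, gfac, grid)
    cache[key] = out
    return out


def _eik_matrix(positions: np.ndarray, grid: np.ndarray,
                box_lengths: np.ndarray) -> np.ndarray:
    """exp(i k . r) as an (N, K) matrix, built from per-dimension power
    tables so only O(N) complex exponentials are evaluated."""
    n = len(positions)
    if n == 0:
        return np.zeros((0, len(grid)), dtype=complex)
    base = np.exp(2j * np.pi * positions / np.asarray(box_lengths))  # (N, 3)
    out = None
    for d in range(3):
        nd = grid[:, d]
        nmax = int(np.abs(nd).max())
        powers = np.empty((nmax + 1, n), dtype=complex)
        powers[0] = 1.0
        for p in range(1, nmax + 1):
            powers[p] = powers[p - 1] * base[:, d]
        mat = powers[np.abs(nd)]          # (K, N)
        neg = nd < 0
        if neg.any():
            mat[neg] = np.conj(mat[neg])
        out = mat if out is None else out * mat
    return out.T


def coulomb_ewald(state: SystemState, params: ForceFieldParams,
                  neutralize_background: bool = False):
    """Plain Ewald Coulomb energy/forces for the periodic cell.

    Returns ``(EnergyBreakdown, forces)`` with real, reciprocal, self and
    (when requested) uniform-background components filled in.  A cell
    with nonzero net charge diverges unless ``neutralize_background`` is
    true, in which case the implicit-background correction
    ``-pi Q^2 k_e / (2 V alpha^2 eps_r)`` is added and reported.
    """
    params.validate_against(state.box)
    forces = np.zeros_like(state.positions)
    ke = params.coulomb_constant / params.relative_dielectric
    idx = _charged_indices(state)
    q = state.charges[idx]
    Q = float(q.sum())
    bd = EnergyBreakdown()
    if len(idx) == 0:
        return bd, forces
    if abs(Q) > 1e-9 and not neutralize_background:
        raise NonNeutralCellError(
            f"Ewald sum for a cell with net charge {Q:+.3f} e requires the "
            "implicit neutralizing background (neutralize_background=True)")
    alpha = ewald_alpha(params)

    # real space (within cutoff, minimum image)
    if len(idx) >= 2:
        a, b = np.triu_indices(len(idx), 1)
        ii, jj = _filter_excluded(state, idx[a], idx[b])
        dr, r2 = _pair_distances(state, ii, jj)
        within = r2 < params.cutoff ** 2
        ii, jj, dr, r2 = ii[within], jj[within], dr[within], r2[within]
        if len(ii):
            _check_overlap(r2)
            r = np.sqrt(r2)
            qq = state.charges[ii] * state.charges[jj]
            e_r = ke * qq * erfc(alpha * r) / r
            bd.coulomb_real = float(e_r.sum())
            # -dU/dr
            fmag = ke * qq * (erfc(alpha * r) / r2
                              + 2 * alpha / np.sqrt(np.pi) * np.exp(-alpha * alpha * r2) / r)
            fv = (fmag / r)[:, None] * dr
            _scatter_forces(forces, ii, jj, fv)

    # reciprocal space
    kv, k2, gfac, grid = _kvectors(tuple(state.box.lengths), alpha,
                                   params.ewald_accuracy, state._cache)
    eik = _eik_matrix(state.positions[idx], grid, state.box.lengths)
    S = q @ eik                              # (K,)
    V = state.box.volume
    pref = ke * 2 * np.pi / V
    bd.coulomb_reciprocal = float(2.0 * pref * np.sum(gfac * np.abs(S) ** 2))
    # forces: F_j = 2 * 2*pref * q_j sum_k gfac k Im(conj(S) e^{ik r_j})
    m = np.imag(np.conj(S)[None, :] * eik)   # (Nq, K)
    fk = (m * gfac[None, :]) @ kv            # (Nq, 3)
    forces[idx] += (2.0 * 2.0 * pref) * q[:, None] * fk

    # self energy
    bd.coulomb_self = float(-ke * alpha / np.sqrt(np.pi) * np.sum(q * q))

    # excluded-pair correction (bonded pairs are not meant to interact,
    # but the reciprocal sum includes them): subtract the erf part
    excl = _excluded_pairs(state)
    if excl:
        pairs = [(i, j) for i, j in excl
                 if state.charges[i] != 0 and state.charges[j] != 0
                 and not (state.nb_ghost[i] or state.nb_ghost[j])]
        if pairs:
            pi = np.array([p[0] for p in pairs])
            pj = np.array([p[1] for p in pairs])
            dr, r2 = _pair_distances(state, pi, pj)
            r = np.sqrt(r2)
            qq = state.charges[pi] * state.charges[pj]
            bd.coulomb_real += float(np.sum(-ke * qq * erf(alpha * r) / r))
            fmag = -ke * qq * (erf(alpha * r) / r2
                               - 2 * alpha / np.sqrt(np.pi) * np.exp(-alpha * alpha * r2) / r)
            fv = (fmag / r)[:, None] * dr
            _scatter_forces(forces, pi, pj, fv)

    # uniform-background correction for a charged cell
    if abs(Q) > 1e-9:
        bd.background_correction = float(
            -ke * np.pi * Q * Q / (2 * V * alpha * alpha))
    return bd, forces


# ---------------------------------------------------------------------------
# total

def total_energy_forces(state: SystemState, params: ForceFieldParams,
                        electrostatics: str = "pme",
                        neutralize_background: bool = True):
    """Full potential: bonded + LJ + Coulomb via the chosen backend.

    ``electrostatics`` is ``"pme"`` (Ewald summation) or ``"switch"``
    (switched cutoff), mirroring the run-configuration vocabulary.
    """
    eb, fb = bonded_energy_forces(state)
    el, fl = lj_energy_forces(state, params)
    bd = EnergyBreakdown(lj=el, bonded=eb)
    forces = fb + fl
    if electrostatics == "pme":
        bc, fc = coulomb_ewald(state, params, neutralize_background)
        bd = bd + bc
        forces += fc
    elif electrostatics == "switch":
        ec, fc = coulomb_cutoff(state, params)
        bd.coulomb_real = ec
        forces += fc
    else:
        raise ValueError(f"unknown electrostatics backend {electrostatics!r}")
    return bd, forces


# ---------------------------------------------------------------------------
# incremental site-charging energy (for nonequilibrium work accumulation)

def site_charge_coeffs(state: SystemState, params: ForceFieldParams,
                       bead_index: int, electrostatics: str = "pme",
                       neutralize_background: bool = True):
    """Coefficients (a, b) such that the Coulomb energy as a function of the
    charge q on ``bead_index`` is ``a q^2 + b q + const`` at fixed
    coordinates.  Lets a lambda increment's energy change be computed in
    O(N + K) instead of a full re-summation; validated against full
    energy differences in the test suite.
    """
    if state.nb_ghost[bead_index]:
        return 0.0, 0.0
    ke = params.coulomb_constant / params.relative_dielectric
    others = _charged_indices(state)
    others = others[others != bead_index]
    dr = state.positions[others] - state.positions[bead_index]
    dr = state.box.minimum_image(dr)
    r = np.sqrt(np.einsum("ij,ij->i", dr, dr))
    qo = state.charges[others]
    excl = _excluded_pairs(state)
    excl_with = {j for i, j in excl if i == bead_index} | \
                {i for i, j in excl if j == bead_index}
    not_excl = np.array([j not in excl_with for j in others], dtype=bool) \
        if len(others) else np.zeros(0, dtype=bool)

    if electrostatics == "switch":
        within = (r < params.cutoff) & not_excl
        s = switch_value(r[within], params.switch_start, params.cutoff)
        b = float(np.sum(ke * qo[within] * s / r[within]))
        return 0.0, b

    alpha = ewald_alpha(params)
    # real space + exclusion correction
    within = (r < params.cutoff) & not_excl
    b = float(np.sum(ke * qo[within] * erfc(alpha * r[within]) / r[within]))
    exc = ~not_excl
    if exc.any():
        b += float(np.sum(-ke * qo[exc] * erf(alpha * r[exc]) / r[exc]))
    # reciprocal: |S|^2 = |S_o|^2 + 2 q Re(conj(S_o) e^{ik r_i}) + q^2
    kv, k2, gfac, grid = _kvectors(tuple(state.box.lengths), alpha,
                                   params.ewald_accuracy, state._cache)
    V = state.box.volume
    pref = 2.0 * ke * 2 * np.pi / V  # half-space factor 2 included
    eik_i = _eik_matrix(state.positions[bead_index][None, :], grid,
                        state.box.lengths)[0]
    if len(others):
        S_o = state.charges[others] @ _eik_matrix(
            state.positions[others], grid, state.box.lengths)
    else:
        S_o = np.zeros(len(kv), dtype=complex)
    b += float(pref * np.sum(gfac * 2.0 * np.real(np.conj(S_o) * eik_i)))
    a = float(pref * np.sum(gfac))
    # self
    a += -ke * alpha / np.sqrt(np.pi)
    # background
    if neutralize_background:
        Q_o = float(state.charges[others].sum())
        c_bg = -ke * np.pi / (2 * V * alpha * alpha)
        a += c_bg
        b += 2.0 * c_bg * Q_o
    return a, b


def charge_increment_energy(state: SystemState, params: ForceFieldParams,
                            bead_index: int, q_old: float, q_new: float,
                            electrostatics: str = "pme",
                            neutralize_background: bool = True) -> float:
    """Energy change of setting bead ``bead_index``'s charge q_old -> q_new
    at fixed coordinates."""
    a, b = site_charge_coeffs(state, params, bead_index, electrostatics,
                              neutralize_background)
    return a * (q_new ** 2 - q_old ** 2) + b * (q_new - q_old)
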