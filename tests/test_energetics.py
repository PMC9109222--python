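"""Energy and force contracts: closed forms, brute-force oracles, the
Madelung lattice sum, and gradient/invariance properties."""

import numpy as np
import pytest

from cgcph.energetics import (EnergyBreakdown, NonNeutralCellError,
                              OverlapError, charge_increment_energy,
                              coulomb_cutoff, coulomb_ewald, lj_energy_forces,
                              switch_value, total_energy_forces)
from cgcph.fixtures import FixtureSpec, build
from cgcph.model import KE, ForceFieldParams

from conftest import bare_state


def wide_params(cutoff, switch_start, eps_r=15.0, accuracy=1e-6):
    return ForceFieldParams(cutoff=cutoff, switch_start=switch_start,
                            relative_dielectric=eps_r,
                            ewald_accuracy=accuracy)


# ---------------------------------------------------------------------------
# Lennard-Jones

class TestLennardJones:
    def params(self):
        return wide_params(cutoff=2.0, switch_start=1.8)

    def pair_at(self, r, epsilon=1.0):
        return bare_state([[0, 0, 0], [r, 0, 0]], [0, 0], 6.0,
                          epsilon=epsilon)

    def test_zero_crossing_at_sigma(self):
        e, _ = lj_energy_forces(self.pair_at(0.47), self.params())
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth_at_two_to_one_sixth_sigma(self):
        e, _ = lj_energy_forces(self.pair_at(0.47 * 2 ** (1 / 6), 2.5),
                                self.params())
        assert e == pytest.approx(-2.5, rel=1e-12)

    def test_many_bead_energy_matches_brute_force_pair_sum(self):
        rng = np.random.default_rng(11)
        pos = rng.uniform(1.5, 4.5, (7, 3))
        state = bare_state(pos, np.zeros(7), 10.0, epsilon=1.3)
        params = self.params()
        e, _ = lj_energy_forces(state, params)
        # independent brute-force loop over pairs (minimum image by hand)
        expected = 0.0
        for i in range(7):
            for j in range(i + 1, 7):
                d = pos[i] - pos[j]
                d -= 10.0 * np.round(d / 10.0)
                r = np.linalg.norm(d)
                if r >= params.cutoff:
                    continue
                sr6 = (0.47 / r) ** 6
                u = 4 * 1.3 * (sr6 ** 2 - sr6)
                if r > params.switch_start:
                    x = (r - params.switch_start) / (params.cutoff
                                                     - params.switch_start)
                    u *= 1 - 3 * x ** 2 + 2 * x ** 3
                expected += u
        assert e == pytest.approx(expected, rel=1e-10)

    def test_overlapping_beads_raise(self):
        with pytest.raises(OverlapError):
            lj_energy_forces(self.pair_at(1e-8), self.params())

    def test_switch_function_is_continuous_at_both_ends(self):
        r = np.array([1.8 - 1e-9, 1.8 + 1e-9, 2.0 - 1e-9])
        s = switch_value(r, 1.8, 2.0)
        assert s[0] == pytest.approx(1.0, abs=1e-8)
        assert s[1] == pytest.approx(1.0, abs=1e-8)
        assert s[2] == pytest.approx(0.0, abs=1e-8)


# ---------------------------------------------------------------------------
# switched-cutoff Coulomb

class TestCoulombCutoff:
    def test_unit_charge_pair_closed_form(self):
        state = bare_state([[0, 0, 0], [1.0, 0, 0]], [1.0, -1.0], 6.0)
        params = wide_params(cutoff=1.4, switch_start=1.1)
        e, _ = coulomb_cutoff(state, params)
        assert e == pytest.approx(-KE / 15.0, rel=1e-12)

    def test_pair_beyond_cutoff_is_exactly_zero(self):
        state = bare_state([[0, 0, 0], [2.0, 0, 0]], [1.0, -1.0], 6.0)
        e, _ = coulomb_cutoff(state, wide_params(1.4, 1.1))
        assert e == 0.0

    def test_random_charges_match_brute_force_pair_sum(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 8, (9, 3))
        q = rng.choice([-1.0, 0.0, 1.0], 9)
        state = bare_state(pos, q, 8.0)
        params = wide_params(cutoff=3.0, switch_start=2.0)
        e, _ = coulomb_cutoff(state, params)
        expected = 0.0
        for i in range(9):
            for j in range(i + 1, 9):
                d = pos[i] - pos[j]
                d -= 8.0 * np.round(d / 8.0)
                r = np.linalg.norm(d)
                if r >= 3.0 or q[i] * q[j] == 0:
                    continue
                x = max(0.0, (r - 2.0) / 1.0)
                s = 1 - 3 * x ** 2 + 2 * x ** 3
                expected += KE * q[i] * q[j] / (15.0 * r) * s
        assert e == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# Ewald

def evjen_madelung(n_shells=8):
    """Independent Madelung-constant oracle: Evjen-weighted direct lattice
    sum over expanding shells of the rock-salt lattice."""
    n = n_shells
    idx = np.arange(-n, n + 1)
    ii, jj, kk = np.meshgrid(idx, idx, idx, indexing="ij")
    r = np.sqrt(ii ** 2 + jj ** 2 + kk ** 2).astype(float)
    sign = (-1.0) ** (np.abs(ii) + np.abs(jj) + np.abs(kk))
    w = np.ones_like(r)
    for a in (ii, jj, kk):
        w *= np.where(np.abs(a) == n, 0.5, 1.0)
    mask = r > 0
    return -np.sum(sign[mask] * w[mask] / r[mask])


class TestEwald:
    def test_rock_salt_energy_reproduces_madelung_sum(self):
        lattice = build(FixtureSpec(kind="ionic_lattice", n_molecules=2,
                                    lattice_spacing=0.5))
        params = ForceFieldParams(cutoff=0.45, switch_start=0.3,
                                  relative_dielectric=1.0,
                                  ewald_accuracy=1e-8)
        bd, _ = coulomb_ewald(lattice, params)
        m = evjen_madelung()
        expected = -8 * m * KE / (2 * 0.5)
        assert bd.total == pytest.approx(expected, rel=1e-3)
        assert bd.total == pytest.approx(expected, rel=2e-4)

    def test_energy_scales_inversely_with_lattice_constant(self):
        energies = []
        for d in (0.5, 1.0):
            lattice = build(FixtureSpec(kind="ionic_lattice", n_molecules=2,
                                        lattice_spacing=d))
            params = ForceFieldParams(cutoff=0.9 * d, switch_start=0.6 * d,
                                      relative_dielectric=1.0,
                                      ewald_accuracy=1e-8)
            bd, _ = coulomb_ewald(lattice, params)
            energies.append(bd.total)
        assert energies[0] == pytest.approx(2 * energies[1], rel=1e-6)

    def test_neutral_random_system_matches_large_cutoff_limit(self):
        rng = np.random.default_rng(5)
        pos = 10.0 + rng.uniform(0, 2.0, (8, 3))  # cluster in a 24 nm box
        q = np.array([1.0, -1.0] * 4)
        state = bare_state(pos, q, 24.0)
        params_ewald = wide_params(cutoff=9.0, switch_start=8.0,
                                   accuracy=1e-7)
        bd, _ = coulomb_ewald(state, params_ewald)
        e_cut, _ = coulomb_cutoff(state, wide_params(cutoff=9.0,
                                                     switch_start=8.9))
        assert bd.total == pytest.approx(e_cut, rel=1e-2)

    def test_charged_cell_needs_background(self):
        state = bare_state([[2.0, 2.0, 2.0]], [1.0], 4.0)
        params = wide_params(cutoff=1.5, switch_start=1.0)
        bd, _ = coulomb_ewald(state, params, neutralize_background=True)
        assert np.isfinite(bd.total)
        assert bd.background_correction != 0.0
        with pytest.raises(NonNeutralCellError):
            coulomb_ewald(state, params, neutralize_background=False)

    def test_energy_invariant_under_integer_lattice_translation(
            self, small_micelle, small_micelle_params):
        state = small_micelle
        state.set_site_state(0, True)
        state.set_site_state(1, True)
        bd0, _ = coulomb_ewald(state, small_micelle_params, True)
        shifted = state.copy()
        shifted.positions += state.box.lengths * np.array([1.0, -2.0, 3.0])
        shifted.positions[:] = shifted.box.wrap(shifted.positions)
        bd1, _ = coulomb_ewald(shifted, small_micelle_params, True)
        assert bd1.total == pytest.approx(bd0.total, rel=1e-6)

    def test_energy_independent_of_splitting_parameter(self, small_micelle):
        state = small_micelle  # 8 deprotonated heads: charged system
        totals = []
        for alpha in (3.0, 6.0):  # 2x range; truncations kept converged
            params = ForceFieldParams(cutoff=1.2, switch_start=0.9,
                                      ewald_accuracy=1e-10,
                                      ewald_alpha=alpha)
            bd, _ = coulomb_ewald(state, params, True)
            totals.append(bd.total)
        assert totals[0] == pytest.approx(totals[1], rel=1e-5)

    def test_breakdown_total_is_sum_of_components(self, small_micelle,
                                                  small_micelle_params):
        bd, _ = total_energy_forces(small_micelle, small_micelle_params,
                                    "pme")
        parts = (bd.lj + bd.coulomb_real + bd.coulomb_reciprocal
                 + bd.coulomb_self + bd.background_correction + bd.bonded)
        assert bd.total == pytest.approx(parts, rel=1e-12)


# ---------------------------------------------------------------------------
# gradients and incremental charging

class TestForceConsistency:
    @pytest.mark.parametrize("electro", ["pme", "switch"])
    def test_forces_are_negative_gradient(self, small_micelle,
                                          small_micelle_params, electro):
        state = small_micelle
        _, forces = total_energy_forces(state, small_micelle_params, electro)
        h = 1e-5
        rng = np.random.default_rng(2)
        for bead in rng.choice(state.n_beads, 4, replace=False):
            for d in range(3):
                state.positions[bead, d] += h
                ep, _ = total_energy_forces(state, small_micelle_params,
                                            electro)
                state.positions[bead, d] -= 2 * h
                em, _ = total_energy_forces(state, small_micelle_params,
                                            electro)
                state.positions[bead, d] += h
                fd = -(ep.total - em.total) / (2 * h)
                scale = max(1.0, abs(forces[bead, d]))
                assert abs(fd - forces[bead, d]) / scale < 1e-4

    @pytest.mark.parametrize("electro", ["pme", "switch"])
    def test_charge_increment_matches_full_energy_difference(
            self, small_micelle, small_micelle_params, electro):
        state = small_micelle
        bead = state.sites[0].bead_index

        def coulomb(st):
            if electro == "pme":
                bd, _ = coulomb_ewald(st, small_micelle_params, True)
                return bd.total
            e, _ = coulomb_cutoff(st, small_micelle_params)
            return e

        du = charge_increment_energy(state, small_micelle_params, bead,
                                     -1.0, -0.25, electro)
        after = state.copy()
        after.charges[bead] = -0.25
        assert du == pytest.approx(coulomb(after) - coulomb(state),
                                   rel=1e-9, abs=1e-9)
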