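"""Constant-pH engine contracts: Hill-equation gate, Metropolis switch
acceptance, state restoration, stochastic charge neutralization and the
cycle loop invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgcph.cphmd import (CpHConfig, NeutralizationError, attempt_switch,
                         deprotonation_likelihood, neutralize_charge,
                         preswitch, run_cphmd)
from cgcph.dynamics import Thermostat
from cgcph.energetics import coulomb_ewald
from cgcph.fixtures import FixtureSpec, build, toy_params
from cgcph.model import SwitchProtocol, TitratableSite, net_charge

from conftest import bare_state


class TestDeprotonationLikelihood:
    @pytest.mark.parametrize("ph,pka,n,expected", [
        (5.0, 5.0, 1.0, 0.5),
        (7.3, 7.3, 0.4, 0.5),
        (5.73, 4.73, 1.0, 10.0 / 11.0),
        (2.73, 4.73, 1.0, 1.0 / 101.0),
    ])
    def test_closed_form_values(self, ph, pka, n, expected):
        assert deprotonation_likelihood(ph, pka, n) == pytest.approx(expected)

    @given(ph=st.floats(-2, 16), pka=st.floats(0, 14),
           n=st.floats(0.1, 3.0))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_ph_and_bounded(self, ph, pka, n):
        s = deprotonation_likelihood(ph, pka, n)
        assert 0.0 <= s <= 1.0
        assert deprotonation_likelihood(ph + 0.5, pka, n) >= s

    def test_rejects_nonpositive_hill_coefficient(self):
        with pytest.raises(ValueError):
            deprotonation_likelihood(7.0, 7.0, 0.0)


def make_site(deprotonated=False, pka=4.73):
    return TitratableSite(bead_index=0, charge_protonated=0.0,
                          charge_deprotonated=-1.0, pka_ref=pka,
                          deprotonated=deprotonated)


class TestPreswitch:
    def test_strongly_basic_ph_always_deprotonates(self):
        rng = np.random.default_rng(0)
        site = make_site(deprotonated=False)
        assert all(preswitch(site, 12.0, rng) for _ in range(50))

    def test_at_pka_both_directions_always_accepted(self):
        rng = np.random.default_rng(1)
        assert all(preswitch(make_site(False), 4.73, rng) for _ in range(30))
        assert all(preswitch(make_site(True), 4.73, rng) for _ in range(30))

    def test_deprotonation_one_unit_below_pka_accepted_at_one_tenth(self):
        rng = np.random.default_rng(2)
        site = make_site(deprotonated=False)
        n_trials = 4000
        hits = sum(preswitch(site, 3.73, rng) for _ in range(n_trials))
        rate = hits / n_trials
        se = np.sqrt(0.1 * 0.9 / n_trials)
        assert abs(rate - 0.1) < 3 * se


class TestAttemptSwitch:
    def setup_run(self, two_step=True, ph=4.73, seed=0):
        state = build(FixtureSpec(kind="fa_solution", n_molecules=1,
                                  box_lengths=(2.0, 2.0, 2.0), seed=6))
        params = toy_params(cutoff=0.9, switch_start=0.7,
                            ewald_accuracy=1e-3)
        from cgcph.dynamics import minimize_energy
        minimize_energy(state, params, 30, electrostatics="switch")
        config = CpHConfig(ph=ph, cycle_md_steps=2,
                           protocol=SwitchProtocol(n_steps=3, two_step=two_step),
                           neutralize=False, seed=seed,
                           electrostatics="switch")
        thermo = Thermostat(temperature=300.0, friction=2.0, dt=0.02)
        return state, config, params, thermo

    def test_rejection_restores_state_exactly(self):
        # full switch with a hopeless pH bias: rejection is certain
        state, config, params, thermo = self.setup_run(two_step=False,
                                                       ph=-20.0)
        state.set_site_state(0, deprotonated=False)
        snap_pos = state.positions.copy()
        snap_vel = state.velocities.copy()
        snap_q = state.charges.copy()
        result, log = attempt_switch(state, 0, config, params, thermo)
        assert not log.accepted
        assert np.array_equal(result.positions, snap_pos)
        assert np.array_equal(result.velocities, snap_vel)
        assert np.array_equal(result.charges, snap_q)
        assert not result.sites[0].deprotonated

    def test_extreme_acid_ph_keeps_site_protonated(self):
        state, config, params, thermo = self.setup_run(two_step=True,
                                                       ph=-30.0)
        for cycle in range(25):
            state, log = attempt_switch(state, 0, config, params, thermo,
                                        cycle)
            assert not state.sites[0].deprotonated

    def test_accepted_implies_preswitch_passed(self):
        state, config, params, thermo = self.setup_run(two_step=True, ph=6.0)
        for cycle in range(20):
            state, log = attempt_switch(state, 0, config, params, thermo,
                                        cycle)
            assert log.preswitch_pass or not log.accepted


class TestNeutralizeCharge:
    def water_bath(self, solute_q, water_q, seed=0):
        n_w = len(water_q)
        positions = np.concatenate([[[0.5, 0.5, 0.5]],
                                    np.random.default_rng(seed).uniform(
                                        1.0, 3.5, (n_w, 3))])
        charges = np.concatenate([[solute_q], water_q])
        return bare_state(positions, charges, 4.0,
                          is_water=[False] + [True] * n_w, seed=seed)

    def test_neutral_state_with_no_charged_waters_unchanged(self):
        state = self.water_bath(0.0, np.zeros(6))
        before = state.charges.copy()
        neutralize_charge(state)
        assert np.array_equal(state.charges, before)

    def test_two_fresh_carboxylates_get_two_positive_waters(self):
        state = self.water_bath(-2.0, np.zeros(8))
        neutralize_charge(state)
        assert net_charge(state) == 0
        wq = state.charges[state.is_water]
        assert np.count_nonzero(wq) == 2
        assert set(wq[wq != 0]) == {1.0}

    def test_opposite_charged_waters_all_reverted_when_neutral(self):
        state = self.water_bath(0.0, np.array([1.0, 1.0, -1.0, -1.0, 0, 0]))
        neutralize_charge(state)
        assert net_charge(state) == 0
        assert np.count_nonzero(state.charges[state.is_water]) == 0

    @given(solute=st.integers(-4, 4),
           plus=st.integers(0, 3), minus=st.integers(0, 3))
    @settings(max_examples=40, deadline=None)
    def test_charged_water_count_is_minimal_and_cell_neutral(self, solute,
                                                             plus, minus):
        water_q = np.concatenate([np.ones(plus), -np.ones(minus),
                                  np.zeros(8)])
        state = self.water_bath(float(solute), water_q, seed=1)
        neutralize_charge(state)
        assert net_charge(state) == 0
        assert np.count_nonzero(state.charges[state.is_water]) == abs(solute)

    def test_error_when_waters_cannot_absorb_imbalance(self):
        state = self.water_bath(-5.0, np.zeros(2))
        with pytest.raises(NeutralizationError):
            neutralize_charge(state)


class TestRunCphmd:
    def micelle_run(self, neutralize, electro="switch", n_cycles=30,
                    seed=3):
        state = build(FixtureSpec(kind="micelle", n_molecules=8,
                                  box_lengths=(3.0, 3.0, 3.0), seed=4))
        params = toy_params(ewald_accuracy=1e-3)
        from cgcph.dynamics import minimize_energy
        minimize_energy(state, params, 40, electrostatics="switch")
        config = CpHConfig(ph=6.0, cycle_md_steps=2,
                           protocol=SwitchProtocol(n_steps=2),
                           neutralize=neutralize, seed=seed,
                           electrostatics=electro)
        thermo = Thermostat(temperature=300.0, friction=2.0, dt=0.02)
        return run_cphmd(state, config, params, thermo, n_cycles)

    def test_zero_cycles_returns_empty_record_and_same_configuration(
            self, single_site_state, water_box_params, thermostat):
        config = CpHConfig(ph=7.0, cycle_md_steps=2,
                           protocol=SwitchProtocol(n_steps=2), seed=0)
        final, record, logs = run_cphmd(single_site_state, config,
                                        water_box_params, thermostat, 0)
        assert record.n_frames == 0 and logs == []
        assert np.array_equal(final.positions, single_site_state.positions)

    def test_constant_charge_mode_is_neutral_after_every_cycle(self):
        _, record, logs = self.micelle_run(neutralize=True, n_cycles=40)
        assert all(log.net_charge_after == 0 for log in logs)

    def test_fluctuating_ewald_run_reports_background_artifact(self):
        final, record, logs = self.micelle_run(neutralize=False,
                                               electro="pme", n_cycles=10)
        assert net_charge(final) != 0
        params = toy_params(ewald_accuracy=1e-3)
        bd, _ = coulomb_ewald(final, params, neutralize_background=True)
        assert bd.background_correction != 0.0

    def test_same_seed_reproduces_cycle_log_exactly(self):
        logs_a = self.micelle_run(neutralize=True, n_cycles=15, seed=9)[2]
        logs_b = self.micelle_run(neutralize=True, n_cycles=15, seed=9)[2]
        assert [(l.site_index, l.accepted, l.work_w) for l in logs_a] == \
               [(l.site_index, l.accepted, l.work_w) for l in logs_b]

    def test_noninteracting_site_tracks_hill_law(self, single_site_state,
                                                 water_box_params,
                                                 thermostat):
        """Quick detailed-balance check at two pH values (the full 8-point
        chi-squared version runs in the acceptance suite)."""
        from cgcph.cphmd import deprotonation_likelihood
        for ph, seed in ((4.73, 1), (5.73, 2)):
            config = CpHConfig(ph=ph, cycle_md_steps=2,
                               protocol=SwitchProtocol(n_steps=2), seed=seed,
                               electrostatics="switch")
            _, record, _ = run_cphmd(single_site_state, config,
                                     water_box_params, thermostat, 600)
            frac = record.deprotonated_fraction[100:].mean()
            s = deprotonation_likelihood(ph, 4.73)
            # binary series with fast mixing: conservative se
            se = np.sqrt(s * (1 - s) / 120)
            assert abs(frac - s) < 4 * se
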