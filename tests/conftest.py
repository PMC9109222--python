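"""Shared fixtures: small toy systems built fresh per test."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cgcph.fixtures import FixtureSpec, build, toy_params
from cgcph.dynamics import Thermostat, minimize_energy
from cgcph.model import (ForceFieldParams, SimulationBox, SystemState,
                         TitratableSite)


@pytest.fixture
def water_box_params():
    """Parameters sized for the 1.6 nm single-site box."""
    return toy_params(cutoff=0.7, switch_start=0.5, ewald_accuracy=1e-3)


@pytest.fixture
def single_site_state(water_box_params):
    state = build(FixtureSpec(kind="single_site", coupling=0.0, seed=3))
    minimize_energy(state, water_box_params, 30, electrostatics="switch")
    return state


@pytest.fixture
def small_micelle_params():
    return toy_params(cutoff=1.2, switch_start=0.9, ewald_accuracy=1e-4)


@pytest.fixture
def small_micelle(small_micelle_params):
    state = build(FixtureSpec(kind="micelle", n_molecules=8,
                              box_lengths=(3.0, 3.0, 3.0), seed=4))
    minimize_energy(state, small_micelle_params, 40, electrostatics="switch")
    return state


@pytest.fixture
def thermostat():
    return Thermostat(temperature=300.0, friction=2.0, dt=0.02)


def bare_state(positions, charges, box_length, *, sigma=0.47, epsilon=0.0,
               mass=72.0, bonds=(), bond_r0=0.47, bond_k=1250.0,
               sites=(), is_water=None, seed=0, type_names=None,
               nb_ghost=None):
    """Hand-rolled minimal SystemState for closed-form checks."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    charges = np.asarray(charges, dtype=float)
    bonds = np.asarray(bonds, dtype=int).reshape(-1, 2)
    return SystemState(
        positions=positions,
        velocities=np.zeros((n, 3)),
        charges=charges,
        masses=np.full(n, mass),
        lj_sigma=np.full(n, sigma),
        lj_epsilon=np.full(n, epsilon),
        type_names=list(type_names) if type_names else ["X"] * n,
        is_water=(np.zeros(n, bool) if is_water is None
                  else np.asarray(is_water, bool)),
        mol_ids=np.arange(n),
        sites=list(sites),
        box=SimulationBox(np.array([box_length] * 3, dtype=float)),
        bond_indices=bonds,
        bond_r0=np.full(len(bonds), bond_r0),
        bond_k=np.full(len(bonds), bond_k),
        nb_ghost=nb_ghost,
        rng=np.random.default_rng(seed))
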