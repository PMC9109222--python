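"""Canonical validation studies at desk scale.

These functions pin the study conditions — fixture geometry, pH grids,
cycle counts, switch protocol and analysis windowing — for the
validation runs the package is judged by: the dispersed-site gold
titration (Hill law recovered exactly by construction), the
single-molecule titration, the 30-mer micelle comparisons and the
charge-neutrality run.  Problem sizes are toy scale by design: boxes of
1.6-4 nm, hundreds of beads, and switch protocols of a few steps; the
methods note discusses what that does and does not probe.
"""

from __future__ import annotations

import numpy as np

from .cphmd import CpHConfig, run_cphmd
from .dynamics import Thermostat, md_segment, minimize_energy
from .fixtures import OLEIC_PKA, FixtureSpec, build, toy_params
from .model import SwitchProtocol
from .titration import (TitrationRecord, fit_titration, select_window,
                        titrate, titration_table)

#: Reference pKa of the single-molecule (Fmoc-dipeptide-like) analogue.
SINGLE_MOLECULE_PKA = 3.61

#: The standard titration protocol grid.
GOLD_GRID = [4.0, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0]


def default_thermostat() -> Thermostat:
    return Thermostat(temperature=300.0, friction=2.0, dt=0.02)


def burn_in(records, fraction=0.3):
    """Drop the leading fraction of each record (protonation-state
    equilibration at toy scale, where the windowed-std criterion of the
    full-length protocol is not resolvable)."""
    out = []
    for r in records:
        k = int(fraction * r.n_frames)
        out.append(TitrationRecord(r.ph, r.times[k:], r.per_site_series[k:]))
    return out


def gold_titration(seed: int = 7, n_cycles: int = 2000):
    """Dispersed-in-water reference titration: a zero-coupling titratable
    site (reference pKa 4.73) titrated over the standard grid with Ewald
    electrostatics and constant charge.

    The site exchanges no work with its surroundings, so the engine's
    stationary occupancy must reproduce the Hill law with n = 1 — any
    deviation beyond sampling noise indicates an acceptance-rule defect.
    Returns ``(records, table, fit)``.
    """
    state = build(FixtureSpec(kind="single_site", coupling=0.0,
                              pka_ref=OLEIC_PKA, seed=3))
    params = toy_params(cutoff=0.7, switch_start=0.5, ewald_accuracy=1e-3)
    minimize_energy(state, params, 30, electrostatics="switch")
    thermo = default_thermostat()
    records = titrate(state, GOLD_GRID, params, thermo, n_cycles,
                      cycle_md_steps=3, protocol=SwitchProtocol(n_steps=3),
                      neutralize=True, electrostatics="pme", seed=seed)
    records = burn_in(records, 0.1)
    # earliest stable window over the remainder (a single site's occupancy
    # is Bernoulli, so the stability threshold is just above its ceiling)
    records = [select_window(r, 0.51, 0.75 * (r.times[-1] - r.times[0]))
               for r in records]
    table = titration_table(records)
    return records, table, fit_titration(table)


def single_molecule_titration(seed: int = 21, n_cycles: int = 2000):
    """Single isolated titratable molecule, two-step switch evaluation,
    pH grid bracketing the reference pKa by +-2 units.

    Run with fluctuating charge: in a desk-scale periodic cell a
    stochastic counterion would ion-pair with the lone site (a pure
    finite-size artifact); without it the engine's stationary law is the
    Hill equation with n = 1 at a constant, self-interaction-shifted
    apparent pKa.  Returns ``(records, table, fit)``.
    """
    state = build(FixtureSpec(kind="fa_solution", n_molecules=1,
                              box_lengths=(2.4, 2.4, 2.4),
                              pka_ref=SINGLE_MOLECULE_PKA, seed=5))
    params = toy_params(cutoff=1.0, switch_start=0.75, ewald_accuracy=1e-3)
    minimize_energy(state, params, 40, electrostatics="switch")
    grid = [round(SINGLE_MOLECULE_PKA - 2 + 0.5 * k, 2) for k in range(9)]
    records = titrate(state, grid, params, default_thermostat(), n_cycles,
                      cycle_md_steps=3,
                      protocol=SwitchProtocol(n_steps=5, two_step=True),
                      neutralize=False, electrostatics="pme", seed=seed)
    records = burn_in(records, 0.2)
    table = titration_table(records)
    return records, table, fit_titration(table)


def micelle_state(seed: int = 1):
    """Frozen 30-mer micelle study system: 4 nm box (a full solvation
    shell beyond the cutoff), fully deprotonated initial state."""
    state = build(FixtureSpec(kind="micelle", n_molecules=30,
                              box_lengths=(4.0, 4.0, 4.0),
                              pka_ref=OLEIC_PKA, seed=seed))
    params = toy_params(ewald_accuracy=3e-3)
    minimize_energy(state, params, 60, electrostatics="switch")
    return state, params


def micelle_titration(charge_mode: str = "constant", seed: int = 12,
                      n_cycles: int = 900, electrostatics: str = "pme"):
    """30-mer micelle titration over the standard grid, in constant- or
    fluctuating-charge mode under either electrostatics backend.
    Returns ``(table, fit)``."""
    state, params = micelle_state()
    records = titrate(state, GOLD_GRID, params, default_thermostat(),
                      n_cycles, cycle_md_steps=5,
                      protocol=SwitchProtocol(n_steps=3, two_step=True),
                      neutralize=(charge_mode == "constant"),
                      electrostatics=electrostatics, seed=seed)
    table = titration_table(burn_in(records, 0.3))
    return table, fit_titration(table)


def micelle_replicates(charge_mode: str = "constant", seeds=(12, 22, 32),
                       n_cycles: int = 700, electrostatics: str = "pme"):
    """Replicate micelle titrations with independent seeds.

    The micelle curves carry run-to-run variability beyond the per-fit
    covariance (counterion configurations are metastable on these
    trajectory lengths), so directional comparisons use the spread
    across replicates.  Returns a list of fits.
    """
    return [micelle_titration(charge_mode, seed=s, n_cycles=n_cycles,
                              electrostatics=electrostatics)[1]
            for s in seeds]


def neutrality_run(n_cycles: int = 10_000, seed: int = 8):
    """Long constant-charge cycle loop on a 30-mer micelle (switched
    cutoff electrostatics; the neutrality bookkeeping is backend
    independent).  Returns the cycle logs."""
    state = build(FixtureSpec(kind="micelle", n_molecules=30,
                              box_lengths=(3.0, 3.0, 3.0),
                              pka_ref=OLEIC_PKA, seed=2))
    params = toy_params(ewald_accuracy=1e-3)
    minimize_energy(state, params, 50, electrostatics="switch")
    config = CpHConfig(ph=6.0, cycle_md_steps=1,
                       protocol=SwitchProtocol(n_steps=1), neutralize=True,
                       seed=seed, electrostatics="switch")
    _, _, logs = run_cphmd(state, config, params, default_thermostat(),
                           n_cycles)
    return logs
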