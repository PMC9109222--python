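"""Langevin dynamics and nonequilibrium lambda-switch trajectories.

The propagator is BAOAB-split Langevin dynamics: a velocity half-kick
(B), a position half-drift (A), the exact Ornstein-Uhlenbeck velocity
update (O), the second half-drift (A) and a final half-kick (B) with
re-evaluated forces.  With the friction set to zero the O step is the
identity and the scheme reduces to velocity Verlet, which is what the
energy-conservation property test exercises.

A switch trajectory drives one titratable site's coupling parameter
lambda linearly from its current endpoint to the opposite one over
``protocol.n_steps`` MD steps.  Each step first applies the lambda
increment at fixed coordinates — accumulating the nonequilibrium work
``W += U(lambda + dlambda) - U(lambda)`` — and then advances the
dynamics by one thermostatted MD step, so the environment relaxes while
the charge is turned on or off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import KB, CgcphError, ForceFieldParams, SwitchProtocol, SystemState
from .energetics import charge_increment_energy, total_energy_forces

_FORCE_LIMIT = 1e7  # kJ/mol/nm; beyond this the integration has blown up


class IntegrationBlowupError(CgcphError):
    pass


@dataclass
class Thermostat:
    """Langevin thermostat settings (NVT)."""

    temperature: float = 300.0  # K
    friction: float = 1.0       # ps^-1
    dt: float = 0.02            # ps, formal
    seed: int | None = None     # optional: reseeds the state rng on entry

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")

    @property
    def kt(self) -> float:
        return KB * self.temperature


def _check_forces(forces: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(forces)) or np.abs(forces).max() > _FORCE_LIMIT:
        raise IntegrationBlowupError(
            f"force overflow at step {step}: max |F| = {np.abs(forces).max():.3e}")


def _baoab_step(state: SystemState, params: ForceFieldParams,
                thermostat: Thermostat, forces: np.ndarray,
                electrostatics: str, neutralize_background: bool,
                step: int) -> np.ndarray:
    """One BAOAB step in place; returns the forces at the new positions."""
    dt = thermostat.dt
    inv_m = 1.0 / state.masses[:, None]
    state.velocities += 0.5 * dt * forces * inv_m
    state.positions += 0.5 * dt * state.velocities
    if thermostat.friction > 0:
        c1 = np.exp(-thermostat.friction * dt)
        sigma = np.sqrt(thermostat.kt / state.masses[:, None] * (1.0 - c1 * c1))
        noise = state.rng.standard_normal(state.velocities.shape)
        state.velocities = c1 * state.velocities + sigma * noise
    state.positions += 0.5 * dt * state.velocities
    state.positions[:] = state.box.wrap(state.positions)
    _, forces = total_energy_forces(state, params, electrostatics,
                                    neutralize_background)
    _check_forces(forces, step)
    state.velocities += 0.5 * dt * forces * inv_m
    state.time_formal += dt * 1e-3  # ps -> ns
    return forces


def minimize_energy(state: SystemState, params: ForceFieldParams,
                    n_steps: int = 50, max_displacement: float = 0.02,
                    electrostatics: str = "pme",
                    neutralize_background: bool = True) -> SystemState:
    """Displacement-capped steepest descent to relax hot starting
    configurations before dynamics.  Mutates and returns ``state``."""
    for _ in range(n_steps):
        _, forces = total_energy_forces(state, params, electrostatics,
                                        neutralize_background)
        fmax = np.abs(forces).max()
        if fmax < 10.0:  # kJ/mol/nm; already relaxed
            break
        step = min(max_displacement / fmax, 1e-4)
        state.positions += step * forces
        state.positions[:] = state.box.wrap(state.positions)
    return state


def md_segment(state: SystemState, params: ForceFieldParams,
               thermostat: Thermostat, n_steps: int,
               electrostatics: str = "pme",
               neutralize_background: bool = True) -> SystemState:
    """Advance the state by ``n_steps`` of equilibrium Langevin dynamics.

    Mutates and returns ``state``.  Charges and protonation flags are
    untouched; positions are wrapped into the periodic box; the random
    stream advances deterministically from the state rng (or from
    ``thermostat.seed`` when set).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if thermostat.seed is not None:
        state.rng = np.random.default_rng(thermostat.seed)
    if n_steps == 0:
        return state
    _, forces = total_energy_forces(state, params, electrostatics,
                                    neutralize_background)
    _check_forces(forces, 0)
    for step in range(n_steps):
        forces = _baoab_step(state, params, thermostat, forces,
                             electrostatics, neutralize_background, step)
    return state


def switch_trajectory(state: SystemState, site_index: int,
                      protocol: SwitchProtocol, params: ForceFieldParams,
                      thermostat: Thermostat, electrostatics: str = "pme",
                      neutralize_background: bool = True
                      ) -> tuple[SystemState, float]:
    """Drive one site to its opposite protonation endpoint; return the
    candidate state and the accumulated nonequilibrium work W (kJ/mol).

    The input state is not modified; the candidate is a copy whose site
    flag, lambda and charge are at the opposite endpoint.  The work is
    the sum over steps of the fixed-coordinate energy change caused by
    each lambda increment (the energy-difference convention of
    nonequilibrium candidate-switch schemes).
    """
    lam0 = float(state.lambda_coupling[site_index])
    if lam0 not in (0.0, 1.0):
        raise ValueError("switch must start from a lambda endpoint")
    cand = state.copy()
    site = cand.sites[site_index]
    lam1 = 1.0 - lam0
    n = protocol.n_steps
    dlam = (lam1 - lam0) / n
    thermo = Thermostat(temperature=thermostat.temperature,
                        friction=thermostat.friction, dt=protocol.dt)
    work = 0.0
    lam = lam0

    def increment(lam_new: float) -> float:
        nonlocal work, lam
        q_old = site.charge_at(lam)
        q_new = site.charge_at(lam_new)
        changed = q_new != q_old
        if changed:
            work += charge_increment_energy(
                cand, params, site.bead_index, q_old, q_new,
                electrostatics, neutralize_background)
        cand.lambda_coupling[site_index] = lam_new
        cand.charges[site.bead_index] = q_new
        lam = lam_new
        return changed

    # time-symmetric (Strang) schedule: half-increment, then n MD steps
    # with full increments in between, closing with a half-increment —
    # the mirror image of the protocol is the protocol itself, which the
    # Metropolis acceptance on W presumes
    increment(lam0 + 0.5 * dlam)
    _, forces = total_energy_forces(cand, params, electrostatics,
                                    neutralize_background)
    _check_forces(forces, 0)
    for step in range(n):
        forces = _baoab_step(cand, params, thermo, forces,
                             electrostatics, neutralize_background, step)
        last = step == n - 1
        changed = increment(lam + (0.5 if last else 1.0) * dlam)
        if changed and not last and not cand.nb_ghost[site.bead_index]:
            # forces must see the new charge before the next half-kick
            _, forces = total_energy_forces(cand, params, electrostatics,
                                            neutralize_background)
    cand.set_site_state(site_index, deprotonated=(lam1 == 1.0))
    return cand, work
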