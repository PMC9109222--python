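"""The constant-pH engine: cycle scheduling, two-step switch evaluation
and stochastic charge neutralization.

Each cycle runs a stretch of equilibrium coarse-grained MD, then picks
one titratable site uniformly at random and attempts a protonation-state
change through a nonequilibrium lambda-switch trajectory accepted by a
Metropolis criterion.  With the two-step evaluation enabled, a cheap
preswitch gate — Metropolis sampling of the Hill-equation occupancy at
the site's reference pKa — filters attempts before the expensive switch
trajectory is paid for, and the full switch is then accepted with
``min(1, exp(-W/kT))``.  With the preswitch disabled (the escalated
protocol used to resolve large apparent-pKa shifts) the pH bias moves
into the full-switch acceptance, ``min(1, exp(-W/kT) * 10^{s(pH-pKa)})``
with ``s = +1`` for deprotonation and ``-1`` for protonation.  The two
modes sample the same stationary ensemble; for a site with no
environment coupling that ensemble is the Hill law with n = 1, which is
the engine's gold validation test.

After every cycle the stochastic charge neutralizer may rewrite water
bead charges so the periodic cell stays exactly neutral with the
minimum possible number of charged waters — the +1 water bead standing
in for an Eigen cation (H9O4+), the -1 water for a hydrated hydroxide —
without inserting beads, adding bonds or touching coordinates.  Keeping
the cell neutral is what makes Ewald electrostatics artifact-free: a
net-charged cell is only finite through an implicit uniform background
charge whose energy the energetics module reports separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (CgcphError, ForceFieldParams, SwitchProtocol, SystemState,
                    net_charge)
from .dynamics import Thermostat, md_segment, switch_trajectory

_LN10 = np.log(10.0)


class NeutralizationError(CgcphError):
    pass


@dataclass
class CpHConfig:
    """Settings for one constant-pH run at a single pH."""

    ph: float
    cycle_md_steps: int = 10
    protocol: SwitchProtocol = field(default_factory=SwitchProtocol)
    neutralize: bool = True          # "constant" (True) vs "fluctuating" charge
    seed: int = 0
    electrostatics: str = "pme"      # "pme" | "switch"
    redraw_velocities_on_reject: bool = False

    def __post_init__(self) -> None:
        if self.cycle_md_steps < 1:
            raise ValueError("cycle_md_steps must be >= 1")
        if self.electrostatics not in ("pme", "switch"):
            raise ValueError("electrostatics must be 'pme' or 'switch'")

    @property
    def charge_mode(self) -> str:
        return "constant" if self.neutralize else "fluctuating"


@dataclass
class CycleLog:
    """One cycle's bookkeeping record."""

    cycle_index: int
    site_index: int
    preswitch_pass: bool
    work_w: float
    accepted: bool
    net_charge_before: float
    net_charge_after: float
    n_charged_waters: int

    def as_tsv(self) -> str:
        return "\t".join(str(v) for v in (
            self.cycle_index, self.site_index, int(self.preswitch_pass),
            f"{self.work_w:.6g}", int(self.accepted),
            f"{self.net_charge_before:g}", f"{self.net_charge_after:g}",
            self.n_charged_waters))

    TSV_HEADER = ("cycle\tsite\tpreswitch_pass\twork_kJ_mol\taccepted\t"
                  "net_charge_before\tnet_charge_after\tn_charged_waters")


def deprotonation_likelihood(ph: float, pka: float, n: float = 1.0) -> float:
    """Hill-equation likelihood of deprotonation S at a given pH.

    ``S = 1 / (1 + 10^{n (pKa - pH)})``; monotone increasing in pH and
    exactly 1/2 at pH = pKa.
    """
    if n <= 0:
        raise ValueError("Hill coefficient n must be > 0")
    expo = n * (pka - ph)
    if expo > 300:
        return 0.0
    return 1.0 / (1.0 + 10.0 ** expo)


def _metropolis(log_ratio: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(log_ratio))."""
    if log_ratio >= 0:
        return True
    return bool(rng.random() < np.exp(log_ratio))


def preswitch(site, ph: float, rng: np.random.Generator) -> bool:
    """Cheap Hill-equation gate on a proposed protonation-state change.

    Deprotonation proposals are accepted with min(1, S/(1-S)),
    protonation with min(1, (1-S)/S), where S comes from the Hill
    equation (n = 1) at the site's reference pKa — a Metropolis kernel
    whose stationary occupancy is exactly S.
    """
    sign = -1.0 if site.deprotonated else 1.0   # proposal direction
    log_ratio = sign * _LN10 * (ph - site.pka_ref)
    return _metropolis(log_ratio, rng)


def attempt_switch(state: SystemState, site_index: int, config: CpHConfig,
                   params: ForceFieldParams, thermostat: Thermostat,
                   cycle_index: int = 0) -> tuple[SystemState, CycleLog]:
    """One protonation-state switch attempt on ``site_index``.

    Returns the post-attempt state and a log record.  On rejection the
    returned state's coordinates, velocities and charges are bit-identical
    to the pre-attempt snapshot (velocities optionally redrawn from the
    Maxwell-Boltzmann distribution when configured); the clock and the
    random stream still advance.
    """
    site = state.sites[site_index]
    q_before = net_charge(state)
    sign = -1.0 if site.deprotonated else 1.0
    nb = config.electrostatics == "pme"

    if config.protocol.two_step:
        if not preswitch(site, config.ph, state.rng):
            log = CycleLog(cycle_index, site_index, False, 0.0, False,
                           q_before, q_before, _n_charged_waters(state))
            return state, log
        pre_ok = True
    else:
        pre_ok = True  # no gate: full switch at every attempt

    cand, work = switch_trajectory(state, site_index, config.protocol,
                                   params, thermostat, config.electrostatics,
                                   neutralize_background=nb)
    log_ratio = -work / thermostat.kt
    if not config.protocol.two_step:
        log_ratio += sign * _LN10 * (config.ph - site.pka_ref)
    accepted = _metropolis(log_ratio, cand.rng)

    if accepted:
        result = cand
    else:
        result = state.copy()
        result.time_formal = cand.time_formal
        result.rng.bit_generator.state = cand.rng.bit_generator.state
        if config.redraw_velocities_on_reject:
            sigma = np.sqrt(thermostat.kt / result.masses[:, None])
            result.velocities = sigma * result.rng.standard_normal(
                result.velocities.shape)
    log = CycleLog(cycle_index, site_index,
                   pre_ok if config.protocol.two_step else True,
                   work, accepted, q_before, net_charge(result),
                   _n_charged_waters(result))
    return result, log


def _n_charged_waters(state: SystemState) -> int:
    return int(np.count_nonzero(state.charges[state.is_water]))


def neutralize_charge(state: SystemState,
                      rng: np.random.Generator | None = None) -> SystemState:
    """Rewrite water bead charges so the cell is exactly neutral with the
    minimum number of charged waters.

    Solute (non-water) charge Q_s must be balanced by total water charge
    -Q_s.  Waters charged with the wrong sign are reverted to neutral;
    surplus right-sign waters are reverted at random; any remaining
    deficit is covered by picking neutral waters uniformly at random and
    charging them.  Positions, velocities, bonds and bead identities are
    untouched.
    """
    if rng is None:
        rng = state.rng
    water = np.nonzero(state.is_water)[0]
    if len(water) == 0:
        if abs(net_charge(state)) > 1e-9:
            raise NeutralizationError("no water beads available to neutralize")
        return state
    solute_q = float(state.charges[~state.is_water].sum())
    target = -round(solute_q)
    if abs(solute_q - round(solute_q)) > 1e-9:
        raise NeutralizationError(
            f"solute charge {solute_q} is not integer-valued")
    sign = 1.0 if target > 0 else -1.0
    wq = state.charges[water]
    wrong = water[(wq != 0) & (np.sign(wq) != sign)] if target != 0 else \
        water[wq != 0]
    state.charges[wrong] = 0.0
    if target != 0:
        right = water[np.sign(state.charges[water]) == sign]
        need = abs(target) - len(right)
        if need < 0:
            drop = rng.choice(right, size=-need, replace=False)
            state.charges[drop] = 0.0
        elif need > 0:
            neutral = water[state.charges[water] == 0.0]
            if need > len(neutral):
                raise NeutralizationError(
                    f"need {need} neutral waters to absorb the charge "
                    f"imbalance but only {len(neutral)} are available")
            pick = rng.choice(neutral, size=need, replace=False)
            state.charges[pick] = sign
    return state


def run_cphmd(state: SystemState, config: CpHConfig,
              params: ForceFieldParams, thermostat: Thermostat,
              n_cycles: int):
    """Run the full constant-pH cycle loop.

    Returns ``(final_state, TitrationRecord, [CycleLog, ...])``.  The
    record holds the per-site protonation flags after every cycle,
    stamped with the effective simulation time.
    """
    from .titration import TitrationRecord  # deferred: avoids import cycle
    from .model import effective_time

    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    state = state.copy()
    state.rng = np.random.default_rng(config.seed)
    nb = config.electrostatics == "pme"
    logs: list[CycleLog] = []
    times: list[float] = []
    series: list[np.ndarray] = []
    for cycle in range(n_cycles):
        md_segment(state, params, thermostat, config.cycle_md_steps,
                   config.electrostatics, neutralize_background=nb)
        site_index = int(state.rng.integers(len(state.sites)))
        state, log = attempt_switch(state, site_index, config, params,
                                    thermostat, cycle_index=cycle)
        if config.neutralize:
            neutralize_charge(state)
            log.net_charge_after = net_charge(state)
            log.n_charged_waters = _n_charged_waters(state)
        logs.append(log)
        times.append(effective_time(state.time_formal))
        series.append(np.array([s.deprotonated for s in state.sites]))
    record = TitrationRecord(
        ph=config.ph,
        times=np.asarray(times),
        per_site_series=(np.vstack(series) if series
                         else np.zeros((0, len(state.sites)), dtype=bool)))
    return state, record, logs
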