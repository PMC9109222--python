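# Methods

## The model

`cgcph` simulates titratable coarse-grained systems at constant pH with a
hybrid nonequilibrium-MD/Monte-Carlo (neMD/MC) scheme. A system is a set of
beads (about four heavy atoms each) in an orthorhombic periodic box; a subset
of beads are titratable sites with two charge states (protonated /
deprotonated, e.g. 0 / −1 e for a carboxylate) and a reference pKa — the pKa
the group would have with no environment coupling.

Each cycle:

1. **Equilibrium MD.** BAOAB-split Langevin dynamics (NVT) for a fixed number
   of steps. Charges and protonation flags do not change.
2. **Switch attempt.** One site is picked uniformly at random. A coupling
   parameter λ (0 = protonated, 1 = deprotonated) is driven to the opposite
   endpoint over `n_steps` MD steps on a time-symmetric (Strang) schedule:
   half-increment, MD step, full increments between steps, closing
   half-increment. The site charge is linear in λ. The nonequilibrium work is
   accumulated as the fixed-coordinate energy change of each λ increment,
   computed in O(N + K) from the quadratic dependence of the Coulomb energy on
   the one changing charge (validated against full energy differences).
3. **Metropolis acceptance.** With the *two-step evaluation* enabled, a cheap
   preswitch gate first samples the Hill-equation occupancy
   S = 1/(1 + 10^{pKa−pH}) at the reference pKa (Metropolis kernel:
   deprotonation accepted with min(1, S/(1−S)), protonation with the inverse
   ratio); only gated-through proposals pay for a switch trajectory, which is
   then accepted with min(1, e^{−W/kT}). With the preswitch disabled (the
   escalated 1500-step protocol for large apparent-pKa shifts) the pH bias
   moves into the full acceptance, min(1, e^{−W/kT}·10^{s(pH−pKa)}) with
   s = +1 for deprotonation. The pH-bias factor appears in exactly one stage;
   putting it in both would square the bias and double the apparent Hill
   coefficient. Both modes therefore share one stationary law, and for a site
   with zero environment coupling that law is the Hill equation with n = 1 —
   the engine's gold test. On rejection the pre-attempt coordinates,
   velocities and charges are restored exactly (velocity redraw is a config
   option).
4. **Stochastic charge neutralization** (constant-charge mode). Water-bead
   charges are rewritten so the cell is exactly neutral with the minimum
   number of charged waters: wrong-sign charged waters are reverted, surplus
   right-sign waters are reverted at random, and any remaining imbalance is
   covered by charging uniformly chosen neutral waters ±1 e (a +1 water bead
   stands in for an Eigen cation H₉O₄⁺). No beads, bonds or coordinates
   change. In fluctuating-charge mode the cell charge drifts with the
   protonation state and the Ewald sum is only finite through an implicit
   uniform background whose energy, −π k_e Q²/(2Vα²ε_r), is reported
   separately — it is exactly the artifact neutralization removes.

## Energetics

* Lennard-Jones 12-6 with a C¹ cubic switch (potential multiplied by
  1 − 3x² + 2x³ for x = (r−r_s)/(r_c−r_s)); Lorentz–Berthelot combination
  with per-pair overrides.
* Coulomb via (a) the same switched cutoff or (b) plain Ewald summation
  (real-space erfc within the cutoff, reciprocal Gaussian sum, self term,
  bonded-pair exclusion corrections). Plain rather than mesh-interpolated
  Ewald: the systems are ≤ 10³ beads, where the O(N·K) reciprocal sum is not
  the bottleneck and exactness is easier to audit. α is set from
  `ewald_accuracy` (erfc(αr_c) ≈ tol) with the k-space extent matched; the
  total is splitting-independent to < 10⁻⁵ over a 2× α range.
* Harmonic bonds; 1-2 pairs excluded from nonbonded sums. Fixture molecules
  are 2–3 beads, so no angle terms are needed.
* Beads can be flagged nonbonded ghosts (dummy particles): excluded from all
  nonbonded sums while their charge still counts for the cell total. This
  realises "zero environment coupling" exactly.

Forces are checked as −∇U by central differences (< 10⁻⁴ relative). The
Lennard-Jones pair loop optionally runs through a numba kernel with identical
arithmetic (numpy path retained and tested against it); a Verlet neighbour
list with a 0.3 nm skin is rebuilt automatically when any bead has moved more
than half the skin.

## Parameters and units

nm, ps, kJ/mol, amu, e, K. Defaults: T = 300 K, friction 1–2 ps⁻¹, formal
dt = 0.02 ps, ε_r = 15 (standard for non-polarizable coarse-grained water),
cutoff 1.2 nm with switch from 0.9 nm (scaled down for sub-3 nm boxes so the
cutoff stays under half the box), k_e = 138.935 kJ mol⁻¹ nm e⁻². All reported
times are *effective* times: coarse-grained dynamics diffuse about four times
faster than the formal clock, so effective time = 4 × formal time.

The toy force field: every bead has σ = 0.47 nm and mass 72 amu; ε = 4.0
kJ/mol for water/head pairs, 3.5 for tail–tail, and 2.0 for tail–water
(hydrophobic mismatch, which drives self-assembly). Water beads fill boxes at
8.3 nm⁻³ (four waters per bead at liquid density). Titratable heads are
0/−1 e with reference pKa 4.73 for the fatty-acid analogue and 3.61 for the
single-molecule analogue.

## Titration analysis

Records hold per-cycle, per-site protonation flags stamped with effective
time. Analysis is time-and-molecule averaged: per-frame mean over sites, then
a time mean over an equilibration window — the earliest contiguous stretch of
the requested effective length whose std of the mean protonation is below a
backend threshold (defaults 0.05 for Ewald, 0.1 for switched cutoff), so the
initial protonation guess is excluded. The windowed fractions versus pH are
fit with f(pH) = 1/(1+10^{n(pKa−pH)}) by weighted least squares
(inverse-variance from the windowed standard error; unweighted fallback when
the variance collapses at the titration extremes), initialised at n = 1 and
pKa = the pH nearest half-occupancy; parameter uncertainties come from the
fit covariance. The Hill n of the *analysis* is a free parameter; the n = 1
inside the preswitch is a distinct, fixed protocol constant.

The default pH grid is the standard titration protocol: the first unit step,
then 0.5 increments (4, 5, 5.5, … 8); uniform grids are available by explicit
step.

## Aggregation observables

Shrake–Rupley SASA on Fibonacci sphere points (bead radius σ/2, probe 0.24 nm
≈ half a water bead; surfaces evaluated without periodic images, as the
quantity of interest is a compact aggregate's exposed surface; exactly
coincident spheres are collapsed to one surface). Aggregation propensity
AP(t) = SASA(t₀)/SASA(t), so AP = 1 at t₀ and AP > 1 on surface burial.
Aggregates are single-linkage clusters over minimum inter-molecular bead
distances (periodic), contact cutoff 0.6 nm ≈ the first coarse-grained
solvation shell. Charge statistics are per molecule: net charge, and the sum
of absolute charges over charged groups (one group = one bead at this
resolution).

## Study conditions at desk scale

The validation studies (`cgcph.studies`) run in minutes on one CPU by scaling
the problem, not the method:

* **Dispersed site (gold test):** one zero-coupling site + 33 waters in a
  1.6 nm box, 8-point grid, 2000 cycles/pH, 3 MD steps/cycle, 3-step
  switches, Ewald + constant charge. Because W ≡ 0, the fitted Hill n tests
  the acceptance rules alone.
* **Single molecule:** a 2-bead amphiphile in a 2.4 nm box, two-step
  evaluation, 9-point grid bracketing the reference pKa ±2, 2000 cycles/pH,
  fluctuating charge. In a cell this small a stochastic counterion would
  ion-pair with the lone site (ε_r = 15 puts the Bjerrum length at 3.7 nm,
  about the box size) — a finite-size artifact, not a property of the method,
  so the single-molecule study avoids it. The periodic charging
  self-interaction shifts the apparent pKa by a constant (≈ −0.97 units here)
  and leaves n untouched.
* **30-mer micelle:** 4.0 nm box (a full solvation shell beyond the cutoff),
  fully deprotonated start, 700–900 cycles/pH, 5 MD steps/cycle, 3-step
  switches, first 30% discarded as burn-in. With 30 sites the per-frame std
  of the mean protonation is ~0.09, so the full-length window thresholds are
  not resolvable at this sample size and a fixed burn-in fraction stands in
  for window selection in these qualitative runs. Directional comparisons
  that involve the Hill coefficient use three independent-seed replicates
  with the standard error taken across replicates: counterion configurations
  are metastable on toy trajectories, so single-fit covariances understate
  (or, misfit-scaled, erratically overstate) the run-to-run spread. The
  aggregation-induced pKa upshift is measured on the Ewald runs;
  anticooperativity is sharpest — as in the reference titrations this toy
  emulates — under the switched cutoff with constant charge.
* **Neutrality run:** 10⁴ cycles on a 30-mer micelle; the cell charge is
  asserted to be exactly zero after every cycle.

What the toys do probe: acceptance-rule correctness (detailed balance),
charge bookkeeping, the direction of aggregation-induced pKa shifts and
anticooperativity, and the Ewald/background energetics. What they do not:
force-field-calibrated pKa values, bilayer/micelle numbers tied to a specific
parameterization, or effects that rest on dielectric inhomogeneity — in a
uniform-ε_r cell the implicit background *always* stabilizes net charge, so
the sign of the constant-vs-fluctuating apparent-pKa gap at affordable box
sizes is noise-dominated (measured gaps −0.2 to +0.3 pKa units across
protocols and seeds); the corresponding directional check is expected to fail
and is retained as a documented limitation. Counterion physics at this scale
also over-binds once fully equilibrated, which is why the micelle studies use
short trajectories from the freshly neutralized state.

## Numerical choices

* Overlapping beads (< 10⁻⁶ nm) and force overflow (> 10⁷ kJ/mol/nm) raise
  errors naming the step; fixture lattices are jittered to start > 0.3 nm
  apart, and a displacement-capped steepest-descent `minimize_energy` relaxes
  hot starts (the CLI does this automatically).
* Determinism: every source of randomness flows from config seeds through
  one `numpy` Generator per run; identical configs give byte-identical
  tabular outputs, and per-pH runs derive independent seeds from the sweep
  seed.
* Degenerate fits (all fractions at one extreme, < 3 distinct pH) and
  windows that never stabilize raise informative errors rather than
  returning numbers.
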