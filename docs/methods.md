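# Methods

## Model

### Lattice and excluded volume

The simulation uses the two-dimensional bond fluctuation model (BFM). Every
particle — chain monomer, drug molecule or solvent molecule — occupies a 2×2
plaquette of lattice sites, addressed by its lower-left *anchor* site
`(x, y)` with `0 ≤ x ≤ W−2`, `0 ≤ y ≤ h_y−2`. No two plaquettes may share a
site (self-avoidance), and the box walls are hard: there are no periodic
boundaries, which is appropriate for a tablet sitting in a finite solvent
column.

### Bonds

Consecutive monomers of a chain are connected by bonds whose squared length
must lie in {4, 5, 8, 9, 10, 13}. Enumerating all integer vectors with these
lengths gives exactly 36 allowed bond vectors. This is the standard 2D BFM
restriction: together with excluded volume it makes chain crossing
impossible under unit-step moves, so entanglement is represented correctly
at the lattice level.

### Contacts and energetics

Two particles are nearest-neighbour contacts when their anchors are within
Chebyshev distance 2 of each other — a shell of 24 anchor offsets (the 5×5
anchor block minus the centre), giving a lattice coordination number
z = 24. The contact energy between species a and b is `E_ab` (in units of
k_BT; the code fixes k_BT = 1). The total energy is the sum of `E_ab` over
all contact pairs, each pair counted once.

The swelling stage parameterizes the energies with a single *relative
hydrophobicity* H:

    E_cc = ε₀·H        (chain–chain)
    E_cs = ε₀·(1 − H)  (chain–solvent)
    E_cd = E_dd = E_ds = E_ss = 0

with ε₀ = 0.8. H trades chain cohesion against chain solvation: negative H
makes the solvent strongly attractive to chains, H near 0–1 is a hydrophilic
swellable matrix, and large H (e.g. H = 3) is a strongly hydrophobic,
self-cohesive matrix that resists hydration. The equivalent Flory–Huggins
interaction parameter follows from the contact energies as

    χ₁₂ = z·(w₁₂ − (w₁₁ + w₂₂)/2) / k_BT = 24·ε₀·(1 − 1.5·H),

implemented in `flory_huggins_chi` (and the general form in
`flory_huggins_chi_general`).

### Dynamics

Elementary moves displace one particle by one lattice unit in ±x or ±y.
A move is rejected if it leaves the box or overlaps another plaquette, then
if it would take any bond of the moved monomer outside the allowed set, and
finally by the Metropolis criterion: accepted with probability
min(1, e^(−ΔE)) where ΔE is the contact-energy change. One *attempted move*
is the time unit of the simulation; rejected moves advance time like
accepted ones.

Drug and solvent particles are mobile from the start of the swelling run.
Chains are initially frozen (a glassy matrix) and a chain becomes
permanently mobile the first time any of its monomers has a solvent contact
— checked once at t = 0 and after every accepted solvent move. This
hydration-controlled activation is the mechanism that couples solvent
penetration to matrix swelling.

### Time conversion

A run of `Tdis` attempted moves over `N = Nc·Nm + Nd + Ns` particles
corresponds to a physical time

    t_f = Tdis / N   (hours, by convention),

implemented in `final_time`. With the full-scale defaults
(Nc = 45, Nm = 30, Nd = 200, Ns = 1000, Tdis = 10⁹) this gives
t_f ≈ 3.92×10⁵; analysis output reports times in attempted moves and the
conversion is applied only where a physical-time axis is requested.

## Tablet construction

`build_tablet` runs four deterministic stages, each drawing from an
independent child stream of the builder seed (`numpy SeedSequence`):

1. **Globular chain seeding.** Chains are grown one at a time from seeds on
   a ⌈√Nc⌉ grid, using only the short bonds {4, 5} and preferring sites
   close to the seed (compact, globular conformations). Growth dead-ends
   trigger a restart of the chain (up to 200 attempts) and finally an error
   naming the chain; this keeps impossible geometries loud rather than
   silently degraded.
2. **Sedimentation.** 10⁶ moves under a gravity-like potential
   E_j = y_j/(2·h_y), alternating (p = ½ each) single-monomer moves and
   rigid whole-chain moves. The acceptance rule charges an ascending move
   the full destination potential while descending and lateral moves are
   free. A literal per-step energy difference of ±1/(2·h_y) is so small
   (equilibrium height ratio e^½ across the whole box) that it produces no
   visible settling at this budget; the chosen rule realizes the intended
   phenomenology — chains settle into a dense bottom layer — and is this
   package's design choice for the stage.
3. **Pore formation.** 10⁶ single-monomer moves with transiently attractive
   chain–chain contacts (E_cc = −2.0, everything else athermal). Chains
   cluster locally, which opens vacancies (pores) inside the sediment.
   Setting `pore_ecc = 0` reduces the stage to pure steric diffusion.
4. **Population.** The matrix *surface profile* is the per-column maximum
   chain plaquette height. Drug plaquettes are placed uniformly at random
   strictly below the profile (inside the matrix, filling pore space) and
   solvent strictly above it. If fewer positions exist than requested the
   builder reports the achievable count instead of silently placing fewer.

**Realism limits of the generator.** The tablet is two-dimensional; chains
are short (default Nm = 30) and monodisperse; sedimentation and pore
formation are kinetic protocols, not equilibrated ensembles, so the initial
matrix density and pore structure depend on the move budgets; the drug is a
monomeric penetrant with athermal interactions; solvent is initialized as a
uniform layer rather than a reservoir with inflow.

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `nc` | 45 | chains | full-scale matrix size used by the study conditions |
| `nm` | 30 | monomers/chain | long enough for orientational relaxation, short enough for the budget |
| `nd` | 200 | monomers | drug load that fits the default pore volume |
| `ns` | 1000 | monomers | solvent layer several contact shells deep |
| `width`, `height` | 256 | lattice sites | tablet plus solvent column with free headroom |
| `sediment_moves` | 10⁶ | attempted moves | settles the default chain count to the floor |
| `pore_moves` | 10⁶ | attempted moves | consolidates the sediment without freezing it |
| `pore_ecc` | −2.0 | k_BT | strong transient cohesion; 0 disables the stage |
| `h` | 0.0 | — | neutral default; the study regimes are −0.3, 0.3, 3 |
| `eps0` | 0.8 | k_BT | energy scale of the H-split (must be > 0) |
| `tdis` | 10⁹ | attempted moves | full dissolution budget |
| `snapshot_interval` | 10⁵ | attempted moves | trajectory and HSR sampling resolution |
| `hsr_window` | 10⁵ | attempted moves | averaging window for the hydration rate |
| `theta_pf` | 5% of mean free-solvent density | — | penetration-front threshold |
| `theta_sf` | 50% of bulk chain density | — | swelling-front threshold |
| `theta_ef` | 5% of bulk chain density | — | erosion-front threshold |

## Analysis definitions

- **Density profiles.** For each snapshot, per-species 1D vertical profiles:
  site coverage per unit bin area (each plaquette contributes 2 sites to each
  of rows y and y+1; bins of `bin_width` lattice rows across the full box
  width).
- **Fronts.** From the profiles, with linear interpolation between bins:
  the *penetration front* is the lowest height at which solvent density
  falls below θ_pf (deepest solvent reach), the *swelling front* is where
  chain density first drops below θ_sf (top of the dense matrix) and the
  *erosion front* is the highest point where chain density still exceeds
  θ_ef (outer gel boundary). Thresholds default to fractions of the t = 0
  bulk values and are all overridable. Undefined fronts are NaN, never
  fabricated.
- **HSR (hydration/solvation rate).** Chain–solvent contact pairs per 10⁵
  attempted moves, averaged over the trailing `hsr_window` and counted at
  snapshot boundaries, reported per chain.
- **Orientational relaxation.** C_EE(t) = ⟨R_EE(t)·R_EE(0)⟩/⟨R_EE(0)²⟩ over
  solvent-activated chains (C_EE(0) = 1), fitted by C = e^(−t/τ). A
  non-decaying series is reported as τ = ∞ rather than a spurious number.
- **Translational transport.** ΔR²_cm(t), the mean-square displacement of
  activated-chain centres of mass (0 at t = 0), fitted by ΔR² = α·t^β on
  log–log axes.
- **Swelling kinetics.** First-order model S(t) = S_eq·(1 − e^(−kt)) fitted
  by nonlinear least squares. The fit is flagged `low_confidence` when
  k·t_max < 2, i.e. when the observation window ends well before
  saturation and S_eq is an extrapolation. Parameter-recovery statistics in
  the test suite use a 0–200 h window (≈ 4.4 time constants at the reference
  k = 0.022 h⁻¹), chosen so that S_eq is determined by the data rather than
  the extrapolation.

## Numerical choices

- **Kernels.** The bulk Monte Carlo loops are numba-jitted functions over
  flat int64 arrays (positions, species, bonds, an anchor-occupancy grid and
  a site grid), reaching ~10⁷ attempted moves per second on one core.
  Contact energies in the kernels are evaluated from the anchor grid (a
  cell-list lookup over the 5×5 anchor window), which is exactly equivalent
  to an all-pairs scan. The Python-level API additionally provides a
  `VerletList` whose cached candidate lists auto-rebuild when any particle
  drifts beyond half the skin, so list-based energies are always exact.
- **Randomness and determinism.** All randomness derives from user-provided
  integer seeds. The builder splits its seed into independent child streams
  per stage via `numpy.random.SeedSequence`; jitted kernels use numba's
  global NumPy legacy RNG, seeded once per stage (reduced mod 2³¹−1).
  Identical seeds and configurations reproduce trajectories bitwise — this
  is tested, not aspirational.
- **Fitting.** `scipy.optimize.curve_fit` for the exponential and
  first-order swelling models (with a log-linear polyfit initial guess);
  log–log `numpy.polyfit` for the power law. Non-positive values are
  excluded from log fits; fits require at least five usable points and raise
  otherwise.
- **Trajectory format.** A self-describing columnar text format
  (`#BFMSWELL-TRAJECTORY v1`, `#META key=value`, `#SNAPSHOT <stamp>` and one
  row per particle), optionally gzip-compressed. The reader streams
  snapshot-by-snapshot; corrupt rows are reported with their line numbers
  and truncated files with the last valid snapshot stamp.

## Limitations

- Two-dimensional: absolute front positions, exponents and rates are not
  quantitative predictions for 3D tablets; the model targets regime
  comparisons (e.g. across H) rather than absolute release curves.
- Solvent is a finite layer, not a stirred reservoir; very long runs deplete
  the free solvent near the matrix.
- Drug dissolution is purely steric/diffusive (athermal drug); no
  drug–polymer binding or solubility limit is modelled.
- Chain activation is binary and permanent; there is no re-vitrification.
- The 2×10⁷-move, 8-chain configuration used for regime comparisons in the
  test suite is a deliberately small setting; stochastic variation between
  replicate tablets is substantial at that scale, and the suite averages
  over replicates rather than interpreting single runs.
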