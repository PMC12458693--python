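# Methods

## Model and ensembles

Hosts are rigid collections of point-charge + Lennard-Jones sites; waters are
rigid multi-site molecules (TIP4P by default: O-H 0.9572 A, H-O-H 104.52 deg,
M site 0.15 A along the bisector, q_H +0.52 e, q_M -1.04 e, sigma_O
3.15365 A, eps_O 0.155 kcal/mol; other rigid 3/4-site models plug in through
`WaterModel`). Nonbonded energies use Lorentz-Berthelot combination, a 10 A
cutoff with CHARMM-style energy switching over the last 0.5 A,

    S(r) = (rc^2 - r^2)^2 (rc^2 + 2 r^2 - 3 ron^2) / (rc^2 - ron^2)^3 ,

and a half-harmonic droplet restraint U = k/2 (d - R)^2 (k = 1.5 kcal/mol/A^2,
R = 30 A by default) outside the solvent sphere. The cutoff acts per molecule
pair on the oxygen-oxygen (water-water) or oxygen-site (host-water) distance
so a water's sites always switch together. For ligand-environment softcore
interactions the switch is applied per site pair; within the desk-scale boxes
every distance is far inside the switching onset, so the two conventions
coincide there. Site-site separations below 0.05 A are treated as hard
overlaps (infinite energy, auto-reject) rather than errors.

The GCMC region is a closed axis-aligned box (conventionally the bounding box
of the crystallographic network oxygens plus 1 A). A water belongs to the
region iff its oxygen is inside. Sampling is Metropolis Monte Carlo in the
muVT ensemble with the chemical potential carried as the Adams B value:

    P_accept(insert) = min(1, e^B / (N+1) * e^(-beta dU))
    P_accept(delete) = min(1, N e^(-B)   * e^(-beta dU))

with trial waters placed uniformly in the box with uniform orientation. B
absorbs the thermal-wavelength and volume constants, so the ideal-gas law
`<N> = e^B` is exact — the anchor for several tests. Displacement moves that
would carry an oxygen across the box boundary are rejected outright (the
reverse proposal crosses too, so detailed balance is preserved); insertion
and deletion are therefore the only N-changing moves, which keeps the region
bookkeeping trivial at a small cost in diffusion efficiency.

Replica exchange across the B ladder swaps configurations of adjacent
replicas with probability `min(1, exp[(B_m - B_n)(N_n - N_m)])` (valid
because all replicas share one potential), alternating even/odd pairings.
Every replica owns an independent RNG stream derived from the master seed,
so ladders are reproducible bit for bit.

## Grand Canonical Integration

With the dimensionless, volume-normalised configurational integrals Z_N, the
grand partition function is Xi(B) = sum_N e^{BN} Z_N / N!, and
d(beta Omega)/dB = -<N>. The bulk reference enters through

    B_equil = beta mu'_hyd + ln(V_region / V0),

with mu'_hyd = -6.2 kcal/mol and V0 = 30 A^3 for TIP4P at 298 K (standard
literature values; both are explicit configuration fields). Integrating the
titration curve from the empty limit exactly to B_equil, the Helmholtz and
standard-state terms cancel and the network binding free energy relative to
bulk is

    dG_bind = -kT * Int_{B_0}^{B_equil} <N> dB .

For cycle legs over a fixed retained set of n waters, the integral stops at
the B* where the (monotonised) curve reaches n and

    beta dG_bind(n) = -Int_{B_0}^{B*} <N> dB + n B* - n B_equil .

Because a deep site's occupancy plateaus slightly below the integer at finite
temperature, B* is accepted once the plateau is within `plateau_tol` (0.05)
of n; the combination `-Int + n B*` is stationary along a plateau, so the
choice is second-order insensitive. Integration is trapezoidal on the
simulated grid (an optional monotone-logistic fit is available and flagged in
the output); the per-repeat values are pooled to a mean and standard error.
A curve whose lowest-B occupancy is not ~0 raises an error advising a longer
ladder.

## Hydration sites and crystal comparison

Oxygen positions pooled over production frames are clustered by
average-linkage hierarchical clustering (scipy) cut at 2.4 A. Occupancy is
the fraction of frames in which a cluster is populated (capped at 1 even if
a site transiently holds two waters). Sites below 30% occupancy are dropped
(inclusive boundary). The true positive rate counts a crystallographic site
as matched if any predicted centroid lies within 1.5 A (inclusive); the
metric is per crystal site, so one predicted site may satisfy several
crystal sites — the literal reading of the sensitivity definition, noted
here because a greedy one-to-one matching would score slightly differently.

## Alchemical legs and MBAR

Dual topology: both end-state ligands are present; the environment couples
to ligand B with weight lambda and to A with (1 - lambda) through softcore
forms

    U_LJ = 4 eps l [ (d(1-l) + (r/sig)^6)^-2 - (d(1-l) + (r/sig)^6)^-1 ]
    U_C  = C q_a q_b l / sqrt(d_c (1-l) + r^2)

with d = 0.2 and d_c configurable per transformation (default 2.0). These
reduce to the plain potentials at l = 1, vanish at l = 0, and stay finite at
r = 0 for l < 1. A-B cross interactions are excluded; a zero-rest-length
harmonic "dummy bond" (k = 10 kcal/mol/A^2) tethers the two centers of
geometry, and rigid-body ligand moves (when enabled) apply identical
translations/rotations to both copies. Note the forms are nonlinear in
lambda, so for two identical superposed ligands the profile is symmetric in
lambda <-> 1-lambda and matches the single-ligand value at the endpoints,
but not in between — only endpoint quantities are physical.

Each window is sampled canonically; network waters are confined to the GCMC
box so the alchemical and grand canonical legs share one configuration
space. Water moves mix small rigid-body displacements with occasional
box-uniform redraws ("jump" moves, probability 0.2): a symmetric proposal
that restores ergodicity when a ligand core splits the box into basins a
small step cannot connect — without it the low-lambda windows equilibrate
into the wrong basin and the leg estimate is biased by several tenths of a
kcal/mol on the toy systems. Adjacent-window replica exchange uses the
standard two-configuration criterion; only the lambda-dependent energy
enters, since the water-water terms cancel.

At every sample the reduced potential is evaluated at all windows. The MBAR
equations are solved by minimising the convex pseudo-likelihood
(L-BFGS with analytic gradient) followed by self-consistent polish to 1e-10;
the asymptotic covariance uses the SVD form of the weight-matrix estimator,
and a warning flags divergent uncertainties when the adjacent-window overlap
matrix has entries below 1e-6. A two-state BAR (bracketed root solve of the
Bennett implicit equation) is implemented independently as a cross-check;
the two agree to <= 1e-6 on shared samples in the test suite. `pymbar` is
not a dependency; the estimator here is self-contained and validated against
closed forms (harmonic wells, discrete-state enumeration).

## Cycles

The cycle fixes its orientation once: closure = |dG_wet + dG_net(A) - dG_dry
- dG_net(B)|, errors combined in quadrature; `solvent_contribution` =
dG_wet - dG_dry equals dG_net(B) - dG_net(A) exactly when the closure is
zero, and every report prints the convention. The standard toy cycle
(`cycle_pair` preset) keeps the ligand pair fixed in the alchemical legs so
that all four legs sample exactly the same degrees of freedom (the GCMC legs
have a rigid host); with that choice the cycle closes in the
infinite-sampling limit, and at desk sampling closes well below 1 kcal/mol.
The displaced-water convention of real series is honoured by computing both
network legs over the common retained set (the fixed-n GCI form above).

## Synthetic systems

A designed hydration site is created by a triad of charged LJ particles
(two pseudo-donors +q, one acceptor -2q; sigma 2.9 A, eps 0.12 kcal/mol)
on a 55-degree cone 2.8 A from the site position. The charge q is tuned by
bisection until the minimised host-water energy at the site hits the
requested well depth (+-0.2 kcal/mol); after assembly the triads are
re-centered for up to four iterations to cancel cross-triad field drift,
and the build fails unless every site holds a local minimum within 0.5 A of
its designed position. All triads share one polarity: alternating donor/
acceptor patterns along a chain create spurious off-site minima at these
distances. Because a site must out-compete bulk water (mu'_hyd plus the
entropy cost of confinement), stably bound sites need depths of roughly
-12 to -14 kcal/mol; the presets use that regime, with ~5 A site spacing
(the residual water-water coupling there is weak and, under these fields,
slightly anti-cooperative — the series narrative below does not depend on
its sign). Ligand "compounds" are neutral LJ occluders at blocked sites
plus optional polar contacts: a pseudo-donor charge 2.85 A from a surviving
site (facing the bound water's open acceptor side) with a farther
compensating charge, which measurably deepens that site.

What the generator emulates: the statistical structure of a congeneric
ligand series that sequentially displaces waters from a small cooperative
network — occupancy titration, network destabilisation on displacement,
re-stabilisation through new hydrogen-bond-like contacts. What it does not:
protein flexibility, force-field chemistry, real water-network geometry
(2.8 A hydrogen-bond spacing), bulk solvent around the pocket, or the
magnitudes of any published system. Passing tests therefore demonstrate the
correctness of the machinery (sampling, integration, estimation, assembly),
not quantitative transfer to proteins.

## The exact grid oracle

For boxes this small the grand partition function can be evaluated directly:
Riemann (midpoint) sums over a position grid that tiles the box exactly,
times a deterministic SO(3) product quadrature (trapezoid in the periodic
Euler angles — spectrally accurate — and Gauss-Legendre in cos beta), give
Z_1; pair and triple sums over a Boltzmann-pruned state set (states more
than 15 kT above the minimum dropped) give Z_2 and Z_3 with the same Adams
normalisation as the engine, so titration curves, occupancy distributions
and network free energies are directly comparable. The Boltzmann factor of
a hydrogen-bonded site is sharply peaked in both position and orientation,
so the quadrature is adaptive: basin cells are re-evaluated on a 3x finer
sub-grid with an 8x denser orientation set, and each cell's weight is
rescaled by the refined/coarse ratio (also applied inside the pair sums,
valid because water-water terms vary on the inter-site scale, much coarser
than a cell). When the 15 kT window still holds too many states, the
lowest-energy states are retained up to a fixed cap (an error only if the
cap cuts inside 6 kT of the minimum, i.e. into thermally relevant weight).
Enumeration is guarded (max_n <= 3, bounded state counts);
convergence is checked by re-running refined, not assumed. Random
orientation sets were tried first and rejected: for a deep site their
estimates scatter by several tenths in ln Z_1 even at 2048 samples, which
the product quadrature reduces to ~0.02.

## Numerical choices and desk-scale defaults

* Temperature 298 K; k_B = 0.0019872041 kcal/mol/K; Coulomb constant
  332.0637 kcal A/mol/e^2.
* Default move mix 35/35/20/10 (insert/delete/region/bulk displacement) per
  the general design; the cage presets use 45/45/10/0 because they contain
  no bulk waters and N-mixing dominates convergence there.
* Desk B ladders: the full -19..-7.5 ladder in 0.5 steps is the configured
  default; validation runs use a 1.0-step ladder (the trapezoid error on
  these smooth sigmoids is ~0.01 kcal/mol) with 2 repeats and 8000-12000
  production moves per replica, exchange attempted every 250 moves. These
  sizes put the GCI-vs-oracle discrepancy at ~0.03 kcal/mol, shrinking with
  more sampling.
* The half-harmonic restraint convention (k/2 x^2 vs k x^2) and the
  energy-vs-force switching convention are genuinely ambiguous in the
  method's lineage; this package uses k/2 x^2 and energy switching, both
  configurable.
* Ions are not simulated; chloride seen in related crystal structures would
  be a host site here if ever needed.

## Known limitations

* Hosts are strictly rigid; there is no bonded force field, no PBC/Ewald.
* The oracle's triple enumeration limits exact references to networks of
  <= 3 waters; larger networks are validated only through properties.
* MBAR uncertainties are asymptotic and do not correct for sample
  autocorrelation; repeat-based spreads are reported where repeats exist.
* The alchemical "bulk" environment is a waters-in-box droplet, not a
  periodic solvent box.
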