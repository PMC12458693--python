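# gcwater

Grand canonical Monte Carlo (GCMC) water sampling and network free energies
for protein-binding-site hydration, at desk scale.

Buried water networks in binding sites can make or break a ligand series:
displacing a water that is happy where it is costs binding affinity, while
displacing a frustrated one, or donating new hydrogen bonds to the survivors,
gains it. `gcwater` implements the computational workflow used to quantify
these effects:

* a **GCMC engine** that inserts/deletes rigid waters (TIP4P by default) in a
  defined region of a rigid host, at a ladder of Adams B values with replica
  exchange. In the Adams bookkeeping the insertion/deletion acceptances are
  `min(1, e^B e^(-beta dU)/(N+1))` and `min(1, N e^(-B) e^(-beta dU))`, so an
  ideal gas obeys `<N> = e^B` exactly;
* **Grand Canonical Integration (GCI)**: from `d(beta Omega)/dB = -<N>`, the
  binding free energy of the region's water network relative to bulk is
  `dG_bind = -kT * area under the titration curve` up to `B_equil = beta
  mu'_hyd + ln(V_region/V0)`, the B value representing equilibrium with bulk
  water;
* **hydration-site analysis**: average-linkage clustering of sampled oxygen
  positions (2.4 A cut), occupancy filtering (30%), and a true positive rate
  `TPR = TP/(TP+FN)` against crystallographic waters (1.5 A match radius);
* **dual-topology alchemical legs** with softcore LJ/Coulomb potentials and a
  hand-rolled **MBAR** estimator (cross-checked against BAR and closed forms);
* **free-energy cycles** combining two alchemical legs (waters present /
  absent) with two GCMC network legs, with explicit sign conventions and a
  closure-error diagnostic;
* a **synthetic-systems module**: rigid polar "cage" hosts with designed
  water sites (well depths tuned by bisection), nested ligand series that
  occlude sites and add hydrogen-bond-like polar contacts, and an exact
  **grid grand-partition oracle** that makes every stage verifiable without
  external data.

Full-scale protein applications (flexible hosts, force-field preparation,
10^8-move sampling) are out of scope; every quantitative claim here is tested
on synthetic cages against exact references.

## Worked example

Titrate the one-site cage preset, integrate the curve, cluster the sampled
waters and compare with the designed (crystal) sites:

```bash
gcwater run -o demo --seed 1
gcwater report -o demo
```

The bundle `demo/` then contains `titration.csv`, `network_free_energy.json`,
`sites.json` and `tpr.json`. With the shipped defaults (full ladder
B = -19 .. -7.5 in 0.5 steps, two repeats, 8000 production moves per replica)
the summary prints, among other lines:

```
Titration curve
  B      <N>    SE
 -19.00  0.006  0.006
 -17.00  0.012  0.000
 -15.00  0.050  0.012
 -13.00  0.356  0.094
 -11.00  0.725  0.013
  -9.00  0.944  0.031

Network binding free energy
  "b_equil": -11.791424822406814,
  "dg_kcal_mol": -0.646844050300805,
  "n_equil": 0.6333937943982966,
  "n_equil_reported": 1,

Crystal-water comparison
  "tp": 1, "fn": 0, "tpr": 1.0
```

i.e. the single designed site titrates from empty to occupied across the
ladder, binds its water by about -0.65 kcal/mol relative to bulk at
`B_equil ~ -11.8` (the exact grid-oracle value for this cage is -0.60; the
residual gap shrinks with longer runs), and the predicted hydration site
lands within 1.5 A of the designed position (TPR = 1). The same library calls drive the two-site, weak-site,
cycle-pair and four-compound network-series presets; see `docs/methods.md`
for the model behind each.

Python API sketch:

```python
from gcwater import *
from gcwater.synthetic import one_site_cage, make_cage_host, make_region

spec = one_site_cage()
host, region = make_cage_host(spec), make_region(spec)
b_eq = equilibrium_b(BulkWaterReference(), region, EnergyParams())
trajs = {b: [t] for b, t in ...}  # run_ladder(...) per repeat
net = gci_network_binding_free_energy(occupancy_curve(trajs), b_eq,
                                      BulkWaterReference())
```

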