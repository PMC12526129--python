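# hybridff

A toolkit for building and validating **hybrid united-atom /
coarse-grained (UA-CG) force fields** for peptide-aggregation
simulation, and for analysing the condensate-maturation trajectories
such models produce.

Amyloid formation inside biomolecular condensates needs two things at
once: chemistry-specific local contacts (which set beta-sheet registry)
and mesoscale phase behaviour (droplet formation, cluster coalescence).
A practical answer is a mixed-resolution model — united-atom detail for
the aggregation-prone segment, coarse-grained beads for the rest — whose
total energy splits exactly as

    U_total = U_UA + U_CG + U_UA-CG

with 12-6 Lennard-Jones (4 eps_ij [(sigma_ij/r)^12 - (sigma_ij/r)^6])
plus reaction-field Coulomb pair terms and two global scaling factors:
`eps_cg` on CG-CG well depths and `eps_dual` on cross-resolution well
depths.  The package provides, as a library with a thin CLI:

* **forcefield** — the pair table, scaling layer, and an exact three-way
  energy decomposition with minimum-image periodic boundaries;
* **sampler** — BAOAB Langevin dynamics and a Metropolis pair-distance
  sampler, with harmonic umbrella biasing of a COM separation
  (default ladder: 20 windows over 0.25-1.0 nm, k = 1000 kJ/mol/nm^2);
* **wham** — self-consistent WHAM reconstruction of potentials of mean
  force (PMFs) and first-minimum (depth, position) descriptors;
* **calibration** — stage one: derivative-free fitting of pair LJ cross
  terms against reference PMFs; stage two: grid-scan selection of the
  scaling factors by matching single-chain radius-of-gyration (Rg)
  distributions (1-D Wasserstein distance by default);
* **aggregation** — single-linkage cluster kinetics and power-law growth
  exponents (alpha near 1: diffusion-limited coagulation; alpha << 1:
  reaction-limited), inter-cluster encounter statistics, geometric
  beta-strand detection, and amyloid registry classification
  (in-register parallel L1-L1...F4-F4 versus antiparallel
  L1-F4...F4-L1);
* **fixtures** — deterministic generators for every test input: the
  144 ordered side-chain-analog dimers, toy homopolymers, ideal
  beta-sheets of known registry, a micelle-forming amphiphile box, and
  synthetic growth/encounter series.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Umbrella-sample a Leu(UA)-Val(CG) dimer, rebuild the PMF with WHAM and
read off the binding well (`examples/02_umbrella_pmf.py`):

```python
from hybridff import first_minimum, wham
from hybridff.fixtures import analog_dimer, default_pair_table
from hybridff.sampler import SimulationConditions, sample_umbrella_set

table = default_pair_table()          # eps_cg = 0.2, eps_dual = 0.8
dimer = analog_dimer("LEU", "VAL")    # first member UA, second CG

conditions = SimulationConditions(temperature=310.0, n_steps=40000, seed=1)
windows = sample_umbrella_set(dimer, table, [0], [1], conditions=conditions, method="mc")
profile = wham(windows, grid=(0.25, 1.0, 0.01), temperature=310.0)
print(first_minimum(profile))
```

Output:

```
sampled 20 windows, 3600 production points each
first minimum: depth = 2.67 kJ/mol at r = 0.523 nm
effective pair parameters: eps = 2.677 kJ/mol, sigma = 0.460 nm
analytic well: depth ~ 2.677 kJ/mol at r = 0.516 nm
```

The reconstructed well depth (2.67 kJ/mol) and position (0.523 nm) match
the analytic well of the `eps_dual`-scaled pair potential to within
sampling error — the two descriptors the stage-one parameter fit
optimises.  Stage two works the same way on Rg distributions
(`examples/04_calibrate_scaling.py`): a reference ensemble generated at
cohesion scaling 0.2 is recovered from the grid {0.1, ..., 1.0} with a
Wasserstein distance of 0.0085 nm at the selected factor.

The other examples cover the energy decomposition, cross-term fitting,
growth-exponent recovery (0.910 +/- 0.002 and 0.250 +/- 0.002 over 20
seeds for planted diffusion- and reaction-limited exponents), registry
classification and the micelle core-corona ordering statistic
(+0.227 nm for charged heads versus -0.007 nm for the symmetric
control).

## Command line

```bash
hybridff fixtures --kind beta-sheet --registry antiparallel --out sheet.gro
hybridff sample --table ff.dat --pair LEU:VAL --windows-dir windows/
hybridff pmf --windows windows/ --out pmf.dat
hybridff fit-pair --reference pmf.dat --out fit.json
hybridff calibrate --reference rg.txt --out calib.json
hybridff analyze --traj frames/ --out analysis/ --cutoff 0.6
```

All subcommands are deterministic given their flags and seeds.

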