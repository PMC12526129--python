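# Methods

`hybridff` implements the machinery of a hybrid united-atom /
coarse-grained (UA-CG) force field for peptide aggregation studies: the
cross-resolution nonbonded energy model, the two-stage parameterization
that calibrates it, and the analysis suite used to characterise
condensate maturation (cluster kinetics, encounter statistics, amyloid
registry).  This note records the model, its assumptions, the numerical
choices, and what the desk-scale validations do and do not show.

## Energy model

A system mixes particles tagged `UA` (united-atom, chemistry-resolved)
and `CG` (coarse-grained bead).  The nonbonded energy decomposes exactly
into three terms,

    U_total = U_UA + U_CG + U_UA-CG,

because every pair is routed to exactly one term by its two resolution
tags.  Pair interactions are

* 12-6 Lennard-Jones, U(r) = 4 eps_ij [(sigma_ij/r)^12 - (sigma_ij/r)^6],
  with eps_ij the well depth (kJ/mol) and sigma_ij the zero crossing
  (nm).  Missing pairs combine by Lorentz-Berthelot
  (eps_ij = sqrt(eps_i eps_j), sigma_ij = (sigma_i+sigma_j)/2); stored
  pair rows override the rule — pair-specific fitting is the point of
  stage one.
* reaction-field Coulomb with a single 1.2 nm cutoff shared with LJ:
  U(r) = f q_i q_j / eps_r (1/r + k_rf r^2 - c_rf), with
  k_rf = 1/(2 r_c^3) for a conducting boundary (eps_rf = infinity, the
  MARTINI convention; finite eps_rf is supported) and c_rf chosen so the
  potential vanishes at the cutoff.  The relative dielectric defaults to
  eps_r = 15.  For the conducting boundary the force is also continuous
  at the cutoff.

Two dimensionless global factors form the scaling layer: `eps_cg`
(default 0.2) multiplies every CG-CG LJ well depth and `eps_dual`
(default 0.8) every UA-CG well depth; UA-UA terms are never scaled and
sigma is never modified, so the scaling layer tunes cohesion strength
without touching excluded volume.  Scaling LJ only is the default; a
flag (`scale_cg_coulomb`) extends `eps_cg` to CG-CG Coulomb terms for
users who want the literal "all nonbonded" reading — no dielectric
change is implied by the default.  Both factors are sanity-bounded to
(0, 2].

Numerical choices: LJ is potential-shifted to zero at the cutoff by
default (`shift_lj`) so toy dynamics conserve energy; shifting changes
no force and no bare-pair analytic value.  Minimum-image convention over
orthorhombic boxes.  Bonded exclusions are the 1-2 and 1-3 neighbour
pairs implied by the harmonic bond list (bonds and angles appear only as
harmonic toy terms; torsions, H-bond terms and elastic networks are out
of scope).  Units are GROMACS conventions throughout: nm, kJ/mol, ps,
elementary charge, amu.

## Samplers

Two seed-deterministic routes generate equilibrium samples:

* **BAOAB Langevin** over full coordinates (default 310 K, friction
  2 ps^-1, time step 0.01 ps).  With friction and temperature taken to
  zero the O step is the identity and the scheme reduces to velocity
  Verlet; the suite verifies energy conservation in that limit,
  equipartition in a stiff harmonic well, and free-diffusion MSD against
  D = kT/(m*gamma).
* **Metropolis Monte Carlo** over the scalar pair separation of a dimer
  (exact for an isolated pair, no Jacobian — r is treated as a 1-D
  coordinate, consistent with the PMF convention below).  Proposal width
  defaults to ~0.7*sqrt(kT/k_bias), clipped to [0.005, 0.05] nm, so
  stiff umbrella windows still move.  Boltzmann fidelity is verified by
  a chi-square test on a double-well density with an
  autocorrelation-corrected effective sample size, and by the closed
  form Var(r) = kT/(k_model + k_bias) for a biased harmonic coordinate.

Umbrella windows restrain the mass-weighted COM separation of two
particle groups with a harmonic bias (default k = 1000 kJ mol^-1 nm^-2).
The default ladder is 20 uniformly spaced centres spanning 0.25-1.0 nm.
Production-style setups often restrain one molecule positionally and
displace the other along an axis; the toy sampler biases the scalar COM
distance directly — equivalent for PMF purposes.  Each window discards
its first 10% as equilibration (configurable; 10% is a conservative
desk choice).

## WHAM and minimum descriptors

Windows are combined by the standard self-consistent WHAM iteration in
log space (logsumexp), stopping when the maximum change in window
offsets drops below 1e-7 kJ/mol (max 1e5 iterations).  Adjacent windows
must share populated bins; a gap raises an error naming its location,
and weak overlap warns.  Default grid: 0.01 nm bins over 0.25-1.0 nm.
No Jacobian correction is applied by default (the samplers treat r as a
1-D coordinate); a flag removes the 2 kT ln r radial entropy for data
produced by 3-D sampling.

Profiles carry an explicit zero convention, defaulting to
zero-at-largest-sampled-r so the **first-minimum depth** means binding
free energy relative to the separated pair.  The first minimum is found
by a discrete scan from small r (optional moving-average smoothing),
with parabolic sub-bin refinement of the position through the minimum
bin and its neighbours.  The plateau reference is the median of the last
`plateau_bins` populated bins: 1 (the default) is exact for analytic
profiles; ~8 suppresses single-bin boundary noise on sampled profiles,
whose depth estimate is otherwise anchored to one noisy histogram bin.
Profiles without an interior minimum return a distinct no-minimum
result, not an error.

Validation: a single effectively-unbiased window reproduces Boltzmann
inversion; eight overlapping windows reconstruct an analytic double well
to RMSD < 0.2 kJ/mol on well-sampled bins; the reconstruction error
shrinks with sampling length.  Note that well-depth estimates through
the full umbrella pipeline converge slowly — at ~3,000 samples per
window the depth of a ~2 kJ/mol well still carries ~0.2-0.4 kJ/mol of
error accumulated across window junctions; the examples therefore use
20,000 samples per window where truth recovery is displayed.

## Two-stage calibration

**Stage one** fits pair-specific cross terms (eps_ij, sigma_ij) so a
model dimer PMF reproduces the reference PMF's first-minimum depth and
position.  The objective w_d |Δdepth| + w_p |Δposition| (defaults
w_d = 1 (kJ/mol)^-1, w_p = 10 nm^-1, i.e. 0.1 nm of position miss trades
against 1 kJ/mol of depth miss) is minimised by Nelder-Mead with bound
clipping; trial parameters whose profile has no interior minimum are
penalised, not fatal.  Because (depth, position) maps bijectively to
(eps, sigma) for a 12-6 well, self-consistent recovery is exact up to
descriptor noise; the suite verifies recovery of random planted
parameters within ±5% on eps and ±0.01 nm on sigma.

**Stage two** calibrates the scalar scaling factors against a
single-chain radius-of-gyration (Rg) reference.  The search is a grid
scan (round factor values are the practice this supports, and noise
handling stays trivial), selecting the candidate minimising a distribution distance —
1-D Wasserstein by default (robust to binning; equals the shift for
location families), with Kolmogorov-Smirnov and peak-position
alternatives.  Ties break toward the smaller candidate so the scan is
order-independent.  The two-stage usage fixes `eps_cg` first, then scans
`eps_dual` with `eps_cg` held.

The calibration ensemble generator is a freely-jointed sticky bead chain
(10 beads, 0.38 nm bonds, LJ cohesion eps_scale * 4.0 kJ/mol,
sigma 0.45 nm, 1-2/1-3 exclusions) sampled by Metropolis pivot moves at
310 K.  It is explicitly a surrogate for a real peptide monomer: it
reproduces the mechanism that makes Rg calibration work — stronger
cohesion compacts the chain monotonically, so P(Rg) identifies the
scaling factor — but not the chemistry, solvent or charge pattern of any
real chain.  Passing recovery tests therefore shows the calibration
*procedure* is sound, not that any particular peptide's ensemble is
reproduced.

## Aggregation analysis

* **Clustering**: single-linkage over chains — two chains link when any
  inter-chain particle distance (minimum image) is below the cutoff
  (default 0.6 nm between heavy particles; the criterion is a package
  choice, exposed as a flag).  Clusters are connected components;
  partitions are invariant under relabeling and monotone in the cutoff.
  "Largest aggregate" is counted in chains, not mass.
* **Growth kinetics**: the largest-cluster size n(t) is fitted by
  least squares on ln n vs ln t.  Exponents near 1 signal
  diffusion-limited coagulation (clusters merge on encounter); much
  smaller exponents signal reaction-limited coagulation over an
  activation barrier at contact.
* **Encounter statistics**: clusters are unwrapped across periodic
  boundaries by a connected-component walk before mass-weighted COMs are
  taken (a naive COM of wrapped coordinates is wrong), then the COM-COM
  distance gets the minimum-image treatment.  Encounters are maximal
  intervals below a threshold (default 30 angstrom); fusion is detected
  when the tracked chain sets fall into one single-linkage cluster.
* **Beta strands** (geometric criterion; no hydrogen-bond assignment is
  possible for CG-containing chains): a residue is pseudo-extended when
  its Calpha(i-1)-Calpha(i+1) distance exceeds 0.64 nm — ideal extended
  geometry gives 0.70 nm, ideal helix ~0.55 nm, so the threshold
  separates the two with margin — and a run of >= 3 extended residues
  is a strand only if >= 3 consecutive residues have a cross-chain
  Calpha partner within 0.42-0.58 nm (ideal sheet spacing 0.48 nm).
  All thresholds are configurable and validated on ideal-geometry
  fixtures.
* **Registry**: strand-pair orientation comes from the sign of the dot
  product of strand direction vectors (|cos| < 0.3, near-perpendicular,
  is "other").  Residue pairing maps each L1/V2/F3/F4 residue to its
  nearest cross-strand Calpha among the partner's L1VFF4 residues.  A
  pair is amyloid-registered only if the map matches the in-register
  parallel template (L1-L1, V2-V2, F3-F3, F4-F4) or the in-register
  antiparallel template (L1-F4, V2-F3, F3-V2, F4-L1) exactly;
  single-residue shifts classify as "other".  Classification is
  symmetric in its arguments; strands with fewer than 3 template
  residues are "unclassifiable" (distinct from "other").
* **Fractions**: the beta fraction is strand residues over cluster
  residues; amyloid / parallel / antiparallel fractions are per
  classified strand pair, frame-weighted by cluster size (per-residue
  and per-pair denominators are both available since the appropriate
  denominator is a modelling choice).  Zero classified pairs yield
  zero fractions with an explicit flag.

## Fixtures

All generators are pure functions of their arguments (bit-reproducible
per seed).  The 12 side-chain analogs (Leu, Val, Cys, Ser, Asn, Gln,
Glu, Arg, Lys, His, Phe, Trp) enumerate into 144 *ordered* dimers — each
heterodimer appears twice with resolutions swapped — in a 3 x 4 x 3 nm
box; their per-analog eps/sigma/charge/mass values are synthetic
surrogates ordered plausibly by hydrophobicity and size, not a published
force field, and the toy boxes contain no explicit solvent (solvent
effects are implicit in the effective pair parameters).  The coil
backbone bead alias (`BB_P5` -> Asn side-chain parameters) is honoured
by the table reader.  The beta-sheet builder uses 0.35 nm intra-strand
and 0.48 nm inter-strand spacing so the detection thresholds hold with
margin, and constructs parallel, antiparallel and shifted registries
exactly.  The micelle toy packs two-bead amphiphiles (sticky UA tail,
eps 6.0 kJ/mol; weak charged CG head, +1 e) at moderate density in a
4 nm box; under Langevin relaxation the tails nucleate a core and the
charged heads form a corona, measured by the radial ordering statistic
(mean head distance minus mean tail distance from the largest cluster's
COM, time-averaged over the second half of the run because single
frames are too noisy for the symmetry control).  With zero head charge
and equal well depths the two species are exchangeable and the
statistic vanishes in expectation — the control for the core-corona
claim.

## Problem sizes

The validation suite runs at desk scale by design: dimers and ~10-bead
chains for sampling checks, 16-amphiphile boxes for the micelle
property, 8-20 umbrella windows with 10^3-10^4 Metropolis samples each,
and 20-seed synthetic ensembles for the kinetics fitters.  These sizes
make every property testable in seconds to minutes while leaving the
algorithms identical to what larger systems would use.

## Known limitations

* The micro- to millisecond observables of real condensate simulations
  (droplet formation, cluster coalescence kinetics, beta-sheet onset
  sizes, registry statistics of real peptides) are far beyond the toy
  samplers; the analysis suite is validated on constructed and synthetic
  inputs with known answers instead.
* No Ewald electrostatics, no barostat, no constraint algorithms, no
  water models; reaction field plus a single cutoff only.
* The WHAM implementation provides no bootstrap error bars yet (per-bin
  counts are retained in the data model as the hook).
* The geometric beta-strand criterion is a stand-in for H-bond-based
  assignment and is only validated on ideal geometry; real, thermalised
  strands near the thresholds will classify noisily.
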