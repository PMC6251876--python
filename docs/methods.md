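# Methods

This note documents the model, its parameters, the numerical choices, and the
limits of what the synthetic test systems can demonstrate.

## Coordinate frame and units

Energies are kcal/mol, lengths Å, time fs, masses Da, temperatures K
(k_B = 0.0019872041 kcal/mol/K; 1 pN·Å = 0.0143932 kcal/mol; 1 kcal/mol =
4.184×10⁻⁴ Da·Å²/fs²). The membrane normal is the z-axis with the bilayer
midplane at z = 0 and the hydrophobic slab spanning −15 Å < z < 15 Å.

## Bead model and native topology

Each residue contributes a Cα bead and, for non-glycine residues, a Cβ bead;
glycine's interaction site is its Cα, the standard coarse-grained convention.
The native topology retains all bead pairs (Cα–Cα, Cα–Cβ, Cβ–Cβ) whose native
distance is below r_c = 7 Å and whose residue separation is at least
s_min = 3. The floor excludes pairs already governed by the bonded terms; its
value is a package decision (surfaced in `SBMParams`), as is the Cα/Cβ-only
bead set. Contact widths follow σ_ij = |i−j|^0.15 Å and weights γ_ij are 1.0
for |i−j| < 5 and 0.5 otherwise, so local (helical) contacts are strengthened
relative to nonlocal ones — with the deliberate consequence that helices stay
formed while tertiary structure unfolds. Contact strengths carry no
z-dependence: helices do not become easier to unravel outside the membrane,
which means highly extended states have smaller end-to-end distances than a
helix-to-coil transition would produce. This is a known limitation, not a
target of the model.

## Contact potential

V_AMH-Go = −(1/2) Σ_i |E_i|^p with E_i = Σ_j ε_ij(r_ij) and

ε_ij(r) = −|ε/a|^{1/p} Θ(r_c − r_ij^N) γ_ij exp[−(r − r_ij^N)²/(2σ_ij²)].

The normalization a = (1/8N) Σ_i |Σ_j γ_ij Θ(r_c − r_ij^N)|^p makes the
native-state energy exactly −4Nε for any topology with at least one contact
(each pair enters the E_i of both its beads; the identity is an algebraic
consequence and is verified numerically in the tests). Defaults: ε = 0.8
kcal/mol, p = 1 (pairwise additive; the |E_i|^p machinery is implemented
generally but exercised at p = 1). An empty contact set is an error because
the well depths divide by a.

## Backbone terms

The backbone potential is a set of generic substitutes referenced to the
native geometry, each zero at the native structure:

- **V_con** — harmonic Cα(i)–Cα(i+1) and Cα–Cβ bonds at native lengths,
  k_bond = 100 kcal/mol/Å².
- **V_chain** — harmonic pseudo-angles on cos θ at native values,
  k_angle = 20 kcal/mol.
- **V_χ** — a chirality restraint on the scalar triple product
  [(Cα_{i+1}−Cα_i) × (Cα_{i−1}−Cα_i)] · (Cβ_i−Cα_i), normalized by its
  native magnitude, k_chi = 5 kcal/mol; fixes Cβ handedness.
- **V_rama** — a dihedral bias k_rama (1 − cos(φ − φ⁰)) on the Cα
  pseudo-dihedral of residues assigned helix in the input secondary
  structure, φ⁰ taken from the native structure; k_rama = 2 kcal/mol. This is
  how the input secondary-structure string enters the model.
- **V_excl** — soft-sphere repulsion k_excl (r_ex − r)² for r < r_ex = 4 Å
  between bead pairs with residue separation ≥ s_min that are not native
  contacts, k_excl = 20 kcal/mol/Å².

Stiffnesses are configuration values; the defaults keep helices intact
through tertiary unfolding at low force and are stable at the 5 fs timestep.
All forces are analytic and validated against central differences (h = 10⁻⁵ Å,
relative tolerance 10⁻⁴) in the test suite.

## Implicit bilayer

Every membrane term is modulated by the switching envelope
Θ(z, z_m) = ½tanh[k_m(z + z_m)] + ½tanh[k_m(z_m − z)], k_m = 0.2 Å⁻¹, which
is ≈1 deep inside the slab, 0.5 at |z| = z_m, and →0 outside.

- **Burial** (z_m = 15 Å, k_burial = 1): Σ_i A(σ_i) Θ(z_i) over the Cα
  z-coordinates of *all* residues, with A the water-octanol transfer free
  energies (kcal/mol) shipped in `data/burial_scale.csv` keyed by one- and
  three-letter codes (e.g. Trp −2.09, Leu −1.25, Asp +3.64). Hydrophobic
  residues are stabilized inside the membrane.
- **Orientation** (z_m = 12 Å, k_orientation = 0.1 kcal/mol/Å²): for each
  transmembrane helix, the switched cylindrical radius of gyration
  R_g² = Σ_i m_i (r_i − r_cm)² Θ(z_i) / Σ_i m_i with r_i = √(x_i²+y_i²) the
  lab-frame radial coordinate, equal Cα masses, and the unswitched total mass
  in the denominator. The radial-coordinate form is implemented literally
  (differences of scalar radii, not planar distances). A consequence worth
  knowing: the term is invariant under rotation about z but *not* under x–y
  translation for tilted helices; a vertical straight helix has R_g ≈ 0
  wherever it stands. The z_m = 12 Å half-width lets a helix lie flat on the
  interface, penetrating ~3 Å, without a large penalty. Interfacial
  (non-transmembrane) helices are excluded from this term and the next.
- **Helix pair** (z_m = 15 Å on each helix COM z, k_helix_pair = 0.5
  kcal/mol): k Σ_{i<j} f(r_ij) Θ(z_i) Θ(z_j) with r_ij the distance between
  helix Cα centers of mass and f the quintic
  f(r) = −3.7673e−6 r⁵ + 6.0103e−4 r⁴ − 3.4889e−2 r³ + 8.9378e−1 r² −
  9.4119 r + 26.745 (kcal/mol), a fit to lipid-mediated interactions of 5 Å
  cylindrical inclusions in a DMPC bilayer. The printed polynomial diverges at
  large r and the source data covers short/intermediate separations, so f is
  evaluated up to 30 Å and ramped linearly to zero over 30–32 Å (0 beyond);
  the ramp keeps the energy continuous, with a documented derivative kink at
  the two edges. Note the polynomial as printed is *attractive*
  (negative) over ≈4.4–18.7 Å and repulsive only beyond ≈18.7 Å; prose
  descriptions of this interaction as repulsive at 10–25 Å do not match the
  printed coefficients, which are implemented verbatim rather than "fixed".

## Sampling

Dynamics is BAOAB Langevin with a 5 fs timestep, friction γ = 1/(10 000 fs),
and uniform 110 Da bead masses (the mass choice is the package's; an average
residue mass). Frames and an energy breakdown are saved every `save_every`
steps (default 4000). Umbrella sampling biases the end-to-end distance D
(terminal Cα pair) with U = k_d (D − D₀)², k_d = 0.02 kcal/mol/Å², plus
z-only tethers k_z (z − z_c)² on each terminus with k_z = 0.1 kcal/mol/Å²,
z_c = −17 Å. The **harmonic convention carries no ½ factor**; a wrong factor
of two would silently distort the reweighting, so the convention is a config
switch (`half_factor`) recorded in run metadata. A constant pulling force
enters as −k_force·D (1 pN = 0.0143932 kcal/mol/Å). The production window
schedule is 40–112 Å in 2 Å steps plus 118–340 Å in 6 Å steps — 75 centers as
printed, although the accompanying prose counts "seventy" simulations; the
generator follows the printed ranges. Temperature replica exchange uses the
12-rung ladder 300, 335, 373, 417, 465, 519, 579, 645, 720, 803, 896, 1000 K,
attempting adjacent-pair configuration swaps every 4000 steps with the
Metropolis rule min(1, exp[(β_i − β_j)(E_i − E_j)]), alternating even and odd
pairs; z-tethers are assumed active in all windows and rungs.

## Free-energy analysis

Frames pooled across windows and temperatures (the leading equilibration
fraction, default 3/4, is discarded — mirroring analysis of the final quarter
of production runs at 373 K) are combined with MBAR. The estimator is
implemented in `memfold.mbar` as the standard convex-objective solver with
analytic gradient plus self-consistent polish; it is validated against
analytic harmonic-umbrella free energies (< 0.1 kT RMS) and constructed
double-well gaps. Target states may rescale the contact energies of pairs
whose residues both lie in a chosen window (default boost 1.2×, i.e. +20%)
— the perturbation acts on stored pair-energy partial sums; the
normalization a is *not* recomputed — and/or add the −k_force·D tilt.

F(D, Z) grids use 2 Å × 0.5 Å bins by default (configurable; the desk-scale
toy runs use coarser 4 Å × 2 Å bins), F = −ln Σ w per bin shifted so the
global minimum is 0 (the zero is the global minimum, not the native bin), and
empty bins are masked unreachable rather than capped. Minimum-free-energy
paths are Dijkstra on the 8-connected bin lattice with node weights e^F
(relative to the grid minimum, avoiding overflow) and edge weights the mean
of the two node weights; ties resolve deterministically through the ordered
adjacency construction, and path cost is the quantity checked against
independent solvers. Representative structures of a (D, Z) region are the n
lowest-potential-energy frames in the box, superposed by least-squares
rigid-body fit on Cα (an ordinary Kabsch fit; for single-chain,
circular-permutation-free structures this matches more elaborate alignment
schemes).

Reporting temperature for kT defaults to 373 K, the analysis temperature;
the reduced-unit analytic toys use k_B·T = 1. Low/high-force presets are
defined operationally: k_force is scanned until the lowest nonnative basin
sits ≈6.5 kT above the native basin (low force) or extended states sit
≈10 kT below it (high force).

## Synthetic test systems

The fixture generators define the package's study conditions:

- **Ideal helices** — rise 1.5 Å/residue, radius 2.3 Å, 100°/residue turn;
  Cβ beads 1.5 Å radially outward.
- **Toy hairpin** — 45 residues by default: two antiparallel 19-residue
  poly-Leu transmembrane helices at 10 Å axis separation joined by a 7-residue
  polar G/N/S loop arcing over the interface; ≈360 native contacts. Sized so
  a full umbrella + replica-exchange + MBAR smoke test (3 windows at D = 15,
  30, 45 Å × 2 temperatures × 10⁵ steps) runs in minutes on one CPU. The
  desk-scale runs use a denser save interval (250 steps) than production so
  the reweighting has enough frames.
- **Analytic umbrella ensembles** — exact Boltzmann samples (fine-grid
  inverse-CDF with in-cell jitter) from declared 1-D potentials under each
  window bias, with the true free-energy curve attached as metadata. The 2-D
  two-basin variant is a quartic double well in D (exactly known saddle
  height) times a Gaussian channel in Z whose center slides between an
  "inserted" and an "interface" level on the extended-basin flank — placed
  away from the saddle so that binning does not smear the barrier.
- **Toy grids** — hand-built F(D, Z) surfaces with walls, gaps, and wells for
  validating the path search against exhaustive enumeration.

What passing these tests shows — and does not. The analytic ensembles verify
the estimator stack (MBAR, binning, path search) end to end against known
truth; the hairpin run verifies that the physical pipeline produces a
connected, two-region landscape with the folded-inserted state as the global
minimum and a path to the extended interface states. None of this
demonstrates quantitative barrier heights for a real protein: those depend on
parameterization of the membrane terms and on cluster-scale sampling (tens of
windows × 12 temperatures × 10⁷–10⁸ steps), far beyond the desk-scale runs
exercised here.

## Numerical choices and degenerate inputs

- MBAR convergence: L-BFGS on the convex objective, then self-consistent
  iteration to 10⁻⁹ relative; non-overlapping states surface as a convergence
  error advising on window spacing.
- Normalization a is cached per topology; mutating contact weights in place
  after an energy call and reusing the same topology object is not supported
  (rebuild or use `rescaled_params`).
- Chirality restraints with vanishing native triple product (collinear
  backbone) are dropped at construction.
- Grids degenerate to a single occupied bin raise; unreachable path
  endpoints raise with the offending bin named.
- Langevin runs abort with the step number if |V| exceeds a configurable
  blow-up threshold; same-seed runs are bitwise reproducible, and replica
  exchange derives per-replica streams from one master seed.
- Trajectory formats: multi-model PDB (CA/CB records, author numbering,
  10⁻³ Å precision) for interoperability, NPZ for lossless runtime storage;
  energy tables are CSV written at full float precision so cached pipeline
  reruns are bit-identical.
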