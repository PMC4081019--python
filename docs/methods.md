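# Methods

## The model

`ubscape` implements a two-bead coarse-grained "flexible binding" model
for dimeric ubiquitin (diUb).  Each of the 76 residues of a ubiquitin
unit is represented by a backbone bead at the C-alpha position and, for
non-glycine residues, a sidechain bead at the centre of mass of the
sidechain heavy atoms (146 beads per monomer, 292 per dimer).  The
Hamiltonian splits into a folding part and a binding part:

    H = V_folding + V_binding

**V_folding** is a structure-based (Go-like) potential defined by a
reference monomer structure: harmonic bonds `k_b (r - r0)^2` along the
backbone and from each backbone bead to its sidechain bead, harmonic
angles, a cosine dihedral series `k1 (1 - cos(phi - phi0)) +
k3 (1 - cos 3(phi - phi0))` on backbone quadruples, sidechain
orientation terms (one angle plus one improper dihedral per sidechain),
a 12-10 well `eps_c [5 (rn/r)^12 - 6 (rn/r)^10]` for every native
contact, and a truncated-shifted `(sigma/r)^12` repulsion between all
remaining pairs further than three bonds apart on the bond graph.
Native contacts are residue pairs at sequence separation >= 3 with any
heavy-atom pair within 4.5 A, realised between the coarse-grained beads
of the touching groups (CA-CA, CA-SC, SC-SC), each storing its native
bead distance.  Contact and backbone-dihedral strengths are rescaled at
fixed combined total so that their summed strengths sit at a 2:1 ratio —
the stability/flexibility balance conventional for structure-based
models; the ratio, like every force constant, is exposed in
`TopologyParams` / `ForceFieldParams`.

**V_binding** acts only between the two monomers:

* Debye-Hueckel electrostatics between charged sidechain beads,
  `f q_i q_j exp(-r/lambda_D) / (eps_r r)` with `f = 138.935` epsilon nm
  /e^2, dielectric `eps_r = 80`, and the screening length computed from
  the salt concentration (0.1 M monovalent salt at 298 K gives
  lambda_D ~ 10 A).  Charges follow pH 7: +1 Lys/Arg, -1 Asp/Glu, +0.5
  His (configurable), backbone beads and termini neutral.  The sum is
  truncated with a potential shift at 3 lambda_D.
* a hydrophobic attraction between sidechain beads,
  `-lambda_HP eps_ij s(r)` with the switching function
  `s(r) = [1 + tanh(C (r0 - r))]/2`, optimum `r0 = 8.0 A`, width
  `C = 1.0 per A`, and overall scale `lambda_HP = 0.92`.  The pair
  strengths `eps_ij` derive from the Miyazawa-Jernigan contact-energy
  table (1996 revision, Table V upper triangle; its most attractive
  entry is e(L,F) = -7.37) through
  `eps_ij = clamp_[0,1]((ebar + alpha (e_ij - ebar)) / (2 ebar))` with
  `alpha = 1` (sequence-flavoured) and `ebar = -3.7`, zeroing any
  non-negative raw entry so charged-pair effects are not double-counted
  against the DH term.
* for a covalently linked dimer, exactly one harmonic linkage bond:
  distal G76 backbone bead to the proximal lysine sidechain bead
  (isopeptide, r0 = 0.40 nm; K6/K11/K27/K29/K33/K48/K63) or to the
  proximal M1 backbone bead (peptide, r0 = 0.38 nm; linear chains).
  The "free" model is the same two-monomer system without this bond.

## Units

Lengths are nm, energies are native-contact units epsilon (nominally
kJ/mol), charges elementary.  `k_B = 0.00831451` energy per temperature
unit, so the working reduced temperature T = 50 corresponds to
`k_B T = 0.416` epsilon.  Masses are uniform 1.0 (configurable).

## Sampling

A BAOAB-splitting Langevin integrator samples the model at T = 50 with
time step 0.0005 and friction equal to the inverse thermostat coupling
time (1.0) — chosen for accurate configurational sampling at this step
size.  The effective protein concentration (default 5 mM) is realised
as a cubic periodic box, `side = (n / (c N_A))^(1/3)` (8.73 nm for two
molecules at 5 mM), with minimum-image convention on every displacement.
Production runs use eight independent replicas with distinct seeds and a
shared parameter set; every run is exactly reproducible from its seed,
checkpointable, and records per-frame energy terms.  Initial conditions
place two folded monomers at a random relative orientation — surface
separation 1 nm for the free model, linkage bond at its reference
length for linked models — followed by a capped gradient-descent
relaxation to remove placement clashes.  Velocities are
Maxwell-Boltzmann from the run seed.  A free monomer at T = 50 stays
folded (mean fraction of native contacts ~ 0.87 on the bundled
reference fold), consistent with the working temperature sitting below
the folding temperature.

## Analysis stack

Per-frame order parameters: the monomer centroid distance `d_com`
(unweighted over all beads); centroid distances between the I44
(L8, I44, V70) and I36 (L8, I36, L71, L73) hydrophobic surface patches,
with `d_I36I44` the minimum of the two cross pairings; the distal-M1 to
proximal-G76 backbone distance (the smFRET-like coordinate); and the
interfacial `E_elec` / `E_HP` decomposition taken directly from the two
binding terms of the Hamiltonian.  Before any inter-monomer geometry is
measured the proximal monomer is remapped to its periodic image nearest
the distal one.

Frames are classified by the precedence open -> closed -> I36-I36 ->
I36-I44 -> other-compact with cutoffs at the free-energy barrier tops:
open when `d_com >= 3.2` nm, closed when `d_I44I44 <= 0.86` nm,
I36-I36 when `d_I36I36 <= 0.96` nm (other interfaces unformed),
I36-I44 when `d_I36I44 <= 0.93` nm (I44-I44 unformed).  Populations are
averaged per replica with the standard deviation taken across replicas.
Free-energy surfaces are `-k_B T ln P` over binned order parameters,
shifted to a zero minimum, with empty bins flagged (never imputed);
distance axes default to 0.05 nm bins, RMSD axes to 0.025 nm.
Interfacial contact profiles count inter-monomer bead pairs within
0.8 nm (aligned with the hydrophobic optimum) over frames with
`d_com <= 3.2` nm, attributed per residue; the interface symmetry score
is the Pearson correlation of the distal and proximal profiles, and
"hot spots" are residues averaging more than one interfacial contact.
RMSD uses Kabsch superposition on backbone beads; RMSF superposes each
frame onto the iteratively refined mean structure.  The integrated
autocorrelation time (via the standard initial-sequence estimator) and
the ratio of series length to it serve as the convergence index.

Entropy-enthalpy decomposition bins an order parameter x into 50
equal-width bins and computes `F(x) = -k_B T ln P(x)`, `H(x)` as the
mean potential energy conditioned on x (both shifted by their minima),
and `TS = H - F`; the correlations rho_SF and rho_HF between the TS/H
and F curves are taken over bins with at least 10 samples and diagnose
whether a landscape difference is entropy- or enthalpy-driven.

The dissociation constant of the two-molecule system uses the declared
pairwise convention `Kd = ((1-Pb)^2/Pb) (n^2/(N_A V)) (1/n)`; a
mass-action variant (`[M]^2/[D]`, a factor 2 larger at n = 2) is
selectable, and Pb at 0 or 1 yields a one-sided bound.  The three-state
reconciliation maps a (open, closed, compact) vector onto the apparent
two-state readouts of closed-referenced and open-referenced experiments
(`1 - closed` and `1 - open` respectively), which shows how two
two-state analyses of the same multi-state system can disagree.  The
entropy cost of the topological constraint follows the Gaussian-chain
loop-closure form `P = (3/(2 pi N_eff b^2))^{3/2} (4 pi/3) I^3` with
N = 152 residues, constraint length I = 4.0 A, persistence length
b = 3.8 A and `N_eff = N/(m+1)` when m constraints are already present;
Delta S = k_B ln P.

## The synthetic reference structures

No experimental ubiquitin coordinates ship with the package, so
`synthetic_fixtures` provides generated inputs:

* a **synthetic ubiquitin monomer** — the real 76-residue sequence on an
  idealized fold reproducing the native secondary-structure topology:
  a five-stranded sheet in the native strand order
  beta2-beta1-beta5-beta3-beta4 (beta1 parallel to beta5, which places
  M1 next to the K63 loop), the alpha1 helix packed above the sheet, a
  3-10 turn, and a flexible C-terminal tail.  Strands and loops carry a
  small pleat so no backbone triple is collinear.  Sidechains point off
  the sheet faces/helix surface, with the I44/I36 patch residues on one
  face.  This stand-in preserves bead counts, charges, linkage-site
  topology and patch definitions, but not crystallographic geometry:
  quantitative populations measured on it characterise the method, not
  experimental ubiquitin, and per-state numbers (in particular the
  closed-state geometry, which depends on exact surface
  complementarity) should not be compared digit-for-digit with
  measurements on the real protein.
* a **miniature two-domain dimer** (12-residue beta-hairpin domains,
  exact isometric copies facing each other) whose native conformation is
  the minimum of its own generated topology — the primary fixture for
  energetics and integrator tests;
* **state-mixture trajectories** that place patch centroids (not full
  interfaces) at distances provably satisfying the classification
  rules, with exact multinomial counts and ground-truth labels;
* a **harmonic two-bead fixture** with the closed-form bond-length
  variance `k_B T/(2k)` for integrator acceptance tests.

## Problem sizes

The bundled test suite and the reproduction script run scaled-down
surveys — typically 3-4 replicas of 60,000-100,000 steps per linkage
model — sized for a desk-class single CPU.  At this scale individual
replicas hold only a handful of binding/unbinding transitions, so
per-replica state fractions fluctuate strongly; aggregated contrasts
(e.g. linear/K63-linked chains sampling more open conformations than
K11-linked ones) are reproducible, while precise population percentages
require production-scale sampling (eight long replicas per model).

## Known limitations

* The synthetic fold approximates ubiquitin topology only; interface
  geometries that depend on atomic packing (the closed I44-I44 state)
  are under-represented on it.
* No replica exchange or reweighting; single-temperature sampling only.
* No explicit solvent or pH machinery: pH enters only through the fixed
  charge set.
* Chains longer than two units are out of scope; the linkage machinery
  supports exactly one inter-monomer bond.
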