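# ubscape

Coarse-grained binding landscapes of ubiquitin dimers.

Polyubiquitin chains encode distinct cellular signals through eight
covalent linkage topologies: the C-terminal G76 of one ubiquitin (Ub)
unit bonds to one of the seven lysines (K6, K11, K27, K29, K33, K48,
K63) or to the N-terminal M1 of another.  `ubscape` implements a
two-bead "flexible binding" model for the minimal chain, the diUb dimer,
and the analysis stack needed to map how linkage topology reshapes its
conformational landscape.  It is aimed at computational structural
biologists who want a fast, fully reproducible testbed for
linkage-dependent protein-protein landscapes.

The Hamiltonian is

    H = V_folding + V_binding

where `V_folding` is a structure-based (Go-like) potential that keeps
each 146-bead Ub unit near its reference fold (bonds, angles, cosine
dihedrals, 12-10 native-contact wells, excluded volume), and
`V_binding` acts only between units: Debye-Hückel screened
electrostatics between charged sidechain beads
(`f q_i q_j e^{-r/λ_D}/(ε_r r)`, ε_r = 80, λ_D ≈ 10 Å at 0.1 M salt),
a Miyazawa–Jernigan-derived hydrophobic attraction between sidechain
beads (`-λ_HP ε_ij [1 + tanh(C(r_0 - r))]/2`, λ_HP = 0.92, r_0 = 8 Å),
and — for linked chains — a single harmonic isopeptide (r_0 = 0.40 nm)
or peptide (r_0 = 0.38 nm) bond.  Sampling is BAOAB Langevin dynamics at
reduced temperature T = 50 in a periodic box sized to the working
protein concentration (5 mM), with independent seeded replicas.
Trajectories are classified into open / closed / compact states (the
compact state subdivided by which hydrophobic patches, I44 = {L8, I44,
V70} or I36 = {L8, I36, L71, L73}, meet across the interface), and the
stack computes free-energy surfaces, interfacial contact profiles and
symmetry scores, entropy–enthalpy decompositions, dissociation
constants and loop-closure entropies.  See `docs/methods.md` for the
full model description.

No experimental coordinates ship with the package: a synthetic
ubiquitin stand-in (real sequence, idealized native-topology fold) and
a miniature two-domain dimer are generated by `ubscape.synthetic_fixtures`,
so everything runs without downloads.  Results on the stand-in
characterise the method, not crystallographic ubiquitin.

## Worked example

```python
import numpy as np
from ubscape.pipeline import run_linkage_model

res = run_linkage_model("K48", steps=60000, n_replicas=3, seed_base=100)
p = res.populations
print(f"open    {p.fractions['open']:5.1f} % (SD {p.sd['open']:.1f})")
print(f"closed  {p.fractions['closed']:5.1f} %")
print(f"compact {p.compact:5.1f} %")
print(f"interfacial E_HP {res.mean_e_hp:6.2f}  E_elec {res.mean_e_elec:6.2f}")
print(f"interface symmetry score {res.symmetry:5.2f}")
```

prints (seed 100, synthetic stand-in):

```
open     29.7 % (SD 24.4)
closed    0.0 %
compact  70.3 %
interfacial E_HP -14.11  E_elec  -1.53
interface symmetry score -0.18
```

Reading: at this desk scale the K48-linked dimer spends about two
thirds of its time in compact (interface-formed) conformations, its
interface is stabilised by the hydrophobic term (E_HP in native-contact
energy units, ~0.4 kJ/mol-equivalent each), and the covalent linkage
breaks the distal/proximal symmetry of the interfacial contact profile
(score well below 1).  The large between-replica SD is expected: each
short replica holds only a few binding/unbinding transitions, and the
closed (I44-I44) state requires surface complementarity the synthetic
fold does not possess.

The same machinery is scriptable from the shell:

```
ubscape build --linkage K48 -o k48.json
ubscape simulate --topology k48.json --replicas 8 --steps 60000 --seed-base 1000 --out runs/
ubscape analyze  --topology k48.json --traj runs/ --out tables/
ubscape states   --topology k48.json --traj runs/ --out states.tsv
ubscape report   --states-tsv states.tsv --out report.json
```

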