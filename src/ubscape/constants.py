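"""Physical constants, amino-acid data and the Miyazawa-Jernigan contact table.

Internal unit system (the "reduced" convention of coarse-grained
structure-based models):

* length  : nm
* energy  : epsilon, the native-contact energy unit (nominally 1 kJ/mol)
* k_B     : 0.00831451 epsilon per temperature unit, so that a reduced
            temperature T = 50 corresponds to k_B T = 0.4157 epsilon
* charge  : elementary charge e

With epsilon identified with kJ/mol, the Coulomb prefactor is
f = 138.935485 epsilon nm / e^2.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant in reduced energy per reduced temperature unit.
KB = 0.00831451

#: Coulomb prefactor e^2/(4 pi eps0) in epsilon*nm (epsilon == kJ/mol).
COULOMB_PREFACTOR = 138.935485

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214076e23

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Sidechain charges at neutral pH 7 (His is configurable, default +0.5).
DEFAULT_HIS_CHARGE = 0.5
SIDECHAIN_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

#: Human/yeast ubiquitin sequence, 76 residues (6 glycines -> 146 beads).
UBIQUITIN_SEQUENCE = (
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGKQLEDGRTLSDYNIQKESTLHLVLRLRGG"
)

#: Residue ordering of the contact-energy table below.
MJ_RESIDUE_ORDER = "CMFILVWYAGTSNQDEHRKP"

# Miyazawa-Jernigan inter-residue contact energies e_ij (1996 revision,
# Table V upper triangle, units of RT).  Stored as the upper triangle in
# the row order of MJ_RESIDUE_ORDER; symmetrized on load.  The most
# attractive entry is e(L,F) = -7.37.
_MJ_UPPER = [
    # C      M      F      I      L      V      W      Y      A      G      T      S      N      Q      D      E      H      R      K      P
    [-5.44, -4.99, -5.80, -5.50, -5.83, -4.96, -4.95, -4.16, -3.57, -3.16, -3.11, -2.86, -2.59, -2.85, -2.41, -2.27, -3.60, -2.57, -1.95, -3.07],
    [None, -5.46, -6.56, -6.02, -6.41, -5.32, -5.55, -4.91, -3.94, -3.39, -3.51, -3.03, -2.95, -3.30, -2.57, -2.89, -3.98, -3.12, -2.48, -3.45],
    [None, None, -7.26, -6.84, -7.37, -6.29, -6.16, -5.66, -4.81, -4.13, -4.28, -4.02, -3.75, -4.10, -3.48, -3.56, -4.77, -3.98, -3.36, -4.25],
    [None, None, None, -6.54, -7.04, -6.05, -5.78, -5.25, -4.58, -3.78, -4.03, -3.52, -3.24, -3.67, -3.17, -3.27, -4.14, -3.63, -3.01, -3.76],
    [None, None, None, None, -7.04, -6.48, -6.14, -5.67, -4.91, -4.16, -4.34, -3.92, -3.74, -4.04, -3.40, -3.59, -4.54, -4.03, -3.37, -4.20],
    [None, None, None, None, None, -5.52, -5.18, -4.62, -4.04, -3.38, -3.46, -3.05, -2.83, -3.07, -2.48, -2.67, -3.58, -3.07, -2.49, -3.32],
    [None, None, None, None, None, None, -5.06, -4.66, -3.82, -3.42, -3.22, -2.99, -3.07, -3.11, -2.84, -2.99, -3.98, -3.41, -2.69, -3.73],
    [None, None, None, None, None, None, None, -4.17, -3.36, -3.01, -3.01, -2.78, -2.76, -2.97, -2.76, -2.79, -3.52, -3.16, -2.60, -3.19],
    [None, None, None, None, None, None, None, None, -2.72, -2.31, -2.32, -2.01, -1.84, -1.89, -1.70, -1.51, -2.41, -1.83, -1.31, -2.03],
    [None, None, None, None, None, None, None, None, None, -2.24, -2.08, -1.82, -1.74, -1.66, -1.59, -1.22, -2.15, -1.72, -1.15, -1.87],
    [None, None, None, None, None, None, None, None, None, None, -2.12, -1.96, -1.88, -1.90, -1.80, -1.74, -2.42, -1.90, -1.31, -1.90],
    [None, None, None, None, None, None, None, None, None, None, None, -1.67, -1.58, -1.49, -1.63, -1.48, -2.11, -1.62, -1.05, -1.57],
    [None, None, None, None, None, None, None, None, None, None, None, None, -1.68, -1.71, -1.68, -1.51, -2.08, -1.64, -1.21, -1.53],
    [None, None, None, None, None, None, None, None, None, None, None, None, None, -1.54, -1.46, -1.42, -1.98, -1.80, -1.29, -1.73],
    [None, None, None, None, None, None, None, None, None, None, None, None, None, None, -1.21, -1.02, -2.32, -2.29, -1.68, -1.33],
    [None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, -0.91, -2.15, -2.27, -1.80, -1.26],
    [None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, -3.05, -2.16, -1.35, -2.25],
    [None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, -1.55, -0.59, -1.70],
    [None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, -0.12, -0.97],
    [None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, None, -1.75],
]


def mj_raw_table() -> np.ndarray:
    """Return the symmetric 20x20 MJ contact-energy table (RT units).

    Rows/columns follow :data:`MJ_RESIDUE_ORDER`.
    """
    m = np.zeros((20, 20))
    for i, row in enumerate(_MJ_UPPER):
        for j, v in enumerate(row):
            if v is not None:
                m[i, j] = v
                m[j, i] = v
    return m


#: Atom names treated as backbone in all-atom input.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})
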