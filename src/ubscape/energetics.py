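"""Hamiltonian of the flexible binding model: H = V_folding + V_binding.

V_folding is the structure-based part (bonds, angles, dihedrals, native
contacts, excluded-volume repulsion) that keeps each ubiquitin unit near
its folded basin.  V_binding acts only *between* monomers and consists of
Debye-Hueckel screened electrostatics between charged sidechain beads and
an MJ-derived hydrophobic attraction between sidechain beads, plus the
single covalent linkage bond when present.

The interfacial decomposition E_elec / E_HP reported throughout the
analysis stack is exactly the two binding terms of this Hamiltonian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import COULOMB_PREFACTOR, KB
from .model_builder import BeadModel, CGTopology, HydrophobicMatrix

__all__ = [
    "ForceFieldParams", "EnergyBreakdown", "EnergyModel",
    "debye_length", "elec_energy", "hp_energy", "sbm_energy",
    "total_energy", "forces",
]

# SI constants for the ionic-screening formula
_E_CHARGE = 1.602176634e-19
_EPS0 = 8.8541878128e-12
_KB_SI = 1.380649e-23
_NA = 6.02214076e23


def debye_length(concentration: float, eps_r: float = 80.0,
                 temperature_k: float = 298.0) -> float:
    """Debye screening length in Angstrom for a monovalent salt.

    kappa^-2 = eps0 eps_r kB T / (2 N_A e^2 I), I in mol/L.
    At 0.1 M, eps_r = 80, 298 K this is ~10 A.
    """
    if concentration <= 0:
        raise ValueError("salt concentration must be positive")
    ionic = concentration * 1000.0 * _NA  # ions per m^3 per species
    kappa2 = 2.0 * _E_CHARGE**2 * ionic / (_EPS0 * eps_r * _KB_SI * temperature_k)
    return 1.0 / np.sqrt(kappa2) * 1e10


@dataclass
class ForceFieldParams:
    """Non-bonded parameters of the binding potential (lengths in nm,
    energies in contact units epsilon)."""

    #: hydrophobic scale calibrated against the measured Ub-Ub affinity
    lambda_hp: float = 0.92
    #: optimal interfacial hydrophobic distance (8.0 A)
    r0_hp: float = 0.8
    #: switching steepness, 1.0 per Angstrom expressed in nm^-1
    c_switch: float = 10.0
    eps_r: float = 80.0
    salt_m: float = 0.1
    temperature_k: float = 298.0
    #: excluded-volume diameters by bead kind
    sigma_backbone: float = 0.40
    sigma_sidechain: float = 0.45
    rep_eps: float = 1.0
    rep_cutoff_factor: float = 2.5
    #: DH truncation (units of the Debye length)
    elec_cutoff_debye: float = 3.0
    k_B: float = KB

    @property
    def debye_length_nm(self) -> float:
        return debye_length(self.salt_m, self.eps_r, self.temperature_k) / 10.0

    @property
    def hp_cutoff(self) -> float:
        # where the switching function falls below 1e-4
        return self.r0_hp + np.arctanh(1.0 - 2e-4) / self.c_switch


@dataclass
class EnergyBreakdown:
    e_bond: float = 0.0
    e_angle: float = 0.0
    e_dihedral: float = 0.0
    e_contact: float = 0.0
    e_repulsive: float = 0.0
    e_link: float = 0.0
    e_elec: float = 0.0
    e_hp: float = 0.0

    @property
    def e_total(self) -> float:
        return (self.e_bond + self.e_angle + self.e_dihedral + self.e_contact
                + self.e_repulsive + self.e_link + self.e_elec + self.e_hp)

    @property
    def folding(self) -> float:
        return (self.e_bond + self.e_angle + self.e_dihedral
                + self.e_contact + self.e_repulsive)

    @property
    def binding(self) -> float:
        return self.e_elec + self.e_hp + self.e_link

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "EnergyBreakdown":
        return cls(e_bond=float(v[_kernels.E_BOND]), e_angle=float(v[_kernels.E_ANGLE]),
                   e_dihedral=float(v[_kernels.E_DIH]), e_contact=float(v[_kernels.E_CONTACT]),
                   e_repulsive=float(v[_kernels.E_REP]), e_link=float(v[_kernels.E_LINK]),
                   e_elec=float(v[_kernels.E_ELEC]), e_hp=float(v[_kernels.E_HP]))

    def as_dict(self) -> dict:
        return {
            "E_bond": self.e_bond, "E_angle": self.e_angle,
            "E_dihedral": self.e_dihedral, "E_contact": self.e_contact,
            "E_repulsive": self.e_repulsive, "E_link": self.e_link,
            "E_elec": self.e_elec, "E_HP": self.e_hp, "E_total": self.e_total,
        }


class EnergyModel:
    """Precompiled pair tables + kernel dispatch for one system.

    Builds, once, the index arrays for every interaction term of the
    Hamiltonian; ``energy``/``forces`` then evaluate any conformation of
    the same system.  ``box`` (cubic side, nm) activates minimum-image
    periodic boundary conditions.
    """

    def __init__(self, model: BeadModel, topology: CGTopology,
                 hp_matrix: HydrophobicMatrix | None = None,
                 params: ForceFieldParams | None = None,
                 box: float | None = None):
        self.model = model
        self.topology = topology
        self.params = params or ForceFieldParams()
        self.hp_matrix = hp_matrix
        self.box = 0.0 if box is None else float(box)
        self.use_pbc = box is not None
        self._build_tables()

    def _build_tables(self) -> None:
        topo = self.topology
        p = self.params
        n = topo.n_beads
        if n != len(self.model):
            raise ValueError("topology and model bead counts differ")
        kinds = self.model.kinds()
        mono = self.model.monomer_labels()
        q = self.model.charges()

        # pair bookkeeping as boolean matrices (systems are small)
        excluded = np.zeros((n, n), bool)
        for i, j in topo.exclusions:
            excluded[i, j] = excluded[j, i] = True
        in_contact = np.zeros((n, n), bool)
        for i, j in topo.contacts:
            in_contact[i, j] = in_contact[j, i] = True

        iu, ju = np.triu_indices(n, k=1)
        free = ~excluded[iu, ju] & ~in_contact[iu, ju]
        self._rep = np.stack([iu[free], ju[free]], axis=1).astype(np.int64)
        sig = np.where(kinds == 0, p.sigma_backbone, p.sigma_sidechain)
        self._rep_sig = 0.5 * (sig[self._rep[:, 0]] + sig[self._rep[:, 1]])

        inter = (mono[iu] != mono[ju]) & ~excluded[iu, ju]
        elec_mask = inter & (q[iu] * q[ju] != 0.0)
        self._elec = np.stack([iu[elec_mask], ju[elec_mask]], axis=1).astype(np.int64)
        self._elec_qq = q[self._elec[:, 0]] * q[self._elec[:, 1]]

        hp_mask = inter & (kinds[iu] == 1) & (kinds[ju] == 1)
        hp_pairs = np.stack([iu[hp_mask], ju[hp_mask]], axis=1).astype(np.int64)
        if self.hp_matrix is not None and hp_pairs.size:
            types = self.model.res_types()
            order = self.hp_matrix.residue_order
            tidx = np.array([order.index(t) for t in types])
            eps_ij = self.hp_matrix.eps[tidx[hp_pairs[:, 0]], tidx[hp_pairs[:, 1]]]
            keep = eps_ij > 0
            hp_pairs = hp_pairs[keep]
            self._hp_eps = p.lambda_hp * eps_ij[keep]
        else:
            hp_pairs = np.zeros((0, 2), np.int64)
            self._hp_eps = np.zeros(0)
        self._hp = hp_pairs

        link = topo.linkage
        if link.type != "free":
            self._link = np.array([[link.donor, link.acceptor]], np.int64)
            self._link_r0 = np.array([link.r0_link])
            self._link_k = np.array([link.k_b])
        else:
            self._link = np.zeros((0, 2), np.int64)
            self._link_r0 = np.zeros(0)
            self._link_k = np.zeros(0)

    def _eval(self, xyz: np.ndarray):
        xyz = np.ascontiguousarray(xyz, dtype=np.float64)
        if xyz.shape != (self.topology.n_beads, 3):
            raise ValueError("conformation bead count mismatch")
        topo, p = self.topology, self.params
        f = np.zeros_like(xyz)
        e = _kernels.eval_all(
            xyz, self.box, self.use_pbc,
            topo.bonds.astype(np.int64), topo.bond_r0, topo.bond_k,
            topo.angles.astype(np.int64), topo.angle_t0, topo.angle_k,
            topo.dihedrals.astype(np.int64), topo.dih_p0, topo.dih_k1, topo.dih_k3,
            topo.contacts.astype(np.int64), topo.contact_rn, topo.contact_eps,
            self._rep, self._rep_sig, p.rep_eps, p.rep_cutoff_factor,
            self._link, self._link_r0, self._link_k,
            self._elec, self._elec_qq, COULOMB_PREFACTOR / p.eps_r,
            p.debye_length_nm, p.elec_cutoff_debye * p.debye_length_nm,
            self._hp, self._hp_eps, p.r0_hp, p.c_switch, p.hp_cutoff,
            f,
        )
        return EnergyBreakdown.from_vector(e), f

    def energy(self, xyz: np.ndarray) -> EnergyBreakdown:
        return self._eval(xyz)[0]

    def forces(self, xyz: np.ndarray):
        """Return (per-bead forces = -grad H, EnergyBreakdown)."""
        e, f = self._eval(xyz)
        return f, e


# ---------------------------------------------------------------------------
# standalone per-term evaluators (used by the analysis stack)
# ---------------------------------------------------------------------------

def _inter_pairs(model: BeadModel):
    mono = model.monomer_labels()
    idx0 = np.where(mono == 0)[0]
    idx1 = np.where(mono == 1)[0]
    return idx0, idx1


def elec_energy(model: BeadModel, params: ForceFieldParams | None = None,
                xyz: np.ndarray | None = None):
    """Inter-monomer Debye-Hueckel energy and per-pair terms.

    Pure pair sum without truncation — used as the interfacial E_elec
    observable; the simulation kernel applies the shifted cutoff.
    """
    params = params or ForceFieldParams()
    xyz = model.coords() if xyz is None else np.asarray(xyz)
    q = model.charges()
    idx0, idx1 = _inter_pairs(model)
    lam = params.debye_length_nm
    kq = COULOMB_PREFACTOR / params.eps_r
    terms = []
    total = 0.0
    for i in idx0:
        if q[i] == 0:
            continue
        for j in idx1:
            if q[j] == 0:
                continue
            r = float(np.linalg.norm(xyz[i] - xyz[j]))
            v = kq * q[i] * q[j] * np.exp(-r / lam) / r
            terms.append((int(i), int(j), v))
            total += v
    return total, terms


def hp_energy(model: BeadModel, matrix: HydrophobicMatrix,
              params: ForceFieldParams | None = None,
              xyz: np.ndarray | None = None):
    """Inter-monomer hydrophobic energy and per-pair terms.

    Pair term: -lambda_HP eps_ij s(r), s(r) = (1 + tanh(C (r0 - r)))/2.
    """
    params = params or ForceFieldParams()
    xyz = model.coords() if xyz is None else np.asarray(xyz)
    kinds = model.kinds()
    types = model.res_types()
    idx0, idx1 = _inter_pairs(model)
    terms = []
    total = 0.0
    for i in idx0:
        if kinds[i] != 1:
            continue
        for j in idx1:
            if kinds[j] != 1:
                continue
            eps = matrix.strength(types[i], types[j])
            if eps == 0.0:
                continue
            r = float(np.linalg.norm(xyz[i] - xyz[j]))
            s = 0.5 * (1.0 + np.tanh(params.c_switch * (params.r0_hp - r)))
            v = -params.lambda_hp * eps * s
            terms.append((int(i), int(j), v))
            total += v
    return total, terms


def sbm_energy(xyz: np.ndarray, model: BeadModel, topology: CGTopology,
               params: ForceFieldParams | None = None,
               box: float | None = None) -> EnergyBreakdown:
    """Folding (structure-based) terms only; binding fields left zero."""
    em = EnergyModel(model, topology, hp_matrix=None, params=params, box=box)
    e = em.energy(xyz)
    return EnergyBreakdown(e_bond=e.e_bond, e_angle=e.e_angle,
                           e_dihedral=e.e_dihedral, e_contact=e.e_contact,
                           e_repulsive=e.e_repulsive)


def total_energy(xyz: np.ndarray, model: BeadModel, topology: CGTopology,
                 hp_matrix: HydrophobicMatrix | None = None,
                 params: ForceFieldParams | None = None,
                 box: float | None = None) -> EnergyBreakdown:
    """Full Hamiltonian V_folding + V_binding with all fields populated."""
    return EnergyModel(model, topology, hp_matrix, params, box).energy(xyz)


def forces(xyz: np.ndarray, model: BeadModel, topology: CGTopology,
           hp_matrix: HydrophobicMatrix | None = None,
           params: ForceFieldParams | None = None,
           box: float | None = None):
    """Per-bead forces -grad H (and the energy breakdown)."""
    return EnergyModel(model, topology, hp_matrix, params, box).forces(xyz)
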