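"""Two-bead coarse-grained model construction for ubiquitin units.

Each residue is represented by a backbone bead at the C-alpha position and
(except glycine) a sidechain bead at the centre of mass of the sidechain
heavy atoms.  Interactions *within* a monomer are structure-based (bonds,
angles, dihedrals and a native-contact map taken from a reference
structure); interactions *between* monomers are physics-based and are
handled by :mod:`ubscape.energetics`.  A dimer is optionally closed by a
single harmonic linkage bond: an isopeptide bond from the distal G76
backbone bead to a proximal lysine sidechain bead (r0 = 0.40 nm) or a
peptide bond to the proximal M1 backbone bead (r0 = 0.38 nm).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .constants import (
    BACKBONE_ATOMS,
    DEFAULT_HIS_CHARGE,
    MJ_RESIDUE_ORDER,
    SIDECHAIN_CHARGE,
    THREE_TO_ONE,
    mj_raw_table,
)

TOPOLOGY_SCHEMA_VERSION = 1

#: The nine recognised linkage names.
LINKAGE_TYPES = ("free", "M1", "K6", "K11", "K27", "K29", "K33", "K48", "K63")

#: Linkage reference lengths in nm: isopeptide for the seven lysines,
#: peptide for the linear (M1) chain.
LINKAGE_R0 = {
    "M1": 0.38,
    **{k: 0.40 for k in ("K6", "K11", "K27", "K29", "K33", "K48", "K63")},
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ResidueRecord:
    """One residue of the all-atom input after altloc/het filtering."""

    chain_id: str
    res_index: int           # 1-based, as in the PDB file
    res_name: str            # 3-letter code
    #: list of (atom name, element, position in Angstrom, occupancy, altloc)
    atoms: list

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.res_name]

    def atom_position(self, name: str) -> np.ndarray:
        for a in self.atoms:
            if a[0] == name:
                return np.asarray(a[2], dtype=float)
        raise KeyError(f"residue {self.res_name}{self.res_index}: no atom {name!r}")

    def heavy_atoms(self, group: str) -> list:
        """Heavy atoms of the 'backbone' or 'sidechain' group."""
        out = []
        for a in self.atoms:
            if a[1] == "H":
                continue
            is_bb = a[0] in BACKBONE_ATOMS
            if (group == "backbone") == is_bb:
                out.append(a)
        return out


@dataclass
class Bead:
    monomer: str             # 'distal' or 'proximal'
    res_index: int           # 1..76 for ubiquitin
    kind: str                # 'backbone' or 'sidechain'
    position: np.ndarray     # nm
    mass: float = 1.0
    charge: float = 0.0
    res_type: str = "X"      # 1-letter code


@dataclass
class BeadModel:
    """Ordered bead list for one or two monomers.

    Ordering is deterministic: by monomer (distal before proximal), then
    residue index, backbone before sidechain.
    """

    beads: list
    n_monomers: int = 1
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.beads)

    def coords(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.beads), 3):
            raise ValueError("coordinate shape mismatch")
        for b, p in zip(self.beads, xyz):
            b.position = p.copy()

    # -- lookup helpers ----------------------------------------------------
    def index_of(self, monomer: str, res_index: int, kind: str) -> int:
        for i, b in enumerate(self.beads):
            if b.monomer == monomer and b.res_index == res_index and b.kind == kind:
                return i
        raise KeyError(f"no bead ({monomer}, {res_index}, {kind})")

    def monomer_labels(self) -> np.ndarray:
        """0 for distal/first monomer, 1 for proximal/second."""
        first = self.beads[0].monomer
        return np.array([0 if b.monomer == first else 1 for b in self.beads])

    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    def kinds(self) -> np.ndarray:
        return np.array([0 if b.kind == "backbone" else 1 for b in self.beads])

    def res_types(self) -> list:
        return [b.res_type for b in self.beads]

    def res_indices(self) -> np.ndarray:
        return np.array([b.res_index for b in self.beads])


@dataclass
class NativeContact:
    """Intra-monomer native contact between two beads (i < j)."""

    i: int
    j: int
    r_n: float               # native CG bead distance, nm
    eps: float = 1.0


@dataclass
class LinkageSpec:
    type: str = "free"
    donor: int = -1          # distal G76 backbone bead index
    acceptor: int = -1       # proximal Lys sidechain / M1 backbone bead index
    r0_link: float = 0.0     # nm
    k_b: float = 10000.0     # epsilon / nm^2


@dataclass
class HydrophobicMatrix:
    """MJ-derived hydrophobic strengths, normalised to [0, 1].

    eps[i, j] = clamp_[0,1]( (ebar + alpha (e_ij - ebar)) / (2 ebar) ),
    with entries whose transform is negative (raw e_ij >= 0) set to zero.
    With alpha = 1 this reduces to e_ij / (2 ebar).
    """

    eps: np.ndarray
    raw: np.ndarray
    ebar: float = -3.7
    alpha: float = 1.0
    residue_order: str = MJ_RESIDUE_ORDER

    def strength(self, a: str, b: str) -> float:
        ia = self.residue_order.index(a)
        ib = self.residue_order.index(b)
        return float(self.eps[ia, ib])

    def index_of(self, a: str) -> int:
        return self.residue_order.index(a)


@dataclass
class CGTopology:
    """Bonded terms, native contacts, linkage and exclusions of a CG model."""

    n_beads: int
    bonds: np.ndarray        # (nb, 2) int
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray       # (na, 3) int
    angle_t0: np.ndarray
    angle_k: np.ndarray
    dihedrals: np.ndarray    # (nd, 4) int
    dih_p0: np.ndarray
    dih_k1: np.ndarray       # coefficient of 1 - cos(phi - phi0)
    dih_k3: np.ndarray       # coefficient of 1 - cos(3 (phi - phi0))
    contacts: np.ndarray     # (nc, 2) int
    contact_rn: np.ndarray
    contact_eps: np.ndarray
    linkage: LinkageSpec = field(default_factory=LinkageSpec)
    exclusions: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        d = {
            "schema_version": TOPOLOGY_SCHEMA_VERSION,
            "n_beads": int(self.n_beads),
            "bonds": self.bonds.tolist(),
            "bond_r0": self.bond_r0.tolist(),
            "bond_k": self.bond_k.tolist(),
            "angles": self.angles.tolist(),
            "angle_t0": self.angle_t0.tolist(),
            "angle_k": self.angle_k.tolist(),
            "dihedrals": self.dihedrals.tolist(),
            "dih_p0": self.dih_p0.tolist(),
            "dih_k1": self.dih_k1.tolist(),
            "dih_k3": self.dih_k3.tolist(),
            "contacts": self.contacts.tolist(),
            "contact_rn": self.contact_rn.tolist(),
            "contact_eps": self.contact_eps.tolist(),
            "linkage": {
                "type": self.linkage.type,
                "donor": self.linkage.donor,
                "acceptor": self.linkage.acceptor,
                "r0_link": self.linkage.r0_link,
                "k_b": self.linkage.k_b,
            },
            "exclusions": self.exclusions.tolist(),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "CGTopology":
        d = json.loads(text)
        if d.get("schema_version") != TOPOLOGY_SCHEMA_VERSION:
            raise ValueError("unsupported topology schema version")
        link = LinkageSpec(**d["linkage"])
        arr = lambda k, dt: np.asarray(d[k], dtype=dt).reshape(-1) if np.ndim(d[k]) <= 1 else np.asarray(d[k], dtype=dt)

        def iarr(key, width):
            a = np.asarray(d[key], dtype=int)
            return a.reshape(-1, width) if a.size else np.zeros((0, width), int)

        return cls(
            n_beads=d["n_beads"],
            bonds=iarr("bonds", 2), bond_r0=arr("bond_r0", float), bond_k=arr("bond_k", float),
            angles=iarr("angles", 3), angle_t0=arr("angle_t0", float), angle_k=arr("angle_k", float),
            dihedrals=iarr("dihedrals", 4), dih_p0=arr("dih_p0", float),
            dih_k1=arr("dih_k1", float), dih_k3=arr("dih_k3", float),
            contacts=iarr("contacts", 2), contact_rn=arr("contact_rn", float),
            contact_eps=arr("contact_eps", float),
            linkage=link, exclusions=iarr("exclusions", 2),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CGTopology":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def parse_pdb(path) -> list:
    """Parse a PDB file into a list of :class:`ResidueRecord`.

    Waters and hetero residues are dropped; alternate locations are
    resolved by highest occupancy (ties keep the first, i.e. altloc 'A').
    """
    try:
        pdb_file = pdbio.PDBFile.read(path)
    except Exception as exc:
        raise IOError(f"cannot read PDB file {path!r}: {exc}") from exc
    try:
        atoms = pdb_file.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy"]
        )
    except Exception as exc:
        raise ValueError(f"no protein residues in {path!r}: {exc}") from exc
    atoms = atoms[struc.filter_amino_acids(atoms)]
    atoms = atoms[np.isin(atoms.res_name, list(THREE_TO_ONE))]
    if atoms.array_length() == 0:
        raise ValueError("no protein residues")

    residues: list = []
    for start in struc.get_residue_starts(atoms):
        mask = (
            (atoms.chain_id == atoms.chain_id[start])
            & (atoms.res_id == atoms.res_id[start])
        )
        sub = atoms[mask]
        names = list(sub.atom_name)
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom after altloc resolution in residue "
                f"{sub.res_name[0]}{int(sub.res_id[0])}"
            )
        rec = ResidueRecord(
            chain_id=str(sub.chain_id[0]),
            res_index=int(sub.res_id[0]),
            res_name=str(sub.res_name[0]),
            atoms=[
                (str(n), str(e), np.array(c, dtype=float), 1.0, "")
                for n, e, c in zip(sub.atom_name, sub.element, sub.coord)
            ],
        )
        if not np.all(np.isfinite([a[2] for a in rec.atoms])):
            raise ValueError(f"non-finite coordinates in residue {rec.res_index}")
        residues.append(rec)
    return residues


# ---------------------------------------------------------------------------
# coarse graining
# ---------------------------------------------------------------------------

def coarse_grain(residues: list, monomer: str = "distal") -> BeadModel:
    """Map all-atom residues onto the two-bead representation.

    The backbone bead sits on the C-alpha atom; the sidechain bead on the
    centre of mass of the sidechain heavy atoms (glycine has none).
    Positions are converted from Angstrom to nm.
    """
    beads: list = []
    for rec in residues:
        try:
            ca = rec.atom_position("CA")
        except KeyError as exc:
            raise ValueError(f"missing CA in residue {rec.res_index}") from exc
        one = rec.one_letter
        beads.append(Bead(monomer, rec.res_index, "backbone", ca / 10.0, res_type=one))
        if one == "G":
            continue
        sc = rec.heavy_atoms("sidechain")
        if not sc:
            warnings.warn(
                f"non-Gly residue {rec.res_name}{rec.res_index} has no sidechain "
                "heavy atoms; backbone bead only", stacklevel=2,
            )
            continue
        com = np.mean([a[2] for a in sc], axis=0)
        beads.append(Bead(monomer, rec.res_index, "sidechain", com / 10.0, res_type=one))
    return BeadModel(beads=beads, n_monomers=1)


def assign_charges(model: BeadModel, his_charge: float = DEFAULT_HIS_CHARGE) -> BeadModel:
    """Assign pH-7 charges: +1 Lys/Arg, -1 Asp/Glu, +q_His His (sidechain
    beads only; backbone beads and termini are uncharged)."""
    for b in model.beads:
        if b.kind != "sidechain":
            b.charge = 0.0
        elif b.res_type == "H":
            b.charge = his_charge
        else:
            b.charge = SIDECHAIN_CHARGE.get(b.res_type, 0.0)
    return model


# ---------------------------------------------------------------------------
# native contacts
# ---------------------------------------------------------------------------

def _cg_bead_position(rec: ResidueRecord, kind: str) -> np.ndarray:
    if kind == "backbone":
        return rec.atom_position("CA") / 10.0
    sc = rec.heavy_atoms("sidechain")
    return np.mean([a[2] for a in sc], axis=0) / 10.0


def _monomer_bead_index(residues: list, res_index: int, kind: str) -> int:
    """Bead index under the deterministic ordering (per monomer)."""
    idx = 0
    for rec in residues:
        has_sc = rec.one_letter != "G" and len(rec.heavy_atoms("sidechain")) > 0
        if rec.res_index == res_index:
            if kind == "backbone":
                return idx
            if not has_sc:
                raise KeyError(f"residue {res_index} has no sidechain bead")
            return idx + 1
        idx += 2 if has_sc else 1
    raise KeyError(f"residue {res_index} not found")


def detect_native_contacts(
    residues: list, cutoff: float = 4.5, min_seq_sep: int = 3
) -> list:
    """Detect native contacts from all-atom geometry.

    Residue pairs separated by at least ``min_seq_sep`` in sequence whose
    heavy-atom groups approach within ``cutoff`` (Angstrom) contribute a
    bead-pair contact (CA-CA, CA-SC or SC-SC, by which groups touch).  The
    contact stores the native CG bead distance in nm.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_seq_sep < 1:
        raise ValueError("sequence separation must be >= 1")
    contacts: list = []
    n = len(residues)
    groups = {}
    for rec in residues:
        groups[rec.res_index] = {
            "backbone": np.array([a[2] for a in rec.heavy_atoms("backbone")]),
            "sidechain": np.array([a[2] for a in rec.heavy_atoms("sidechain")]),
        }
    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = residues[a], residues[b]
            if abs(rb.res_index - ra.res_index) < min_seq_sep:
                continue
            for ga in ("backbone", "sidechain"):
                xa = groups[ra.res_index][ga]
                if xa.size == 0:
                    continue
                for gb in ("backbone", "sidechain"):
                    xb = groups[rb.res_index][gb]
                    if xb.size == 0:
                        continue
                    d2 = np.sum((xa[:, None, :] - xb[None, :, :]) ** 2, axis=-1)
                    if np.min(d2) <= cutoff**2:
                        pa = _cg_bead_position(ra, ga)
                        pb = _cg_bead_position(rb, gb)
                        i = _monomer_bead_index(residues, ra.res_index, ga)
                        j = _monomer_bead_index(residues, rb.res_index, gb)
                        i, j = (i, j) if i < j else (j, i)
                        contacts.append(
                            NativeContact(i, j, float(np.linalg.norm(pa - pb)), 1.0)
                        )
    return contacts


# ---------------------------------------------------------------------------
# hydrophobic matrix
# ---------------------------------------------------------------------------

def build_hydrophobic_matrix(
    raw: np.ndarray | None = None, alpha: float = 1.0, ebar: float = -3.7
) -> HydrophobicMatrix:
    """Normalise the raw MJ table into [0, 1] hydrophobic strengths."""
    if raw is None:
        raw = mj_raw_table()
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (20, 20) or not np.allclose(raw, raw.T):
        raise ValueError("raw MJ table must be a symmetric 20x20 matrix")
    if ebar == 0:
        raise ValueError("ebar must be nonzero")
    eps = (ebar + alpha * (raw - ebar)) / (2.0 * ebar)
    eps[raw >= 0] = 0.0
    eps = np.clip(eps, 0.0, 1.0)
    return HydrophobicMatrix(eps=eps, raw=raw, ebar=ebar, alpha=alpha)


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

@dataclass
class TopologyParams:
    """Force-constant conventions of the structure-based terms.

    Energies follow V = k (x - x0)^2 for bonds/angles (no 1/2), the
    standard cosine series for dihedrals, and a 12-10 well for contacts.
    ``contact_dihedral_ratio`` rescales contact strengths against backbone
    dihedral strengths at fixed combined total (stability vs flexibility
    balance of the folded unit).
    """

    k_bond: float = 10000.0          # epsilon / nm^2
    k_angle: float = 20.0            # epsilon / rad^2
    k_dihedral: float = 1.0          # epsilon (3-phi term gets 0.5 k)
    k_improper: float = 10.0         # sidechain orientation dihedral
    eps_contact: float = 1.0
    contact_dihedral_ratio: float = 2.0


def _merge_models(models: list) -> BeadModel:
    labels = ["distal", "proximal"]
    beads = []
    for m, lab in zip(models, labels):
        for b in m.beads:
            beads.append(replace(b, monomer=lab, position=np.array(b.position)))
    return BeadModel(beads=beads, n_monomers=len(models),
                     source_id="+".join(m.source_id for m in models))


def build_topology(
    models,
    linkage: str = "free",
    contacts: list | None = None,
    params: TopologyParams | None = None,
) -> tuple:
    """Build the structure-based topology for one monomer or a dimer.

    Parameters
    ----------
    models : BeadModel or list of BeadModel
        One monomer, or [distal, proximal].  Each monomer's bonded terms
        and native distances are measured from its own coordinates.
    linkage : str
        One of the nine linkage names.  Any non-free linkage requires two
        monomers and adds exactly one inter-monomer harmonic bond.
    contacts : list of NativeContact, optional
        Monomer contact map (bead indices local to one monomer).  If
        omitted an empty map is used (useful for toy systems).

    Returns
    -------
    (dimer_model, topology)
    """
    if linkage not in LINKAGE_TYPES:
        raise ValueError(
            f"unknown linkage {linkage!r}; valid values are {', '.join(LINKAGE_TYPES)}"
        )
    if isinstance(models, BeadModel):
        models = [models]
    if linkage != "free" and len(models) != 2:
        raise ValueError("a covalent linkage requires two monomers")
    params = params or TopologyParams()
    contacts = contacts or []

    model = _merge_models(models)
    xyz = model.coords()
    kinds = model.kinds()
    resid = model.res_indices()
    mono = model.monomer_labels()
    n = len(model)

    bonds, bond_r0, bond_k = [], [], []
    angles, angle_t0 = [], []
    dihedrals, dih_p0, dih_k1, dih_k3 = [], [], [], []
    all_contacts, c_rn, c_eps = [], [], []
    n_backbone_dih = 0

    offset = 0
    for m in models:
        nb = len(m)
        bb = [offset + i for i in range(nb) if kinds[offset + i] == 0]
        # backbone chain bonds
        for a, b in zip(bb[:-1], bb[1:]):
            bonds.append((a, b))
            bond_r0.append(np.linalg.norm(xyz[a] - xyz[b]))
            bond_k.append(params.k_bond)
        # backbone-sidechain bonds
        sc_of = {}
        for i in range(nb):
            gi = offset + i
            if kinds[gi] == 1:
                ca = offset + i - 1  # bb bead precedes its sc bead
                sc_of[resid[gi]] = gi
                bonds.append((ca, gi))
                bond_r0.append(np.linalg.norm(xyz[ca] - xyz[gi]))
                bond_k.append(params.k_bond)
        # backbone angles
        for a, b, c in zip(bb[:-2], bb[1:-1], bb[2:]):
            angles.append((a, b, c))
            angle_t0.append(_angle(xyz[a], xyz[b], xyz[c]))
        # sidechain orientation: angle + improper dihedral
        for k_res, sc in sc_of.items():
            ca = sc - 1
            pos = bb.index(ca)
            nb_prev = bb[pos - 1] if pos > 0 else None
            nb_next = bb[pos + 1] if pos + 1 < len(bb) else None
            anchor = nb_prev if nb_prev is not None else nb_next
            angles.append((anchor, ca, sc))
            angle_t0.append(_angle(xyz[anchor], xyz[ca], xyz[sc]))
            if nb_prev is not None and nb_next is not None:
                quad = (nb_prev, nb_next, ca, sc)
                dihedrals.append(quad)
                dih_p0.append(_dihedral(*(xyz[q] for q in quad)))
                dih_k1.append(params.k_improper)
                dih_k3.append(0.0)
        # backbone dihedrals
        for a, b, c, d in zip(bb[:-3], bb[1:-2], bb[2:-1], bb[3:]):
            dihedrals.append((a, b, c, d))
            dih_p0.append(_dihedral(xyz[a], xyz[b], xyz[c], xyz[d]))
            dih_k1.append(params.k_dihedral)
            dih_k3.append(0.5 * params.k_dihedral)
            n_backbone_dih += 1
        # native contacts (local indices -> global)
        for ct in contacts:
            all_contacts.append((offset + ct.i, offset + ct.j))
            c_rn.append(ct.r_n)
            c_eps.append(ct.eps * params.eps_contact)
        offset += nb

    # contact/dihedral rescaling: fixed contact:backbone-dihedral strength
    # ratio at fixed combined total
    sum_c = float(np.sum(c_eps))
    sum_d = n_backbone_dih * params.k_dihedral
    if sum_c > 0 and sum_d > 0:
        total = sum_c + sum_d
        R = params.contact_dihedral_ratio
        fc = (R / (1.0 + R)) * total / sum_c
        fd = (1.0 / (1.0 + R)) * total / sum_d
        c_eps = [e * fc for e in c_eps]
        for i in range(len(dihedrals)):
            if dih_k3[i] > 0:  # backbone dihedrals carry the 3-phi term
                dih_k1[i] *= fd
                dih_k3[i] *= fd

    # linkage bond
    link = LinkageSpec(type=linkage)
    if linkage != "free":
        donor = model.index_of("distal", max(resid[mono == 0]), "backbone")
        if linkage == "M1":
            acceptor = model.index_of("proximal", 1, "backbone")
        else:
            k_res = int(linkage[1:])
            acceptor = model.index_of("proximal", k_res, "sidechain")
        link = LinkageSpec(
            type=linkage, donor=donor, acceptor=acceptor,
            r0_link=LINKAGE_R0[linkage], k_b=params.k_bond,
        )

    # exclusions: all pairs within three bonds on the bond graph (the
    # standard 1-2/1-3/1-4 non-bonded exclusion), linkage bond included
    adj = [[] for _ in range(n)]
    all_bonds = list(bonds)
    if link.type != "free":
        all_bonds.append((link.donor, link.acceptor))
    for a, b in all_bonds:
        adj[a].append(b)
        adj[b].append(a)
    excl = set()
    for start in range(n):
        seen = {start: 0}
        frontier = [start]
        for depth in (1, 2, 3):
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in seen:
                        seen[w] = depth
                        nxt.append(w)
                        if w > start:
                            excl.add((start, w))
                        elif w < start:
                            excl.add((w, start))
            frontier = nxt

    topo = CGTopology(
        n_beads=n,
        bonds=np.array(bonds, int).reshape(-1, 2),
        bond_r0=np.array(bond_r0), bond_k=np.array(bond_k),
        angles=np.array(angles, int).reshape(-1, 3),
        angle_t0=np.array(angle_t0), angle_k=np.full(len(angles), params.k_angle),
        dihedrals=np.array(dihedrals, int).reshape(-1, 4),
        dih_p0=np.array(dih_p0), dih_k1=np.array(dih_k1), dih_k3=np.array(dih_k3),
        contacts=np.array(all_contacts, int).reshape(-1, 2),
        contact_rn=np.array(c_rn), contact_eps=np.array(c_eps),
        linkage=link,
        exclusions=np.array(sorted(excl), int).reshape(-1, 2),
    )
    return model, topo


def _angle(a, b, c) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    return float(np.arctan2(y, x))


# ---------------------------------------------------------------------------
# reference dimers and PDB output
# ---------------------------------------------------------------------------

def map_reference_dimer(path, linkage: str, chain_roles=None) -> BeadModel:
    """Coarse-grain an experimental two-chain dimer for use as an RMSD
    reference, labelling the chain that donates its C-terminal G76 tail to
    the linkage as distal.

    ``chain_roles`` maps {'distal': chain_id, 'proximal': chain_id} and
    overrides automatic donor detection.
    """
    if linkage not in LINKAGE_TYPES or linkage == "free":
        raise ValueError("reference mapping requires a covalent linkage type")
    residues = parse_pdb(path)
    chains = sorted({r.chain_id for r in residues})
    if len(chains) != 2:
        raise ValueError(f"expected 2 chains, found {len(chains)}")
    by_chain = {c: [r for r in residues if r.chain_id == c] for c in chains}

    if chain_roles:
        distal_chain = chain_roles["distal"]
        proximal_chain = chain_roles["proximal"]
    else:
        # donor chain: its last residue's C(=G76 carboxyl) is nearest the
        # acceptor site on the partner chain
        def donor_score(donor_c, acceptor_c):
            tail = by_chain[donor_c][-1]
            try:
                tail_pos = tail.atom_position("C")
            except KeyError:
                tail_pos = tail.atom_position("CA")
            if linkage == "M1":
                site = by_chain[acceptor_c][0]
                site_pos = site.atom_position("CA")
            else:
                k_res = int(linkage[1:])
                cand = [r for r in by_chain[acceptor_c] if r.res_index == k_res]
                if not cand:
                    return np.inf
                sc = cand[0].heavy_atoms("sidechain")
                site_pos = (
                    np.mean([a[2] for a in sc], axis=0) if sc
                    else cand[0].atom_position("CA")
                )
            return float(np.linalg.norm(tail_pos - site_pos))

        s01 = donor_score(chains[0], chains[1])
        s10 = donor_score(chains[1], chains[0])
        if not np.isfinite(min(s01, s10)):
            raise ValueError(
                "cannot identify donor chain; pass chain_roles explicitly"
            )
        distal_chain = chains[0] if s01 <= s10 else chains[1]
        proximal_chain = chains[1] if distal_chain == chains[0] else chains[0]

    distal = coarse_grain(by_chain[distal_chain], "distal")
    proximal = coarse_grain(by_chain[proximal_chain], "proximal")
    merged = _merge_models([distal, proximal])
    merged.source_id = str(path)
    return merged


def write_bead_pdb(model: BeadModel, path) -> None:
    """Write the bead model as a PDB with pseudo-atoms (backbone 'CA',
    sidechain 'CB'); residue numbering preserved."""
    n = len(model)
    arr = struc.AtomArray(n)
    from .constants import ONE_TO_THREE

    chain_ids = {"distal": "A", "proximal": "B"}
    for i, b in enumerate(model.beads):
        arr.chain_id[i] = chain_ids.get(b.monomer, "A")
        arr.res_id[i] = b.res_index
        arr.res_name[i] = ONE_TO_THREE.get(b.res_type, "UNK")
        arr.atom_name[i] = "CA" if b.kind == "backbone" else "CB"
        arr.element[i] = "C"
        arr.coord[i] = np.asarray(b.position) * 10.0  # nm -> Angstrom
    f = pdbio.PDBFile()
    f.set_structure(arr)
    f.write(path)
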