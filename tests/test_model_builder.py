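"""Model construction: PDB parsing, coarse graining, contacts, charges,
the hydrophobic matrix and topology assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ubscape.constants import UBIQUITIN_SEQUENCE, mj_raw_table
from ubscape.model_builder import (
    LINKAGE_TYPES, CGTopology, TopologyParams, assign_charges,
    build_hydrophobic_matrix, build_topology, coarse_grain,
    detect_native_contacts, map_reference_dimer, parse_pdb, write_bead_pdb,
)
from ubscape.synthetic_fixtures import make_mini_dimer, ub_monomer_residues


# ---------------------------------------------------------------------------
# parse_pdb
# ---------------------------------------------------------------------------

def _pdb_line(serial, name, res, chain, resid, x, y, z, occ=1.0, altloc=" ",
              element="C"):
    return (f"ATOM  {serial:5d} {name:<4s}{altloc}{res:<3s} {chain}{resid:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}")


def test_parse_pdb_roundtrip_via_bead_writer(tmp_path, mini_dimer):
    path = tmp_path / "beads.pdb"
    write_bead_pdb(mini_dimer.model, str(path))
    residues = parse_pdb(str(path))
    assert len(residues) == 2 * mini_dimer.spec.n_residues
    chains = {r.chain_id for r in residues}
    assert chains == {"A", "B"}


def test_parse_pdb_empty_file_is_an_error(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("END\n")
    with pytest.raises(Exception, match="[Nn]o protein residues"):
        parse_pdb(str(p))


def test_parse_pdb_altloc_keeps_highest_occupancy(tmp_path):
    lines = [
        _pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
        _pdb_line(2, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0, occ=0.6, altloc="A"),
        _pdb_line(3, "CA", "ALA", "A", 1, 9.0, 0.0, 0.0, occ=0.4, altloc="B"),
        _pdb_line(4, "CB", "ALA", "A", 1, 1.5, 1.0, 0.0),
        "END",
    ]
    p = tmp_path / "altloc.pdb"
    p.write_text("\n".join(lines) + "\n")
    residues = parse_pdb(str(p))
    assert len(residues) == 1
    # altloc A (occupancy 0.6) retained
    assert residues[0].atom_position("CA")[0] == pytest.approx(1.0)


def test_parse_pdb_drops_waters_and_hetero(tmp_path):
    lines = [
        _pdb_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
        "HETATM    2  O   HOH A   2       5.000   0.000   0.000  1.00  0.00           O",
        "END",
    ]
    p = tmp_path / "wat.pdb"
    p.write_text("\n".join(lines) + "\n")
    residues = parse_pdb(str(p))
    assert [r.res_name for r in residues] == ["GLY"]


# ---------------------------------------------------------------------------
# coarse_grain
# ---------------------------------------------------------------------------

def test_glycine_gets_single_bead(ub_residues):
    model = coarse_grain(ub_residues, "distal")
    gly = [b for b in model.beads if b.res_type == "G"]
    assert all(b.kind == "backbone" for b in gly)
    assert len(gly) == UBIQUITIN_SEQUENCE.count("G")


def test_bead_count_formula(ub_residues):
    # N_beads = N_res + (N_res - N_gly): 76 + 70 = 146 for ubiquitin
    model = coarse_grain(ub_residues, "distal")
    n_gly = UBIQUITIN_SEQUENCE.count("G")
    assert len(model) == 76 + (76 - n_gly) == 146


def test_single_heavy_atom_sidechain_bead_sits_on_that_atom(mini_dimer):
    # Ala-like residues carry only CB; the sidechain bead is its position
    for rec in mini_dimer.residues_distal:
        sc = rec.heavy_atoms("sidechain")
        if len(sc) == 1:
            model = coarse_grain([rec], "distal")
            assert model.beads[1].kind == "sidechain"
            np.testing.assert_allclose(model.beads[1].position, sc[0][2] / 10.0)
            break
    else:
        pytest.fail("fixture lacks a single-heavy-atom sidechain")


def test_bead_ordering_deterministic(ub_residues):
    model = coarse_grain(ub_residues, "distal")
    resid = model.res_indices()
    kinds = model.kinds()
    assert np.all(np.diff(resid) >= 0)
    # within a residue, backbone precedes sidechain
    for r in np.unique(resid):
        k = kinds[resid == r]
        assert list(k) == sorted(k)


# ---------------------------------------------------------------------------
# native contacts
# ---------------------------------------------------------------------------

def test_contacts_match_brute_force_oracle(mini_dimer):
    """Contact detection equals an exhaustive heavy-atom double loop on an
    8-residue fragment."""
    residues = mini_dimer.residues_distal[:8]
    cutoff, min_sep = 4.5, 3
    got = detect_native_contacts(residues, cutoff, min_sep)
    got_keys = {(c.i, c.j) for c in got}

    expected = set()
    from ubscape.model_builder import _monomer_bead_index
    for a in range(len(residues)):
        for b in range(a + 1, len(residues)):
            ra, rb = residues[a], residues[b]
            if abs(rb.res_index - ra.res_index) < min_sep:
                continue
            for ga in ("backbone", "sidechain"):
                for gb in ("backbone", "sidechain"):
                    xa = [at[2] for at in ra.heavy_atoms(ga)]
                    xb = [at[2] for at in rb.heavy_atoms(gb)]
                    if not xa or not xb:
                        continue
                    dmin = min(np.linalg.norm(p - q) for p in xa for q in xb)
                    if dmin <= cutoff:
                        i = _monomer_bead_index(residues, ra.res_index, ga)
                        j = _monomer_bead_index(residues, rb.res_index, gb)
                        expected.add((min(i, j), max(i, j)))
    assert got_keys == expected


def test_contacts_exclude_close_sequence_neighbours(ub_residues):
    contacts = detect_native_contacts(ub_residues)
    model = coarse_grain(ub_residues, "distal")
    resid = model.res_indices()
    for c in contacts:
        assert abs(int(resid[c.j]) - int(resid[c.i])) >= 3
        assert c.i < c.j
        assert c.r_n > 0


def test_contacts_canonical_no_duplicates(ub_residues):
    contacts = detect_native_contacts(ub_residues)
    keys = [(c.i, c.j) for c in contacts]
    assert len(keys) == len(set(keys))


def test_contact_argument_validation(ub_residues):
    with pytest.raises(ValueError):
        detect_native_contacts(ub_residues, cutoff=-1.0)
    with pytest.raises(ValueError):
        detect_native_contacts(ub_residues, min_seq_sep=0)


# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------

def test_charges_at_neutral_ph(ub_free_system):
    model = ub_free_system.model
    for b in model.beads:
        if b.kind == "backbone":
            assert b.charge == 0.0
        elif b.res_type in "KR":
            assert b.charge == 1.0
        elif b.res_type in "DE":
            assert b.charge == -1.0
        elif b.res_type == "H":
            assert b.charge == 0.5
        else:
            assert b.charge == 0.0


def test_dimer_net_charge_is_twice_monomer(ub_residues):
    mono = assign_charges(coarse_grain(ub_residues, "distal"))
    from ubscape.synthetic_fixtures import ub_dimer_system
    dimer = ub_dimer_system("free").model
    assert dimer.charges().sum() == pytest.approx(2 * mono.charges().sum())


# ---------------------------------------------------------------------------
# hydrophobic matrix
# ---------------------------------------------------------------------------

def test_mj_minimum_is_leu_phe():
    m = mj_raw_table()
    assert m.min() == pytest.approx(-7.37)
    i, j = np.unravel_index(m.argmin(), m.shape)
    assert {"L", "F"} == {"CMFILVWYAGTSNQDEHRKP"[i], "CMFILVWYAGTSNQDEHRKP"[j]}


def test_hp_matrix_normalisation_construction():
    raw = mj_raw_table()
    hm = build_hydrophobic_matrix(raw)
    # alpha=1: eps = e/(2 ebar); an entry equal to 2*ebar maps to 1
    raw2 = raw.copy()
    raw2[0, 1] = raw2[1, 0] = 2 * (-3.7)
    hm2 = build_hydrophobic_matrix(raw2)
    assert hm2.eps[0, 1] == pytest.approx(1.0)
    # non-negative raw entries are zeroed
    raw3 = raw.copy()
    raw3[2, 3] = raw3[3, 2] = 0.5
    assert build_hydrophobic_matrix(raw3).eps[2, 3] == 0.0
    assert hm.eps.min() >= 0.0 and hm.eps.max() <= 1.0


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_hp_matrix_bounds_symmetry_idempotence(seed):
    rng = np.random.default_rng(seed)
    raw = rng.uniform(-9, 1, (20, 20))
    raw = 0.5 * (raw + raw.T)
    hm = build_hydrophobic_matrix(raw)
    assert np.all(hm.eps >= 0) and np.all(hm.eps <= 1)
    np.testing.assert_allclose(hm.eps, hm.eps.T)
    np.testing.assert_allclose(np.clip(hm.eps, 0, 1), hm.eps)


def test_hp_matrix_rejects_bad_input():
    raw = mj_raw_table()
    with pytest.raises(ValueError):
        build_hydrophobic_matrix(raw, ebar=0.0)
    bad = raw.copy()
    bad[0, 1] += 1.0
    with pytest.raises(ValueError):
        build_hydrophobic_matrix(bad)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def test_free_model_has_no_inter_monomer_bonded_terms(ub_free_system):
    topo = ub_free_system.topology
    model = ub_free_system.model
    mono = model.monomer_labels()
    assert topo.linkage.type == "free"
    for arr in (topo.bonds, topo.angles, topo.dihedrals, topo.contacts):
        for row in arr:
            assert len(set(mono[list(row)])) == 1


@pytest.mark.parametrize("linkage,acceptor_res,acceptor_kind,r0", [
    ("K48", 48, "sidechain", 0.40),
    ("K63", 63, "sidechain", 0.40),
    ("K6", 6, "sidechain", 0.40),
    ("M1", 1, "backbone", 0.38),
])
def test_linkage_bond_connects_named_beads(linkage, acceptor_res,
                                           acceptor_kind, r0):
    from ubscape.synthetic_fixtures import ub_dimer_system
    sys_ = ub_dimer_system(linkage)
    link = sys_.topology.linkage
    model = sys_.model
    assert link.r0_link == pytest.approx(r0)
    assert model.index_of("distal", 76, "backbone") == link.donor
    assert model.index_of("proximal", acceptor_res, acceptor_kind) == link.acceptor
    # linkage pair appears in the exclusion list
    pair = (min(link.donor, link.acceptor), max(link.donor, link.acceptor))
    assert pair in {tuple(e) for e in map(tuple, sys_.topology.exclusions)}


def test_unknown_linkage_lists_valid_names(ub_residues):
    m = coarse_grain(ub_residues, "distal")
    with pytest.raises(ValueError) as err:
        build_topology([m, m], linkage="K99")
    for name in LINKAGE_TYPES:
        assert name in str(err.value)


def test_linkage_requires_two_monomers(ub_residues):
    m = coarse_grain(ub_residues, "distal")
    with pytest.raises(ValueError, match="two monomers"):
        build_topology(m, linkage="K48")


def test_every_bonded_pair_is_excluded(mini_dimer):
    topo = mini_dimer.topology
    excl = {tuple(e) for e in map(tuple, topo.exclusions)}
    for i, j in topo.bonds:
        assert (min(i, j), max(i, j)) in excl


def test_contacts_disjoint_from_bonds(mini_dimer):
    topo = mini_dimer.topology
    bonds = {tuple(sorted(b)) for b in map(tuple, topo.bonds)}
    contacts = {tuple(sorted(c)) for c in map(tuple, topo.contacts)}
    assert not bonds & contacts


def test_topology_serialization_roundtrip(tmp_path, mini_dimer):
    topo = mini_dimer.topology
    path = tmp_path / "topo.json"
    topo.save(path)
    back = CGTopology.load(path)
    for attr in ("bonds", "bond_r0", "bond_k", "angles", "angle_t0", "angle_k",
                 "dihedrals", "dih_p0", "dih_k1", "dih_k3", "contacts",
                 "contact_rn", "contact_eps", "exclusions"):
        np.testing.assert_array_equal(getattr(topo, attr), getattr(back, attr))
    assert back.linkage == topo.linkage


def test_contact_dihedral_rescaling_ratio(ub_free_system):
    topo = ub_free_system.topology
    params = TopologyParams()
    sum_c = topo.contact_eps.sum()
    backbone = topo.dih_k3 > 0
    sum_d = topo.dih_k1[backbone].sum()
    assert sum_c / sum_d == pytest.approx(params.contact_dihedral_ratio)


def test_map_reference_dimer_identifies_donor_chain(tmp_path, mini_dimer):
    # bead-PDB of the K48-linked mini system: chain A tail was placed
    # next to chain B, so A must be labelled distal
    path = tmp_path / "ref.pdb"
    write_bead_pdb(mini_dimer.model, str(path))
    ref = map_reference_dimer(str(path), "K6", chain_roles={"distal": "A",
                                                            "proximal": "B"})
    assert ref.n_monomers == 2
    assert ref.beads[0].monomer == "distal"
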