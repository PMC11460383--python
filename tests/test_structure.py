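"""Structure parsing, typing, selections, Dmax and round-trips."""

import numpy as np
import pytest

import solscat as ss
from solscat.residues import PROTEIN_RESIDUES
from solscat.structure import StructureError, _max_dist_brute

from conftest import model_from_points


def atom_line(serial, name, res, chain, seq, x, y, z, element,
              occ=1.0, altloc=" ", record="ATOM  "):
    return (f"{record}{serial:5d} {name:<4s}{altloc}{res:<3s} {chain}"
            f"{seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


def write_pdb_text(tmp_path, lines, name="fixture.pdb"):
    p = tmp_path / name
    p.write_text("\n".join(lines + ["END"]) + "\n")
    return p


# ----------------------------------------------------------------- parsing

def test_three_atom_identity_parse(tmp_path):
    path = write_pdb_text(tmp_path, [
        atom_line(1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0, "N"),
        atom_line(2, "CA", "ALA", "A", 1, 2.5, 2.0, 3.0, "C"),
        atom_line(3, "C", "ALA", "A", 1, 4.0, 2.0, 3.5, "C"),
    ])
    m = ss.read_structure(path)
    assert m.n_atoms == 3
    np.testing.assert_allclose(m.positions,
                               [[1, 2, 3], [2.5, 2, 3], [4, 2, 3.5]])


def test_altloc_highest_occupancy_wins_ties_first(tmp_path):
    path = write_pdb_text(tmp_path, [
        atom_line(1, "CA", "GLY", "A", 1, 1.0, 0, 0, "C", occ=0.6, altloc="A"),
        atom_line(2, "CA", "GLY", "A", 1, 9.0, 0, 0, "C", occ=0.4, altloc="B"),
        atom_line(3, "N", "GLY", "A", 1, 2.0, 0, 0, "N", occ=0.5, altloc="A"),
        atom_line(4, "N", "GLY", "A", 1, 8.0, 0, 0, "N", occ=0.5, altloc="B"),
    ])
    m = ss.read_structure(path)
    assert m.n_atoms == 2
    xs = dict(zip(m.atom_names, m.positions[:, 0]))
    assert xs["CA"] == 1.0      # higher occupancy
    assert xs["N"] == 2.0       # tie -> first in file


def test_model_selection_and_missing_model(tmp_path):
    lines = (["MODEL        1",
              atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C"), "ENDMDL",
              "MODEL        2",
              atom_line(1, "CA", "GLY", "A", 1, 5, 0, 0, "C"), "ENDMDL"])
    path = write_pdb_text(tmp_path, lines)
    m1 = ss.read_structure(path)                 # default: first model
    m2 = ss.read_structure(path, model=2)
    assert m1.positions[0, 0] == 0 and m2.positions[0, 0] == 5
    with pytest.raises(StructureError, match="model 3"):
        ss.read_structure(path, model=3)


def test_biomt_assembly_expansion(tmp_path):
    lines = [
        "REMARK 350 BIOMOLECULE: 1",
        "REMARK 350 APPLY THE FOLLOWING TO CHAINS: A",
        "REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000",
        "REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000",
        "REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000",
        "REMARK 350   BIOMT1   2 -1.000000  0.000000  0.000000       20.00000",
        "REMARK 350   BIOMT2   2  0.000000 -1.000000  0.000000        0.00000",
        "REMARK 350   BIOMT3   2  0.000000  0.000000  1.000000        0.00000",
        atom_line(1, "CA", "GLY", "A", 1, 1.0, 2.0, 3.0, "C"),
    ]
    path = write_pdb_text(tmp_path, lines)
    asym = ss.read_structure(path)
    asm = ss.read_structure(path, assembly="1")
    assert asym.n_atoms == 1 and asm.n_atoms == 2
    np.testing.assert_allclose(sorted(asm.positions[:, 0]), [1.0, 19.0])
    with pytest.raises(StructureError, match="assembly"):
        ss.read_structure(path, assembly="9")


def test_water_and_het_filters(tmp_path):
    path = write_pdb_text(tmp_path, [
        atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C"),
        atom_line(2, "O", "HOH", "A", 2, 5, 0, 0, "O", record="HETATM"),
        atom_line(3, "C1", "XLG", "A", 3, 8, 0, 0, "C", record="HETATM"),
    ])
    assert ss.read_structure(path).n_atoms == 1
    assert ss.read_structure(path, include_het=True).n_atoms == 2
    m = ss.read_structure(path, include_het=True, include_waters=True)
    assert m.n_atoms == 3
    assert "H2O" in m.type_labels


def test_explicit_hydrogens_merged_on_unknown_residue(tmp_path):
    # methanol-like fragment: C with 3 H, O with 1 H
    path = write_pdb_text(tmp_path, [
        atom_line(1, "C1", "MOH", "A", 1, 0.0, 0, 0, "C", record="HETATM"),
        atom_line(2, "O1", "MOH", "A", 1, 1.4, 0, 0, "O", record="HETATM"),
        atom_line(3, "H1", "MOH", "A", 1, -0.5, 0.9, 0, "H", record="HETATM"),
        atom_line(4, "H2", "MOH", "A", 1, -0.5, -0.9, 0, "H", record="HETATM"),
        atom_line(5, "H3", "MOH", "A", 1, -0.5, 0, 0.9, "H", record="HETATM"),
        atom_line(6, "H4", "MOH", "A", 1, 1.8, 0.9, 0, "H", record="HETATM"),
    ])
    m = ss.read_structure(path, include_het=True)
    assert m.n_atoms == 2
    assert sorted(m.group_labels) == ["CH3", "OH"]


# ------------------------------------------------------------------ typing

def test_standard_residue_typing(tmp_path):
    path = write_pdb_text(tmp_path, [
        atom_line(1, "N", "ALA", "A", 1, 0, 0, 0, "N"),
        atom_line(2, "CA", "ALA", "A", 1, 1.5, 0, 0, "C"),
        atom_line(3, "CB", "ALA", "A", 1, 2.0, 1.2, 0, "C"),
        atom_line(4, "CA", "GLY", "A", 2, 4.0, 0, 0, "C"),
        atom_line(5, "N", "PRO", "A", 3, 6.0, 0, 0, "N"),
    ])
    m = ss.read_structure(path)
    labels = dict(zip(zip(m.res_names, m.atom_names), m.group_labels))
    assert labels[("ALA", "CB")] == "CH3"
    assert labels[("ALA", "N")] == "NH"      # backbone amide, non-proline
    assert labels[("ALA", "CA")] == "CH"
    assert labels[("GLY", "CA")] == "CH2"
    assert labels[("PRO", "N")] == "N"


def test_protein_type_count_between_10_and_15(tmp_path, rng):
    lines, serial = [], 1
    for seq, (res, atoms) in enumerate(PROTEIN_RESIDUES.items(), start=1):
        for name in atoms:
            if name == "OXT":
                continue
            x, y, z = rng.uniform(0, 50, 3)
            el = name[0] if name[0] in "CNOS" else name[1]
            lines.append(atom_line(serial, name, res, "A", seq, x, y, z, el))
            serial += 1
    m = ss.read_structure(write_pdb_text(tmp_path, lines))
    assert 10 <= m.n_types <= 15


def test_assignment_order_independent(small_mixed_model, rng):
    m = small_mixed_model
    perm = rng.permutation(m.n_atoms)
    m2 = ss.assign_atom_types(m.subset(perm))
    assert m2.type_labels == m.type_labels
    assert [m2.group_labels[i] for i in np.argsort(perm)] == list(m.group_labels)


# ------------------------------------------------------- effective electrons

def test_effective_electrons_vacuum_and_solvent(small_mixed_model):
    m0 = small_mixed_model.with_solvent_ed(0.0)
    np.testing.assert_allclose(ss.effective_electrons(m0), m0.z_electrons)
    dz = ss.effective_electrons(small_mixed_model)
    np.testing.assert_allclose(
        dz, small_mixed_model.z_electrons - 0.334 * small_mixed_model.volumes)
    # CH2 has negative net electrons in water
    tab = small_mixed_model.table["CH2"]
    assert tab.z - 0.334 * tab.volume < 0


def test_sum_delta_z_matches_debye_forward_scattering(small_mixed_model):
    i0 = ss.dd_xs(small_mixed_model, np.array([0.0])).i[0]
    sdz = small_mixed_model.delta_z.sum()
    assert abs(i0 - sdz**2) / abs(i0) < 1e-10


# ------------------------------------------------------------------- dmax

def test_max_pair_distance_two_atoms():
    m, _ = ss.make_fixture("two_atom", d=5.0)
    assert ss.max_pair_distance(m) == pytest.approx(5.0, abs=1e-12)
    with pytest.raises(StructureError):
        ss.max_pair_distance(m.subset(np.array([0])))


def test_max_pair_distance_matches_brute_force(rng):
    pts = rng.normal(scale=15, size=(200, 3))
    ref = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)).max()
    assert _max_dist_brute(pts, block=64) == pytest.approx(ref, rel=1e-12)
    m = model_from_points(pts.round(3), "C")
    ref = np.sqrt(((m.positions[:, None] - m.positions[None]) ** 2).sum(-1)).max()
    assert ss.max_pair_distance(m) == pytest.approx(ref, rel=1e-12)


def test_convex_hull_path_equals_blocked_scan(rng):
    pts = rng.normal(scale=30, size=(3500, 3))
    m = model_from_points(pts.round(3), "C")
    assert m.n_atoms > 3000  # hull path
    assert ss.max_pair_distance(m) == pytest.approx(_max_dist_brute(m.positions),
                                                    rel=1e-12)


# ------------------------------------------------------------- round trips

def test_sites_tsv_round_trip(tmp_path, small_mixed_model):
    path = tmp_path / "sites.tsv"
    ss.write_sites_tsv(small_mixed_model, path)
    m2 = ss.read_sites_tsv(path)
    np.testing.assert_array_equal(m2.positions, small_mixed_model.positions)
    assert list(m2.group_labels) == list(small_mixed_model.group_labels)
    assert m2.solvent_ed == small_mixed_model.solvent_ed
    assert [r for r in m2][0] == [r for r in small_mixed_model][0]


def test_fixture_pdb_round_trip(tmp_path):
    m, _ = ss.make_fixture("sphere", n=40, radius=9, seed=5,
                           labels=["C", "N", "O"])
    path = tmp_path / "fix.pdb"
    ss.write_pdb(m, path)
    m2 = ss.read_structure(path)
    np.testing.assert_array_equal(m2.positions, m.positions)
    assert list(m2.group_labels) == list(m.group_labels)


# -------------------------------------------------------------- selections

def test_selection_mini_language(small_mixed_model):
    m = small_mixed_model
    sel = ss.parse_selection("resi 1-10")
    assert sel.mask(m).sum() == 10
    sel = ss.parse_selection("chain A and resi 1-5,8")
    assert sel.mask(m).sum() == 6
    assert ss.parse_selection("chain B").mask(m).sum() == 0
    with pytest.raises(StructureError):
        ss.parse_selection("bogus A")
    with pytest.raises(StructureError):
        m.subset(ss.parse_selection("chain B").mask(m))


def test_mmcif_reading_matches_pdb(tmp_path):
    import gemmi
    pdb = write_pdb_text(tmp_path, [
        atom_line(1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0, "N"),
        atom_line(2, "CA", "ALA", "A", 1, 2.5, 2.0, 3.0, "C"),
        atom_line(3, "CB", "ALA", "A", 1, 3.0, 3.2, 3.0, "C"),
    ])
    st = gemmi.read_structure(str(pdb))
    st.setup_entities()
    cif = tmp_path / "fixture.cif"
    st.make_mmcif_document().write_file(str(cif))
    m_pdb = ss.read_structure(pdb)
    m_cif = ss.read_structure(cif)
    np.testing.assert_allclose(m_cif.positions, m_pdb.positions)
    assert list(m_cif.group_labels) == list(m_pdb.group_labels)


def test_resname_selection(tmp_path):
    path = write_pdb_text(tmp_path, [
        atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C"),
        atom_line(2, "C1", "BCD", "A", 2, 5, 0, 0, "C", record="HETATM"),
        atom_line(3, "C2", "BCD", "A", 2, 6, 0, 0, "C", record="HETATM"),
    ])
    m = ss.read_structure(path, include_het=True, selection="resname BCD")
    assert m.n_atoms == 2 and set(m.res_names) == {"BCD"}
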