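import numpy as np
import pytest

from neosurf.chem import RADIUS_TABLES
from neosurf.peptides import build_extended_peptide
from neosurf.structure import (
    EmptyStructureError,
    PDBError,
    PDBParseError,
    assign_radii,
    read_pdb,
    write_pdb,
)

MINIMAL = "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"


def test_minimal_record_parses_to_single_atom():
    s = read_pdb(MINIMAL, detect_roles=False)
    assert list(s.chains) == ["A"]
    res = s.chains["A"][0]
    assert res.name == "ALA" and len(res.atoms) == 1
    atom = res.atoms[0]
    assert atom.name == "CA" and np.allclose(atom.coords, 0.0)
    assert atom.is_backbone


def test_roundtrip_preserves_names_coords_chains():
    pep = build_extended_peptide("GASLVWR", chain_id="B")
    text = write_pdb(pep)
    back = read_pdb(text, detect_roles=False)
    text2 = write_pdb(back)
    assert text == text2
    assert back.sequence("B") == "GASLVWR"
    for r1, r2 in zip(pep.chains["B"], back.chains["B"]):
        for a1, a2 in zip(r1.atoms, r2.atoms):
            assert a1.name == a2.name
            assert np.allclose(a1.coords, a2.coords, atol=1e-3)


def test_altloc_keeps_highest_occupancy_conformer():
    text = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C\n"
        "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C\n"
        "ATOM      3  CB AALA A   1       1.500   0.000   0.000  0.60  0.00           C\n"
        "ATOM      4  CB BALA A   1       9.500   0.000   0.000  0.40  0.00           C\n"
    )
    s = read_pdb(text, detect_roles=False)
    res = s.chains["A"][0]
    # hand-filtered record list: conformer A wins both groups
    assert [a.name for a in res.atoms] == ["CA", "CB"]
    assert all(a.altloc == "A" for a in res.atoms)
    assert res.atom("CA").coords[0] == 0.0


def test_altloc_tie_broken_alphabetically():
    text = (
        "ATOM      1  CA BALA A   1       9.000   0.000   0.000  0.50  0.00           C\n"
        "ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
    )
    s = read_pdb(text, detect_roles=False)
    assert s.chains["A"][0].atom("CA").altloc == "A"


def test_altloc_filtering_never_increases_atom_count():
    text = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
        "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.50  0.00           C\n"
        "ATOM      3  CA CALA A   1       2.000   0.000   0.000  0.50  0.00           C\n"
    )
    s = read_pdb(text, detect_roles=False)
    assert s.n_atoms() == 1


def test_waters_hydrogens_and_ligand_hetatm_excluded():
    text = (
        MINIMAL
        + "ATOM      2  HA  ALA A   1       0.500   0.500   0.000  1.00  0.00           H\n"
        + "HETATM    3  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O\n"
        + "HETATM    4  C1  NAG A 201       8.000   8.000   8.000  1.00  0.00           C\n"
    )
    s = read_pdb(text, detect_roles=False)
    assert s.n_atoms() == 1
    s2 = read_pdb(text, keep_hydrogens=True, detect_roles=False)
    assert s2.n_atoms() == 2


def test_malformed_atom_line_reports_line_number():
    bad = MINIMAL + "ATOM      2  CB  ALA A   1       bad_coords_here\n"
    with pytest.raises(PDBParseError) as err:
        read_pdb(bad)
    assert "line 2" in str(err.value)


def test_empty_input_raises():
    with pytest.raises(EmptyStructureError):
        read_pdb("REMARK nothing here\n")


def test_writer_emits_one_ter_per_chain_and_fixed_columns():
    pep = build_extended_peptide("AA", chain_id="A")
    pep.chains["B"] = [r.copy() for r in pep.chains["A"]]
    text = write_pdb(pep)
    assert text.count("\nTER") + text.startswith("TER") == 2
    line = text.splitlines()[0]
    x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
    a = pep.chains["A"][0].atoms[0]
    assert np.allclose([x, y, z], a.coords, atol=5e-4)


def test_writer_rejects_long_atom_names():
    pep = build_extended_peptide("A")
    pep.chains["A"][0].atoms[0].name = "TOOLONG"
    with pytest.raises(PDBError):
        write_pdb(pep)


def test_assign_radii_default_table_and_unknown_element():
    pep = build_extended_peptide("ACW")
    out = assign_radii(pep)
    assert all(a.radius > 0 for a in out.atoms())
    carbon = out.chains["A"][0].atom("CA")
    assert carbon.radius == RADIUS_TABLES["bondi"]["C"]
    pep.chains["A"][0].atoms[0].element = "ZZ"
    with pytest.raises(KeyError):
        assign_radii(pep)


def test_alternate_radius_table_changes_radii():
    pep = build_extended_peptide("AC")
    bondi = assign_radii(pep, "bondi")
    chothia = assign_radii(pep, "chothia")
    rb = [a.radius for a in bondi.atoms()]
    rc = [a.radius for a in chothia.atoms()]
    assert rb != rc
    with pytest.raises(KeyError):
        assign_radii(pep, "no-such-table")


def test_peptide_chain_autodetection(groove_fixture):
    s, _ = groove_fixture
    text = write_pdb(s)
    back = read_pdb(text)
    assert back.peptide_chain == "P"
    assert back.mhc_chain == "M"
    # pseudo-atoms share a name but carry no altloc: all must survive
    assert back.n_atoms() == s.n_atoms()


def test_peptide_chain_length_invariant():
    pep = build_extended_peptide("AAAA")
    with pytest.raises(ValueError):
        from neosurf.structure import Structure
        Structure(pep.chains, peptide_chain="A")
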