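import numpy as np
import pytest

from neosurf._geom import dihedral
from neosurf.builder import (
    clash_score,
    graft_peptide,
    refine,
    select_final_model,
)
from neosurf.epitopes import make_mep
from neosurf.peptides import get_chi, ideal_residue, place_side_chain
from neosurf.structure import Atom, Residue, Structure, write_pdb
from neosurf.synthetic import GrooveSpec, make_groove_complex


@pytest.fixture(scope="module")
def template_44():
    s, _ = make_groove_complex("LSCLNWSTL", "uduuuuuud", GrooveSpec(seed=4),
                               structure_id="TPL")
    return s


def coords_of(structure, chain):
    return np.array([a.coords for r in structure.chains[chain] for a in r.atoms])


def test_identity_graft_is_bitwise(template_44):
    mep = make_mep("same", "LSCLNWSTL", 3, "H-2Db")
    out = graft_peptide(template_44, mep)
    assert np.array_equal(coords_of(out, "P"), coords_of(template_44, "P"))
    assert np.array_equal(coords_of(out, "M"), coords_of(template_44, "M"))


def test_single_substitution_is_local(template_44):
    mep = make_mep("mut", "LSALNWSTL", 3, "H-2Db")   # C3A
    out = graft_peptide(template_44, mep)
    for i, (r_new, r_old) in enumerate(zip(out.chains["P"],
                                           template_44.chains["P"])):
        old = np.array([a.coords for a in r_old.atoms])
        new = np.array([a.coords for a in r_new.atoms])
        if i == 2:
            assert r_new.name == "ALA"
            bb_old = np.array([a.coords for a in r_old.atoms if a.is_backbone])
            bb_new = np.array([a.coords for a in r_new.atoms if a.is_backbone])
            assert np.array_equal(bb_old, bb_new)
        else:
            assert np.array_equal(old, new)


def test_graft_places_mutant_cys_in_groove(template_44):
    mep = make_mep("44-1", "LSCLNWSTL", 3, "H-2Db")
    out = graft_peptide(template_44, mep)
    assert out.sequence("P") == "LSCLNWSTL"
    assert out.chains["P"][2].name == "CYS"
    assert out.peptide_chain == "P"


def test_graft_length_tolerance(template_44):
    # one residue shorter: template peptide trimmed at the C-terminus
    shorter = make_mep("s", "LSCLNWST", 3, "H-2Db")
    out = graft_peptide(template_44, shorter)
    assert len(out.chains["P"]) == 8
    # one residue longer: chain extended with an ideal frame
    longer = make_mep("l", "LSCLNWSTLV", 3, "H-2Db")
    out2 = graft_peptide(template_44, longer)
    assert out2.sequence("P") == "LSCLNWSTLV"
    # beyond +-1 is rejected
    short_template, _ = make_groove_complex("LSCLNWST", "u" * 8, GrooveSpec(seed=4))
    with pytest.raises(ValueError, match="length"):
        graft_peptide(short_template, longer)


def test_place_side_chain_geometry():
    res = ideal_residue("CYS")
    frame = {k: res.atom(k).coords for k in ("N", "CA", "C")}
    assert place_side_chain(frame, "G") == []
    ala = place_side_chain(frame, "A")
    assert [a.name for a in ala] == ["CB"]
    d = np.linalg.norm(ala[0].coords - frame["CA"])
    assert d == pytest.approx(1.53, abs=0.02)


def test_chi_copied_from_shared_tree():
    """Ser built on a Cys frame inherits chi1: O-gamma tracks S-gamma."""
    cys = ideal_residue("CYS")
    frame = {k: cys.atom(k).coords for k in ("N", "CA", "C")}
    ser = place_side_chain(frame, "S", chi_source=cys)
    by_name = {a.name: a for a in ser}
    chi_ser = dihedral(frame["N"], frame["CA"], by_name["CB"].coords,
                       by_name["OG"].coords)
    chi_cys = get_chi(cys)[0]
    assert abs(chi_ser - chi_cys) < 5.0


def test_place_side_chain_requires_backbone():
    res = ideal_residue("ALA")
    with pytest.raises(ValueError):
        place_side_chain({"N": res.atom("N").coords, "CA": res.atom("CA").coords},
                         "S")


def test_clash_score_closed_forms():
    def two(d):
        a = Atom("A", "C", np.array([0.0, 0, 0]), radius=1.7)
        b = Atom("B", "C", np.array([d, 0, 0]), radius=1.7)
        return Structure({"A": [Residue("DUM", "1", [a])],
                          "B": [Residue("DUM", "1", [b])]})

    # separated atoms score zero; overlap of 0.5 A scores 0.25
    assert clash_score(two(3.6)) == 0.0
    assert clash_score(two(1.7 + 1.7 - 0.5)) == pytest.approx(0.25, rel=1e-9)


def test_refine_fixed_point_on_clash_free_model(template_44):
    mep = make_mep("same", "LSCLNWSTL", 3, "H-2Db")
    model = graft_peptide(template_44, mep)
    base = clash_score(model)
    if base == 0.0:
        refined = refine(model, n_restarts=4, seed=1)
        assert refined.clash_score == 0.0
        assert np.array_equal(coords_of(refined.structure, "P"),
                              coords_of(model, "P"))


def test_refine_is_deterministic(template_44):
    mep = make_mep("mut", "LSWLNWSTL", 3, "H-2Db")   # bulky substitution
    model = graft_peptide(template_44, mep)
    a = refine(model, n_restarts=4, seed=9)
    b = refine(model, n_restarts=4, seed=9)
    assert a.clash_score == b.clash_score
    assert write_pdb(a.structure) == write_pdb(b.structure)
    c = refine(model, n_restarts=4, seed=10)
    # a different seed explores different restarts (coordinates may differ)
    assert c.clash_score <= clash_score(model) + 1e-12


def test_refine_reduces_constructed_overlap(template_44):
    """A bulky residue grafted into a snug buried pocket must be relaxed."""
    mep = make_mep("mut", "LWCLNWSTL", 3, "H-2Db")   # S2W at buried anchor
    model = graft_peptide(template_44, mep)
    start = clash_score(model)
    assert start > 0
    refined = refine(model, n_restarts=6, seed=2)
    assert refined.clash_score < start


def test_refine_never_moves_backbone(template_44):
    mep = make_mep("mut", "LWCLNWSTL", 3, "H-2Db")
    model = graft_peptide(template_44, mep)
    refined = refine(model, n_restarts=4, seed=5, template=template_44)
    for r0, r1 in zip(model.chains["P"], refined.structure.chains["P"]):
        bb0 = np.array([a.coords for a in r0.atoms if a.is_backbone])
        bb1 = np.array([a.coords for a in r1.atoms if a.is_backbone])
        assert np.array_equal(bb0, bb1)
    assert refined.ca_rmsd_to_template == pytest.approx(0.0, abs=1e-9)


def test_select_final_model_prefers_exposure_over_score(template_44):
    mep = make_mep("44-1", "LSCLNWSTL", 3, "H-2Db")
    model = graft_peptide(template_44, mep)
    candidates = refine(model, n_restarts=4, seed=1, return_candidates=True)
    best_any = select_final_model(candidates, mep, desired_state="any",
                                  n_points=240)
    assert best_any.clash_score == min(c.clash_score for c in candidates)
    best_out = select_final_model(candidates, mep, desired_state="out",
                                  n_points=240)
    assert best_out.mutant_flag == "out"
    # impossible request falls back with a warning
    fallback = select_final_model(candidates, mep, desired_state="in",
                                  n_points=240)
    assert fallback.warning is not None
    with pytest.raises(ValueError):
        select_final_model([], mep)
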