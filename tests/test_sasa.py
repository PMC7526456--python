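import math

import numpy as np
import pytest

from neosurf.sasa import (
    annotate_in_out,
    atom_sasa,
    reference_backbone_area,
    reference_sidechain_area,
    residue_sasa,
)
from neosurf.structure import Structure, assign_radii
from neosurf.peptides import build_extended_peptide
from neosurf.synthetic import GrooveSpec, make_groove_complex, random_atom_cloud

from oracles import isolated_sphere_area, mc_sasa, two_sphere_areas


def test_isolated_sphere_matches_closed_form(atom_factory):
    a = atom_factory(0, 0, 0, r=1.9)
    area = atom_sasa([a], probe=1.4, n_points=960)[0]
    assert area == pytest.approx(4 * math.pi * 3.3**2, rel=1e-12)
    assert area == pytest.approx(136.848, abs=1e-3)


def test_distant_atoms_have_isolated_areas(atom_factory):
    atoms = [atom_factory(0, 0, 0, r=1.7), atom_factory(100, 0, 0, r=1.5, element="O")]
    areas = atom_sasa(atoms, probe=1.4, n_points=960)
    assert areas[0] == pytest.approx(isolated_sphere_area(1.7, 1.4), rel=1e-12)
    assert areas[1] == pytest.approx(isolated_sphere_area(1.5, 1.4), rel=1e-12)


@pytest.mark.parametrize("r1,r2,d", [(1.7, 1.7, 1.5), (1.9, 1.5, 2.0), (1.7, 1.4, 0.9)])
def test_two_sphere_lens_matches_cap_formula(atom_factory, r1, r2, d):
    atoms = [atom_factory(0, 0, 0, r=r1), atom_factory(d, 0, 0, r=r2)]
    areas = atom_sasa(atoms, probe=1.4, n_points=960)
    exact = two_sphere_areas(r1, r2, d, 1.4)
    assert areas[0] == pytest.approx(exact[0], rel=0.01)
    assert areas[1] == pytest.approx(exact[1], rel=0.01)


def test_coincident_identical_atoms_well_defined(atom_factory):
    atoms = [atom_factory(0, 0, 0), atom_factory(0, 0, 0)]
    areas = atom_sasa(atoms, probe=1.4, n_points=960)
    assert np.all(np.isfinite(areas))
    assert areas[0] == areas[1]


def test_monte_carlo_oracle_agreement_on_random_clouds():
    """Quadrature vs random-direction surface sampling within 2% of total."""
    for n, seed in [(5, 1), (12, 2), (20, 3), (30, 4)]:
        atoms = random_atom_cloud(n, box=8.0, min_sep=1.5, seed=seed)
        coords = np.array([a.coords for a in atoms])
        radii = np.array([a.radius for a in atoms])
        sr = atom_sasa(atoms, probe=1.4, n_points=960).sum()
        mc = mc_sasa(coords, radii, probe=1.4, n_samples=20000, seed=seed).sum()
        assert sr == pytest.approx(mc, rel=0.02)


def test_occlusion_monotonicity_and_bounds():
    atoms = random_atom_cloud(12, box=8.0, min_sep=1.5, seed=9)
    base = atom_sasa(atoms, probe=1.4, n_points=480)
    more = atoms + random_atom_cloud(6, box=8.0, min_sep=1.5, seed=10)
    crowded = atom_sasa(more, probe=1.4, n_points=480)[: len(atoms)]
    assert np.all(crowded <= base + 1e-9)
    caps = np.array([4 * math.pi * (a.radius + 1.4) ** 2 for a in atoms])
    assert np.all(base >= 0) and np.all(base <= caps + 1e-9)


def test_probe_zero_recovers_vdw_area(atom_factory):
    a = atom_factory(0, 0, 0, r=1.8)
    assert atom_sasa([a], probe=0.0, n_points=960)[0] == pytest.approx(
        4 * math.pi * 1.8**2, rel=1e-12)


def test_quadrature_convergence_under_doubling(groove_fixture):
    s, _ = groove_fixture
    r1 = residue_sasa(s, "P", n_points=480)
    r2 = residue_sasa(s, "P", n_points=960)
    assert r2.structure_total == pytest.approx(r1.structure_total, rel=0.005)


def test_per_residue_conservation(groove_fixture):
    s, _ = groove_fixture
    report = residue_sasa(s, "P", n_points=240)
    for row in report.rows:
        assert row.total == pytest.approx(row.backbone + row.sidechain, rel=1e-9)
    assert report.structure_total == pytest.approx(
        sum(r.total for r in report.rows), rel=1e-9)
    # per-residue totals equal the sum of constituent atom areas in context
    all_atoms = list(s.atoms())
    pep_idx = [i for i, a in enumerate(all_atoms)
               if any(a is b for r in s.chains["P"] for b in r.atoms)]
    atom_total = atom_sasa(all_atoms, n_points=240, subset=pep_idx).sum()
    assert report.structure_total == pytest.approx(atom_total, rel=1e-9)


def test_apolar_counts_carbon_and_sulfur_only():
    pep = assign_radii(build_extended_peptide("C"))
    report = residue_sasa(pep, "A", n_points=480)
    row = report.rows[0]
    all_atoms = pep.chains["A"][0].atoms
    areas = atom_sasa(all_atoms, n_points=480)
    expect = sum(ar for ar, a in zip(areas, all_atoms) if a.element in ("C", "S"))
    assert row.apolar == pytest.approx(expect, rel=1e-9)
    assert row.apolar < row.total  # N and O contribute polar area


def test_adding_groove_never_increases_residue_area(groove_fixture):
    s, _ = groove_fixture
    pep_only = Structure({"P": [r.copy() for r in s.chains["P"]]}, peptide_chain="P")
    free = residue_sasa(pep_only, "P", n_points=240)
    occluded = residue_sasa(s, "P", n_points=240)
    for f, o in zip(free.rows, occluded.rows):
        assert o.total <= f.total + 1e-9


def test_reference_sidechain_areas():
    assert reference_sidechain_area("G") == 0.0
    for x in "ASLWRC":
        ref = reference_sidechain_area(x, 1.4, 480)
        assert ref > 0
    # doubled quadrature moves the reference by < 0.5%
    assert reference_sidechain_area("L", 1.4, 960) == pytest.approx(
        reference_sidechain_area("L", 1.4, 480), rel=0.005)
    with pytest.raises(KeyError):
        reference_sidechain_area("X")


def test_buried_groove_sidechain_far_below_reference(groove_fixture):
    """The fully exposed reference dominates every buried side chain; exposed
    side chains sit near (occasionally just above) it, since the groove
    conformer is splayed away from its own backbone."""
    s, labels = groove_fixture
    report = residue_sasa(s, "P", n_points=480)
    for row, lab in zip(report.rows, labels):
        ref = reference_sidechain_area(row.one_letter, 1.4, 480)
        assert ref > 0
        if lab == "in":
            assert row.sidechain < 0.25 * ref
        else:
            assert row.sidechain < 1.3 * ref


def test_annotation_matches_groove_ground_truth(groove_fixture):
    s, labels = groove_fixture
    report = annotate_in_out(residue_sasa(s, "P", n_points=480))
    assert [r.flag for r in report.rows] == labels


def test_rotating_side_chain_into_floor_decreases_area():
    spec = GrooveSpec(seed=3)
    up, _ = make_groove_complex("LSCLNWSTL", "uuuuuuuud", spec)
    down, _ = make_groove_complex("LSCLNWSTL", "uuduuuuud", spec)
    r_up = residue_sasa(up, "P", n_points=480).rows[2]
    r_down = residue_sasa(down, "P", n_points=480).rows[2]
    assert r_down.sidechain < r_up.sidechain


def test_glycine_flag_from_backbone_reference():
    ref_bb = reference_backbone_area("G", 1.4, 480)
    assert ref_bb > 0
    pep = assign_radii(build_extended_peptide("AGA"))
    report = annotate_in_out(residue_sasa(pep, "A", n_points=480))
    gly = report.rows[1]
    assert gly.ratio == 0.0
    assert gly.flag == "out"      # free tripeptide: backbone fully exposed


def test_annotation_threshold_validation(groove_fixture):
    s, _ = groove_fixture
    report = residue_sasa(s, "P", n_points=240)
    with pytest.raises(ValueError):
        annotate_in_out(report, ratio_hi=20, ratio_lo=50)


def test_input_validation(atom_factory):
    a = atom_factory(0, 0, 0)
    with pytest.raises(ValueError):
        atom_sasa([a], probe=-0.1)
    with pytest.raises(ValueError):
        atom_sasa([a], n_points=16)
    bare = atom_factory(0, 0, 0)
    bare.radius = 0.0
    with pytest.raises(ValueError):
        atom_sasa([bare])
    s = assign_radii(build_extended_peptide("AA"))
    with pytest.raises(KeyError):
        residue_sasa(s, "Z")


def test_cross_check_against_biotite():
    """Independent library implementation agrees on a random cloud."""
    import biotite.structure as struc

    atoms = random_atom_cloud(15, box=8.0, min_sep=1.5, seed=21)
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.coords for a in atoms], dtype=np.float32)
    arr.element = np.array([a.element for a in atoms])
    arr.atom_name = np.array([a.name for a in atoms])
    arr.res_id = np.ones(len(atoms), dtype=int)
    arr.res_name = np.array(["UNK"] * len(atoms))
    arr.chain_id = np.array(["A"] * len(atoms))
    radii = np.array([a.radius for a in atoms])
    ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                     vdw_radii=radii).sum()
    mine = atom_sasa(atoms, probe=1.4, n_points=960).sum()
    assert mine == pytest.approx(ref, rel=0.02)
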