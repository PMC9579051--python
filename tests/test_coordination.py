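"""Mg axial ligands, hydration classes and hydrogen-bond geometry."""

import numpy as np
import pytest

from photosys.coordination import (DI_HYDRATED, MONO_HYDRATED, ANHYDROUS,
                                   axial_ligands, find_hbonds,
                                   hydration_census)
from photosys.model import Atom, Chain, Residue, StructureModel, \
    classify_components
from photosys.synth import SyntheticSpec, generate_monomer
from photosys.io import parse_structure


def _chl(seq, mg, chain="P", code="CLA"):
    mg = np.asarray(mg, float)
    atoms = [Atom("MG", "MG", mg)]
    for name, d in (("NA", (2.05, 0, 0)), ("NB", (0, 2.05, 0)),
                    ("NC", (-2.05, 0, 0)), ("ND", (0, -2.05, 0))):
        atoms.append(Atom(name, "N", mg + d))
    return Residue(code, seq, chain, atoms=atoms)


def _water(seq, pos, chain="P"):
    return Residue("HOH", seq, chain, atoms=[Atom("O", "O", pos)])


def _model(residues):
    return classify_components(StructureModel([Chain("P",
                                                     residues=residues)]))


def test_isolated_chlorophyll_square_planar():
    rec = axial_ligands(_model([_chl(601, (0, 0, 0))]), ("P", 601, "CLA"))
    assert rec.axial_ligands == []
    assert rec.coordination_number == 4
    assert rec.hydration_class == ANHYDROUS


def test_single_axial_water_mono_hydrated():
    model = _model([_chl(601, (0, 0, 0)), _water(901, (0, 0, 2.2))])
    rec = axial_ligands(model, ("P", 601, "CLA"))
    assert [l.category for l in rec.axial_ligands] == ["water"]
    assert rec.axial_ligands[0].distance == pytest.approx(2.2)
    assert rec.coordination_number == 5
    assert rec.hydration_class == MONO_HYDRATED


def test_two_axial_waters_di_hydrated():
    model = _model([_chl(601, (0, 0, 0)), _water(901, (0, 0, 2.2)),
                    _water(902, (0, 0, -2.3))])
    rec = axial_ligands(model, ("P", 601, "CLA"))
    assert rec.hydration_class == DI_HYDRATED
    assert rec.coordination_number == 6


def test_own_ring_nitrogens_never_ligands():
    """A neighbouring chlorophyll's ring N can ligate, but never the
    site's own tetrapyrrole nitrogens."""
    model = _model([_chl(601, (0, 0, 0)), _chl(602, (0, 0, 4.0))])
    rec = axial_ligands(model, ("P", 601, "CLA"))
    assert all(l.residue.auth_seq_id != 601 for l in rec.axial_ligands)


def test_non_chlorophyll_site_raises():
    model = _model([_water(901, (0, 0, 0))])
    with pytest.raises((TypeError, KeyError)):
        axial_ligands(model, ("P", 901, "HOH"))


def test_ligands_match_allpairs_oracle(dimer_fixture):
    _, _, model = dimer_fixture
    cutoff = 2.9
    entries = [(r, a) for r, a in model.atoms()
               if a.is_heavy and a.element.upper() in ("N", "O", "S")]
    for chl in model.chlorophylls():
        mg = chl.mg.pos
        expected = sorted(
            (round(float(np.linalg.norm(a.pos - mg)), 9),
             r.key, a.name)
            for r, a in entries
            if r is not chl and np.linalg.norm(a.pos - mg) <= cutoff)
        rec = axial_ligands(model, chl, cutoff)
        got = sorted((round(l.distance, 9), l.residue.key, l.atom_name)
                     for l in rec.axial_ligands)
        assert got == expected


def test_hydration_classes_match_manifest(dimer_fixture):
    _, manifest, model = dimer_fixture
    stats = hydration_census(model)
    got = {f"{r.site[0]}:{r.site[2]}:{r.site[1]}": r.hydration_class
           for r in stats.records}
    assert got == manifest["hydration"]["classes"]
    # hydration classes partition the chlorophyll set
    assert len(stats.records) == len(model.chlorophylls())


def test_hydration_ratio_from_generator(monomer_fixture):
    _, manifest, model = monomer_fixture
    stats = hydration_census(model)
    assert stats.frac_water_coordinated_a == pytest.approx(
        manifest["hydration"]["frac_a"])
    assert stats.frac_water_coordinated_b == pytest.approx(
        manifest["hydration"]["frac_b"])
    assert stats.ratio_b_over_a == pytest.approx(4.0)


def test_zero_waters_ratio_unavailable(tmp_path):
    spec = SyntheticSpec(water_coord_fraction_a=0.0,
                         water_coord_fraction_b=0.0, n_free_waters=0,
                         seed=4)
    path, _ = generate_monomer(spec, tmp_path / "dry.cif")
    stats = hydration_census(parse_structure(path))
    assert stats.frac_water_coordinated_a == 0.0
    assert stats.frac_water_coordinated_b == 0.0
    assert stats.ratio_b_over_a is None


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _ser(seq, og, chain="A"):
    og = np.asarray(og, float)
    return Residue("SER", seq, chain, atoms=[
        Atom("CB", "C", og + (1.4, 0, 0)),
        Atom("OG", "O", og),
    ])


def _gly(seq, o, chain="B"):
    o = np.asarray(o, float)
    return Residue("GLY", seq, chain, atoms=[
        Atom("C", "C", o + (0, 1.2, 0)),
        Atom("O", "O", o),
    ])


def _two_chain_model(res_a, res_b):
    m = StructureModel([Chain("A", residues=res_a),
                        Chain("B", residues=res_b)])
    return classify_components(m)


def test_distant_residues_no_bond():
    model = _two_chain_model([_ser(1, (0, 0, 0))], [_gly(1, (10, 0, 0))])
    assert find_hbonds(model, "chain=A", "chain=B") == []


def test_hydroxyl_to_carbonyl_bond_found():
    model = _two_chain_model([_ser(1, (0, 0, 0))], [_gly(1, (-2.9, 0, 0))])
    bonds = find_hbonds(model, "chain=A", "chain=B")
    assert len(bonds) == 1
    b = bonds[0]
    assert (b.donor_atom, b.acceptor_atom) == ("OG", "O")
    assert b.distance == pytest.approx(2.9)
    assert b.donor_angle == pytest.approx(180.0)


def test_bad_donor_angle_rejected():
    # acceptor on the same side as the antecedent CB -> angle ~0
    model = _two_chain_model([_ser(1, (0, 0, 0))], [_gly(1, (2.8, 0, 0))])
    assert find_hbonds(model, "chain=A", "chain=B") == []


def test_water_donor_needs_distance_only():
    water = Residue("HOH", 901, "A", atoms=[Atom("O", "O", (0.0, 0, 0))])
    model = _two_chain_model([water], [_gly(1, (-3.0, 0, 0))])
    bonds = find_hbonds(model, "chain=A", "chain=B")
    assert len(bonds) == 1
    assert bonds[0].donor_angle is None


def test_planted_interface_bonds_match_manifest(dimer_groups, dimer_fixture):
    model, _, g1, g2 = dimer_groups
    _, manifest, _ = dimer_fixture
    bonds = find_hbonds(model, g1, g2)
    got = {frozenset((f"{b.donor_residue.chain_id}:"
                      f"{b.donor_residue.comp_code}:"
                      f"{b.donor_residue.auth_seq_id}",
                      f"{b.acceptor_residue.chain_id}:"
                      f"{b.acceptor_residue.comp_code}:"
                      f"{b.acceptor_residue.auth_seq_id}"))
           for b in bonds}
    expected = {frozenset(pair)
                for pair in manifest["interface"]["hbond_pairs"]}
    assert got == expected


def test_hbonds_symmetric_in_group_order(dimer_groups):
    model, _, g1, g2 = dimer_groups

    def key(b):
        return frozenset((b.donor_residue.key, b.donor_atom,
                          b.acceptor_residue.key, b.acceptor_atom))

    ab = {key(b) for b in find_hbonds(model, g1, g2)}
    ba = {key(b) for b in find_hbonds(model, g2, g1)}
    assert ab == ba


def test_shrinking_dmax_never_adds_bonds(dimer_groups):
    model, _, g1, g2 = dimer_groups
    wide = {(b.donor_residue.key, b.acceptor_residue.key)
            for b in find_hbonds(model, g1, g2, d_max=3.5)}
    narrow = {(b.donor_residue.key, b.acceptor_residue.key)
              for b in find_hbonds(model, g1, g2, d_max=2.85)}
    assert narrow <= wide
    assert len(narrow) < len(wide)   # the 2.9 Å amide pair drops out
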