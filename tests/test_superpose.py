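"""Kabsch superposition and van der Waals clash detection."""

import numpy as np
import pytest

from photosys.model import Atom, Chain, Residue, StructureModel, \
    classify_components
from photosys.superpose import (DegeneratePairingError, detect_clashes,
                                kabsch, kabsch_superpose, overlap_analysis)
from photosys.synth import random_rotation


def _ca_chain(chain_id, coords):
    residues = [Residue("ALA", i + 1, chain_id,
                        atoms=[Atom("CA", "C", c)])
                for i, c in enumerate(coords)]
    return Chain(chain_id, residues=residues)


def _ca_model(coords, chain_id="A"):
    return classify_components(
        StructureModel([_ca_chain(chain_id, coords)]))


@pytest.fixture
def cloud():
    return np.random.default_rng(2).uniform(0, 30, size=(40, 3))


def test_identity_superposition(cloud):
    model = _ca_model(cloud)
    sup = kabsch_superpose(model, model, [("A", "A")])
    assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)
    assert sup.n_pairs == 40


def test_recovers_planted_transform(cloud):
    rng = np.random.default_rng(7)
    R = random_rotation(rng)
    t = np.array([4.0, -11.0, 2.5])
    moved = _ca_model(cloud @ R.T + t)
    target = _ca_model(cloud)
    sup = kabsch_superpose(moved, target, [("A", "A")])
    # inverse transform: (R^T, -R^T t)
    np.testing.assert_allclose(sup.rotation, R.T, atol=1e-6)
    np.testing.assert_allclose(sup.translation, -R.T @ t, atol=1e-6)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)


def test_noisy_superposition_beats_random_rotations(cloud):
    rng = np.random.default_rng(3)
    noisy = cloud + rng.normal(scale=0.1, size=cloud.shape)
    sup = kabsch_superpose(_ca_model(noisy), _ca_model(cloud), [("A", "A")])
    assert 0.05 <= sup.rmsd <= 0.2
    c0, c1 = noisy.mean(0), cloud.mean(0)
    for _ in range(100):
        R = random_rotation(rng)
        rmsd = np.sqrt(np.mean(np.sum(
            ((noisy - c0) @ R.T - (cloud - c1)) ** 2, axis=1)))
        assert sup.rmsd <= rmsd + 1e-12


def test_kabsch_matches_grid_search_oracle():
    """Exhaustive small-angle grid about z on a planar toy problem."""
    pts = np.array([[1.0, 0, 0], [0, 2.0, 0], [-1.5, 0.5, 0],
                    [0.5, -1.0, 0]])
    true_angle = np.deg2rad(9.0)

    def rot_z(a):
        return np.array([[np.cos(a), -np.sin(a), 0],
                         [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])

    target = pts @ rot_z(true_angle).T
    _, _, rmsd = kabsch(pts, target)
    grid = [np.sqrt(np.mean(np.sum((pts @ rot_z(a).T - target) ** 2,
                                   axis=1)))
            for a in np.deg2rad(np.arange(0, 360, 0.05))]
    assert rmsd <= min(grid) + 1e-9


def test_degenerate_pairings_raise():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(DegeneratePairingError):
        kabsch(line, line)
    with pytest.raises(DegeneratePairingError):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


def test_rmsd_invariant_under_common_rigid_transform(cloud):
    rng = np.random.default_rng(9)
    noisy = cloud + rng.normal(scale=0.3, size=cloud.shape)
    base = kabsch_superpose(_ca_model(noisy), _ca_model(cloud),
                            [("A", "A")]).rmsd
    R = random_rotation(rng)
    t = np.array([3.0, 3.0, -8.0])
    moved = kabsch_superpose(_ca_model(noisy @ R.T + t),
                             _ca_model(cloud @ R.T + t),
                             [("A", "A")]).rmsd
    assert moved == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# clashes
# ---------------------------------------------------------------------------

def _atom_model(chain_id, entries):
    residues = [Residue("UNK", i + 1, chain_id,
                        atoms=[Atom(name, element, pos)])
                for i, (name, element, pos) in enumerate(entries)]
    return classify_components(
        StructureModel([Chain(chain_id, residues=residues)]))


def test_clash_overlap_arithmetic():
    a = _atom_model("A", [("C1", "C", (0.0, 0, 0))])
    b = _atom_model("B", [("C1", "C", (1.0, 0, 0))])
    report = detect_clashes(a, b)
    assert len(report) == 1
    # overlap = (1.70 + 1.70 - 0.40) - 1.00
    assert report.clashes[0].overlap == pytest.approx(2.0)


def test_distant_atoms_no_clash():
    a = _atom_model("A", [("C1", "C", (0.0, 0, 0))])
    b = _atom_model("B", [("C1", "C", (10.0, 0, 0))])
    assert len(detect_clashes(a, b)) == 0


def test_clash_boundary_is_strict():
    a = _atom_model("A", [("C1", "C", (0.0, 0, 0))])
    at_limit = _atom_model("B", [("C1", "C", (3.00, 0, 0))])
    inside = _atom_model("B", [("C1", "C", (2.99, 0, 0))])
    assert len(detect_clashes(a, at_limit)) == 0
    assert len(detect_clashes(a, inside)) == 1


def test_clash_count_monotone_in_tolerance():
    rng = np.random.default_rng(1)
    pts_a = rng.uniform(0, 12, size=(40, 3))
    pts_b = rng.uniform(0, 12, size=(40, 3))
    a = _atom_model("A", [("C1", "C", p) for p in pts_a])
    b = _atom_model("B", [("C1", "C", p) for p in pts_b])
    counts = [len(detect_clashes(a, b, tolerance=tol))
              for tol in (0.0, 0.4, 0.8, 1.2)]
    assert counts == sorted(counts, reverse=True)


def test_element_radii_used():
    a = _atom_model("A", [("O1", "O", (0.0, 0, 0))])
    # O + O: limit 1.52*2 - 0.4 = 2.64
    assert len(detect_clashes(a, _atom_model("B",
                                             [("O1", "O",
                                               (2.65, 0, 0))]))) == 0
    assert len(detect_clashes(a, _atom_model("B",
                                             [("O1", "O",
                                               (2.60, 0, 0))]))) == 1


def test_overlap_analysis_far_probe_clean(dimer_fixture):
    """A probe placed 100 Å away after anchoring yields zero clashes."""
    _, _, model = dimer_fixture
    # reference = copy of the dimer with an extra far-away probe chain
    probe = _ca_chain("X", np.array([[300.0, 300.0, 300.0],
                                     [303.5, 300.0, 300.0],
                                     [300.0, 303.5, 300.0]]))
    ref = StructureModel(
        [c for c in model.transformed(np.eye(3), np.zeros(3)).chains]
        + [probe], source_id="probe_ref")
    classify_components(ref)
    sup, report = overlap_analysis(ref, model, [("A", "A"), ("B", "B")],
                                   probe_chains=["X"],
                                   against_chains=["A2", "B2", "P2"])
    assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
    assert len(report) == 0


def test_overlap_analysis_detects_planted_overlap(dimer_fixture):
    """Anchoring monomer 1 of the dimer onto monomer 2 maps its partner
    subunits onto occupied space: the probe must clash."""
    _, manifest, model = dimer_fixture
    # anchor chains of monomer 1 onto the equivalent chains of monomer 2;
    # the C2 symmetry sends monomer 2 chains onto monomer 1 positions,
    # so probing with monomer-2 chains against monomer-1 chains collides.
    pairing = [("A", "A2"), ("B", "B2"), ("C", "C2"), ("D", "D2")]
    sup, report = overlap_analysis(model, model, pairing,
                                   probe_chains=["A2", "B2"],
                                   against_chains=["A", "B"])
    assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
    verdicts = report.verdicts(min_clashes=10)
    assert verdicts.get(("A2", "A"), False) or \
        verdicts.get(("B2", "B"), False)
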