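"""Chlorophyll Mg-Mg network construction, grouping and export."""

import numpy as np
import pytest

from photosys.inventory import cofactor_census
from photosys.model import Atom, Chain, Residue, StructureModel, \
    classify_components
from photosys.network import (brute_force_edges, build_network, export_graph,
                              inter_group_edges,
                              likely_inter_subunit_pathways, read_edge_tsv)
from photosys.synth import chlorophyll_cloud_model, random_rotation


def _chl(seq, mg, chain="P"):
    mg = np.asarray(mg, float)
    return Residue("CLA", seq, chain, atoms=[
        Atom("MG", "MG", mg), Atom("NA", "N", mg + (2.05, 0, 0))])


def _model(*chains):
    return classify_components(StructureModel(list(chains)))


def _edge_keys(graph):
    return {tuple(sorted((e.a.site, e.b.site))) for e in graph.edges}


def test_single_chlorophyll_graph():
    g = build_network(_model(Chain("P", residues=[_chl(601, (0, 0, 0))])))
    assert (g.n_nodes, g.n_edges) == (1, 0)


def test_closed_threshold_boundary():
    near = _model(Chain("P", residues=[_chl(601, (0, 0, 0)),
                                       _chl(602, (23.0, 0, 0))]))
    far = _model(Chain("P", residues=[_chl(601, (0, 0, 0)),
                                      _chl(602, (23.01, 0, 0))]))
    assert build_network(near).n_edges == 1
    assert build_network(far).n_edges == 0


@pytest.mark.parametrize("seed", range(8))
def test_kdtree_matches_bruteforce_oracle(seed):
    model = chlorophyll_cloud_model(n=30, box=55.0, seed=seed)
    fast = _edge_keys(build_network(model, use_kdtree=True))
    slow = _edge_keys(build_network(model, use_kdtree=False))
    oracle = brute_force_edges(model)
    assert fast == oracle
    assert slow == oracle


def test_edges_match_manifest(dimer_fixture):
    _, manifest, model = dimer_fixture
    graph = build_network(model)
    got = {tuple(sorted((f"{e.a.site[0]}:{e.a.site[2]}:{e.a.site[1]}",
                         f"{e.b.site[0]}:{e.b.site[2]}:{e.b.site[1]}")))
           for e in graph.edges}
    expected = {tuple(sorted((a, b)))
                for a, b, _ in manifest["network"]["edges"]}
    assert got == expected


def test_inter_group_planted_pair(dimer_fixture):
    _, manifest, model = dimer_fixture
    grouping = manifest["grouping"]
    cross = inter_group_edges(build_network(model, grouping=grouping))
    assert len(cross) == 1
    sites = {cross[0].a.site, cross[0].b.site}
    assert sites == {("P", 888, "CLA"), ("P2", 888, "CLA")}
    assert cross[0].distance == pytest.approx(
        manifest["spec"]["cross_pair_distance"], abs=1e-3)


def test_single_group_has_no_cross_edges(dimer_fixture):
    _, _, model = dimer_fixture
    grouping = {c.chain_id: "ALL" for c in model.chains}
    assert inter_group_edges(build_network(model, grouping=grouping)) == []


def test_unmapped_chain_raises(dimer_fixture):
    _, _, model = dimer_fixture
    with pytest.raises(KeyError):
        inter_group_edges(build_network(model), grouping={"P": "M1"})


def test_group_label_swap_invariance(dimer_fixture):
    _, manifest, model = dimer_fixture
    g1 = manifest["grouping"]
    g2 = {k: ("M1" if v == "M2" else "M2") for k, v in g1.items()}
    e1 = {(tuple(sorted((a.site, b.site))), round(d, 6))
          for a, b, d in ((e.a, e.b, e.distance) for e in
                          inter_group_edges(build_network(model,
                                                          grouping=g1)))}
    e2 = {(tuple(sorted((a.site, b.site))), round(d, 6))
          for a, b, d in ((e.a, e.b, e.distance) for e in
                          inter_group_edges(build_network(model,
                                                          grouping=g2)))}
    assert e1 == e2


def test_increasing_cutoff_never_removes_edges(monomer_fixture):
    _, _, model = monomer_fixture
    small = _edge_keys(build_network(model, cutoff=15.0))
    large = _edge_keys(build_network(model, cutoff=23.0))
    assert small <= large


def test_graph_invariant_under_rigid_transform(monomer_fixture):
    _, _, model = monomer_fixture
    R = random_rotation(np.random.default_rng(5))
    moved = model.transformed(R, np.array([11.0, -2.0, 30.0]))
    d0 = sorted(round(e.distance, 6) for e in build_network(model).edges)
    d1 = sorted(round(e.distance, 6) for e in build_network(moved).edges)
    assert _edge_keys(build_network(model)) == _edge_keys(
        build_network(moved))
    np.testing.assert_allclose(d1, d0, atol=1e-6)


def test_width_weight_decreases_with_distance(monomer_fixture):
    _, _, model = monomer_fixture
    edges = sorted(build_network(model).edges, key=lambda e: e.distance)
    weights = [e.width_weight for e in edges]
    assert all(w > 0 for w in weights)
    assert weights == sorted(weights, reverse=True)


def test_likely_pathways_one_per_chain_pair(dimer_fixture):
    _, _, model = dimer_fixture
    graph = build_network(model)
    best = likely_inter_subunit_pathways(graph)
    pairs = [tuple(sorted((e.a.chain_id, e.b.chain_id))) for e in best]
    assert len(pairs) == len(set(pairs))
    for e in best:
        rivals = [r.distance for r in graph.edges
                  if {r.a.chain_id, r.b.chain_id} ==
                  {e.a.chain_id, e.b.chain_id}]
        assert e.distance == min(rivals)


def test_export_roundtrip_and_census_consistency(dimer_fixture, tmp_path):
    _, _, model = dimer_fixture
    graph = build_network(model)
    out = tmp_path / "edges.tsv"
    export_graph(graph, out, "edge_tsv")
    rows = read_edge_tsv(out)
    assert len(rows) == graph.n_edges
    by_dist = sorted(round(e.distance, 3) for e in graph.edges)
    assert sorted(d for _, _, d in rows) == pytest.approx(by_dist)
    assert graph.n_nodes == cofactor_census(model).count("chlorophyll_a") + \
        cofactor_census(model).count("chlorophyll_b")


def test_graphml_export(dimer_fixture, tmp_path):
    import networkx as nx
    _, _, model = dimer_fixture
    graph = build_network(model)
    out = tmp_path / "net.graphml"
    export_graph(graph, out, "graphml")
    g = nx.read_graphml(out)
    assert g.number_of_nodes() == graph.n_nodes
    assert g.number_of_edges() == graph.n_edges


def test_empty_graph_exports_valid_file(tmp_path):
    g = build_network(_model(Chain("P", residues=[_chl(601, (0, 0, 0))])))
    out = tmp_path / "empty.tsv"
    export_graph(g, out, "edge_tsv")
    assert read_edge_tsv(out) == []
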