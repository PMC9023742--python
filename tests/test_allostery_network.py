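"""DCCM, contact graphs, communities and pathways vs independent oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from allopath.allostery_network import (
    AllosteryGraph,
    CorrelationMatrix,
    build_graph,
    compute_dccm,
    detect_communities,
    intercommunity_strength,
    optimal_path,
    pathway_table,
    suboptimal_paths,
)

from conftest import make_ensemble, make_topology
from oracles import (
    all_partitions,
    brute_force_modularity,
    naive_girvan_newman,
    random_weighted_graph,
)


def graph_from_nx(g: nx.Graph) -> AllosteryGraph:
    return AllosteryGraph(graph=g, contact_cutoff=4.5, occupancy_min=0.75, log_base="e")


# --- DCCM --------------------------------------------------------------------

def test_dccm_diagonal_and_colinear_motion():
    rng = np.random.default_rng(0)
    n, f = 12, 2000
    ref = rng.uniform(0, 40, size=(n, 3))
    frames = ref[None] + rng.normal(scale=0.02, size=(f, n, 3))
    drive = rng.normal(scale=1.0, size=(f, 1, 3))
    frames[:, 0:1, :] += drive   # beads 0 and 1 move identically
    frames[:, 1:2, :] += drive
    frames[:, 2:3, :] -= drive   # bead 2 mirrors them
    dccm = compute_dccm(make_ensemble(frames))
    c = dccm.values
    np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)
    assert c[0, 1] > 0.93
    assert c[0, 2] < -0.93


def test_dccm_matches_closed_form_from_planted_covariance(toy20):
    dccm = compute_dccm(toy20["ensemble"])
    exact = toy20["truth"].exact_dccm()
    assert np.abs(dccm.values - exact).max() < 0.05


def test_dccm_invariant_to_global_rigid_motion(toy20):
    from allopath.synthetic_complex import inject_rigid_motions

    ens = toy20["ensemble"]
    sub = make_ensemble(ens.frames[:400], topology=ens.topology)
    shaken = inject_rigid_motions(sub, seed=3)
    a = compute_dccm(sub).values
    b = compute_dccm(shaken).values
    np.testing.assert_allclose(a, b, atol=1e-6)


def test_dccm_rejects_zero_variance_residue():
    frame = np.random.default_rng(1).uniform(0, 20, size=(4, 3))
    frames = np.repeat(frame[None], 5, axis=0)  # constant ensemble
    with pytest.raises(ValueError, match="zero-variance"):
        compute_dccm(make_ensemble(frames))


# --- graph construction ------------------------------------------------------

def occupancy_ensemble(within_frames: int, total: int = 10):
    """Three beads in a line; pair (1,2) inside 4.5 Å in the first
    ``within_frames`` frames and far outside afterwards."""
    frames = np.repeat(
        np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0], [0.0, 40, 0]])[None], total, axis=0
    )
    frames[within_frames:, 2, 0] = 30.0
    frames += np.random.default_rng(2).normal(scale=1e-4, size=frames.shape)
    return make_ensemble(frames)


def test_occupancy_threshold_is_inclusive_at_75_percent():
    ens = occupancy_ensemble(8)
    dccm = compute_dccm(ens)
    g = build_graph(ens, dccm, contact_cutoff=4.5, occupancy_min=0.75)
    assert g.graph.has_edge(2, 3)  # 8/10 frames
    ens7 = occupancy_ensemble(7)
    g7 = build_graph(ens7, compute_dccm(ens7), contact_cutoff=4.5, occupancy_min=0.75)
    assert not g7.graph.has_edge(2, 3)  # 7/10 frames


def test_edge_distance_is_minus_log_correlation():
    ens = occupancy_ensemble(10)
    dccm = compute_dccm(ens)
    g = build_graph(ens, dccm, occupancy_min=0.75)
    for u, v, attrs in g.graph.edges(data=True):
        assert attrs["distance"] == pytest.approx(-math.log(abs(attrs["correlation"])), abs=1e-12)
        assert attrs["distance"] >= 0
    g10 = build_graph(ens, dccm, occupancy_min=0.75, log_base="10")
    for u, v, attrs in g10.graph.edges(data=True):
        assert attrs["distance"] == pytest.approx(-math.log10(abs(attrs["correlation"])), abs=1e-12)


def test_raising_occupancy_threshold_never_adds_edges(toy20):
    ens = toy20["ensemble"]
    dccm = compute_dccm(ens)
    loose = build_graph(ens, dccm, occupancy_min=0.5)
    tight = build_graph(ens, dccm, occupancy_min=0.9)
    assert set(tight.graph.edges) <= set(loose.graph.edges)
    tight_cut = build_graph(ens, dccm, contact_cutoff=4.0, occupancy_min=0.5)
    assert set(tight_cut.graph.edges) <= set(loose.graph.edges)


def test_invalid_occupancy_threshold_rejected(toy20):
    ens = toy20["ensemble"]
    dccm = compute_dccm(ens)
    with pytest.raises(ValueError):
        build_graph(ens, dccm, occupancy_min=0.0)


# --- communities -------------------------------------------------------------

def two_cliques_bridge():
    g = nx.Graph()
    for offset in (0, 3):
        for u, v in itertools.combinations(range(offset, offset + 3), 2):
            g.add_edge(u, v, distance=1.0)
    g.add_edge(2, 3, distance=1.0)
    return g


def test_two_cliques_split_at_the_bridge_matches_global_optimum():
    g = two_cliques_bridge()
    part = detect_communities(graph_from_nx(g))
    assert part.as_sets() == [{0, 1, 2}, {3, 4, 5}]
    best = max(all_partitions(g.nodes), key=lambda p: brute_force_modularity(g, p))
    assert {frozenset(s) for s in part.as_sets()} == {frozenset(s) for s in best}
    assert part.modularity == pytest.approx(brute_force_modularity(g, best), abs=1e-12)


def test_complete_graph_is_one_community():
    g = nx.complete_graph(5)
    nx.set_edge_attributes(g, 1.0, "distance")
    part = detect_communities(graph_from_nx(g))
    assert part.n_communities == 1


def test_empty_graph_rejected():
    with pytest.raises(ValueError, match="empty"):
        detect_communities(graph_from_nx(nx.Graph()))


def test_disconnected_components_are_never_merged():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (10, 11), (11, 12)], distance=0.5)
    part = detect_communities(graph_from_nx(g))
    cid = part.community_of
    assert cid[0] != cid[10]


def test_girvan_newman_agrees_with_naive_oracle_on_random_graphs():
    rng = np.random.default_rng(424)
    for _ in range(100):
        g = random_weighted_graph(rng)
        if g.number_of_edges() == 0:
            continue
        ours = {frozenset(c) for c in detect_communities(graph_from_nx(g)).as_sets()}
        assert ours == naive_girvan_newman(g)


def test_planted_communities_recovered(complex80):
    ens, truth = complex80["ensemble"], complex80["truth"]
    dccm = compute_dccm(ens)
    graph = build_graph(ens, dccm)
    part = detect_communities(graph)
    nodes = sorted(graph.graph.nodes)
    ari = adjusted_rand_score(
        [truth.community_of[r] for r in nodes], [part.community_of[r] for r in nodes]
    )
    assert ari >= 0.9


# --- intercommunity strength -------------------------------------------------

def test_intercommunity_strength_conservation():
    g = two_cliques_bridge()
    ag = graph_from_nx(g)
    part = detect_communities(ag)
    strength = intercommunity_strength(ag, part)
    mat = strength.to_numpy()
    np.testing.assert_allclose(mat, mat.T)
    # single bridge: the only cross strength is that edge's betweenness
    bc = nx.edge_betweenness_centrality(g, weight="distance")
    bridge = bc[(2, 3)] if (2, 3) in bc else bc[(3, 2)]
    assert mat[0, 1] == pytest.approx(bridge)
    counts = intercommunity_strength(ag, part, measure="count")
    assert counts.to_numpy()[0, 1] == 1.0


def test_no_cross_edges_gives_zero_strength():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (2, 3)], distance=1.0)
    ag = graph_from_nx(g)
    part = detect_communities(ag)
    assert intercommunity_strength(ag, part).to_numpy().sum() == 0.0


# --- optimal paths -----------------------------------------------------------

def test_three_node_line():
    g = nx.Graph()
    g.add_edge(1, 2, distance=1.0)
    g.add_edge(2, 3, distance=1.0)
    rep = optimal_path(graph_from_nx(g), 1, 3)
    assert rep.optimal_path == [1, 2, 3]
    assert rep.optimal_length == pytest.approx(2.0)
    assert rep.n_residues == 3


def test_floyd_warshall_matches_dijkstra_on_random_graphs():
    rng = np.random.default_rng(99)
    for _ in range(100):
        n = 50
        g = nx.gnp_random_graph(n, 0.08, seed=int(rng.integers(2**31)))
        for u, v in g.edges():
            g.edges[u, v]["distance"] = float(rng.uniform(0.05, 3.0))
        ag = graph_from_nx(g)
        source = int(rng.integers(n))
        lengths = nx.single_source_dijkstra_path_length(g, source, weight="distance")
        for sink in rng.integers(0, n, size=5):
            sink = int(sink)
            rep = optimal_path(ag, source, sink)
            if sink in lengths:
                assert rep.optimal_length == pytest.approx(lengths[sink], abs=1e-9)
                walked = sum(
                    g.edges[a, b]["distance"]
                    for a, b in zip(rep.optimal_path, rep.optimal_path[1:])
                )
                assert walked == pytest.approx(rep.optimal_length, abs=1e-9)
            else:
                assert not rep.connected


def test_disconnected_pair_reports_no_path():
    g = nx.Graph()
    g.add_edge(1, 2, distance=1.0)
    g.add_node(7)
    rep = optimal_path(graph_from_nx(g), 1, 7)
    assert rep.optimal_path is None and not rep.connected


def test_planted_pathway_recovered_from_sampled_ensemble(complex80):
    ens = complex80["ensemble"]
    graph = build_graph(ens, compute_dccm(ens))
    rep = optimal_path(graph, 70, 5)
    assert rep.optimal_path == complex80["truth"].path


# --- suboptimal paths --------------------------------------------------------

def test_zero_tolerance_keeps_only_optimal_paths():
    g = nx.cycle_graph(4)
    nx.set_edge_attributes(g, 1.0, "distance")
    rep = suboptimal_paths(graph_from_nx(g), 0, 2, tolerance=0.0)
    assert rep.n_suboptimal == 2  # two symmetric two-edge routes
    assert all(len(p) == 3 for p in rep.suboptimal_paths)


def test_suboptimal_counts_match_exhaustive_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(30):
        g = random_weighted_graph(rng, n_max=10)
        nodes = sorted(g)
        source, sink = nodes[0], nodes[-1]
        tolerance = float(rng.uniform(0.0, 2.0))
        rep = suboptimal_paths(graph_from_nx(g), source, sink, tolerance=tolerance)
        assert not rep.truncated
        lengths = [
            sum(g.edges[a, b]["distance"] for a, b in zip(p, p[1:]))
            for p in nx.all_simple_paths(g, source, sink)
        ]
        optimal = min(lengths)
        expected = sum(1 for l in lengths if l <= optimal + tolerance + 1e-12)
        assert rep.n_suboptimal == expected
        assert rep.optimal_length == pytest.approx(optimal, abs=1e-9)
        assert all(
            sum(g.edges[a, b]["distance"] for a, b in zip(p, p[1:]))
            >= rep.optimal_length - 1e-9
            for p in rep.suboptimal_paths
        )


def test_expansion_cap_flags_truncation():
    g = nx.complete_graph(9)
    nx.set_edge_attributes(g, 1.0, "distance")
    rep = suboptimal_paths(graph_from_nx(g), 0, 8, tolerance=10.0, max_expansions=50)
    assert rep.truncated


def test_pathway_table_composes_components(toy20):
    ens = toy20["ensemble"]
    graph = build_graph(ens, compute_dccm(ens), occupancy_min=0.5)
    table = pathway_table(graph, [(1, 20)], tolerance=0.5)
    assert len(table) == 1
    rep = suboptimal_paths(graph, 1, 20, tolerance=0.5)
    row = table.iloc[0]
    assert row["optimal_length"] == pytest.approx(rep.optimal_length)
    assert row["n_residues"] == rep.n_residues
    assert row["n_suboptimal"] == rep.n_suboptimal


def test_correlation_matrix_validation():
    bad = np.array([[1.0, 0.5], [0.4, 1.0]])
    with pytest.raises(ValueError, match="symmetric"):
        CorrelationMatrix(values=bad, res_indices=np.array([1, 2]), n_frames=10)
    bad2 = np.array([[1.0, 1.5], [1.5, 1.0]])
    with pytest.raises(ValueError, match="<= 1"):
        CorrelationMatrix(values=bad2, res_indices=np.array([1, 2]), n_frames=10)
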