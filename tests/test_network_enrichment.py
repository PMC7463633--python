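"""Similarity indices, network layers, RWR, permutation null, clustering,
and cluster over-representation."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from fusemet.network_enrichment import (
    FingerprintSet,
    PathwayDatabase,
    build_chemical_network,
    build_pathway_network,
    build_universe,
    enrich_clusters,
    extract_subnetwork,
    fuse_networks,
    jaccard_index,
    louvain_partition,
    map_seeds,
    permutation_percentiles,
    random_walk_restart,
    tanimoto_index,
)


def random_weighted_graph(n, p, rng):
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.1, 3.0))
    return g


def rwr_direct_solve(g, seeds, r):
    """Dense linear-algebra oracle: p = r (I − (1−r) W)⁻¹ e, renormalized."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    colsum = a.sum(axis=0)
    w = np.divide(a, np.where(colsum == 0, 1.0, colsum)[None, :])
    w[:, colsum == 0] = 0.0
    e = np.zeros(len(nodes))
    for s in seeds:
        e[nodes.index(s)] = 1.0 / len(seeds)
    p = r * np.linalg.solve(np.eye(len(nodes)) - (1 - r) * w, e)
    return dict(zip(nodes, p / p.sum()))


# --------------------------------------------------------------------- #
# seeds and universe
# --------------------------------------------------------------------- #

def test_map_seeds_partitions_by_annotation(toy_pathway_db):
    candidates = [f"m{i}" for i in range(1, 8)] + ["x1", "x2"]
    seeds = map_seeds(candidates, toy_pathway_db)
    assert seeds.mapped == [f"m{i}" for i in range(1, 8)]
    assert seeds.unmapped == ["x1", "x2"]
    full = map_seeds(["m1", "m4"], toy_pathway_db)
    assert full.unmapped == []
    with pytest.raises(ValueError, match="no seeds mappable"):
        map_seeds(["y1"], toy_pathway_db)


def test_build_universe_is_union_of_seed_pathways(toy_pathway_db):
    seeds = map_seeds(["m1"], toy_pathway_db)
    pids, universe = build_universe(seeds, toy_pathway_db)
    assert pids == {"P1"}
    assert universe == {"m1", "m2", "m3"}
    seeds2 = map_seeds(["m2", "m3"], toy_pathway_db)
    pids2, universe2 = build_universe(seeds2, toy_pathway_db)
    assert pids2 == {"P1", "P2"}          # shared pathway appears once
    assert universe2 == {"m1", "m2", "m3", "m4"}


# --------------------------------------------------------------------- #
# similarity indices
# --------------------------------------------------------------------- #

@pytest.mark.parametrize("a,b,expected", [
    ({"P1", "P2"}, {"P1", "P2"}, 1.0),
    ({"P1"}, {"P2"}, 0.0),
    ({"P1", "P2"}, {"P2", "P3"}, 1 / 3),
])
def test_jaccard_hand_cases(a, b, expected):
    assert jaccard_index(a, b) == pytest.approx(expected)


def test_tanimoto_hand_cases():
    assert tanimoto_index([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0
    assert tanimoto_index([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0
    # a = 2, b = 2, c = 1 -> 1/(2+2-1) = 1/3
    assert tanimoto_index([1, 1, 0, 0], [0, 1, 1, 0]) == pytest.approx(1 / 3)
    with pytest.raises(ValueError, match="length"):
        tanimoto_index([1, 0], [1, 0, 1])


def test_similarities_match_exhaustive_oracles_on_random_pairs():
    rng = np.random.default_rng(11)
    universe_pathways = [f"P{i}" for i in range(12)]
    for _ in range(1000):
        a = set(rng.choice(universe_pathways,
                           size=int(rng.integers(1, 8)), replace=False))
        b = set(rng.choice(universe_pathways,
                           size=int(rng.integers(1, 8)), replace=False))
        brute = sum(1 for x in a if x in b) / len(a | b)
        assert jaccard_index(a, b) == pytest.approx(brute, abs=1e-15)
        x = (rng.random(64) < 0.4).astype(int)
        y = (rng.random(64) < 0.4).astype(int)
        if x.sum() == 0:
            x[0] = 1
        if y.sum() == 0:
            y[1] = 1
        c = int(sum(1 for i in range(64) if x[i] and y[i]))
        brute_t = c / (int(x.sum()) + int(y.sum()) - c)
        assert tanimoto_index(x, y) == pytest.approx(brute_t, abs=1e-15)


# --------------------------------------------------------------------- #
# network layers
# --------------------------------------------------------------------- #

def test_pathway_network_matches_bruteforce_adjacency(toy_pathway_db):
    universe = {"m1", "m2", "m3", "m4"}
    net = build_pathway_network(universe, toy_pathway_db)
    ann = toy_pathway_db.annotations
    for u in universe:
        for v in universe:
            if u >= v:
                continue
            j = len(ann[u] & ann[v]) / len(ann[u] | ann[v])
            if j > 0:
                assert net[u][v]["weight"] == pytest.approx(j)
            else:
                assert not net.has_edge(u, v)
    # metabolites sharing exactly one pathway and nothing else: complete, w=1
    db2 = PathwayDatabase(pathways={"Q": {"a", "b", "c"}})
    net2 = build_pathway_network({"a", "b", "c"}, db2)
    assert net2.number_of_edges() == 3
    assert all(w == 1.0 for _, _, w in net2.edges(data="weight"))


def test_chemical_network_binarization_matches_sort_oracle():
    rng = np.random.default_rng(3)
    ids = [f"m{i}" for i in range(15)]  # 105 pairs
    fps = FingerprintSet(length=64, bits={
        i: np.clip((rng.random(64) < 0.4).astype(np.uint8), 0, 1) for i in ids})
    for i in ids:
        if fps.bits[i].sum() == 0:
            fps.bits[i][0] = 1
    net = build_chemical_network(ids, fps, percentile_cut=90)
    sims = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            sims.append((tanimoto_index(fps.bits[ids[a]], fps.bits[ids[b]]),
                         ids[a], ids[b]))
    threshold = np.percentile([s[0] for s in sims], 90)
    expected = {(min(a, b), max(a, b)) for s, a, b in sims if s >= threshold}
    got = {(min(u, v), max(u, v)) for u, v in net.edges}
    assert got == expected
    assert all(w == 1.0 for _, _, w in net.edges(data="weight"))


def test_chemical_network_degenerate_and_isolation_rules():
    ids = ["a", "b", "c", "d"]
    same = np.array([1, 0, 1, 0], dtype=np.uint8)
    fps = FingerprintSet(length=4, bits={i: same.copy() for i in ids[:3]})
    net = build_chemical_network(ids, fps, percentile_cut=90)
    # all pairwise similarities equal -> complete graph on fingerprinted nodes
    assert net.subgraph(ids[:3]).number_of_edges() == 3
    # member without fingerprint stays isolated
    assert net.degree("d") == 0
    with pytest.raises(ValueError, match="two fingerprinted"):
        build_chemical_network(["a", "d"], FingerprintSet(
            length=4, bits={"a": same.copy()}), 90)


def test_fusion_sums_weights_and_commutes():
    p = nx.Graph(layer="pathway")
    p.add_edge("a", "b", weight=0.4)
    p.add_edge("b", "c", weight=0.25)
    c = nx.Graph(layer="chemical")
    c.add_edge("a", "b", weight=1.0)
    c.add_node("d")
    fused = fuse_networks(p, c)
    assert fused["a"]["b"]["weight"] == pytest.approx(1.4)
    assert fused["b"]["c"]["weight"] == pytest.approx(0.25)
    assert not fused.has_edge("a", "d")
    assert set(fused.nodes) == {"a", "b", "c", "d"}
    other = fuse_networks(c, p)
    assert sorted(fused.edges(data="weight")) == sorted(other.edges(data="weight"))


# --------------------------------------------------------------------- #
# random walk with restarts
# --------------------------------------------------------------------- #

def test_rwr_restart_one_returns_seed_vector():
    g = nx.path_graph(5)
    for u, v in g.edges:
        g[u][v]["weight"] = 1.0
    res = random_walk_restart(g, [1, 3], restart_prob=1.0)
    assert res.scores[1] == pytest.approx(0.5)
    assert res.scores[3] == pytest.approx(0.5)
    assert res.scores[0] == 0.0


def test_rwr_path_graph_matches_direct_solve():
    g = nx.path_graph(3)
    for u, v in g.edges:
        g[u][v]["weight"] = 1.0
    res = random_walk_restart(g, [0], restart_prob=0.5, tol=1e-13)
    oracle = rwr_direct_solve(g, [0], 0.5)
    for n in g.nodes:
        assert res.scores[n] == pytest.approx(oracle[n], abs=1e-9)


def test_rwr_matches_direct_solve_on_random_graphs():
    rng = np.random.default_rng(17)
    for _ in range(25):
        g = random_weighted_graph(int(rng.integers(5, 51)), 0.2, rng)
        nodes = sorted(g.nodes)
        seeds = list(rng.choice(nodes, size=min(4, len(nodes)), replace=False))
        res = random_walk_restart(g, seeds, 0.7, tol=1e-13)
        oracle = rwr_direct_solve(g, seeds, 0.7)
        assert res.converged
        assert sum(res.scores.values()) == pytest.approx(1.0, abs=1e-9)
        for n in nodes:
            assert res.scores[n] == pytest.approx(oracle[n], abs=1e-8)


def test_rwr_requires_seeds_in_network():
    g = nx.path_graph(3)
    with pytest.raises(ValueError):
        random_walk_restart(g, [])
    with pytest.raises(ValueError):
        random_walk_restart(g, [99])


# --------------------------------------------------------------------- #
# permutation percentiles and subnetwork extraction
# --------------------------------------------------------------------- #

def test_permutation_percentiles_deterministic_and_bounded():
    rng = np.random.default_rng(8)
    g = random_weighted_graph(40, 0.15, rng)
    seeds = [0, 1, 2]
    prop = random_walk_restart(g, seeds)
    a = permutation_percentiles(g, prop, 3, n_perm=300, rng_seed=5)
    b = permutation_percentiles(g, prop, 3, n_perm=300, rng_seed=5)
    assert a.percentiles == b.percentiles
    assert all(0 <= v <= 100 for v in a.percentiles.values())
    # a node whose observed score exceeds every null draw sits at exactly 100
    from fusemet.network_enrichment import PropagationResult
    sky = dict(prop.scores)
    node = sorted(g.nodes)[0]
    sky[node] = 2.0  # above any probability mass a null draw can produce
    forced = permutation_percentiles(
        g, PropagationResult(scores=sky, restart_prob=0.7,
                             iterations=1, converged=True),
        3, n_perm=300, rng_seed=5)
    assert forced.percentiles[node] == 100.0


def test_percentile_monotone_in_observed_score():
    rng = np.random.default_rng(12)
    g = random_weighted_graph(25, 0.25, rng)
    prop = random_walk_restart(g, [0, 1])
    bumped_scores = dict(prop.scores)
    node = sorted(g.nodes)[5]
    bumped_scores[node] = bumped_scores[node] * 1.5
    from fusemet.network_enrichment import PropagationResult
    bumped = PropagationResult(scores=bumped_scores, restart_prob=0.7,
                               iterations=prop.iterations, converged=True)
    a = permutation_percentiles(g, prop, 2, n_perm=200, rng_seed=1)
    b = permutation_percentiles(g, bumped, 2, n_perm=200, rng_seed=1)
    assert b.percentiles[node] >= a.percentiles[node]


def test_extract_subnetwork_boundary_inclusive():
    g = nx.path_graph(4)
    for u, v in g.edges:
        g[u][v]["weight"] = 1.0
    from fusemet.network_enrichment import PermutationResult
    perms = PermutationResult(
        percentiles={0: 10.0, 1: 97.0, 2: 96.9, 3: 50.0},
        n_permutations=100, seed_size=1, rng_seed=0)
    sub = extract_subnetwork(g, perms, seeds=[0], cutoff=97)
    assert set(sub.nodes) == {0, 1}   # 97.0 kept, 96.9 dropped, seed kept
    only_seeds = extract_subnetwork(g, PermutationResult(
        percentiles={n: 0.0 for n in g.nodes}, n_permutations=100,
        seed_size=1, rng_seed=0), seeds=[2], cutoff=97)
    assert set(only_seeds.nodes) == {2}


# --------------------------------------------------------------------- #
# clustering and enrichment
# --------------------------------------------------------------------- #

def test_louvain_separates_components_and_is_deterministic():
    g = nx.Graph()
    for tri in (("a", "b", "c"), ("x", "y", "z")):
        for i in range(3):
            g.add_edge(tri[i], tri[(i + 1) % 3], weight=1.0)
    part = louvain_partition(g, rng_seed=0)
    assert len(set(part.values())) == 2
    assert part["a"] == part["b"] == part["c"]
    assert part["x"] == part["y"] == part["z"]
    assert part == louvain_partition(g, rng_seed=0)
    complete = nx.complete_graph(6)
    for u, v in complete.edges:
        complete[u][v]["weight"] = 1.0
    assert len(set(louvain_partition(complete, rng_seed=0).values())) == 1


def test_enrichment_closed_form_hypergeometric():
    # cluster = the 5 members of pathway P out of a 20-metabolite background:
    # p = 1 / C(20, 5)
    members = {f"m{i}" for i in range(5)}
    others = {f"o{i}" for i in range(15)}
    db = PathwayDatabase(pathways={"P": set(members),
                                   "Q": set(others)})
    partition = {m: 0 for m in members}
    rows = enrich_clusters(partition, db, members | others)
    row = rows[rows["pathway_id"] == "P"].iloc[0]
    assert row["p_value"] == pytest.approx(1 / math.comb(20, 5))
    assert row["overlap"] == 5
    assert row["background_size"] == 20


def test_enrichment_skips_unannotated_clusters_and_validates_background():
    db = PathwayDatabase(pathways={"P": {"a", "b"}})
    rows = enrich_clusters({"u1": 0, "u2": 0}, db, {"u1", "u2", "a", "b"})
    assert len(rows) == 0
    with pytest.raises(ValueError, match="background"):
        enrich_clusters({"a": 0, "zz": 0}, db, {"a", "b"})


def test_enrichment_flags_q_below_threshold(toy_pathway_db):
    partition = {"m5": 0, "m6": 0, "m7": 0, "m1": 1, "m4": 1}
    rows = enrich_clusters(partition, toy_pathway_db,
                           set(toy_pathway_db.metabolites))
    gamma = rows[(rows["cluster_id"] == 0) & (rows["pathway_id"] == "P3")]
    assert len(gamma) == 1
    assert (rows["enriched"] == (rows["q_value"] < 0.05)).all()
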