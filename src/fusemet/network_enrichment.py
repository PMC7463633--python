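"""Fused-network pathway enrichment by random walk with restarts.

The procedure prioritizes metabolites proximal to a phenotype-associated seed
set on a consensus metabolite network and tests the resulting clusters for
pathway over-representation:

1. seed metabolites are those that map to the pathway database; the analysis
   universe is every metabolite belonging to any seed-containing pathway;
2. a *pathway co-membership* network connects universe metabolites with edge
   weight equal to the Jaccard index of their pathway annotation sets;
3. a *chemical similarity* network connects metabolites whose fingerprint
   Tanimoto similarity reaches the 90th percentile of all pairwise values
   (binarized to weight 1);
4. the two layers are fused by summing edge weights;
5. random walk with restarts from the seed set scores every node; the score
   of each node is compared with its distribution over many random seed sets
   of the same size, and nodes at or above the 97th empirical percentile are
   extracted (with the seeds) as a subnetwork;
6. Louvain community detection partitions the subnetwork, and each cluster is
   tested for pathway over-representation (one-sided hypergeometric, BH
   corrected, q < 0.05).

Networks are ``networkx.Graph`` objects with a ``weight`` attribute per edge
and a ``layer`` graph attribute (``pathway``, ``chemical``, ``fused`` or
``subnetwork``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import benjamini_hochberg

logger = logging.getLogger(__name__)


# ===================================================================== #
# pathway annotations and fingerprints
# ===================================================================== #

@dataclass
class PathwayDatabase:
    """Metabolite → pathway annotations with pathway metadata.

    ``pathways`` maps pathway_id → member metabolite set; ``names`` carries a
    human-readable name per pathway.  The reverse map ``annotations`` is kept
    consistent automatically.
    """

    pathways: dict
    names: dict = field(default_factory=dict)
    annotations: dict = field(init=False)

    def __post_init__(self) -> None:
        for pid, members in self.pathways.items():
            if not members:
                raise ValueError(f"empty pathway {pid!r}")
            self.pathways[pid] = set(members)
        self.annotations = {}
        for pid, members in self.pathways.items():
            for m in members:
                self.annotations.setdefault(m, set()).add(pid)
        for pid in self.pathways:
            self.names.setdefault(pid, pid)

    def __contains__(self, metabolite_id) -> bool:
        return metabolite_id in self.annotations

    @property
    def metabolites(self) -> set:
        return set(self.annotations)

    # -- I/O ----------------------------------------------------------- #
    @classmethod
    def from_gmt(cls, path) -> "PathwayDatabase":
        pathways, names = {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                pid, desc, members = parts[0], parts[1], parts[2:]
                if pid in pathways:
                    raise ValueError(f"duplicate pathway {pid!r}")
                pathways[pid] = set(m for m in members if m)
                names[pid] = desc or pid
        return cls(pathways=pathways, names=names)

    @classmethod
    def from_long_tsv(cls, path) -> "PathwayDatabase":
        """Two-column long format: metabolite_id<TAB>pathway_id."""
        df = pd.read_csv(path, sep="\t")
        mcol, pcol = df.columns[:2]
        pathways: dict = {}
        for _, row in df.iterrows():
            pathways.setdefault(row[pcol], set()).add(row[mcol])
        return cls(pathways=pathways)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for pid in sorted(self.pathways):
                members = "\t".join(sorted(self.pathways[pid]))
                fh.write(f"{pid}\t{self.names[pid]}\t{members}\n")


@dataclass
class FingerprintSet:
    """Fixed-length binary chemical fingerprints per metabolite."""

    length: int
    bits: dict  # metabolite_id -> np.ndarray(uint8) of shape (length,)

    def __post_init__(self) -> None:
        for mid, vec in self.bits.items():
            arr = np.asarray(vec, dtype=np.uint8)
            if arr.shape != (self.length,):
                raise ValueError(f"fingerprint length mismatch for {mid!r}")
            self.bits[mid] = arr

    @classmethod
    def from_tsv(cls, path) -> "FingerprintSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        bits = {}
        length = None
        for _, row in df.iterrows():
            vec = np.frombuffer(row.iloc[1].encode(), dtype=np.uint8) - ord("0")
            if length is None:
                length = len(vec)
            bits[row.iloc[0]] = vec.astype(np.uint8)
        if length is None:
            raise ValueError("empty fingerprint file")
        return cls(length=length, bits=bits)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metabolite_id\tfingerprint\n")
            for mid in sorted(self.bits):
                fh.write(mid + "\t" + "".join(map(str, self.bits[mid])) + "\n")


@dataclass
class SeedSet:
    """Candidate metabolites split by pathway-annotation coverage."""

    mapped: list
    unmapped: list


def map_seeds(candidates, db: PathwayDatabase) -> SeedSet:
    """Partition candidate metabolites by presence in the pathway database."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate metabolites")
    mapped = [c for c in candidates if c in db]
    unmapped = [c for c in candidates if c not in db]
    if not mapped:
        raise ValueError("no seeds mappable to the pathway database")
    logger.info("mapped %d / %d candidates to pathways", len(mapped),
                len(candidates))
    return SeedSet(mapped=mapped, unmapped=unmapped)


def build_universe(seeds: SeedSet, db: PathwayDatabase) -> tuple[set, set]:
    """Pathways containing ≥1 seed, and the union of their member sets."""
    if not seeds.mapped:
        raise ValueError("seed set has no mapped metabolites")
    pathway_ids = {pid for s in seeds.mapped for pid in db.annotations[s]}
    universe = set().union(*(db.pathways[pid] for pid in pathway_ids))
    return pathway_ids, universe


# ===================================================================== #
# similarity indices and network layers
# ===================================================================== #

def jaccard_index(a, b) -> float:
    """|a ∩ b| / |a ∪ b| for two annotation sets."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def tanimoto_index(x, y) -> float:
    """c / (a + b − c) on binary fingerprints (a, b set bits; c shared)."""
    x = np.asarray(x, dtype=np.uint8)
    y = np.asarray(y, dtype=np.uint8)
    if x.shape != y.shape:
        raise ValueError("fingerprint length mismatch")
    a = int(x.sum())
    b = int(y.sum())
    c = int((x & y).sum())
    if a + b - c == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return c / (a + b - c)


def build_pathway_network(universe, db: PathwayDatabase) -> nx.Graph:
    """Pathway co-membership network; edge weight = annotation Jaccard > 0."""
    nodes = sorted(universe)
    missing = [n for n in nodes if n not in db]
    if missing:
        raise ValueError(f"universe members without annotations: {missing[:5]}")
    g = nx.Graph(layer="pathway")
    g.add_nodes_from(nodes)
    ann = db.annotations
    for i, u in enumerate(nodes):
        au = ann[u]
        for v in nodes[i + 1:]:
            inter = len(au & ann[v])
            if inter:
                g.add_edge(u, v, weight=inter / len(au | ann[v]))
    return g


def build_chemical_network(universe, fps: FingerprintSet,
                           percentile_cut: float = 90.0,
                           nonzero_only: bool = False) -> nx.Graph:
    """Binarized chemical-similarity network over fingerprinted metabolites.

    All pairwise Tanimoto similarities among universe members with
    fingerprints are computed; pairs at or above the ``percentile_cut``-th
    percentile of that distribution become weight-1 edges.  Members without a
    fingerprint stay isolated in this layer.  ``nonzero_only`` restricts the
    percentile to nonzero similarities.
    """
    nodes = sorted(universe)
    withfp = [n for n in nodes if n in fps.bits]
    if len(withfp) < 2:
        raise ValueError("need at least two fingerprinted universe members")
    mat = np.stack([fps.bits[n] for n in withfp]).astype(np.int64)
    counts = mat.sum(axis=1)
    inter = mat @ mat.T
    denom = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, inter / np.where(denom == 0, 1, denom), 0.0)
    iu = np.triu_indices(len(withfp), k=1)
    pairvals = sim[iu]
    pool = pairvals[pairvals > 0] if nonzero_only else pairvals
    if pool.size == 0:
        raise ValueError("no pairwise similarities to threshold")
    threshold = np.percentile(pool, percentile_cut)
    g = nx.Graph(layer="chemical", tanimoto_threshold=float(threshold))
    g.add_nodes_from(nodes)
    keep = pairvals >= threshold
    for i, j in zip(iu[0][keep], iu[1][keep]):
        g.add_edge(withfp[i], withfp[j], weight=1.0)
    return g


def fuse_networks(pathway_net: nx.Graph, chemical_net: nx.Graph) -> nx.Graph:
    """Consensus network: union of nodes, edge weights summed across layers."""
    g = nx.Graph(layer="fused")
    g.add_nodes_from(pathway_net.nodes)
    g.add_nodes_from(chemical_net.nodes)
    for net in (pathway_net, chemical_net):
        for u, v, w in net.edges(data="weight"):
            if g.has_edge(u, v):
                g[u][v]["weight"] += w
            else:
                g.add_edge(u, v, weight=w)
    return g


def write_edge_list(net: nx.Graph, path) -> None:
    layer = net.graph.get("layer", "")
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\tlayer\n")
        for u, v, w in sorted(net.edges(data="weight")):
            fh.write(f"{u}\t{v}\t{w:.17g}\t{layer}\n")


# ===================================================================== #
# random walk with restarts and permutation null
# ===================================================================== #

@dataclass
class PropagationResult:
    """Stationary RWR proximity scores (sum to 1)."""

    scores: dict
    restart_prob: float
    iterations: int
    converged: bool


@dataclass
class PermutationResult:
    """Per-node empirical percentile of the observed RWR score vs random seeds."""

    percentiles: dict
    n_permutations: int
    seed_size: int
    rng_seed: int


def _adjacency(net: nx.Graph) -> tuple[list, np.ndarray]:
    nodes = sorted(net.nodes)
    w = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    return nodes, w


def _column_normalized(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    colsum = w.sum(axis=0)
    dangling = colsum == 0
    wn = np.divide(w, np.where(dangling, 1.0, colsum)[None, :])
    wn[:, dangling] = 0.0
    return wn, dangling


def random_walk_restart(net: nx.Graph, seeds, restart_prob: float = 0.7,
                        tol: float = 1e-10, max_iter: int = 10000
                        ) -> PropagationResult:
    """Iterate p ← (1−r)·W·p + r·e to convergence in L1.

    ``W`` is the column-stochastic weighted adjacency (each column divided by
    its weighted degree); ``e`` is uniform over the seed set; dangling
    (isolated) nodes redistribute their mass to the seed vector, keeping the
    chain stochastic.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    if not 0 < restart_prob <= 1:
        raise ValueError("restart_prob must be in (0, 1]")
    nodes, w = _adjacency(net)
    index = {n: i for i, n in enumerate(nodes)}
    bad = [s for s in seeds if s not in index]
    if bad:
        raise ValueError(f"seeds not in network: {bad[:5]}")
    e = np.zeros(len(nodes))
    e[[index[s] for s in seeds]] = 1.0 / len(seeds)
    wn, dangling = _column_normalized(w)
    p = e.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        spill = p[dangling].sum()
        p_new = (1 - restart_prob) * (wn @ p + spill * e) + restart_prob * e
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            converged = True
            break
        p = p_new
    if not converged:
        logger.warning("RWR did not converge in %d iterations", max_iter)
    return PropagationResult(
        scores={n: float(p[i]) for i, n in enumerate(nodes)},
        restart_prob=restart_prob, iterations=it, converged=converged,
    )


def _fundamental_matrix(net: nx.Graph, restart_prob: float
                        ) -> tuple[list, np.ndarray]:
    """K = r·(I − (1−r)·W)⁻¹; RWR scores are K·e renormalized to sum 1.

    With dangling mass redirected to the seed vector, the stationary solution
    is proportional to K·e, so one dense inverse serves every seed set.
    """
    nodes, w = _adjacency(net)
    wn, _ = _column_normalized(w)
    n = len(nodes)
    k = restart_prob * np.linalg.inv(np.eye(n) - (1 - restart_prob) * wn)
    return nodes, k


def permutation_percentiles(net: nx.Graph, observed: PropagationResult,
                            seed_size: int, n_perm: int = 10000,
                            rng_seed: int = 0,
                            exclude=None) -> PermutationResult:
    """Empirical per-node percentile of observed scores under random seeding.

    Each permutation draws ``seed_size`` nodes uniformly without replacement
    and scores the network by RWR (via the precomputed fundamental matrix, so
    thousands of permutations cost one matrix inverse plus column means).
    Percentile = 100·(#null < observed + ½·#null = observed)/n_perm
    (midrank tie handling).
    """
    nodes, k = _fundamental_matrix(net, observed.restart_prob)
    pool = [n for n in nodes if not (exclude and n in exclude)]
    if seed_size > len(pool):
        raise ValueError("seed_size exceeds number of eligible nodes")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(rng_seed)
    pool_idx = np.array([nodes.index(n) for n in pool])
    obs = np.array([observed.scores[n] for n in nodes])
    less = np.zeros(len(nodes))
    equal = np.zeros(len(nodes))
    for _ in range(n_perm):
        pick = rng.choice(pool_idx, size=seed_size, replace=False)
        null = k[:, pick].mean(axis=1)
        null = null / null.sum()
        less += null < obs
        equal += null == obs
    pct = 100.0 * (less + 0.5 * equal) / n_perm
    return PermutationResult(
        percentiles={n: float(pct[i]) for i, n in enumerate(nodes)},
        n_permutations=n_perm, seed_size=seed_size, rng_seed=rng_seed,
    )


def extract_subnetwork(net: nx.Graph, perms: PermutationResult, seeds,
                       cutoff: float = 97.0) -> nx.Graph:
    """Induced subgraph on seeds plus nodes at percentile ≥ cutoff (inclusive)."""
    seeds = set(seeds)
    missing = [n for n in net.nodes if n not in perms.percentiles]
    if missing:
        raise ValueError(f"percentiles missing for nodes: {missing[:5]}")
    keep = seeds | {n for n, p in perms.percentiles.items()
                    if n in net and p >= cutoff}
    sub = net.subgraph(keep).copy()
    sub.graph["layer"] = "subnetwork"
    return sub


# ===================================================================== #
# clustering and enrichment
# ===================================================================== #

def louvain_partition(net: nx.Graph, rng_seed: int = 0) -> dict:
    """Weighted Louvain communities; dense integer ids, deterministic by seed."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comms = nx.community.louvain_communities(net, weight="weight",
                                             seed=rng_seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    return {node: cid for cid, members in enumerate(comms) for node in members}


def enrich_clusters(partition: dict, db: PathwayDatabase, background,
                    fdr: float = 0.05, joint_correction: bool = True
                    ) -> pd.DataFrame:
    """Per-cluster pathway over-representation (one-sided hypergeometric).

    The population is the annotated part of ``background``; for each cluster
    and each pathway with at least one annotated cluster member, the
    hypergeometric tail probability of the observed overlap is computed and
    BH-corrected (jointly across all cluster × pathway tests by default,
    per-cluster otherwise).  Rows carry an ``enriched`` flag for q < ``fdr``.
    """
    background = set(background)
    clusters: dict = {}
    for node, cid in partition.items():
        clusters.setdefault(cid, set()).add(node)
    for cid, members in clusters.items():
        if not members <= background:
            raise ValueError(f"cluster {cid} not contained in background")
    bg_annotated = {m for m in background if m in db}
    rows = []
    for cid in sorted(clusters):
        cluster_annotated = clusters[cid] & bg_annotated
        if not cluster_annotated:
            continue
        touched = sorted({pid for m in cluster_annotated
                          for pid in db.annotations[m]})
        for pid in touched:
            members_bg = db.pathways[pid] & bg_annotated
            overlap = len(cluster_annotated & members_bg)
            p = stats.hypergeom.sf(
                overlap - 1, len(bg_annotated), len(members_bg),
                len(cluster_annotated))
            rows.append({
                "cluster_id": cid,
                "pathway_id": pid,
                "pathway_name": db.names.get(pid, pid),
                "overlap": overlap,
                "cluster_annotated": len(cluster_annotated),
                "background_annotated": len(members_bg),
                "background_size": len(bg_annotated),
                "p_value": float(p),
            })
    out = pd.DataFrame(rows)
    if out.empty:
        out["q_value"] = []
        out["enriched"] = []
        return out
    if joint_correction:
        out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    else:
        out["q_value"] = np.nan
        for cid in out["cluster_id"].unique():
            mask = out["cluster_id"] == cid
            out.loc[mask, "q_value"] = benjamini_hochberg(
                out.loc[mask, "p_value"].to_numpy())
    out["enriched"] = out["q_value"] < fdr
    return out.sort_values(["cluster_id", "q_value", "pathway_id"]
                           ).reset_index(drop=True)
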