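"""Gene-pathway network construction, geodesic scoring and permutation nulls.

Genes are nodes; two genes are linked when at least one pathway
annotates both, and the edge carries the set of shared pathways. Every
shortest path (geodesic) between a pair of differentially expressed
genes whose nodes are *all* DEGs adds one to the score of each gene,
each link, and each pathway carried by each traversed link. Statistical
significance per pathway comes from an empirical null distribution of
scores over random node sets matched in size to the mapped DEG set.

The graph is a simple graph with per-edge pathway-label sets, so
geodesic lengths are pathway-independent; with unit edge weights,
Dijkstra's algorithm reduces to breadth-first search, implemented here
with a shortest-path predecessor DAG to enumerate *all* geodesics, not
one representative. Both the number of gene pairs with an edge
("pair edges") and the number of (pair, pathway) incidences are
reported as network size measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import NetworkError, PathCapExceeded, SchemaError
from .synthetic import PathwayAnnotation

logger = logging.getLogger(__name__)

DEFAULT_PATH_CAP = 1_000_000
_TINY_P = np.finfo(float).tiny


@dataclass
class GenePathwayNetwork:
    """Simple graph over genes with per-edge shared-pathway label sets."""

    graph: nx.Graph
    pathway_ids: list[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_pair_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_incidences(self) -> int:
        """Sum over links of the number of shared pathways each carries."""
        return sum(len(d["pathways"]) for _u, _v, d in self.graph.edges(data=True))

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    @cached_property
    def _adj(self) -> dict:
        return {u: sorted(nbrs) for u, nbrs in self.graph.adj.items()}

    @cached_property
    def _edge_pathways(self) -> dict:
        return {
            (u, v) if u <= v else (v, u): tuple(sorted(d["pathways"]))
            for u, v, d in self.graph.edges(data=True)
        }

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


@dataclass
class ScoreTable:
    """Zero-initialized geodesic-traversal counts per gene, link and pathway."""

    gene_score: dict
    edge_score: dict
    pathway_score: dict
    n_deg_mapped: int
    n_paths: int = 0


@dataclass
class NullDistribution:
    """Per-pathway network scores of random DEG-sized node sets."""

    scores: pd.DataFrame  # one row per replicate, one column per pathway
    seed: int
    n_deg_mapped: int

    @property
    def n_perm(self) -> int:
        return len(self.scores)


def build_network(ann: PathwayAnnotation) -> GenePathwayNetwork:
    """Link every pair of genes that shares at least one pathway.

    The edge attribute ``pathways`` is the full set of pathways
    annotating both endpoints. Genes sharing no pathway with any other
    gene are not nodes. Pathways contributing no link still appear in
    the pathway universe (with score zero downstream).
    """
    if not ann.pathways:
        raise NetworkError("empty annotation yields an empty network")
    g: nx.Graph = nx.Graph()
    for pid, (_desc, members) in ann.pathways.items():
        members = sorted(members)
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                if g.has_edge(u, v):
                    g.edges[u, v]["pathways"] = g.edges[u, v]["pathways"] | {pid}
                else:
                    g.add_edge(u, v, pathways=frozenset({pid}))
    if g.number_of_nodes() == 0:
        raise NetworkError("annotation produces no shared-pathway links")
    net = GenePathwayNetwork(graph=g, pathway_ids=list(ann.pathways))
    logger.info(
        "network: %d nodes, %d pair edges, %d pathway incidences, %d pathways",
        net.n_nodes,
        net.n_pair_edges,
        net.n_incidences,
        net.n_pathways,
    )
    return net


def _bfs_dag(adj: dict, source: str):
    """BFS distances and shortest-path predecessor lists from ``source``."""
    dist = {source: 0}
    preds: dict = {source: []}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            du = dist[u]
            for w in adj[u]:
                d = dist.get(w)
                if d is None:
                    dist[w] = du + 1
                    preds[w] = [u]
                    nxt.append(w)
                elif d == du + 1:
                    preds[w].append(u)
        frontier = nxt
    return dist, preds


@dataclass
class Geodesics:
    """All minimum-length paths between one node pair."""

    paths: list
    exhaustive: bool = True

    def __iter__(self):
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)


def all_shortest_paths(
    net: GenePathwayNetwork, pair: tuple, path_cap: int | None = None
) -> Geodesics:
    """Enumerate every geodesic between a node pair on the unweighted graph.

    Returns an empty set when the pair is disconnected. If ``path_cap``
    is given and the enumeration exceeds it, the result is truncated
    and flagged non-exhaustive with a warning.
    """
    u, v = pair
    if u == v:
        raise NetworkError("geodesics are defined for distinct nodes only")
    for x in (u, v):
        if x not in net.graph:
            raise NetworkError(f"node {x!r} not in network")
    dist, preds = _bfs_dag(net._adj, u)
    if v not in dist:
        return Geodesics(paths=[])
    paths: list = []
    stack = [(v, (v,))]
    while stack:
        node, path = stack.pop()
        if node == u:
            paths.append(tuple(reversed(path)))
            if path_cap is not None and len(paths) >= path_cap:
                logger.warning(
                    "geodesic enumeration for (%s, %s) capped at %d paths", u, v, path_cap
                )
                return Geodesics(paths=paths, exhaustive=False)
            continue
        for p in preds[node]:
            stack.append((p, path + (p,)))
    return Geodesics(paths=paths)


def score_network(
    net: GenePathwayNetwork,
    deg_set,
    pathway_increment: str = "per_edge",
    path_cap: int = DEFAULT_PATH_CAP,
) -> ScoreTable:
    """Score genes, links and pathways by DEG-only geodesics.

    For every unordered pair of mapped DEGs, every geodesic of the full
    network whose nodes all lie in the DEG set adds one to each node on
    the path, each link on the path, and — under the default
    ``per_edge`` rule — one per traversed link per pathway that link
    carries. The alternative ``per_path`` rule adds at most one per
    path per pathway (the union of the path's link labels). Pairs in
    different components contribute nothing. Exceeding ``path_cap``
    total enumerated geodesics aborts the run.
    """
    if pathway_increment not in ("per_edge", "per_path"):
        raise SchemaError(f"unknown pathway_increment {pathway_increment!r}")
    nodes = net.graph
    deg = sorted(g for g in set(deg_set) if g in nodes)
    dropped = len(set(deg_set)) - len(deg)
    if dropped:
        logger.info("%d DEG(s) not mapped to the network were dropped", dropped)

    gene_score = dict.fromkeys(net.graph.nodes, 0)
    edge_score = dict.fromkeys(net._edge_pathways, 0)
    pathway_score = dict.fromkeys(net.pathway_ids, 0)
    edge_pathways = net._edge_pathways
    adj = net._adj
    deg_members = set(deg)
    n_paths = 0

    for i, u in enumerate(deg):
        if i + 1 == len(deg):
            break
        dist, preds = _bfs_dag(adj, u)
        for v in deg[i + 1 :]:
            if v not in dist:
                continue
            # Backtrack the predecessor DAG from v, pruning at any
            # non-DEG node: interior nodes of a qualifying geodesic
            # must themselves be DEGs.
            stack = [(v, (v,))]
            while stack:
                node, path = stack.pop()
                if node == u:
                    n_paths += 1
                    if n_paths > path_cap:
                        raise PathCapExceeded(
                            f"more than {path_cap} DEG-only geodesics; raise "
                            "path_cap or reduce the DEG set"
                        )
                    seen_pathways = set() if pathway_increment == "per_path" else None
                    prev = None
                    for x in path:  # orientation is irrelevant to scoring
                        gene_score[x] += 1
                        if prev is not None:
                            key = (prev, x) if prev <= x else (x, prev)
                            edge_score[key] += 1
                            if pathway_increment == "per_edge":
                                for pid in edge_pathways[key]:
                                    pathway_score[pid] += 1
                            else:
                                seen_pathways.update(edge_pathways[key])
                        prev = x
                    if seen_pathways:
                        for pid in seen_pathways:
                            pathway_score[pid] += 1
                    continue
                for p in preds[node]:
                    if p == u or p in deg_members:
                        stack.append((p, path + (p,)))
    return ScoreTable(
        gene_score=gene_score,
        edge_score=edge_score,
        pathway_score=pathway_score,
        n_deg_mapped=len(deg),
        n_paths=n_paths,
    )


def permutation_null(
    net: GenePathwayNetwork,
    n_deg_mapped: int,
    n_perm: int = 1000,
    seed: int = 0,
    pathway_increment: str = "per_edge",
    path_cap: int = DEFAULT_PATH_CAP,
) -> NullDistribution:
    """Empirical null: score random node sets matched in size to the DEG set.

    Each replicate draws ``n_deg_mapped`` nodes uniformly without
    replacement from the network nodes (not the full gene universe) and
    scores them exactly as the observed set.
    """
    nodes = np.array(net.nodes())
    if not 0 < n_deg_mapped <= len(nodes):
        raise NetworkError(
            f"n_deg_mapped must be in 1..{len(nodes)}, got {n_deg_mapped}"
        )
    rng = np.random.default_rng(seed)
    mat = np.zeros((n_perm, net.n_pathways), dtype=np.int64)
    cols = list(net.pathway_ids)
    for r in range(n_perm):
        subset = rng.choice(nodes, size=n_deg_mapped, replace=False)
        table = score_network(
            net, subset.tolist(), pathway_increment=pathway_increment, path_cap=path_cap
        )
        mat[r, :] = [table.pathway_score[p] for p in cols]
    return NullDistribution(
        scores=pd.DataFrame(mat, columns=cols), seed=seed, n_deg_mapped=n_deg_mapped
    )


def pathway_pvalues(
    obs: ScoreTable,
    null: NullDistribution,
    alpha: float = 0.05,
    null_model: str = "empirical",
) -> pd.DataFrame:
    """Per-pathway significance of the observed scores against the null.

    ``empirical`` (default) uses the add-one pseudocount
    p = (1 + #{null >= observed}) / (1 + n_perm), which cannot reach
    zero. ``gaussian`` fits a normal tail to the null mean and SD and
    reports the one-sided upper-tail probability — a smooth
    approximation able to resolve p-values below the empirical floor.
    Results are sorted by ascending p with pathway ID as tie-break.
    """
    if set(obs.pathway_score) != set(null.scores.columns):
        raise SchemaError("observed and null pathway universes differ")
    if null_model not in ("empirical", "gaussian"):
        raise SchemaError(f"unknown null_model {null_model!r}")
    rows = []
    for pid in sorted(obs.pathway_score):
        o = obs.pathway_score[pid]
        col = null.scores[pid].to_numpy()
        if null_model == "empirical":
            p = (1 + int((col >= o).sum())) / (1 + len(col))
        else:
            mean, sd = col.mean(), col.std(ddof=1)
            if sd == 0:
                p = 1.0 if o <= mean else _TINY_P
            else:
                p = max(float(norm.sf((o - mean) / sd)), _TINY_P)
        rows.append((pid, o, p, p < alpha))
    out = pd.DataFrame(
        rows, columns=["pathway_id", "observed_score", "empirical_p", "significant"]
    )
    return out.sort_values(
        ["empirical_p", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
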