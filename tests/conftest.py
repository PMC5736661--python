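import networkx as nx
import numpy as np
import pytest

from degnet.synthetic import PathwayAnnotation


def annotation(**pathways) -> PathwayAnnotation:
    """Shorthand: annotation(P1='AB', P2='BC') -> two pathways with those members."""
    return PathwayAnnotation(
        pathways={pid: (pid.lower(), frozenset(genes)) for pid, genes in pathways.items()}
    )


def brute_force_scores(net, deg_set, pathway_increment="per_edge"):
    """Independent oracle: enumerate all simple paths per DEG pair with
    networkx, keep those of full-network geodesic length whose nodes are
    all DEGs, and accumulate the scores by direct counting."""
    g = net.graph
    deg = sorted(set(deg_set) & set(g.nodes))
    gene = dict.fromkeys(g.nodes, 0)
    edge = {tuple(sorted(e)): 0 for e in g.edges}
    pathway = dict.fromkeys(net.pathway_ids, 0)
    n_paths = 0
    for i, u in enumerate(deg):
        for v in deg[i + 1 :]:
            if not nx.has_path(g, u, v):
                continue
            min_len = nx.shortest_path_length(g, u, v)
            for path in nx.all_simple_paths(g, u, v, cutoff=min_len):
                if len(path) - 1 != min_len:
                    continue
                if any(x not in deg_set for x in path):
                    continue
                n_paths += 1
                labels = set()
                for x in path:
                    gene[x] += 1
                for a, b in zip(path, path[1:]):
                    key = tuple(sorted((a, b)))
                    edge[key] += 1
                    pids = g.edges[a, b]["pathways"]
                    if pathway_increment == "per_edge":
                        for pid in pids:
                            pathway[pid] += 1
                    else:
                        labels |= pids
                for pid in labels:
                    pathway[pid] += 1
    return gene, edge, pathway, n_paths


def random_annotation(rng: np.random.Generator, n_genes, n_pathways, size_range):
    genes = [chr(ord("A") + i) for i in range(n_genes)]
    lo, hi = size_range
    pathways = {}
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        pathways[f"P{i}"] = (f"pathway {i}", frozenset(members.tolist()))
    return PathwayAnnotation(pathways=pathways)


@pytest.fixture
def path_graph_net():
    """A - B - C with each edge carried by its own pathway."""
    from degnet.pathnet import build_network

    return build_network(annotation(Pa="AB", Pb="BC"))
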