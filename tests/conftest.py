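import numpy as np
import pandas as pd
import pytest

from mraxis.network import RegulatoryEdge


@pytest.fixture
def chain_edges():
    """t -> a -> b -> c -> d, all tf_dna, confidence 1."""
    return [
        RegulatoryEdge("t", "a", "tf_dna", 1.0),
        RegulatoryEdge("a", "b", "tf_dna", 1.0),
        RegulatoryEdge("b", "c", "tf_dna", 1.0),
        RegulatoryEdge("c", "d", "tf_dna", 1.0),
    ]


@pytest.fixture
def diamond_edges():
    """t -> {a, b}; a -> c (0.9), b -> c (0.5)."""
    return [
        RegulatoryEdge("t", "a", "tf_dna", 1.0),
        RegulatoryEdge("t", "b", "tf_dna", 1.0),
        RegulatoryEdge("a", "c", "tf_dna", 0.9),
        RegulatoryEdge("b", "c", "tf_dna", 0.5),
    ]


def random_graph(rng, max_nodes=20):
    """Small random directed graph with random confidences and gene scores."""
    n = int(rng.integers(3, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for src in nodes:
        for dst in nodes:
            if src != dst and rng.random() < 0.25:
                kind = "tf_dna" if rng.random() < 0.7 else "ppi"
                edges.append(
                    RegulatoryEdge(src, dst, kind, float(rng.uniform(0.05, 1.0)))
                )
    scores = {node: float(rng.normal()) for node in nodes}
    return nodes, edges, scores


@pytest.fixture
def ranked_small():
    """Four genes ranked 3 > 2 > 1 > 0.5."""
    return pd.DataFrame(
        {"gene": ["g1", "g2", "g3", "g4"], "score": [3.0, 2.0, 1.0, 0.5]}
    )


def oracle_network_score(root, edges, scores, max_depth=3, kinds=("tf_dna", "ppi")):
    """Independent oracle: BFS levels via networkx, explicit parent choice."""
    import networkx as nx

    g = nx.DiGraph()
    for e in edges:
        if e.kind in kinds:
            if g.has_edge(e.source, e.target):
                g[e.source][e.target]["conf"] = max(
                    g[e.source][e.target]["conf"], e.confidence
                )
            else:
                g.add_edge(e.source, e.target, conf=e.confidence)
    if root not in g:
        return 0.0
    dist = nx.single_source_shortest_path_length(g, root, cutoff=max_depth)
    total = 0.0
    for node, d in dist.items():
        if node == root or d == 0:
            continue
        parents = [p for p in g.predecessors(node) if dist.get(p, 99) == d - 1]
        parent = min(parents, key=lambda p: (-g[p][node]["conf"], p))
        total += (
            scores.get(node, 0.0)
            * g[parent][node]["conf"]
            / (d * g.out_degree(parent))
        )
    return total


def brute_force_es(scores, hits, weight=1.0):
    """Independent plain-loop running-sum ES oracle."""
    n = len(scores)
    nh = sum(hits)
    denom = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    running, best = 0.0, 0.0
    for s, h in zip(scores, hits):
        if h:
            running += (abs(s) ** weight) / denom if denom else 1.0 / nh
        else:
            running -= 1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best
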