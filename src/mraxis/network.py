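"""Master-regulator inference from TF-DNA and protein-interaction networks.

Each candidate transcription factor (TF) is rooted in a depth-bounded
subnetwork (breadth-first expansion, default maximum edge distance 3) over
TF->target regulatory edges (MARA-style, directed) and protein-protein
edges (String-style, symmetric). The TF's influence over differential
expression is summarised by the network score

    N_t = sum over subnetwork genes r of  S_r * S_n / (D_r * L_r)

where S_r is the signed gene significance score, S_n the confidence of the
edge through which r was reached, D_r its BFS distance from the root, and
L_r the out-degree of its parent in the full network. TFs are ranked on
three sub-scores — N over the TF-DNA network alone, N over the combined
TF-DNA + PPI network, and the -log10 hypergeometric enrichment of direct
targets among differentially expressed genes — by summing the per-metric
ranks (rank 1 = largest sub-score; smallest aggregate = strongest
candidate).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegulatoryEdge",
    "SubnetworkNode",
    "TFSubnetwork",
    "RegulatorScore",
    "build_subnetwork",
    "network_score",
    "direct_target_enrichment",
    "rank_regulators",
    "score_regulators",
    "read_edges",
]

EDGE_KINDS = ("tf_dna", "ppi")


@dataclass(frozen=True)
class RegulatoryEdge:
    source: str
    target: str
    kind: str  # tf_dna (directed) or ppi (stored as two directed edges)
    confidence: float

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if not 0.0 < self.confidence <= 1.0:
            raise ValueError(f"confidence must lie in (0, 1], got {self.confidence}")
        if self.source == self.target:
            raise ValueError(f"self-loop on {self.source!r}")


@dataclass(frozen=True)
class SubnetworkNode:
    gene_id: str
    distance: int
    parent: str
    parent_out_degree: int
    edge_confidence: float


@dataclass
class TFSubnetwork:
    root_tf: str
    nodes: list[SubnetworkNode] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)

    def genes(self) -> set[str]:
        return {n.gene_id for n in self.nodes}


@dataclass(frozen=True)
class RegulatorScore:
    tf: str
    sub_scores: tuple[float, float, float]
    metric_ranks: tuple[float, float, float]
    aggregate_rank: float


def _adjacency(edges, kinds):
    """Out-adjacency {source: [(target, confidence), ...]} over selected kinds."""
    adj: dict[str, list[tuple[str, float]]] = defaultdict(list)
    for e in edges:
        if e.kind in kinds:
            adj[e.source].append((e.target, e.confidence))
    return adj


def build_subnetwork(
    root_tf: str,
    edges,
    max_depth: int = 3,
    kinds=EDGE_KINDS,
) -> TFSubnetwork:
    """Breadth-first subnetwork of ``root_tf`` up to ``max_depth`` edges away.

    Each gene is recorded once, at its minimum distance. When several
    same-distance parents reach a gene, the edge with the highest
    confidence wins, then the lexicographically smallest parent id.
    ``parent_out_degree`` is the parent's out-degree over the selected
    kinds on the full network.

    Raises
    ------
    KeyError if ``root_tf`` has no outgoing edge of the selected kinds and
    does not appear in the network at all.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    kinds = tuple(kinds)
    adj = _adjacency(edges, kinds)
    known = set(adj)
    for targets in adj.values():
        known.update(t for t, _ in targets)
    if root_tf not in known:
        raise KeyError(f"root TF {root_tf!r} absent from the network")
    out_degree = {src: len(t) for src, t in adj.items()}

    visited = {root_tf}
    frontier = [root_tf]
    nodes: list[SubnetworkNode] = []
    for depth in range(1, max_depth + 1):
        # candidate parents for each newly reachable gene at this depth
        candidates: dict[str, tuple[float, str]] = {}
        for parent in frontier:
            for target, conf in adj.get(parent, ()):
                if target in visited:
                    continue
                best = candidates.get(target)
                # prefer higher confidence, then lexicographically smaller parent
                key = (-conf, parent)
                if best is None or key < best:
                    candidates[target] = key
        frontier = []
        for gene in sorted(candidates):
            neg_conf, parent = candidates[gene]
            nodes.append(
                SubnetworkNode(
                    gene_id=gene,
                    distance=depth,
                    parent=parent,
                    parent_out_degree=out_degree[parent],
                    edge_confidence=-neg_conf,
                )
            )
            visited.add(gene)
            frontier.append(gene)
        if not frontier:
            break
    return TFSubnetwork(root_tf=root_tf, nodes=nodes)


def network_score(
    subnetwork: TFSubnetwork,
    gene_scores: dict[str, float] | pd.DataFrame,
    absolute: bool = False,
) -> float:
    """Distance- and degree-weighted network score of a TF subnetwork.

    ``N = sum_r S_r * S_n / (D_r * L_r)``. Genes missing from
    ``gene_scores`` contribute 0. With ``absolute=True`` the magnitude
    |S_r| enters the sum instead of the signed score.
    """
    if isinstance(gene_scores, pd.DataFrame):
        gene_scores = dict(zip(gene_scores["gene"], gene_scores["score"]))
    total = 0.0
    for node in subnetwork.nodes:
        if node.parent_out_degree < 1:
            raise RuntimeError(
                f"node {node.gene_id} has parent out-degree "
                f"{node.parent_out_degree}; subnetwork is inconsistent"
            )
        s_r = gene_scores.get(node.gene_id, 0.0)
        if absolute:
            s_r = abs(s_r)
        total += s_r * node.edge_confidence / (node.distance * node.parent_out_degree)
    return total


def direct_target_enrichment(
    tf: str,
    edges,
    de_genes: set[str],
    universe: set[str],
) -> float:
    """-log10 upper-tail hypergeometric p of direct-target/DE-gene overlap.

    Direct targets are the TF's depth-1 ``tf_dna`` targets. The p-value is
    ``P(X >= k)`` for the overlap ``k`` under sampling ``|de_genes|`` genes
    from a universe containing ``|targets|`` successes.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    targets = {e.target for e in edges if e.kind == "tf_dna" and e.source == tf}
    targets &= universe
    k = len(targets & de_genes)
    # P(X >= k); sf(k-1) is the upper tail including k
    p = stats.hypergeom.sf(k - 1, len(universe), len(targets), len(de_genes))
    p = min(max(float(p), np.finfo(float).tiny), 1.0)
    return -np.log10(p)


def rank_regulators(sub_scores: pd.DataFrame) -> list[RegulatorScore]:
    """Aggregate-rank TFs from a table of three sub-scores.

    Parameters
    ----------
    sub_scores : DataFrame with columns ``tf``, ``m1``, ``m2``, ``m3``.

    Each metric is ranked descending (rank 1 = largest; ties share the
    average rank); the aggregate rank is the sum of the three metric
    ranks and the output is sorted ascending by aggregate (strongest
    first), ties broken by TF identifier.
    """
    for col in ("tf", "m1", "m2", "m3"):
        if col not in sub_scores.columns:
            raise ValueError(f"sub-score table lacks column {col!r}")
    if sub_scores[["m1", "m2", "m3"]].isna().any().any():
        raise ValueError("missing sub-score")
    ranks = {
        m: stats.rankdata(-sub_scores[m].to_numpy(dtype=float), method="average")
        for m in ("m1", "m2", "m3")
    }
    results = []
    for i, row in enumerate(sub_scores.itertuples(index=False)):
        r = (ranks["m1"][i], ranks["m2"][i], ranks["m3"][i])
        results.append(
            RegulatorScore(
                tf=row.tf,
                sub_scores=(row.m1, row.m2, row.m3),
                metric_ranks=r,
                aggregate_rank=float(sum(r)),
            )
        )
    results.sort(key=lambda s: (s.aggregate_rank, s.tf))
    return results


def score_regulators(
    edges,
    gene_scores: pd.DataFrame,
    de_genes: set[str],
    universe: set[str] | None = None,
    max_depth: int = 3,
    absolute: bool = False,
) -> pd.DataFrame:
    """Score and rank every TF that sources a ``tf_dna`` edge.

    Sub-scores per TF: ``m1`` network score over the TF-DNA network alone,
    ``m2`` over the combined TF-DNA + PPI network, ``m3`` the -log10
    hypergeometric enrichment of direct targets among ``de_genes``.

    Returns a DataFrame ``tf m1 m2 m3 rank1 rank2 rank3 aggregate_rank``
    sorted strongest-first.
    """
    tfs = sorted({e.source for e in edges if e.kind == "tf_dna"})
    if not tfs:
        raise ValueError("no tf_dna edges: nothing to score")
    if universe is None:
        universe = {e.source for e in edges} | {e.target for e in edges}
        universe |= set(gene_scores["gene"])
    de_genes = set(de_genes) & universe
    scores = dict(zip(gene_scores["gene"], gene_scores["score"]))
    rows = []
    for tf in tfs:
        sub_dna = build_subnetwork(tf, edges, max_depth=max_depth, kinds=("tf_dna",))
        sub_all = build_subnetwork(tf, edges, max_depth=max_depth, kinds=EDGE_KINDS)
        rows.append(
            {
                "tf": tf,
                "m1": network_score(sub_dna, scores, absolute=absolute),
                "m2": network_score(sub_all, scores, absolute=absolute),
                "m3": direct_target_enrichment(tf, edges, de_genes, universe),
            }
        )
    ranked = rank_regulators(pd.DataFrame(rows))
    return pd.DataFrame(
        {
            "tf": [r.tf for r in ranked],
            "m1": [r.sub_scores[0] for r in ranked],
            "m2": [r.sub_scores[1] for r in ranked],
            "m3": [r.sub_scores[2] for r in ranked],
            "rank1": [r.metric_ranks[0] for r in ranked],
            "rank2": [r.metric_ranks[1] for r in ranked],
            "rank3": [r.metric_ranks[2] for r in ranked],
            "aggregate_rank": [r.aggregate_rank for r in ranked],
        }
    )


def read_edges(path) -> list[RegulatoryEdge]:
    """Read an edge-list TSV with header source, target, kind, confidence."""
    table = pd.read_csv(path, sep="\t")
    required = {"source", "target", "kind", "confidence"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"edge list {path} lacks columns: {sorted(missing)}")
    return [
        RegulatoryEdge(row.source, row.target, row.kind, float(row.confidence))
        for row in table.itertuples(index=False)
    ]
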