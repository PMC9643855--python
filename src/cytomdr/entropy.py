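"""Information-theoretic interaction scores for SNP panels.

Each SNP's main effect is the mutual information I(A;C) between its
genotype and the case/control class, reported as a percentage of the class
entropy H(C). Each SNP pair is scored by the interaction information
IG(A;B;C) = I(AB;C) - I(A;C) - I(B;C), also as % of H(C): a positive score
means the pair carries class information beyond its parts (synergy), a
negative score means shared, redundant information; zero is neutral.
Entropies are empirical plug-in estimates in bits; the base cancels in the
percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .datamodel import DegenerateInputError, GenotypeDataset

SYNERGY, REDUNDANCY, NEUTRAL = "synergy", "redundancy", "neutral"


def entropy(distribution: Sequence[float]) -> float:
    """Shannon entropy in bits of a finite probability vector (0 log 0 = 0)."""
    p = np.asarray(distribution, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _empirical_entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    return entropy(counts / counts.sum())


def _joint_codes(columns: list[np.ndarray]) -> np.ndarray:
    """Collapse parallel code vectors into one joint-outcome code vector."""
    joint = columns[0].astype(np.int64).copy()
    for col in columns[1:]:
        joint = joint * (int(col.max()) + 2) + col
    return joint


def mutual_information_pct(
    ds: GenotypeDataset, attributes: str | Sequence[str]
) -> float:
    """I(A;C) as a percentage of H(C), A the (joint) genotype attribute.

    Multiple attributes are combined over their product genotype space.
    Complete cases only; raises if the class entropy is zero.
    """
    attrs = [attributes] if isinstance(attributes, str) else list(attributes)
    mask = ds.complete_cases(attrs)
    status = ds.status.to_numpy()[mask]
    h_c = _empirical_entropy(status)
    if h_c == 0:
        raise DegenerateInputError("single-class data: H(C) = 0")
    cols = [ds.genotypes[a].to_numpy()[mask] for a in attrs]
    a = _joint_codes(cols)
    h_a = _empirical_entropy(a)
    h_ac = _empirical_entropy(_joint_codes([a, status.astype(np.int64)]))
    mi = h_a + h_c - h_ac
    return float(100.0 * mi / h_c)


def interaction_information_pct(
    ds: GenotypeDataset, snpA: str, snpB: str
) -> float:
    """IG(A;B;C) = I(AB;C) - I(A;C) - I(B;C), as % of H(C).

    Positive = synergy, negative = redundancy. All three terms are computed
    on the subjects complete for both SNPs, so the decomposition is exact.
    """
    mask = ds.complete_cases([snpA, snpB])
    sub = ds.subset(mask=mask)
    return (
        mutual_information_pct(sub, [snpA, snpB])
        - mutual_information_pct(sub, snpA)
        - mutual_information_pct(sub, snpB)
    )


def _categorize(score: float) -> str:
    if score > 0:
        return SYNERGY
    if score < 0:
        return REDUNDANCY
    return NEUTRAL


@dataclass
class InteractionNetwork:
    """Node and edge entropy scores of a SNP panel.

    ``nodes`` maps rsid -> I(A;C)%; ``edges`` maps (rsidA, rsidB) (panel
    order) -> IG%; ``categories`` labels each edge synergy/redundancy/neutral.
    """

    nodes: dict[str, float]
    edges: dict[tuple[str, str], float]
    categories: dict[tuple[str, str], str]

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"snp": s, "node_pct": v} for s, v in self.nodes.items()]
        )

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "snpA": a,
                    "snpB": b,
                    "edge_pct": v,
                    "category": self.categories[(a, b)],
                }
                for (a, b), v in self.edges.items()
            ]
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for s, v in self.nodes.items():
            g.add_node(s, pct=v)
        for (a, b), v in self.edges.items():
            g.add_edge(a, b, pct=v, category=self.categories[(a, b)])
        return g


def build_network(
    ds: GenotypeDataset, snps: Sequence[str] | None = None
) -> InteractionNetwork:
    """Score every SNP and SNP pair of the panel by entropy percentages."""
    snps = list(snps) if snps is not None else ds.snps
    if len(snps) < 2:
        raise ValueError("network needs at least 2 SNPs")
    nodes = {s: mutual_information_pct(ds, s) for s in snps}
    edges, cats = {}, {}
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            key = (snps[i], snps[j])
            score = interaction_information_pct(ds, *key)
            edges[key] = score
            cats[key] = _categorize(score)
    return InteractionNetwork(nodes=nodes, edges=edges, categories=cats)


def interaction_dendrogram(network: InteractionNetwork) -> str:
    """Average-linkage dendrogram over the pairwise interaction scores.

    Dissimilarity d(A,B) = S_max - S(A,B), with S the edge score and S_max
    its maximum over edges, so the strongest synergy merges first (at height
    0). Returns the tree in Newick format with branch lengths equal to
    height differences.
    """
    names = list(network.nodes)
    n = len(names)
    if n < 2:
        raise ValueError("dendrogram needs at least 2 nodes")
    s_max = max(network.edges.values())
    dist = np.zeros((n, n))
    for (a, b), score in network.edges.items():
        i, j = names.index(a), names.index(b)
        dist[i, j] = dist[j, i] = s_max - score
    z = linkage(squareform(dist, checks=False), method="average")
    return _linkage_to_newick(z, names)


def _linkage_to_newick(z: np.ndarray, names: list[str]) -> str:
    root = to_tree(z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(root.left, root.dist)
    right = render(root.right, root.dist)
    return f"({left},{right});"
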