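"""Weighted feature graph, community detection, and independent-set selection.

Every pair of features (i, j) carries the blended weight

    W_ij = beta * Relevancy_ij - (1 - beta) * Redundancy_ij     (i != j)
    W_ii = 1

where Relevancy is the mean AMGM dispersion of the two endpoints and
Redundancy the absolute cosine similarity of their expression vectors.  The
raw weights are rescaled into (0, 1) with the SoftMax (logistic) scaling

    What_ij = 1 / (1 + exp(-(W_ij - Wbar) / sigma))

with Wbar, sigma the mean and standard deviation of the off-diagonal weights.
Communities are found by Louvain modularity maximization on the scaled
weights; within each community, mutually redundant features are pruned by
taking a maximum independent set (MIS) of the gamma-thresholded adjacency —
exactly for small communities, via the Boppana–Halldorsson clique-removal
approximation for large ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import sys

import networkx as nx
import numpy as np
import pandas as pd

from .amgm import AMGMScores

__all__ = [
    "FeatureGraph",
    "CommunityPartition",
    "AdjacencyMatrix",
    "CandidatePanel",
    "build_weight_matrix",
    "softmax_scale",
    "louvain_partition",
    "threshold_adjacency",
    "mis_select",
    "select_candidates",
    "exact_mis",
    "clique_removal_mis",
]

#: Communities at or below this size use the exact branch-and-bound MIS solver.
DEFAULT_EXACT_MIS_CAP = 25


@dataclass
class FeatureGraph:
    """Fully weighted feature graph with raw (W) and SoftMax-scaled (What) weights."""

    feature_ids: list[str]
    W: np.ndarray
    beta: float
    amgm: np.ndarray
    What: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.feature_ids)

    @property
    def edge_count(self) -> int:
        """Number of weighted pairs: all unordered pairs plus self-pairs, n(n+1)/2."""
        n = self.n_nodes
        return n * (n + 1) // 2

    def to_networkx(self) -> nx.Graph:
        """Scaled off-diagonal weights as an undirected graph (no self-loops)."""
        if self.What is None:
            raise ValueError("call softmax_scale first")
        g = nx.Graph()
        g.add_nodes_from(self.feature_ids)
        n = self.n_nodes
        iu, ju = np.triu_indices(n, k=1)
        g.add_weighted_edges_from(
            (self.feature_ids[i], self.feature_ids[j], float(self.What[i, j]))
            for i, j in zip(iu, ju)
        )
        return g

    def edge_list_frame(self) -> pd.DataFrame:
        if self.What is None:
            raise ValueError("call softmax_scale first")
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return pd.DataFrame(
            {
                "source": [self.feature_ids[i] for i in iu],
                "target": [self.feature_ids[j] for j in ju],
                "weight_raw": self.W[iu, ju],
                "weight_scaled": self.What[iu, ju],
            }
        )


@dataclass
class CommunityPartition:
    """Louvain community labels and the modularity of the final partition."""

    membership: dict[str, int]
    n_communities: int
    modularity: float

    def community_nodes(self, label: int) -> list[str]:
        return sorted(f for f, c in self.membership.items() if c == label)


@dataclass
class AdjacencyMatrix:
    """Boolean adjacency from thresholding scaled weights: a_ij = 1 iff What_ij > gamma, i != j."""

    feature_ids: list[str]
    a: np.ndarray
    gamma: float

    def neighbors(self, feature_id: str) -> list[str]:
        i = self.feature_ids.index(feature_id)
        return [self.feature_ids[j] for j in np.flatnonzero(self.a[i])]


@dataclass
class CandidatePanel:
    """Features surviving per-community MIS selection."""

    feature_ids: list[str]
    community: dict[str, int]
    amgm: dict[str, float]
    beta: float
    gamma: float
    communities: dict[int, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "community": [self.community[f] for f in self.feature_ids],
                "amgm": [self.amgm[f] for f in self.feature_ids],
            }
        )


def build_weight_matrix(X_selected, amgm: AMGMScores, beta: float) -> FeatureGraph:
    """Blend relevancy (mean AMGM) against redundancy (absolute cosine)."""
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    values = np.asarray(X_selected.values, dtype=float)
    ids = list(X_selected.feature_ids)
    score_map = amgm.as_dict()
    missing = [f for f in ids if f not in score_map]
    if missing:
        raise ValueError(f"AMGM scores missing for features: {missing[:5]}")
    r = np.array([score_map[f] for f in ids])

    norms = np.linalg.norm(values, axis=0)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(f"zero-norm feature vector {ids[zero[0]]!r}: cosine undefined")
    unit = values / norms
    redundancy = np.abs(unit.T @ unit)
    np.clip(redundancy, 0.0, 1.0, out=redundancy)
    relevancy = 0.5 * (r[:, None] + r[None, :])
    W = beta * relevancy - (1.0 - beta) * redundancy
    np.fill_diagonal(W, 1.0)
    return FeatureGraph(feature_ids=ids, W=W, beta=beta, amgm=r)


def softmax_scale(graph: FeatureGraph) -> FeatureGraph:
    """Logistic-rescale raw weights into (0, 1).

    The center and spread are the mean and population standard deviation of
    the off-diagonal upper-triangle weights; the constant diagonal would bias
    them and is excluded.
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes to scale weights")
    iu, ju = np.triu_indices(n, k=1)
    off = graph.W[iu, ju]
    center, spread = off.mean(), off.std()
    if spread == 0.0:
        raise ValueError("all weights identical: SoftMax scaling undefined")
    graph.What = 1.0 / (1.0 + np.exp(-(graph.W - center) / spread))
    return graph


def louvain_partition(graph: FeatureGraph, seed: int = 0) -> CommunityPartition:
    """Louvain modularity maximization on the scaled weights (self-loops dropped)."""
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    g = graph.to_networkx()
    if graph.n_nodes == 1:
        membership = {graph.feature_ids[0]: 0}
        return CommunityPartition(membership, 1, 0.0)
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    membership = {f: i for i, c in enumerate(comms) for f in c}
    q = nx.community.modularity(g, comms, weight="weight")
    return CommunityPartition(membership, len(comms), float(q))


def threshold_adjacency(graph: FeatureGraph, gamma: float) -> AdjacencyMatrix:
    """Boolean adjacency a_ij = 1 iff What_ij > gamma (strict) and i != j."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must be in (0, 1)")
    if graph.What is None:
        raise ValueError("call softmax_scale first")
    a = graph.What > gamma
    np.fill_diagonal(a, False)
    return AdjacencyMatrix(feature_ids=list(graph.feature_ids), a=a, gamma=gamma)


def exact_mis(neighbor_masks: list[int]) -> int:
    """Exact maximum independent set by branch and bound over bitmasks.

    Vertices are branched in ascending index with the include-branch first, so
    the first optimum found — and returned — is the lexicographically smallest
    maximum independent set by vertex index.  Returns the chosen set as a
    bitmask.
    """
    n = len(neighbor_masks)
    best_size = -1
    best_set = 0

    def dfs(avail: int, chosen: int, size: int) -> None:
        nonlocal best_size, best_set
        if size + avail.bit_count() <= best_size:
            return
        if avail == 0:
            if size > best_size:
                best_size, best_set = size, chosen
            return
        v = (avail & -avail).bit_length() - 1
        bit = 1 << v
        dfs(avail & ~bit & ~neighbor_masks[v], chosen | bit, size + 1)
        dfs(avail & ~bit, chosen, size)

    dfs((1 << n) - 1, 0, 0)
    return best_set


def clique_removal_mis(neighbor_masks: list[int]) -> int:
    """Boppana–Halldorsson clique-removal approximation of a maximum
    independent set, over bitmask adjacency.

    Repeatedly runs the Ramsey split (branch on the lowest-index vertex into
    its neighborhood and non-neighborhood, keeping the larger clique and the
    larger independent set of the two branches), records the independent set,
    and removes the clique until no vertex remains.  Returns the best
    independent set found, as a bitmask.  Deterministic: vertices are always
    branched in ascending index order.
    """
    n = len(neighbor_masks)
    limit = sys.getrecursionlimit()
    if 4 * n + 100 > limit:
        sys.setrecursionlimit(4 * n + 100)
    try:

        def ramsey(mask: int) -> tuple[int, int]:
            if mask == 0:
                return 0, 0
            bit = mask & -mask
            v = bit.bit_length() - 1
            rest = mask & ~bit
            c1, i1 = ramsey(rest & neighbor_masks[v])
            c2, i2 = ramsey(rest & ~neighbor_masks[v])
            c1 |= bit
            i2 |= bit
            clique = c1 if c1.bit_count() >= c2.bit_count() else c2
            indep = i1 if i1.bit_count() >= i2.bit_count() else i2
            return clique, indep

        best = 0
        mask = (1 << n) - 1
        while mask:
            clique, indep = ramsey(mask)
            if indep.bit_count() > best.bit_count():
                best = indep
            mask &= ~clique
        return best
    finally:
        sys.setrecursionlimit(limit)


def mis_select(
    adjacency: AdjacencyMatrix,
    community_nodes: list[str],
    exact_cap: int = DEFAULT_EXACT_MIS_CAP,
) -> list[str]:
    """Independent set of features within one community.

    Exact branch-and-bound for communities up to ``exact_cap`` nodes
    (lexicographically smallest optimum, so ties break toward the lowest
    feature ID); Boppana–Halldorsson clique removal above the cap.  Output is
    sorted by feature ID.
    """
    if not community_nodes:
        raise ValueError("community_nodes must be non-empty")
    nodes = sorted(community_nodes)
    idx = {f: i for i, f in enumerate(adjacency.feature_ids)}
    cols = np.array([idx[f] for f in nodes], dtype=int)
    sub = adjacency.a[np.ix_(cols, cols)]
    m = len(nodes)
    # Python ints: numpy shifts overflow beyond 63 nodes
    masks = [sum(1 << int(j) for j in np.flatnonzero(sub[i])) for i in range(m)]
    chosen = exact_mis(masks) if m <= exact_cap else clique_removal_mis(masks)
    return [nodes[i] for i in range(m) if chosen >> i & 1]


def select_candidates(
    graph: FeatureGraph,
    partition: CommunityPartition,
    adjacency: AdjacencyMatrix,
    exact_cap: int = DEFAULT_EXACT_MIS_CAP,
) -> CandidatePanel:
    """Union of the per-community independent sets."""
    if set(graph.feature_ids) != set(partition.membership) or set(graph.feature_ids) != set(
        adjacency.feature_ids
    ):
        raise ValueError("graph, partition and adjacency must share the same node set")
    amgm_map = dict(zip(graph.feature_ids, map(float, graph.amgm)))
    selected: list[str] = []
    community: dict[str, int] = {}
    per_community: dict[int, list[str]] = {}
    for label in range(partition.n_communities):
        nodes = partition.community_nodes(label)
        picked = mis_select(adjacency, nodes, exact_cap=exact_cap)
        per_community[label] = picked
        for f in picked:
            community[f] = label
        selected.extend(picked)
    return CandidatePanel(
        feature_ids=selected,
        community=community,
        amgm={f: amgm_map[f] for f in selected},
        beta=graph.beta,
        gamma=adjacency.gamma,
        communities=per_community,
    )
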