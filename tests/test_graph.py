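"""Feature graph construction, scaling, communities, and MIS node selection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from panelminer import (
    AdjacencyMatrix,
    FeatureGraph,
    LabeledExpression,
    build_weight_matrix,
    louvain_partition,
    mis_select,
    select_candidates,
    softmax_scale,
    threshold_adjacency,
)
from panelminer.amgm import AMGMScores, amgm_scores
from panelminer.graph import clique_removal_mis, exact_mis

from .conftest import brute_force_mis_size


def scores_for(ids, values):
    r = np.asarray(values, dtype=float)
    return AMGMScores(feature_ids=list(ids), r=r, am=r, gm=np.ones_like(r), mean=r, variant="modified")


def cohort_from_columns(cols: dict[str, list[float]]):
    ids = list(cols)
    values = np.array([cols[f] for f in ids], dtype=float).T
    return LabeledExpression(
        values=values,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        feature_ids=ids,
        labels=np.array(["x"] * values.shape[0], dtype=object),
    )


# ---------------------------------------------------------------------------
# weight matrix


def test_diagonal_is_one_and_symmetric():
    X = cohort_from_columns({"a": [1, 0, 0], "b": [0, 1, 0], "c": [1, 1, 0]})
    g = build_weight_matrix(X, scores_for("abc", [1.2, 1.4, 1.1]), beta=0.5)
    assert np.all(np.diag(g.W) == 1.0)
    assert np.array_equal(g.W, g.W.T)


def test_orthogonal_features_weight_is_pure_relevancy():
    X = cohort_from_columns({"a": [1, 0], "b": [0, 1]})
    g = build_weight_matrix(X, scores_for("ab", [1.2, 1.4]), beta=0.5)
    assert g.W[0, 1] == pytest.approx(0.5 * 1.3, abs=1e-12)


def test_identical_features_weight_hand_value():
    X = cohort_from_columns({"a": [1, 2, 3], "b": [2, 4, 6]})  # cos = 1
    g = build_weight_matrix(X, scores_for("ab", [1.2, 1.2]), beta=0.6)
    assert g.W[0, 1] == pytest.approx(0.6 * 1.2 - 0.4, abs=1e-12)


def test_zero_norm_feature_rejected():
    X = cohort_from_columns({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(ValueError, match="b"):
        build_weight_matrix(X, scores_for("ab", [1.2, 1.0]), beta=0.5)


@pytest.mark.parametrize("beta", [0.0, 1.0, -0.1, 2.0])
def test_beta_out_of_range_rejected(beta):
    X = cohort_from_columns({"a": [1, 0], "b": [0, 1]})
    with pytest.raises(ValueError):
        build_weight_matrix(X, scores_for("ab", [1.2, 1.4]), beta=beta)


def test_edge_count_identity_counts_self_pairs():
    g = FeatureGraph(
        feature_ids=[f"f{i}" for i in range(1545)],
        W=np.empty((0, 0)),
        beta=0.6,
        amgm=np.empty(0),
    )
    assert g.edge_count == 1545 * 1546 // 2 == 1_194_285


# ---------------------------------------------------------------------------
# SoftMax scaling


def graph_from_W(W, ids=None):
    n = W.shape[0]
    ids = ids or [f"f{i}" for i in range(n)]
    return FeatureGraph(feature_ids=ids, W=W.astype(float), beta=0.5, amgm=np.ones(n))


def test_softmax_center_and_one_sigma():
    W = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
    g = softmax_scale(graph_from_W(W))
    off = np.array([0.2, 0.4, 0.6])
    center, spread = off.mean(), off.std()
    i, j = 0, 2  # W_ij = 0.4 = mean of off-diagonal weights
    assert g.What[i, j] == pytest.approx(0.5)
    # entry one sigma above the mean
    k = np.argwhere(np.isclose(W, center + spread))
    assert g.What[1, 2] == pytest.approx(1 / (1 + np.exp(-(0.6 - center) / spread)))
    assert 1 / (1 + np.exp(-1.0)) == pytest.approx(0.73106, abs=1e-5)


def test_softmax_preserves_ordering():
    rng = np.random.default_rng(0)
    W = rng.normal(size=(6, 6))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 1.0)
    g = softmax_scale(graph_from_W(W))
    iu, ju = np.triu_indices(6, 1)
    assert np.array_equal(np.argsort(W[iu, ju]), np.argsort(g.What[iu, ju]))
    assert np.all((g.What > 0) & (g.What < 1))


def test_softmax_flat_weights_rejected():
    W = np.full((3, 3), 0.3)
    np.fill_diagonal(W, 1.0)
    with pytest.raises(ValueError, match="identical"):
        softmax_scale(graph_from_W(W))


# ---------------------------------------------------------------------------
# Louvain communities


def _modularity_oracle(g: nx.Graph):
    """Best modularity over every partition of the nodes (brute force)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[head] + part[i]] + part[i + 1 :]
            yield [[head]] + part

    best, best_q = None, -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(g, part, weight="weight")
        if q > best_q:
            best, best_q = part, q
    return best, best_q


def test_two_cliques_split_into_two_communities():
    """Louvain should find the optimum the brute-force oracle certifies."""
    n = 8
    W = np.full((n, n), 0.05)
    for block in (range(4), range(4, 8)):
        for i, j in itertools.combinations(block, 2):
            W[i, j] = W[j, i] = 0.9
    np.fill_diagonal(W, 1.0)
    g = softmax_scale(graph_from_W(W))
    part = louvain_partition(g, seed=1)
    assert part.n_communities == 2
    comms = {frozenset(part.community_nodes(c)) for c in range(2)}
    assert comms == {frozenset(f"f{i}" for i in range(4)), frozenset(f"f{i}" for i in range(4, 8))}
    oracle_part, oracle_q = _modularity_oracle(g.to_networkx())
    assert part.modularity == pytest.approx(oracle_q, abs=1e-9)


def test_single_node_graph():
    g = FeatureGraph(feature_ids=["a"], W=np.ones((1, 1)), beta=0.5, amgm=np.ones(1))
    g.What = np.ones((1, 1)) * 0.5
    part = louvain_partition(g, seed=0)
    assert part.n_communities == 1


def test_modularity_beats_singletons(small_cohort):
    from panelminer import fit_normalization, minmax_normalize, remove_redundant_features

    reduced, _ = remove_redundant_features(small_cohort)
    scaled = minmax_normalize(reduced, fit_normalization(reduced))
    scores = amgm_scores(scaled)
    g = softmax_scale(build_weight_matrix(scaled, scores, beta=0.6))
    part = louvain_partition(g, seed=0)
    nxg = g.to_networkx()
    singleton_q = nx.community.modularity(nxg, [{u} for u in nxg.nodes], weight="weight")
    assert part.modularity >= singleton_q


# ---------------------------------------------------------------------------
# adjacency thresholding


def test_threshold_is_strict_with_zero_diagonal():
    W = np.array([[1.0, 0.1, 0.9], [0.1, 1.0, 0.5], [0.9, 0.5, 1.0]])
    g = softmax_scale(graph_from_W(W))
    gamma = float(g.What[1, 2])  # exactly at an existing value
    adj = threshold_adjacency(g, gamma)
    assert not adj.a[1, 2]  # strict inequality
    assert adj.a[0, 2]
    assert not adj.a.diagonal().any()
    assert np.array_equal(adj.a, adj.a.T)


def test_gamma_near_one_gives_empty_adjacency():
    W = np.array([[1.0, 0.1, 0.9], [0.1, 1.0, 0.5], [0.9, 0.5, 1.0]])
    g = softmax_scale(graph_from_W(W))
    adj = threshold_adjacency(g, 1 - 1e-12)
    assert not adj.a.any()


@pytest.mark.parametrize("gamma", [0.0, 1.0, -0.5, 2.0])
def test_gamma_out_of_range_rejected(gamma):
    W = np.eye(2)
    g = graph_from_W(W)
    g.What = np.full((2, 2), 0.5)
    with pytest.raises(ValueError):
        threshold_adjacency(g, gamma)


# ---------------------------------------------------------------------------
# MIS selection


def adjacency_from_edges(ids, edges, gamma=0.3):
    n = len(ids)
    a = np.zeros((n, n), dtype=bool)
    pos = {f: i for i, f in enumerate(ids)}
    for u, v in edges:
        a[pos[u], pos[v]] = a[pos[v], pos[u]] = True
    return AdjacencyMatrix(feature_ids=list(ids), a=a, gamma=gamma)


def test_path_has_unique_mis():
    adj = adjacency_from_edges("abc", [("a", "b"), ("b", "c")])
    assert mis_select(adj, ["a", "b", "c"]) == ["a", "c"]


def test_triangle_tie_breaks_to_lowest_id():
    adj = adjacency_from_edges("abc", [("a", "b"), ("b", "c"), ("a", "c")])
    assert mis_select(adj, ["a", "b", "c"]) == ["a"]


def test_edgeless_community_keeps_everything():
    adj = adjacency_from_edges("abcd", [])
    assert mis_select(adj, ["d", "b", "a", "c"]) == ["a", "b", "c", "d"]


def test_empty_community_rejected():
    adj = adjacency_from_edges("ab", [])
    with pytest.raises(ValueError):
        mis_select(adj, [])


def _random_masks(rng, m, p):
    a = np.triu((rng.random((m, m)) < p), k=1)
    a = a | a.T
    return a, [int(sum(1 << j for j in np.flatnonzero(a[i]))) for i in range(m)]


def test_exact_mis_matches_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(40):
        m = int(rng.integers(2, 12))
        a, masks = _random_masks(rng, m, rng.uniform(0.1, 0.9))
        chosen = exact_mis(masks)
        size = chosen.bit_count()
        assert size == brute_force_mis_size(a)
        nodes = [i for i in range(m) if chosen >> i & 1]
        assert all(not a[i, j] for i, j in itertools.combinations(nodes, 2))


def test_clique_removal_output_independent_and_half_optimal():
    rng = np.random.default_rng(7)
    for _ in range(60):
        m = int(rng.integers(2, 21))
        a, masks = _random_masks(rng, m, rng.uniform(0.1, 0.9))
        approx = clique_removal_mis(masks)
        nodes = [i for i in range(m) if approx >> i & 1]
        assert all(not a[i, j] for i, j in itertools.combinations(nodes, 2))
        if m <= 16:
            assert approx.bit_count() >= 0.5 * brute_force_mis_size(a)


@pytest.mark.parametrize(
    "edges,n,expect",
    [
        ([("f0", "f1"), ("f1", "f2"), ("f2", "f3")], 4, 2),  # path
        (list(itertools.combinations([f"f{i}" for i in range(5)], 2)), 5, 1),  # clique
        ([], 6, 6),  # edgeless
    ],
)
def test_clique_removal_exact_on_structured_graphs(edges, n, expect):
    ids = [f"f{i}" for i in range(n)]
    adj = adjacency_from_edges(ids, edges)
    assert len(mis_select(adj, ids, exact_cap=0)) == expect


# ---------------------------------------------------------------------------
# candidate panel


def test_edgeless_communities_select_all_nodes():
    X = cohort_from_columns({"a": [1, 0, 1], "b": [0, 1, 0], "c": [1, 1, 0], "d": [0, 0, 1]})
    scores = scores_for("abcd", [1.1, 1.2, 1.3, 1.4])
    g = softmax_scale(build_weight_matrix(X, scores, beta=0.5))
    part = louvain_partition(g, seed=0)
    adj = threshold_adjacency(g, 1 - 1e-9)  # nothing adjacent
    panel = select_candidates(g, part, adj)
    assert sorted(panel.feature_ids) == ["a", "b", "c", "d"]


def test_panel_members_pairwise_independent_within_community(planted_cohort):
    from panelminer import fit_normalization, minmax_normalize, remove_redundant_features

    reduced, _ = remove_redundant_features(planted_cohort)
    scaled = minmax_normalize(reduced, fit_normalization(reduced))
    scores = amgm_scores(scaled)
    g = softmax_scale(build_weight_matrix(scaled, scores, beta=0.6))
    part = louvain_partition(g, seed=2)
    adj = threshold_adjacency(g, 0.3)
    panel = select_candidates(g, part, adj)
    assert len(panel) > 0
    pos = {f: i for i, f in enumerate(adj.feature_ids)}
    for label, members in panel.communities.items():
        for u, v in itertools.combinations(members, 2):
            assert not adj.a[pos[u], pos[v]]


def test_redundant_block_yields_one_member_per_community_when_adjacent(planted_cohort):
    """Fully redundant blocks whose internal scaled weight clears gamma are
    mutually adjacent, so at most one member per community can be selected."""
    from panelminer import fit_normalization, minmax_normalize, remove_redundant_features

    reduced, _ = remove_redundant_features(planted_cohort)
    scaled = minmax_normalize(reduced, fit_normalization(reduced))
    scores = amgm_scores(scaled)
    g = softmax_scale(build_weight_matrix(scaled, scores, beta=0.6))
    part = louvain_partition(g, seed=2)
    adj = threshold_adjacency(g, 0.3)
    panel = select_candidates(g, part, adj)
    pos = {f: i for i, f in enumerate(adj.feature_ids)}
    blocks: dict[str, list[str]] = {}
    for f in adj.feature_ids:
        if f.startswith("red_b"):
            blocks.setdefault(f.split("_")[1], []).append(f)
    for block, members in blocks.items():
        internally_adjacent = all(
            adj.a[pos[u], pos[v]] for u, v in itertools.combinations(members, 2)
        )
        if internally_adjacent:
            for label in panel.communities:
                chosen = [f for f in panel.communities[label] if f in members]
                assert len(chosen) <= 1
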