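"""Correlation thresholding, connectivity enforcement, scale-free diagnostic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dynmod as dm
from dynmod.datasets import ExpressionDataset
from dynmod.network import CoexpressionNetwork


def dataset_from(values):
    values = np.asarray(values, float)
    genes = [f"g{i:03d}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame({"group": "patient"}, index=pd.Index(samples, name="sample_id"))
    return ExpressionDataset(pd.DataFrame(values, index=genes, columns=samples), meta)


def test_correlation_matches_textbook_formula():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, (10, 20))
    corr = dm.correlation_matrix(dataset_from(x))
    for i in range(10):
        for j in range(10):
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            expected = (xi @ xj) / math.sqrt((xi @ xi) * (xj @ xj))
            assert corr[i, j] == pytest.approx(expected, abs=1e-10)
    assert np.allclose(corr, corr.T, atol=1e-12)
    assert np.allclose(np.diag(corr), 1.0)


def test_perfect_anticorrelation():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    corr = dm.correlation_matrix(dataset_from(np.vstack([g, -g, g * 2])))
    assert corr[0, 1] == pytest.approx(-1.0)
    assert corr[0, 2] == pytest.approx(1.0)


def test_zero_variance_gene_gets_zero_correlation():
    x = np.vstack([np.ones(5), np.arange(5.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        corr = dm.correlation_matrix(dataset_from(x))
    assert corr[0, 1] == 0.0 and corr[0, 0] == 1.0


def test_q1_gives_complete_graph():
    rng = np.random.default_rng(1)
    corr = dm.correlation_matrix(dataset_from(rng.normal(0, 1, (8, 10))))
    net = dm.threshold_network(corr, [f"g{i:03d}" for i in range(8)], q=1.0)
    assert net.n_edges == 8 * 7 // 2


def test_exact_retention_count_200_genes():
    """Top 10% of 19,900 pairs is exactly 1,990 edges."""
    rng = np.random.default_rng(2)
    corr = dm.correlation_matrix(dataset_from(rng.normal(0, 1, (200, 30))))
    net = dm.threshold_network(corr, [f"g{i:03d}" for i in range(200)], q=0.10)
    assert len(net.edges) == 1990


def test_threshold_against_brute_force_sort():
    """5-gene matrix, q=0.2: the 2 highest-|r| pairs, by exhaustive sort."""
    rng = np.random.default_rng(3)
    corr = dm.correlation_matrix(dataset_from(rng.normal(0, 1, (5, 12))))
    ids = [f"g{i:03d}" for i in range(5)]
    net = dm.threshold_network(corr, ids, q=0.2)
    pairs = sorted(
        ((abs(corr[i, j]), ids[i], ids[j]) for i in range(5) for j in range(i + 1, 5)),
        reverse=True,
    )
    expected = {(a, b) for _, a, b in pairs[:2]}
    assert {(a, b) for a, b, _ in net.edges} == expected
    assert net.threshold_value == pytest.approx(pairs[1][0])


@given(st.integers(5, 25), st.floats(0.05, 1.0), st.integers(0, 10_000))
def test_retention_count_property(n, q, seed):
    """Edge count is ceil(q*P) for any matrix with distinct |r| values."""
    rng = np.random.default_rng(seed)
    corr = dm.correlation_matrix(dataset_from(rng.normal(0, 1, (n, n + 5))))
    net = dm.threshold_network(corr, [f"g{i:03d}" for i in range(n)], q=q)
    assert len(net.edges) == math.ceil(q * n * (n - 1) / 2)


def make_two_cliques():
    """Two 4-node cliques joined by one weak cross correlation."""
    ids = [f"g{i:03d}" for i in range(8)]
    corr = np.eye(8)
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    corr[i, j] = 0.9
    corr[0, 4] = corr[4, 0] = 0.3  # the strongest cross-pair
    corr[1, 5] = corr[5, 1] = 0.2
    return corr, ids


def test_connectivity_adds_best_cross_pair():
    corr, ids = make_two_cliques()
    net = dm.threshold_network(corr, ids, q=12 / 28)  # exactly the 12 clique edges
    assert not net.is_connected()
    fixed = dm.enforce_connectivity(net, corr)
    assert fixed.is_connected()
    assert fixed.augmented_edges == [("g000", "g004", pytest.approx(0.3))]
    assert fixed.edges == net.edges


def test_connected_network_unchanged():
    rng = np.random.default_rng(4)
    corr = dm.correlation_matrix(dataset_from(rng.normal(0, 1, (10, 15))))
    net = dm.threshold_network(corr, [f"g{i:03d}" for i in range(10)], q=0.5)
    if net.is_connected():
        fixed = dm.enforce_connectivity(net, corr)
        assert fixed.augmented_edges == []


def test_k_components_need_k_minus_1_edges():
    """Three isolated cliques: exactly 2 augmenting edges."""
    ids = [f"g{i:03d}" for i in range(9)]
    corr = np.eye(9) * 0.0
    np.fill_diagonal(corr, 1.0)
    rng = np.random.default_rng(5)
    for block in (range(3), range(3, 6), range(6, 9)):
        for i in block:
            for j in block:
                if i != j:
                    corr[i, j] = 0.9
    cross = rng.uniform(0.01, 0.2, (9, 9))
    cross = (cross + cross.T) / 2
    mask = corr == 0.0
    corr[mask] = cross[mask]
    net = dm.threshold_network(corr, ids, q=9 / 36)  # the 9 clique edges
    fixed = dm.enforce_connectivity(net, corr)
    assert len(fixed.augmented_edges) == 2
    assert fixed.is_connected()


def test_network_tsv_round_trip(tmp_path):
    corr, ids = make_two_cliques()
    net = dm.enforce_connectivity(dm.threshold_network(corr, ids, q=12 / 28), corr)
    p = tmp_path / "net.tsv"
    net.to_tsv(p)
    back = CoexpressionNetwork.from_tsv(p)
    assert back.gene_ids == net.gene_ids
    assert back.edges == net.edges
    assert back.augmented_edges == net.augmented_edges
    assert back.threshold_value == net.threshold_value


def net_from_nx(g):
    return CoexpressionNetwork(
        timestamp=0,
        gene_ids=tuple(f"n{v}" for v in sorted(g.nodes)),
        edges=[(f"n{min(a, b)}", f"n{max(a, b)}", 0.5) for a, b in g.edges],
        threshold_value=0.5,
    )


def test_preferential_attachment_fits_power_law():
    import networkx as nx

    net = net_from_nx(nx.barabasi_albert_graph(1000, 3, seed=0))
    exponent, r2 = dm.degree_distribution_fit(net)
    assert r2 >= 0.7
    assert exponent > 0


def test_clique_fits_worse_than_scale_free():
    import networkx as nx

    _, r2_ba = dm.degree_distribution_fit(net_from_nx(nx.barabasi_albert_graph(300, 3, seed=1)))
    # a near-regular dense random graph: narrow degree distribution
    _, r2_reg = dm.degree_distribution_fit(net_from_nx(nx.gnp_random_graph(300, 0.5, seed=1)))
    assert r2_ba > r2_reg


def test_ring_lattice_has_too_few_distinct_degrees():
    import networkx as nx

    net = net_from_nx(nx.cycle_graph(30))
    with pytest.raises(ValueError, match="distinct degrees"):
        dm.degree_distribution_fit(net)
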