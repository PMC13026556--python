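import math

import numpy as np
import pandas as pd
import pytest

from lectnet.coexpression_net import CorrelationMatrix, spearman_matrix
from lectnet.differential_net import (
    DifferentialNetwork,
    build_differential_network,
    compare_networks,
    differential_zscore,
    fisher_z,
    identify_hubs,
    match_density_threshold,
    node_degrees,
)

from conftest import make_log2


def corr_from(rho_matrix, n_samples, condition="t", genes=None):
    rho_matrix = np.asarray(rho_matrix, dtype=float)
    genes = genes or [f"G{i}" for i in range(len(rho_matrix))]
    return CorrelationMatrix(genes=genes, rho=rho_matrix,
                             n_samples=n_samples, condition=condition)


def net_from_edges(edges, nodes, threshold=3.0, n_T=100, n_C=100):
    df = pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "rho_T": 0.5, "rho_C": 0.0,
          "z_T": 0.55, "z_C": 0.0, "Z": 4.0} for a, b in edges])
    if df.empty:
        df = pd.DataFrame(columns=["gene_a", "gene_b", "rho_T", "rho_C",
                                   "z_T", "z_C", "Z"])
    return DifferentialNetwork(nodes=list(nodes), edges=df,
                               z_threshold=threshold, n_T=n_T, n_C=n_C)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_odd_symmetry(self, rng):
        for r in rng.uniform(0, 0.999, size=20):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-15)

    def test_closed_form_at_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(1.5 / 0.5),
                                              abs=1e-15)

    def test_clamped_at_unity(self):
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.01)


class TestDifferentialZscore:
    def test_zero_at_equal_correlations(self):
        for rho in (0.0, 0.3, -0.7):
            assert differential_zscore(rho, rho, 50, 80) == 0.0

    def test_antisymmetric_under_cohort_swap(self):
        z = differential_zscore(0.6, 0.1, 145, 255)
        assert differential_zscore(0.1, 0.6, 255, 145) == pytest.approx(-z)

    def test_arithmetic_oracle_at_study_cohort_sizes(self):
        """Step-by-step evaluation with n=145 tumor and 255 control samples."""
        zT = math.atanh(0.6)
        zC = math.atanh(0.1)
        expected = (zT - zC) / math.sqrt(1 / (145 - 3) + 1 / (255 - 3))
        assert differential_zscore(0.6, 0.1, 145, 255) == pytest.approx(
            expected, abs=1e-14)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            differential_zscore(0.5, 0.0, 3, 100)

    def test_increases_with_sample_size(self):
        zs = [differential_zscore(0.5, 0.1, n, n) for n in (10, 50, 200, 1000)]
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_variance_correction_shrinks_score(self):
        plain = differential_zscore(0.5, 0.1, 50, 50)
        corrected = differential_zscore(0.5, 0.1, 50, 50,
                                        variance_correction=True)
        assert corrected == pytest.approx(plain / math.sqrt(1.06))

    def test_strictly_increasing_in_rho_T(self):
        grid = np.linspace(-0.9, 0.9, 19)
        zs = [differential_zscore(r, 0.2, 40, 40) for r in grid]
        assert all(b > a for a, b in zip(zs, zs[1:]))


class TestBuildDifferentialNetwork:
    def test_identical_matrices_give_empty_network(self, rng):
        m = np.array([[1, 0.4, 0.2], [0.4, 1, 0.6], [0.2, 0.6, 1.0]])
        net = build_differential_network(corr_from(m, 100), corr_from(m, 150))
        assert net.n_edges == 0

    def test_single_pair_membership_decided_by_oracle(self):
        z = (math.atanh(0.9) - 0.0) / math.sqrt(1 / 97 + 1 / 97)
        assert z >= 3  # the oracle says this edge qualifies
        m_T = np.array([[1, 0.9], [0.9, 1.0]])
        m_C = np.eye(2)
        net = build_differential_network(corr_from(m_T, 100),
                                         corr_from(m_C, 100))
        assert net.n_edges == 1
        assert net.edges.iloc[0]["Z"] == pytest.approx(z, abs=1e-12)

    def test_unbounded_threshold_gives_complete_graph(self, rng):
        g = 6
        m = np.eye(g)
        net = build_differential_network(
            corr_from(m, 50), corr_from(m, 50),
            z_threshold=-np.inf, positive_only=False)
        assert net.n_edges == g * (g - 1) // 2

    def test_positive_only_mask_drops_negative_tumor_links(self):
        m_T = np.array([[1, -0.2], [-0.2, 1.0]])
        m_C = np.array([[1, -0.9], [-0.9, 1.0]])
        with_mask = build_differential_network(corr_from(m_T, 100),
                                               corr_from(m_C, 100))
        without = build_differential_network(corr_from(m_T, 100),
                                             corr_from(m_C, 100),
                                             positive_only=False)
        assert with_mask.n_edges == 0
        assert without.n_edges == 1  # -0.9 -> -0.2 is a big "increase"

    def test_gene_set_mismatch_rejected(self):
        a = corr_from(np.eye(2), 50, genes=["A", "B"])
        b = corr_from(np.eye(2), 50, genes=["A", "C"])
        with pytest.raises(ValueError):
            build_differential_network(a, b)

    def test_composition_identity_against_oracle(self, rng):
        """Z equals (atanh r_T - atanh r_C)/denominator on 1000 draws."""
        rho = rng.uniform(-0.95, 0.95, size=(1000, 2))
        ns = rng.integers(5, 500, size=(1000, 2))
        for (rT, rC), (nT, nC) in zip(rho, ns):
            expected = (math.atanh(rT) - math.atanh(rC)) / math.sqrt(
                1 / (nT - 3) + 1 / (nC - 3))
            assert differential_zscore(rT, rC, int(nT), int(nC)) == \
                pytest.approx(expected, abs=1e-12)


class TestMatchDensityThreshold:
    def test_identical_comparison_reproduces_density(self, rng):
        data_T = rng.normal(size=(8, 60))
        data_T[1] = 0.8 * data_T[0] + 0.2 * rng.normal(size=60)
        data_C = rng.normal(size=(8, 60))
        cT = spearman_matrix(make_log2(data_T - data_T.min() + 1))
        cC = spearman_matrix(make_log2(data_C - data_C.min() + 1))
        ref = build_differential_network(cT, cC, z_threshold=2.0)
        assert ref.n_edges >= 1
        thr, net = match_density_threshold(ref, cT, cC)
        assert net.density == pytest.approx(ref.density)

    def test_empty_reference_rejected(self):
        ref = net_from_edges([], nodes=["A", "B"])
        with pytest.raises(ValueError):
            match_density_threshold(ref, corr_from(np.eye(2), 50),
                                    corr_from(np.eye(2), 50))

    def test_exhaustive_scan_oracle(self, rng):
        """Chosen threshold equals a brute-force scan over distinct Z values."""
        from lectnet.differential_net import differential_scores
        data_T = rng.normal(size=(10, 50))
        data_C = rng.normal(size=(10, 50))
        cT = spearman_matrix(make_log2(data_T - data_T.min() + 1))
        cC = spearman_matrix(make_log2(data_C - data_C.min() + 1))
        ref = net_from_edges([("A", "B"), ("A", "C"), ("B", "C")],
                             nodes=["A", "B", "C", "D"])  # density 3/6
        thr, net = match_density_threshold(ref, cT, cC)
        scores = differential_scores(cT, cC)["Z"].to_numpy()
        possible = 45
        best = None
        for t in sorted(set(scores), reverse=True):
            d = (scores >= t).sum() / possible
            if best is None or abs(d - ref.density) < abs(best[1] - ref.density):
                best = (t, d)
        assert thr == pytest.approx(best[0])
        assert net.density == pytest.approx(best[1])


class TestDegreesAndHubs:
    def test_triangle_degrees(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("A", "C")],
                             nodes=["A", "B", "C"])
        assert node_degrees(net).to_dict() == {"A": 2, "B": 2, "C": 2}

    def test_star_degrees_and_isolated_flag(self):
        leaves = [f"L{i}" for i in range(8)]
        net = net_from_edges([("HUB", l) for l in leaves],
                             nodes=["HUB"] + leaves + ["ISO"])
        deg = node_degrees(net, include_isolated=True)
        assert deg["HUB"] == 8 and deg["ISO"] == 0
        assert "ISO" not in node_degrees(net, include_isolated=False)

    def test_degrees_match_adjacency_row_sums(self, rng):
        nodes = [f"N{i}" for i in range(15)]
        adj = np.triu(rng.random((15, 15)) < 0.3, k=1)
        edges = [(nodes[i], nodes[j]) for i, j in zip(*np.where(adj))]
        net = net_from_edges(edges, nodes=nodes)
        deg = node_degrees(net, include_isolated=True)
        full = adj + adj.T
        for i, n in enumerate(nodes):
            assert deg[n] == full[i].sum()

    def test_star_hub_is_the_center(self):
        leaves = [f"L{i}" for i in range(8)]
        net = net_from_edges([("HUB", l) for l in leaves],
                             nodes=["HUB"] + leaves)
        report = identify_hubs(net, percentile=80)
        assert report.hubs == {"HUB"}
        assert report.degree_cutoff == 8

    def test_uniform_degrees_make_every_node_a_hub(self):
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")],
                             nodes=list("ABCD"))
        assert identify_hubs(net, percentile=80).hubs == {"A", "B", "C", "D"}

    def test_percentile_zero_selects_all_connected(self):
        leaves = [f"L{i}" for i in range(5)]
        net = net_from_edges([("HUB", l) for l in leaves],
                             nodes=["HUB"] + leaves + ["ISO"])
        hubs = identify_hubs(net, percentile=0).hubs
        assert hubs == {"HUB", *leaves}  # isolated node excluded

    def test_hub_set_invariant_to_relabeling(self, rng):
        nodes = [f"N{i}" for i in range(12)]
        adj = np.triu(rng.random((12, 12)) < 0.4, k=1)
        edges = [(nodes[i], nodes[j]) for i, j in zip(*np.where(adj))]
        net = net_from_edges(edges, nodes=nodes)
        mapping = {n: f"X{i}" for i, n in enumerate(reversed(nodes))}
        renamed = net_from_edges([(mapping[a], mapping[b]) for a, b in edges],
                                 nodes=[mapping[n] for n in nodes])
        h1 = identify_hubs(net).hubs
        h2 = identify_hubs(renamed).hubs
        assert {mapping[n] for n in h1} == h2

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            identify_hubs(net_from_edges([], nodes=["A", "B"]))


class TestCompareNetworks:
    def test_self_comparison_is_perfect(self):
        nodes = [f"N{i}" for i in range(9)]
        edges = ([("N0", n) for n in nodes[1:7]]
                 + [("N1", n) for n in nodes[2:7]])
        net = net_from_edges(edges, nodes=nodes)
        rho, (only_a, shared, only_b) = compare_networks(net, net, min_degree=1)
        assert rho == pytest.approx(1.0)
        assert only_a == set() and only_b == set()
        assert shared == identify_hubs(net).hubs

    def test_disjoint_hub_sets(self):
        a = net_from_edges([("A", f"X{i}") for i in range(5)],
                           nodes=["A", "B"] + [f"X{i}" for i in range(5)])
        b = net_from_edges([("B", f"X{i}") for i in range(5)],
                           nodes=["A", "B"] + [f"X{i}" for i in range(5)])
        _, (only_a, shared, only_b) = compare_networks(a, b, min_degree=1)
        assert shared == set()
        assert "A" in only_a and "B" in only_b

    def test_insufficient_shared_genes_rejected(self):
        a = net_from_edges([("A", "B")], nodes=["A", "B"])
        with pytest.raises(ValueError):
            compare_networks(a, a, min_degree=5)
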