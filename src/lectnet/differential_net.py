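"""Differential co-expression networks, hub calling and cross-cohort agreement.

For each gene pair the Spearman correlations in the tumor and control
cohorts are Fisher Z-transformed and compared with the two-sample
correlation z-score

    Z = (z_T - z_C) / sqrt(1/(n_T - 3) + 1/(n_C - 3))

which is approximately standard normal when the true correlations are
equal.  Pairs with Z at or above a threshold (default 3) form the
differential network: links whose co-expression increased significantly in
the tumor condition.  Hubs are the most connected nodes — the top 20% of
the degree distribution over connected nodes by default.  A validation
cohort is compared against the discovery network after re-thresholding its
z-scores so both networks have comparable density.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .coexpression_net import CorrelationMatrix

__all__ = [
    "DifferentialNetwork",
    "HubReport",
    "fisher_z",
    "differential_zscore",
    "differential_scores",
    "build_differential_network",
    "match_density_threshold",
    "node_degrees",
    "identify_hubs",
    "compare_networks",
]

_CLAMP = 1.0 - 1e-15

# Fisher's variance 1/(n-3) is exact only for Pearson correlations; the
# Spearman asymptotic variance is about 1.06/(n-3).  The uncorrected form
# is the default; set variance_correction=True for the conservative one.
_SPEARMAN_VAR_FACTOR = 1.06


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """arctanh of a correlation, clamping |rho| -> 1 to keep the value finite."""
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho_arr) > 1):
        raise ValueError("|rho| must not exceed 1")
    out = np.arctanh(np.clip(rho_arr, -_CLAMP, _CLAMP))
    return float(out) if np.isscalar(rho) or out.ndim == 0 else out


def differential_zscore(
    rho_T: float | np.ndarray,
    rho_C: float | np.ndarray,
    n_T: int,
    n_C: int,
    variance_correction: bool = False,
) -> float | np.ndarray:
    """Z-score for the increase in correlation from control to tumor."""
    if n_T <= 3 or n_C <= 3:
        raise ValueError("both cohorts need more than 3 samples")
    k = _SPEARMAN_VAR_FACTOR if variance_correction else 1.0
    denom = np.sqrt(k / (n_T - 3) + k / (n_C - 3))
    z = (fisher_z(rho_T) - fisher_z(rho_C)) / denom
    return float(z) if np.isscalar(rho_T) and np.isscalar(rho_C) else z


@dataclass
class DifferentialNetwork:
    """Gene pairs whose tumor co-expression significantly exceeds control.

    ``edges`` columns: gene_a, gene_b, rho_T, rho_C, z_T, z_C, Z.  Every
    retained edge has Z >= z_threshold.  Density is edge count divided by
    the number of possible pairs among all nodes.
    """

    nodes: list[str]
    edges: pd.DataFrame
    z_threshold: float
    n_T: int
    n_C: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        g = len(self.nodes)
        possible = g * (g - 1) // 2
        return self.n_edges / possible if possible else 0.0

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b,
                       rho_T=row.rho_T, rho_C=row.rho_C, Z=row.Z)
        return g

    def save_edgelist(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def save_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), path)


@dataclass
class HubReport:
    """Degree table, percentile cutoff and resulting hub set."""

    degree_table: pd.Series  # gene -> degree, connected nodes only
    percentile: float
    degree_cutoff: float
    hubs: set[str]

    def to_frame(self) -> pd.DataFrame:
        df = self.degree_table.rename("degree").to_frame()
        df["is_hub"] = df.index.isin(self.hubs)
        return df.sort_values("degree", ascending=False)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")


def differential_scores(
    corr_T: CorrelationMatrix,
    corr_C: CorrelationMatrix,
    positive_only: bool = True,
    variance_correction: bool = False,
) -> pd.DataFrame:
    """Z-scores for all gene pairs of two matched correlation matrices.

    ``positive_only`` restricts candidate pairs to those with rho_T > 0,
    mirroring the removal of negative links from the tumor network before
    looking for co-expression gains.
    """
    if corr_T.genes != corr_C.genes:
        raise ValueError("correlation matrices cover different gene sets")
    genes = corr_T.genes
    ii, jj = np.triu_indices(len(genes), k=1)
    rho_T = corr_T.rho[ii, jj]
    rho_C = corr_C.rho[ii, jj]
    if positive_only:
        keep = rho_T > 0
        ii, jj, rho_T, rho_C = ii[keep], jj[keep], rho_T[keep], rho_C[keep]
    z_T = fisher_z(rho_T)
    z_C = fisher_z(rho_C)
    Z = differential_zscore(rho_T, rho_C, corr_T.n_samples, corr_C.n_samples,
                            variance_correction=variance_correction)
    return pd.DataFrame({
        "gene_a": [genes[i] for i in ii],
        "gene_b": [genes[j] for j in jj],
        "rho_T": rho_T, "rho_C": rho_C,
        "z_T": np.atleast_1d(z_T), "z_C": np.atleast_1d(z_C),
        "Z": np.atleast_1d(Z),
    })


def build_differential_network(
    corr_T: CorrelationMatrix,
    corr_C: CorrelationMatrix,
    z_threshold: float = 3.0,
    positive_only: bool = True,
    variance_correction: bool = False,
) -> DifferentialNetwork:
    """Threshold the pairwise z-scores; keep edges with Z >= z_threshold."""
    scores = differential_scores(corr_T, corr_C, positive_only=positive_only,
                                 variance_correction=variance_correction)
    edges = scores[scores["Z"] >= z_threshold].reset_index(drop=True)
    return DifferentialNetwork(nodes=list(corr_T.genes), edges=edges,
                               z_threshold=z_threshold,
                               n_T=corr_T.n_samples, n_C=corr_C.n_samples)


def match_density_threshold(
    reference: DifferentialNetwork,
    corr_T2: CorrelationMatrix,
    corr_C2: CorrelationMatrix,
    positive_only: bool = True,
) -> tuple[float, DifferentialNetwork]:
    """Threshold a second comparison so its density matches a reference.

    Candidate thresholds are the distinct z-scores of the second
    comparison; the one minimizing |density - reference.density| wins, ties
    broken toward the higher (stricter) threshold.
    """
    if reference.n_edges == 0:
        raise ValueError("reference network has no edges")
    scores = differential_scores(corr_T2, corr_C2, positive_only=positive_only)
    g = len(corr_T2.genes)
    possible = g * (g - 1) // 2
    z_vals = np.sort(scores["Z"].unique())
    if z_vals.size == 0:
        raise ValueError("second comparison has no candidate pairs")
    # density at threshold t = (# Z >= t) / possible; scan high to low so
    # ties resolve to the stricter threshold
    best_t, best_gap = None, np.inf
    for t in z_vals[::-1]:
        density = float((scores["Z"] >= t).sum()) / possible
        gap = abs(density - reference.density)
        if gap < best_gap:
            best_t, best_gap = float(t), gap
    net = DifferentialNetwork(
        nodes=list(corr_T2.genes),
        edges=scores[scores["Z"] >= best_t].reset_index(drop=True),
        z_threshold=best_t,
        n_T=corr_T2.n_samples, n_C=corr_C2.n_samples,
    )
    return best_t, net


def node_degrees(
    net: DifferentialNetwork, include_isolated: bool = False
) -> pd.Series:
    """Degree per node; isolated nodes appear (with 0) only when requested."""
    graph = net.to_graph()
    deg = pd.Series(dict(graph.degree()), dtype=int)
    deg = deg.reindex(net.nodes).fillna(0).astype(int)
    if not include_isolated:
        deg = deg[deg >= 1]
    return deg


def identify_hubs(net: DifferentialNetwork, percentile: float = 80.0) -> HubReport:
    """Call hubs as the top (100 - percentile)% of connected nodes by degree.

    The degree distribution is taken over nodes with degree >= 1 (isolated
    panel genes carry no differential signal and are excluded).  The cutoff
    is the degree of the k-th most connected node, k = max(1,
    floor((100 - percentile)/100 * n)); all nodes at or above the cutoff
    are hubs, so ties at the cutoff are included.
    """
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    deg = node_degrees(net, include_isolated=False)
    if deg.empty:
        raise ValueError("network has no edges; no degree distribution")
    n = len(deg)
    k = max(1, int(np.floor((100.0 - percentile) / 100.0 * n)))
    cutoff = float(np.sort(deg.to_numpy())[::-1][k - 1])
    hubs = set(deg.index[deg >= cutoff])
    return HubReport(degree_table=deg, percentile=percentile,
                     degree_cutoff=cutoff, hubs=hubs)


def compare_networks(
    net_A: DifferentialNetwork,
    net_B: DifferentialNetwork,
    min_degree: int = 5,
    hub_percentile: float = 80.0,
) -> tuple[float, tuple[set[str], set[str], set[str]]]:
    """Degree agreement and hub overlap between two differential networks.

    The degree rank correlation (Spearman) is computed over shared genes
    reaching ``min_degree`` links in at least one network.  Hub sets come
    from :func:`identify_hubs` on each network and are partitioned into
    (only_A, shared, only_B).
    """
    shared_genes = [g for g in net_A.nodes if g in set(net_B.nodes)]
    deg_A = node_degrees(net_A, include_isolated=True).reindex(shared_genes)
    deg_B = node_degrees(net_B, include_isolated=True).reindex(shared_genes)
    mask = (deg_A >= min_degree) | (deg_B >= min_degree)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 shared genes reach min_degree")
    rho, _ = stats.spearmanr(deg_A[mask], deg_B[mask])
    hubs_A = identify_hubs(net_A, percentile=hub_percentile).hubs
    hubs_B = identify_hubs(net_B, percentile=hub_percentile).hubs
    overlap = (hubs_A - hubs_B, hubs_A & hubs_B, hubs_B - hubs_A)
    return float(rho), overlap
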