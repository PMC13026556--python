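"""Per-condition Spearman co-expression matrices and positive-link networks.

Co-expression between two genes is measured by Spearman's rank correlation
across samples of one condition.  The per-condition co-expression network
keeps only positively correlated pairs: the biological question is an
increase of coordinated expression, and negative links are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "CoexpressionNetwork",
    "spearman_matrix",
    "build_coexpression_network",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation matrix over a gene set."""

    genes: list[str]
    rho: np.ndarray
    n_samples: int
    condition: str

    def __post_init__(self) -> None:
        g = len(self.genes)
        if self.rho.shape != (g, g):
            raise ValueError("rho shape does not match gene list")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples (Fisher variance 1/(n-3))")
        if not np.allclose(self.rho, self.rho.T):
            raise ValueError("rho must be symmetric")
        if np.nanmax(np.abs(self.rho)) > 1 + 1e-12:
            raise ValueError("|rho| must not exceed 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.genes, columns=self.genes)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class CoexpressionNetwork:
    """Undirected network of positively co-expressed gene pairs.

    Every node of the correlation matrix is retained, including isolated
    ones; edge weights are the Spearman coefficients (strictly positive).
    """

    nodes: list[str]
    edges: pd.DataFrame  # columns: gene_a, gene_b, rho
    condition: str

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, rho=row.rho)
        return g

    def save_edgelist(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def save_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), path)


def spearman_matrix(mat: ExpressionMatrix) -> CorrelationMatrix:
    """Pairwise Spearman correlation (average ranks for ties) across samples.

    Genes with constant expression have undefined rank correlation; their
    entries are set to 0 with a warning rather than propagating NaN.
    """
    if mat.units != "normalized_log2":
        raise ValueError("co-expression is computed on normalized log2 values")
    if mat.n_samples < 4:
        raise ValueError("need at least 4 samples")
    if mat.n_genes < 2:
        raise ValueError("need at least 2 genes")
    values = mat.data.to_numpy(dtype=float)
    with warnings.catch_warnings():
        # constant genes are handled explicitly below
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, _ = stats.spearmanr(values, axis=1)
    if np.ndim(rho) == 0:  # scipy collapses the 2-gene case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(rho, dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        logger.warning("constant genes set to rho=0: %s",
                       list(mat.data.index[constant]))
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(genes=mat.genes, rho=rho,
                             n_samples=mat.n_samples, condition=mat.condition)


def build_coexpression_network(
    corr: CorrelationMatrix, min_rho: float = 0.0
) -> CoexpressionNetwork:
    """Keep every gene pair with rho strictly above ``min_rho``."""
    genes = corr.genes
    ii, jj = np.triu_indices(len(genes), k=1)
    mask = corr.rho[ii, jj] > min_rho
    edges = pd.DataFrame({
        "gene_a": [genes[i] for i in ii[mask]],
        "gene_b": [genes[j] for j in jj[mask]],
        "rho": corr.rho[ii[mask], jj[mask]],
    })
    return CoexpressionNetwork(nodes=list(genes), edges=edges,
                               condition=corr.condition)
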