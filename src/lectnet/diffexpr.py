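"""Per-gene differential expression on log2-normalized values.

The fold change is the difference of per-gene means on the log2 scale
(tumor minus control).  Significance comes from a per-gene two-sample
Welch t-test with Benjamini-Hochberg FDR adjustment across genes; a gene
is called differentially expressed only when |log2FC| >= 1.5 AND the
adjusted p-value is below 0.05 (both thresholds configurable).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel_io import ExpressionMatrix

__all__ = ["log2_fold_change", "differential_expression"]


def _check_gene_match(mat_T: ExpressionMatrix, mat_C: ExpressionMatrix) -> None:
    if list(mat_T.genes) != list(mat_C.genes):
        raise ValueError("tumor and control matrices cover different gene sets")
    if mat_T.units != "normalized_log2" or mat_C.units != "normalized_log2":
        raise ValueError("differential expression runs on normalized log2 values")


def log2_fold_change(mat_T: ExpressionMatrix, mat_C: ExpressionMatrix) -> pd.Series:
    """Difference of per-gene means on the log2 scale (tumor - control)."""
    _check_gene_match(mat_T, mat_C)
    fc = mat_T.data.mean(axis=1) - mat_C.data.mean(axis=1)
    return fc.rename("log2FC")


def differential_expression(
    mat_T: ExpressionMatrix,
    mat_C: ExpressionMatrix,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene DE table: log2FC, raw_p, adj_p (BH), flag_de.

    ``flag_de`` is the conjunction |log2FC| >= fc_threshold and
    adj_p < alpha.  Welch's unequal-variance t-test is the default;
    ``equal_var=True`` switches to the pooled-variance test.
    """
    _check_gene_match(mat_T, mat_C)
    if mat_T.n_samples < 2 or mat_C.n_samples < 2:
        raise ValueError("each condition needs at least 2 samples")
    fc = log2_fold_change(mat_T, mat_C)
    t_vals = mat_T.data.to_numpy(dtype=float)
    c_vals = mat_C.data.to_numpy(dtype=float)
    _, raw_p = stats.ttest_ind(t_vals, c_vals, axis=1, equal_var=equal_var)
    # identical constant genes yield NaN p; no evidence of change
    raw_p = np.where(np.isnan(raw_p), 1.0, raw_p)
    _, adj_p, _, _ = multipletests(raw_p, method="fdr_bh")
    flag = (fc.abs() >= fc_threshold) & (adj_p < alpha)
    return pd.DataFrame({
        "log2FC": fc,
        "raw_p": raw_p,
        "adj_p": adj_p,
        "flag_de": flag,
    }, index=mat_T.data.index)


def save_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")
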