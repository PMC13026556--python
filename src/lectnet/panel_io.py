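"""Gene panels, expression matrices, low-count filtering and normalization.

The entry point of the pipeline is a pair of raw count matrices (genes x
samples, one per condition) and a small gene panel annotated by family
(siglec / galectin / C-type lectin).  This module reads and validates both,
subsets the matrix to the panel, drops genes whose total count across
samples falls below a threshold, and applies median-of-ratios size-factor
normalization followed by a log2(x + 1) transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "GenePanel",
    "ExpressionMatrix",
    "SizeFactors",
    "load_panel",
    "save_panel",
    "load_expression",
    "save_expression",
    "subset_to_panel",
    "filter_low_expression",
    "estimate_size_factors",
    "normalize_log2",
]


class Family(str, Enum):
    """Lectin family labels used in panel files."""

    SIGLEC = "siglec"
    GALECTIN = "galectin"
    CTYPE = "ctype"


@dataclass(frozen=True)
class GenePanel:
    """An ordered, duplicate-free list of (gene symbol, family) entries."""

    entries: tuple[tuple[str, Family], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("panel must be non-empty")
        symbols = [s for s, _ in self.entries]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols in panel: {dupes}")

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.entries]

    def family_counts(self) -> dict[Family, int]:
        counts = {f: 0 for f in Family}
        for _, fam in self.entries:
            counts[fam] += 1
        return counts

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one condition.

    ``units`` is ``"raw_counts"`` for non-negative integers straight off the
    quantifier, or ``"normalized_log2"`` after :func:`normalize_log2`.
    """

    data: pd.DataFrame  # genes in rows, samples in columns
    condition: str
    units: str = "raw_counts"

    _UNITS = ("raw_counts", "normalized_log2")

    def __post_init__(self) -> None:
        if self.units not in self._UNITS:
            raise ValueError(f"units must be one of {self._UNITS}")
        if self.data.empty:
            raise ValueError("expression matrix is empty")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.data.index.is_unique:
            raise ValueError("gene symbols must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if self.units == "raw_counts" and (self.data.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample positive multipliers equalizing sequencing depth."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be strictly positive")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def load_panel(path: str | Path) -> GenePanel:
    """Read a two-column (symbol, family) delimited panel file.

    Lines starting with ``#`` are ignored; a header row is optional and
    detected by an unrecognized family label in column two.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if raw.shape[1] < 2:
        raise ValueError("panel file needs two columns: symbol, family")
    rows = raw.iloc[:, :2].dropna()
    valid = {f.value for f in Family}
    entries: list[tuple[str, Family]] = []
    for i, (symbol, fam) in enumerate(rows.itertuples(index=False)):
        fam_l = str(fam).strip().lower()
        if fam_l not in valid:
            if i == 0:  # tolerate a header row
                continue
            raise ValueError(f"unknown family label {fam!r} for gene {symbol!r}")
        entries.append((str(symbol).strip(), Family(fam_l)))
    return GenePanel(tuple(entries))


def save_panel(panel: GenePanel, path: str | Path) -> None:
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    with open(path, "w") as fh:
        for symbol, fam in panel.entries:
            fh.write(f"{symbol}{sep}{fam.value}\n")


def load_expression(path: str | Path, condition: str) -> ExpressionMatrix:
    """Read a delimited counts file (genes in rows, header = sample ids).

    Duplicate gene rows are collapsed by summation (counts are additive);
    the collapse is logged.
    """
    df = _read_delimited(path)
    if df.empty:
        raise ValueError(f"empty expression matrix in {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    if not df.index.is_unique:
        n_dup = df.index.duplicated().sum()
        logger.warning("collapsing %d duplicate gene rows by sum in %s", n_dup, path)
        df = df.groupby(level=0, sort=False).sum()
    return ExpressionMatrix(data=df, condition=condition, units="raw_counts")


def save_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    mat.data.to_csv(path, sep=sep)


def subset_to_panel(
    mat: ExpressionMatrix, panel: GenePanel
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict the matrix to panel genes, in panel order.

    Returns the subset matrix and the list of panel genes absent from the
    matrix.  Raises if no panel gene is present at all.
    """
    present = [g for g in panel.symbols if g in mat.data.index]
    missing = [g for g in panel.symbols if g not in mat.data.index]
    if not present:
        raise ValueError("no panel gene found in the expression matrix")
    if missing:
        logger.info("%d panel genes absent from matrix: %s", len(missing), missing)
    sub = mat.data.loc[present]
    return ExpressionMatrix(sub, condition=mat.condition, units=mat.units), missing


def filter_low_expression(
    mat: ExpressionMatrix, min_total: float = 500
) -> ExpressionMatrix:
    """Drop genes whose total count across samples is below ``min_total``.

    The rule is strict: a gene summing to exactly ``min_total`` is kept.
    """
    if mat.units != "raw_counts":
        raise ValueError("low-expression filter applies to raw counts")
    totals = mat.data.sum(axis=1)
    keep = totals >= min_total
    removed = list(mat.data.index[~keep])
    if removed:
        logger.info("filtered %d low-count genes (< %g total): %s",
                    len(removed), min_total, removed)
    if not keep.any():
        raise ValueError("all genes removed by the low-expression filter")
    return ExpressionMatrix(mat.data.loc[keep], condition=mat.condition,
                            units="raw_counts")


def estimate_size_factors(mat: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Reference genes are those with a nonzero count in every sample; each
    sample's factor is the median over reference genes of
    count / geometric-mean-across-samples.
    """
    if mat.units != "raw_counts":
        raise ValueError("size factors are estimated from raw counts")
    counts = mat.data.to_numpy(dtype=float)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no reference gene without zeros; cannot estimate size factors")
    log_counts = np.log(counts[ref])
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    ratios = np.exp(log_counts - log_geomean)
    factors = np.median(ratios, axis=0)
    return SizeFactors(pd.Series(factors, index=mat.data.columns, name="size_factor"))


def normalize_log2(mat: ExpressionMatrix, sf: SizeFactors) -> ExpressionMatrix:
    """Divide each sample by its size factor and apply log2(x + 1)."""
    if mat.units != "raw_counts":
        raise ValueError("normalize_log2 expects raw counts")
    if list(sf.factors.index) != mat.samples:
        raise ValueError("size factors do not match matrix samples")
    norm = np.log2(mat.data / sf.factors + 1.0)
    return ExpressionMatrix(norm, condition=mat.condition, units="normalized_log2")
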