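"""Per-gene expression-derived and structural covariates.

Expression summaries operate on a genes x tissues abundance matrix (any
non-negative units; tau and breadth are scale-free or threshold-based).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def tau(expr: np.ndarray) -> float:
    """Tissue-specificity index: sum_i (1 - x_i/x_max) / (n - 1).

    0 for uniformly expressed (housekeeping) genes, 1 for single-tissue
    expression; invariant to positive rescaling.  NaN when the gene is
    silent in every tissue.
    """
    x = np.asarray(expr, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires at least 2 tissues")
    if (x < 0).any():
        raise ValueError("tau requires non-negative abundances")
    m = x.max()
    if m == 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (x.size - 1))


def breadth(expr: np.ndarray, threshold: float = 0.0) -> int:
    """Number of tissues with abundance strictly above ``threshold``."""
    x = np.asarray(expr, dtype=float)
    return int((x > threshold).sum())


def zscore(values: np.ndarray) -> np.ndarray:
    """Across-gene standardization (sample sd); rank-preserving."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zscore undefined for (near-)constant input")
    return (x - x.mean()) / sd


def expression_summary(matrix: pd.DataFrame, how: str = "mean") -> pd.Series:
    """Per-gene abundance summary across tissues ('mean' or 'max')."""
    if how == "mean":
        return matrix.mean(axis=1)
    if how == "max":
        return matrix.max(axis=1)
    raise ValueError(f"unknown summary {how!r}")


def covariate_table(
    matrix: pd.DataFrame,
    breadth_threshold: float = 0.0,
    summary: str = "mean",
    structural: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per gene: expression level, Z-score, breadth, tau.

    ``structural`` columns (lengths, exon counts, GC, ...) are passed
    through by gene_id join; they are upstream annotation, not computed
    here.
    """
    level = expression_summary(matrix, summary)
    out = pd.DataFrame(
        {
            "expression_level": level,
            "expression_z": zscore(level.to_numpy()),
            "breadth": [breadth(row, breadth_threshold) for row in matrix.to_numpy()],
            "tau": [tau(row) for row in matrix.to_numpy()],
        },
        index=matrix.index,
    )
    if structural is not None:
        out = out.join(structural, how="left")
    out.index.name = "gene_id"
    return out
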