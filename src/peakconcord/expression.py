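"""Differential-expression labels and the cross-dataset expression filters.

Real datasets bring their own DE tables (fitted upstream by dedicated count
models); this module reads those, applies the |log2FC| / q-value thresholds,
and additionally provides a simple Welch-on-log internal test so synthetic
end-to-end runs need no external fitter. Quantile normalization and the
low-expression filter used when comparing heterogeneous datasets live here
too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import parse_de_table
from .types import CountMatrix

__all__ = [
    "ExpressionChange",
    "quantile_normalize",
    "gene_log2fc",
    "call_de_genes",
]


@dataclass(frozen=True)
class ExpressionChange:
    """Per-gene expression change with its differential call."""

    gene_id: str
    log2fc: float
    qvalue: float | None
    is_de: bool
    direction: str  # "up", "down", or "none"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.is_de:
            if self.direction == "none":
                raise ValueError("DE gene must have a direction")
            if self.direction == "up" and self.log2fc < 0:
                raise ValueError("direction 'up' with negative log2fc")
            if self.direction == "down" and self.log2fc > 0:
                raise ValueError("direction 'down' with positive log2fc")


def quantile_normalize(matrix: CountMatrix) -> CountMatrix:
    """Force identical per-column value distributions by rank-wise averaging.

    Each column's sorted values are replaced by the across-column mean at
    each rank; ties within a column receive the mean of the reference values
    over their tied rank span. Column means are equal afterwards.
    """
    values = matrix.values
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    ranks = np.empty(n, dtype=float)
    for j in range(values.shape[1]):
        col_sorted = sorted_vals[:, j]
        # average reference over tied spans within this column
        ranks[:] = reference
        start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    ranks[start:i] = reference[start:i].mean()
                start = i
        out[order[:, j], j] = ranks
    return matrix.with_values(out, units="quantile_normalized")


def gene_log2fc(
    expr: CountMatrix,
    cond_a: str,
    cond_b: str,
    pseudocount: float = 1.0,
    min_expression: float = 0.0,
) -> pd.DataFrame:
    """Per-gene log2 fold change (cond_b over cond_a) with low-expression drops.

    Genes whose maximum replicate mean across the two conditions falls below
    ``min_expression`` are flagged ``dropped`` (their log2fc is still
    reported for audit).
    """
    m_a = expr.condition_mean(cond_a)
    m_b = expr.condition_mean(cond_b)
    with np.errstate(divide="ignore"):
        lfc = np.log2((m_b + pseudocount) / (m_a + pseudocount))
    return pd.DataFrame(
        {
            "mean_a": m_a,
            "mean_b": m_b,
            "log2fc": lfc,
            "dropped": np.maximum(m_a, m_b) < min_expression,
        },
        index=pd.Index(expr.row_ids, name="gene_id"),
    )


def _changes_from_frame(
    df: pd.DataFrame,
    lfc_threshold: float,
    q_threshold: float | None,
) -> list[ExpressionChange]:
    out = []
    has_q = "qvalue" in df.columns and q_threshold is not None
    for row in df.itertuples():
        lfc = float(row.log2fc)
        q = float(row.qvalue) if has_q else None
        is_de = abs(lfc) >= lfc_threshold and (q is None or q <= q_threshold)
        if getattr(row, "dropped", False):
            is_de = False
        direction = "none" if not is_de else ("up" if lfc > 0 else "down")
        out.append(ExpressionChange(str(row.Index), lfc, q, is_de, direction))
    return out


def call_de_genes(
    source,
    cond_a: str | None = None,
    cond_b: str | None = None,
    lfc_threshold: float = 0.5,
    q_threshold: float = 0.05,
    mode: str = "table",
    pseudocount: float = 1.0,
    min_expression: float = 0.0,
) -> list[ExpressionChange]:
    """Label differentially expressed genes.

    mode="table": ``source`` is a DE-table path or DataFrame with columns
    gene_id, log2fc, qvalue; DE iff |log2fc| >= lfc_threshold and
    qvalue <= q_threshold.

    mode="internal_test": ``source`` is an expression CountMatrix; per gene a
    Welch two-sample t-test on log2(value + 1) between the two conditions,
    Benjamini-Hochberg adjusted, combined with the same thresholds on the
    (pseudocounted) TPM-scale log2 fold change.

    mode="threshold_only": |log2fc| alone decides — for datasets without
    replicates or q-values.
    """
    if mode == "table":
        df = parse_de_table(source) if isinstance(source, str) else source.copy()
        missing = [c for c in ("gene_id", "log2fc", "qvalue") if c not in df.columns]
        if missing:
            raise ValueError(f"DE table missing columns {missing}")
        df = df.set_index("gene_id")
        return _changes_from_frame(df, lfc_threshold, q_threshold)

    if mode not in ("internal_test", "threshold_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(source, CountMatrix):
        raise TypeError(f"mode {mode!r} requires an expression CountMatrix")
    if cond_a is None or cond_b is None:
        raise ValueError("cond_a and cond_b are required for matrix modes")

    df = gene_log2fc(source, cond_a, cond_b, pseudocount, min_expression)
    if mode == "threshold_only":
        return _changes_from_frame(df.drop(columns="qvalue", errors="ignore"),
                                   lfc_threshold, None)

    log_a = np.log2(source.values[:, source.condition_columns(cond_a)] + 1.0)
    log_b = np.log2(source.values[:, source.condition_columns(cond_b)] + 1.0)
    t_res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    pvals = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)
    df["qvalue"] = multipletests(pvals, method="fdr_bh")[1]
    return _changes_from_frame(df, lfc_threshold, q_threshold)
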