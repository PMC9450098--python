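"""Per-gene concordance between accessibility and expression changes.

A gene's assigned peaks are compared with its expression change: peaks
differentially accessible in the same direction are concordant, opposite
ones discordant, and the concordant proportion (concordant / assigned) is
the central per-gene statistic. Differentially expressed genes split into
concordant (>= 1 concordant differential peak) and nonconcordant (none)
groups per direction. Collapse, correlation, overlap and distribution
utilities support the genome-wide comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import PeakGeneAssignment
from .diffpeaks import DiffPeakSet
from .expression import ExpressionChange

__all__ = [
    "GeneConcordance",
    "CorrelationResult",
    "gene_concordance",
    "classify_groups",
    "collapse_gene_accessibility",
    "pearson_bootstrap",
    "ks_compare",
    "fisher_overlap",
    "select_top_genes",
]

GROUPS = (
    "up_concordant",
    "up_nonconcordant",
    "down_concordant",
    "down_nonconcordant",
    "not_de",
)


@dataclass
class GeneConcordance:
    gene_id: str
    expr_log2fc: float
    de_direction: str  # "up", "down", "none"
    n_assigned_peaks: int
    n_diff_concordant: int
    n_diff_discordant: int
    group: str = "not_de"

    @property
    def proportion_concordant(self) -> float:
        if self.n_assigned_peaks == 0:
            return 0.0
        return self.n_diff_concordant / self.n_assigned_peaks

    @property
    def is_de(self) -> bool:
        return self.de_direction != "none"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_points: int
    seed: int


def _diff_directions(
    diff_peaks: DiffPeakSet | Mapping[str, str], pair: tuple[str, str] | None
) -> dict[str, str]:
    if isinstance(diff_peaks, DiffPeakSet):
        if pair is None:
            if len(diff_peaks.tables) != 1:
                raise ValueError("multiple condition pairs present; specify one")
            pair = next(iter(diff_peaks.tables))
        return diff_peaks.tables[pair]["direction"].to_dict()
    return dict(diff_peaks)


def gene_concordance(
    expr_changes: Sequence[ExpressionChange],
    diff_peaks: DiffPeakSet | Mapping[str, str],
    assignment: PeakGeneAssignment,
    pair: tuple[str, str] | None = None,
) -> list[GeneConcordance]:
    """Count concordant/discordant differential peaks for every gene.

    For genes that are not DE the comparison direction is the sign of their
    expression log2FC (>= 0 reads as up), so the proportion statistic is
    defined genome-wide, not only for DE genes.
    """
    directions = _diff_directions(diff_peaks, pair)
    gene_peaks = assignment.gene_to_peaks()
    out = []
    missing = 0
    for ch in expr_changes:
        peaks = gene_peaks.get(ch.gene_id, [])
        if not peaks:
            missing += 1
        expr_dir = ch.direction if ch.is_de else ("up" if ch.log2fc >= 0 else "down")
        n_conc = sum(1 for p in peaks if directions.get(p) == expr_dir)
        n_disc = sum(
            1 for p in peaks if p in directions and directions[p] != expr_dir
        )
        out.append(
            GeneConcordance(
                gene_id=ch.gene_id,
                expr_log2fc=ch.log2fc,
                de_direction=ch.direction if ch.is_de else "none",
                n_assigned_peaks=len(peaks),
                n_diff_concordant=n_conc,
                n_diff_discordant=n_disc,
            )
        )
    if missing:
        warnings.warn(
            f"{missing} genes had no assigned peaks (proportion set to 0)",
            stacklevel=2,
        )
    return classify_groups(out)


def classify_groups(concordances: Sequence[GeneConcordance]) -> list[GeneConcordance]:
    """Label each gene's group in place and return the list.

    DE genes with at least one concordant differential peak are
    {up,down}_concordant; DE genes with none are {up,down}_nonconcordant;
    everything else is not_de. Discordant peaks never disqualify a gene.
    """
    for c in concordances:
        if not c.is_de:
            c.group = "not_de"
        elif c.n_diff_concordant >= 1:
            c.group = f"{c.de_direction}_concordant"
        else:
            c.group = f"{c.de_direction}_nonconcordant"
    return list(concordances)


def concordance_frame(concordances: Sequence[GeneConcordance]) -> pd.DataFrame:
    """Plot-ready table: expression change vs concordant proportion per gene."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in concordances],
            "expr_log2fc": [c.expr_log2fc for c in concordances],
            "de_direction": [c.de_direction for c in concordances],
            "n_assigned_peaks": [c.n_assigned_peaks for c in concordances],
            "n_diff_concordant": [c.n_diff_concordant for c in concordances],
            "n_diff_discordant": [c.n_diff_discordant for c in concordances],
            "proportion_concordant": [c.proportion_concordant for c in concordances],
            "group": [c.group for c in concordances],
        }
    ).set_index("gene_id")


def collapse_gene_accessibility(
    peak_log2fc: Mapping[str, float],
    assignment: PeakGeneAssignment,
    mode: str = "median",
) -> pd.Series:
    """One accessibility change per gene from its assigned peaks' log2FCs.

    median: plain median (mean of the central pair for even counts).
    max: the signed value of largest absolute magnitude; on an exact
    magnitude tie the positive value wins. Genes with no assigned peak
    carrying a log2FC are excluded.
    """
    if mode not in ("median", "max"):
        raise ValueError(f"mode must be 'median' or 'max', got {mode!r}")
    values: dict[str, float] = {}
    skipped = 0
    for gene, peaks in assignment.gene_to_peaks().items():
        fcs = np.array([peak_log2fc[p] for p in peaks if p in peak_log2fc])
        if fcs.size == 0:
            skipped += 1
            continue
        if mode == "median":
            values[gene] = float(np.median(fcs))
        else:
            best = np.max(np.abs(fcs))
            values[gene] = float(best if best in fcs else -best)
    if skipped:
        warnings.warn(f"{skipped} genes had no peaks with a log2FC", stacklevel=2)
    return pd.Series(values, name=f"{mode}_log2fc").sort_index()


def pearson_bootstrap(
    x,
    y,
    n_boot: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson r with a percentile bootstrap 95% CI over paired resamples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    n = x.size
    boots = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        m = n_boot - filled
        idx = rng.integers(0, n, size=(m, n))
        bx, by = x[idx], y[idx]
        sx = bx.std(axis=1)
        sy = by.std(axis=1)
        ok = (sx > 0) & (sy > 0)  # degenerate resamples are redrawn
        bx, by = bx[ok], by[ok]
        if bx.shape[0]:
            cx = bx - bx.mean(axis=1, keepdims=True)
            cy = by - by.mean(axis=1, keepdims=True)
            rb = (cx * cy).sum(axis=1) / (
                np.sqrt((cx**2).sum(axis=1)) * np.sqrt((cy**2).sum(axis=1))
            )
            boots[filled : filled + rb.size] = rb
            filled += rb.size
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(r, float(lo), float(hi), n_boot, n, seed)


def ks_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test (asymptotic p-value)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def fisher_overlap(
    de_genes: set[str], diff_peak_genes: set[str], universe: set[str]
) -> tuple[np.ndarray, float]:
    """Fisher's exact test on DE status vs having >= 1 differential peak.

    Rows: DE / not DE; columns: has / lacks a differential assigned peak.
    Two-sided p sums hypergeometric tables at most as probable as observed.
    """
    if not universe:
        raise ValueError("empty universe")
    if not de_genes <= universe or not diff_peak_genes <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    a = len(de_genes & diff_peak_genes)
    b = len(de_genes - diff_peak_genes)
    c = len(diff_peak_genes - de_genes)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return table, p


def select_top_genes(
    scores: Mapping[str, float],
    k: int = 100,
    mode: str = "by_abs_log2fc",
) -> list[str]:
    """Deterministic top-k gene selection.

    by_abs_log2fc ranks by |score| (most differential), by_expression by the
    score itself (most highly expressed); ties break lexicographically on
    gene_id, and the returned list is sorted by gene_id.
    """
    if mode not in ("by_abs_log2fc", "by_expression_in_condition"):
        raise ValueError(f"unknown mode {mode!r}")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds pool of {len(scores)} genes")
    key = (lambda g: (-abs(scores[g]), g)) if mode == "by_abs_log2fc" else (
        lambda g: (-scores[g], g)
    )
    return sorted(sorted(scores, key=key)[:k])
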