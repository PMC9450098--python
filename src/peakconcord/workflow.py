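"""End-to-end convenience pipeline over a synthetic or parsed dataset.

Wires the stages together with the default study design: control-control
pairs among the ethanol groups calibrate the FDR grid, each dose is
compared against the first control group, differential-expression labels
come from the chosen DE route, and concordance is evaluated for the
top-dose comparison under the nearest-TSS assignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assignment import PeakGeneAssignment, assign_peaks
from .concordance import (
    GeneConcordance,
    collapse_gene_accessibility,
    gene_concordance,
    pearson_bootstrap,
)
from .diffpeaks import DiffPeakSet, ThresholdGrid, call_differential_peaks
from .expression import ExpressionChange, call_de_genes
from .simulate import SyntheticDataset
from .types import CountMatrix

__all__ = ["ConcordanceResult", "run_concordance_analysis"]


@dataclass
class ConcordanceResult:
    diff_peaks: DiffPeakSet
    grid: ThresholdGrid
    normalized: CountMatrix
    assignment: PeakGeneAssignment
    expr_changes: list[ExpressionChange]
    concordances: list[GeneConcordance]
    pair: tuple[str, str]

    def de_group_fractions(self) -> pd.Series:
        """Fraction of DE genes per concordance group."""
        de = [c for c in self.concordances if c.is_de]
        if not de:
            return pd.Series(dtype=float)
        counts = pd.Series([c.group for c in de]).value_counts()
        return counts / len(de)

    def frac_concordant_of_de(self) -> float:
        de = [c for c in self.concordances if c.is_de]
        if not de:
            return float("nan")
        return sum(c.group.endswith("_concordant") for c in de) / len(de)

    def median_collapse_pearson(
        self, mode: str = "median", n_boot: int = 1000, seed: int = 0
    ):
        """Pearson r between per-gene collapsed accessibility change and
        expression log2FC, over genes with at least one assigned peak."""
        comp = next(
            c for c in self.grid.experimental_pairs
            if (c.cond_a, c.cond_b) == self.pair
        )
        peak_log2fc = dict(zip(comp.peak_ids, comp.log2fc))
        collapsed = collapse_gene_accessibility(peak_log2fc, self.assignment, mode)
        expr = pd.Series(
            {c.gene_id: c.expr_log2fc for c in self.concordances}
        )
        common = collapsed.index.intersection(expr.index)
        return pearson_bootstrap(
            collapsed[common].to_numpy(), expr[common].to_numpy(),
            n_boot=n_boot, seed=seed,
        )


def run_concordance_analysis(
    dataset: SyntheticDataset,
    fdr_cutoff: float = 0.0025,
    de_mode: str = "internal_test",
    lfc_threshold: float = 0.5,
    q_threshold: float = 0.05,
    grid: ThresholdGrid | None = None,
) -> ConcordanceResult:
    controls = dataset.control_conditions
    doses = dataset.experimental_conditions
    control_pairs = list(itertools.combinations(controls, 2))
    experimental_pairs = [(controls[0], d) for d in doses]
    diff, grid, normalized = call_differential_peaks(
        dataset.atac, control_pairs, experimental_pairs,
        fdr_cutoff=fdr_cutoff, grid=grid,
    )
    assignment = assign_peaks(dataset.peaks, dataset.genes, method="nearest")
    pair = (controls[0], doses[-1])
    expr_changes = call_de_genes(
        dataset.expression, cond_a=pair[0], cond_b=pair[1],
        lfc_threshold=lfc_threshold, q_threshold=q_threshold, mode=de_mode,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # genes with zero peaks are expected
        concordances = gene_concordance(expr_changes, diff, assignment, pair=pair)
    return ConcordanceResult(
        diff_peaks=diff,
        grid=grid,
        normalized=normalized,
        assignment=assignment,
        expr_changes=expr_changes,
        concordances=concordances,
        pair=pair,
    )
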