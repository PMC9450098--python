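"""Control-calibrated empirical-FDR differential-accessibility caller.

The caller scans a grid of (minimum fold change, minimum normalized count)
thresholds. In each grid cell the number of peaks passing in
control-vs-control comparisons estimates the false-positive count expected
under the null, giving a per-cell estimated FDR:

    est_FDR = (n_conditions x est. false positives per condition)
              / (total passing peaks over experimental comparisons)

Differential peaks are then pooled from every cell whose estimated FDR
falls below the cutoff (default 0.25%).

Per-cell passing counts are computed with a 2D histogram plus reverse
cumulative sums (a survival table over grid cells), and the pooled union
with a prefix-OR over qualifying cells — both O(n_peaks + n_cells) per
comparison. Monotonicity of passing sets under threshold increase is exact
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .types import CountMatrix

__all__ = [
    "NormalizationFactors",
    "PairComparison",
    "ThresholdGrid",
    "DiffPeakSet",
    "normalize_counts",
    "peak_fold_change",
    "build_threshold_grid",
    "estimate_grid_fdr",
    "pool_differential_peaks",
    "call_differential_peaks",
]

DEFAULT_FDR_CUTOFF = 0.0025


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample depth factors: total in-peak reads / mean total over samples."""

    sample_ids: tuple[str, ...]
    factors: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors, index=list(self.sample_ids), name="factor")


def normalize_counts(raw: CountMatrix) -> tuple[CountMatrix, NormalizationFactors]:
    """Depth-normalize so every sample has the same total in-peak signal.

    factor_s = total_s / mean(totals); normalized = raw / factor_s.
    """
    totals = raw.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {raw.samples[zero[0]].sample_id!r} has zero total in-peak count"
        )
    factors = totals / totals.mean()
    normalized = raw.with_values(raw.values / factors, units="normalized_fragments")
    return normalized, NormalizationFactors(tuple(raw.sample_ids), factors)


@dataclass
class PairComparison:
    """Per-peak statistics for one condition-vs-condition comparison.

    ``direction`` is +1 where cond_b (the experimental side) has the larger
    mean, else -1. ``max_mean`` is the larger of the two replicate means
    before pseudocount — the quantity the grid's count axis thresholds.
    """

    cond_a: str
    cond_b: str
    peak_ids: list[str]
    fold_change: np.ndarray
    log2fc: np.ndarray
    direction: np.ndarray
    max_mean: np.ndarray

    @property
    def label(self) -> str:
        return f"{self.cond_a}_vs_{self.cond_b}"


def peak_fold_change(
    normalized: CountMatrix,
    cond_a: str,
    cond_b: str,
    pseudocount: float = 1.0,
) -> PairComparison:
    """Fold change, direction and max condition mean per peak for one pair.

    The pseudocount enters the fold-change ratio only; ``max_mean`` stays on
    the raw normalized scale so the grid's count axis is unaffected.
    """
    m_a = normalized.condition_mean(cond_a)
    m_b = normalized.condition_mean(cond_b)
    pa, pb = m_a + pseudocount, m_b + pseudocount
    if np.any(pa <= 0) or np.any(pb <= 0):
        raise ValueError("zero mean with zero pseudocount; set pseudocount > 0")
    hi, lo = np.maximum(pa, pb), np.minimum(pa, pb)
    return PairComparison(
        cond_a=cond_a,
        cond_b=cond_b,
        peak_ids=list(normalized.row_ids),
        fold_change=hi / lo,
        log2fc=np.log2(pb / pa),
        direction=np.where(m_b > m_a, 1, -1).astype(np.int8),
        max_mean=np.maximum(m_a, m_b),
    )


def _exponential_steps(lo: float, hi: float, n: int) -> np.ndarray:
    steps = lo * (hi / lo) ** (np.arange(n) / (n - 1))
    steps[0], steps[-1] = lo, hi  # pin endpoints against round-off
    return steps


@dataclass
class ThresholdGrid:
    """The (fold-change x min-count) threshold grid with per-cell FDR estimates.

    ``est_fps``, ``n_experimental`` and ``est_fdr`` are filled by
    :func:`estimate_grid_fdr`; cells whose experimental comparisons pass no
    peak carry an +inf FDR sentinel and can never qualify for pooling.
    """

    fc_steps: np.ndarray
    ct_steps: np.ndarray
    est_fps: np.ndarray | None = None
    n_experimental: np.ndarray | None = None
    est_fdr: np.ndarray | None = None
    control_pairs: list[PairComparison] = field(default_factory=list)
    experimental_pairs: list[PairComparison] = field(default_factory=list)
    n_conditions: int | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.fc_steps), len(self.ct_steps)

    def cell_indices(self, comp: PairComparison) -> tuple[np.ndarray, np.ndarray]:
        """Largest step index each peak reaches on each axis (-1: below all)."""
        fc_idx = np.searchsorted(self.fc_steps, comp.fold_change, side="right") - 1
        ct_idx = np.searchsorted(self.ct_steps, comp.max_mean, side="right") - 1
        return fc_idx, ct_idx

    def survival_counts(self, comp: PairComparison) -> np.ndarray:
        """count[i, j] = passing peaks at thresholds (fc_steps[i], ct_steps[j])."""
        n_fc, n_ct = self.shape
        fc_idx, ct_idx = self.cell_indices(comp)
        keep = (fc_idx >= 0) & (ct_idx >= 0)
        hist = np.zeros((n_fc, n_ct))
        np.add.at(hist, (fc_idx[keep], ct_idx[keep]), 1)
        surv = np.flip(np.flip(hist, 0).cumsum(0), 0)
        return np.flip(np.flip(surv, 1).cumsum(1), 1)

    def passing_mask(self, comp: PairComparison, i: int, j: int) -> np.ndarray:
        """Boolean per-peak mask for one cell (i, j)."""
        return (comp.fold_change >= self.fc_steps[i]) & (
            comp.max_mean >= self.ct_steps[j]
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format audit dump: one row per grid cell."""
        if self.est_fdr is None:
            raise ValueError("grid FDR not yet estimated")
        fc, ct = np.meshgrid(self.fc_steps, self.ct_steps, indexing="ij")
        return pd.DataFrame(
            {
                "fc_step": fc.ravel(),
                "ct_step": ct.ravel(),
                "est_fps": self.est_fps.ravel(),
                "n_experimental": self.n_experimental.ravel(),
                "est_fdr": self.est_fdr.ravel(),
            }
        )


def build_threshold_grid(
    fc_min: float = 1.5,
    fc_max: float = 10.0,
    ct_min: float = 30.0,
    ct_max: float = 237.0,
    n_fc: int = 50,
    n_ct: int = 50,
) -> ThresholdGrid:
    """Exponentially spaced thresholds: step_i = lo * (hi/lo)^(i/(n-1))."""
    if not (1 <= fc_min < fc_max):
        raise ValueError(f"need 1 <= fc_min < fc_max, got ({fc_min}, {fc_max})")
    if not (0 < ct_min < ct_max):
        raise ValueError(f"need 0 < ct_min < ct_max, got ({ct_min}, {ct_max})")
    if n_fc < 2 or n_ct < 2:
        raise ValueError("need >= 2 steps per axis")
    return ThresholdGrid(
        fc_steps=_exponential_steps(fc_min, fc_max, n_fc),
        ct_steps=_exponential_steps(ct_min, ct_max, n_ct),
    )


def estimate_grid_fdr(
    normalized: CountMatrix,
    control_pairs: Sequence[tuple[str, str]],
    experimental_pairs: Sequence[tuple[str, str]],
    grid: ThresholdGrid,
    pseudocount: float = 1.0,
    n_conditions: int | None = None,
    combine: str = "mean",
) -> ThresholdGrid:
    """Fill every grid cell with its control-calibrated estimated FDR.

    Control pairs (control-vs-control comparisons, where any passing peak is
    by construction a false positive) give the expected false-positive count
    per condition; ``n_conditions`` defaults to the number of experimental
    pairs. ``combine`` chooses mean (default) or sum over control pairs.
    """
    if not control_pairs or not experimental_pairs:
        raise ValueError("need at least one control pair and one experimental pair")
    if combine not in ("mean", "sum"):
        raise ValueError(f"combine must be 'mean' or 'sum', got {combine!r}")
    grid.control_pairs = [
        peak_fold_change(normalized, a, b, pseudocount) for a, b in control_pairs
    ]
    grid.experimental_pairs = [
        peak_fold_change(normalized, a, b, pseudocount) for a, b in experimental_pairs
    ]
    grid.n_conditions = (
        len(experimental_pairs) if n_conditions is None else int(n_conditions)
    )
    control_counts = np.stack([grid.survival_counts(c) for c in grid.control_pairs])
    exp_counts = np.stack([grid.survival_counts(c) for c in grid.experimental_pairs])
    grid.est_fps = (
        control_counts.mean(axis=0) if combine == "mean" else control_counts.sum(axis=0)
    )
    grid.n_experimental = exp_counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = grid.n_conditions * grid.est_fps / grid.n_experimental
    fdr[grid.n_experimental == 0] = np.inf
    grid.est_fdr = fdr
    return grid


@dataclass
class DiffPeakSet:
    """Pooled differential peaks per experimental condition pair.

    Each table is indexed by peak_id with columns direction ("up"/"down"),
    log2fc, and max_mean.
    """

    tables: dict[tuple[str, str], pd.DataFrame]
    fdr_cutoff: float

    def peaks(self, pair: tuple[str, str]) -> pd.DataFrame:
        return self.tables[pair]

    def peak_ids(self, pair: tuple[str, str]) -> set[str]:
        return set(self.tables[pair].index)

    def union_peak_ids(self) -> set[str]:
        out: set[str] = set()
        for df in self.tables.values():
            out |= set(df.index)
        return out

    def n_peaks(self, pair: tuple[str, str] | None = None) -> int:
        if pair is not None:
            return len(self.tables[pair])
        return len(self.union_peak_ids())


def pool_differential_peaks(
    grid: ThresholdGrid, fdr_cutoff: float = DEFAULT_FDR_CUTOFF
) -> DiffPeakSet:
    """Union of passing peaks over all cells with est_fdr strictly below cutoff.

    A peak passing cell (i, j) also passes every cell with lower thresholds,
    so membership reduces to: does any qualifying cell lie at-or-below the
    peak's own (fold change, count) cell? That is a prefix-OR lookup.
    """
    if grid.est_fdr is None:
        raise ValueError("grid FDR not yet estimated; run estimate_grid_fdr first")
    qualifying = grid.est_fdr < fdr_cutoff
    dominated = np.maximum.accumulate(np.maximum.accumulate(qualifying, axis=0), axis=1)
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for comp in grid.experimental_pairs:
        fc_idx, ct_idx = grid.cell_indices(comp)
        in_grid = (fc_idx >= 0) & (ct_idx >= 0)
        pooled = np.zeros(len(comp.peak_ids), dtype=bool)
        pooled[in_grid] = dominated[fc_idx[in_grid], ct_idx[in_grid]]
        idx = np.flatnonzero(pooled)
        tables[(comp.cond_a, comp.cond_b)] = pd.DataFrame(
            {
                "direction": np.where(comp.direction[idx] > 0, "up", "down"),
                "log2fc": comp.log2fc[idx],
                "max_mean": comp.max_mean[idx],
            },
            index=pd.Index([comp.peak_ids[i] for i in idx], name="peak_id"),
        )
    return DiffPeakSet(tables=tables, fdr_cutoff=fdr_cutoff)


def call_differential_peaks(
    raw: CountMatrix,
    control_pairs: Sequence[tuple[str, str]],
    experimental_pairs: Sequence[tuple[str, str]],
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    grid: ThresholdGrid | None = None,
    pseudocount: float = 1.0,
    n_conditions: int | None = None,
    combine: str = "mean",
) -> tuple[DiffPeakSet, ThresholdGrid, CountMatrix]:
    """End-to-end caller: normalize, grid, estimate FDR, pool.

    Returns the pooled peak set, the filled grid (for audit dumps) and the
    depth-normalized matrix.
    """
    normalized, _ = normalize_counts(raw)
    if grid is None:
        grid = build_threshold_grid()
    grid = estimate_grid_fdr(
        normalized,
        control_pairs,
        experimental_pairs,
        grid,
        pseudocount=pseudocount,
        n_conditions=n_conditions,
        combine=combine,
    )
    return pool_differential_peaks(grid, fdr_cutoff), grid, normalized
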