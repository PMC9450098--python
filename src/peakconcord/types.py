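"""Shared domain types for the concordance pipeline.

All genomic coordinates are 0-based, half-open (BED native). Any 1-based
source must be converted at the boundary; nothing downstream re-converts.
Chromosome names are compared by exact string match — no "chr" prefix
normalization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SampleInfo",
    "CountMatrix",
    "TadDomain",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval; a summit is an interval of width 1."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Deterministic reference point: floor of the interval midpoint."""
        return (self.start + self.end) // 2

    @property
    def label(self) -> str:
        return self.name if self.name is not None else f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its canonical transcription start site.

    The TSS is carried explicitly rather than derived from strand + span,
    which sidesteps the plus/minus-strand end ambiguity entirely.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.gene_start <= self.tss <= self.gene_end):
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} outside body "
                f"[{self.gene_start}, {self.gene_end}]"
            )


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample: condition label, replicate index, control role."""

    sample_id: str
    condition: str
    replicate: int
    role: str  # "control" or "experimental"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.role not in ("control", "experimental"):
            raise ValueError(f"role must be control/experimental, got {self.role!r}")


@dataclass(frozen=True)
class TadDomain:
    """A topologically associating domain used to constrain peak-gene linking."""

    chrom: str
    start: int
    end: int
    tad_id: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid TAD span [{self.start}, {self.end})")

    def contains(self, chrom: str, pos: int) -> bool:
        """Strict interior membership on the half-open span."""
        return chrom == self.chrom and self.start <= pos < self.end


class CountMatrix:
    """Rows (peaks or genes) x samples matrix of nonnegative values.

    ``units`` declares the scale ("fragments", "normalized_fragments",
    "TPM", "quantile_normalized", ...). Columns follow sample-sheet order.
    """

    def __init__(
        self,
        row_ids: Sequence[str],
        samples: Sequence[SampleInfo],
        values,
        units: str = "fragments",
    ) -> None:
        values = np.asarray(values, dtype=float)
        row_ids = list(row_ids)
        samples = list(samples)
        if values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if values.shape != (len(row_ids), len(samples)):
            raise ValueError(
                f"shape {values.shape} inconsistent with {len(row_ids)} rows x "
                f"{len(samples)} samples"
            )
        if len(set(row_ids)) != len(row_ids):
            raise ValueError("row_ids must be unique")
        keys = [(s.condition, s.replicate) for s in samples]
        if len(set(keys)) != len(keys):
            raise ValueError("(condition, replicate) pairs must be unique")
        if np.any(values < 0):
            raise ValueError("count matrix must be nonnegative")
        self.row_ids = row_ids
        self.samples = samples
        self.values = values
        self.units = units
        self._row_index = {r: i for i, r in enumerate(row_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    def condition_columns(self, condition: str) -> np.ndarray:
        cols = np.array(
            [i for i, s in enumerate(self.samples) if s.condition == condition],
            dtype=int,
        )
        if cols.size == 0:
            raise KeyError(f"unknown condition {condition!r}")
        return cols

    def condition_mean(self, condition: str) -> np.ndarray:
        """Replicate mean per row for one condition."""
        return self.values[:, self.condition_columns(condition)].mean(axis=1)

    def row_indexer(self, row_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._row_index[r] for r in row_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown row id {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.sample_ids)

    def with_values(self, values, units: str | None = None) -> "CountMatrix":
        return CountMatrix(self.row_ids, self.samples, values, units or self.units)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CountMatrix({self.shape[0]} rows x {self.shape[1]} samples, "
            f"units={self.units!r})"
        )
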