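"""Consensus peak atlas construction from per-replicate summit calls.

Two steps mirror the standard workflow: (1) per condition, keep only summit
clusters supported by a majority of replicates; (2) concatenate the
condition-level summits/peaks and merge anything within a fixed gap into
single non-overlapping atlas peaks, which become the row universe for all
downstream count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .types import GenomicInterval

__all__ = [
    "SummitCluster",
    "majority_rule_summits",
    "merge_intervals",
    "build_consensus_atlas",
]


@dataclass
class SummitCluster:
    chrom: str
    members: list[tuple[int, int]]  # (position, replicate index)

    @property
    def replicate_support(self) -> int:
        return len({rep for _, rep in self.members})

    @property
    def representative(self) -> int:
        """Lower median for odd member counts; floor of the central-pair mean
        for even counts. Deterministic and insensitive to input order."""
        pos = sorted(p for p, _ in self.members)
        n = len(pos)
        if n % 2 == 1:
            return pos[n // 2]
        return (pos[n // 2 - 1] + pos[n // 2]) // 2


def _cluster_positions(
    points: list[tuple[str, int, int]], link_distance: int
) -> list[SummitCluster]:
    """Single-linkage clustering of summit positions per chromosome.

    On a sorted axis, single linkage at distance d is exactly: break between
    consecutive points whose spacing exceeds d.
    """
    clusters: list[SummitCluster] = []
    points = sorted(points)
    current: SummitCluster | None = None
    for chrom, pos, rep in points:
        if (
            current is not None
            and chrom == current.chrom
            and pos - current.members[-1][0] <= link_distance
        ):
            current.members.append((pos, rep))
        else:
            current = SummitCluster(chrom, [(pos, rep)])
            clusters.append(current)
    return clusters


def majority_rule_summits(
    replicate_summit_sets: Sequence[Sequence[GenomicInterval]],
    min_replicates: int = 2,
    link_distance: int = 50,
) -> list[GenomicInterval]:
    """Retain only summits reproduced in at least ``min_replicates`` replicates.

    Summits from all replicates are single-linkage clustered at
    ``link_distance``; each sufficiently supported cluster emits one width-1
    interval at its representative position, sorted by (chrom, position).
    """
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    if min_replicates > len(replicate_summit_sets):
        raise ValueError(
            f"min_replicates={min_replicates} exceeds the "
            f"{len(replicate_summit_sets)} replicate sets provided"
        )
    points = [
        (s.chrom, s.start, rep)
        for rep, summits in enumerate(replicate_summit_sets)
        for s in summits
    ]
    kept = []
    for cluster in _cluster_positions(points, link_distance):
        if cluster.replicate_support >= min_replicates:
            p = cluster.representative
            kept.append(GenomicInterval(cluster.chrom, p, p + 1))
    return sorted(kept)


def merge_intervals(
    intervals: Sequence[GenomicInterval], max_gap: int = 50
) -> list[GenomicInterval]:
    """Coalesce intervals whose gap (next.start - prev.end) is <= ``max_gap``.

    Matches ``bedtools merge -d`` semantics: merging is transitive, touching
    or overlapping intervals (gap <= 0) always merge, and the output is
    sorted and non-overlapping with pairwise gaps > ``max_gap``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not intervals:
        return []
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
        if merged and iv.chrom == merged[-1].chrom and iv.start - merged[-1].end <= max_gap:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def build_consensus_atlas(
    condition_peak_sets: Sequence[Sequence[GenomicInterval]],
    max_gap: int = 50,
) -> list[GenomicInterval]:
    """Merge all condition-level peak sets into one non-overlapping atlas.

    Output peaks receive stable ids ``peak_000001...`` in coordinate order;
    the atlas is the row universe for every downstream count matrix.
    """
    if not condition_peak_sets:
        raise ValueError("at least one condition peak set is required")
    pooled = [iv for s in condition_peak_sets for iv in s]
    if not pooled:
        raise ValueError("union of condition peak sets is empty; nothing to analyze")
    merged = merge_intervals(pooled, max_gap=max_gap)
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, f"peak_{i + 1:06d}")
        for i, iv in enumerate(merged)
    ]
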